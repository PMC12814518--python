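"""Stochastic serial-passage simulator for phage-assisted selection.

The generative model mirrors a phage-assisted noncontinuous selection
(PANCS) campaign: a pool of phage, each carrying one library variant,
goes through discrete passages.  Each passage (i) infects a culture with
a fixed number of phage (the bottleneck, default 1e5) drawn multinomially
from the current pool composition, (ii) lets every genome produce
offspring in proportion to its propagation factor rho(v) — the expected
per-passage offspring multiplier, proportional to the measured fold
propagation of the variant — and (iii) renormalizes.  Each passage's pool
(and the input pool) is sampled by sequencing: a multinomial draw of
``read_depth`` reads.

Three features of the real campaign are modeled explicitly:

* **Chaperonin (GroELS) buffering** — overexpressing GroELS partially
  rescues assembly-defective variants.  It is modeled as a factor
  ``groels_buffer`` in (0, 1] that multiplies every variant's log10
  fitness deficit relative to wild type: 1 means no rescue, 0.5 halves
  every deficit.
* **Hitchhiker mutations** — rare spontaneous second-site mutations
  outside the mutagenized window that boost a carrier's propagation and
  inflate its apparent enrichment.  Carriers are tracked as a parallel
  sub-pool per variant with ``rho * hitchhiker_boost``; acquisition is
  per-genome per-passage with probability ``hitchhiker_rate`` (default
  0 = off).
* **Deterministic limit** — ``bottleneck=None`` replaces the multinomial
  infection draw by its expectation, giving the closed-form dynamics
  odds(t) = odds(0) * (rho1/rho2)**t used by analytic tests.

Everything is reproducible: one ``numpy`` generator seeded from
``params.seed`` drives all draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readcount import CountTable
from .variant_space import (
    AMINO_ACIDS,
    PROTEIN_ALPHABET,
    STOP,
    LibraryDesign,
    enumerate_protein_variants,
    reverse_translate,
)

__all__ = [
    "SelectionSimParams",
    "GroundTruth",
    "PassagePool",
    "SimulationError",
    "default_ground_truth",
    "default_input_abundance",
    "run_selection",
    "simulate_competition",
    "emit_fastq",
]

#: Per-position log10 penalty assigned to a stop codon: effectively lethal
#: (rho <= 1e-10 * rho_wt per stop at full stringency, still <= 1e-5 under
#: the strongest buffering considered).
STOP_PENALTY = 10.0


class SimulationError(RuntimeError):
    """Raised when the simulated pool degenerates (e.g. all-zero frequencies)."""


@dataclass
class GroundTruth:
    """True per-variant propagation fitness underlying a simulation.

    ``penalties`` is a 21-amino-acid x n_positions table of log10
    propagation deficits; a variant's rho is
    ``rho_wt * 10 ** (-buffer * sum_of_penalties)``.  Wild-type residues
    carry zero penalty by construction, so the wild-type protein anchors
    the scale at ``rho_wt``.
    """

    design: LibraryDesign
    penalties: pd.DataFrame  # index: PROTEIN_ALPHABET, columns: 0..n_positions-1
    rho_wt: float = 1000.0
    #: A variant is called assembly-competent when its total log10 deficit
    #: is below this bound (within tenfold of wild-type propagation).
    competent_deficit_bound: float = 1.0

    def total_penalty(self, protein_seq: str) -> float:
        return float(
            sum(self.penalties.at[aa, i] for i, aa in enumerate(protein_seq))
        )

    def rho(self, protein_seq: str, groels_buffer: float = 1.0) -> float:
        """Propagation factor under the given chaperonin buffering."""
        return self.rho_wt * 10.0 ** (-groels_buffer * self.total_penalty(protein_seq))

    def rho_map(self, groels_buffer: float = 1.0) -> dict[str, float]:
        """rho for every variant in the full saturation space."""
        return {
            v.protein_seq: self.rho(v.protein_seq, groels_buffer)
            for v in enumerate_protein_variants(self.design)
        }

    def is_competent(self, protein_seq: str, groels_buffer: float = 1.0) -> bool:
        return (
            groels_buffer * self.total_penalty(protein_seq)
            < self.competent_deficit_bound
        )


@dataclass
class SelectionSimParams:
    """Full parameterization of one simulated selection arm.

    ``propagation_factor`` maps protein variant -> rho under the
    unbuffered (-GroELS) condition; ``groels_buffer`` rescales log
    deficits relative to the wild-type variant's rho (1 = no rescue).
    ``bottleneck=None`` selects the deterministic expectation instead of
    multinomial infection sampling.
    """

    design: LibraryDesign
    propagation_factor: Mapping[str, float]
    input_abundance: Mapping[str, float]
    n_passages: int = 3
    bottleneck: int | None = 100_000
    read_depth: int = 450_000
    groels_buffer: float = 1.0
    hitchhiker_rate: float = 0.0
    hitchhiker_boost: float = 100.0
    seed: int = 0
    passage_labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1 (or None for deterministic)")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not 0.0 < self.groels_buffer <= 1.0:
            raise ValueError("groels_buffer must be in (0, 1]")
        if any(r <= 0 for r in self.propagation_factor.values()):
            raise ValueError("propagation factors must be > 0")
        if any(a < 0 for a in self.input_abundance.values()):
            raise ValueError("input abundances must be >= 0")
        if sum(self.input_abundance.values()) <= 0:
            raise ValueError("input abundances must sum to > 0")
        object.__setattr__(
            self,
            "passage_labels",
            ("input",) + tuple(f"P{i}" for i in range(1, self.n_passages + 1)),
        )

    def effective_rho(self) -> pd.Series:
        """rho per variant after applying chaperonin buffering.

        Buffering multiplies each variant's log10 deficit relative to the
        wild-type rho; variants fitter than wild type are left untouched
        (buffering rescues defects, it does not penalize improvements).
        """
        rho = pd.Series(self.propagation_factor, dtype=float)
        rho = rho.loc[sorted(rho.index)]
        if self.groels_buffer == 1.0:
            return rho
        wt = self.design.wildtype_protein
        rho_wt = float(rho.get(wt, rho.max()))
        deficit = np.log10(rho_wt) - np.log10(rho)
        buffered = np.where(deficit > 0, deficit * self.groels_buffer, deficit)
        return pd.Series(rho_wt * 10.0 ** (-buffered), index=rho.index)


@dataclass
class PassagePool:
    """Pool composition after one passage (index 0 = input)."""

    passage: int
    frequencies: pd.Series  # per variant, sums to 1
    titer: float  # total phage produced by the passage

    def __post_init__(self) -> None:
        total = float(self.frequencies.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimulationError(f"frequencies sum to {total}, not 1")


def default_ground_truth(
    design: LibraryDesign,
    seed: int = 0,
    rho_wt: float = 1000.0,
    neutral_fraction: float = 0.13,
    deleterious_range: tuple[float, float] = (0.25, 1.3),
) -> GroundTruth:
    """Draw a per-(amino acid, position) penalty table for a library.

    Penalties follow a two-component mixture shaped like the observed
    library: a small fraction (default 13%) of substitutions are
    near-neutral (log10 deficit uniform on [0, 0.2]) and the rest are
    deleterious (uniform on ``deleterious_range``); stop codons get a
    lethal penalty per position.  Wild-type residues have zero penalty,
    so the wild-type protein sits exactly at ``rho_wt``.  With the
    default three-passage selection these choices put roughly 80% of
    analyzed variants in the depleted class and a few percent in the
    positive class.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = deleterious_range
    table = pd.DataFrame(
        0.0, index=list(PROTEIN_ALPHABET), columns=range(design.n_positions)
    )
    for pos in range(design.n_positions):
        wt_aa = design.wildtype_protein[pos]
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            if rng.random() < neutral_fraction:
                table.at[aa, pos] = rng.uniform(0.0, 0.2)
            else:
                table.at[aa, pos] = rng.uniform(lo, hi)
        table.at[STOP, pos] = STOP_PENALTY
    return GroundTruth(design=design, penalties=table, rho_wt=rho_wt)


def default_input_abundance(
    design: LibraryDesign,
    seed: int = 0,
    sigma: float = 1.15,
    variants: Sequence[str] | None = None,
) -> dict[str, float]:
    """Log-normal pre-selection pool composition.

    Abundances are log-normal around uniform (natural-log sigma default
    1.15), emulating the uneven representation of a cloned saturation
    library: at the default read depth a realistic minority of variants
    falls below the 10-read detection threshold.
    """
    if variants is None:
        variants = sorted(v.protein_seq for v in enumerate_protein_variants(design))
    rng = np.random.default_rng(seed)
    return {v: float(x) for v, x in zip(variants, rng.lognormal(0.0, sigma, len(variants)))}


def _sample_pool(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    return rng.multinomial(n, freqs).astype(float)


def run_selection(
    params: SelectionSimParams,
) -> tuple[list[PassagePool], CountTable, pd.DataFrame]:
    """Simulate one selection arm.

    Returns the per-passage pools, the sequencing :class:`CountTable`
    (one multinomial draw of ``read_depth`` reads per passage, including
    the input pool), and the emission table — the exact read counts drawn,
    as a DataFrame — which serves as the oracle for FASTQ round-trip
    tests.
    """
    rng = np.random.default_rng(params.seed)
    rho = params.effective_rho()
    variants = list(rho.index)
    abundance = pd.Series(params.input_abundance, dtype=float).reindex(variants).fillna(0.0)
    if abundance.sum() <= 0:
        raise SimulationError("input pool is empty")
    n = len(variants)

    # state: plain carriers and hitchhiker carriers per variant
    f_plain = abundance.to_numpy() / abundance.sum()
    f_hitch = np.zeros(n)
    rho_plain = rho.to_numpy()
    rho_hitch = rho_plain * params.hitchhiker_boost

    pools = [PassagePool(0, pd.Series(f_plain + f_hitch, index=variants), titer=float("nan"))]
    for p in range(1, params.n_passages + 1):
        freqs = np.concatenate([f_plain, f_hitch])
        total = freqs.sum()
        if total <= 0:
            raise SimulationError(f"pool degenerate before passage {p}")
        freqs = freqs / total
        if params.bottleneck is None:
            drawn = freqs
            scale = 1.0
        else:
            drawn = _sample_pool(rng, params.bottleneck, freqs)
            scale = float(params.bottleneck)
            if drawn.sum() <= 0:
                raise SimulationError(f"bottleneck draw empty at passage {p}")
        c_plain, c_hitch = drawn[:n].copy(), drawn[n:].copy()
        if params.hitchhiker_rate > 0:
            if params.bottleneck is None:
                moved = c_plain * params.hitchhiker_rate
            else:
                moved = rng.binomial(c_plain.astype(int), params.hitchhiker_rate).astype(float)
            c_plain -= moved
            c_hitch += moved
        w_plain = c_plain * rho_plain
        w_hitch = c_hitch * rho_hitch
        offspring = w_plain.sum() + w_hitch.sum()
        if offspring <= 0:
            raise SimulationError(f"no offspring at passage {p}")
        f_plain = w_plain / offspring
        f_hitch = w_hitch / offspring
        pools.append(
            PassagePool(p, pd.Series(f_plain + f_hitch, index=variants), titer=offspring * scale)
        )

    emission = {}
    for label, pool in zip(params.passage_labels, pools):
        emission[label] = _sample_pool(rng, params.read_depth, pool.frequencies.to_numpy()).astype(int)
    emission_df = pd.DataFrame(emission, index=variants)
    emission_df.index.name = "variant"
    table = CountTable(design=params.design, counts=emission_df.copy())
    return pools, table, emission_df


@dataclass
class CompetitionResult:
    """Outcome of a two-variant competition (Sanger-style majority calls)."""

    pools: list[PassagePool]
    majority_calls: list[str]  # per passage, including the input pool
    wt_label: str
    mutant_label: str

    @property
    def first_wt_majority(self) -> int | None:
        """First passage index at which the wild type is the majority call."""
        for i, call in enumerate(self.majority_calls):
            if call == self.wt_label:
                return i
        return None


def simulate_competition(
    wt_fraction: float,
    advantage: float,
    design: LibraryDesign | None = None,
    n_passages: int = 3,
    bottleneck: int | None = 100_000,
    seed: int = 0,
    mutant_protein: str | None = None,
) -> CompetitionResult:
    """Two-variant spike-in competition with per-passage majority calls.

    Models the benchmark where a wild-type variant, seeded at
    ``wt_fraction`` of the pool against an assembly-deficient mutant with
    a ``1/advantage`` propagation factor, takes over the pool within a
    few passages.  The majority call per passage (argmax frequency) is a
    surrogate for a Sanger chromatogram of the pool.
    """
    if not 0.0 < wt_fraction < 1.0:
        raise ValueError("wt_fraction must be in (0, 1)")
    if advantage <= 0:
        raise ValueError("advantage must be > 0")
    if design is None:
        design = LibraryDesign()
    wt = design.wildtype_protein
    if mutant_protein is None:
        alt = "A" if wt[0] != "A" else "G"
        mutant_protein = alt + wt[1:]
    params = SelectionSimParams(
        design=design,
        propagation_factor={wt: float(advantage), mutant_protein: 1.0},
        input_abundance={wt: wt_fraction, mutant_protein: 1.0 - wt_fraction},
        n_passages=n_passages,
        bottleneck=bottleneck,
        read_depth=1000,
        seed=seed,
    )
    pools, _table, _em = run_selection(params)
    # Sanger-style majority call per passage; a numerically tied pool keeps
    # the previous call (a chromatogram tie is not a new majority)
    calls: list[str] = []
    for pool in pools:
        ordered = pool.frequencies.sort_values(ascending=False)
        if len(ordered) > 1 and ordered.iloc[0] - ordered.iloc[1] <= 1e-9 and calls:
            calls.append(calls[-1])
        else:
            calls.append(str(ordered.index[0]))
    return CompetitionResult(
        pools=pools, majority_calls=calls, wt_label=wt, mutant_label=mutant_protein
    )


def emit_fastq(
    emission: pd.DataFrame,
    design: LibraryDesign,
    out_dir: str | Path,
    prefix: str = "passage",
) -> dict[str, Path]:
    """Write an emission table as one FASTQ file per passage.

    Each read is ``flank_up + canonical codon window + flank_down`` with
    uniform high quality; read counts per variant equal the emission
    table exactly, so counting the files must reproduce the table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    windows = {v: reverse_translate(v, design) for v in emission.index}
    for label in emission.columns:
        path = out_dir / f"{prefix}_{label}.fastq"
        with open(path, "w") as fh:
            i = 0
            for variant, count in emission[label].items():
                seq = design.flank_up + windows[variant] + design.flank_down
                qual = "I" * len(seq)
                for _ in range(int(count)):
                    fh.write(f"@sim_{label}_{i}\n{seq}\n+\n{qual}\n")
                    i += 1
        paths[label] = path
    return paths


def ground_truth_to_tsv(truth: GroundTruth, path: str | Path, groels_buffer: float = 1.0) -> None:
    """Write per-variant true rho and competence class as TSV."""
    rows = []
    for v in sorted(x.protein_seq for x in enumerate_protein_variants(truth.design)):
        rows.append(
            {
                "variant": v,
                "rho": truth.rho(v, groels_buffer),
                "log10_rho": math.log10(truth.rho(v, groels_buffer)),
                "assembly_competent": truth.is_competent(v, groels_buffer),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
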