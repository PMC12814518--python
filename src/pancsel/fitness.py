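"""Per-variant frequency trajectories, log-ratio fitness, and classification.

The fitness score of a variant is the base-10 log of the ratio of its
read fraction in the final selection passage to its read fraction in the
input pool:

    fitness = log10(f_final / f_input)

Zero means unchanged relative abundance; -1.0 is a tenfold drop.  A
variant with zero reads in the final passage is *depleted* — an explicit
class, not a -inf score (no pseudocounts are used).  The
assembly-outcome rule is: a variant is predicted to have lowered
assembly efficiency iff it is depleted or its fitness is -1.0 or lower
(the bound is inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .readcount import CountTable
from .variant_space import STOP

__all__ = [
    "LOWERED_ASSEMBLY_BOUND",
    "FitnessRecord",
    "SelectionSummary",
    "ArmComparison",
    "fractions",
    "fitness_score",
    "fitness_table",
    "classify",
    "compare_arms",
    "fold_propagation",
]

#: Fitness at or below this bound predicts lowered assembly efficiency
#: (together with complete depletion).  The bound is inclusive.
LOWERED_ASSEMBLY_BOUND = -1.0

CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"
CLASS_DEPLETED = "depleted"


@dataclass(frozen=True)
class FitnessRecord:
    """One variant's selection outcome."""

    variant: str
    f_input: float
    f_final: float
    trajectory: tuple[float, ...]
    fitness: float | None  # None when depleted
    outcome_class: str
    lowered_assembly_predicted: bool

    @property
    def contains_stop(self) -> bool:
        return STOP in self.variant


@dataclass(frozen=True)
class SelectionSummary:
    """Headline statistics of one selection arm."""

    n_analyzed: int
    n_depleted: int
    n_positive: int
    fraction_positive: float
    fraction_lowered_assembly: float


@dataclass
class ArmComparison:
    """Contrast between two selection arms over the same variant set."""

    summary_minus: SelectionSummary
    summary_plus: SelectionSummary
    positive_ratio: float  # fraction_positive(+) / fraction_positive(-)
    depleted_change: int  # n_depleted(+) - n_depleted(-)
    rescued: frozenset[str]  # depleted without the chaperonin, not with


def fractions(table: CountTable, passage: str) -> pd.Series:
    """Read fraction per retained variant in one passage; sums to 1."""
    if passage not in table.counts.columns:
        raise ValueError(f"passage {passage!r} not in table")
    col = table.counts[passage]
    total = int(col.sum())
    if total == 0:
        raise ValueError(f"passage {passage!r} has zero total reads")
    return col / total


def fitness_score(f_input: float, f_final: float) -> float | None:
    """log10(f_final / f_input); ``None`` (depleted) when f_final is 0."""
    if f_input <= 0:
        raise ValueError("f_input must be > 0 (apply the detection threshold first)")
    if f_final < 0:
        raise ValueError("f_final must be >= 0")
    if f_final == 0:
        return None
    return math.log10(f_final) - math.log10(f_input)


def fitness_table(
    table: CountTable,
    input_passage: str | None = None,
    final_passage: str | None = None,
    lowered_bound: float = LOWERED_ASSEMBLY_BOUND,
) -> pd.DataFrame:
    """Per-variant fitness records for one thresholded selection arm.

    Returns a DataFrame indexed by variant with the trajectory fractions
    (one ``f_<passage>`` column per passage), ``fitness`` (NaN when
    depleted), ``outcome_class`` and ``lowered_assembly_predicted``.
    The input passage defaults to the first column and the final passage
    to the last.
    """
    passages = table.passages
    if input_passage is None:
        input_passage = passages[0]
    if final_passage is None:
        final_passage = passages[-1]
    # a passage where every retained variant dropped out has undefined
    # fractions; treat it as all-zero (everything depleted) rather than a
    # failure so fully-purged arms are still classifiable
    def _frac(p: str) -> pd.Series:
        if int(table.counts[p].sum()) == 0:
            return pd.Series(0.0, index=table.counts.index)
        return fractions(table, p)

    frac = pd.DataFrame({f"f_{p}": _frac(p) for p in passages})
    f_in = frac[f"f_{input_passage}"]
    f_fin = frac[f"f_{final_passage}"]
    if (f_in <= 0).any():
        bad = f_in.index[f_in <= 0][0]
        raise ValueError(
            f"variant {bad!r} has zero input fraction; apply the detection threshold first"
        )
    depleted = table.counts[final_passage] == 0
    with np.errstate(divide="ignore"):
        fitness = np.where(depleted, np.nan, np.log10(f_fin) - np.log10(f_in))
    out = frac.copy()
    out["f_input"] = f_in
    out["f_final"] = f_fin
    out["fitness"] = fitness
    out["outcome_class"] = np.select(
        [depleted, fitness > 0], [CLASS_DEPLETED, CLASS_POSITIVE], CLASS_NEGATIVE
    )
    out["lowered_assembly_predicted"] = depleted | (fitness <= lowered_bound)
    out["contains_stop"] = [STOP in v for v in out.index]
    out.index.name = "variant"
    return out


def records(table: pd.DataFrame) -> list[FitnessRecord]:
    """Materialize a fitness DataFrame as :class:`FitnessRecord` objects."""
    traj_cols = [c for c in table.columns if c.startswith("f_") and c not in ("f_input", "f_final")]
    out = []
    for variant, row in table.iterrows():
        fit = None if math.isnan(row["fitness"]) else float(row["fitness"])
        out.append(
            FitnessRecord(
                variant=str(variant),
                f_input=float(row["f_input"]),
                f_final=float(row["f_final"]),
                trajectory=tuple(float(row[c]) for c in traj_cols),
                fitness=fit,
                outcome_class=str(row["outcome_class"]),
                lowered_assembly_predicted=bool(row["lowered_assembly_predicted"]),
            )
        )
    return out


def classify(table: pd.DataFrame) -> SelectionSummary:
    """Summarize an arm's fitness table into headline statistics."""
    if len(table) == 0:
        raise ValueError("empty record set")
    n = len(table)
    n_depleted = int((table["outcome_class"] == CLASS_DEPLETED).sum())
    n_positive = int((table["outcome_class"] == CLASS_POSITIVE).sum())
    n_lowered = int(table["lowered_assembly_predicted"].sum())
    return SelectionSummary(
        n_analyzed=n,
        n_depleted=n_depleted,
        n_positive=n_positive,
        fraction_positive=n_positive / n,
        fraction_lowered_assembly=n_lowered / n,
    )


def compare_arms(table_minus: pd.DataFrame, table_plus: pd.DataFrame) -> ArmComparison:
    """Contrast -chaperonin and +chaperonin arms variant-by-variant.

    Both tables must cover the same retained variant set.  ``rescued``
    is the set of variants depleted in the minus arm but not in the plus
    arm.
    """
    if set(table_minus.index) != set(table_plus.index):
        raise ValueError("arms were analyzed over different variant sets")
    s_minus = classify(table_minus)
    s_plus = classify(table_plus)
    dep_minus = set(table_minus.index[table_minus["outcome_class"] == CLASS_DEPLETED])
    dep_plus = set(table_plus.index[table_plus["outcome_class"] == CLASS_DEPLETED])
    ratio = (
        float("inf")
        if s_minus.fraction_positive == 0 and s_plus.fraction_positive > 0
        else (s_plus.fraction_positive / s_minus.fraction_positive if s_minus.fraction_positive else float("nan"))
    )
    return ArmComparison(
        summary_minus=s_minus,
        summary_plus=s_plus,
        positive_ratio=ratio,
        depleted_change=s_plus.n_depleted - s_minus.n_depleted,
        rescued=frozenset(dep_minus - dep_plus),
    )


def fold_propagation(output_titer: float, input_titer: float) -> float:
    """Phage produced per phage used to infect (output / input titer)."""
    if input_titer <= 0:
        raise ValueError("input_titer must be > 0")
    return output_titer / input_titer


def write_fitness_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Per-variant TSV: trajectory fractions, fitness, class, prediction."""
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_summary_tsv(summary: SelectionSummary, path: str | Path, arm: str = "") -> None:
    row = {"arm": arm, **summary.__dict__}
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
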