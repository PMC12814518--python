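"""End-to-end pipeline: config, run bundle, and text report.

A run goes simulate (or load FASTQ) -> count -> detection threshold ->
fitness -> enrichment heatmap, writing every intermediate as TSV plus a
manifest that reconciles read and variant counts at each stage.  A run
is fully determined by its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .aa_heatmap import enrichment_matrix, positive_set
from .fitness import (
    LOWERED_ASSEMBLY_BOUND,
    classify,
    compare_arms,
    fitness_table,
    write_fitness_tsv,
)
from .readcount import CountTable, apply_detection_threshold, count_fastq
from .sim_selection import (
    SelectionSimParams,
    default_ground_truth,
    default_input_abundance,
    run_selection,
)
from .variant_space import LibraryDesign

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "report_summary"]

log = logging.getLogger("pancsel")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one input source must be present: ``fastq`` (mapping of arm
    name -> {passage label -> path}) or ``simulate`` (simulator
    parameters; arms are derived from ``groels_buffers``).
    """

    design: LibraryDesign
    out_dir: Path
    seed: int = 0
    min_input_reads: int = 10
    lowered_bound: float = LOWERED_ASSEMBLY_BOUND
    heatmap_mode: str = "literal"
    fastq: Mapping[str, Mapping[str, str]] | None = None
    simulate: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        if (self.fastq is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'fastq' and 'simulate' must be given")
        if self.min_input_reads < 0:
            raise ConfigError("min_input_reads must be >= 0")
        if not (self.lowered_bound == self.lowered_bound):  # NaN guard
            raise ConfigError("lowered_bound must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = base or Path.cwd()
        lib = raw.get("library", {})
        design_kwargs = {}
        for key in ("n_positions", "wildtype_protein", "flank_up", "flank_down"):
            if key in lib:
                design_kwargs[key] = lib[key]
        if "position_labels" in lib:
            design_kwargs["position_labels"] = tuple(lib["position_labels"])
        design = LibraryDesign(**design_kwargs)
        analysis = raw.get("analysis", {})
        run = raw.get("run", {})
        fastq = raw.get("fastq")
        if fastq is not None:
            fastq = {
                arm: {p: str((base / f)) for p, f in files.items()}
                for arm, files in fastq.items()
            }
        return cls(
            design=design,
            out_dir=Path(run.get("out_dir", "pancsel_out")),
            seed=int(run.get("seed", 0)),
            min_input_reads=int(analysis.get("min_input_reads", 10)),
            lowered_bound=float(analysis.get("lowered_bound", LOWERED_ASSEMBLY_BOUND)),
            heatmap_mode=str(analysis.get("heatmap_mode", "literal")),
            fastq=fastq,
            simulate=raw.get("simulate"),
        )


def _simulate_arms(config: PipelineConfig) -> dict[str, CountTable]:
    sim = dict(config.simulate or {})
    design = config.design
    truth = default_ground_truth(
        design,
        seed=config.seed,
        rho_wt=float(sim.get("rho_wt", 1000.0)),
        neutral_fraction=float(sim.get("neutral_fraction", 0.13)),
    )
    abundance = default_input_abundance(
        design, seed=config.seed + 1, sigma=float(sim.get("abundance_sigma", 1.15))
    )
    buffers = sim.get("groels_buffers", {"minus_groels": 1.0, "plus_groels": 0.5})
    tables: dict[str, CountTable] = {}
    for arm, buf in buffers.items():
        params = SelectionSimParams(
            design=design,
            propagation_factor=truth.rho_map(1.0),
            input_abundance=abundance,
            n_passages=int(sim.get("n_passages", 3)),
            bottleneck=sim.get("bottleneck", 100_000),
            read_depth=int(sim.get("read_depth", 450_000)),
            groels_buffer=float(buf),
            hitchhiker_rate=float(sim.get("hitchhiker_rate", 0.0)),
            hitchhiker_boost=float(sim.get("hitchhiker_boost", 100.0)),
            seed=config.seed,
        )
        _pools, table, _emission = run_selection(params)
        tables[arm] = table
    return tables


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write the result bundle.

    The bundle contains, per arm: raw and thresholded count TSVs, a
    per-variant fitness TSV and a one-line summary TSV; plus the
    enrichment-matrix TSV over the arms' intersected positive set, an
    arm-comparison JSON when there are exactly two arms, and a manifest
    reconciling counts at every stage.  Identical config and seed give a
    byte-identical bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "min_input_reads": config.min_input_reads,
        "lowered_bound": config.lowered_bound,
        "heatmap_mode": config.heatmap_mode,
        "fitness_definition": "log10(f_final / f_input), frequencies, final passage = last",
        "arms": {},
    }

    if config.simulate is not None:
        log.info("simulating arms (seed=%d)", config.seed)
        tables = _simulate_arms(config)
        manifest["input"] = {"mode": "simulate", **dict(config.simulate)}
    else:
        assert config.fastq is not None
        tables = {
            arm: count_fastq(files, config.design) for arm, files in config.fastq.items()
        }
        manifest["input"] = {"mode": "fastq", "arms": {a: dict(f) for a, f in config.fastq.items()}}

    # threshold each arm, then restrict every arm to the variants retained in
    # all arms: the input library is one pool, so cross-arm comparisons are
    # only defined on the common retained set
    thresholded: dict[str, CountTable] = {}
    censuses: dict[str, Any] = {}
    for arm, table in tables.items():
        table.to_tsv(out / f"counts_{arm}.tsv", out / f"rejects_{arm}.tsv")
        thresholded[arm], censuses[arm] = apply_detection_threshold(
            table, config.min_input_reads
        )
    common = sorted(
        set.intersection(*(set(t.counts.index) for t in thresholded.values()))
    )
    manifest["n_common_retained"] = len(common)

    fit_tables: dict[str, pd.DataFrame] = {}
    for arm, table in tables.items():
        log.info("arm %s: thresholding / fitness", arm)
        census = censuses[arm]
        sub = CountTable(
            design=config.design,
            counts=thresholded[arm].counts.loc[common].copy(),
            rejected=table.rejected.copy(),
        )
        sub.to_tsv(out / f"counts_{arm}_thresholded.tsv")
        fit = fitness_table(sub, lowered_bound=config.lowered_bound)
        fit_tables[arm] = fit
        write_fitness_tsv(fit, out / f"fitness_{arm}.tsv")
        summary = classify(fit)
        pd.DataFrame([{"arm": arm, **summary.__dict__}]).to_csv(
            out / f"summary_{arm}.tsv", sep="\t", index=False
        )
        manifest["arms"][arm] = {
            "raw_reads": {p: int(n) for p, n in table.raw_totals.items()},
            "accepted_reads": {p: int(n) for p, n in table.totals.items()},
            "rejected_reads": {p: int(n) for p, n in table.rejected.sum(axis=0).items()},
            "n_detected": census.n_detected,
            "n_retained": census.n_retained,
            "n_dropped": census.n_dropped,
            "summary": summary.__dict__,
        }

    arms = sorted(fit_tables)
    positives = positive_set([fit_tables[a] for a in arms])
    starting = set(fit_tables[arms[0]].index)
    matrix = enrichment_matrix(positives, starting, config.design, mode=config.heatmap_mode)
    matrix.to_tsv(out / "enrichment_matrix.tsv")
    manifest["heatmap"] = {
        "arms_intersected": arms,
        "n_positive": matrix.n_positive,
        "n_starting": matrix.n_starting,
    }
    if len(arms) == 2:
        comparison = compare_arms(fit_tables[arms[0]], fit_tables[arms[1]])
        manifest["arm_comparison"] = {
            "minus_arm": arms[0],
            "plus_arm": arms[1],
            "positive_ratio": comparison.positive_ratio,
            "depleted_change": comparison.depleted_change,
            "n_rescued": len(comparison.rescued),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def report_summary(bundle_dir: str | Path, top_k: int = 10) -> str:
    """Human-readable summary of a result bundle."""
    bundle = Path(bundle_dir)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"incomplete bundle: {manifest_path} missing")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"pancsel {manifest['version']} run (seed {manifest['seed']})"]
    for arm, info in sorted(manifest["arms"].items()):
        s = info["summary"]
        lines.append(
            f"arm {arm}: {s['n_analyzed']} variants analyzed "
            f"({info['n_detected']} detected, threshold {manifest['min_input_reads']} reads); "
            f"{s['n_depleted']} depleted; "
            f"{100 * s['fraction_positive']:.1f}% positive fitness; "
            f"{100 * s['fraction_lowered_assembly']:.1f}% predicted lowered assembly"
        )
        fit_path = bundle / f"fitness_{arm}.tsv"
        if not fit_path.exists():
            raise FileNotFoundError(f"incomplete bundle: {fit_path} missing")
        fit = pd.read_csv(fit_path, sep="\t", index_col="variant", keep_default_na=False)
        fit["fitness"] = pd.to_numeric(fit["fitness"], errors="coerce")
        top = fit["fitness"].dropna().sort_values(ascending=False).head(top_k)
        tops = ", ".join(f"{v} ({x:+.2f})" for v, x in top.items())
        lines.append(f"  top {len(top)} enriched: {tops}")
    if "arm_comparison" in manifest:
        c = manifest["arm_comparison"]
        lines.append(
            f"chaperonin effect ({c['plus_arm']} vs {c['minus_arm']}): "
            f"positive fraction x{c['positive_ratio']:.2f}, "
            f"depleted {c['depleted_change']:+d}, {c['n_rescued']} variants rescued"
        )
    h = manifest["heatmap"]
    lines.append(
        f"enrichment matrix over {h['n_positive']} dual-positive variants "
        f"of {h['n_starting']} starting (stops excluded)"
    )
    return "\n".join(lines)
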