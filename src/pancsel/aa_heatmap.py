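"""Per-position amino-acid enrichment over positive-fitness variants.

For each mutagenized position and amino acid, the enrichment score is
the base-10 log of the ratio of the amino acid's occurrences among the
positive-fitness variants to its occurrences among all detected starting
variants.  A "total" column pools occurrences over all positions (a
variant contributes once per position slot, so "DRD" counts D twice in
the total).  Because the positive set is a subset of the starting set,
every defined cell is <= 0 under this literal count-ratio definition; an
optional centered mode subtracts the overall retention log-ratio
log10(|positive| / |starting|) so enrichment above the library-wide
survival shows up as a positive value.  Stop-containing variants are
excluded.  Amino acids with zero occurrences among the positives get a
zero-occurrence sentinel (the crossed-out cells of a heat map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_space import AMINO_ACIDS, STOP, LibraryDesign

__all__ = [
    "ZERO_OCCURRENCE",
    "NOT_IN_LIBRARY",
    "EnrichmentMatrix",
    "positive_set",
    "enrichment_matrix",
]

#: TSV rendering of a cell whose amino acid never occurs among positives.
ZERO_OCCURRENCE = "NA:zero_occurrence"
#: TSV rendering of a cell whose amino acid never occurs in the starting set.
NOT_IN_LIBRARY = "NA:not_in_library"

TOTAL = "total"


@dataclass
class EnrichmentMatrix:
    """20 amino acids x (positions + total) of log10 count-ratio scores.

    ``scores`` holds NaN where a sentinel applies; ``zero_occurrence``
    and ``not_in_library`` are boolean masks distinguishing the two
    sentinel cases.  ``mode`` records whether scores are literal count
    ratios or centered on the overall retention ratio.
    """

    scores: pd.DataFrame
    zero_occurrence: pd.DataFrame
    not_in_library: pd.DataFrame
    mode: str
    n_positive: int
    n_starting: int

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.round(6).astype(object)
        out = out.mask(self.zero_occurrence, ZERO_OCCURRENCE)
        out = out.mask(self.not_in_library, NOT_IN_LIBRARY)
        out.index.name = "amino_acid"
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode}\tn_positive={self.n_positive}\tn_starting={self.n_starting}\n")
            out.to_csv(fh, sep="\t")


def positive_set(records_by_arm: Sequence[pd.DataFrame]) -> set[str]:
    """Variants with positive fitness in *every* given arm, stops excluded.

    Each element of ``records_by_arm`` is a fitness table (one selection
    arm).  The result is the intersection of the arms' positive classes
    with stop-containing variants removed.
    """
    arms = list(records_by_arm)
    if not arms:
        raise ValueError("at least one arm of fitness records is required")
    sets = [
        set(t.index[(t["outcome_class"] == "positive") & ~t["contains_stop"]])
        for t in arms
    ]
    return set.intersection(*sets)


def _occurrences(variants: Iterable[str], n_positions: int) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=list(range(n_positions)))
    for v in variants:
        for pos, aa in enumerate(v):
            if aa != STOP:
                counts.at[aa, pos] += 1
    return counts


def enrichment_matrix(
    positive: set[str],
    starting: set[str],
    design: LibraryDesign,
    mode: str = "literal",
) -> EnrichmentMatrix:
    """Compute the per-position amino-acid enrichment matrix.

    ``positive`` must be a subset of ``starting``; both are sets of
    protein variant strings (stop-containing members are ignored).  With
    ``mode="literal"`` cells are log10(occurrences among positive /
    occurrences among starting), which is <= 0 everywhere; with
    ``mode="centered"`` the overall retention log-ratio is subtracted.
    """
    if not starting:
        raise ValueError("starting set is empty")
    if not positive <= starting:
        raise ValueError("positive set must be a subset of the starting set")
    if mode not in ("literal", "centered"):
        raise ValueError(f"unknown mode {mode!r}")
    pos_clean = [v for v in positive if STOP not in v]
    start_clean = [v for v in starting if STOP not in v]
    num = _occurrences(pos_clean, design.n_positions)
    den = _occurrences(start_clean, design.n_positions)
    num[TOTAL] = num.sum(axis=1)
    den[TOTAL] = den.sum(axis=1)
    labels = list(design.position_labels) + [TOTAL]
    num.columns = labels
    den.columns = labels

    not_in_library = den == 0
    zero_occurrence = (num == 0) & ~not_in_library
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log10(num / den)
    scores = pd.DataFrame(scores, index=num.index, columns=labels)
    scores = scores.mask(zero_occurrence | not_in_library)
    if mode == "centered":
        scores = scores - math.log10(len(pos_clean) / len(start_clean))
    return EnrichmentMatrix(
        scores=scores,
        zero_occurrence=zero_occurrence,
        not_in_library=not_in_library,
        mode=mode,
        n_positive=len(pos_clean),
        n_starting=len(start_clean),
    )


def plot_heatmap(matrix: EnrichmentMatrix, path: str | Path) -> None:
    """Basic matplotlib rendering with crossed-out zero-occurrence cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 8))
    data = matrix.scores.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.scores.columns)), [str(c) for c in matrix.scores.columns])
    ax.set_yticks(range(len(matrix.scores.index)), list(matrix.scores.index))
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if matrix.zero_occurrence.iloc[i, j]:
                ax.text(j, i, "x", ha="center", va="center", color="red")
    fig.colorbar(im, ax=ax, label=f"enrichment score ({matrix.mode})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
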