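"""Amplicon read counting: FASTQ -> protein-level variant count table.

Each read is expected to contain the mutagenized window between the
design's fixed flanks.  Extraction is by exact flank match with the
exact expected spacing; reads that fail (flank missing, wrong spacing,
ambiguous base in the window) are tallied by reason, never silently
dropped, so ``accepted + rejected = total`` holds per passage.  Base
qualities are ignored — the downstream detection threshold (minimum
input reads) is the noise filter.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .variant_space import (
    LibraryDesign,
    VariantKey,
    WindowRejection,
    collapse_to_protein,
    translate_window,
)

__all__ = [
    "REJECTION_REASONS",
    "CountTable",
    "ThresholdCensus",
    "extract_window",
    "count_fastq",
    "apply_detection_threshold",
]

#: Enumerated reasons a read can fail window extraction.
REJECTION_REASONS = (
    "flank_not_found",
    "bad_spacing",
    "ambiguous_base",
    "bad_window_length",
)


@dataclass
class CountTable:
    """Variant x passage read counts plus per-passage rejection tallies.

    ``counts`` is indexed by protein variant string with one integer
    column per passage label (input first); ``rejected`` is indexed by
    rejection reason with the same columns.
    """

    design: LibraryDesign
    counts: pd.DataFrame
    rejected: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = pd.DataFrame(
                0, index=list(REJECTION_REASONS), columns=self.counts.columns
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts.index.name = "variant"
        self.rejected.index.name = "reason"

    @property
    def passages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Accepted reads per passage."""
        return self.counts.sum(axis=0)

    @property
    def raw_totals(self) -> pd.Series:
        """All reads per passage, accepted plus rejected."""
        return self.totals + self.rejected.sum(axis=0)

    def to_tsv(self, counts_path: str | Path, rejects_path: str | Path | None = None) -> None:
        df = self.counts.copy()
        df.index.name = "variant"
        df.to_csv(counts_path, sep="\t")
        if rejects_path is not None:
            rej = self.rejected.copy()
            rej.index.name = "reason"
            rej.to_csv(rejects_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        design: LibraryDesign,
        counts_path: str | Path,
        rejects_path: str | Path | None = None,
    ) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant", keep_default_na=False)
        counts = counts.astype(int)
        rejected = None
        if rejects_path is not None:
            rejected = pd.read_csv(rejects_path, sep="\t", index_col="reason").astype(int)
        return cls(design=design, counts=counts, rejected=rejected)


def extract_window(read_sequence: str, design: LibraryDesign) -> tuple[str | None, str | None]:
    """Locate the mutagenized window in one read.

    Returns ``(window, None)`` on success or ``(None, reason)`` with one
    of :data:`REJECTION_REASONS` on failure.  The upstream flank is
    searched by exact match on the forward strand first, then on the
    reverse complement; the downstream flank must follow at exactly
    ``3 * n_positions`` nucleotides.
    """
    seq = read_sequence.upper()
    if design.flank_up not in seq:
        seq = reverse_complement(seq)
        if design.flank_up not in seq:
            return None, "flank_not_found"
    start = seq.index(design.flank_up) + len(design.flank_up)
    end = start + design.window_length
    tail = seq[end : end + len(design.flank_down)]
    if tail != design.flank_down:
        if design.flank_down in seq:
            return None, "bad_spacing"
        return None, "flank_not_found"
    window = seq[start:end]
    if set(window) - set("ACGT"):
        return None, "ambiguous_base"
    return window, None


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _count_one_fastq(path: str | Path, design: LibraryDesign) -> tuple[dict[str, int], dict[str, int]]:
    counts: dict[VariantKey, int] = {}
    rejected = dict.fromkeys(REJECTION_REASONS, 0)
    with _open_maybe_gzip(path) as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            window, reason = extract_window(seq, design)
            if window is None:
                rejected[reason] += 1  # type: ignore[index]
                continue
            try:
                key = translate_window(window, design)
            except WindowRejection as exc:
                rejected[exc.reason] += 1
                continue
            counts[key] = counts.get(key, 0) + 1
    protein = {k.protein_seq: c for k, c in collapse_to_protein(counts).items()}
    return protein, rejected


def count_fastq(
    files: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]],
    design: LibraryDesign,
) -> CountTable:
    """Count variants in one FASTQ per passage.

    ``files`` maps passage label -> FASTQ path (plain or .gz), in passage
    order (input first).  Synonymous codon windows are collapsed to
    protein level.
    """
    items = list(files.items()) if isinstance(files, Mapping) else list(files)
    per_passage: dict[str, dict[str, int]] = {}
    rejects: dict[str, dict[str, int]] = {}
    for label, path in items:
        try:
            per_passage[label], rejects[label] = _count_one_fastq(path, design)
        except OSError as exc:
            raise RuntimeError(f"passage {label!r}: cannot read FASTQ {path}") from exc
    labels = [label for label, _ in items]
    counts = (
        pd.DataFrame(per_passage, columns=labels)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    rejected = pd.DataFrame(rejects, columns=labels).reindex(list(REJECTION_REASONS)).fillna(0).astype(int)
    return CountTable(design=design, counts=counts, rejected=rejected)


@dataclass
class ThresholdCensus:
    """Bookkeeping for the input-library detection threshold."""

    min_input_reads: int
    n_detected: int
    n_retained: int
    n_dropped: int


def apply_detection_threshold(
    table: CountTable,
    min_input_reads: int = 10,
    input_passage: str | None = None,
) -> tuple[CountTable, ThresholdCensus]:
    """Keep variants with at least ``min_input_reads`` in the input passage.

    The default of 10 input reads is the detection threshold that defines
    the analyzed library; everything downstream (fitness, enrichment)
    sees only retained variants.
    """
    if input_passage is None:
        input_passage = table.passages[0]
    if input_passage not in table.counts.columns:
        raise ValueError(f"input passage {input_passage!r} not in table")
    keep = table.counts[table.counts[input_passage] >= min_input_reads]
    n_detected = int((table.counts[input_passage] > 0).sum())
    census = ThresholdCensus(
        min_input_reads=min_input_reads,
        n_detected=n_detected,
        n_retained=len(keep),
        n_dropped=len(table.counts) - len(keep),
    )
    out = CountTable(design=table.design, counts=keep.copy(), rejected=table.rejected.copy())
    return out, census
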