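"""Site-saturation variant space: library design, codon windows, protein variants.

A site-saturation library randomizes a short run of codons (here three,
RbcL residues 331-333) embedded in fixed sequence context.  At the protein
level the variant space is the set of all strings over the 21-letter
alphabet (20 amino acids plus the stop symbol ``*``), i.e. ``21**n``
variants for ``n`` mutagenized codons.  Counting and fitness analysis are
done at the protein level; synonymous codon windows are collapsed by
summing their read counts.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AMINO_ACIDS",
    "PROTEIN_ALPHABET",
    "STOP",
    "GENETIC_CODE",
    "LibraryDesign",
    "VariantKey",
    "WindowRejection",
    "enumerate_protein_variants",
    "translate_window",
    "collapse_to_protein",
    "reverse_translate",
]

STOP = "*"

#: The 20 proteinogenic amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Protein alphabet used for variant accounting: 20 amino acids + stop.
PROTEIN_ALPHABET = AMINO_ACIDS + STOP

_STANDARD = unambiguous_dna_by_id[1]

#: Standard genetic code, codon -> one-letter amino acid, stops mapped to '*'.
GENETIC_CODE: Mapping[str, str] = {
    **_STANDARD.forward_table,
    **{c: STOP for c in _STANDARD.stop_codons},
}

_DNA = set("ACGT")


@dataclass(frozen=True)
class LibraryDesign:
    """Description of one site-saturation mutagenesis library.

    Parameters
    ----------
    n_positions
        Number of consecutive mutagenized codons.
    position_labels
        Residue numbers of the mutagenized positions (for reporting only).
    wildtype_protein
        Wild-type amino acids at the mutagenized positions, one letter each.
    flank_up, flank_down
        Fixed nucleotide sequence immediately up/downstream of the
        mutagenized window, used to anchor window extraction from reads.
        The defaults are synthetic stand-ins (the real amplicon context is
        not part of this package); any A/C/G/T strings work.
    """

    n_positions: int = 3
    position_labels: tuple[int, ...] = (331, 332, 333)
    wildtype_protein: str = "DRA"
    flank_up: str = "ACTGGTACCGTTGTAGGTAAACTGGAAGG"
    flank_down: str = "TGATCCATGGGTCACCCGTGGGGTAACGC"
    genetic_code: Mapping[str, str] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genetic_code is None:
            object.__setattr__(self, "genetic_code", GENETIC_CODE)
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if len(self.position_labels) != self.n_positions:
            raise ValueError("position_labels length must equal n_positions")
        if len(self.wildtype_protein) != self.n_positions:
            raise ValueError("wildtype_protein length must equal n_positions")
        for name in ("flank_up", "flank_down"):
            flank = getattr(self, name)
            if not flank or set(flank) - _DNA:
                raise ValueError(f"{name} must be a non-empty A/C/G/T string")

    @property
    def window_length(self) -> int:
        """Length in nucleotides of the mutagenized window."""
        return 3 * self.n_positions

    @property
    def n_protein_variants(self) -> int:
        """Size of the protein-level variant space, ``21**n_positions``."""
        return len(PROTEIN_ALPHABET) ** self.n_positions


@dataclass(frozen=True)
class VariantKey:
    """One library member, identified at codon and/or protein level.

    ``codon_seq`` may be ``None`` when only protein-level information
    exists (e.g. after synonymous collapse).
    """

    protein_seq: str
    codon_seq: str | None = None

    def __post_init__(self) -> None:
        if self.codon_seq is not None:
            if len(self.codon_seq) != 3 * len(self.protein_seq):
                raise ValueError("codon_seq length must be 3x protein_seq length")
            translated = _translate(self.codon_seq)
            if translated != self.protein_seq:
                raise ValueError(
                    f"codon_seq {self.codon_seq!r} translates to {translated!r}, "
                    f"not {self.protein_seq!r}"
                )

    @property
    def contains_stop(self) -> bool:
        return STOP in self.protein_seq


class WindowRejection(Exception):
    """A codon window that cannot be translated (bad length or characters).

    Batch counting code catches this and tallies the read as rejected
    instead of propagating the exception.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _translate(codon_seq: str) -> str:
    return "".join(
        GENETIC_CODE[codon_seq[i : i + 3]] for i in range(0, len(codon_seq), 3)
    )


def enumerate_protein_variants(design: LibraryDesign) -> set[VariantKey]:
    """All protein-level variants of the saturation library.

    Returns every string over the 21-letter alphabet of length
    ``design.n_positions``; cardinality is ``21**n_positions`` (9261 for
    the three-codon library).
    """
    return {
        VariantKey(protein_seq="".join(aas))
        for aas in itertools.product(PROTEIN_ALPHABET, repeat=design.n_positions)
    }


def translate_window(codon_seq: str, design: LibraryDesign) -> VariantKey:
    """Translate an extracted codon window into a :class:`VariantKey`.

    Raises :class:`WindowRejection` for a wrong-length window or non-ACGT
    characters; batch counting converts that into a rejected-read tally.
    """
    if len(codon_seq) != design.window_length:
        raise WindowRejection("bad_window_length")
    if set(codon_seq) - _DNA:
        raise WindowRejection("ambiguous_base")
    protein = "".join(
        design.genetic_code[codon_seq[i : i + 3]]
        for i in range(0, len(codon_seq), 3)
    )
    return VariantKey(protein_seq=protein, codon_seq=codon_seq)


def collapse_to_protein(
    codon_counts: Mapping[VariantKey, int]
) -> dict[VariantKey, int]:
    """Sum counts over synonymous codon windows.

    Keys of the result carry only ``protein_seq``; the total count is
    conserved exactly.
    """
    out: dict[str, int] = defaultdict(int)
    for key, count in codon_counts.items():
        if key.codon_seq is None:
            raise ValueError(f"key {key.protein_seq!r} lacks a codon_seq")
        out[key.protein_seq] += count
    return {VariantKey(protein_seq=p): c for p, c in out.items()}


def reverse_translate(protein_seq: str, design: LibraryDesign | None = None) -> str:
    """A canonical codon window encoding ``protein_seq``.

    Uses the alphabetically first codon for each amino acid (TAA for
    stop); the choice is arbitrary but deterministic, which is all the
    simulator's FASTQ emission needs.
    """
    code = design.genetic_code if design is not None else GENETIC_CODE
    by_aa: dict[str, str] = {}
    for codon in sorted(code):
        aa = code[codon]
        by_aa.setdefault(aa, codon)
    try:
        return "".join(by_aa[aa] for aa in protein_seq)
    except KeyError as exc:
        raise ValueError(f"no codon for amino acid {exc.args[0]!r}") from exc


def variant_labels(variants: Iterable[VariantKey]) -> list[str]:
    """Sorted protein-string labels for a collection of variants."""
    return sorted(v.protein_seq for v in variants)
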