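"""Reading-frame overlay: codon-position classes, translation, mutation effects.

An element that overlaps an open reading frame has each of its bases doing
double duty: positions 1 and 2 of a codon are largely fixed by the encoded
amino acid, while the third ("wobble") position is free to drift wherever
the genetic code is degenerate.  This module paints those classes onto an
element given the 1-based position of the first codon base, translates the
in-frame region, and reports the coding consequence of a single-base change.

Only the standard genetic code is supported.  Stop codons appear in peptides
as ``'*'``; a codon containing ``N`` translates to ``'X'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .seqmodel import AnnotatedSequence

#: per-position overlay classes
PRE_ORF = "pre_orf"
CODON_POS1 = "codon_pos1"
CODON_POS2 = "codon_pos2"
WOBBLE = "wobble"
POST_ORF = "post_orf"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stops included as '*'
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD.stop_codons})


def codon_to_aa(codon: str) -> str:
    """Translate one codon; 'X' if it contains N (or anything non-ACGT)."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    return GENETIC_CODE.get(codon, "X")


def forced_codon_positions(codon: str) -> set[int]:
    """Codon positions (1-3) where no alternative base preserves the amino acid.

    Used by the neighbor-bias exclusion policy: a base "fixed by the encoded
    amino acid" is one whose every substitution is non-synonymous.
    """
    codon = codon.upper()
    aa = codon_to_aa(codon)
    forced = set()
    if aa == "X":
        return forced
    for pos in range(3):
        alt_aas = {
            codon_to_aa(codon[:pos] + b + codon[pos + 1:])
            for b in "ACGT"
            if b != codon[pos]
        }
        if aa not in alt_aas:
            forced.add(pos + 1)
    return forced


@dataclass(frozen=True)
class CodonOverlay:
    """Per-position codon classes of an element under a fixed reading frame."""

    element_length: int
    frame_start: int
    per_position: tuple[str, ...]
    n_codons: int
    peptide: str

    @property
    def peptide_no_stop(self) -> str:
        """Peptide with a single trailing stop mark removed, if present."""
        return self.peptide.rstrip("*")

    def positions_of(self, cls: str) -> list[int]:
        return [i + 1 for i, c in enumerate(self.per_position) if c == cls]

    def codon_index(self, position: int) -> Optional[int]:
        """1-based codon number containing ``position``, None outside the ORF."""
        if self.per_position[position - 1] in (PRE_ORF, POST_ORF):
            return None
        return (position - self.frame_start) // 3 + 1

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in (PRE_ORF, CODON_POS1, CODON_POS2, WOBBLE, POST_ORF)}
        for c in self.per_position:
            counts[c] += 1
        return counts


def overlay_frame(seq: AnnotatedSequence, frame_start: int) -> CodonOverlay:
    """Assign each position of ``seq`` a codon-overlay class.

    Positions before ``frame_start`` are ``pre_orf``; from ``frame_start`` the
    classes cycle codon position 1, 2, wobble; 1-2 trailing bases that do not
    complete a codon are ``post_orf``.
    """
    length = len(seq)
    if not 1 <= frame_start <= length:
        raise ValueError(f"frame_start {frame_start} outside 1..{length}")
    n_codons = (length - frame_start + 1) // 3
    classes = [PRE_ORF] * (frame_start - 1)
    cycle = (CODON_POS1, CODON_POS2, WOBBLE)
    for k in range(n_codons * 3):
        classes.append(cycle[k % 3])
    classes.extend([POST_ORF] * (length - len(classes)))
    peptide = (
        translate_region(seq, frame_start) if n_codons >= 1 else ""
    )
    return CodonOverlay(
        element_length=length,
        frame_start=frame_start,
        per_position=tuple(classes),
        n_codons=n_codons,
        peptide=peptide,
    )


def translate_region(seq: AnnotatedSequence, frame_start: int) -> str:
    """Translate the in-frame region of ``seq`` starting at ``frame_start``.

    One letter per complete codon; trailing bases that do not complete a
    codon are ignored.  Raises if fewer than three in-frame bases exist.
    """
    length = len(seq)
    if not 1 <= frame_start <= length:
        raise ValueError(f"frame_start {frame_start} outside 1..{length}")
    region = seq.residues[frame_start - 1:]
    if len(region) < 3:
        raise ValueError("fewer than 3 in-frame bases; nothing to translate")
    return "".join(
        codon_to_aa(region[k:k + 3]) for k in range(0, len(region) - 2, 3)
    )


@dataclass(frozen=True)
class MutationEffect:
    """Coding consequence of a single-base substitution."""

    position: int
    old_base: str
    new_base: str
    codon_index: Optional[int]
    codon_position_class: str
    old_peptide: str
    new_peptide: str
    synonymous: bool


def mutation_effect(
    seq: AnnotatedSequence,
    frame_start: int,
    position: int,
    new_base: str,
) -> MutationEffect:
    """Report the effect of substituting ``new_base`` at ``position``.

    Peptides are computed before and after the change; the substitution is
    synonymous when they are equal (a change outside the ORF is reported as
    synonymous by location).
    """
    overlay = overlay_frame(seq, frame_start)
    old_base = seq.base(position)
    new_base = new_base.upper()
    if new_base == old_base:
        raise ValueError(f"position {position} already holds {old_base!r}")
    mutated = seq.with_substitution(position, new_base)
    old_pep = overlay.peptide
    new_pep = translate_region(mutated, frame_start) if overlay.n_codons else ""
    return MutationEffect(
        position=position,
        old_base=old_base,
        new_base=new_base,
        codon_index=overlay.codon_index(position),
        codon_position_class=overlay.per_position[position - 1],
        old_peptide=old_pep,
        new_peptide=new_pep,
        synonymous=old_pep == new_pep,
    )
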