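"""Core sequence and alignment containers plus FASTA/Clustal I/O.

Coordinates throughout the package are 1-based and inclusive, matching the
base-position naming convention used for regulatory elements (T1 = a T at
position 1, G6 = a G at position 6, and so on).  Input sequences are
normalised to uppercase; ``N`` is accepted and treated as "unknown": it never
matches in identity or invariance comparisons and is excluded from GC/CpG
denominators by the composition module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, TextIO, Union

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

#: Roles an element can play in the locus under study.
ROLES = (
    "exonic_silencer",
    "silencer_b",
    "full_silencer",
    "enhancer",
    "embedded_silencer",
    "generic",
)


class ParseError(ValueError):
    """Raised when an input stream cannot be interpreted as requested."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """A DNA sequence with coordinate and reading-frame metadata.

    Parameters
    ----------
    id:
        Free-text label (FASTA description is retained verbatim on input).
    residues:
        DNA string over ``{A, C, G, T, N}``; normalised to uppercase.
    frame_start:
        Optional 1-based index of the first base of the first codon, for
        elements that overlap an open reading frame.
    role:
        One of :data:`ROLES`; purely descriptive.
    """

    id: str
    residues: str
    frame_start: Optional[int] = None
    role: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(
                i + 1 for i, c in enumerate(self.residues) if c in bad
            )
            raise ParseError(
                f"sequence {self.id!r} contains illegal character "
                f"{self.residues[pos - 1]!r} at position {pos}"
            )
        if self.frame_start is not None and not (
            1 <= self.frame_start <= len(self.residues)
        ):
            raise ValueError(
                f"frame_start {self.frame_start} outside sequence "
                f"{self.id!r} of length {len(self.residues)}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]

    def with_substitution(self, position: int, new_base: str) -> "AnnotatedSequence":
        """Return a copy with the base at ``position`` replaced."""
        new_base = new_base.upper()
        if new_base not in DNA_ALPHABET:
            raise ValueError(f"illegal base {new_base!r}")
        old = self.base(position)
        if old == new_base:
            raise ValueError(
                f"position {position} already holds {old!r}"
            )
        residues = (
            self.residues[: position - 1] + new_base + self.residues[position:]
        )
        return AnnotatedSequence(
            id=self.id, residues=residues, frame_start=self.frame_start, role=self.role
        )


@dataclass(frozen=True)
class SpeciesRecord:
    """A species label with its divergence age from the reference lineage.

    ``divergence_age`` is in Mya (million years ago); the reference species
    itself has age 0.
    """

    name: str
    divergence_age: float

    def __post_init__(self) -> None:
        if self.divergence_age < 0:
            raise ValueError(
                f"divergence age of {self.name!r} must be >= 0 Mya"
            )


@dataclass
class OrthologLadder:
    """Species-ordered homologs of a reference element.

    Members are kept sorted by ascending divergence age; a member's sequence
    may be ``None`` when no ortholog could be located for that species
    (recorded as *no data*, which downstream analyses treat differently from
    an ortholog that fails to align).
    """

    reference: AnnotatedSequence
    members: list[tuple[SpeciesRecord, Optional[AnnotatedSequence]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        names = [sp.name for sp, _ in self.members]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species name in ladder")
        self.members = sorted(self.members, key=lambda m: m[0].divergence_age)

    def __len__(self) -> int:
        return len(self.members)

    def species(self) -> list[SpeciesRecord]:
        return [sp for sp, _ in self.members]


@dataclass(frozen=True)
class MultipleAlignment:
    """Rows of (label, gapped residue string) with equal gapped length."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise ParseError(f"ragged alignment rows: lengths {sorted(lengths)}")
        object.__setattr__(
            self,
            "rows",
            tuple((label, gapped.upper()) for label, gapped in self.rows),
        )
        for label, gapped in self.rows:
            bad = set(gapped) - DNA_ALPHABET - {"-"}
            if bad:
                raise ParseError(
                    f"row {label!r} contains illegal characters {sorted(bad)}"
                )
            # ungapping must yield a valid sequence (i.e. non-empty)
            if not gapped.replace("-", ""):
                raise ParseError(f"row {label!r} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def labels(self) -> list[str]:
        return [label for label, _ in self.rows]

    def row(self, label: str) -> str:
        for lab, gapped in self.rows:
            if lab == label:
                return gapped
        raise KeyError(f"no alignment row labelled {label!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _as_handle(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_fasta(source: Union[str, TextIO]) -> list[AnnotatedSequence]:
    """Parse multi-record FASTA from a text stream or string.

    Order is preserved and the full description line is retained as the id.
    Raises :class:`ParseError` on empty input or residues outside
    ``{A, C, G, T, N}`` (after uppercasing), naming the offending record and
    position.
    """
    records = list(SeqIO.parse(_as_handle(source), "fasta"))
    if not records:
        raise ParseError("no FASTA records found")
    out = []
    for rec in records:
        out.append(AnnotatedSequence(id=rec.description, residues=str(rec.seq)))
    return out


def write_fasta(
    sequences: Iterable[AnnotatedSequence], handle: TextIO, width: int = 60
) -> None:
    """Write sequences as wrapped FASTA."""
    recs = [
        SeqRecord(Seq(s.residues), id=s.id.split()[0],
                  description=" ".join(s.id.split()[1:]))
        for s in sequences
    ]
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(recs)


def read_alignment(
    source: Union[str, TextIO], dialect: str = "aligned_fasta"
) -> MultipleAlignment:
    """Read a multiple alignment in aligned-FASTA or Clustal format.

    ``dialect`` is ``"aligned_fasta"`` or ``"clustal"``; Clustal conservation
    lines are ignored and a version suffix on the CLUSTAL header is
    tolerated (both via Biopython's parser).
    """
    fmt = {"aligned_fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(_as_handle(source), fmt)
    except ValueError as exc:
        raise ParseError(f"cannot parse {dialect} alignment: {exc}") from exc
    return MultipleAlignment(
        rows=tuple((rec.id, str(rec.seq)) for rec in aln)
    )


def read_ladder_tsv(source: Union[str, TextIO]) -> list[SpeciesRecord]:
    """Read a species ladder as 2-column TSV: species_name, divergence_age_mya."""
    handle = _as_handle(source)
    records = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"ladder line {lineno}: expected 2 tab-separated columns"
            )
        name, age = parts
        try:
            records.append(SpeciesRecord(name=name, divergence_age=float(age)))
        except ValueError as exc:
            raise ParseError(f"ladder line {lineno}: {exc}") from exc
    if not records:
        raise ParseError("empty species ladder")
    return records


# ---------------------------------------------------------------------------
# Packaged fixtures: the SMIM45 regulatory elements
# ---------------------------------------------------------------------------

#: fixture key -> (role, frame_start)
_FIXTURE_META = {
    "full_silencer": ("full_silencer", None),
    "exonic_silencer": ("exonic_silencer", 3),
    "silencer_b": ("silencer_b", None),
    "enhancer1": ("enhancer", None),
    "enhancer2": ("enhancer", None),
    "embedded_silencer": ("embedded_silencer", None),
    "enhancer3": ("enhancer", None),
}

FIXTURE_KEYS = tuple(_FIXTURE_META)


def _fixture_records() -> dict[str, AnnotatedSequence]:
    text = (
        resources.files("regevol.data")
        .joinpath("smim45_elements.fasta")
        .read_text()
    )
    return {seq.id.split()[0]: seq for seq in read_fasta(text)}


def load_fixture(name: str) -> AnnotatedSequence:
    """Return one of the packaged SMIM45 element sequences.

    Keys: ``full_silencer`` (230 bp), ``exonic_silencer`` (38 bp, reading
    frame starting at base 3), ``silencer_b`` (192 bp), ``enhancer1``
    (210 bp), ``enhancer2`` (628 bp), ``embedded_silencer`` (60 bp),
    ``enhancer3`` (512 bp).  The full silencer is the concatenation of the
    exonic silencer and silencer b.
    """
    if name not in _FIXTURE_META:
        raise KeyError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_META)}"
        )
    role, frame_start = _FIXTURE_META[name]
    raw = _fixture_records()[name]
    return AnnotatedSequence(
        id=raw.id, residues=raw.residues, frame_start=frame_start, role=role
    )
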