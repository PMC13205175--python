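"""Identity-versus-age dating of regulatory element origination.

A short element is dated by asking, for successively older species, whether
a homolog with convincing pairwise identity can still be found.  Raw percent
identity is the evidence: above ``present_threshold`` the element is called
present, below ``absent_threshold`` absent, and the band in between is the
"twilight zone" where homology can be neither asserted nor excluded.  The
origination age is bracketed by the oldest species where the element is
present and the youngest older species where it is not.

Thresholds default to present >= 55% and absent <= 45%, bracketing the
judgment calls this kind of analysis makes in practice (identities near 80%
are treated as clear homology, ~40-45% as noise); both are configurable and
are echoed in every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentParams, global_align, percent_identity
from .seqmodel import AnnotatedSequence, OrthologLadder

PRESENT = "present"
TWILIGHT = "twilight"
ABSENT = "absent"
NO_DATA = "no_data"


@dataclass(frozen=True)
class SpeciesIdentity:
    species: str
    divergence_age: float
    identity_pct: Optional[float]  # None when no ortholog sequence exists
    verdict: str


@dataclass(frozen=True)
class OriginationCall:
    """Verdicts per species and the implied origination age bracket (Mya).

    ``origination_age_upper`` is None when every (data-bearing) species is
    called present — the bracket is open-ended beyond the oldest species
    sampled.  Both bounds are None when no species is called present.
    """

    species: tuple[SpeciesIdentity, ...]
    present_threshold: float
    absent_threshold: float
    oldest_present_species: Optional[str]
    origination_age_lower: Optional[float]
    origination_age_upper: Optional[float]


def call_from_identities(
    table: Sequence[tuple[str, float, Optional[float]]],
    present_threshold: float = 55.0,
    absent_threshold: float = 45.0,
) -> OriginationCall:
    """Origination call from precomputed (species, age, identity%) rows.

    ``identity`` of None marks a species with no locatable ortholog; it is
    recorded as ``no_data`` and ignored when bracketing.
    """
    if not absent_threshold < present_threshold:
        raise ValueError("require absent_threshold < present_threshold")
    if not table:
        raise ValueError("empty ladder")
    rows = []
    for name, age, ident in sorted(table, key=lambda r: r[1]):
        if ident is None:
            verdict = NO_DATA
        elif ident >= present_threshold:
            verdict = PRESENT
        elif ident <= absent_threshold:
            verdict = ABSENT
        else:
            verdict = TWILIGHT
        rows.append(
            SpeciesIdentity(
                species=name, divergence_age=age, identity_pct=ident,
                verdict=verdict,
            )
        )
    present = [r for r in rows if r.verdict == PRESENT]
    if not present:
        return OriginationCall(
            species=tuple(rows),
            present_threshold=present_threshold,
            absent_threshold=absent_threshold,
            oldest_present_species=None,
            origination_age_lower=None,
            origination_age_upper=None,
        )
    oldest = max(present, key=lambda r: r.divergence_age)
    older_nonpresent = [
        r.divergence_age
        for r in rows
        if r.verdict in (ABSENT, TWILIGHT)
        and r.divergence_age > oldest.divergence_age
    ]
    return OriginationCall(
        species=tuple(rows),
        present_threshold=present_threshold,
        absent_threshold=absent_threshold,
        oldest_present_species=oldest.species,
        origination_age_lower=oldest.divergence_age,
        origination_age_upper=min(older_nonpresent) if older_nonpresent else None,
    )


def origination_call(
    element: AnnotatedSequence,
    ladder: OrthologLadder,
    present_threshold: float = 55.0,
    absent_threshold: float = 45.0,
    params: Optional[AlignmentParams] = None,
) -> OriginationCall:
    """Date the origination of ``element`` along an ortholog ladder.

    Identities are computed by semi-global pairwise alignment (free end
    gaps) of the element against each member sequence; members with no
    sequence are recorded as ``no_data``.  Verdicts do not depend on the
    input order of ladder members.
    """
    if not ladder.members:
        raise ValueError("empty ladder")
    table = []
    for sp, seq in ladder.members:
        if seq is None:
            table.append((sp.name, sp.divergence_age, None))
        else:
            aln = global_align(element, seq, params=params, end_gaps_free=True)
            table.append((sp.name, sp.divergence_age, percent_identity(aln)))
    return call_from_identities(
        table,
        present_threshold=present_threshold,
        absent_threshold=absent_threshold,
    )
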