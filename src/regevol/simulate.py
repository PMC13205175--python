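"""Forward simulator of ortholog ladders with known per-position ground truth.

The generative model mirrors the constraint structure this package is built
to detect.  An ancestral element evolves independently down each branch of a
star phylogeny (one branch per species, length = its divergence age in My):

* **frozen** positions never mutate — they model bases held invariant by an
  unknown constraint on the DNA itself;
* **codon-constrained** positions (codon positions 1/2 when a reading frame
  is given and ``purifying`` is on) accept only synonymous changes — the
  "cultivator" constraint of an overlapping ORF;
* all other positions drift **freely**.

Substitution counts per site are Poisson with rate ``mu`` (substitutions per
site per My).  At sites immediately adjacent to a frozen position, the
mutated base is G or C with probability ``neighbor_gc_bias`` (beta) — drawn
uniformly from {G, C} minus the current base — and otherwise A or T, so beta
is exactly the probability that an accepted neighbor mutation yields G or C
and :func:`recover_beta` estimates it by a plain binomial proportion.
Elsewhere the mutated base is uniform over the three alternatives.

Indels are off by default; when enabled, the true alignment against the
ancestor is retained so conservation analyses can be tested without
re-inferring an alignment.  All randomness flows from the mandatory config
seed; the same config always yields a byte-identical ladder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binomtest

from .codons import CODON_POS1, CODON_POS2, codon_to_aa, overlay_frame
from .seqmodel import (
    AnnotatedSequence,
    MultipleAlignment,
    OrthologLadder,
    SpeciesRecord,
)

FROZEN = "frozen"
CODON_CONSTRAINED = "codon_constrained"
FREE = "free"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ladder.

    Either ``ancestral_sequence`` is given, or ``length`` (with
    ``gc_fraction``) and the ancestor is generated.  ``mu`` is in
    substitutions per site per My; ``neighbor_gc_bias`` (beta) is the
    probability that a mutation at a neighbor of a frozen position produces
    G or C; ``indel_rate`` is indel events per site per My.  ``seed`` is
    mandatory — there is no hidden global randomness.
    """

    ladder: tuple[SpeciesRecord, ...]
    seed: int
    ancestral_sequence: Optional[str] = None
    length: Optional[int] = None
    gc_fraction: float = 0.5
    frame_start: Optional[int] = None
    mu: float = 0.002
    frozen_positions: frozenset[int] = frozenset()
    purifying: bool = False
    neighbor_gc_bias: float = 0.92
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.ladder:
            raise ValueError("ladder must name at least one species")
        if self.mu < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.neighbor_gc_bias <= 1:
            raise ValueError("neighbor_gc_bias must be in [0, 1]")
        if (self.ancestral_sequence is None) == (self.length is None):
            raise ValueError(
                "give exactly one of ancestral_sequence or length"
            )
        if self.ancestral_sequence is not None:
            bad = set(self.ancestral_sequence.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"ancestral sequence has non-ACGT {sorted(bad)}")
        n = (
            len(self.ancestral_sequence)
            if self.ancestral_sequence is not None
            else self.length
        )
        for p in self.frozen_positions:
            if not 1 <= p <= n:
                raise ValueError(f"frozen position {p} outside 1..{n}")
        if self.frame_start is not None and not 1 <= self.frame_start <= n:
            raise ValueError("frame_start out of range")


@dataclass(frozen=True)
class Substitution:
    """One accepted substitution on one branch."""

    species: str
    position: int  # 1-based ancestral coordinate
    old_base: str
    new_base: str
    frozen_neighbor: bool


@dataclass(frozen=True)
class IndelEvent:
    species: str
    kind: str  # "insertion" | "deletion"
    position: int  # ancestral coordinate (after which / starting at which)
    length: int


@dataclass(frozen=True)
class SimulationTruth:
    classes: tuple[str, ...]  # per ancestral position
    substitutions: tuple[Substitution, ...]
    indels: tuple[IndelEvent, ...]
    true_alignment: Optional[MultipleAlignment]  # set when indels enabled


@dataclass(frozen=True)
class SimulatedLadder:
    ladder: OrthologLadder
    truth: SimulationTruth
    config: SimulationConfig

    def as_alignment(self) -> MultipleAlignment:
        """The true multiple alignment of reference and members.

        With indels disabled the simulated sequences are columnwise
        comparable and the alignment is gapless; with indels enabled the
        tracked true alignment is returned.  Downstream conservation
        analyses can consume this directly instead of re-inferring an
        alignment.
        """
        if self.truth.true_alignment is not None:
            return self.truth.true_alignment
        rows = [("reference", self.ladder.reference.residues)]
        rows += [(sp.name, seq.residues) for sp, seq in self.ladder.members]
        return MultipleAlignment(rows=tuple(rows))


def _generate_ancestor(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_ladder(config: SimulationConfig) -> SimulatedLadder:
    """Evolve the ancestor down every branch and return ladder plus truth."""
    rng = np.random.default_rng(config.seed)
    ancestor = (
        config.ancestral_sequence.upper()
        if config.ancestral_sequence is not None
        else _generate_ancestor(rng, config.length, config.gc_fraction)
    )
    L = len(ancestor)
    frozen = config.frozen_positions
    neighbors = {
        q
        for p in frozen
        for q in (p - 1, p + 1)
        if 1 <= q <= L and q not in frozen
    }
    overlay = (
        overlay_frame(
            AnnotatedSequence(id="ancestor", residues=ancestor),
            config.frame_start,
        )
        if config.frame_start is not None
        else None
    )
    constrained = set()
    if config.purifying and overlay is not None:
        for cls in (CODON_POS1, CODON_POS2):
            constrained.update(overlay.positions_of(cls))
    classes = tuple(
        FROZEN
        if p in frozen
        else CODON_CONSTRAINED
        if p in constrained
        else FREE
        for p in range(1, L + 1)
    )

    members: list[tuple[SpeciesRecord, AnnotatedSequence]] = []
    subs: list[Substitution] = []
    indels: list[IndelEvent] = []
    member_slots: dict[str, list[str]] = {}
    species_sorted = sorted(config.ladder, key=lambda s: s.divergence_age)

    for sp in species_sorted:
        seq = list(ancestor)
        counts = rng.poisson(config.mu * sp.divergence_age, size=L)
        for p in frozen:
            counts[p - 1] = 0  # frozen sites never change
        for site in np.nonzero(counts)[0]:
            pos = int(site) + 1
            for _ in range(int(counts[site])):
                cur = seq[site]
                if pos in neighbors:
                    if rng.random() < config.neighbor_gc_bias:
                        opts = [b for b in "GC" if b != cur]
                    else:
                        opts = [b for b in "AT" if b != cur]
                else:
                    opts = [b for b in "ACGT" if b != cur]
                new = opts[int(rng.integers(len(opts)))]
                if pos in constrained:
                    idx = overlay.codon_index(pos)
                    start = overlay.frame_start + (idx - 1) * 3 - 1
                    codon = "".join(seq[start:start + 3])
                    mutated = list(codon)
                    mutated[pos - 1 - start] = new
                    if codon_to_aa("".join(mutated)) != codon_to_aa(codon):
                        continue  # purifying rejection
                seq[site] = new
                subs.append(
                    Substitution(
                        species=sp.name,
                        position=pos,
                        old_base=cur,
                        new_base=new,
                        frozen_neighbor=pos in neighbors,
                    )
                )

        # indels operate on slots: slot 0 holds insertions before base 1,
        # slot i >= 1 holds ancestral base i (possibly deleted) plus any
        # bases inserted immediately after it
        slots = [""] + seq
        if config.indel_rate > 0:
            n_events = rng.poisson(config.indel_rate * L * sp.divergence_age)
            for _ in range(int(n_events)):
                if rng.random() < 0.5:
                    length = int(rng.integers(1, 4))
                    after = int(rng.integers(0, L + 1))
                    insert = "".join(
                        "ACGT"[int(rng.integers(4))] for _ in range(length)
                    )
                    slots[after] = slots[after] + insert
                    indels.append(
                        IndelEvent(sp.name, "insertion", after, length)
                    )
                else:
                    length = int(rng.integers(1, 4))
                    for _try in range(50):
                        start = int(rng.integers(1, L + 1))
                        span = range(start, min(start + length, L + 1))
                        if any(p in frozen for p in span):
                            continue
                        if all(slots[p] == "" for p in span):
                            continue  # already deleted
                        for p in span:
                            slots[p] = slots[p][1:] if slots[p] else ""
                        indels.append(
                            IndelEvent(
                                sp.name, "deletion", start, len(list(span))
                            )
                        )
                        break
        member_slots[sp.name] = slots
        residues = "".join(slots)
        members.append(
            (sp, AnnotatedSequence(id=sp.name, residues=residues))
        )

    reference = AnnotatedSequence(
        id="reference",
        residues=ancestor,
        frame_start=config.frame_start,
    )
    true_alignment = None
    if config.indel_rate > 0:
        widths = [
            max(
                [1 if i > 0 else 0]
                + [len(member_slots[sp.name][i]) for sp in species_sorted]
            )
            for i in range(L + 1)
        ]
        ref_slots = [""] + list(ancestor)
        rows = [
            (
                "reference",
                "".join(s.ljust(w, "-") for s, w in zip(ref_slots, widths)),
            )
        ]
        for sp in species_sorted:
            rows.append(
                (
                    sp.name,
                    "".join(
                        s.ljust(w, "-")
                        for s, w in zip(member_slots[sp.name], widths)
                    ),
                )
            )
        true_alignment = MultipleAlignment(rows=tuple(rows))

    return SimulatedLadder(
        ladder=OrthologLadder(reference=reference, members=members),
        truth=SimulationTruth(
            classes=classes,
            substitutions=tuple(subs),
            indels=tuple(indels),
            true_alignment=true_alignment,
        ),
        config=config,
    )


@dataclass(frozen=True)
class BetaEstimate:
    """Binomial estimate of the neighbor G/C bias from simulation truth."""

    beta_hat: float
    n: int
    k: int
    ci_low: float
    ci_high: float
    confidence_level: float = 0.95


def recover_beta(
    simulated: SimulatedLadder, confidence_level: float = 0.95
) -> BetaEstimate:
    """Estimate beta from the accepted frozen-neighbor mutations.

    ``beta_hat`` is the pooled fraction of accepted mutations at
    frozen-neighbor sites that produced G or C, with an exact
    (Clopper-Pearson) binomial confidence interval.  Raises when no
    qualifying mutation occurred.
    """
    qualifying = [
        s for s in simulated.truth.substitutions if s.frozen_neighbor
    ]
    if not qualifying:
        raise ValueError("no accepted mutations at frozen-neighbor sites")
    n = len(qualifying)
    k = sum(1 for s in qualifying if s.new_base in "GC")
    ci = binomtest(k, n).proportion_ci(
        confidence_level=confidence_level, method="exact"
    )
    return BetaEstimate(
        beta_hat=k / n,
        n=n,
        k=k,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        confidence_level=confidence_level,
    )
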