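"""GC/CpG composition, CpG cluster enrichment, motif and tandem-repeat scans.

CpG counting is single-strand and overlapping, on the sequence as given;
a CpG here is a C immediately 5' of a G.  ``N`` is excluded from both the
numerator and the denominator of the GC fraction and can never form part of
a counted CpG.  High local GC and CpG density is the composition signature
of silencer maturation in the locus this package models, so these counts
are first-class outputs rather than incidental statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .seqmodel import AnnotatedSequence


@dataclass(frozen=True)
class CompositionReport:
    length: int
    n_gc: int
    n_n: int
    n_cpg: int
    cpg_positions: tuple[int, ...]

    @property
    def gc_fraction(self) -> Optional[float]:
        """G+C over non-N bases; None for an all-N sequence."""
        denom = self.length - self.n_n
        return None if denom == 0 else self.n_gc / denom


def composition(seq: AnnotatedSequence) -> CompositionReport:
    """Exact GC and overlapping CpG counts for one sequence."""
    s = seq.residues
    cpg = tuple(
        i + 1 for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"
    )
    return CompositionReport(
        length=len(s),
        n_gc=sum(1 for c in s if c in "GC"),
        n_n=s.count("N"),
        n_cpg=len(cpg),
        cpg_positions=cpg,
    )


@dataclass(frozen=True)
class ClusterEnrichment:
    """How surprising is the observed CpG count for this composition?

    Two null models are provided.  ``binomial_tail`` treats the L-1
    dinucleotide start sites as independent Bernoulli trials with per-site
    CG probability ``p_hat = freq(C) * freq(G)`` (mononucleotide frequencies
    from the sequence itself) and reports P(X >= k).  ``shuffle_null``
    permutes the residues (exactly preserving mononucleotide counts) and
    reports the fraction of shuffles with at least the observed count.  The
    two agree when the independence approximation is adequate; for strongly
    skewed compositions the permutation null is the safer reference.
    """

    k_observed: int
    model: str
    p_hat: float
    p_value: float
    n_shuffles: Optional[int] = None
    seed: Optional[int] = None


def cpg_cluster_pvalue(
    seq: AnnotatedSequence,
    model: str = "binomial_tail",
    n_shuffles: int = 10_000,
    seed: Optional[int] = None,
) -> ClusterEnrichment:
    """Upper-tail p-value for the sequence's CpG count under a null model.

    ``seed`` is required for ``shuffle_null`` so every report is
    reproducible.  A sequence with no CpG has p-value 1 under both models.
    """
    s = seq.residues
    if len(s) < 2:
        raise ValueError("need at least 2 bases")
    k = composition(seq).n_cpg
    non_n = len(s) - s.count("N")
    p_hat = (
        (s.count("C") / non_n) * (s.count("G") / non_n) if non_n else 0.0
    )
    if model == "binomial_tail":
        p_value = float(stats.binom.sf(k - 1, len(s) - 1, p_hat))
        return ClusterEnrichment(
            k_observed=k, model=model, p_hat=p_hat, p_value=p_value
        )
    if model == "shuffle_null":
        if n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if seed is None:
            raise ValueError("shuffle_null requires a seed")
        rng = np.random.default_rng(seed)
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        c, g = ord("C"), ord("G")
        hits = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(arr)
            hits += int(np.sum((perm[:-1] == c) & (perm[1:] == g)) >= k)
        return ClusterEnrichment(
            k_observed=k,
            model=model,
            p_hat=p_hat,
            p_value=hits / n_shuffles,
            n_shuffles=n_shuffles,
            seed=seed,
        )
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int  # 1-based inclusive
    end: int
    matched_text: str


_TOKEN = re.compile(r"([ACGTN])(\{(\d+)(?:,(\d+))?\})?")


def _compile_pattern(pattern: str) -> str:
    """Compile the motif mini-language to a regex.

    The language is fixed letters over ACGTN with optional bounded repeats,
    e.g. ``TAAT T{2,6} GT`` (whitespace ignored).  Anything else is
    malformed.
    """
    compact = "".join(pattern.split()).upper()
    if not compact:
        raise ValueError("empty motif pattern")
    out = []
    pos = 0
    while pos < len(compact):
        m = _TOKEN.match(compact, pos)
        if m is None:
            raise ValueError(
                f"malformed motif pattern {pattern!r} at offset {pos}"
            )
        letter, _, lo, hi = m.groups()
        out.append(letter if letter != "N" else "[ACGT]")
        if lo is not None:
            if hi is not None and int(hi) < int(lo):
                raise ValueError(f"bad repeat bounds in {pattern!r}")
            out.append(m.group(2))
        pos = m.end()
    return "".join(out)


def motif_scan(seq: AnnotatedSequence, pattern: str) -> list[MotifHit]:
    """All (possibly overlapping) hits of ``pattern``, ascending by start.

    At each start position the longest match of the pattern is reported.
    """
    rx = re.compile(f"(?=({_compile_pattern(pattern)}))")
    hits = []
    for m in rx.finditer(seq.residues):
        text = m.group(1)
        start = m.start() + 1
        hits.append(
            MotifHit(
                pattern_id=pattern,
                start=start,
                end=start + len(text) - 1,
                matched_text=text,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemRepeat:
    """A maximal array of >= 2 adjacent copies of a repeat unit.

    Each copy is within ``max_mismatches_per_copy`` substitutions of the
    *first* copy (not a consensus), which keeps detection deterministic.
    Coordinates are 1-based inclusive.
    """

    unit: str
    n_copies: int
    start: int
    end: int
    max_mismatches_per_copy: int


def _mismatches(x: str, y: str) -> int:
    return sum(1 for a, b in zip(x, y) if a != b)


def tandem_repeat_scan(
    seq: AnnotatedSequence,
    min_unit: int = 4,
    max_mismatches_per_copy: int = 0,
    max_unit: Optional[int] = None,
) -> list[TandemRepeat]:
    """Maximal tandem arrays in ``seq``, sorted by start then unit length.

    An array anchored at start ``s`` with unit ``seq[s : s+u]`` is reported
    when it holds at least two adjacent copies, cannot be extended by a
    further full copy on the right, and the unit-length window immediately
    to the left is not itself a copy (left-maximality, so each array is
    reported once at its leftmost anchor).  Partial trailing copies are
    ignored.
    """
    if min_unit < 4:
        raise ValueError("min_unit must be >= 4")
    s = seq.residues
    n = len(s)
    top_unit = max_unit if max_unit is not None else n // 2
    found = []
    for u in range(min_unit, top_unit + 1):
        for start in range(0, n - 2 * u + 1):
            unit = s[start:start + u]
            # left-maximality: the window to the left must not be a copy
            if start - u >= 0 and _mismatches(s[start - u:start], unit) <= max_mismatches_per_copy:
                continue
            k = 1
            while (
                start + (k + 1) * u <= n
                and _mismatches(s[start + k * u:start + (k + 1) * u], unit)
                <= max_mismatches_per_copy
            ):
                k += 1
            if k >= 2:
                found.append(
                    TandemRepeat(
                        unit=unit,
                        n_copies=k,
                        start=start + 1,
                        end=start + k * u,
                        max_mismatches_per_copy=max_mismatches_per_copy,
                    )
                )
    return sorted(found, key=lambda r: (r.start, len(r.unit)))
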