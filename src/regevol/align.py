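"""Pairwise global alignment with affine gaps and percent identity.

A Needleman-Wunsch/Gotoh dynamic program over three states (match/mismatch,
gap in the second sequence, gap in the first).  A gap run of length ``L``
costs ``gap_open + (L - 1) * gap_extend``: the first gapped base is charged
the opening penalty, each further base the extension penalty.  Defaults
(match +5, mismatch -4, open 10, extend 0.5) follow the EDNAFULL convention
of the standard global-alignment tools.

Traceback is deterministic: at equal score the diagonal move is preferred,
then a gap in the second sequence, then a gap in the first.  ``N`` scores as
a mismatch against everything and never counts as identical.  Terminal gaps
are penalised by default (true global mode); ``end_gaps_free=True`` gives
semi-global behaviour for locating a short element inside a longer region.

Percent identity uses the full alignment length, gap columns included, as
its denominator (the convention of the cited pairwise tools); this is stated
in every report the package emits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqmodel import AnnotatedSequence

_NEG = float("-inf")
# state indices, also the traceback preference order
_M, _X, _Y = 0, 1, 2  # diagonal, gap-in-b (a base vs '-'), gap-in-a


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for :func:`global_align`."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not self.match > self.mismatch:
            raise ValueError("require match > mismatch")

    def score_pair(self, x: str, y: str) -> float:
        # N is unknown: never a match
        if x == y and x != "N":
            return self.match
        return self.mismatch


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of a pairwise global alignment."""

    gapped_a: str
    gapped_b: str
    score: float
    n_identical: int
    n_columns: int

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b) or self.n_columns < 1:
            raise ValueError("gapped rows must have equal positive length")

    @property
    def identity(self) -> float:
        """Fraction of identical columns over all columns, gaps included."""
        return self.n_identical / self.n_columns


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent identity of an alignment, reported to 0.1%."""
    return round(100.0 * aln.identity, 1)


def global_align(
    a: AnnotatedSequence | str,
    b: AnnotatedSequence | str,
    params: AlignmentParams | None = None,
    end_gaps_free: bool = False,
) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` against ``b``.

    Returns the maximum-score alignment under the affine gap model, with a
    deterministic traceback (diagonal, then gap-in-b, then gap-in-a at
    ties).  The input pair is canonicalised by sequence order before the
    dynamic program runs, so reported identity does not depend on argument
    order even when distinct optimal alignments tie on score.  With
    ``end_gaps_free`` the leading and trailing gap runs of either sequence
    are unpenalised and excluded from the score.
    """
    sa = a.residues if isinstance(a, AnnotatedSequence) else a.upper()
    sb = b.residues if isinstance(b, AnnotatedSequence) else b.upper()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignmentParams()
    if sa > sb:
        flipped = _align_core(sb, sa, params, end_gaps_free)
        return PairwiseAlignment(
            gapped_a=flipped.gapped_b,
            gapped_b=flipped.gapped_a,
            score=flipped.score,
            n_identical=flipped.n_identical,
            n_columns=flipped.n_columns,
        )
    return _align_core(sa, sb, params, end_gaps_free)


def _align_core(
    sa: str, sb: str, params: AlignmentParams, end_gaps_free: bool
) -> PairwiseAlignment:
    n, m = len(sa), len(sb)
    open_, ext = params.gap_open, params.gap_extend

    # score[s][i][j]: best score of an alignment of a[:i], b[:j] ending in
    # state s.  X consumes a base of a against a gap; Y the reverse.
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if end_gaps_free else -(open_ + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if end_gaps_free else -(open_ + (j - 1) * ext)

    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            s = params.score_pair(ai, sb[j - 1])
            row_m[j] = s + max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            row_x[j] = max(
                prev_m[j] - open_, prev_x[j] - ext, prev_y[j] - open_
            )
            row_y[j] = max(
                row_m[j - 1] - open_, row_x[j - 1] - open_, row_y[j - 1] - ext
            )

    def best_state(i: int, j: int) -> tuple[int, float]:
        cands = (M[i][j], X[i][j], Y[i][j])
        s = max(cands)
        return cands.index(s), s  # index() keeps the M > X > Y preference

    if end_gaps_free:
        # best cell on the last row/column; prefer (n, m), then fewer
        # trailing gaps in b, then fewer trailing gaps in a
        end_i, end_j = n, m
        state, best = best_state(n, m)
        for j in range(m - 1, -1, -1):
            st, sc = best_state(n, j)
            if sc > best:
                end_i, end_j, state, best = n, j, st, sc
        for i in range(n - 1, -1, -1):
            st, sc = best_state(i, m)
            if sc > best:
                end_i, end_j, state, best = i, m, st, sc
    else:
        end_i, end_j = n, m
        state, best = best_state(n, m)

    # traceback (recomputing each cell's argmax with the same tie order)
    cols_a: list[str] = []
    cols_b: list[str] = []
    # free trailing gaps
    cols_a.extend(reversed(sa[end_i:]))
    cols_b.extend("-" * (n - end_i))
    cols_a.extend("-" * (m - end_j))
    cols_b.extend(reversed(sb[end_j:]))

    def pick(cands: tuple[float, float, float]) -> int:
        # first index attaining the maximum: M > X > Y preference
        best_val = max(cands)
        return cands.index(best_val)

    i, j = end_i, end_j
    while i > 0 or j > 0:
        if state == _M:
            cols_a.append(sa[i - 1])
            cols_b.append(sb[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = pick((M[i][j], X[i][j], Y[i][j]))
        elif state == _X:
            cols_a.append(sa[i - 1])
            cols_b.append("-")
            i -= 1
            if j == 0:
                # boundary: remaining prefix of a against leading gaps
                cols_a.extend(reversed(sa[:i]))
                cols_b.extend("-" * i)
                i = 0
                break
            # candidates exactly as the fill computed X[i+1][j]
            state = pick(
                (M[i][j] - open_, X[i][j] - ext, Y[i][j] - open_)
            )
        else:  # _Y
            cols_a.append("-")
            cols_b.append(sb[j - 1])
            j -= 1
            if i == 0:
                cols_a.extend("-" * j)
                cols_b.extend(reversed(sb[:j]))
                j = 0
                break
            state = pick(
                (M[i][j] - open_, X[i][j] - open_, Y[i][j] - ext)
            )

    gapped_a = "".join(reversed(cols_a))
    gapped_b = "".join(reversed(cols_b))
    n_identical = sum(
        1
        for x, y in zip(gapped_a, gapped_b)
        if x == y and x not in "-N"
    )
    return PairwiseAlignment(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        score=best,
        n_identical=n_identical,
        n_columns=len(gapped_a),
    )
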