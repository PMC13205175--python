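"""Independent brute-force oracles used to validate the implementations.

Everything here recomputes results by exhaustive enumeration or naive
scanning, deliberately sharing no code with the package internals.
"""

from __future__ import annotations


def enumerate_alignment_scores(a, b, match, mismatch, gap_open, gap_extend,
                               end_gaps_free=False):
    """Yield the score of every global alignment of ``a`` and ``b``.

    An alignment is a sequence of moves: D (align a base of each), X (a
    base of ``a`` against a gap), Y (a base of ``b`` against a gap).  A gap
    run of length L costs ``gap_open + (L - 1) * gap_extend``; with
    ``end_gaps_free`` the leading and the trailing maximal gap runs cost
    nothing.
    """

    def score(moves):
        # split into runs, charge gap runs, optionally refund terminal runs
        total = 0.0
        i = j = 0
        runs = []  # (kind, length) in order
        for mv in moves:
            if runs and runs[-1][0] == mv and mv in "XY":
                runs[-1][1] += 1
            else:
                runs.append([mv, 1])
        for k, (kind, length) in enumerate(runs):
            if kind == "D":
                for _ in range(length):
                    x, y = a[i], b[j]
                    total += match if (x == y and x != "N") else mismatch
                    i += 1
                    j += 1
            else:
                if kind == "X":
                    i += length
                else:
                    j += length
                terminal = k == 0 or k == len(runs) - 1
                if not (end_gaps_free and terminal):
                    total -= gap_open + (length - 1) * gap_extend
        return total

    def walk(i, j, moves):
        if i == len(a) and j == len(b):
            yield score(moves)
            return
        if i < len(a) and j < len(b):
            yield from walk(i + 1, j + 1, moves + "D")
        if i < len(a):
            yield from walk(i + 1, j, moves + "X")
        if j < len(b):
            yield from walk(i, j + 1, moves + "Y")

    yield from walk(0, 0, "")


def best_alignment_score(a, b, match=5, mismatch=-4, gap_open=10,
                         gap_extend=0.5, end_gaps_free=False):
    return max(
        enumerate_alignment_scores(
            a, b, match, mismatch, gap_open, gap_extend, end_gaps_free
        )
    )


def naive_cpg_positions(s):
    return [i + 1 for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]


def naive_substring_hits(s, pattern):
    return [
        i + 1 for i in range(len(s) - len(pattern) + 1)
        if s[i:i + len(pattern)] == pattern
    ]


def naive_invariance(rows):
    """Column-by-column invariance flags for gapless equal-length rows.

    The first row is the reference; a position is invariant when every row
    carries the same base there and it is not N.
    """
    ref = rows[0]
    flags = []
    for col in range(len(ref)):
        base = ref[col]
        flags.append(
            base not in "-N"
            and all(r[col] == base for r in rows[1:])
        )
    return flags


def naive_maximal_runs(flags):
    """(start, end) 1-based inclusive maximal True runs via full scan."""
    runs = []
    n = len(flags)
    for i in range(n):
        for j in range(i, n):
            if all(flags[i:j + 1]) and (i == 0 or not flags[i - 1]) \
                    and (j == n - 1 or not flags[j + 1]):
                runs.append((i + 1, j + 1))
    return sorted(set(runs))


def naive_tandem_repeats(s, min_unit, max_mm):
    """Exhaustive search over all (start, unit length) anchor pairs."""
    def mm(x, y):
        return sum(1 for p, q in zip(x, y) if p != q)

    n = len(s)
    out = []
    for u in range(min_unit, n // 2 + 1):
        for start in range(0, n - 2 * u + 1):
            unit = s[start:start + u]
            if start - u >= 0 and mm(s[start - u:start], unit) <= max_mm:
                continue  # not the leftmost anchor
            k = 1
            while start + (k + 1) * u <= n and \
                    mm(s[start + k * u:start + (k + 1) * u], unit) <= max_mm:
                k += 1
            if k >= 2:
                out.append((start + 1, start + k * u, unit, k))
    return sorted(out)
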