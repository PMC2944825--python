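"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
exact integer arithmetic, sharing no code path with the implementation it
checks.
"""

from itertools import product
from math import comb

from domainsnp.io_formats import AMINO_ACIDS


# ---------------------------------------------------------------------------
# Pattern matching by exhaustive expansion enumeration
# ---------------------------------------------------------------------------

def pattern_expansion_count(pattern) -> int:
    """Number of concrete repeat-count assignments of a pattern."""
    n = 1
    for el in pattern.elements:
        n *= el.max_repeat - el.min_repeat + 1
    return n


def _vector_matches(pattern, vector, sequence, start0) -> int:
    """Length consumed if the repeat-count vector matches at ``start0``
    (0-based), else -1."""
    pos = start0
    for el, count in zip(pattern.elements, vector):
        for _ in range(count):
            if pos >= len(sequence) or not el.admits(sequence[pos]):
                return -1
            pos += 1
    return pos - start0


def brute_force_scan(pattern, sequence):
    """All match spans (1-based inclusive) by enumerating every concrete
    expansion of the pattern at every start.

    Per matching start the reported span comes from the lexicographically
    greatest feasible repeat vector in element order — the longest-first
    greedy resolution the scanner documents.
    """
    ranges = [
        range(el.max_repeat, el.min_repeat - 1, -1) for el in pattern.elements
    ]
    starts = [0] if pattern.n_anchor else range(len(sequence))
    spans = []
    for s in starts:
        chosen = None
        for vector in product(*ranges):  # lexicographically decreasing
            length = _vector_matches(pattern, vector, sequence, s)
            if length < 0 or length == 0:
                continue
            if pattern.c_anchor and s + length != len(sequence):
                continue
            chosen = (s + 1, s + length)
            break
        if chosen is not None:
            spans.append(chosen)
    return spans


# ---------------------------------------------------------------------------
# Profile alignment by exhaustive path enumeration
# ---------------------------------------------------------------------------

def brute_force_profile(scores, sequence, gap_open, gap_extend):
    """Best local profile alignment by enumerating every alignment path.

    ``scores`` is an L x 20 array-like; alignments start and end with a
    match, may insert sequence residues or delete profile positions in
    between (affine: each maximal run of one gap type costs
    ``gap_open + (run - 1) * gap_extend``), and score ties are broken
    toward the smallest start, then the smallest end.
    Returns ``(best_score, (start, end))``, 1-based inclusive.
    """
    L = len(scores)
    n = len(sequence)
    cols = [AMINO_ACIDS.index(aa) for aa in sequence]
    best = [None]  # (score, start, end)

    def consider(score, start, end):
        b = best[0]
        if (
            b is None
            or score > b[0]
            or (score == b[0] and (start < b[1] or (start == b[1] and end < b[2])))
        ):
            best[0] = (score, start, end)

    def walk(i, j, score, start, last):
        # i profile rows consumed, j sequence positions consumed (1-based)
        if last == "M":
            consider(score, start, j)
        if i < L and j < n:
            walk(i + 1, j + 1, score + scores[i][cols[j]], start, "M")
        if j < n and last is not None:
            cost = gap_extend if last == "I" else gap_open
            walk(i, j + 1, score + cost, start, "I")
        if i < L and last is not None:
            cost = gap_extend if last == "D" else gap_open
            walk(i + 1, j, score + cost, start, "D")

    for i0 in range(L):
        for j0 in range(n):
            walk(i0 + 1, j0 + 1, scores[i0][cols[j0]], j0 + 1, "M")
    return best[0][0], (best[0][1], best[0][2])


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by exact integer combinatorics
# ---------------------------------------------------------------------------

def exact_upper_tail(N, K, n, k) -> float:
    """P(X >= k) as a ratio of exact integers."""
    hi = min(n, K)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return num / comb(N, n)


def exact_tail_table(N, K, n):
    """P(X >= k) for every attainable k, as exact integer ratios."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    pmf = [comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)]
    denom = comb(N, n)
    out = {}
    suffix = 0
    for i in range(hi, lo - 1, -1):
        suffix += pmf[i - lo]
        out[i] = suffix / denom
    return out
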