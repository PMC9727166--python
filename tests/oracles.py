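"""Independent oracles used by the test suite.

These deliberately re-derive results with different algorithms/code paths
than the package: a pure-Python Gotoh dynamic program for local alignment
scores, a re-implementation of the documented greedy set-cover rule plus an
exhaustive minimum-cover search, and closed-form Welch t-test formulas.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {letter: i for i, letter in enumerate(_B62.alphabet)}


def _pair_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[_B62_INDEX[a], _B62_INDEX[b]])


def gotoh_local_score(query: str, target: str,
                      gap_open: int = 12, gap_extend: int = 1) -> float:
    """Smith–Waterman score with affine gaps via the three-matrix Gotoh DP.

    ``gap_open`` is the total cost of a length-1 gap (open 11 + extend 1).
    """
    m, n = len(query), len(target)
    NEG = -1e9
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (move along target)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _pair_score(query[i - 1], target[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def greedy_cover_oracle(predecessors: dict[str, set[str]],
                        lengths: dict[str, int]) -> list[tuple[str, frozenset[str]]]:
    """Re-implementation of the documented greedy rule on plain dicts.

    ``predecessors[v]`` is the set of nodes with a qualifying edge onto v
    (every node includes itself).  Returns (representative, members) in
    selection order.
    """
    uncovered = set(predecessors)
    out = []
    while uncovered:
        ranked = sorted(
            uncovered,
            key=lambda v: (
                -len((predecessors[v] | {v}) & uncovered),
                -lengths.get(v, 0),
                v,
            ),
        )
        rep = ranked[0]
        members = frozenset((predecessors[rep] | {rep}) & uncovered)
        uncovered -= members
        out.append((rep, members))
    return out


def minimum_cover_size(predecessors: dict[str, set[str]]) -> int:
    """Exhaustive minimum number of representative stars covering all nodes."""
    nodes = sorted(predecessors)
    universe = frozenset(nodes)
    sets = {v: frozenset(predecessors[v] | {v}) for v in nodes}
    for size in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, size):
            covered = frozenset().union(*(sets[v] for v in combo))
            if covered == universe:
                return size
    raise AssertionError("unreachable: singleton sets always cover")


def harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def welch_closed_form(a, b) -> tuple[float, float, float]:
    """Welch t, Welch–Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p
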