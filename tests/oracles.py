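"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the transport oracle
enumerates integer-valued transportation plans (contingency tables with
fixed margins) instead of solving a linear program, and the rank oracle
recomputes Spearman correlation as Pearson on average ranks from first
principles.
"""

from __future__ import annotations

from collections import Counter
from math import gcd
from typing import Sequence

import numpy as np


def _lcm(a: int, b: int) -> int:
    return a * b // gcd(a, b)


def min_cost_transport_enumeration(
    a_counts: Sequence[int], b_counts: Sequence[int], cost: np.ndarray
) -> float:
    """Exact optimum of the transportation problem between the normalized
    count distributions a_counts / sum and b_counts / sum.

    Margins are scaled to a common integer total; because the
    transportation polytope with integral margins has integral vertices,
    the best integer-valued plan attains the LP optimum. Plans are
    enumerated recursively cell by cell with cost pruning. Exponential —
    for tiny instances only.
    """
    a_counts = [int(v) for v in a_counts]
    b_counts = [int(v) for v in b_counts]
    total_a, total_b = sum(a_counts), sum(b_counts)
    scale = _lcm(total_a, total_b)
    rows = [v * (scale // total_a) for v in a_counts]
    cols = [v * (scale // total_b) for v in b_counts]
    m, n = len(rows), len(cols)
    cost = np.asarray(cost, dtype=float)
    best = [np.inf]

    def fill_row(i: int, j: int, row_rem: int, col_rem: list[int], acc: float):
        if acc >= best[0]:
            return
        if i == m:
            best[0] = acc
            return
        if j == n - 1:
            if row_rem <= col_rem[j]:
                col_rem[j] -= row_rem
                fill_row(i + 1, 0, rows[i + 1] if i + 1 < m else 0,
                         col_rem, acc + row_rem * cost[i, j])
                col_rem[j] += row_rem
            return
        for f in range(min(row_rem, col_rem[j]) + 1):
            col_rem[j] -= f
            fill_row(i, j + 1, row_rem - f, col_rem, acc + f * cost[i, j])
            col_rem[j] += f

    fill_row(0, 0, rows[0], cols, 0.0)
    return best[0] / scale


def wmd_enumeration_oracle(doc: Sequence[str], ref: Sequence[str],
                           vectors: dict[str, np.ndarray]) -> float:
    """Word mover's distance by exhaustive plan enumeration (tiny inputs)."""
    doc_counts = Counter(t for t in doc if t in vectors)
    ref_counts = Counter(t for t in ref if t in vectors)
    if not doc_counts or not ref_counts:
        return float("nan")
    dw, rw = sorted(doc_counts), sorted(ref_counts)
    cost = np.array([[np.linalg.norm(vectors[x] - vectors[y]) for y in rw]
                     for x in dw])
    return min_cost_transport_enumeration(
        [doc_counts[w] for w in dw], [ref_counts[w] for w in rw], cost
    )


def spearman_rank_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho as Pearson correlation of average ranks, from scratch."""

    def average_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # 1-based average rank
            i = j
        return ranks

    rx = average_ranks(np.asarray(x, dtype=float))
    ry = average_ranks(np.asarray(y, dtype=float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
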