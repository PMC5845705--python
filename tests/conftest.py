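"""Shared fixtures and independent oracle implementations.

Oracles here are deliberately naive (brute force / enumeration / closed
form) and independent of the library code paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata

from neurosync import synth
from neurosync.protocol import qc_protocol


# --------------------------------------------------------------------fixtures
@pytest.fixture(scope="session")
def sync_movie():
    """One synchronous 50-cell movie with baseline + K+ protocol (shared)."""
    protocol = qc_protocol()
    movie, gt = synth.simulate_recording(
        "synchronous", duration_s=640.0, n_cells=50, width_px=320, height_px=288,
        protocol=protocol, seed=11,
    )
    return movie, gt, protocol


# --------------------------------------------------------------------- oracles
def prominence_oracle(x: np.ndarray) -> list[tuple[int, float]]:
    """O(n^2) topographic prominence of every strict local maximum.

    For each peak, walk left and right until higher terrain (or the signal
    edge); the prominence is the peak height minus the higher of the two
    interval minima.
    """
    x = np.asarray(x, dtype=float)
    out = []
    for i in range(1, len(x) - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < len(x) and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        out.append((i, x[i] - max(left_min, right_min)))
    return out


def wilcoxon_exact_oracle(before, after) -> float:
    """Two-tailed signed-rank p by exhaustive sign-flip enumeration."""
    d = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    dist = np.array([np.sum(np.asarray(signs) * ranks) for signs in product([0, 1], repeat=n)])
    p_le = np.mean(dist <= w_plus)
    p_ge = np.mean(dist >= w_plus)
    return min(1.0, 2 * min(p_le, p_ge))


def assignment_oracle(cost: np.ndarray, cost_non_assignment: float) -> float:
    """Minimum total cost over every match/unmatch combination.

    Pairs costing more than the non-assignment cost are never linked; every
    unlinked row and column adds the non-assignment cost.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape

    def rec(row: int, free_cols: frozenset) -> float:
        if row == n:
            return cost_non_assignment * len(free_cols)
        best = cost_non_assignment + rec(row + 1, free_cols)  # row unmatched
        for j in free_cols:
            if cost[row, j] <= cost_non_assignment:
                best = min(best, cost[row, j] + rec(row + 1, free_cols - {j}))
        return best

    return rec(0, frozenset(range(m)))
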