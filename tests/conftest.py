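"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: Ward
merges by exhaustive minimal-variance search, hypergeometric tails by
explicit combinatorial sums, rank-sum p-values by enumeration, and the
log-rank statistic from the per-event-time hypergeometric moments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitosig.containers import ExpressionMatrix


# --------------------------------------------------------------- oracles


def ward_merge_sequence_bruteforce(points: np.ndarray) -> list[frozenset]:
    """Exhaustive Ward clustering: repeatedly merge the pair of clusters
    whose union minimizes the increase in total within-cluster sum of
    squares, Delta = |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2.
    Returns the merged member-sets in order.
    """
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            ca = points[list(a)].mean(axis=0)
            cb = points[list(b)].mean(axis=0)
            delta = len(a) * len(b) / (len(a) + len(b)) * float(((ca - cb) ** 2).sum())
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def scipy_merge_sequence(Z: np.ndarray, n: int) -> list[frozenset]:
    """Member-sets of each merge in a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (left, right, _, _) in enumerate(Z):
        merged = members[int(left)] | members[int(right)]
        members[n + step] = merged
        merges.append(merged)
    return merges


def hypergeom_upper_tail(x: int, M: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(M, K, n), by explicit summation."""
    total = math.comb(M, n)
    acc = 0
    for i in range(x, min(K, n) + 1):
        if n - i > M - K:
            continue
        acc += math.comb(K, i) * math.comb(M - K, n - i)
    return acc / total


def ranksum_p_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            count += 1
        total += 1
    return count / total


def logrank_two_group_oracle(times, events, groups) -> float:
    """Two-group log-rank chi-square from hypergeometric moments at each
    distinct event time (aggregated risk sets, standard tie handling)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (groups == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def fine_grid_auc(log_doses: np.ndarray, viability: np.ndarray, n_grid: int = 20001) -> float:
    """AUC oracle: dense-grid trapezoid over the linearly interpolated curve."""
    grid = np.linspace(log_doses[0], log_doses[-1], n_grid)
    return float(np.trapezoid(np.interp(grid, log_doses, viability), grid))


# --------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20231025)


@pytest.fixture
def small_expr():
    """6 cells x 4 genes with easy-to-reason-about values."""
    data = pd.DataFrame(
        {
            "g1": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "g2": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
            "g3": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            "g4": [0.0, 2.0, 0.0, 2.0, 0.0, 2.0],
        },
        index=[f"c{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)
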