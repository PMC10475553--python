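"""MultiSURF relief weights for binary feature matrices.

Relief-family algorithms weight features by contrasting their values
between near neighbors of the same class (hits) and of the opposite class
(misses): a feature that differs between near misses gains weight, one
that differs between near hits loses it.  MultiSURF replaces a fixed
neighbor count with an adaptive per-instance radius — instance j is "near"
target i when d(i, j) < T_i - D_i, where T_i is i's mean distance to all
other instances and the dead-band D_i is half their standard deviation.
This makes the algorithm sensitive to univariate effects as well as 2-way
and 3-way interactions without any neighbor-count parameter.

Every instance acts as a target (no sampling), so the weights are
deterministic given the data.  On binary features the distance is the
Hamming fraction, which coincides with the mean per-feature diff of the
discrete relief formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ProblemData

__all__ = ["ReliefWeights", "multisurf", "multisurf_naive"]


@dataclass
class ReliefWeights:
    """Per-feature MultiSURF weights.

    ``neighbor_definition`` records the convention used (threshold, strict
    inequality, dead-band, normalization) so results are comparable across
    implementations; ``n_isolated`` counts target instances with no near
    neighbor, which contribute nothing.
    """

    W: pd.Series
    n_instances: int
    n_isolated: int = 0
    neighbor_definition: dict = field(
        default_factory=lambda: {
            "radius": "T_i - D_i",
            "T": "mean pairwise distance of target i",
            "D": "half the (population) std of those distances",
            "near": "d_ij < T_i - D_i (strict)",
            "distance": "Hamming fraction",
            "normalization": "per target by near-hit / near-miss counts, then by n",
        }
    )

    def ranking(self) -> list[tuple[str, float]]:
        order = self.W.sort_values(ascending=False, kind="stable")
        return list(order.items())


def multisurf(problem: ProblemData) -> ReliefWeights:
    """MultiSURF weights for a binary classification problem (vectorized)."""
    X = problem.X.to_numpy(dtype=float)
    y = problem.y
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 instances")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    # pairwise Hamming fraction: mean |x_i - x_j| over features
    diff_counts = X @ (1.0 - X).T
    D = (diff_counts + diff_counts.T) / p

    W = np.zeros(p)
    n_isolated = 0
    same = y[:, None] == y[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    T = D.sum(axis=1) / (n - 1)
    for i in range(n):
        d = D[i]
        dev = d[off_diag[i]] - T[i]
        radius = T[i] - 0.5 * np.sqrt(np.mean(dev * dev))
        near = off_diag[i] & (d < radius)
        hits = near & same[i]
        misses = near & ~same[i]
        nh, nm = int(hits.sum()), int(misses.sum())
        if nh == 0 and nm == 0:
            n_isolated += 1
            continue
        diffs = np.abs(X - X[i])  # (n, p)
        if nh:
            W -= diffs[hits].sum(axis=0) / (n * nh)
        if nm:
            W += diffs[misses].sum(axis=0) / (n * nm)
    return ReliefWeights(
        W=pd.Series(W, index=problem.X.columns),
        n_instances=n,
        n_isolated=n_isolated,
    )


def multisurf_naive(X, y) -> np.ndarray:
    """Naive O(n^2 p) scalar-loop MultiSURF, kept as an independent oracle.

    Implements the same convention as :func:`multisurf` with explicit
    loops and no shared code path; used only in tests and sanity checks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for f in range(p):
                s += abs(X[i, f] - X[j, f])
            dist[i, j] = s / p
    W = np.zeros(p)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        t_i = sum(dist[i, j] for j in others) / len(others)
        var = sum((dist[i, j] - t_i) ** 2 for j in others) / len(others)
        radius = t_i - 0.5 * var ** 0.5
        hits = [j for j in others if dist[i, j] < radius and y[j] == y[i]]
        misses = [j for j in others if dist[i, j] < radius and y[j] != y[i]]
        for f in range(p):
            if hits:
                W[f] -= sum(abs(X[i, f] - X[j, f]) for j in hits) / (n * len(hits))
            if misses:
                W[f] += sum(abs(X[i, f] - X[j, f]) for j in misses) / (n * len(misses))
    return W
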