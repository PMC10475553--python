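"""Phi-coefficient association and collinearity screening.

The phi-coefficient of two binary variables is the Pearson correlation of
their 0/1 encodings, computable in closed form from the 2x2 contingency
table; its significance is assessed with the usual two-sided t-test for a
correlation coefficient.  The collinearity screen computes the full
pairwise phi matrix plus a variance inflation factor (VIF) per indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureTable

__all__ = ["PhiResult", "CollinearityReport", "phi", "collinearity"]


class ConstantVectorError(ValueError):
    """Raised when phi is requested for a constant (zero-variance) vector."""


@dataclass(frozen=True)
class PhiResult:
    r_phi: float
    p_value: float
    n: int


def phi(x, y) -> PhiResult:
    """Phi-coefficient of two binary vectors with a two-sided t-test.

    r = (n11 n00 - n10 n01) / sqrt(n1. n0. n.1 n.0), and the p-value comes
    from t = r sqrt((n-2) / (1-r^2)) against Student t with n-2 df.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (set(np.unique(x)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("inputs must be binary 0/1 vectors")
    if x.min() == x.max() or y.min() == y.max():
        raise ConstantVectorError("phi undefined for a constant vector")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    n1_, n0_ = n11 + n10, n01 + n00
    n_1, n_0 = n11 + n01, n10 + n00
    r = (n11 * n00 - n10 * n01) / math.sqrt(
        float(n1_) * float(n0_) * float(n_1) * float(n_0)
    )
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return PhiResult(r_phi=r, p_value=p, n=n)


@dataclass
class CollinearityReport:
    """Pairwise phi matrix, its p-values, and per-indicator VIF.

    VIF(f) = 1/(1 - R^2) from the least-squares regression of indicator f
    on all other indicators (with intercept); a perfectly collinear
    indicator is reported as +inf and flagged.
    """

    phi_matrix: pd.DataFrame
    p_value_matrix: pd.DataFrame
    vif: pd.Series

    @property
    def flagged(self) -> list[str]:
        return list(self.vif.index[~np.isfinite(self.vif)])

    def high_pairs(self, threshold: float = 0.5) -> list[tuple[str, str, float]]:
        """Feature pairs with |phi| above the report threshold."""
        cols = list(self.phi_matrix.columns)
        out = []
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                r = float(self.phi_matrix.at[a, b])
                if abs(r) >= threshold:
                    out.append((a, b, r))
        return sorted(out, key=lambda t: -abs(t[2]))


def _vif_one(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ConstantVectorError("VIF undefined for a constant column")
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def collinearity(table: FeatureTable) -> CollinearityReport:
    """Pairwise phi/p matrices and VIFs for every indicator column."""
    cols = table.feature_names
    if len(cols) < 2:
        raise ValueError("need at least two features")
    X = table.X.to_numpy(dtype=float)
    p = len(cols)
    phi_m = np.eye(p)
    pv_m = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            res = phi(X[:, i].astype(int), X[:, j].astype(int))
            phi_m[i, j] = phi_m[j, i] = res.r_phi
            pv_m[i, j] = pv_m[j, i] = res.p_value
    vif = pd.Series({c: _vif_one(X, j) for j, c in enumerate(cols)})
    return CollinearityReport(
        phi_matrix=pd.DataFrame(phi_m, index=cols, columns=cols),
        p_value_matrix=pd.DataFrame(pv_m, index=cols, columns=cols),
        vif=vif,
    )
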