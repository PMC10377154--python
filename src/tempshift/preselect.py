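"""Pre-selection of temporally dynamic genes by cubic-in-time regression.

Before the GP model comparison, real-data workflows keep only genes
whose expression changes with developmental time. Each gene is fitted by
ordinary least squares on {1, t, t^2, t^3} pooling all groups, and genes
with R^2 above a threshold (default 0.5) are retained. Constant-
expression genes have R^2 defined as 0 and are never retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["cubic_r2", "filter_dynamic_genes", "CubicTrendFilter"]


def cubic_r2(expression, time) -> float:
    """Coefficient of determination of an OLS cubic fit of expression on time.

    Requires at least 5 observations and a non-constant time vector;
    constant expression returns 0 by convention.
    """
    y = np.asarray(expression, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    if y.size != t.size:
        raise ValueError(f"{y.size} expression values for {t.size} times")
    if y.size < 5:
        raise ValueError(f"need >= 5 observations, got {y.size}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite expression or time values")
    if np.ptp(t) == 0:
        raise ValueError("constant time vector")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    # center/scale time for conditioning; R^2 is invariant to this
    ts = (t - t.mean()) / np.ptp(t)
    X = np.vander(ts, 4, increasing=True)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


def filter_dynamic_genes(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    r2_threshold: float = 0.5,
) -> tuple[list, pd.DataFrame]:
    """Retain genes whose cubic R^2 reaches the threshold.

    Returns the retained gene list and a per-gene table with columns
    ``r2`` and ``retained``. ``metadata`` must be indexed by sample and
    supply the ``time`` coordinate (already on the analysis scale, e.g.
    log2 of post-conceptional days).
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in [0, 1], got {r2_threshold}")
    missing = [c for c in expression.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    time = metadata.loc[list(expression.columns), "time"].to_numpy(dtype=float)

    r2s = {}
    for gene_id, row in expression.iterrows():
        vals = row.to_numpy(dtype=float)
        keep = np.isfinite(vals)
        r2s[gene_id] = cubic_r2(vals[keep], time[keep])
    table = pd.DataFrame({"r2": pd.Series(r2s)})
    table.index.name = "gene_id"
    # constant genes carry r2 == 0 from the convention and a threshold of 0
    # must still exclude them, so require positive variance via r2 > 0 there
    if r2_threshold == 0.0:
        table["retained"] = table["r2"] > 0.0
    else:
        table["retained"] = table["r2"] >= r2_threshold
    retained = [g for g in expression.index if table.loc[g, "retained"]]
    return retained, table


class CubicTrendFilter(SelectorMixin, BaseEstimator):
    """Feature selector keeping genes with a cubic time trend.

    X is (n_samples, n_genes); y is the per-sample time coordinate.
    After ``fit``, ``r2_`` holds per-gene R^2 and ``get_support()`` the
    retained mask, so the filter drops into sklearn pipelines ahead of
    downstream models.
    """

    def __init__(self, r2_threshold: float = 0.5):
        self.r2_threshold = r2_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_genes)")
        t = np.asarray(y, dtype=float).ravel()
        if t.size != X.shape[0]:
            raise ValueError("y (time) length must match n_samples")
        self.r2_ = np.array([cubic_r2(X[:, j], t) for j in range(X.shape[1])])
        if self.r2_threshold == 0.0:
            self.support_ = self.r2_ > 0.0
        else:
            self.support_ = self.r2_ >= self.r2_threshold
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
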