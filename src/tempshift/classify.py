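"""Three-way gene classification from the two log-likelihood ratios.

Two threshold modes are supported:

* fixed -- DiffShape if LLRshape < Lambda_shape; shift if
  LLRshape >= Lambda_shape and LLRshift > Lambda_shift; else no_shift
  (the multi-area analysis uses Lambda_shape = Lambda_shift = 50);
* adaptive -- cutoffs derived from the cohort's LLRshape distribution:
  DiffShape below mean - 2 sd, shift above the mean with
  LLRshift > 10 (the case/control analysis defaults).

Ties at a threshold resolve toward the less extreme class (no_shift).
LLRs are plain log-likelihood differences (no factor of 2); the
thresholds are interpreted on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import GeneResult

__all__ = [
    "assign_labels",
    "classify_fixed",
    "classify_adaptive",
    "label_frame",
    "LLRThresholdClassifier",
    "ClassificationThresholds",
]

LABELS = ("DiffShape", "shift", "no_shift", "unclassified")

DEFAULT_FIXED_SHAPE = 50.0
DEFAULT_FIXED_SHIFT = 50.0
DEFAULT_ADAPTIVE_SHIFT = 10.0


@dataclass(frozen=True)
class ClassificationThresholds:
    """Resolved cutoffs actually applied to a cohort."""

    mode: str
    shape_cutoff: float  # below -> DiffShape
    shape_gate: float  # at/above (fixed) or above (adaptive) -> shift eligible
    shift_cutoff: float  # LLRshift must exceed this for shift
    strict_gate: bool  # adaptive mode gates LLRshape strictly above the mean


def _resolve(mode, llr_shape, lambda_shape, lambda_shift) -> ClassificationThresholds:
    if mode == "fixed":
        if not (np.isfinite(lambda_shape) and np.isfinite(lambda_shift)):
            raise ValueError("fixed mode requires finite lambda_shape and lambda_shift")
        return ClassificationThresholds("fixed", lambda_shape, lambda_shape, lambda_shift, False)
    if mode == "adaptive":
        finite = llr_shape[np.isfinite(llr_shape)]
        if finite.size < 2:
            raise ValueError("adaptive mode needs >= 2 genes with defined LLRshape")
        m = float(finite.mean())
        s = float(finite.std(ddof=1))
        return ClassificationThresholds("adaptive", m - 2.0 * s, m, lambda_shift, True)
    raise ValueError(f"unknown mode {mode!r}")


def assign_labels(
    llr_shape,
    llr_shift,
    mode: str = "fixed",
    lambda_shape: float = DEFAULT_FIXED_SHAPE,
    lambda_shift: float | None = None,
) -> tuple[np.ndarray, ClassificationThresholds]:
    """Label genes from LLR arrays; NaN LLRs yield ``unclassified``."""
    llr_shape = np.asarray(llr_shape, dtype=float)
    llr_shift = np.asarray(llr_shift, dtype=float)
    if llr_shape.shape != llr_shift.shape:
        raise ValueError("LLR arrays must have equal shape")
    if lambda_shift is None:
        lambda_shift = DEFAULT_FIXED_SHIFT if mode == "fixed" else DEFAULT_ADAPTIVE_SHIFT
    thr = _resolve(mode, llr_shape, lambda_shape, lambda_shift)

    labels = np.full(llr_shape.shape, "no_shift", dtype=object)
    defined = np.isfinite(llr_shape) & np.isfinite(llr_shift)
    labels[~defined] = "unclassified"
    labels[defined & (llr_shape < thr.shape_cutoff)] = "DiffShape"
    if thr.strict_gate:
        gate = llr_shape > thr.shape_gate
    else:
        gate = llr_shape >= thr.shape_gate
    labels[defined & gate & (llr_shift > thr.shift_cutoff)] = "shift"
    return labels, thr


def _apply(results: list[GeneResult], labels) -> list[GeneResult]:
    for r, lab in zip(results, labels):
        r.label = str(lab)
    return results


def classify_fixed(
    results: list[GeneResult],
    lambda_shape: float = DEFAULT_FIXED_SHAPE,
    lambda_shift: float = DEFAULT_FIXED_SHIFT,
) -> list[GeneResult]:
    """Label results in place with fixed LLR thresholds; returns them."""
    shape = np.array([r.llr_shape for r in results], dtype=float)
    shift = np.array([r.llr_shift for r in results], dtype=float)
    labels, _ = assign_labels(shape, shift, "fixed", lambda_shape, lambda_shift)
    return _apply(results, labels)


def classify_adaptive(
    results: list[GeneResult],
    lambda_shift: float = DEFAULT_ADAPTIVE_SHIFT,
) -> list[GeneResult]:
    """Label results with cohort-adaptive LLRshape cutoffs."""
    shape = np.array([r.llr_shape for r in results], dtype=float)
    shift = np.array([r.llr_shift for r in results], dtype=float)
    labels, _ = assign_labels(shape, shift, "adaptive", lambda_shift=lambda_shift)
    return _apply(results, labels)


def label_frame(
    frame: pd.DataFrame,
    mode: str = "fixed",
    lambda_shape: float = DEFAULT_FIXED_SHAPE,
    lambda_shift: float | None = None,
) -> tuple[pd.DataFrame, ClassificationThresholds]:
    """Label a results table (columns ``llr_shape``, ``llr_shift``)."""
    labels, thr = assign_labels(
        frame["llr_shape"].to_numpy(),
        frame["llr_shift"].to_numpy(),
        mode,
        lambda_shape,
        lambda_shift,
    )
    out = frame.copy()
    out["label"] = labels
    return out, thr


class LLRThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper: fit resolves cutoffs, predict labels genes.

    X is (n_genes, 2) with columns [LLRshape, LLRshift]; ``fit`` computes
    the adaptive cutoffs from the cohort (a no-op for fixed mode) and
    ``predict`` returns the string labels.
    """

    def __init__(self, mode: str = "fixed", lambda_shape: float = DEFAULT_FIXED_SHAPE,
                 lambda_shift: float | None = None):
        self.mode = mode
        self.lambda_shape = lambda_shape
        self.lambda_shift = lambda_shift

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_genes, 2): LLRshape, LLRshift")
        lam = self.lambda_shift
        if lam is None:
            lam = DEFAULT_FIXED_SHIFT if self.mode == "fixed" else DEFAULT_ADAPTIVE_SHIFT
        self.thresholds_ = _resolve(self.mode, X[:, 0], self.lambda_shape, lam)
        self.classes_ = np.array(LABELS, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "thresholds_")
        X = np.asarray(X, dtype=float)
        thr = self.thresholds_
        labels = np.full(X.shape[0], "no_shift", dtype=object)
        defined = np.isfinite(X[:, 0]) & np.isfinite(X[:, 1])
        labels[~defined] = "unclassified"
        labels[defined & (X[:, 0] < thr.shape_cutoff)] = "DiffShape"
        gate = X[:, 0] > thr.shape_gate if thr.strict_gate else X[:, 0] >= thr.shape_gate
        labels[defined & gate & (X[:, 1] > thr.shift_cutoff)] = "shift"
        return labels
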