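"""Squared-exponential kernel and covariance assembly for the three
model structures compared per gene.

All three models share one latent Gaussian process with the squared-
exponential kernel k(t, t') = sigma_f^2 exp(-(t - t')^2 / (2 l^2)) and
i.i.d. Gaussian observation noise. They differ only in how observations
from different groups covary:

* ``independence`` -- each group is an unrelated draw: the covariance is
  block-diagonal (cross-group entries are exactly zero);
* ``no_shift`` -- all groups sample one shared trajectory at their raw
  times: the full kernel over the pooled time vector;
* ``shift`` -- groups share one trajectory shape but group i is evaluated
  at adjusted times x_i - dt_i (reference dt fixed at 0).
"""

from __future__ import annotations

import numpy as np

from .data import MODEL_KINDS, GroupedTimes, KernelParams

__all__ = ["sq_exp_kernel", "assemble_covariance", "adjusted_times"]

#: relative diagonal jitter (times sigma_f^2) added before factorization
JITTER_SCALE = 1e-8


def sq_exp_kernel(t1, t2, params: KernelParams):
    """Evaluate the squared-exponential kernel k(t1, t2).

    Broadcasts over array inputs; the observation-noise term is *not*
    included (it enters only on the diagonal of an assembled covariance).
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ValueError("kernel inputs must be finite")
    d = t1 - t2
    return params.sigma_f**2 * np.exp(-(d * d) / (2.0 * params.length_scale**2))


def adjusted_times(times: GroupedTimes, shifts: np.ndarray) -> np.ndarray:
    """Pooled time vector with each group's shift subtracted."""
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (times.n_groups,):
        raise ValueError(
            f"expected {times.n_groups} shifts, got shape {shifts.shape}"
        )
    if shifts[0] != 0.0:
        raise ValueError("the reference (first) group's shift must be 0")
    return times.pooled - shifts[times.codes]


def assemble_covariance(
    times: GroupedTimes,
    model_kind: str,
    params: KernelParams,
    shifts: np.ndarray | None = None,
    jitter_scale: float = JITTER_SCALE,
) -> np.ndarray:
    """Build the N x N observation covariance for one model structure.

    Parameters
    ----------
    times : GroupedTimes
        Per-group time vectors; N is the total number of observations.
    model_kind : {"independence", "no_shift", "shift"}
        Cross-group covariance structure (see module docstring).
    params : KernelParams
        Shared kernel hyperparameters (one triple across groups).
    shifts : array of shape (n_groups,), optional
        Per-group time shifts; required for the shift model (ignored for
        independence, and must be absent or all zero for no_shift).
    jitter_scale : float
        Diagonal jitter relative to ``sigma_f**2`` for numerical
        positive-definiteness.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if model_kind == "shift":
        if shifts is None:
            raise ValueError("the shift model requires a shift vector")
        u = adjusted_times(times, shifts)
    else:
        if model_kind == "no_shift" and shifts is not None and np.any(
            np.asarray(shifts) != 0.0
        ):
            raise ValueError("no_shift model takes zero shifts only")
        u = times.pooled

    S = sq_exp_kernel(u[:, None], u[None, :], params)
    if model_kind == "independence":
        codes = times.codes
        S = np.where(codes[:, None] == codes[None, :], S, 0.0)
    diag = params.noise_sd**2 + jitter_scale * params.sigma_f**2
    return S + diag * np.eye(times.n_total)
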