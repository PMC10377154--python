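"""Exact Gaussian-process marginal likelihood and its maximization.

The marginal likelihood of centered observations y under covariance K is

    log p(y) = -1/2 y' K^{-1} y - 1/2 log|K| - N/2 log(2 pi),

evaluated through a Cholesky factorization. Hyperparameters are optimized
on the log scale (log sigma_f, log l, log sigma) plus, for the shift
model, one raw time shift per non-reference group, with analytic
gradients (d logL / d theta = 1/2 tr[(a a' - K^{-1}) dK/d theta],
a = K^{-1} y) and L-BFGS-B. A deterministic ladder of length-scale
starting values spanning the observed time range guards against the
short-length-scale local optima a quasi-Newton search can fall into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .data import GeneSeries, KernelParams, ModelFit
from .kernels import JITTER_SCALE

__all__ = ["log_marginal_likelihood", "maximize_likelihood", "FitSettings"]

_LOG2PI = float(np.log(2.0 * np.pi))


def log_marginal_likelihood(y: np.ndarray, K: np.ndarray) -> float:
    """Gaussian log density of ``y`` under N(0, K) via Cholesky.

    Raises ``np.linalg.LinAlgError`` if K is not positive definite; callers
    assembling covariances should have added jitter first.
    """
    y = np.asarray(y, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError(f"K has shape {K.shape}, expected ({n}, {n})")
    L = np.linalg.cholesky(K)
    alpha = linalg.cho_solve((L, True), y, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * _LOG2PI)


@dataclass
class FitSettings:
    """Optimizer configuration for marginal-likelihood maximization.

    ``length_scale_fracs`` are multiplied by the observed time span to
    form the restart ladder of length-scale starting values; the largest
    (the full span) follows the advice to start smooth to avoid
    overfitting local optima. ``sigma_floor_frac`` floors the noise sd at
    a small fraction of the data standard deviation so the covariance
    stays well conditioned for noiseless inputs. ``shift_bound_factor``
    bounds each time shift at +/- factor * (pooled time span). The
    default keeps every group substantially overlapping the others: far
    beyond half a span shifts stop being identifiable — a slid-out group
    decouples and the likelihood rewards degenerate optima, and periodic
    trajectories alias at whole periods.
    """

    length_scale_fracs: tuple[float, ...] = (0.25, 0.5, 1.0)
    sigma_floor_frac: float = 1e-4
    jitter_scale: float = JITTER_SCALE
    shift_bound_factor: float = 0.6
    max_iter: int = 300
    gtol: float = 1e-6


def _nll_and_grad(theta, t, codes, y, kind, n_groups, jitter_scale):
    """Negative log marginal likelihood and gradient at theta.

    theta = [log sigma_f, log l, log sigma] (+ per-non-reference-group
    shifts for the shift model); y is centered.
    """
    n = y.size
    log_sf, log_l, log_s = theta[:3]
    sf2 = np.exp(2.0 * log_sf)
    l2 = np.exp(2.0 * log_l)
    s2 = np.exp(2.0 * log_s)

    if kind == "shift":
        full = np.concatenate(([0.0], theta[3:]))
        u = t - full[codes]
    else:
        u = t
    D = u[:, None] - u[None, :]
    S = sf2 * np.exp(-(D * D) / (2.0 * l2))
    if kind == "independence":
        S *= codes[:, None] == codes[None, :]
    jit = jitter_scale * sf2
    K = S + (s2 + jit) * np.eye(n)

    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    alpha = linalg.cho_solve((L, True), y, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * _LOG2PI

    Kinv = linalg.cho_solve((L, True), np.eye(n), check_finite=False)
    A = np.outer(alpha, alpha) - Kinv  # d logL/d theta = 1/2 sum(A * dK)

    grad = np.empty_like(theta)
    trA = float(np.trace(A))
    grad[0] = 0.5 * (2.0 * float(np.sum(A * S)) + 2.0 * jit * trA)
    grad[1] = 0.5 * float(np.sum(A * (S * (D * D) / l2)))
    grad[2] = 0.5 * 2.0 * s2 * trA
    if kind == "shift":
        M = S * D / l2
        for i in range(1, n_groups):
            e = (codes == i).astype(float)
            dK = M * e[:, None] - M * e[None, :]
            grad[3 + i - 1] = 0.5 * float(np.sum(A * dK))
    return -ll, -grad


def _nll_only(theta, t, codes, y, kind, n_groups, jitter_scale):
    """Negative log marginal likelihood without the gradient."""
    n = y.size
    sf2 = np.exp(2.0 * theta[0])
    l2 = np.exp(2.0 * theta[1])
    s2 = np.exp(2.0 * theta[2])
    if kind == "shift":
        full = np.concatenate(([0.0], theta[3:]))
        u = t - full[codes]
    else:
        u = t
    D = u[:, None] - u[None, :]
    S = sf2 * np.exp(-(D * D) / (2.0 * l2))
    if kind == "independence":
        S *= codes[:, None] == codes[None, :]
    K = S + (s2 + jitter_scale * sf2) * np.eye(n)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return np.inf
    alpha = linalg.cho_solve((L, True), y, check_finite=False)
    return 0.5 * float(y @ alpha) + float(np.sum(np.log(np.diag(L)))) + 0.5 * n * _LOG2PI


def _profile_shift_inits(t, codes, y, n_groups, sd, span, bound, l_fracs=(0.125, 0.25)):
    """Coarse per-group shift starting values from a pairwise profile scan.

    For each non-reference group, the shift is scanned over a coarse grid
    against the reference group alone (other groups excluded, points
    subsampled), under guessed hyperparameters. Joint quasi-Newton runs
    then start from the per-group argmins; this keeps multi-group fits out
    of aliased/misaligned local optima (e.g. periodic data shifted by a
    whole period). Fully deterministic.
    """

    def subsample(idx, cap=40):
        if idx.size <= cap:
            return idx
        order = idx[np.argsort(t[idx], kind="stable")]
        return order[np.linspace(0, idx.size - 1, cap).astype(int)]

    ref_idx = subsample(np.flatnonzero(codes == 0))
    grid = np.linspace(-bound, bound, 81)
    inits = []
    for l_frac in l_fracs:
        sf2 = sd * sd
        l2 = (l_frac * span) ** 2
        s2 = (0.25 * sd) ** 2 + 1e-8 * sf2
        dts = np.zeros(n_groups - 1)
        for i in range(1, n_groups):
            gi = subsample(np.flatnonzero(codes == i))
            tr, ti = t[ref_idx], t[gi]
            yy = np.concatenate((y[ref_idx], y[gi]))
            nlls = np.full(grid.size, np.inf)
            for k, dt in enumerate(grid):
                u = np.concatenate((tr, ti - dt))
                D = u[:, None] - u[None, :]
                K = sf2 * np.exp(-(D * D) / (2.0 * l2)) + s2 * np.eye(u.size)
                try:
                    L = np.linalg.cholesky(K)
                except np.linalg.LinAlgError:
                    continue
                a = linalg.cho_solve((L, True), yy, check_finite=False)
                nlls[k] = 0.5 * float(yy @ a) + float(np.sum(np.log(np.diag(L))))
            if np.isfinite(nlls).any():
                # near-minimal scan values are ties (aliased offsets);
                # start from the minimal-magnitude candidate
                tied = nlls <= nlls.min() + 2.0
                dts[i - 1] = float(grid[tied][np.argmin(np.abs(grid[tied]))])
        inits.append(
            np.concatenate(
                ([np.log(sd), np.log(l_frac * span), np.log(0.25 * sd)], dts)
            )
        )
    return inits


def maximize_likelihood(
    gene: GeneSeries,
    model_kind: str,
    settings: FitSettings | None = None,
    extra_inits: list[np.ndarray] | None = None,
) -> ModelFit:
    """Maximize one model's marginal likelihood for one gene.

    Expression is centered by its pooled mean before fitting (the GP is
    zero-mean); the mean is recorded on the returned fit for trajectory
    reconstruction. Failure of every restart is reported through the
    ``converged`` flag, never as an exception.
    """
    if settings is None:
        settings = FitSettings()
    if model_kind not in ("independence", "no_shift", "shift"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    gt = gene.times
    if model_kind in ("no_shift", "shift") and gt.n_groups < 2:
        raise ValueError(f"{model_kind} model requires at least 2 groups")

    t = gt.pooled
    codes = gt.codes
    y_raw = gene.pooled_values
    mu = float(y_raw.mean())
    y = y_raw - mu
    sd = float(y.std())
    sd_safe = sd if sd > 0 else 1.0
    span = float(t.max() - t.min())
    span_safe = span if span > 0 else 1.0
    floor = settings.sigma_floor_frac * sd_safe

    n_dt = gt.n_groups - 1 if model_kind == "shift" else 0
    log_sd = np.log(sd_safe)
    bounds = [
        (log_sd - 10.0, log_sd + 10.0),
        (np.log(span_safe) - 8.0, np.log(span_safe) + 4.0),
        (np.log(floor), np.log(10.0 * sd_safe)),
    ] + [(-settings.shift_bound_factor * span_safe,
          settings.shift_bound_factor * span_safe)] * n_dt

    inits = []
    for frac in settings.length_scale_fracs:
        x0 = np.concatenate(
            (
                [log_sd, np.log(frac * span_safe), np.log(max(0.25 * sd_safe, 1.5 * floor))],
                np.zeros(n_dt),
            )
        )
        inits.append(x0)
    search_bound = settings.shift_bound_factor * span_safe
    if model_kind == "shift" and sd > 0:
        inits.extend(
            _profile_shift_inits(t, codes, y, gt.n_groups, sd_safe, span_safe, search_bound)
        )
    for x0 in extra_inits or []:
        x0 = np.asarray(x0, dtype=float)
        if x0.size != 3 + n_dt:
            raise ValueError("extra init has wrong length")
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        inits.append(x0)

    best = None
    any_success = False
    for x0 in inits:
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(t, codes, y, model_kind, gt.n_groups, settings.jitter_scale),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": settings.max_iter, "gtol": settings.gtol},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success)
        any_success = any_success or bool(res.success)

    if model_kind == "shift" and best is not None:
        # Coordinate-profile polish: scan each shift over a coarse grid at
        # the joint optimum and re-optimize when a dominating basin appears.
        # Basins within TIE_NATS of the optimum are statistically tied (this
        # happens when shifts are identified only modulo a period); ties
        # resolve to the minimal-magnitude shift, the canonical
        # representative of an aliased offset.
        TIE_NATS = 4.0
        args = (t, codes, y, model_kind, gt.n_groups, settings.jitter_scale)
        grid = np.linspace(-search_bound, search_bound, 81)
        for _ in range(2):
            improved = False
            for j in range(n_dt):
                x = best.x.copy()
                nlls = np.empty(grid.size)
                for k, dt in enumerate(grid):
                    x[3 + j] = dt
                    nlls[k] = _nll_only(x, *args)
                finite = np.isfinite(nlls)
                if not finite.any():
                    continue
                gmin = float(nlls[finite].min())
                tied = finite & (nlls <= gmin + TIE_NATS)
                cand = float(grid[tied][np.argmin(np.abs(grid[tied]))])
                cur = float(best.x[3 + j])
                better_basin = gmin < best.fun - 1e-6
                smaller_tie = (
                    gmin <= best.fun + TIE_NATS
                    and abs(cand - cur) > 0.5
                    and abs(cand) < abs(cur) - 0.1
                )
                if not (better_basin or smaller_tie):
                    continue
                x = best.x.copy()
                if smaller_tie:
                    x[3 + j] = cand
                else:
                    x[3 + j] = float(grid[np.nanargmin(np.where(finite, nlls, np.inf))])
                res = optimize.minimize(
                    _nll_and_grad, x, args=args, method="L-BFGS-B", jac=True,
                    bounds=bounds,
                    options={"maxiter": settings.max_iter, "gtol": settings.gtol},
                )
                if not np.isfinite(res.fun):
                    continue
                strictly_better = res.fun < best.fun - 1e-6
                tied_smaller = (
                    res.fun <= best.fun + TIE_NATS
                    and np.abs(res.x[3:]).sum() < np.abs(best.x[3:]).sum() - 0.1
                )
                if strictly_better or tied_smaller:
                    best = res
                    best_success = bool(res.success)
                    improved = True
            if not improved:
                break

    if best is None:
        return ModelFit(
            kind=model_kind,
            log_likelihood=-np.inf,
            params=None,
            shifts=None,
            converged=False,
            n_restarts=len(inits),
            pooled_mean=mu,
        )

    x = best.x
    params = KernelParams(
        sigma_f=float(np.exp(x[0])),
        length_scale=float(np.exp(x[1])),
        noise_sd=float(np.exp(x[2])),
    )
    shifts = None
    if model_kind == "shift":
        shifts = np.concatenate(([0.0], x[3:]))
    return ModelFit(
        kind=model_kind,
        log_likelihood=float(-best.fun),
        params=params,
        shifts=shifts,
        converged=best_success,
        n_restarts=len(inits),
        pooled_mean=mu,
    )
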