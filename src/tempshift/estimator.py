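"""Scikit-learn style estimators.

``TempShiftGP`` is the per-gene model-comparison engine: given one gene's
samples (time, group) and expression values, it fits the independence,
no-shift and shift Gaussian-process models, exposes the two
log-likelihood ratios used for classification, and predicts the fitted
trajectory. ``LLRThresholdClassifier`` (in :mod:`tempshift.classify`) and
``CubicTrendFilter`` (in :mod:`tempshift.preselect`) cover the other
stages of the workflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import GeneSeries, GroupedTimes, ModelFit
from .gp import FitSettings, maximize_likelihood
from .kernels import sq_exp_kernel

__all__ = ["TempShiftGP"]


def _as_time_group(X):
    """Coerce X into (time array, group-label array)."""
    if isinstance(X, pd.DataFrame):
        if not {"time", "group"}.issubset(X.columns):
            raise ValueError("DataFrame X must have 'time' and 'group' columns")
        return X["time"].to_numpy(dtype=float), X["group"].to_numpy()
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be (n_samples, 2): time and group label")
    return X[:, 0].astype(float), X[:, 1]


class TempShiftGP(BaseEstimator):
    """Gaussian-process comparison of expression trajectories across groups.

    Fits up to three models of one gene's trajectories — groups unrelated
    (``independence``), one shared trajectory (``no_shift``), one shared
    shape with per-group time offsets (``shift``) — by exact GP marginal
    likelihood with a shared squared-exponential kernel, and reports

    * ``llr_shape_``: logL(shift) − logL(independence); very low values
      flag genuinely different trajectory shapes (DiffShape genes);
    * ``llr_shift_``: logL(shift) − logL(no_shift); high values flag real
      temporal offsets (shift genes);
    * ``shifts_``: the estimated per-group time shifts Δt (reference 0).

    Parameters
    ----------
    reference : hashable, optional
        Group label to use as the Δt = 0 reference. Default: the first
        group in order of appearance.
    models : tuple of str
        Which model structures to fit. LLRs requiring an unfitted model
        are left NaN.
    length_scale_fracs : tuple of float
        Restart ladder for the length-scale initial value as fractions of
        the observed time span.
    sigma_floor_frac, jitter_scale, shift_bound_factor, max_iter, gtol :
        Numerical controls; see :class:`tempshift.gp.FitSettings`.
    predict_model : str
        Which fitted model :meth:`predict` reconstructs.

    Examples
    --------
    >>> import numpy as np
    >>> t = np.linspace(5, 15, 30)
    >>> X = np.column_stack([np.r_[t, t], ["a"] * 30 + ["b"] * 30])
    >>> y = np.r_[np.sin(t), np.sin(t - 2)]
    >>> est = TempShiftGP().fit(X, y)
    >>> round(float(est.shifts_[1]), 1)
    2.0
    """

    def __init__(
        self,
        reference=None,
        models: tuple = ("independence", "no_shift", "shift"),
        length_scale_fracs: tuple = (0.25, 0.5, 1.0),
        sigma_floor_frac: float = 1e-4,
        jitter_scale: float = 1e-8,
        shift_bound_factor: float = 0.6,
        max_iter: int = 300,
        gtol: float = 1e-6,
        predict_model: str = "shift",
    ):
        self.reference = reference
        self.models = models
        self.length_scale_fracs = length_scale_fracs
        self.sigma_floor_frac = sigma_floor_frac
        self.jitter_scale = jitter_scale
        self.shift_bound_factor = shift_bound_factor
        self.max_iter = max_iter
        self.gtol = gtol
        self.predict_model = predict_model

    def _settings(self) -> FitSettings:
        return FitSettings(
            length_scale_fracs=tuple(self.length_scale_fracs),
            sigma_floor_frac=self.sigma_floor_frac,
            jitter_scale=self.jitter_scale,
            shift_bound_factor=self.shift_bound_factor,
            max_iter=self.max_iter,
            gtol=self.gtol,
        )

    def _build_series(self, X, y) -> GeneSeries:
        t, g = _as_time_group(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != t.size:
            raise ValueError(f"{y.size} values for {t.size} samples")
        labels = list(dict.fromkeys(g))  # order of appearance
        if self.reference is not None:
            ref = self.reference
            # group labels may arrive as strings through an object array
            if ref not in labels and str(ref) in [str(l) for l in labels]:
                ref = next(l for l in labels if str(l) == str(ref))
            if ref not in labels:
                raise ValueError(f"reference group {self.reference!r} not present")
            labels.remove(ref)
            labels.insert(0, ref)
        times, values = [], []
        for lab in labels:
            m = g == lab
            times.append(t[m])
            values.append(y[m])
        gt = GroupedTimes(labels, times)
        return GeneSeries("gene", gt, values)

    def fit(self, X, y):
        """Fit the requested GP models to one gene's samples.

        Parameters
        ----------
        X : array-like of shape (n_samples, 2) or DataFrame
            Sample time and group label (DataFrame columns ``time`` and
            ``group``).
        y : array-like of shape (n_samples,)
            Expression values (log scale).
        """
        for m in self.models:
            if m not in ("independence", "no_shift", "shift"):
                raise ValueError(f"unknown model {m!r}")
        series = self._build_series(X, y)
        if series.n_groups < 2:
            raise ValueError("at least two groups are required")
        settings = self._settings()

        fits = {}
        if "independence" in self.models:
            fits["independence"] = maximize_likelihood(series, "independence", settings)
        if "no_shift" in self.models:
            fits["no_shift"] = maximize_likelihood(series, "no_shift", settings)
        if "shift" in self.models:
            extra = []
            ns = fits.get("no_shift")
            if ns is not None and ns.params is not None:
                # warm start at the no-shift optimum with zero shifts so the
                # nested no-shift solution is always attainable
                extra.append(
                    np.concatenate(
                        (
                            np.log(
                                [
                                    ns.params.sigma_f,
                                    ns.params.length_scale,
                                    ns.params.noise_sd,
                                ]
                            ),
                            np.zeros(series.n_groups - 1),
                        )
                    )
                )
            fits["shift"] = maximize_likelihood(series, "shift", settings, extra_inits=extra)
            sf, ns = fits["shift"], fits.get("no_shift")
            if (
                ns is not None
                and ns.params is not None
                and sf.log_likelihood < ns.log_likelihood
            ):
                # the no-shift optimum with zero shifts is itself a valid
                # shift-model solution; adopting it keeps the nested-model
                # bound logL(shift) >= logL(no_shift) exact
                fits["shift"] = ModelFit(
                    kind="shift",
                    log_likelihood=ns.log_likelihood,
                    params=ns.params,
                    shifts=np.zeros(series.n_groups),
                    converged=ns.converged,
                    n_restarts=sf.n_restarts,
                    pooled_mean=ns.pooled_mean,
                )

        self.series_ = series
        self.groups_ = series.times.labels
        self.fits_ = fits
        self.log_likelihoods_ = {k: f.log_likelihood for k, f in fits.items()}
        ll = self.log_likelihoods_
        self.llr_shape_ = (
            ll["shift"] - ll["independence"]
            if {"shift", "independence"} <= ll.keys()
            else np.nan
        )
        self.llr_shift_ = (
            ll["shift"] - ll["no_shift"] if {"shift", "no_shift"} <= ll.keys() else np.nan
        )
        sf = fits.get("shift")
        self.shifts_ = sf.shifts.copy() if sf is not None and sf.shifts is not None else None
        self.kernel_params_ = sf.params if sf is not None else None
        self.converged_ = {k: f.converged for k, f in fits.items()}
        return self

    def predict(self, X):
        """Posterior-mean trajectory of ``predict_model`` at new samples.

        X carries (time, group) as in :meth:`fit`; prediction for a group
        uses that group's adjusted time under the fitted model.
        """
        check_is_fitted(self, "fits_")
        kind = self.predict_model
        fit = self.fits_.get(kind)
        if fit is None or fit.params is None:
            raise ValueError(f"model {kind!r} was not fitted")
        t_new, g_new = _as_time_group(X)
        series = self.series_
        gt = series.times
        label_index = {lab: i for i, lab in enumerate(gt.labels)}
        try:
            codes_new = np.array([label_index[g] for g in g_new])
        except KeyError as exc:
            raise ValueError(f"unknown group label {exc.args[0]!r}") from None

        shifts = (
            fit.shifts if fit.shifts is not None else np.zeros(gt.n_groups)
        )
        u_train = gt.pooled - shifts[gt.codes]
        u_new = t_new - shifts[codes_new]
        from .kernels import assemble_covariance

        K = assemble_covariance(gt, kind, fit.params, shifts=fit.shifts)
        Ks = sq_exp_kernel(u_new[:, None], u_train[None, :], fit.params)
        if kind == "independence":
            Ks = np.where(codes_new[:, None] == gt.codes[None, :], Ks, 0.0)
        y_c = series.pooled_values - fit.pooled_mean
        alpha = np.linalg.solve(K, y_c)
        return fit.pooled_mean + Ks @ alpha

    def score(self, X=None, y=None):
        """Maximized log marginal likelihood of the shift model."""
        check_is_fitted(self, "fits_")
        return self.log_likelihoods_.get("shift", np.nan)
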