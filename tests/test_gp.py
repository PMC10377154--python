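"""Marginal likelihood against a naive dense oracle, and optimizer behavior."""

import numpy as np
import pytest

from tempshift import (
    FitSettings,
    GeneSeries,
    GroupedTimes,
    KernelParams,
    assemble_covariance,
    log_marginal_likelihood,
    maximize_likelihood,
)
from tempshift.gp import _nll_and_grad


def naive_mvn_logpdf(y, K):
    """Explicit inverse/determinant Gaussian log-density (independent oracle)."""
    n = len(y)
    return float(
        -0.5 * y @ np.linalg.inv(K) @ y
        - 0.5 * np.log(np.linalg.det(K))
        - 0.5 * n * np.log(2 * np.pi)
    )


@pytest.mark.parametrize(
    "y,K,expected",
    [
        ([0.0], [[1.0]], -0.5 * np.log(2 * np.pi)),
        ([1.0], [[1.0]], -0.5 - 0.5 * np.log(2 * np.pi)),
    ],
)
def test_standard_normal_cases(y, K, expected):
    assert log_marginal_likelihood(np.array(y), np.array(K)) == pytest.approx(expected)


@pytest.mark.parametrize("n", [2, 5, 11, 20])
def test_matches_naive_dense_oracle(n, rng):
    t = np.sort(rng.uniform(0, 10, n))
    p = KernelParams(2.0, 1.5, 0.4)
    gt = GroupedTimes(["a"], [t])
    K = assemble_covariance(gt, "no_shift", p)
    y = rng.normal(0, 1, n)
    assert log_marginal_likelihood(y, K) == pytest.approx(naive_mvn_logpdf(y, K), abs=1e-8)


def test_gradient_matches_finite_differences(rng):
    t = np.sort(rng.uniform(5, 15, 12))
    t2 = np.sort(rng.uniform(5, 15, 10))
    gt = GroupedTimes(["a", "b"], [t, t2])
    y = rng.normal(0, 2, 22)
    y -= y.mean()
    theta = np.array([np.log(2.0), np.log(3.0), np.log(0.5), 1.3])
    f0, g0 = _nll_and_grad(theta, gt.pooled, gt.codes, y, "shift", 2, 1e-8)
    for j in range(theta.size):
        h = 1e-6
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fp, _ = _nll_and_grad(tp, gt.pooled, gt.codes, y, "shift", 2, 1e-8)
        fm, _ = _nll_and_grad(tm, gt.pooled, gt.codes, y, "shift", 2, 1e-8)
        assert g0[j] == pytest.approx((fp - fm) / (2 * h), rel=1e-4, abs=1e-6)


def _duplicated_gene(rng, n=25):
    t = np.sort(rng.uniform(5, 15, n))
    y = np.sin(2 * np.pi * t / 10) + rng.normal(0, 0.2, n)
    gt = GroupedTimes(["a", "b"], [t, t.copy()])
    return GeneSeries("dup", gt, [y, y.copy()])


def test_duplicated_groups_give_zero_shift(rng):
    """Two identical copies of the same data: dt ~ 0, shift == no-shift fit."""
    from tempshift import fit_gene

    gene = _duplicated_gene(rng)
    res = fit_gene(gene)
    assert abs(res.shifts[1]) < 0.05
    assert res.llr_shift == pytest.approx(0.0, abs=0.05)
    assert res.llr_shift >= -1e-3


def test_nesting_shift_dominates_no_shift(rng):
    """The no-shift model is the dt=0 restriction of the shift model, so
    LLRshift can never be materially negative."""
    from tempshift import fit_gene

    for _ in range(3):
        n = 20
        ta, tb = np.sort(rng.uniform(5, 15, n)), np.sort(rng.uniform(5, 15, n))
        ya = rng.normal(0, 1, n)
        yb = rng.normal(0, 1, n)
        gene = GeneSeries("g", GroupedTimes(["a", "b"], [ta, tb]), [ya, yb])
        res = fit_gene(gene)
        assert res.llr_shift >= -1e-3


def test_optimizer_matches_grid_search_oracle(rng):
    """With hyperparameters held fixed, the optimizer's dt agrees with a
    dense grid search over the shift."""
    n = 15
    ta = np.sort(rng.uniform(5, 15, n))
    tb = np.sort(rng.uniform(5, 15, n))
    true_dt = 1.4
    f = lambda t: np.sin(2 * np.pi * t / 10)
    ya = f(ta) + rng.normal(0, 0.1, n)
    yb = f(tb - true_dt) + rng.normal(0, 0.1, n)
    gene = GeneSeries("g", GroupedTimes(["a", "b"], [ta, tb]), [ya, yb])
    fit = maximize_likelihood(gene, "shift")
    p = fit.params
    y = gene.pooled_values - gene.pooled_values.mean()

    theta_base = np.log([p.sigma_f, p.length_scale, p.noise_sd])
    grid = np.arange(-10.0, 10.0 + 1e-9, 0.01)
    nlls = [
        _nll_and_grad(
            np.r_[theta_base, dt], gene.times.pooled, gene.times.codes, y, "shift", 2, 1e-8
        )[0]
        for dt in grid
    ]
    dt_grid = grid[int(np.argmin(nlls))]
    assert fit.shifts[1] == pytest.approx(dt_grid, abs=0.011)


def test_translation_equivariance(rng):
    """Shifting every time of the non-reference group by delta moves its
    estimated dt by delta and leaves the maximized likelihood unchanged."""
    n = 20
    ta, tb = np.sort(rng.uniform(5, 15, n)), np.sort(rng.uniform(5, 15, n))
    f = lambda t: np.sin(2 * np.pi * t / 10)
    ya = f(ta) + rng.normal(0, 0.1, n)
    yb = f(tb - 1.0) + rng.normal(0, 0.1, n)
    gene = GeneSeries("g", GroupedTimes(["a", "b"], [ta, tb]), [ya, yb])
    fit0 = maximize_likelihood(gene, "shift")

    delta = 1.5
    gene2 = GeneSeries("g", GroupedTimes(["a", "b"], [ta, tb + delta]), [ya, yb])
    fit1 = maximize_likelihood(gene2, "shift")
    assert fit1.shifts[1] - fit0.shifts[1] == pytest.approx(delta, abs=0.02)
    assert fit1.log_likelihood == pytest.approx(fit0.log_likelihood, abs=0.05)


def test_failed_fit_is_flagged_not_raised():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    gene = GeneSeries(
        "flat", GroupedTimes(["a", "b"], [t, t]), [np.zeros(4), np.zeros(4)]
    )
    fit = maximize_likelihood(gene, "shift", FitSettings(max_iter=2))
    assert isinstance(fit.converged, bool)  # flagged, no exception


def test_log_marginal_likelihood_shape_mismatch():
    with pytest.raises(ValueError):
        log_marginal_likelihood(np.zeros(3), np.eye(2))
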