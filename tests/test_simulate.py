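"""Generator correctness: reproducibility, closed-form signals, kernel
covariance convergence, and residual-variance accounting."""

import numpy as np
import pytest

from tempshift import (
    KernelParams,
    SimulationSpec,
    mspe,
    residual_variance_fraction,
    residual_variance_summary,
    simulate,
    simulate_cohort,
    simulate_gp,
    simulate_periodic,
    simulate_polynomial,
)
from tempshift.simulate import cohort_to_tables, true_shift_matrix


def test_same_seed_is_byte_reproducible():
    spec = SimulationSpec(generator="gp", model="shift", n_genes=3, n_points=20, seed=11)
    a, b = simulate(spec), simulate(spec)
    for ga, gb in zip(a, b):
        assert np.array_equal(ga.series.pooled_values, gb.series.pooled_values)
        assert np.array_equal(ga.true_shifts, gb.true_shifts)
        assert all(np.array_equal(x, y) for x, y in zip(ga.noise, gb.noise))


def test_generator_dispatch_validates():
    spec = SimulationSpec(generator="gp", n_genes=1, n_points=5, seed=0)
    with pytest.raises(ValueError):
        simulate_periodic(spec)
    with pytest.raises(ValueError):
        simulate_polynomial(spec)
    assert len(simulate_gp(spec)) == 1
    with pytest.raises(ValueError):
        SimulationSpec(generator="periodic", model="independence")
    with pytest.raises(ValueError):
        SimulationSpec(generator="nope")
    with pytest.raises(ValueError):
        SimulationSpec(n_groups=1)


def test_noiseless_no_shift_groups_coincide():
    """With zero noise a pooled no-shift draw on a shared grid is one
    function: both groups carry identical values."""
    spec = SimulationSpec(
        generator="gp",
        model="no_shift",
        n_genes=2,
        n_points=15,
        kernel=KernelParams(5.0, 3.0, 1e-12),
        seed=21,
    )
    genes = simulate(spec)
    grid = genes[0].series.times.times[0]
    spec_times = [grid, grid.copy()]
    genes = simulate(spec, times=spec_times)
    for g in genes:
        va, vb = g.series.values
        # identical up to the tiny sampling jitter (1e-10 sigma_f^2)
        assert np.allclose(va, vb, atol=1e-3)


def test_periodic_signal_closed_form():
    spec = SimulationSpec(
        generator="periodic", model="no_shift", n_genes=1, n_points=5, seed=3,
        periodic_noise_sd=1e-12,
    )
    genes = simulate(spec, times=[np.array([2.5] * 5), np.array([2.5] * 5)])
    assert np.allclose(genes[0].series.values[0], 1.0, atol=1e-9)  # sine peak


def test_polynomial_signal_closed_form():
    spec = SimulationSpec(
        generator="polynomial", model="no_shift", n_genes=1, n_points=5, seed=3,
        poly_noise_sd=1e-12,
    )
    t = np.array([10.0, 12.0, 10.0, 12.0, 10.0])
    genes = simulate(spec, times=[t, t])
    assert np.allclose(genes[0].series.values[0], [0.0, 7.0, 0.0, 7.0, 0.0], atol=1e-9)


def test_gp_draws_match_kernel_covariance():
    """Monte-Carlo covariance of many draws at two fixed times converges
    to the closed-form kernel value (3 standard errors at 10^4 draws)."""
    n_draws = 10_000
    spec = SimulationSpec(
        generator="gp", model="no_shift", n_groups=2, n_genes=n_draws, n_points=2,
        kernel=KernelParams(5.0, 3.0, 1e-12), seed=99,
    )
    t = np.array([7.0, 9.0])
    genes = simulate(spec, times=[t, t])
    vals = np.vstack([g.series.values[0] for g in genes])
    emp = np.cov(vals.T)
    k = KernelParams(5.0, 3.0, 0.0)
    from tempshift import sq_exp_kernel

    expected = sq_exp_kernel(t[:, None], t[None, :], k)
    # var of a sample covariance of bivariate normals ~ (k11*k22 + k12^2)/n
    for i in range(2):
        for j in range(2):
            se = np.sqrt((expected[i, i] * expected[j, j] + expected[i, j] ** 2) / n_draws)
            assert abs(emp[i, j] - expected[i, j]) < 3 * se


def test_three_group_shift_scheme():
    spec = SimulationSpec(generator="gp", model="shift", n_groups=3, n_genes=200,
                          n_points=4, seed=12)
    shifts = true_shift_matrix(simulate(spec))
    assert np.all(shifts[:, 0] == 0.0)
    assert shifts[:, 1].mean() == pytest.approx(2.0, abs=0.3)
    assert shifts[:, 2].mean() == pytest.approx(-2.0, abs=0.3)
    assert shifts[:, 1].std() == pytest.approx(1.0, abs=0.25)


def test_mspe_arithmetic():
    assert mspe([2.0, 2.0], [2.0, 2.0]) == 0.0
    assert mspe([2.1, 1.9], [2.0, 2.0]) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        mspe([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        mspe([], [])


def test_residual_fraction_trivial_cases(rng):
    spec = SimulationSpec(generator="periodic", model="no_shift", n_genes=1,
                          n_points=30, periodic_noise_sd=1e-15, seed=5)
    noiseless = simulate(spec)[0]
    assert residual_variance_fraction(noiseless) == pytest.approx(0.0, abs=1e-12)

    # pure-noise gene: flat signal via a tiny-amplitude GP
    spec = SimulationSpec(generator="gp", model="no_shift", n_genes=1, n_points=30,
                          kernel=KernelParams(1e-9, 3.0, 0.5), seed=6)
    assert residual_variance_fraction(simulate(spec)[0]) == pytest.approx(1.0, abs=1e-4)


def test_periodic_residual_fraction_matches_analytic():
    """sin over one full period has variance 1/2, noise variance 0.09, so
    the residual fraction is ~0.09/0.59 ~ 15.3%."""
    spec = SimulationSpec(generator="periodic", model="no_shift", n_genes=200, seed=7)
    s = residual_variance_summary(simulate(spec))
    assert s["mean"] == pytest.approx(0.09 / 0.59, abs=0.02)


def test_polynomial_residual_fraction_matches_analytic():
    """Var(b u) = b^2 25/3, Var(c u^2) = c^2 500/9 for u ~ U(-5,5):
    fraction ~ 9/83.3 ~ 10.8%."""
    spec = SimulationSpec(generator="polynomial", model="no_shift", n_genes=200, seed=8)
    s = residual_variance_summary(simulate(spec))
    assert s["mean"] == pytest.approx(9.0 / (9.0 + 18.75 + 500.0 / 9.0), abs=0.02)


def test_cohort_tables_round_structure():
    spec = SimulationSpec(generator="periodic", model="shift", n_genes=3, n_points=8, seed=13)
    genes, times = simulate_cohort(spec, ["no_shift", "shift"])
    expr, meta, truth = cohort_to_tables(genes)
    assert expr.shape == (6, 16)
    assert list(meta.columns) == ["group", "time"]
    assert set(truth["model"]) == {"no_shift", "shift"}
    assert (truth.loc[truth["model"] == "no_shift", "dt_group2"] == 0).all()
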