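"""Per-gene orchestration, the sklearn estimator surface, and table fits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from tempshift import (
    GeneSeries,
    GroupedTimes,
    TempShiftGP,
    fit_gene,
    fit_table,
    results_to_frame,
)


def test_estimator_recovers_known_shift(two_group_sine):
    X, y = two_group_sine
    est = TempShiftGP().fit(X, y)
    assert est.groups_ == ("a", "b")
    assert est.shifts_[0] == 0.0
    assert est.shifts_[1] == pytest.approx(2.0, abs=0.25)
    assert est.llr_shift_ > 10
    assert np.isfinite(est.llr_shape_)


def test_estimator_reference_reorders_groups(two_group_sine):
    X, y = two_group_sine
    est = TempShiftGP(reference="b", models=("no_shift", "shift")).fit(X, y)
    assert est.groups_ == ("b", "a")
    # with b as reference, a leads by ~2
    assert est.shifts_[1] == pytest.approx(-2.0, abs=0.25)


def test_estimator_predict_tracks_trajectory(two_group_sine):
    X, y = two_group_sine
    est = TempShiftGP(models=("no_shift", "shift")).fit(X, y)
    t = np.linspace(6, 14, 25)
    pred_a = est.predict(pd.DataFrame({"time": t, "group": "a"}))
    assert np.corrcoef(pred_a, np.sin(2 * np.pi * t / 10))[0, 1] > 0.99
    # group b's trajectory is group a's delayed by the fitted shift
    pred_b = est.predict(pd.DataFrame({"time": t + est.shifts_[1], "group": "b"}))
    assert np.allclose(pred_a, pred_b, atol=1e-6)


def test_estimator_is_cloneable_and_validates(two_group_sine):
    X, y = two_group_sine
    est = TempShiftGP(reference="a", max_iter=50)
    est2 = clone(est)
    assert est2.get_params()["reference"] == "a"
    with pytest.raises(ValueError):
        TempShiftGP(models=("bogus",)).fit(X, y)
    with pytest.raises(ValueError):
        TempShiftGP(reference="missing").fit(X, y)
    with pytest.raises(ValueError):
        TempShiftGP().fit(X.assign(group="a"), y)  # single group


def test_fit_gene_requires_two_groups(rng):
    t = np.sort(rng.uniform(5, 15, 10))
    gene = GeneSeries("g", GroupedTimes(["a"], [t]), [rng.normal(size=10)])
    with pytest.raises(ValueError):
        fit_gene(gene)


def _toy_table(rng, n_genes=4, n=12, with_na=False):
    ta = np.sort(rng.uniform(5, 15, n))
    tb = np.sort(rng.uniform(5, 15, n))
    samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"group": ["a"] * n + ["b"] * n, "time": np.r_[ta, tb]},
        index=pd.Index(samples, name="sample"),
    )
    rows = {}
    for j in range(n_genes):
        f = lambda t: np.sin(2 * np.pi * (t - j) / 10)
        rows[f"gene{j}"] = np.r_[
            f(ta) + rng.normal(0, 0.1, n), f(tb - 1.0) + rng.normal(0, 0.1, n)
        ]
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    if with_na:
        expr.iloc[0, 0] = np.nan
    return expr, meta


def test_fit_table_preserves_order_and_reference(rng):
    expr, meta = _toy_table(rng)
    results = fit_table(expr, meta, settings={"models": ("no_shift", "shift")})
    assert [r.gene for r in results] == list(expr.index)
    for r in results:
        assert r.shifts[0] == 0.0
        assert r.llr_shift >= -1e-3


def test_fit_table_empty_gene_set(rng):
    expr, meta = _toy_table(rng)
    assert fit_table(expr.iloc[:0], meta) == []


def test_fit_table_missing_metadata_errors(rng):
    expr, meta = _toy_table(rng)
    with pytest.raises(ValueError, match="a0"):
        fit_table(expr, meta.drop(index="a0"))


def test_fit_table_drops_missing_values_per_gene(rng):
    expr, meta = _toy_table(rng, with_na=True)
    results = fit_table(expr, meta, settings={"models": ("no_shift", "shift")})
    assert "dropped 1 missing" in results[0].note
    assert np.isfinite(results[0].llr_shift)


def test_fit_table_skips_underpopulated_groups(rng):
    expr, meta = _toy_table(rng)
    expr.loc["gene0", meta.index[meta["group"] == "a"][:-2]] = np.nan  # 2 left in a
    results = fit_table(expr, meta, settings={"models": ("no_shift", "shift")})
    assert results[0].label == "unclassified"
    assert np.isnan(results[0].llr_shift)


def test_results_frame_layout(rng):
    expr, meta = _toy_table(rng, n_genes=2)
    frame = results_to_frame(fit_table(expr, meta))
    for col in ["gene_id", "llr_shape", "llr_shift", "dt_b", "label", "converged"]:
        assert col in frame.columns
    assert list(frame["gene_id"]) == list(expr.index)


def test_fit_table_is_deterministic(rng):
    expr, meta = _toy_table(rng, n_genes=2)
    f1 = results_to_frame(fit_table(expr, meta, settings={"models": ("no_shift", "shift")}))
    f2 = results_to_frame(fit_table(expr, meta, settings={"models": ("no_shift", "shift")}))
    pd.testing.assert_frame_equal(f1, f2)
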