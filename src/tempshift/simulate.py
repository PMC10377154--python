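"""Benchmark generators with known ground-truth time shifts.

Three data families mirror the simulation study conditions:

* ``gp`` -- multivariate-normal draws from the squared-exponential
  kernel covariance (amplitude 5, length scale 3) under each of the
  three generating structures, plus i.i.d. Gaussian noise (sd 0.5 or 1);
* ``periodic`` -- y = sin(2 pi (x - dt) / 10) + noise (sd 0.3, about
  15% of total variance);
* ``polynomial`` -- y = a + b (u - 10) + c (u - 10)^2 with u = x - dt
  and noise sd 3 (about 10% of total variance with a=0, b=1.5, c=1).

Each group's 100 time points are drawn uniform on [5, 15]; the grid is
drawn once per scenario per group and shared across that scenario's
genes (per-gene redraw available via ``redraw_times_per_gene``). The
two-group true shift is fixed at 2; three-group shifts are drawn per
gene from N(2, 1) for group 2 and N(-2, 1) for group 3. Noise
realizations are retained on each :class:`SimulatedGene` so the
generator's residual-variance fraction can be computed exactly.
"""

from __future__ import annotations

import numpy as np

from .data import GeneSeries, GroupedTimes, SimulatedGene, SimulationSpec
from .kernels import sq_exp_kernel

__all__ = [
    "simulate",
    "simulate_gp",
    "simulate_periodic",
    "simulate_polynomial",
    "simulate_cohort",
    "cohort_to_tables",
    "mspe",
    "residual_variance_fraction",
    "residual_variance_summary",
    "true_shift_matrix",
    "estimated_shift_matrix",
]


def _group_labels(n_groups: int) -> list[str]:
    return [f"group{i + 1}" for i in range(n_groups)]


def _draw_times(rng: np.random.Generator, spec: SimulationSpec) -> list[np.ndarray]:
    lo, hi = spec.time_range
    return [np.sort(rng.uniform(lo, hi, spec.n_points)) for _ in range(spec.n_groups)]


def _draw_shifts(rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    """One true shift vector (reference first, fixed at 0)."""
    if spec.model != "shift":
        return np.zeros(spec.n_groups)
    shifts = np.zeros(spec.n_groups)
    if spec.n_groups == 2:
        shifts[1] = spec.two_group_shift
    else:
        for i in range(1, spec.n_groups):
            mean = spec.shift_means[(i - 1) % len(spec.shift_means)]
            shifts[i] = rng.normal(mean, spec.shift_sd)
    return shifts


def _gp_signal(rng, spec, times, shifts) -> list[np.ndarray]:
    u = [t - dt for t, dt in zip(times, shifts)]
    if spec.model == "independence":
        out = []
        for ui in u:
            K = sq_exp_kernel(ui[:, None], ui[None, :], spec.kernel)
            K += 1e-10 * spec.kernel.sigma_f**2 * np.eye(ui.size)
            out.append(np.linalg.cholesky(K) @ rng.standard_normal(ui.size))
        return out
    pooled = np.concatenate(u)
    K = sq_exp_kernel(pooled[:, None], pooled[None, :], spec.kernel)
    K += 1e-10 * spec.kernel.sigma_f**2 * np.eye(pooled.size)
    f = np.linalg.cholesky(K) @ rng.standard_normal(pooled.size)
    return list(np.split(f, np.cumsum([t.size for t in times])[:-1]))


def _periodic_signal(rng, spec, times, shifts) -> list[np.ndarray]:
    return [
        np.sin(2.0 * np.pi * (t - dt) / spec.periodic_period)
        for t, dt in zip(times, shifts)
    ]


def _polynomial_signal(rng, spec, times, shifts) -> list[np.ndarray]:
    a, b, c = spec.poly_coeffs
    out = []
    for t, dt in zip(times, shifts):
        w = (t - dt) - spec.poly_center
        out.append(a + b * w + c * w * w)
    return out


_SIGNALS = {"gp": _gp_signal, "periodic": _periodic_signal, "polynomial": _polynomial_signal}
_NOISE_SD = {
    "gp": lambda spec: spec.kernel.noise_sd,
    "periodic": lambda spec: spec.periodic_noise_sd,
    "polynomial": lambda spec: spec.poly_noise_sd,
}


def simulate(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    times: list[np.ndarray] | None = None,
) -> list[SimulatedGene]:
    """Generate ``spec.n_genes`` genes under one scenario.

    Byte-reproducible for a given ``spec.seed`` (or supplied generator).
    ``times`` optionally fixes the per-group grids (used when several
    scenarios must share one set of samples).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = _group_labels(spec.n_groups)
    signal = _SIGNALS[spec.generator]
    noise_sd = _NOISE_SD[spec.generator](spec)
    if times is not None:
        if len(times) != spec.n_groups:
            raise ValueError("one fixed time grid per group is required")
        shared_times = [np.asarray(t, dtype=float) for t in times]
    else:
        shared_times = None if spec.redraw_times_per_gene else _draw_times(rng, spec)

    genes = []
    for j in range(spec.n_genes):
        times = _draw_times(rng, spec) if shared_times is None else shared_times
        shifts = _draw_shifts(rng, spec)
        f = signal(rng, spec, times, shifts)
        eps = tuple(rng.normal(0.0, noise_sd, t.size) for t in times)
        values = [fi + ei for fi, ei in zip(f, eps)]
        series = GeneSeries(
            f"{spec.generator}_{spec.model}_{j:04d}",
            GroupedTimes(labels, times),
            values,
        )
        genes.append(SimulatedGene(series=series, model=spec.model, true_shifts=shifts, noise=eps))
    return genes


def simulate_gp(spec: SimulationSpec, rng=None) -> list[SimulatedGene]:
    if spec.generator != "gp":
        raise ValueError("spec.generator must be 'gp'")
    return simulate(spec, rng)


def simulate_periodic(spec: SimulationSpec, rng=None) -> list[SimulatedGene]:
    if spec.generator != "periodic":
        raise ValueError("spec.generator must be 'periodic'")
    return simulate(spec, rng)


def simulate_polynomial(spec: SimulationSpec, rng=None) -> list[SimulatedGene]:
    if spec.generator != "polynomial":
        raise ValueError("spec.generator must be 'polynomial'")
    return simulate(spec, rng)


def simulate_cohort(
    spec_base: SimulationSpec, models: list[str], rng: np.random.Generator | None = None
) -> tuple[list[SimulatedGene], list[np.ndarray]]:
    """Generate several scenarios on one shared set of sample times.

    Used when the scenarios must live in a single genes x samples table.
    Returns the concatenated genes and the per-group time grids.
    """
    from dataclasses import replace

    if rng is None:
        rng = np.random.default_rng(spec_base.seed)
    times = _draw_times(rng, spec_base)
    genes: list[SimulatedGene] = []
    for m in models:
        genes.extend(simulate(replace(spec_base, model=m), rng, times=times))
    return genes, times


def cohort_to_tables(genes: list[SimulatedGene]):
    """Build (expression, metadata, truth) DataFrames from a cohort.

    All genes must share one set of per-group time grids (the
    ``simulate_cohort`` contract); samples are named ``<group>_s<k>``.
    """
    import pandas as pd

    first = genes[0].series.times
    labels = first.labels
    sample_ids, sample_group, sample_time = [], [], []
    for lab, t in zip(labels, first.times):
        for k, tk in enumerate(t):
            sample_ids.append(f"{lab}_s{k:03d}")
            sample_group.append(lab)
            sample_time.append(tk)
    meta = pd.DataFrame(
        {"group": sample_group, "time": sample_time}, index=pd.Index(sample_ids, name="sample")
    )

    rows, truth_rows = {}, []
    for g in genes:
        gt = g.series.times
        if gt.labels != labels or any(
            a.size != b.size or not np.allclose(a, b) for a, b in zip(gt.times, first.times)
        ):
            raise ValueError("cohort genes do not share one time grid")
        rows[g.series.gene] = np.concatenate(g.series.values)
        tr = {"gene_id": g.series.gene, "model": g.model}
        for i, lab in enumerate(labels):
            if i:
                tr[f"dt_{lab}"] = g.true_shifts[i]
        truth_rows.append(tr)
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    expr.index.name = "gene_id"
    truth = pd.DataFrame(truth_rows)
    return expr, meta, truth


def mspe(estimated, true) -> float:
    """Mean squared prediction error of estimated vs true shifts."""
    estimated = np.asarray(estimated, dtype=float)
    true = np.asarray(true, dtype=float)
    if estimated.shape != true.shape:
        raise ValueError(
            f"shape mismatch: {estimated.shape} vs {true.shape}"
        )
    if estimated.size == 0:
        raise ValueError("empty shift vectors")
    return float(np.mean((estimated - true) ** 2))


def true_shift_matrix(genes: list[SimulatedGene]) -> np.ndarray:
    """(n_genes, n_groups) matrix of true shifts."""
    return np.vstack([g.true_shifts for g in genes])


def estimated_shift_matrix(results) -> np.ndarray:
    """(n_genes, n_groups) matrix of estimated shifts from GeneResults."""
    return np.vstack([r.shifts for r in results])


def residual_variance_fraction(gene: SimulatedGene) -> float:
    """Noise variance over total variance of the observed values (pooled).

    Returns NaN (with no error) for a degenerate gene whose observed
    values have zero variance.
    """
    eps = np.concatenate(gene.noise)
    y = gene.series.pooled_values
    total = float(np.var(y, ddof=1))
    if total == 0.0:
        return float("nan")
    return float(np.var(eps, ddof=1)) / total


def residual_variance_summary(genes: list[SimulatedGene]) -> dict:
    """Cohort summary of per-gene residual fractions (mean, sd, min, max)."""
    fr = np.array([residual_variance_fraction(g) for g in genes])
    fr = fr[np.isfinite(fr)]
    if fr.size == 0:
        raise ValueError("no gene with defined residual-variance fraction")
    return {
        "mean": float(fr.mean()),
        "sd": float(fr.std(ddof=1)) if fr.size > 1 else 0.0,
        "min": float(fr.min()),
        "max": float(fr.max()),
        "n": int(fr.size),
    }
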