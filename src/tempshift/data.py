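"""Core containers for grouped time-series expression data.

A *gene series* holds one gene's observations across two or more groups
(conditions, brain areas, disease status, ...). Groups may have different
numbers of samples and unmatched time points; the first group is the
reference for all time-shift estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KernelParams",
    "GroupedTimes",
    "GeneSeries",
    "ModelFit",
    "GeneResult",
    "SimulationSpec",
    "SimulatedGene",
]

MODEL_KINDS = ("independence", "no_shift", "shift")


@dataclass(frozen=True)
class KernelParams:
    """Squared-exponential kernel hyperparameters.

    Parameters
    ----------
    sigma_f : float
        Signal amplitude (expression units); the typical departure of the
        latent trajectory from its mean. Must be positive.
    length_scale : float
        Smoothness length scale (time units). Must be positive.
    noise_sd : float
        Standard deviation of the i.i.d. observation noise (expression
        units). Non-negative.
    """

    sigma_f: float
    length_scale: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_f", "length_scale", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma_f <= 0:
            raise ValueError(f"sigma_f must be > 0, got {self.sigma_f}")
        if self.length_scale <= 0:
            raise ValueError(f"length_scale must be > 0, got {self.length_scale}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


class GroupedTimes:
    """Ordered per-group time vectors; the first group is the reference."""

    def __init__(self, labels: Sequence, times: Sequence[np.ndarray]):
        labels = tuple(labels)
        times = tuple(np.asarray(t, dtype=float).ravel() for t in times)
        if len(labels) != len(times):
            raise ValueError("labels and times must have equal length")
        if len(labels) < 1:
            raise ValueError("at least one group is required")
        if len(set(labels)) != len(labels):
            raise ValueError(f"group labels must be unique, got {labels}")
        for lab, t in zip(labels, times):
            if t.size == 0:
                raise ValueError(f"group {lab!r} has an empty time vector")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"group {lab!r} has non-finite times")
        self.labels = labels
        self.times = times

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(t.size for t in self.times)

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(self.times)

    @property
    def codes(self) -> np.ndarray:
        """Integer group index per pooled observation."""
        return np.repeat(np.arange(self.n_groups), self.sizes)

    @property
    def span(self) -> float:
        p = self.pooled
        return float(p.max() - p.min())

    def __repr__(self) -> str:  # pragma: no cover
        return f"GroupedTimes(labels={self.labels}, sizes={self.sizes})"


class GeneSeries:
    """One gene's observations: per-group time and expression vectors."""

    def __init__(self, gene: str, times: GroupedTimes, values: Sequence[np.ndarray]):
        values = tuple(np.asarray(v, dtype=float).ravel() for v in values)
        if len(values) != times.n_groups:
            raise ValueError("one expression vector per group is required")
        for lab, t, v in zip(times.labels, times.times, values):
            if v.size != t.size:
                raise ValueError(
                    f"gene {gene!r} group {lab!r}: {v.size} values for {t.size} times"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"gene {gene!r} group {lab!r} has non-finite values")
        self.gene = gene
        self.times = times
        self.values = values

    @property
    def pooled_values(self) -> np.ndarray:
        return np.concatenate(self.values)

    @property
    def n_groups(self) -> int:
        return self.times.n_groups

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSeries({self.gene!r}, groups={self.times.labels})"


@dataclass
class ModelFit:
    """Result of maximizing one model's marginal likelihood for one gene."""

    kind: str
    log_likelihood: float
    params: KernelParams | None
    shifts: np.ndarray | None = None  # full per-group vector, reference = 0
    converged: bool = False
    n_restarts: int = 0
    pooled_mean: float = 0.0


@dataclass
class GeneResult:
    """Per-gene model comparison: likelihoods, LLRs, shifts, class label."""

    gene: str
    group_labels: tuple
    logl_independence: float = np.nan
    logl_no_shift: float = np.nan
    logl_shift: float = np.nan
    llr_shape: float = np.nan
    llr_shift: float = np.nan
    shifts: np.ndarray | None = None
    kernel_params: KernelParams | None = None
    converged: dict = field(default_factory=dict)
    label: str | None = None
    note: str = ""


@dataclass
class SimulationSpec:
    """Configuration of one simulated benchmark scenario.

    The defaults are the benchmark study conditions: 100 genes of 100
    points per group, times uniform on [5, 15], squared-exponential
    amplitude 5 and length scale 3, GP noise sd 0.5, sine noise sd 0.3,
    quadratic coefficients (0, 1.5, 1.0) with noise sd 3; two-group true
    shift fixed at 2, three-group shifts drawn from N(2,1) / N(-2,1).
    """

    generator: str = "gp"  # gp | periodic | polynomial
    model: str = "shift"  # independence | no_shift | shift
    n_groups: int = 2
    n_genes: int = 100
    n_points: int = 100
    time_range: tuple[float, float] = (5.0, 15.0)
    kernel: KernelParams = field(default_factory=lambda: KernelParams(5.0, 3.0, 0.5))
    periodic_noise_sd: float = 0.3
    periodic_period: float = 10.0
    poly_coeffs: tuple[float, float, float] = (0.0, 1.5, 1.0)
    poly_center: float = 10.0
    poly_noise_sd: float = 3.0
    two_group_shift: float = 2.0
    shift_means: tuple[float, ...] = (2.0, -2.0)  # cycled over non-reference groups
    shift_sd: float = 1.0
    redraw_times_per_gene: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.generator not in ("gp", "periodic", "polynomial"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.generator != "gp" and self.model == "independence":
            raise ValueError("independence scenario is only defined for the gp generator")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.time_range
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"invalid time_range {self.time_range}")
        for name in ("periodic_noise_sd", "poly_noise_sd", "periodic_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SimulatedGene:
    """A generated gene with its ground truth retained.

    ``noise`` keeps the realized error vectors per group so that the
    residual-variance fraction of the generator can be computed exactly.
    """

    series: GeneSeries
    model: str
    true_shifts: np.ndarray
    noise: tuple[np.ndarray, ...]
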