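"""Configuration objects shared across the pipeline.

All tunables are plain dataclasses with eager validation so that a bad run
configuration fails before any expensive stage starts.  Defaults mirror the
study design the simulator emulates: ~41 flock-year groups of ~150 Merino
yearlings, fibre diameter (FD) profiled every 5 mm along the wool staple with
10-27 records per animal, body weight (BW) recorded 5-20 times between birth
and wool sampling, and weaning at a mean age of 90 days (range 62-119).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "SmoothingConfig",
    "AlignmentConfig",
    "IndicatorConfig",
    "GeneticsConfig",
    "RunConfig",
    "DEFAULT_TRUE_VARIANCES",
]

#: trait -> (additive, maternal permanent environmental, residual) variance of
#: the latent log-susceptibility scalar that scales an animal's response to
#: disturbances.  h2 = 0.1 puts recovered indicator heritabilities in the low
#: range typical of resilience traits.
DEFAULT_TRUE_VARIANCES: dict[str, tuple[float, float, float]] = {
    "FD": (0.10, 0.05, 0.85),
    "BW": (0.10, 0.05, 0.85),
}


def _as_pd_matrix(mat: Sequence[Sequence[float]], name: str) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(arr)
    if eig.min() <= 0:
        raise ValueError(f"{name} must be positive definite (min eig {eig.min():.3g})")
    return arr


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_flock_years: int = 41
    animals_per_group: int = 150
    n_sires_per_group: int = 10
    n_dams_per_group: int = 75
    sire_sharing: float = 0.5  #: fraction of a group's sires drawn from the shared pool
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_variances: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_VARIANCES)
    )
    genetic_correlations: Sequence[Sequence[float]] = field(
        default_factory=lambda: [[1.0, 0.5], [0.5, 1.0]]
    )
    weaning_day_mean: float = 90.0
    weaning_day_range: tuple[float, float] = (62.0, 119.0)
    # weaning disturbance (in standardized trait units, scaled by susceptibility)
    dip_depth: float = 1.5
    dip_response_days: float = 18.0
    dip_recovery_days: float = 35.0
    dip_recovery_fraction: float = 0.9  #: fraction of the drop regained at the crest
    n_groups_without_dip: int = 0
    # random unknown disturbances
    perturbation_rate: float = 1.2  #: expected transient disturbances per 100 days
    perturbation_amp: float = 0.7
    perturbation_width_days: float = 12.0
    # individual phase variation and noise
    phase_sd: float = 0.10
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"FD": 0.35, "BW": 0.30}
    )
    # observation schedules
    fd_step: float = 5.0  #: mm between successive fibre-diameter measurements
    fd_records_range: tuple[int, int] = (10, 27)
    bw_records_range: tuple[int, int] = (5, 20)
    sampling_age_mean: float = 300.0
    sampling_age_range: tuple[float, float] = (210.0, 390.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_flock_years",
            "animals_per_group",
            "n_sires_per_group",
            "n_dams_per_group",
            "n_snps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for trait, comps in self.true_variances.items():
            if len(comps) != 3 or any(v < 0 for v in comps):
                raise ValueError(f"true_variances[{trait!r}] must be 3 non-negative values")
            if sum(comps) <= 0:
                raise ValueError(f"true_variances[{trait!r}] must not be all zero")
        self.genetic_correlations = _as_pd_matrix(
            self.genetic_correlations, "genetic_correlations"
        )
        if self.genetic_correlations.shape[0] != len(self.true_variances):
            raise ValueError("genetic_correlations dimension must match number of traits")
        if not (0 <= self.n_groups_without_dip <= self.n_flock_years):
            raise ValueError("n_groups_without_dip must be in [0, n_flock_years]")
        if self.phase_sd < 0 or self.dip_depth < 0 or self.perturbation_rate < 0:
            raise ValueError("disturbance magnitudes must be non-negative")
        lo, hi = self.weaning_day_range
        if not lo <= self.weaning_day_mean <= hi:
            raise ValueError("weaning_day_mean must lie in weaning_day_range")

    @property
    def traits(self) -> list[str]:
        return list(self.true_variances)


@dataclass
class SmoothingConfig:
    """Penalized B-spline settings for one series type.

    ``order`` follows the fda convention (number of polynomial pieces'
    coefficients; degree = order - 1): 3 (quadratic) for body weight and 4
    (cubic) for fibre diameter.  The curvature penalty weight ``lambda_smooth``
    defaults to 2500 for both series.
    """

    order: int = 4
    penalty_derivative: int = 2
    lambda_smooth: float = 2500.0
    n_quantile_knots: int = 10
    extra_knots: tuple[float, ...] = ()
    prediction_step: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if self.n_quantile_knots < 2:
            raise ValueError("n_quantile_knots must be >= 2")
        if self.prediction_step <= 0:
            raise ValueError("prediction_step must be > 0")
        if self.penalty_derivative != 2:
            raise ValueError("only the curvature (second-derivative) penalty is supported")


def default_smoothing(series: str) -> SmoothingConfig:
    """Per-series defaults: cubic/1 mm for FD, quadratic/10 d with early extra
    knots for BW (lambs are not weighed between birth and weaning, so the BW
    record density is low before ~90 days)."""
    if series == "FD":
        return SmoothingConfig(order=4, prediction_step=1.0)
    if series == "BW":
        return SmoothingConfig(order=3, prediction_step=10.0, extra_knots=(30.0, 60.0))
    raise ValueError(f"unknown series {series!r}")


@dataclass
class AlignmentConfig:
    """Elastic-alignment settings.

    ``lambda_grid`` is the sensitivity grid of warping-penalty weights; the
    per-series defaults (FD 0.2, BW 0.6) are the operating points.
    """

    lambda_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)
    default_lambda: dict[str, float] = field(
        default_factory=lambda: {"FD": 0.2, "BW": 0.6}
    )
    max_iter: int = 20
    tol: float = 1e-4
    slope_window: float = 5.0

    def __post_init__(self) -> None:
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("alignment lambdas must be >= 0")
        if self.slope_window <= 1:
            raise ValueError("slope_window must exceed 1")


@dataclass
class IndicatorConfig:
    prominence_sd: float = 0.1  #: minimum extremum prominence, in units of the group sd of the mean curve
    search_span: float = 0.4  #: fraction of the domain after the anchor searched for the dip
    staple_tip_is_birth: bool = True
    use_group_window: bool = True  #: evaluate ROC at flock-year window positions (vs per-animal extrema)
    outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.prominence_sd < 0:
            raise ValueError("prominence_sd must be >= 0")
        if not 0 < self.search_span <= 1:
            raise ValueError("search_span must be in (0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")


@dataclass
class GeneticsConfig:
    alpha: float = 0.95  #: weight of G in the blended genomic matrix G_w
    max_iter: int = 200
    em_warmup: int = 3
    loglik_tol: float = 1e-8
    param_tol: float = 1e-6
    variance_floor: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class RunConfig:
    """Top-level configuration of an end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    smoothing: dict[str, SmoothingConfig] = field(
        default_factory=lambda: {"FD": default_smoothing("FD"), "BW": default_smoothing("BW")}
    )
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    series: tuple[str, ...] = ("FD", "BW")
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.series:
            if s not in self.smoothing:
                raise ValueError(f"no smoothing config for series {s!r}")
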