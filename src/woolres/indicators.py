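"""Resilience indicators from deviations around the flock-year mean curve.

General indicators (any disturbance): natural log of the deviation variance
(Lnvar), lag-1 autocorrelation (Auto), skewness (third standardized moment)
and mean absolute change (ABS) of each animal's deviations from its
flock-year Fréchet mean.  Weaning-specific indicators: rates of change over
the collapse (ROC_response) and recovery (ROC_recovery) phases of the
group-level weaning window, and the area between the individual curve and
the group mean over that window (ABC; negative = stronger response / slower
recovery).  Indicators exceeding 3 group SD are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import IndicatorConfig
from .elastic import GroupAlignment

__all__ = [
    "DeviationSeries",
    "WeaningWindow",
    "compute_deviations",
    "lnvar",
    "auto",
    "skewness",
    "abs_change",
    "detect_weaning_window",
    "map_age_to_staple",
    "roc_traits",
    "abc",
    "general_indicators",
    "indicator_table",
    "remove_outliers",
]

GENERAL_TRAITS = ("Lnvar", "Auto", "Skewness", "ABS")
WEANING_TRAITS = ("ROC_response", "ROC_recovery", "ABC")


@dataclass
class DeviationSeries:
    """One animal's deviations x_i = aligned value - group mean on the grid."""

    animal_id: int
    series: str
    grid: np.ndarray
    deviations: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.deviations = np.asarray(self.deviations, dtype=float)
        if self.grid.size != self.deviations.size:
            raise ValueError("grid and deviations must have equal length")
        if self.deviations.size < 3:
            raise ValueError("need at least 3 deviations for any indicator")

    @property
    def n(self) -> int:
        return self.deviations.size


@dataclass
class WeaningWindow:
    """Collapse-and-recovery segment of a group mean curve after weaning."""

    flock_year: str
    series: str
    t_w: float  #: weaning anchor on the grid
    t_min: float | None = None
    t_max: float | None = None
    detected: bool = False

    def __post_init__(self) -> None:
        if self.detected:
            if self.t_min is None or self.t_max is None:
                raise ValueError("detected window must have t_min and t_max")
            if not (self.t_w < self.t_min < self.t_max):
                raise ValueError("window must satisfy t_w < t_min < t_max")


def compute_deviations(ga: GroupAlignment) -> list[DeviationSeries]:
    """Pointwise subtraction of the group mean from each aligned curve."""
    return [
        DeviationSeries(a, ga.series, ga.grid, ga.aligned[i] - ga.mean_function)
        for i, a in enumerate(ga.animals)
    ]


def _check(dev: DeviationSeries, min_n: int) -> np.ndarray:
    x = dev.deviations
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} deviations")
    return x


def lnvar(dev: DeviationSeries) -> float:
    """ln of the (n-1)-denominator variance of the deviations; NaN (flagged
    missing) when the variance is zero."""
    x = _check(dev, 2)
    v = np.sum((x - x.mean()) ** 2) / (x.size - 1)
    # numerically-zero variance (constant deviations) is missing, not -inf
    if v <= 1e-24 * max(1.0, float(np.max(np.abs(x))) ** 2):
        return float("nan")
    return float(np.log(v))


def auto(dev: DeviationSeries) -> float:
    """Lag-1 autocorrelation: n-1 cross products over n squared deviations."""
    x = _check(dev, 3)
    c = x - x.mean()
    den = np.sum(c**2)
    if den == 0:
        return float("nan")
    return float(np.sum(c[:-1] * c[1:]) / den)


def skewness(dev: DeviationSeries) -> float:
    """Third standardized moment of the deviations, with the
    (n-1)-denominator standard deviation."""
    x = _check(dev, 3)
    s = np.sqrt(np.sum((x - x.mean()) ** 2) / (x.size - 1))
    if s == 0:
        return float("nan")
    return float(np.mean(((x - x.mean()) / s) ** 3))


def abs_change(dev: DeviationSeries) -> float:
    """Mean absolute first difference of the deviations."""
    x = _check(dev, 2)
    return float(np.sum(np.abs(np.diff(x))) / (x.size - 1))


def map_age_to_staple(age: float, sampling_age: float, staple_length: float) -> float:
    """Age in days -> staple position in mm, proportional to staple length,
    measured from the birth end (tip) of the staple."""
    if not 0 <= age <= sampling_age:
        raise ValueError("age must lie in [0, sampling_age]")
    return age / sampling_age * staple_length


def detect_weaning_window(
    mean_curve: np.ndarray,
    grid: np.ndarray,
    anchor: float,
    flock_year: str = "",
    series: str = "",
    config: IndicatorConfig | None = None,
) -> WeaningWindow:
    """First qualifying local minimum of the group mean after the weaning
    anchor, then the next local maximum.

    Extrema are sign changes of the first differences; a minimum qualifies
    only if its prominence (drop from the preceding local maximum or the
    anchor value, and rise to the following maximum) exceeds
    ``prominence_sd`` group standard deviations of the mean curve.  When no
    qualifying minimum exists within the search span the window is marked
    undetected and the flock-year is excluded from the weaning traits.
    """
    config = config or IndicatorConfig()
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(mean_curve, dtype=float)
    if not grid[0] <= anchor <= grid[-1]:
        raise ValueError("anchor outside the grid")
    span = grid[-1] - grid[0]
    hi = anchor + config.search_span * span
    thresh = config.prominence_sd * y.std(ddof=1)

    d = np.diff(y)
    sign = np.sign(d)
    # indices i where y[i] is a local min / max (strict sign change)
    mins = [i for i in range(1, y.size - 1) if sign[i - 1] < 0 <= sign[i]]
    maxs = [i for i in range(1, y.size - 1) if sign[i - 1] > 0 >= sign[i]]

    i_anchor = int(np.searchsorted(grid, anchor))
    ref = y[min(i_anchor, y.size - 1)]
    for im in mins:
        if grid[im] <= anchor or grid[im] > hi:
            continue
        later_max = [ix for ix in maxs if ix > im]
        if not later_max:
            continue
        ix = later_max[0]
        drop = ref - y[im]
        rise = y[ix] - y[im]
        if drop >= thresh and rise >= thresh:
            return WeaningWindow(
                flock_year, series, t_w=float(anchor),
                t_min=float(grid[im]), t_max=float(grid[ix]), detected=True,
            )
    return WeaningWindow(flock_year, series, t_w=float(anchor), detected=False)


def roc_traits(
    curve: np.ndarray, grid: np.ndarray, window: WeaningWindow
) -> tuple[float, float]:
    """Rates of change of the animal's aligned curve over the group-level
    response and recovery phases."""
    if not window.detected:
        return float("nan"), float("nan")
    f = lambda t: float(np.interp(t, grid, curve))
    roc_resp = (f(window.t_min) - f(window.t_w)) / (window.t_min - window.t_w)
    roc_rec = (f(window.t_max) - f(window.t_min)) / (window.t_max - window.t_min)
    return float(roc_resp), float(roc_rec)


def abc(
    curve: np.ndarray,
    mean_curve: np.ndarray,
    grid: np.ndarray,
    window: WeaningWindow,
) -> float:
    """Trapezoid area under the animal curve minus the area under the group
    mean over [t_w, t_max]."""
    if not window.detected:
        return float("nan")
    t = np.asarray(grid, dtype=float)
    lo, hi = window.t_w, window.t_max
    inner = t[(t > lo) & (t < hi)]
    tt = np.concatenate([[lo], inner, [hi]])
    fa = np.interp(tt, t, curve)
    fm = np.interp(tt, t, mean_curve)
    return float(np.trapezoid(fa, tt) - np.trapezoid(fm, tt))


def general_indicators(dev: DeviationSeries) -> dict[str, float]:
    return {
        "Lnvar": lnvar(dev),
        "Auto": auto(dev),
        "Skewness": skewness(dev),
        "ABS": abs_change(dev),
    }


def individual_window(
    curve: np.ndarray,
    grid: np.ndarray,
    group_window: WeaningWindow,
    config: IndicatorConfig | None = None,
) -> WeaningWindow:
    """Re-detect the weaning window on one animal's own aligned curve,
    anchored at the group anchor; falls back to the group-level window when
    the individual curve shows no qualifying dip."""
    w = detect_weaning_window(
        curve, grid, group_window.t_w, group_window.flock_year,
        group_window.series, config=config,
    )
    return w if w.detected else group_window


def indicator_table(
    ga: GroupAlignment,
    window: WeaningWindow | None = None,
    config: IndicatorConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-animal indicator table for one aligned flock-year group.

    Weaning traits are present (non-missing) only when a detected window is
    supplied; missingness propagates as NaN, never as zero.  By default the
    ROC traits are evaluated at the flock-year window positions; with
    ``config.use_group_window = False`` each animal's own extrema (within
    its curve, anchored at the group anchor) are used instead.
    """
    config = config or IndicatorConfig()
    rows = []
    for i, animal in enumerate(ga.animals):
        dev = DeviationSeries(animal, ga.series, ga.grid, ga.aligned[i] - ga.mean_function)
        vals = general_indicators(dev)
        if window is not None and window.detected:
            w_i = window if config.use_group_window else individual_window(
                ga.aligned[i], ga.grid, window, config
            )
            rr, rc = roc_traits(ga.aligned[i], ga.grid, w_i)
            vals["ROC_response"] = rr
            vals["ROC_recovery"] = rc
            vals["ABC"] = abc(ga.aligned[i], ga.mean_function, ga.grid, window)
        else:
            vals.update({t: float("nan") for t in WEANING_TRAITS})
        for trait, v in vals.items():
            rows.append((animal, ga.series, trait, v, ga.flock_year))
    return pd.DataFrame(rows, columns=["animal", "series", "trait", "value", "flock_year"])


def remove_outliers(
    traits: pd.DataFrame,
    sd_limit: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass 3-SD outlier filter per trait per flock-year.

    Values with |value - group mean| > sd_limit * group sd are set missing
    and flagged.  Returns the filtered table (with an ``outlier_flag``
    column) and a removal log with one row per masked cell.
    """
    out = traits.reset_index(drop=True).copy()
    out["outlier_flag"] = False
    log_rows = []
    for (fy, series, trait), sub in out.groupby(
        ["flock_year", "series", "trait"], sort=False
    ):
        v = sub["value"].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 3:
            continue
        mu, sd = v[ok].mean(), v[ok].std(ddof=1)
        if sd == 0:
            continue
        bad = ok & (np.abs(v - mu) > sd_limit * sd)
        for ridx in sub.index[bad]:
            log_rows.append(
                (fy, series, trait, int(out.at[ridx, "animal"]), float(out.at[ridx, "value"]))
            )
            out.at[ridx, "outlier_flag"] = True
            out.at[ridx, "value"] = float("nan")
    log = pd.DataFrame(
        log_rows, columns=["flock_year", "series", "trait", "animal", "value"]
    )
    return out, log
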