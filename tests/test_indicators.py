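"""Resilience indicators vs naive brute-force oracles, window detection and
outlier filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woolres.config import IndicatorConfig
from woolres.indicators import (
    DeviationSeries,
    WeaningWindow,
    abc,
    abs_change,
    auto,
    detect_weaning_window,
    lnvar,
    map_age_to_staple,
    remove_outliers,
    roc_traits,
    skewness,
)

GRID10 = np.arange(10, dtype=float)


def dev(x):
    x = np.asarray(x, dtype=float)
    return DeviationSeries(1, "FD", np.arange(x.size, dtype=float), x)


# --- independent naive oracles (plain Python loops) -----------------------

def lnvar_oracle(x):
    n = len(x)
    m = sum(x) / n
    return math.log(sum((v - m) ** 2 for v in x) / (n - 1))


def auto_oracle(x):
    n = len(x)
    m = sum(x) / n
    num = sum((x[i] - m) * (x[i + 1] - m) for i in range(n - 1))
    den = sum((v - m) ** 2 for v in x)
    return num / den


def skew_oracle(x):
    n = len(x)
    m = sum(x) / n
    s = math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))
    return sum(((v - m) / s) ** 3 for v in x) / n


def abs_oracle(x):
    n = len(x)
    return sum(abs(x[i] - x[i - 1]) for i in range(1, n)) / (n - 1)


class TestGeneralIndicators:
    def test_lnvar_hand_value(self):
        assert lnvar(dev([0.5, -0.5, 0.5, -0.5])) == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_lnvar_scaling_rule(self):
        x = np.array([0.3, -0.2, 0.9, 0.1])
        assert lnvar(dev(3.0 * x)) == pytest.approx(lnvar(dev(x)) + 2 * math.log(3.0), abs=1e-12)

    def test_lnvar_constant_is_missing(self):
        assert math.isnan(lnvar(dev([0.2, 0.2, 0.2])))

    def test_auto_hand_values(self):
        assert auto(dev([1, -1, 1, -1])) == pytest.approx(-0.75, abs=1e-12)
        assert auto(dev([1, 1, -1, -1])) == pytest.approx(0.25, abs=1e-12)

    def test_auto_ar1_simulation(self):
        rng = np.random.default_rng(8)
        n, rho = 10_000, 0.8
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.standard_normal() * math.sqrt(1 - rho**2)
        assert auto(dev(x)) == pytest.approx(rho, abs=0.03)

    def test_skewness_hand_values(self):
        assert skewness(dev([-1.0, 0.0, 1.0])) == pytest.approx(0.0, abs=1e-12)
        # [0,0,3]: mean 1, s = sqrt(3); third standardized moment
        expect = (2 * (-1 / math.sqrt(3)) ** 3 + (2 / math.sqrt(3)) ** 3) / 3
        assert skewness(dev([0.0, 0.0, 3.0])) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.385, abs=5e-4)

    def test_skewness_shift_invariance(self):
        x = np.array([0.1, -0.4, 0.9, 0.5, -0.2])
        assert skewness(dev(x + 7.3)) == pytest.approx(skewness(dev(x)), abs=1e-12)

    def test_abs_hand_value(self):
        assert abs_change(dev([0.0, 1.0, 3.0, 2.0])) == pytest.approx(4 / 3, abs=1e-12)
        assert abs_change(dev([0.5, 0.5, 0.5])) == 0.0

    def test_abs_homogeneity(self):
        x = np.array([0.1, -0.7, 0.2, 0.4])
        assert abs_change(dev(-2.5 * x)) == pytest.approx(2.5 * abs_change(dev(x)), abs=1e-12)

    def test_brute_force_equivalence_many_series(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = rng.integers(4, 60)
            x = rng.standard_normal(n) * rng.uniform(0.1, 5)
            d = dev(x)
            assert lnvar(d) == pytest.approx(lnvar_oracle(list(x)), abs=1e-12)
            assert auto(d) == pytest.approx(auto_oracle(list(x)), abs=1e-12)
            assert skewness(d) == pytest.approx(skew_oracle(list(x)), abs=1e-12)
            assert abs_change(d) == pytest.approx(abs_oracle(list(x)), abs=1e-12)

    def test_grid_reversal_invariance(self):
        x = np.array([0.3, -0.1, 0.8, -0.6, 0.2, 0.9])
        d1, d2 = dev(x), dev(x[::-1])
        for f in (lnvar, auto, skewness, abs_change):
            assert f(d1) == pytest.approx(f(d2), abs=1e-12)

    def test_auto_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.standard_normal(rng.integers(3, 30))
            assert abs(auto(dev(x))) <= 1.0 + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40),
        st.floats(-50, 50),
        st.floats(0.01, 100),
    )
    def test_affine_equivariance_properties(self, xs, shift, scale):
        """Location/scale laws hold for arbitrary series: Lnvar picks up
        2 ln(scale), Auto and Skewness are affine-invariant, ABS scales."""
        x = np.asarray(xs)
        if np.ptp(x) < 1e-6:  # (near-)constant series are flagged missing
            return
        d0, d1 = dev(x), dev(scale * x + shift)
        assert lnvar(d1) == pytest.approx(lnvar(d0) + 2 * math.log(scale), abs=1e-6)
        assert auto(d1) == pytest.approx(auto(d0), abs=1e-6)
        assert skewness(d1) == pytest.approx(skewness(d0), abs=1e-6)
        assert abs_change(d1) == pytest.approx(scale * abs_change(d0), rel=1e-9)


class TestWindowDetection:
    @staticmethod
    def _dip_curve(grid, t_dip=40.0, depth=1.0):
        """Smooth curve with a dip bottoming near t_dip, a recovery crest,
        then a slow late decline (like a seasonal group mean)."""
        y = 0.002 * grid
        y -= depth * np.exp(-0.5 * ((grid - t_dip) / 8.0) ** 2)
        y -= 0.8 * np.exp(-0.5 * ((grid - grid[-1]) / 25.0) ** 2)
        return y

    def test_single_dip_located(self):
        grid = np.arange(0.0, 101.0)
        y = self._dip_curve(grid)
        w = detect_weaning_window(y, grid, anchor=25.0)
        assert w.detected
        assert abs(w.t_min - 40.0) <= 1.5
        assert w.t_min < w.t_max

    def test_monotone_curve_not_detected(self):
        grid = np.arange(0.0, 101.0)
        w = detect_weaning_window(0.01 * grid, grid, anchor=25.0)
        assert not w.detected

    def test_shallow_first_dip_skipped(self):
        grid = np.arange(0.0, 151.0)
        y = 0.001 * grid
        y -= 0.02 * np.exp(-0.5 * ((grid - 40) / 4) ** 2)  # below prominence
        y -= 1.0 * np.exp(-0.5 * ((grid - 70) / 8) ** 2)  # the real dip
        y -= 0.8 * np.exp(-0.5 * ((grid - 150) / 25.0) ** 2)  # late decline -> crest
        w = detect_weaning_window(y, grid, anchor=25.0,
                                  config=IndicatorConfig(prominence_sd=0.3, search_span=0.5))
        assert w.detected
        assert abs(w.t_min - 70.0) <= 2.0

    def test_anchor_outside_grid(self):
        grid = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            detect_weaning_window(np.zeros(10), grid, anchor=50.0)

    def test_window_invariant_ordering(self):
        with pytest.raises(ValueError):
            WeaningWindow("A", "FD", t_w=50.0, t_min=40.0, t_max=60.0, detected=True)


class TestAgeMapping:
    @pytest.mark.parametrize(
        "age,samp,staple,expect",
        [(90.0, 300.0, 60.0, 18.0), (0.0, 300.0, 60.0, 0.0), (300.0, 300.0, 60.0, 60.0)],
    )
    def test_proportional(self, age, samp, staple, expect):
        assert map_age_to_staple(age, samp, staple) == pytest.approx(expect)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            map_age_to_staple(400.0, 300.0, 60.0)


class TestWeaningTraits:
    GRID = np.arange(0.0, 201.0)
    WIN = WeaningWindow("A", "BW", t_w=90.0, t_min=110.0, t_max=135.0, detected=True)

    def test_roc_slope_arithmetic(self):
        f = np.interp(self.GRID, [0, 90, 110, 135, 200], [0, 0, -0.4, 0.1, 0.1])
        rr, rc = roc_traits(f, self.GRID, self.WIN)
        assert rr == pytest.approx(-0.02, abs=1e-12)
        assert rc == pytest.approx(0.02, abs=1e-12)

    def test_flat_curve_zero(self):
        rr, rc = roc_traits(np.full(self.GRID.size, 0.7), self.GRID, self.WIN)
        assert rr == 0.0 and rc == 0.0

    def test_undetected_window_missing(self):
        w = WeaningWindow("A", "BW", t_w=90.0, detected=False)
        rr, rc = roc_traits(np.zeros(self.GRID.size), self.GRID, w)
        assert math.isnan(rr) and math.isnan(rc)
        assert math.isnan(abc(np.zeros(self.GRID.size), np.zeros(self.GRID.size), self.GRID, w))

    def test_abc_offsets(self):
        mean = np.sin(self.GRID / 30.0)
        win = WeaningWindow("A", "BW", t_w=100.0, t_min=105.0, t_max=110.0, detected=True)
        assert abc(mean, mean, self.GRID, win) == pytest.approx(0.0, abs=1e-12)
        assert abc(mean + 0.2, mean, self.GRID, win) == pytest.approx(2.0, abs=1e-9)
        assert abc(mean - 0.2, mean, self.GRID, win) == pytest.approx(-2.0, abs=1e-9)

    def test_abc_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(self.GRID.size).cumsum() * 0.01
        m = rng.standard_normal(self.GRID.size).cumsum() * 0.01
        win = WeaningWindow("A", "FD", t_w=90.0, t_min=110.0, t_max=135.0, detected=True)
        lo, hi = int(win.t_w), int(win.t_max)
        expect = np.trapezoid(f[lo:hi + 1], self.GRID[lo:hi + 1]) - np.trapezoid(
            m[lo:hi + 1], self.GRID[lo:hi + 1]
        )
        assert abc(f, m, self.GRID, win) == pytest.approx(expect, abs=1e-10)


class TestOutliers:
    @staticmethod
    def _table(values, fy="A"):
        return pd.DataFrame(
            {
                "animal": np.arange(len(values)),
                "series": "FD",
                "trait": "Lnvar",
                "value": values,
                "flock_year": fy,
            }
        )

    def test_single_gross_outlier_removed(self):
        rng = np.random.default_rng(4)
        vals = np.append(rng.standard_normal(100), 10.0)
        out, log = remove_outliers(self._table(vals))
        assert len(log) == 1
        assert log["animal"].iloc[0] == 100
        assert out["outlier_flag"].sum() == 1
        assert math.isnan(out.loc[100, "value"])

    def test_constant_group_untouched(self):
        out, log = remove_outliers(self._table(np.full(10, 1.5)))
        assert len(log) == 0 and not out["outlier_flag"].any()

    def test_log_rows_equal_masked_cells(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.standard_normal(50), [8.0, -9.0]])
        out, log = remove_outliers(self._table(vals))
        assert len(log) == out["outlier_flag"].sum()

    def test_single_pass_no_reiteration(self):
        # after masking the gross outlier, a borderline value would exceed
        # 3 SD of the cleaned group; a single pass must keep it
        vals = np.concatenate([np.zeros(30), [0.5, 100.0]])
        vals[:30] = np.linspace(-0.1, 0.1, 30)
        out, _ = remove_outliers(self._table(vals))
        assert out["outlier_flag"].sum() == 1
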