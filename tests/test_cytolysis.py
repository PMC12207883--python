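"""Killing-rate estimation: steepest window, normalization, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress

from ctlkit.cytolysis import (RedAreaTimeSeries, fold_change, killing_rate,
                              killing_rates, mean_control,
                              paired_suppression, steepest_window)

TIMES = np.arange(57) * 0.25


def series(areas, times=None, **kw):
    t = TIMES if times is None else times
    return RedAreaTimeSeries(well_id="w", times_h=t,
                             areas_um2=np.asarray(areas, float), **kw)


def brute_force_steepest(times, areas, window_h):
    """Independent oracle: full scan with scipy.stats.linregress."""
    dt = times[1] - times[0]
    npts = int(round(window_h / dt)) + 1
    best = None
    for i in range(len(times) - npts + 1):
        s = linregress(times[i:i + npts], areas[i:i + npts]).slope
        if best is None or s < best[1] - 1e-9 * (1 + abs(best[1])):
            best = (times[i], s)
    return best


class TestSteepestWindow:
    def test_linear_series_returns_slope_and_earliest_window(self):
        for m in (-500.0, 0.0, 250.0):
            start, slope = steepest_window(series(10_000 + m * TIMES), 6.0)
            assert slope == pytest.approx(m)
            assert start == 0.0

    def test_flat_then_decline_selects_decline(self):
        areas = np.where(TIMES <= 4.0, 10_000.0,
                         10_000.0 - 500.0 * (TIMES - 4.0))
        start, slope = steepest_window(series(areas), 6.0)
        oracle = brute_force_steepest(TIMES, areas, 6.0)
        assert (start, slope) == pytest.approx(oracle)
        assert start >= 4.0 and start + 6.0 <= 14.0
        assert slope == pytest.approx(-500.0)

    def test_series_length_equal_to_window(self):
        t = np.arange(25) * 0.25
        start, slope = steepest_window(series(5000 - 100 * t, times=t), 6.0)
        assert start == 0.0
        assert slope == pytest.approx(-100.0)

    def test_too_short_series_raises(self):
        t = np.arange(10) * 0.25
        with pytest.raises(ValueError, match="window"):
            steepest_window(series(np.ones(10) * 100, times=t), 6.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=20_000),
                    min_size=57, max_size=57),
           st.sampled_from([2.0, 4.0, 6.0]))
    def test_matches_brute_force_scan(self, areas, window_h):
        """Oracle equivalence on arbitrary series."""
        s = series(areas)
        got = steepest_window(s, window_h)
        want = brute_force_steepest(TIMES, np.asarray(areas), window_h)
        assert got[1] == pytest.approx(want[1], abs=1e-6)


class TestKillingRate:
    def test_treated_equals_control_gives_zero(self):
        s = series(9000 + 300 * TIMES + 50 * np.sin(TIMES))
        res = killing_rate(s, s)
        assert res.rate_pct_per_h == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_ten_percent_per_hour(self):
        # Decline starts after the first hour so the reference area
        # (first-hour mean) is exactly 10 000 um^2; 9-h assay keeps the
        # declining area positive throughout.
        t = np.arange(37) * 0.25
        control = series(np.full_like(t, 10_000.0), times=t, role="control")
        treated = series(10_000.0 - 1000.0 * np.clip(t - 1.0, 0, None),
                         times=t)
        res = killing_rate(treated, control)
        assert res.rate_pct_per_h == pytest.approx(10.0)
        assert res.reference_area_um2 == pytest.approx(10_000.0)

    def test_mismatched_grids_raise(self):
        a = series(np.ones(57) * 100)
        b = RedAreaTimeSeries("w2", TIMES + 0.1, np.ones(57) * 100)
        with pytest.raises(ValueError, match="time grid"):
            killing_rate(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        """Multiplying both series by c > 0 leaves the rate unchanged."""
        rng = np.random.default_rng(7)
        base = 10_000 + rng.normal(0, 200, 57).cumsum()
        base = np.clip(base, 10.0, None)
        ctrl = np.clip(base + 500, 10.0, None)
        r1 = killing_rate(series(base), series(ctrl)).rate_pct_per_h
        r2 = killing_rate(series(base * c), series(ctrl * c)).rate_pct_per_h
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_time_shift_invariance_of_selected_slope(self):
        """Shifting both series by whole sampling steps leaves the
        selected slope unchanged."""
        rng = np.random.default_rng(11)
        areas = np.clip(8000 + rng.normal(0, 150, 57).cumsum(), 10, None)
        _, s0 = steepest_window(series(areas), 6.0)
        shifted = RedAreaTimeSeries("w", TIMES + 3 * 0.25, areas)
        _, s1 = steepest_window(shifted, 6.0)
        assert s0 == pytest.approx(s1)


class TestCohortHelpers:
    def test_mean_control_averages(self):
        c1 = series(np.full(57, 100.0), role="control")
        c2 = series(np.full(57, 300.0), role="control")
        assert np.allclose(mean_control([c1, c2]).areas_um2, 200.0)

    def test_per_well_pairing_requires_equal_counts(self):
        tr = [series(np.full(57, 100.0))]
        co = [series(np.full(57, 100.0), role="control")] * 2
        with pytest.raises(ValueError, match="equal"):
            killing_rates(tr, co, pairing="per_well")


class TestSummaries:
    def test_fold_change_identity_and_ratio(self):
        assert fold_change([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert fold_change([2, 4, 6], [1, 2, 3]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            fold_change([], [1.0])
        with pytest.raises(ValueError, match="zero"):
            fold_change([1.0], [0.0])

    def test_paired_suppression_bounds(self):
        assert paired_suppression([(5.0, 5.0), (2.0, 2.0)]) == 0.0
        assert paired_suppression([(5.0, 0.0), (2.0, 0.0)]) == 100.0

    def test_paired_suppression_names_bad_pair(self):
        with pytest.raises(ValueError, match="pair 1"):
            paired_suppression([(5.0, 1.0), (0.0, 1.0)])
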