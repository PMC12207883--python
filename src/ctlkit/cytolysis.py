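"""Proliferation-corrected killing-rate estimation from red-area curves.

Target cells carry a red fluorescent protein; the per-well red object area
(um^2) is quantified every 15 min for 14 h.  The change in red area is the
ordinary-least-squares gradient of the treated series over its steepest
contiguous 6-h window, and the killing rate is the difference between the
control-well and treated-well gradients over the *same* window, normalized
to the mean treated area over the first hour and expressed in percent per
hour.  A rate of 10 %/h constitutes efficient killing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np


@dataclass
class RedAreaTimeSeries:
    """Per-well red-object area versus time."""

    well_id: str
    times_h: np.ndarray
    areas_um2: np.ndarray
    role: str = "treated"          # {"treated", "control"}
    group: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.areas_um2, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times_h and areas_um2 must be 1-D and equal length")
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        if np.any(a < 0):
            raise ValueError("areas must be non-negative")
        self.times_h, self.areas_um2 = t, a

    @property
    def step_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])


@dataclass
class KillRateResult:
    rate_pct_per_h: float
    window_start_h: float
    slope_treated_um2_per_h: float
    slope_control_um2_per_h: float
    reference_area_um2: float
    treated_id: str = ""
    control_id: str = ""


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def steepest_window(series: RedAreaTimeSeries, window_h: float,
                    mode: Literal["negative", "abs"] = "negative",
                    ) -> tuple[float, float]:
    """(window_start_h, slope) of the steepest OLS fit over any contiguous
    window of length ``window_h`` aligned to the sampling grid.

    ``mode="negative"`` (default) selects the most negative slope — the
    killing direction; ``mode="abs"`` selects the largest magnitude.  Ties
    break to the earliest window.
    """
    npts = int(round(window_h / series.step_h)) + 1
    if npts > len(series.times_h):
        raise ValueError(
            f"series spans {series.times_h[-1] - series.times_h[0]:g} h, "
            f"shorter than the {window_h:g}-h window")
    slopes = np.array([
        _ols_slope(series.times_h[i:i + npts], series.areas_um2[i:i + npts])
        for i in range(len(series.times_h) - npts + 1)
    ])
    key = slopes if mode == "negative" else -np.abs(slopes)
    # earliest window among numerical ties
    tol = 1e-9 * (1.0 + float(np.abs(key).max()))
    i = int(np.flatnonzero(key <= key.min() + tol)[0])
    return float(series.times_h[i]), float(slopes[i])


def killing_rate(treated: RedAreaTimeSeries, control: RedAreaTimeSeries,
                 window_h: float = 6.0,
                 reference_span_h: float = 1.0,
                 mode: Literal["negative", "abs"] = "negative",
                 ) -> KillRateResult:
    """Proliferation-corrected killing rate in percent of reference area
    per hour (positive = killing).

    The window is selected on the treated series; the control slope is
    computed over the same window; the reference area is the mean treated
    area over the first ``reference_span_h`` hours.
    """
    if len(treated.times_h) != len(control.times_h) or not np.allclose(
            treated.times_h, control.times_h):
        raise ValueError("treated and control series must share a time grid")
    start_h, slope_t = steepest_window(treated, window_h, mode=mode)
    npts = int(round(window_h / treated.step_h)) + 1
    i = int(np.argmin(np.abs(treated.times_h - start_h)))
    slope_c = _ols_slope(control.times_h[i:i + npts],
                         control.areas_um2[i:i + npts])
    early = treated.times_h <= treated.times_h[0] + reference_span_h + 1e-9
    ref = float(treated.areas_um2[early].mean())
    if ref <= 0:
        raise ValueError("non-positive reference area")
    return KillRateResult(
        rate_pct_per_h=(slope_c - slope_t) / ref * 100.0,
        window_start_h=start_h,
        slope_treated_um2_per_h=slope_t,
        slope_control_um2_per_h=slope_c,
        reference_area_um2=ref,
        treated_id=treated.well_id,
        control_id=control.well_id,
    )


def mean_control(controls: Sequence[RedAreaTimeSeries]) -> RedAreaTimeSeries:
    """Group-mean control curve (the default pairing for treated wells)."""
    if not controls:
        raise ValueError("no control series")
    t0 = controls[0].times_h
    for c in controls[1:]:
        if not np.allclose(c.times_h, t0):
            raise ValueError("control series must share a time grid")
    return RedAreaTimeSeries(
        well_id="control_mean", times_h=t0.copy(),
        areas_um2=np.mean([c.areas_um2 for c in controls], axis=0),
        role="control", group=controls[0].group)


def killing_rates(treated: Sequence[RedAreaTimeSeries],
                  controls: Sequence[RedAreaTimeSeries],
                  window_h: float = 6.0,
                  pairing: Literal["group_mean", "per_well"] = "group_mean",
                  window_select: Literal["group", "per_well"] = "group",
                  ) -> list[KillRateResult]:
    """Killing rate for each treated well of a condition.

    ``pairing="group_mean"`` (default) compares every treated well with the
    mean control curve; ``"per_well"`` pairs wells by position and requires
    equal counts.  ``window_select="group"`` (default) locates the steepest
    window once on the mean treated curve and fits every well's slopes over
    that shared window — the window is a property of the condition
    kinetics, and per-well selection would inflate rates through
    max-statistics on noise; ``"per_well"`` selects per well instead.
    """
    if pairing == "group_mean":
        ctrls: Sequence[RedAreaTimeSeries] = [mean_control(controls)] \
            * len(treated)
    else:
        if len(treated) != len(controls):
            raise ValueError("per-well pairing requires equal well counts")
        ctrls = controls

    if window_select == "per_well":
        return [killing_rate(tr, c, window_h)
                for tr, c in zip(treated, ctrls)]

    mean_treated = RedAreaTimeSeries(
        well_id="treated_mean", times_h=treated[0].times_h.copy(),
        areas_um2=np.mean([t.areas_um2 for t in treated], axis=0),
        role="treated", group=treated[0].group)
    start_h, _ = steepest_window(mean_treated, window_h)
    npts = int(round(window_h / mean_treated.step_h)) + 1
    i = int(np.argmin(np.abs(mean_treated.times_h - start_h)))
    out = []
    for tr, c in zip(treated, ctrls):
        if not np.allclose(tr.times_h, c.times_h):
            raise ValueError("treated and control series must share a grid")
        slope_t = _ols_slope(tr.times_h[i:i + npts], tr.areas_um2[i:i + npts])
        slope_c = _ols_slope(c.times_h[i:i + npts], c.areas_um2[i:i + npts])
        early = tr.times_h <= tr.times_h[0] + 1.0 + 1e-9
        ref = float(tr.areas_um2[early].mean())
        out.append(KillRateResult(
            rate_pct_per_h=(slope_c - slope_t) / ref * 100.0,
            window_start_h=start_h, slope_treated_um2_per_h=slope_t,
            slope_control_um2_per_h=slope_c, reference_area_um2=ref,
            treated_id=tr.well_id, control_id=c.well_id))
    return out


def fold_change(values_a: Iterable[float], values_b: Iterable[float]) -> float:
    """Ratio of means, mean(a)/mean(b)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fold_change requires non-empty collections")
    mb = b.mean()
    if mb == 0:
        raise ValueError("denominator mean is zero")
    return float(a.mean() / mb)


def paired_suppression(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean percent reduction over (value_ctl, value_sil) pairs:
    mean of (1 - sil/ctl) x 100."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("paired_suppression requires at least one pair")
    reductions = []
    for i, (ctl, sil) in enumerate(pairs):
        if ctl <= 0:
            raise ValueError(f"pair {i}: value_ctl={ctl} must be > 0")
        reductions.append((1.0 - sil / ctl) * 100.0)
    return float(np.mean(reductions))
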