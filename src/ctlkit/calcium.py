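"""Fura-2 ratiometric calcium traces aligned to tight coupling.

Cells loaded with Fura-2 are imaged with alternating 340-nm and 380-nm
excitation every 10 s; the background-subtracted 340/380 intensity ratio is
proportional to the cytoplasmic calcium concentration.  No absolute
calibration is applied — the raw ratio is the readout.  Ratios are computed
on cell-mean (or pre-extracted) intensities rather than pixelwise to limit
noise amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RatioTrace:
    cell_id: str
    times_s: np.ndarray
    ratio: np.ndarray               # NaN where the 380 denominator failed
    t_couple_s: float
    n_clamped: int = 0              # negative numerators clamped to 0
    n_invalid: int = 0              # non-positive denominators -> NaN


def fura2_ratio(f340, f380, bg340, bg380):
    """(f340 - bg340) / (f380 - bg380), elementwise.

    Negative numerators clamp to 0; non-positive denominators yield NaN.
    Returns ``(ratio, n_clamped, n_invalid)``.
    """
    num = np.asarray(f340, dtype=float) - np.asarray(bg340, dtype=float)
    den = np.asarray(f380, dtype=float) - np.asarray(bg380, dtype=float)
    n_clamped = int(np.sum(num < 0))
    num = np.maximum(num, 0.0)
    invalid = den <= 0
    n_invalid = int(np.sum(invalid))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, np.nan, num / np.where(invalid, 1.0, den))
    if np.isscalar(f340):
        return float(ratio), n_clamped, n_invalid
    return ratio, n_clamped, n_invalid


def build_trace(cell_id: str, times_s: np.ndarray, f340: np.ndarray,
                f380: np.ndarray, bg340, bg380,
                t_couple_s: float) -> RatioTrace:
    ratio, n_cl, n_inv = fura2_ratio(f340, f380, bg340, bg380)
    return RatioTrace(cell_id=cell_id, times_s=np.asarray(times_s, float),
                      ratio=np.asarray(ratio, float),
                      t_couple_s=float(t_couple_s),
                      n_clamped=n_cl, n_invalid=n_inv)


def trace_summary(trace: RatioTrace) -> tuple[float, float, float]:
    """(baseline_mean, post_couple_mean, delta) of the ratio around
    coupling; frames with invalid ratios are ignored."""
    pre = trace.times_s < trace.t_couple_s
    post = ~pre
    baseline = float(np.nanmean(trace.ratio[pre])) if pre.any() else np.nan
    after = float(np.nanmean(trace.ratio[post])) if post.any() else np.nan
    return baseline, after, after - baseline


def align_ratio_traces(traces, frame_interval_s: float = 10.0):
    """Cohort mean +/- SEM of the ratio on a grid of times relative to
    coupling (nearest-frame alignment)."""
    import pandas as pd

    rows = []
    for tr in traces:
        rel = tr.times_s - tr.t_couple_s
        grid = np.rint(rel / frame_interval_s) * frame_interval_s
        for t, r in zip(grid, tr.ratio):
            rows.append({"time_s": float(t), "ratio": r})
    df = pd.DataFrame(rows).dropna()
    out = df.groupby("time_s").agg(ratio_mean=("ratio", "mean"),
                                   ratio_sem=("ratio", "sem"),
                                   n=("ratio", "count")).reset_index()
    return out.fillna({"ratio_sem": 0.0})
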