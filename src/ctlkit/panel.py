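"""Exhaustion-marker panel scoring: gating, positivity, MFI, concordance.

Cytometry data enter as a tidy table (cell_id, condition, is_fmo, marker,
intensity).  Positivity gates are set from fluorescence-minus-one (FMO)
controls; populations are gated sequentially (CD45+ CD14- CD19- CD3+ CD8+);
per-marker changes between conditions are scored against the direction
expected for exhausted CD8+ T cells with pairwise two-sided Mann-Whitney
U tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

MARKER_COLUMNS = ["cell_id", "condition", "is_fmo", "marker", "intensity"]


def to_wide(table: pd.DataFrame, is_fmo: bool = False) -> pd.DataFrame:
    """Pivot the tidy marker table to cells x markers (scored cells only
    by default), keeping the condition column."""
    sub = table[table["is_fmo"] == is_fmo]
    wide = sub.pivot_table(index=["cell_id", "condition"], columns="marker",
                           values="intensity").reset_index()
    wide.columns.name = None
    return wide


def gate_threshold(fmo_intensities, quantile: float = 0.995) -> float:
    """Positivity threshold: the stated quantile of the FMO distribution."""
    x = np.asarray(list(fmo_intensities), dtype=float)
    if len(x) == 0:
        raise ValueError("empty FMO sample")
    return float(np.quantile(x, quantile))


def fmo_thresholds(table: pd.DataFrame, condition: str | None = None,
                   quantile: float = 0.995) -> dict[str, float]:
    """Per-marker FMO thresholds, optionally restricted to one condition."""
    fmo = table[table["is_fmo"]]
    if condition is not None:
        fmo = fmo[fmo["condition"] == condition]
    out = {}
    for marker, grp in fmo.groupby("marker"):
        out[marker] = gate_threshold(grp["intensity"], quantile)
    return out


def sequential_gate(wide: pd.DataFrame, chain,
                    thresholds: dict[str, float]) -> pd.DataFrame:
    """Apply an ordered chain of (marker, sign) gates to a wide table.

    sign "+" keeps cells above the marker's threshold, "-" keeps cells at
    or below it.  An empty chain is the identity.
    """
    out = wide
    for marker, sign in chain:
        if marker not in out.columns:
            raise KeyError(f"marker {marker!r} not in table")
        thr = thresholds[marker]
        keep = out[marker] > thr if sign == "+" else out[marker] <= thr
        out = out[keep]
    return out


def percent_positive(intensities, threshold: float) -> float:
    x = np.asarray(list(intensities), dtype=float)
    if len(x) == 0:
        raise ValueError("empty intensity sample")
    return float(np.mean(x > threshold) * 100.0)


def separation_check(intensities, threshold: float,
                     min_fraction: float = 0.05,
                     min_fold: float = 10.0) -> bool:
    """Whether positive and negative sub-populations are unambiguously
    separated: both hold >= ``min_fraction`` of cells and their medians
    differ by >= ``min_fold``."""
    x = np.asarray(list(intensities), dtype=float)
    pos, neg = x[x > threshold], x[x <= threshold]
    if len(pos) < min_fraction * len(x) or len(neg) < min_fraction * len(x):
        return False
    med_neg = np.median(neg)
    if med_neg <= 0:
        return True
    return bool(np.median(pos) / med_neg >= min_fold)


def mfi(intensities, mode: str = "whole",
        threshold: float | None = None) -> float:
    """Median fluorescence intensity of the whole population or, when the
    separation criterion holds, of the positive population only."""
    x = np.asarray(list(intensities), dtype=float)
    if len(x) == 0:
        raise ValueError("empty intensity sample")
    if mode == "whole":
        return float(np.median(x))
    if mode != "positive_only":
        raise ValueError("mode must be 'whole' or 'positive_only'")
    if threshold is None:
        raise ValueError("positive_only MFI requires a threshold")
    pos = x[x > threshold]
    if len(pos) == 0:
        raise ValueError("no positive cells above threshold")
    if not separation_check(x, threshold):
        raise ValueError("populations not unambiguously separated; "
                         "use mode='whole'")
    return float(np.median(pos))


def load_expected_directions() -> pd.DataFrame:
    """The shipped expected-direction table for exhaustion markers
    (marker, expected {up|down}, marker_class)."""
    path = resources.files("ctlkit.data") / "expected_directions.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    missing = {"marker", "expected", "marker_class"} - set(df.columns)
    if missing:
        raise ValueError(f"expected-direction table missing columns {missing}")
    return df


@dataclass
class ConcordanceResult:
    per_marker: pd.DataFrame
    summary: pd.DataFrame


def percent_positive_stats(table: pd.DataFrame, gate_chain=None,
                           quantile: float = 0.995,
                           experiment_col: str = "experiment",
                           ) -> pd.DataFrame:
    """Per-(condition, experiment, marker) percent-positive values.

    Each experiment is gated independently (``gate_chain``, e.g. the CD8
    lineage chain) with thresholds from its own FMO controls.  The result
    feeds :func:`direction_concordance` as replicate observations.
    """
    if experiment_col not in table.columns:
        table = table.assign(**{experiment_col: 0})
    rows = []
    for (cond, exp_id), sub in table.groupby(["condition", experiment_col]):
        thresholds = fmo_thresholds(sub, quantile=quantile)
        wide = to_wide(sub)
        if gate_chain:
            wide = sequential_gate(wide, gate_chain, thresholds)
        for marker, thr in thresholds.items():
            if marker not in wide.columns:
                continue
            x = wide[marker].dropna().values
            if len(x) == 0:
                continue
            rows.append({"condition": cond, experiment_col: exp_id,
                         "marker": marker,
                         "value": percent_positive(x, thr)})
    return pd.DataFrame(rows)


def direction_concordance(stats: pd.DataFrame, expected: pd.DataFrame,
                          comparisons, alpha: float = 0.05,
                          value_col: str = "value") -> ConcordanceResult:
    """Score per-marker changes against their expected exhaustion direction.

    ``stats`` holds replicate observations per (condition, marker) — per-
    experiment percent-positive values (from
    :func:`percent_positive_stats`), or per-cell intensities with one row
    per cell.  ``comparisons`` is a list of (reference_condition,
    test_condition) pairs; the change is median(test) - median(reference),
    tested by a two-sided Mann-Whitney U.  Categories:
    concordant-significant (expected direction and p < alpha),
    concordant-ns, discordant, unchanged (exactly equal medians).
    """
    exp_dir = dict(zip(expected["marker"], expected["expected"]))
    rows = []
    for marker, want in exp_dir.items():
        sub = stats[stats["marker"] == marker]
        for ref, test in comparisons:
            a_vals = sub.loc[sub["condition"] == ref, value_col].values
            b_vals = sub.loc[sub["condition"] == test, value_col].values
            if len(a_vals) == 0 or len(b_vals) == 0:
                raise ValueError(
                    f"no observations for marker {marker!r} in comparison "
                    f"({ref!r}, {test!r})")
            _, p = mannwhitneyu(b_vals, a_vals, alternative="two-sided")
            diff = float(np.median(b_vals) - np.median(a_vals))
            if diff == 0:
                cat = "unchanged"
            else:
                direction = "up" if diff > 0 else "down"
                if direction == want:
                    cat = ("concordant-significant" if p < alpha
                           else "concordant-ns")
                else:
                    cat = "discordant"
            rows.append({"marker": marker, "reference": ref, "test": test,
                         "expected": want, "median_diff": diff,
                         "p_value": float(p), "category": cat})
    per_marker = pd.DataFrame(rows)
    summary = (per_marker.groupby(["reference", "test", "category"])
               .size().rename("n_markers").reset_index())
    return ConcordanceResult(per_marker=per_marker, summary=summary)


def panel_stats(table: pd.DataFrame, quantile: float = 0.995,
                gate_chain=None) -> pd.DataFrame:
    """Percent-positive and MFI per (condition, marker), FMO-gated.

    ``gate_chain`` optionally pre-gates each condition (e.g. the
    CD45+CD14-CD19-CD3+CD8+ lineage chain).  The MFI mode is positive-only
    where the separation criterion holds, flagged in the output.
    """
    rows = []
    for cond, cond_tbl in table.groupby("condition"):
        thresholds = fmo_thresholds(cond_tbl, quantile=quantile)
        wide = to_wide(cond_tbl)
        if gate_chain:
            wide = sequential_gate(wide, gate_chain, thresholds)
        for marker, thr in thresholds.items():
            if marker not in wide.columns:
                continue
            x = wide[marker].dropna().values
            if len(x) == 0:
                continue
            sep = separation_check(x, thr)
            rows.append({
                "condition": cond, "marker": marker, "threshold": thr,
                "percent_positive": percent_positive(x, thr),
                "mfi": mfi(x, "positive_only" if sep else "whole",
                           thr if sep else None),
                "mfi_mode": "positive_only" if sep else "whole",
                "n_cells": len(x)})
    return pd.DataFrame(rows)


#: The lineage gating chain applied before marker scoring.
LINEAGE_CHAIN = [("CD45", "+"), ("CD14", "-"), ("CD19", "-"),
                 ("CD3", "+"), ("CD8", "+")]
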