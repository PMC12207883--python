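"""File formats: tidy CSVs, TIFF stacks with JSON sidecars, ground truth.

Conventions: times carry unit-suffixed column names (``time_s`` for imaging,
``time_h`` for the killing assay); image coordinates are 0-based row-major;
physical units (pixel size, frame interval) travel in the JSON sidecar next
to each TIFF, never in the pixels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .couples import CoupleTrack
from .cytolysis import RedAreaTimeSeries

CURVE_COLUMNS = ["well_id", "role", "group", "time_h", "area_um2"]
TRACK_COLUMNS = ["couple_id", "frame", "time_s", "interface_width_um",
                 "ctl_width_um", "arc_pos_um", "lamella_angles_deg",
                 "contact_flag"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


# -- red-area curves --------------------------------------------------------

def write_curves_csv(curves, path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times_h, c.areas_um2):
            rows.append({"well_id": c.well_id, "role": c.role,
                         "group": c.group, "time_h": t, "area_um2": a})
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


def read_curves_csv(path) -> list[RedAreaTimeSeries]:
    df = pd.read_csv(path)
    _require_columns(df, CURVE_COLUMNS, path)
    out = []
    for wid, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(RedAreaTimeSeries(
            well_id=str(wid), times_h=grp["time_h"].to_numpy(),
            areas_um2=grp["area_um2"].to_numpy(),
            role=str(grp["role"].iloc[0]), group=str(grp["group"].iloc[0])))
    return out


# -- couple tracks ----------------------------------------------------------

def write_tracks_csv(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append({
                "couple_id": tr.couple_id, "frame": k,
                "time_s": tr.times_s[k],
                "interface_width_um": tr.interface_width_um[k],
                "ctl_width_um": tr.ctl_width_um[k],
                "arc_pos_um": tr.arc_pos_um[k],
                "lamella_angles_deg": ";".join(
                    f"{a:.6g}" for a in tr.lamella_angles_deg[k]),
                "contact_flag": bool(tr.contact_flag[k])})
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks_csv(path) -> list[CoupleTrack]:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"lamella_angles_deg": str})
    _require_columns(df, TRACK_COLUMNS, path)
    out = []
    for cid, grp in df.groupby("couple_id", sort=False):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy(dtype=float)
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        angles = [[float(a) for a in s.split(";") if a]
                  for s in grp["lamella_angles_deg"]]
        out.append(CoupleTrack(
            couple_id=str(cid), frame_interval_s=dt, times_s=times,
            interface_width_um=grp["interface_width_um"].to_numpy(float),
            ctl_width_um=grp["ctl_width_um"].to_numpy(float),
            arc_pos_um=grp["arc_pos_um"].to_numpy(float),
            lamella_angles_deg=angles,
            contact_flag=grp["contact_flag"].astype(str).str.lower()
            .isin(["true", "1"]).to_numpy()))
    return out


# -- TIFF + sidecar ---------------------------------------------------------

def write_movie_tiff(stack: np.ndarray, path, pixel_size_um: float,
                     frame_interval_s: float,
                     channel_names=("F-actin", "target")) -> None:
    """Multi-page TIFF (pages = frames x channels) with a JSON sidecar."""
    import tifffile

    path = Path(path)
    stack = np.asarray(stack)
    tifffile.imwrite(path, stack.astype(np.float32))
    sidecar = {"pixel_size_um": pixel_size_um,
               "frame_interval_s": frame_interval_s,
               "channel_names": list(channel_names),
               "shape": list(stack.shape)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_movie_tiff(path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} for movie {path}")
    sidecar = json.loads(sidecar_path.read_text())
    stack = tifffile.imread(path)
    return np.asarray(stack).reshape(sidecar["shape"]), sidecar


def write_mask_tiff(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path) > 0


# -- tables -----------------------------------------------------------------

def write_marker_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_marker_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "condition", "is_fmo", "marker",
                          "intensity"], path)
    df["is_fmo"] = df["is_fmo"].astype(bool)
    return df


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["couple_id", "coupled"], path)
    return df


def write_ground_truth_jsonl(truths, path) -> None:
    with open(path, "w") as fh:
        for gt in truths:
            d = gt.to_dict() if hasattr(gt, "to_dict") else dict(gt)
            fh.write(json.dumps(_json_safe(d)) + "\n")


def read_ground_truth_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _json_safe(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and np.isnan(v):
            v = None
        out[k] = v
    return out
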