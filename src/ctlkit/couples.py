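"""Cell-couple morphodynamics: track extraction and event scoring.

A CTL converts an initial target-cell contact into a *tight cell couple*
when the contact interface widens to roughly the CTL's own width.  Couple
destabilization then proceeds through off-interface lamellae (protrusions
pointing away from the interface), translocation of the CTL over the target
surface, and finally detachment — a polarity reversal with consistent
leading-edge lamellae on the side opposite the interface (physical contact
loss happens later and is not what is scored here).

All detectors are pure functions of a :class:`CoupleTrack` and explicit
thresholds; angles are degrees in [0, 180] measured from the direction of
the interface (0 = pointing at the interface, 180 = directly opposite), all
lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OBSERVATION_HORIZON_S = 900.0


@dataclass
class CoupleTrack:
    """Per-frame geometric state of one CTL-target couple."""

    couple_id: str
    frame_interval_s: float
    times_s: np.ndarray
    interface_width_um: np.ndarray
    ctl_width_um: np.ndarray
    arc_pos_um: np.ndarray
    lamella_angles_deg: list[list[float]]
    contact_flag: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        n = len(self.times_s)
        for name in ("interface_width_um", "ctl_width_um", "arc_pos_um",
                     "contact_flag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of frames")
        if len(self.lamella_angles_deg) != n:
            raise ValueError("lamella_angles_deg length != number of frames")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def width_ratio(self) -> np.ndarray:
        """Interface width relative to CTL width, NaN where CTL width is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.ctl_width_um > 0,
                         self.interface_width_um / self.ctl_width_um, np.nan)
        return r


# ---------------------------------------------------------------------------
# Event detectors
# ---------------------------------------------------------------------------

def detect_tight_coupling(track: CoupleTrack, width_ratio_min: float = 0.8,
                          persist_frames: int = 2) -> float | None:
    """Time (s from movie start) of tight-couple formation, or None.

    Tight coupling is the first frame at which the interface-to-CTL width
    ratio reaches ``width_ratio_min`` and stays there for ``persist_frames``
    consecutive frames.
    """
    r = track.width_ratio
    ok = np.nan_to_num(r, nan=-1.0) >= width_ratio_min
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= persist_frames:
            return float(track.times_s[i - persist_frames + 1])
    return None


def first_off_interface_lamella(track: CoupleTrack, t_couple_s: float,
                                off_angle_min: float = 90.0) -> float | None:
    """Seconds from coupling to the first lamella pointing off-interface.

    Returns None when censored at the end of the track (the observation
    horizon); the caller records the horizon.
    """
    for k in np.flatnonzero(track.times_s >= t_couple_s):
        if any(a >= off_angle_min for a in track.lamella_angles_deg[k]):
            return float(track.times_s[k] - t_couple_s)
    return None


def detect_translocation(track: CoupleTrack, t_couple_s: float,
                         displacement_min_um: float = 5.0) -> bool:
    """True when the interface ever moves > ``displacement_min_um`` along the
    target boundary from its position at coupling (net, not cumulative)."""
    after = track.times_s >= t_couple_s
    if not after.any():
        return False
    ref = track.arc_pos_um[np.flatnonzero(after)[0]]
    disp = np.abs(track.arc_pos_um[after] - ref)
    return bool(np.nanmax(disp) > displacement_min_um)


def detect_detachment(track: CoupleTrack, t_couple_s: float,
                      opposite_angle_min: float = 150.0,
                      persist_frames: int = 3,
                      ) -> tuple[bool, float | None]:
    """Polarity reversal: a lamella opposite the interface held over
    ``persist_frames`` consecutive frames.

    Returns ``(detached, t_detach_s)`` with the time of the first frame of
    the persistent run, relative to coupling; ``(False, None)`` otherwise.
    """
    idx = np.flatnonzero(track.times_s >= t_couple_s)
    run = 0
    for k in idx:
        hit = any(a >= opposite_angle_min for a in track.lamella_angles_deg[k])
        run = run + 1 if hit else 0
        if run >= persist_frames:
            t0 = track.times_s[k - persist_frames + 1]
            return True, float(t0 - t_couple_s)
    return False, None


def interface_diameter_ratio(track: CoupleTrack, t_couple_s: float,
                             at_times_s) -> np.ndarray:
    """Width ratio sampled at the nearest frame to each requested time
    after coupling."""
    out = []
    for tau in np.atleast_1d(at_times_s):
        k = int(np.argmin(np.abs(track.times_s - (t_couple_s + tau))))
        out.append(track.width_ratio[k])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def score_events(tracks, width_ratio_min: float = 0.8,
                 couple_persist_frames: int = 2,
                 off_angle_min: float = 90.0,
                 displacement_min_um: float = 5.0,
                 opposite_angle_min: float = 150.0,
                 detach_persist_frames: int = 3) -> pd.DataFrame:
    """Run every detector on a collection of tracks -> tidy event table.

    One row per initial contact; event-time columns are NaN when the event
    was not observed, with the observation horizon in ``horizon_s``.
    """
    rows = []
    for tr in tracks:
        t_c = detect_tight_coupling(tr, width_ratio_min, couple_persist_frames)
        row = {"couple_id": tr.couple_id, "coupled": t_c is not None,
               "t_couple_s": np.nan, "t_first_off_lamella_s": np.nan,
               "translocated": False, "detached": False,
               "t_detach_s": np.nan,
               "horizon_s": float(tr.times_s[-1])}
        if t_c is not None:
            row["t_couple_s"] = t_c
            lam = first_off_interface_lamella(tr, t_c, off_angle_min)
            if lam is not None:
                row["t_first_off_lamella_s"] = lam
            row["translocated"] = detect_translocation(
                tr, t_c, displacement_min_um)
            det, t_d = detect_detachment(
                tr, t_c, opposite_angle_min, detach_persist_frames)
            row["detached"] = det
            if t_d is not None:
                row["t_detach_s"] = t_d
        rows.append(row)
    return pd.DataFrame(rows)


def coupling_fraction(events: pd.DataFrame) -> float:
    """Coupled couples / total initial contacts."""
    if len(events) == 0:
        raise ValueError("empty event table")
    return float(events["coupled"].mean())


# ---------------------------------------------------------------------------
# Track extraction from two-channel movies
# ---------------------------------------------------------------------------

def _foreground_mask(frame: np.ndarray):
    """Largest Otsu-thresholded connected component, or None."""
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    if np.ptp(frame) == 0:
        return None
    mask = frame > threshold_otsu(frame)
    if mask.sum() < 5:
        return None
    lab = label(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == np.argmax(counts)


def _boundary(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return mask & ~binary_erosion(mask)


def _lamella_angles(ctl_mask: np.ndarray, iface_centroid: np.ndarray,
                    pixel_size_um: float, near_target: np.ndarray,
                    opening_radius_um: float = 1.6,
                    min_area_um2: float = 0.5) -> tuple[list[float], np.ndarray]:
    """Protrusion angles relative to the interface direction.

    Protrusions are the connected residues of a binary opening of the cell
    mask (structuring disc of radius ``opening_radius_um``): boundary
    extensions too narrow to survive the opening.  Residues abutting the
    target (``near_target``) belong to the interface, as do the slivers the
    opening shaves off the interface corners, and are not lamellae.  Also
    returns the body (opened-mask) boundary points used for robust width
    measurement.
    """
    from scipy.ndimage import binary_opening
    from skimage.measure import label
    from skimage.morphology import disk

    r_px = max(int(round(opening_radius_um / pixel_size_um)), 1)
    body_mask = binary_opening(ctl_mask, structure=disk(r_px))
    if not body_mask.any():
        body_mask = ctl_mask
    cy, cx = np.nonzero(body_mask)
    c = np.array([cy.mean(), cx.mean()])
    u = iface_centroid - c
    phi_iface = np.degrees(np.arctan2(u[0], u[1])) % 360.0

    residue = ctl_mask & ~body_mask & ~near_target
    angles_deg: list[float] = []
    lab = label(residue)
    min_px = min_area_um2 / pixel_size_um ** 2
    for region_id in range(1, lab.max() + 1):
        ry, rx = np.nonzero(lab == region_id)
        if len(ry) < min_px:
            continue
        mean_phi = np.degrees(np.arctan2(ry.mean() - c[0],
                                         rx.mean() - c[1])) % 360.0
        d = abs(mean_phi - phi_iface) % 360.0
        angles_deg.append(min(d, 360.0 - d))
    # Width-bearing body boundary: the full cell outline minus protrusion
    # residues (interface-corner slivers shaved by the opening stay in).
    body = np.argwhere(_boundary(ctl_mask) & ~residue)
    return angles_deg, body


def extract_track(movie: np.ndarray, pixel_size_um: float,
                  frame_interval_s: float, couple_id: str = "couple",
                  contact_dist_um: float = 1.0) -> CoupleTrack:
    """Segment a two-channel movie into a geometric couple track.

    ``movie`` has shape (T, 2, H, W): channel 0 is the CTL (F-actin
    reporter), channel 1 the target cell.  Per frame: per-channel Otsu
    threshold + largest component; the contact arc is the set of CTL
    boundary pixels within ``contact_dist_um`` of the target mask; the
    interface chord is the largest pairwise distance between contact
    pixels; the CTL width is the Feret extent of the cell-body boundary
    parallel to the chord.
    """
    from scipy.ndimage import distance_transform_edt
    from scipy.spatial.distance import pdist, squareform

    movie = np.asarray(movie)
    if movie.ndim != 4 or movie.shape[1] != 2:
        raise ValueError("movie must have shape (T, 2, H, W)")
    if movie.shape[0] < 2:
        raise ValueError("movie must have at least 2 frames")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    n = movie.shape[0]
    iw = np.zeros(n)
    cw = np.zeros(n)
    theta = np.full(n, np.nan)
    contact = np.zeros(n, dtype=bool)
    lam: list[list[float]] = [[] for _ in range(n)]
    missing = [0, 0]
    target_radius_um = np.nan

    for t in range(n):
        ctl = _foreground_mask(movie[t, 0])
        tgt = _foreground_mask(movie[t, 1])
        if ctl is None:
            missing[0] += 1
        if tgt is None:
            missing[1] += 1
        if ctl is None or tgt is None:
            continue

        dist_to_tgt = distance_transform_edt(~tgt) * pixel_size_um
        arc = _boundary(ctl) & (dist_to_tgt <= contact_dist_um)
        pts = np.argwhere(arc)
        if len(pts) < 2:
            cw[t] = 2.0 * np.sqrt(ctl.sum() / np.pi) * pixel_size_um
            continue
        contact[t] = True

        d = squareform(pdist(pts.astype(float)))
        i, j = np.unravel_index(np.argmax(d), d.shape)
        iw[t] = (d[i, j] + 1.0) * pixel_size_um
        chord = (pts[j] - pts[i]).astype(float)
        chord /= np.linalg.norm(chord)

        iface_c = pts.mean(axis=0)
        near_tgt = dist_to_tgt <= 1.5 * contact_dist_um
        angles, body = _lamella_angles(ctl, iface_c, pixel_size_um, near_tgt)
        lam[t] = angles
        proj = body @ chord
        cw[t] = (proj.max() - proj.min() + 1.0) * pixel_size_um

        ty, tx = np.nonzero(tgt)
        tc = np.array([ty.mean(), tx.mean()])
        v = iface_c - tc
        theta[t] = np.arctan2(v[0], v[1])
        target_radius_um = np.sqrt(tgt.sum() / np.pi) * pixel_size_um

    for ch, miss in enumerate(missing):
        if miss >= n / 2.0:
            raise ValueError(
                f"channel {ch} has no foreground in {miss}/{n} frames")

    good = ~np.isnan(theta)
    arc_pos = np.zeros(n)
    if good.any() and np.isfinite(target_radius_um):
        th = theta.copy()
        th[~good] = np.interp(np.flatnonzero(~good), np.flatnonzero(good),
                              theta[good])
        arc_pos = np.unwrap(th) * target_radius_um
        arc_pos -= arc_pos[np.flatnonzero(good)[0]]

    times = np.arange(n) * float(frame_interval_s)
    return CoupleTrack(couple_id=couple_id, frame_interval_s=frame_interval_s,
                       times_s=times, interface_width_um=iw,
                       ctl_width_um=cw, arc_pos_um=arc_pos,
                       lamella_angles_deg=lam, contact_flag=contact)
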