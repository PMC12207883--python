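"""Synthetic geometric couple tracks with complete ground truth.

Each simulated initial CTL-target contact independently converts to a tight
cell couple.  Coupled tracks carry 46 frames at 20-s spacing from coupling
with per-frame interface geometry (interface chord width, CTL width, arc
position of the interface on the target boundary) and lamella angles;
destabilization events (first off-interface lamella, translocation,
detachment) are drawn from the preset's observed statistics via the
censoring-inverted latent distributions in :mod:`ctlkit.sim.events`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ..couples import CoupleTrack
from ..presets import Preset, get_preset
from . import events as ev

#: Persistence (frames) a detachment lamella must hold; detection therefore
#: requires onset no later than frame N_FRAMES - DETACH_PERSIST.
DETACH_PERSIST = 3
_DETACH_MAX_FRAME = ev.N_FRAMES - DETACH_PERSIST  # 43

CTL_WIDTH_UM = 9.0
UNCOUPLED_RATIO = 0.30

#: Width-ratio draw: sd and clip bounds.  The lower clip guarantees that
#: coupled tracks clear the tight-coupling threshold (0.8) robustly.
RATIO_SD = 0.06
RATIO_LO, RATIO_HI = 0.82, 1.20


@lru_cache(maxsize=None)
def _clipped_normal_loc(target_mean: float, sd: float = RATIO_SD,
                        lo: float = RATIO_LO, hi: float = RATIO_HI) -> float:
    """Location of a normal whose [lo, hi]-clipped mean equals the target."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    def clipped_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return (lo * norm.cdf(a) + hi * norm.sf(b)
                + loc * (norm.cdf(b) - norm.cdf(a))
                + sd * (norm.pdf(a) - norm.pdf(b)))

    return brentq(lambda L: clipped_mean(L) - target_mean,
                  lo - 6 * sd, hi + 6 * sd, xtol=1e-9)


@dataclass
class TrackGroundTruth:
    """Every draw made while generating one contact, censored and latent."""

    contact_id: str
    preset_id: str
    coupled: bool
    width_ratio: float = np.nan
    lamella_time_latent_s: float = np.nan
    lamella_frame: int | None = None          # None = censored
    lamella_time_obs_s: float | None = None
    translocated: bool = False
    translocation_onset_s: float | None = None
    detach_flag: bool = False                  # latent (pre-censoring) flag
    detach_time_latent_s: float = np.nan
    detach_frame: int | None = None            # None = not detached in window
    detach_time_obs_s: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, (np.floating, np.integer)):
                d[k] = v.item()
        return d


def _nearest_frame(t_s: float) -> int:
    return int(np.rint(t_s / ev.FRAME_S))


def gen_couple_tracks(preset_id: str | Preset, n_contacts: int, seed: int,
                      frame_interval_s: float = ev.FRAME_S,
                      ) -> tuple[list[CoupleTrack], list[TrackGroundTruth]]:
    """Simulate ``n_contacts`` initial contacts under a condition preset.

    ``preset_id`` may also be a :class:`~ctlkit.presets.Preset` instance,
    e.g. for custom conditions.  Returns the geometric tracks and a
    parallel list of ground-truth records.  Uncoupled contacts yield a
    full-length track whose interface never widens (width ratio ~0.3), so
    tight-coupling detection fails on them.
    """
    if n_contacts < 0:
        raise ValueError("n_contacts must be >= 0")
    preset = (preset_id if isinstance(preset_id, Preset)
              else get_preset(preset_id))
    preset_id = preset.preset_id
    rng = np.random.default_rng(seed)

    m_lam = ev.latent_lamella_mean(preset.lamella_delay_mean_s)
    m_wait = ev.latent_detach_wait_mean(
        preset.detach_time_mean_min * 60.0, m_lam, _DETACH_MAX_FRAME)
    p_det = ev.detection_prob(m_lam, m_wait, _DETACH_MAX_FRAME)
    detach_flag_prob = min(1.0, preset.detach_prob / p_det)

    tracks: list[CoupleTrack] = []
    truths: list[TrackGroundTruth] = []
    times = np.arange(ev.N_FRAMES) * frame_interval_s

    for i in range(n_contacts):
        cid = f"{preset_id}_c{i:05d}"
        coupled = rng.random() < preset.coupling_prob
        gt = TrackGroundTruth(contact_id=cid, preset_id=preset_id,
                              coupled=bool(coupled))
        if not coupled:
            tracks.append(_uncoupled_track(cid, times, rng))
            truths.append(gt)
            continue

        # Interface geometry.
        loc = _clipped_normal_loc(preset.interface_width_ratio_mean)
        ratio = float(np.clip(rng.normal(loc, RATIO_SD), RATIO_LO, RATIO_HI))
        gt.width_ratio = ratio
        ctl_w = float(rng.normal(CTL_WIDTH_UM, 0.4))

        # First off-interface lamella.
        t_lam = float(rng.exponential(m_lam))
        gt.lamella_time_latent_s = t_lam
        k_lam = _nearest_frame(t_lam)
        if k_lam <= ev.N_FRAMES - 1:
            gt.lamella_frame = k_lam
            gt.lamella_time_obs_s = k_lam * frame_interval_s

        # Detachment = lamella onset + extra wait (polarity reversal).
        gt.detach_flag = bool(rng.random() < detach_flag_prob)
        if gt.detach_flag:
            t_det = t_lam + float(rng.exponential(m_wait))
            gt.detach_time_latent_s = t_det
            k_det = max(_nearest_frame(t_det), k_lam)
            if k_det <= _DETACH_MAX_FRAME:
                gt.detach_frame = k_det
                gt.detach_time_obs_s = k_det * frame_interval_s

        # Translocation over the target surface.
        gt.translocated = bool(rng.random() < preset.translocation_prob)
        if gt.translocated:
            onset = int(rng.integers(5, 26))
            gt.translocation_onset_s = onset * frame_interval_s

        tracks.append(_coupled_track(cid, times, ratio, ctl_w, gt, rng))
        truths.append(gt)

    return tracks, truths


def _uncoupled_track(cid: str, times: np.ndarray,
                     rng: np.random.Generator) -> CoupleTrack:
    n = len(times)
    ctl_w = np.full(n, CTL_WIDTH_UM) + rng.normal(0, 0.1, n)
    iw = ctl_w * np.clip(UNCOUPLED_RATIO + rng.normal(0, 0.04, n), 0.05, 0.6)
    arc = np.cumsum(rng.normal(0, 0.15, n))
    angles = [[] for _ in range(n)]
    return CoupleTrack(couple_id=cid, frame_interval_s=float(times[1] - times[0]),
                       times_s=times.copy(), interface_width_um=iw,
                       ctl_width_um=ctl_w, arc_pos_um=arc,
                       lamella_angles_deg=angles,
                       contact_flag=np.ones(n, dtype=bool))


def _coupled_track(cid: str, times: np.ndarray, ratio: float, ctl_w0: float,
                   gt: TrackGroundTruth,
                   rng: np.random.Generator) -> CoupleTrack:
    n = len(times)
    dt = float(times[1] - times[0])
    ctl_w = ctl_w0 + rng.normal(0, 0.08, n)
    per_frame_ratio = np.clip(ratio + rng.normal(0, 0.015, n), 0.81, 1.2)
    iw = ctl_w * per_frame_ratio

    # Arc position: jitter, plus a monotone drift when translocated.
    arc = rng.normal(0, 0.15, n).cumsum() * 0.3
    if gt.translocated:
        onset = int(round(gt.translocation_onset_s / dt))
        total = rng.uniform(7.0, 12.0) * rng.choice([-1.0, 1.0])
        ramp = np.clip((np.arange(n) - onset) / max(n - 1 - onset, 1), 0, 1)
        arc = arc + total * ramp

    angles: list[list[float]] = []
    for k in range(n):
        frame_angles: list[float] = []
        # Occasional interface-proximal ruffles (must not trigger detectors).
        if rng.random() < 0.3:
            frame_angles.append(float(rng.uniform(10, 60)))
        if gt.lamella_frame is not None and k >= gt.lamella_frame:
            frame_angles.append(float(rng.uniform(95, 145)))
        if gt.detach_frame is not None and k >= gt.detach_frame:
            frame_angles.append(float(rng.uniform(155, 178)))
        angles.append(frame_angles)

    return CoupleTrack(couple_id=cid, frame_interval_s=dt,
                       times_s=times.copy(), interface_width_um=iw,
                       ctl_width_um=ctl_w, arc_pos_um=arc,
                       lamella_angles_deg=angles,
                       contact_flag=np.ones(n, dtype=bool))
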