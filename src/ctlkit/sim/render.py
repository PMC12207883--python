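"""Render two-channel image stacks from geometric couple tracks.

An image-level stand-in for spinning-disk midplane data: the target cell is
a large disc, the CTL a disc flattened against a shared straight contact
line so that the rendered interface chord equals the track's interface
width.  Channel 0 carries an F-actin-weighted CTL intensity — a contact
band enriched over cytoplasm, with the central third of the band dimmed
according to the preset's central-clearance parameter — and channel 1 the
target cell.  Optional Poisson photon noise.
"""

from __future__ import annotations

import numpy as np

from ..couples import CoupleTrack
from ..presets import get_preset

PIXEL_SIZE_UM = 0.25
IMAGE_SHAPE = (192, 192)
TARGET_RADIUS_UM = 7.0

BG = 10.0
CYTO = 100.0
BAND_BOOST = 0.6
LAMELLA_INTENSITY = 150.0
TARGET_INTENSITY = 80.0
LAMELLA_RADIUS_UM = 1.3
BAND_DEPTH_UM = 1.5


def render_couple_movie(track: CoupleTrack,
                        pixel_size_um: float = PIXEL_SIZE_UM,
                        image_shape: tuple[int, int] = IMAGE_SHAPE,
                        seed: int = 0,
                        central_clearance: float | str = 0.0,
                        noise: bool = True) -> np.ndarray:
    """Render a track into a (T, 2, H, W) float stack.

    ``central_clearance`` may be a number in [0, 1] (0 = uniform contact
    band, 1 = central third at cytoplasmic background) or a preset id whose
    clearance value is used.
    """
    if len(track) == 0:
        raise ValueError("cannot render an empty track")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if isinstance(central_clearance, str):
        central_clearance = get_preset(central_clearance).central_clearance
    if not 0.0 <= float(central_clearance) <= 1.0:
        raise ValueError("central_clearance must be in [0, 1]")

    rng = np.random.default_rng(seed)
    h, wpx = image_shape
    yy, xx = np.mgrid[0:h, 0:wpx].astype(float) * pixel_size_um
    t0 = np.array([h, wpx], dtype=float) * pixel_size_um / 2.0

    frames = np.empty((len(track), 2, h, wpx), dtype=float)
    for t in range(len(track)):
        frames[t] = _render_frame(track, t, yy, xx, t0,
                                  float(central_clearance))
    frames += BG
    if noise:
        frames = rng.poisson(frames).astype(float)
    return frames


def _render_frame(track: CoupleTrack, t: int, yy, xx, t0,
                  clearance: float) -> np.ndarray:
    r_t = TARGET_RADIUS_UM
    cw = float(track.ctl_width_um[t])
    r = max(cw / 2.0, 1.0)
    chord = float(np.clip(track.interface_width_um[t], 0.0, 0.999 * cw))
    phi = np.pi + float(track.arc_pos_um[t]) / r_t
    n = np.array([np.sin(phi), np.cos(phi)])     # (y, x) unit, target -> CTL
    tang = np.array([n[1], -n[0]])

    # Shared flat contact line at distance x_t from the target centre.
    w_flat = min(chord + 3.0, 2.0 * r_t - 1.0)
    x_t = np.sqrt(max(r_t ** 2 - (w_flat / 2.0) ** 2, 0.0))
    x_cut = np.sqrt(max(r ** 2 - (chord / 2.0) ** 2, 0.0))
    c = t0 + (x_t + x_cut) * n                    # CTL centre

    dn = (yy - t0[0]) * n[0] + (xx - t0[1]) * n[1]     # along n, from target
    dtan = (yy - t0[0]) * tang[0] + (xx - t0[1]) * tang[1]
    d_tgt = np.hypot(yy - t0[0], xx - t0[1])
    d_ctl = np.hypot(yy - c[0], xx - c[1])

    target_mask = (d_tgt <= r_t) & (dn <= x_t)
    ctl_mask = (d_ctl <= r) & (dn >= x_t)

    # Lamellae: circular protrusions on the CTL boundary at the stored
    # angles from the interface direction (consistent side).
    u_int = -n
    lam_mask = np.zeros_like(ctl_mask)
    for ang in track.lamella_angles_deg[t]:
        a = np.radians(ang)
        v = np.array([
            u_int[0] * np.cos(a) + u_int[1] * np.sin(a),
            -u_int[0] * np.sin(a) + u_int[1] * np.cos(a),
        ])
        bc = c + r * v
        bump = (np.hypot(yy - bc[0], xx - bc[1]) <= LAMELLA_RADIUS_UM) \
            & (dn >= x_t)
        lam_mask |= bump

    ch1 = np.zeros_like(yy)
    ch1[ctl_mask | lam_mask] = CYTO
    in_band = ctl_mask & (np.abs(dn - x_t) <= BAND_DEPTH_UM) \
        & (np.abs(dtan) <= chord / 2.0)
    central = in_band & (np.abs(dtan) <= chord / 6.0)
    ch1[in_band] = CYTO * (1.0 + BAND_BOOST)
    ch1[central] = CYTO * (1.0 + BAND_BOOST * (1.0 - clearance))
    ch1[lam_mask & ~ctl_mask] = LAMELLA_INTENSITY

    ch2 = np.zeros_like(yy)
    ch2[target_mask] = TARGET_INTENSITY
    return np.stack([ch1, ch2])
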