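"""Synthetic binary spheroid cross-section masks with analytic ground truth."""

from __future__ import annotations

import numpy as np


def gen_spheroid_mask(shape: str, params: dict | None = None,
                      seed: int = 0) -> np.ndarray:
    """Binary mask of a ``disc``, ``ellipse`` or irregular ``blob``.

    disc:    radius_px (default 50)
    ellipse: a_px, b_px semi-axes (default 60, 30), angle_deg (default 0)
    blob:    radius_px (default 50), amplitude (default 0.15, fraction of
             radius), n_harmonics (default 6); the boundary is a smooth
             random harmonic perturbation of a circle.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if shape == "disc":
        r = float(params.get("radius_px", 50))
        n = int(np.ceil(2 * r)) + 9
        yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2.0
        return (yy ** 2 + xx ** 2) <= r ** 2

    if shape == "ellipse":
        a = float(params.get("a_px", 60))
        b = float(params.get("b_px", 30))
        ang = np.radians(float(params.get("angle_deg", 0.0)))
        n = int(np.ceil(2 * max(a, b))) + 9
        yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2.0
        xr = xx * np.cos(ang) + yy * np.sin(ang)
        yr = -xx * np.sin(ang) + yy * np.cos(ang)
        return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    if shape == "blob":
        r0 = float(params.get("radius_px", 50))
        amp = float(params.get("amplitude", 0.15))
        nh = int(params.get("n_harmonics", 6))
        n = int(np.ceil(2 * r0 * (1 + amp) )) + 9
        yy, xx = np.mgrid[0:n, 0:n] - (n - 1) / 2.0
        theta = np.arctan2(yy, xx)
        rr = np.hypot(yy, xx)
        bound = np.full_like(theta, r0)
        for k in range(2, 2 + nh):
            ak = rng.normal(0.0, amp / k) * r0
            ph = rng.uniform(0, 2 * np.pi)
            bound = bound + ak * np.cos(k * theta + ph)
        return rr <= bound

    raise ValueError(f"unknown shape {shape!r}; use disc, ellipse or blob")
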