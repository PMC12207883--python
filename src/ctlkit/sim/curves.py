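"""Synthetic red-object-area time series for the imaging killing assay.

The assay images adherent mCherry/tdTomato target cells every 15 min for
14 h.  Control wells (no CTL) grow exponentially; treated wells additionally
lose area at the preset's true killing rate, expressed as a per-hour percent
of the first-hour mean area and starting after a fixed 1-h onset lag (target
adhesion and first contacts).  Because the killing deficit is linear in time
after the lag, the steepest-window estimator is insensitive to the lag and,
on noiseless data, recovers the preset rate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..cytolysis import RedAreaTimeSeries
from ..presets import get_preset

TIMES_H = np.round(np.arange(57) * 0.25, 4)   # 0..14 h, 15-min cadence
A0_UM2 = 10_000.0
ONSET_LAG_H = 1.0


@dataclass
class CurveGroundTruth:
    well_id: str
    preset_id: str
    role: str
    kill_rate_true_pct_per_h: float
    proliferation_rate_per_h: float
    onset_lag_h: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)


def gen_red_area_curves(preset_treated: str, preset_control: str,
                        n_wells: int, noise_cv: float, seed: int,
                        ) -> tuple[list[RedAreaTimeSeries],
                                   list[CurveGroundTruth]]:
    """Matched treated/control well curves (``n_wells`` of each).

    Control wells follow ``preset_control``'s proliferation with no killing;
    treated wells follow ``preset_treated``'s proliferation plus its true
    kill-rate deficit.  Areas are clipped at zero, then multiplied by i.i.d.
    lognormal noise with coefficient of variation ``noise_cv``.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    p_t = get_preset(preset_treated)
    p_c = get_preset(preset_control)
    rng = np.random.default_rng(seed)

    first_hour = TIMES_H <= ONSET_LAG_H + 1e-9

    curves: list[RedAreaTimeSeries] = []
    truths: list[CurveGroundTruth] = []
    for role, preset in (("treated", p_t), ("control", p_c)):
        growth = A0_UM2 * np.exp(preset.proliferation_rate_per_h * TIMES_H)
        area = growth.copy()
        kill = preset.kill_rate_true_pct_per_h if role == "treated" else 0.0
        if kill:
            ref = growth[first_hour].mean()
            deficit = kill / 100.0 * ref * np.clip(TIMES_H - ONSET_LAG_H,
                                                   0.0, None)
            area = np.clip(area - deficit, 0.0, None)
        for w in range(n_wells):
            noisy = area * _noise(rng, noise_cv, len(TIMES_H))
            wid = f"{preset.preset_id}_{role}_{w:03d}"
            curves.append(RedAreaTimeSeries(
                well_id=wid, times_h=TIMES_H.copy(), areas_um2=noisy,
                role=role, group=preset.preset_id))
            truths.append(CurveGroundTruth(
                well_id=wid, preset_id=preset.preset_id, role=role,
                kill_rate_true_pct_per_h=kill,
                proliferation_rate_per_h=preset.proliferation_rate_per_h,
                onset_lag_h=ONSET_LAG_H))
    return curves, truths


def gen_ifng_endpoints(preset_id: str, n: int, cv: float,
                       seed: int) -> np.ndarray:
    """Endpoint IFN-gamma supernatant concentrations (pg/ml), lognormal
    around the preset mean with the given CV."""
    preset = get_preset(preset_id)
    rng = np.random.default_rng(seed)
    return preset.ifng_mean_pg_ml * _noise(rng, cv, n)
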