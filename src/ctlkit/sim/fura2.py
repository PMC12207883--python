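"""Synthetic paired 340/380-nm Fura-2 intensity traces.

91 time points at 10-s cadence (0-900 s).  Each cell couples with a target
at a drawn time; responder presets step their ratio up by the preset's
calcium amplitude at coupling (a sustained plateau), suppressed presets
stay flat.  Intensities carry multiplicative measurement noise; the 340-nm
signal is constructed from the target ratio profile and the noisy 380-nm
signal, so the generating ratio is exactly the step profile before noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..presets import get_preset

N_POINTS = 91
DT_S = 10.0
BASELINE_RATIO = 0.8
F380_LEVEL = 600.0
BG340 = 50.0
BG380 = 50.0
NOISE_CV = 0.02


@dataclass
class Fura2Cell:
    cell_id: str
    times_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    bg340: float
    bg380: float
    t_couple_s: float


@dataclass
class Fura2GroundTruth:
    cell_id: str
    preset_id: str
    t_couple_s: float
    baseline_ratio: float
    amplitude: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def gen_fura2_frames(preset_id: str, n_cells: int, seed: int,
                     noise_cv: float = NOISE_CV,
                     ) -> tuple[list[Fura2Cell], list[Fura2GroundTruth]]:
    """Paired 340/380 traces for ``n_cells`` cells under a preset."""
    preset = get_preset(preset_id)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(N_POINTS) * DT_S

    cells, truths = [], []
    for i in range(n_cells):
        t_couple = float(rng.integers(12, 31)) * DT_S
        ratio = np.full(N_POINTS, BASELINE_RATIO)
        ratio[times >= t_couple] += preset.calcium_amplitude
        mult = (rng.lognormal(-np.log1p(noise_cv ** 2) / 2.0,
                              np.sqrt(np.log1p(noise_cv ** 2)),
                              (2, N_POINTS)) if noise_cv > 0
                else np.ones((2, N_POINTS)))
        f380 = BG380 + (F380_LEVEL - BG380) * mult[0]
        f340 = BG340 + ratio * (F380_LEVEL - BG380) * mult[1]
        cid = f"{preset_id}_cell{i:04d}"
        cells.append(Fura2Cell(cell_id=cid, times_s=times.copy(),
                               f340=f340, f380=f380, bg340=BG340,
                               bg380=BG380, t_couple_s=t_couple))
        truths.append(Fura2GroundTruth(
            cell_id=cid, preset_id=preset_id, t_couple_s=t_couple,
            baseline_ratio=BASELINE_RATIO,
            amplitude=preset.calcium_amplitude))
    return cells, truths
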