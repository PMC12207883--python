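"""Synthetic flow-cytometry marker tables with FMO controls.

Each condition draws cells from a small set of leukocyte populations
(CD8 T, CD4 T, B, monocyte, other); lineage markers are positive or
negative by population, and the exhaustion-panel markers are drawn from a
two-component lognormal mixture whose positive fraction and positive-
component median are preset per condition.  One FMO sample per (condition,
marker) is drawn from the negative component only.

The SIL condition is parameterized so that, relative to three-day
stimulated PBMC, PD-1/CTLA-4/LAG-3 shift up and CXCR5/Ki67 shift down (the
expected exhaustion directions), TIGIT is unchanged and TCF-1 moves
opposite to expectation — five of the seven panel markers concordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NEG_MEDIAN = 100.0
NEG_SIGMA = 0.5
POS_SIGMA = 0.4

CONDITIONS = ["PBMC_unstim", "PBMC_stim3d", "1G4_CTL", "1G4_SIL",
              "patient_blood", "patient_TIL"]

LINEAGE_MARKERS = ["CD45", "CD14", "CD19", "CD3", "CD8"]
PANEL_MARKERS = ["PD-1", "CTLA-4", "LAG-3", "TIGIT", "TCF-1", "CXCR5",
                 "Ki67", "TIM-3", "CD25", "CD28"]

#: Population mix per condition: (cd8_t, cd4_t, b, mono, other).
POPULATION_MIX = {
    "PBMC_unstim":   (0.15, 0.25, 0.10, 0.20, 0.30),
    "PBMC_stim3d":   (0.30, 0.40, 0.05, 0.10, 0.15),
    "1G4_CTL":       (0.94, 0.02, 0.01, 0.01, 0.02),
    "1G4_SIL":       (0.92, 0.02, 0.01, 0.01, 0.04),
    "patient_blood": (0.15, 0.25, 0.10, 0.20, 0.30),
    "patient_TIL":   (0.35, 0.30, 0.05, 0.10, 0.20),
}

#: Lineage-marker positivity by population.
_LINEAGE_POS = {
    "CD45": {"cd8_t", "cd4_t", "b", "mono", "other"},
    "CD14": {"mono"},
    "CD19": {"b"},
    "CD3": {"cd8_t", "cd4_t"},
    "CD8": {"cd8_t"},
}

#: (positive fraction, positive-component median) per condition for CD8 T
#: cells; non-CD8 populations draw panel markers from the negative
#: component.
PANEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "PD-1":   {"PBMC_unstim": (0.08, 2000), "PBMC_stim3d": (0.45, 2000),
               "1G4_CTL": (0.60, 2500), "1G4_SIL": (0.92, 4000),
               "patient_blood": (0.15, 2000), "patient_TIL": (0.90, 4000)},
    "CTLA-4": {"PBMC_unstim": (0.05, 1500), "PBMC_stim3d": (0.20, 1500),
               "1G4_CTL": (0.35, 1800), "1G4_SIL": (0.55, 2200),
               "patient_blood": (0.08, 1500), "patient_TIL": (0.40, 1800)},
    "LAG-3":  {"PBMC_unstim": (0.04, 1500), "PBMC_stim3d": (0.35, 1800),
               "1G4_CTL": (0.75, 2500), "1G4_SIL": (0.80, 2500),
               "patient_blood": (0.08, 1500), "patient_TIL": (0.45, 1800)},
    "TIGIT":  {"PBMC_unstim": (0.25, 1800), "PBMC_stim3d": (0.50, 1800),
               "1G4_CTL": (0.50, 2400), "1G4_SIL": (0.50, 3600),
               "patient_blood": (0.30, 1800), "patient_TIL": (0.55, 2400)},
    "TCF-1":  {"PBMC_unstim": (0.60, 1500), "PBMC_stim3d": (0.04, 1500),
               "1G4_CTL": (0.08, 1500), "1G4_SIL": (0.10, 1500),
               "patient_blood": (0.55, 1500), "patient_TIL": (0.10, 1500)},
    "CXCR5":  {"PBMC_unstim": (0.20, 1500), "PBMC_stim3d": (0.30, 1500),
               "1G4_CTL": (0.12, 1500), "1G4_SIL": (0.08, 1200),
               "patient_blood": (0.20, 1500), "patient_TIL": (0.10, 1200)},
    "Ki67":   {"PBMC_unstim": (0.03, 2000), "PBMC_stim3d": (0.85, 3000),
               "1G4_CTL": (0.55, 2500), "1G4_SIL": (0.35, 2000),
               "patient_blood": (0.05, 2000), "patient_TIL": (0.25, 2000)},
    "TIM-3":  {"PBMC_unstim": (0.05, 1800), "PBMC_stim3d": (0.40, 2000),
               "1G4_CTL": (0.80, 3000), "1G4_SIL": (0.85, 3200),
               "patient_blood": (0.08, 1800), "patient_TIL": (0.50, 2200)},
    "CD25":   {"PBMC_unstim": (0.05, 2000), "PBMC_stim3d": (0.70, 3000),
               "1G4_CTL": (0.90, 4000), "1G4_SIL": (0.88, 3800),
               "patient_blood": (0.08, 2000), "patient_TIL": (0.30, 2200)},
    "CD28":   {"PBMC_unstim": (0.80, 2500), "PBMC_stim3d": (0.85, 2500),
               "1G4_CTL": (0.55, 2200), "1G4_SIL": (0.45, 2200),
               "patient_blood": (0.80, 2500), "patient_TIL": (0.60, 2200)},
}

POS_MEDIAN_LINEAGE = 5000.0
FMO_N = 300


@dataclass
class MarkerGroundTruth:
    condition: str
    n_cells: int
    population_counts: dict[str, int]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _lognormal(rng, median: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(np.log(median), sigma, n)


def gen_marker_table(conditions, n_cells_per_condition: int, seed: int,
                     fmo_n: int = FMO_N,
                     ) -> tuple[pd.DataFrame, list[MarkerGroundTruth]]:
    """Tidy marker table (cell_id, condition, is_fmo, marker, intensity,
    population) plus ground truth, for the requested conditions."""
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition label {c!r}; known: "
                             f"{', '.join(CONDITIONS)}")
    if n_cells_per_condition < 0:
        raise ValueError("n_cells_per_condition must be >= 0")
    rng = np.random.default_rng(seed)
    pops = ["cd8_t", "cd4_t", "b", "mono", "other"]

    frames = []
    truths = []
    for cond in conditions:
        n = n_cells_per_condition
        if n == 0:
            # No scored cells: no FMO needed either (empty table, no error).
            truths.append(MarkerGroundTruth(cond, 0, {p: 0 for p in pops}))
            continue
        pop = rng.choice(pops, size=n, p=POPULATION_MIX[cond])
        ids = np.array([f"{cond}_{i:05d}" for i in range(n)])
        counts = {p: int(np.sum(pop == p)) for p in pops}
        truths.append(MarkerGroundTruth(cond, n, counts))

        for marker in LINEAGE_MARKERS:
            is_pos = np.isin(pop, list(_LINEAGE_POS[marker]))
            x = _lognormal(rng, NEG_MEDIAN, NEG_SIGMA, n)
            x[is_pos] = _lognormal(rng, POS_MEDIAN_LINEAGE, POS_SIGMA,
                                   int(is_pos.sum()))
            frames.append(pd.DataFrame(
                {"cell_id": ids, "condition": cond, "is_fmo": False,
                 "marker": marker, "intensity": x, "population": pop}))

        for marker in PANEL_MARKERS:
            frac, med = PANEL_PARAMS[marker][cond]
            x = _lognormal(rng, NEG_MEDIAN, NEG_SIGMA, n)
            cd8 = pop == "cd8_t"
            pos = cd8 & (rng.random(n) < frac)
            x[pos] = _lognormal(rng, med, POS_SIGMA, int(pos.sum()))
            frames.append(pd.DataFrame(
                {"cell_id": ids, "condition": cond, "is_fmo": False,
                 "marker": marker, "intensity": x, "population": pop}))

        # FMO controls: one negative-component sample per marker.
        for marker in LINEAGE_MARKERS + PANEL_MARKERS:
            x = _lognormal(rng, NEG_MEDIAN, NEG_SIGMA, fmo_n)
            fmo_ids = [f"{cond}_fmo_{marker}_{i:04d}" for i in range(fmo_n)]
            frames.append(pd.DataFrame(
                {"cell_id": fmo_ids, "condition": cond, "is_fmo": True,
                 "marker": marker, "intensity": x, "population": "fmo"}))

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["cell_id", "condition", "is_fmo",
                                      "marker", "intensity", "population"])
    return table, truths


def gen_marker_experiments(conditions, n_cells_per_condition: int,
                           n_experiments: int, seed: int,
                           ) -> pd.DataFrame:
    """Stack independent experiment repeats with an ``experiment`` column,
    as used for per-experiment pairwise comparisons between conditions."""
    tables = []
    for e in range(n_experiments):
        table, _ = gen_marker_table(conditions, n_cells_per_condition,
                                    seed + 10_007 * e)
        table = table.assign(experiment=e)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
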