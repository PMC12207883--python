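# ctlkit

Quantification of cytotoxic T lymphocyte (CTL) effector function and its
suppression, for labs using live-cell imaging, calcium imaging, spheroid
co-culture and spectral flow cytometry to characterize primary human CTL —
including the spheroid-suppressed state that models T-cell exhaustion in
vitro.

`ctlkit` implements, as a tested and reusable pipeline:

- **Killing-rate estimation** from red-object-area time courses of an
  imaging cytotoxicity assay.  Target cells carry a red fluorescent
  protein; the per-well red area A(t) (µm²) is imaged every 15 min for
  14 h.  The killing rate is proliferation-corrected and normalized:

      rate = (m_control − m_treated) / A_ref × 100   [% per hour]

  where m is the ordinary-least-squares gradient over the steepest
  contiguous 6-h window of the treated series (the control gradient is
  taken over the same window) and A_ref is the mean treated area over the
  first hour.  A rate of 10 %/h constitutes efficient killing.
- **Cell-couple morphodynamics** from two-channel time-lapse movies or
  pre-extracted geometric tracks (20-s cadence, 15 min): tight-coupling
  detection (interface as wide as the CTL), time to the first
  off-interface lamella, translocation over the target surface, and
  detachment (persistent polarity reversal), with censoring at the
  observation window.
- **Interface F-actin enrichment**: mean reporter intensity over the
  contact band — and over the central third of the interface chord —
  relative to the whole cell, aligned to the time of tight coupling.
  Central F-actin clearance distinguishes productive couples.
- **Fura-2 calcium traces**: background-subtracted 340/380 nm excitation
  ratio (proportional to cytoplasmic calcium) at 10-s cadence, with
  baseline/post-coupling summaries.
- **Spheroid morphometry**: cross-section area, perimeter, circularity
  4πA/P² and roundness 4A/(π·major-axis²) from binary masks.
- **Exhaustion-marker panel scoring**: FMO-based gates, sequential
  CD45⁺CD14⁻CD19⁻CD3⁺CD8⁺ lineage gating, percent-positive and MFI rules,
  and expected-direction concordance (pairwise Mann–Whitney U) for the
  exhaustion panel (PD-1, CTLA-4, LAG-3, TIGIT, TCF-1, CXCR5, Ki67).
- **A synthetic-data generator** (`ctlkit.sim`) that emulates every input
  with known ground truth, parameterized by a preset table of published
  condition statistics — so the full pipeline is testable without any
  data download.

## Worked example

Estimate killing rates for six simulated wells of the strong-stimulus
condition (true rate 10 %/h, 5% measurement noise), then score couple
morphodynamics of the spheroid-suppressed (SIL) condition:

```python
import numpy as np
from ctlkit.sim import gen_red_area_curves, gen_couple_tracks
from ctlkit.cytolysis import killing_rates
from ctlkit.couples import score_events, coupling_fraction

curves, _ = gen_red_area_curves("1G4_CTL_Mel624_pep",
                                "1G4_CTL_Mel624_pep", 6, 0.05, 7)
treated = [c for c in curves if c.role == "treated"]
control = [c for c in curves if c.role == "control"]
rates = [r.rate_pct_per_h for r in killing_rates(treated, control)]
print([round(r, 2) for r in rates], round(np.mean(rates), 2))

tracks, _ = gen_couple_tracks("1G4_SIL_Mel624_pep", 300, 4)
events = score_events(tracks)
coupled = events[events["coupled"]]
print(round(coupling_fraction(events), 3),
      round(coupled["t_first_off_lamella_s"].dropna().mean(), 1))
```

prints

```
[10.55, 9.55, 9.45, 9.75, 10.44, 10.53] 10.05
0.293 29.5
```

— the per-well and mean killing rates recover the 10 %/h ground truth
within noise, and the suppressed cells couple in 29.3% of contacts with
off-interface lamellae after 29.5 s on average: unstable couples despite a
strong stimulus, the morphological signature of suppression.

The same stages are available from the shell:

```bash
ctlkit simulate curves --preset kill_efficient --n 8 --seed 1 --out sim/
ctlkit kill-rate --input sim/curves.csv --out rates.csv
ctlkit run --seed 3 --out run/        # full simulate -> analyze pipeline
```

## Layout

- `src/ctlkit/cytolysis.py` — killing rates, fold changes, paired suppression
- `src/ctlkit/couples.py` — track extraction and event detectors
- `src/ctlkit/factin.py` — interface/central-third enrichment
- `src/ctlkit/calcium.py` — Fura-2 ratio traces
- `src/ctlkit/spheroid.py` — shape metrics
- `src/ctlkit/panel.py` — gating, positivity, MFI, concordance
- `src/ctlkit/sim/` — synthetic generators with ground truth
- `src/ctlkit/presets.py` — the condition preset table
- `docs/methods.md` — models, assumptions, parameter choices, limitations
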