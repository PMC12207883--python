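# Methods

This note documents the models behind `ctlkit`, the tunable parameters and
their defaults, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Killing-rate estimation (`ctlkit.cytolysis`)

The imaging cytotoxicity assay reads out the total red-object area per
well, A(t) in µm², every 15 min for 14 h (57 samples).  Cytolysis appears
as area loss; target-cell proliferation as growth.  The estimator:

1. finds the contiguous window of length `window_h` (default 6 h, aligned
   to the 15-min grid, no sub-sample interpolation) over which the OLS
   gradient of the treated series is most negative (ties break to the
   earliest window; a documented `mode="abs"` flag selects largest
   magnitude instead — the default reads "steepest" in the killing
   direction, since area loss is the quantity of interest);
2. computes the control-series OLS gradient over the *same* window
   (proliferation correction);
3. reports `(m_control − m_treated) / A_ref × 100` in % per hour.

**Normalization reference.** The assay literature reports "% red area
change per hour" without fixing the denominator.  We use the mean treated
area over the first hour (5 samples): robust to single-frame noise,
defined before killing onset, and config-overridable
(`reference_span_h`).

**Cohort estimation** (`killing_rates`). Two defaults matter:

- *Pairing*: each treated well is compared against the group-mean control
  curve (`pairing="group_mean"`); per-well pairing is available.  Whether
  the original assay paired wells individually is not stated; the group
  mean has strictly lower variance.
- *Window selection*: the steepest window is located once on the mean
  treated curve of the condition and then applied to every well
  (`window_select="group"`).  The window is a property of the condition's
  kinetics; selecting it per well would take a maximum over noisy window
  statistics and systematically inflate rates (max-statistics bias, a few
  percent at 5% noise).  Per-well selection remains available, and the
  single-pair `killing_rate` function selects on the series it is given.

IFN-γ enters as endpoint supernatant concentrations (pg/ml); only
descriptive summaries are computed.  `fold_change` is a ratio of means;
`paired_suppression` is the mean over pairs of (1 − SIL/CTL) × 100.

## Couple morphodynamics (`ctlkit.couples`)

A CTL-target couple is described per frame (20 s cadence, 46 frames) by
the interface chord width, the CTL width (Feret extent parallel to the
chord), the arc-length position of the interface centroid on the target
boundary, and the angles of protrusive lamellae measured from the
interface direction (0° = toward the interface, 180° = opposite).

Event operationalizations, all thresholds configurable:

- **Tight coupling**: width ratio ≥ 0.8 sustained for 2 frames.  The
  qualitative definition is "an interface as wide as the CTL"; 0.8 with
  persistence tolerates measurement jitter at the moment of spreading.
- **Off-interface lamella**: any lamella at ≥ 90° after coupling.
- **Translocation**: net (not cumulative) displacement of the interface
  along the target boundary > 5 µm (≈ one CTL radius) from its position
  at coupling.
- **Detachment**: a lamella at ≥ 150° sustained for 3 consecutive frames
  ("consistent" leading-edge lamellae opposite the interface).  This
  scores polarity reversal; physical contact loss occurs later and is not
  scored.

Event times are censored at the 15-min window; censored couples are
excluded from mean-time summaries (matching per-couple dot-plot
statistics).  All detectors are pure functions of the track; each is
checked against a brute-force frame scan in the test suite.

**Track extraction from movies.** Per frame and channel: Otsu threshold,
largest connected component.  The contact arc is the set of CTL boundary
pixels within 1 µm of the target mask; the interface chord is the largest
pairwise distance between contact pixels.  Lamellae are detected
morphologically: connected residues of a binary opening of the CTL mask
(structuring disc radius 1.6 µm, minimum residue area 0.5 µm²) that do not
abut the target; the residue's centroid direction from the opened-body
centroid, relative to the interface direction, is the lamella angle.  The
CTL width is measured on the full boundary minus those residues, so
protrusions do not inflate it.  Quantification is 2-D midplane-only —
consistent with midplane display of the source imaging — and all
thresholds are specified in µm, with the pixel size carried in metadata.
On noise-free renders the width ratio is recovered within 5% per frame
(10% is the tested bound).

## Interface F-actin enrichment (`ctlkit.factin`)

Enrichment is a mean-intensity ratio: mean reporter intensity over a
region divided by the mean over the whole cell.  It is area-independent,
equals exactly 1 under uniformity (and for the whole-cell region), and
the band-area-weighted mean of central-third and peripheral enrichment
reconstructs the whole-interface value exactly.  The whole-interface
region is the set of CTL pixels within 1.5 µm of the contact arc; the
central third is the subset projecting onto the middle third of the
interface chord (chord, not arc).  Both the band depth and the thirds are
configurable.  Summed-fraction normalizations were rejected because they
scale with region area; the exact normalization used by the original
image analysis is not public, so this definition is declared, not
inferred.

## Fura-2 calcium (`ctlkit.calcium`)

Ratio = (F340 − bg340)/(F380 − bg380), computed on cell-mean (or
pre-extracted) intensities rather than pixelwise to limit noise
amplification.  Negative numerators clamp to zero and are counted;
non-positive denominators yield missing values and are counted.  The
default background is the per-frame median outside all cell masks
(configurable to a fixed ROI); no absolute calcium calibration is applied
— the raw ratio is the readout.  `trace_summary` reports baseline mean,
post-coupling mean, and their difference.

## Spheroid morphometry (`ctlkit.spheroid`)

Circularity 4πA/P² and roundness 4A/(π·M²) with M the major axis of the
best-fit ellipse (second moments), the standard particle-analysis
definitions.  The perimeter estimator is the length of the sub-pixel
marching-squares contour after a 5-point moving-average smoothing of its
vertices.  Raw pixel-step chains overestimate smooth boundaries by ~5%
(staircase bias, deflating a disc's circularity to ~0.90); the smoothed
contour is accurate to <1% for discs, squares and rotated shapes alike,
and converges to the geometric perimeter with resolution (tested).
Metrics are invariant to pixel size and uniform scaling and vary <2%
under rotation at adequate resolution.

## Marker panel (`ctlkit.panel`)

Positivity gates are the 0.995 quantile of the per-marker FMO
distribution (standard practice; the source protocol states only that FMO
data set the gates).  Sequential gating applies an ordered chain of
(marker, sign) gates; the shipped lineage chain is
CD45⁺CD14⁻CD19⁻CD3⁺CD8⁺.  MFI defaults to the whole-population median and
switches to the positive population only when the separation criterion
holds — both sub-populations ≥ 5% of cells and medians ≥ 10-fold apart —
a declared operationalization of "unambiguously separated", flagged in
every output row since it changes the reported value.

Expected-direction concordance compares conditions pairwise per marker
with a two-sided Mann–Whitney U test; direction is the sign of the median
difference; categories are concordant-significant (expected direction,
p < 0.05), concordant-ns, discordant, and unchanged (exactly equal
medians).  The intended replicate unit is the independent experiment:
`percent_positive_stats` gates each experiment separately and yields
per-experiment percent-positive values, which is what population-level
marker-change tables compare.  Testing per-cell intensities instead is
possible but conflates cells with replicates and makes median-based
directions unstable for markers whose positive fraction stays below 50%
in both conditions.  Raw p-values are reported without multiple-testing
correction, matching per-marker significance reporting.  The shipped
expected-direction table (`ctlkit/data/expected_directions.csv`) lists
PD-1, CTLA-4, LAG-3, TIGIT up and TCF-1, CXCR5, Ki67 down for exhaustion;
the primary/secondary class split is a package choice (inhibitory
receptors and TCF-1 primary; CXCR5 and Ki67 secondary), as the full
21-antibody panel annotation is not public.

## Synthetic generators (`ctlkit.sim`)

The generators exist so every pipeline stage can be scored against known
ground truth.  Presets encode *observable* condition statistics; the
generator's job is to produce data on which the unmodified pipeline
recovers them.

- **Red-area curves**: control wells grow exponentially (default rate
  0.02 /h, a realistic adherent-line doubling of ~35 h); treated wells
  additionally lose area linearly at the preset killing rate, expressed
  as percent of the first-hour mean area per hour and starting after a
  1-h onset lag (adhesion and first contacts).  The steepest-window
  estimator is insensitive to the lag, and on noiseless curves recovers
  the preset rate to machine precision.  Noise is i.i.d. multiplicative
  lognormal with the requested CV; areas clip at zero.
- **Couple tracks**: contacts couple with the preset probability.  Event
  times are exponential — the simplest memoryless family, since only
  means ± SEM are published.  Because the published numbers are
  *window-censored, frame-quantized observations*, the generator inverts
  the observation process: closed-form bin probabilities give the
  expected observed mean as a function of the latent exponential mean,
  and a scalar root-finder matches it to the preset (`sim/events.py`).
  Detachment is drawn as lamella onset plus an additional exponential
  wait (total calibrated the same way), enforcing the destabilization
  ordering lamella ≤ detachment; the latent detach-flag probability is
  likewise divided by the in-window detection probability.  Ground truth
  records both latent and censored values.  Width ratios are clipped
  normals (clip at 0.82 so coupled tracks robustly clear the 0.8
  detection threshold) with the location calibrated so the clipped mean
  equals the preset mean.
- **Rendering**: cells are discs flattened against a shared straight
  contact line (target radius 7 µm), so the rendered chord equals the
  track's interface width; lamellae are 1.3-µm bumps at their stored
  angles; channel intensities are flat with a contact band boosted 60%
  over cytoplasm and the central third dimmed by the clearance parameter
  (clearance 1 ⇒ central third at cytoplasmic level); Poisson photon
  noise is optional.
- **Fura-2**: 91 points at 10 s; ratio steps from a 0.8 baseline by the
  preset amplitude at a drawn coupling time (a step, so cohort means
  recover the amplitude exactly in expectation); intensities carry 2%
  multiplicative noise.
- **Marker tables**: per condition, cells draw from a five-population
  leukocyte mix; lineage markers are positive by population; panel
  markers are two-component lognormal mixtures (negative median 100,
  σ 0.5; positive medians and fractions per condition) with one
  negative-component FMO sample per (condition, marker).  The SIL vs
  3-day-stimulated parameterization realizes the expected-direction
  pattern: five of seven panel markers shift as expected for exhaustion,
  TIGIT's positive fraction is unchanged and TCF-1 moves slightly up
  (against expectation).
- **Spheroid masks**: analytic discs and ellipses; "blob" masks perturb a
  circle's radius with low-order random harmonics.

What the generators do **not** emulate: real segmentation artifacts
(debris, touching cells, focus drift), z-dimension effects (everything is
midplane), photobleaching, spectral spillover or autofluorescence in
cytometry, well-to-well proliferation heterogeneity, and couple identity
errors.  Passing recovery tests therefore demonstrates correctness of the
estimators and detectors under the stated observation model — not
robustness to every failure mode of real microscopy data.

## Problem sizes and tolerances

Recovery tests use cohorts of 300–800 contacts, 10⁴ draws for
distribution-level fidelity, 6–20 wells per condition and 6 simulated
experiments for the panel comparison — sizes at which binomial/standard
errors are a few percent, so three-standard-error assertions are
meaningful without being slow.  Deterministic identities (noiseless rate,
whole-cell enrichment, oracle equivalences) are asserted to numerical
precision; stochastic recoveries within 3 SEs of the generating value.
All generators are bit-reproducible under fixed seeds.

## Known limitations

- Lamella definitions (angle thresholds, persistence, protrusion
  morphology) are declared operationalizations; the original image
  analysis is described only in non-public supplementary material and may
  differ in detail.
- The coupling-fraction denominator counts *all* initial contacts, though
  tight couples can only form from leading-edge contacts; if a dataset
  annotates contact geometry, the denominator should be restricted
  accordingly.
- `extract_track` assumes one couple per movie and no occlusions or
  collisions; no multi-cell tracking is attempted.
- Spheroid inputs are binary masks; segmentation of raw bright-field
  micrographs is out of scope.
- Cytometry enters as CSV intensity tables; FCS parsing, spectral
  unmixing and clustering/embedding analyses are out of scope.
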