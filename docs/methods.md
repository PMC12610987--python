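# Methods

This note documents the models, parameter choices and numerical decisions
behind `breathsig`, and what the synthetic-data experiments do and do not
demonstrate about real breath data.

## Acquisition model and the simulator

The simulator emulates a buffered end-tidal PTR-TOF-MS acquisition: full
spectra on a dense m/z grid (default 10–685 Da, 0.005 Da spacing), one spectrum
per second for 60 s, 12–16 breath cycles. Ions are deposited as Gaussians with
constant resolving power m/Δm = 1000 (FWHM), adequate for a compact TOF.
Intensities are counts per second (cps).

**Breath waveform.** No published waveform accompanies this kind of recording,
so exhalation is a raised-cosine bump occupying a configurable fraction of each
cycle (default duty 0.5): smooth, differentiable, and with an unambiguous
midpoint that defines the ground-truth end-tidal instant. Wash-in kinetics of
VOCs are not modeled; tracer channels simply co-modulate with the envelope plus
a 2 % inhalation baseline.

**Channels.** Water adduct at m/z 37.038 (baseline 5×10³ cps, exhalation apex
6×10⁵ cps so the EIC crosses the 2×10⁵ cps gate within every breath); tracers
isoprene/dimethyl sulfide/1,2-butadiene at 69.07/63.02/55.03 with exhalation
amplitudes 4/2/1.5 ×10⁴ cps; constant internal standard at 22.0274 (10⁴ cps)
and PerMaSCal calibrants at 21.0220/203.94299/330.85 (5/2/1 ×10⁴ cps). The
water-adduct target follows the instrument convention of the application
(37.038) rather than the theoretical cluster mass; it is configurable.

**Noise** is Gaussian with s.d. `floor + shot·√intensity` (defaults 20 cps and
1.0), clipped at zero — an inexpensive approximation of counting statistics on
the cps scale that reproduces the intensity-dependent scatter tree-based models
see, without full Poisson machinery.

**Mass drift** is mass-proportional: every peak lands at m·(1 + drift_ppm·10⁻⁶).

**Capnostat** is reported in arbitrary "units" on the scale of the 3.5-unit QC
threshold (baseline 0.2, excursion 2.6 by default, i.e. passing); it lags the
water signal by 1 s, which is why it is never used for phase delineation.

**Cohort generator.** Group sizes default to the study scale (160 asthma, 128
COPD, 254 controls). Post-bronchodilator ΔFEV₁ %predicted is drawn per group
from the reported means/s.d.s (16.570 ± 14.040 asthma, 10.583 ± 10.852 COPD,
2 ± 3 controls); ΔFVC adds a smaller independent component, and the BDR label
is then *derived* from the >10 % rule, giving positive rates of roughly 74 %
(asthma) and 56 % (COPD) — close to, though not exactly, the reported 70.1 %
and 45.5 %, which would require a correlation structure the source does not
publish. BDR-positive subjects receive additive biomarker shifts (defaults
+20 ppb FeNO, +0.20 ×10⁹/L eosinophils, +150 IU/mL IgE, −8 % FEV₁ %pred).
Feature channels carry a per-subject latent level (shared between the tidal and
forced maneuvers) plus per-maneuver measurement noise at half the subject s.d.;
planted channels (79.054, 95.054, 118.071, 101.039, 53.037, 71.055, 77.059)
mirror the direction of the reported disease and BDR associations, and 500
uninformative channels model the remaining spectrum.

What passing tests on this generator show: the pipeline recovers structure it
is contractually supposed to recover (cycle counts, planted channels, null
behavior). What they do not show: robustness to real-world artifacts absent
from the generator — overlapping isobars, humidity-dependent ionization,
inter-day drift, irregular breathing, missing maneuvers.

## Preprocessing

**Recalibration.** TOF flight time scales with √m, so the correction is a
quadratic in √(m/z) fitted through the three reference centroids — three
points determine it exactly; residuals therefore measure centroid re-detection
error, not fit error. Centroids use three-point log-parabolic interpolation
around the apex (exact for a noise-free Gaussian), falling back to an
intensity-weighted mean when the log-parabola is ill-conditioned. A reference
apex below 500 cps in the time-averaged spectrum is treated as absent and
raises an error naming the mass. Recalibrating twice changes residuals by
< 1 ppm (idempotence, tested).

**EIC windows** default to ±0.05 Da (no published value); the EIC is the plain
sum of grid intensities in the window, so it scales linearly with intensity.

**Segmentation.** "Local maximum" means a strict maximum over a ±2-spectrum
neighborhood of the lightly smoothed (Savitzky–Golay 5/2) trace, with the first
index of a plateau counting as the maximum — at a 1 s cadence against a ~4 s
breath period, wider neighborhoods merge cycles. Tracer-maximum coincidence
with the water plateau is ±1 spectrum (sub-second tracer lags). The cycle count
is the number of maximal runs of water-above-threshold spectra. Lowering the
water threshold can only grow the selected set (tested monotonicity).

**QC** is the conjunction of capnostat max ≤ 3.5 units (the statistic is
configurable — max by default; the alternative reading, mean, is exposed),
worst calibrant residual < 100 ppm, and ≥ 3 full cycles.

## Featurization

End-tidal spectra are **averaged** (sum and mean differ by a constant the
internal-standard normalization cancels) and smoothed with Savitzky–Golay
window 7, order 3 (no published values; both configurable). Peak windows are
taken at 95 % of the prominence drop; the centroid is the intensity-weighted
mean over the window (scale-invariant), the feature value the trapezoidal area
(apex intensity is available as an alternative; the choice is cancelled by
normalization up to peak-shape effects).

**Alignment** is single-linkage on the pooled, sorted centroids with a
mass-dependent gap threshold interpolated linearly from ±0.015 Da at m/z 42 to
±0.4 Da at m/z 685 (approximately constant relative tolerance across the
published range). Sorting makes it deterministic and sample-order invariant;
ties break toward lower m/z. Features present in strictly more than half of
all samples are kept; missing entries are imputed as 0 (absence = below
detection — defensible on the cps scale because the prevalence rule already
caps sparsity at < 50 %).

**Normalization** divides each sample by its internal-standard feature
(m/z 22.0274), making the matrix invariant to per-sample global intensity
scaling; a missing or non-positive standard raises an error listing the
offending samples. Model features then exclude calibration ions and m/z < 42.

## Annotation

Neutral mass = m/z − 1.00728 Da; the electron mass is deliberately ignored to
keep the arithmetic consistent with the protonation convention (< 8 ppm below
m/z 80, inside the 200 ppm library tolerance but documented here because it
can matter at the 5–10 ppm enumeration tolerance for very light ions). The ppm
convention is signed: (theoretical − measured)/theoretical × 10⁶.

Formula enumeration is a depth-first search, heaviest element first, with
mass-bound pruning; the lightest element's count is solved directly from the
residual mass, so the complexity is the product of the heavy-element ranges.
`max_counts` must be supplied (mass-implied ceilings are available via
`default_max_counts`) — an unbounded search is a config error. Plausibility
requires integer RDBE ≥ 0 (O and S contribute zero; Na counts as a monovalent
substituent) and monovalent atoms ≤ 2C + 2 + N. The tests verify equivalence
with an independent brute-force oracle (pyteomics masses) on 50 random masses
and tolerance nesting.

Isotopologue flagging accepts a +1.00336 Da partner when the median intensity
ratio lies in [0.0107·(1−s), 0.0107·C_max·(1+s)] with slack s = 0.5 and
C_max = ⌊neutral mass/12⌋ — deliberately wide, since the plausible carbon
count is unknown at this stage. The bundled library is a small curated table of
breath-relevant compounds with exact masses computed from atomic masses; the
formic-acid fragment CHO₂⁺ is represented as protonated CO₂ so the [M+H]⁺
arithmetic stays uniform. Annotations are hypotheses; MS/MS confirmation is out
of scope.

## Cohort statistics

BDR labeling uses the strict comparator (ΔFEV₁ or ΔFVC **>** 10 %predicted) as
stated in the methods convention; an inclusive comparator is available because
the literature alternates between the two phrasings. Group comparison routes:
Shapiro–Wilk at α = 0.05 in *every* compared group (the gate level is not
published; 0.05 is the conventional choice) → Welch/ANOVA if all normal,
Mann–Whitney/Kruskal–Wallis otherwise; categorical → chi-square, Fisher's
exact when any expected cell < 5. Missing values are excluded pairwise and the
per-group counts reported. No multiplicity correction is applied (raw p-values
by design); the type-I error of the routed test is verified ≈ nominal on null
simulations.

## Selection and modeling

Stability selection draws ⌊⅔·n⌋ training rows without replacement (redrawing
single-class subsamples), z-scores the subsample (tree ensembles are
scale-insensitive, so this is reproducibility bookkeeping more than
statistics), fits XGBoost (hist, depth 3, 50 trees, η 0.3 by default) and
extracts **gain** importances (weight/cover are available). The per-feature
median over iterations ranks features; per-maneuver top-30 lists are
intersected for the consensus set (ties toward lower m/z; an empty
intersection warns and returns empty). A top-percentile selector (default
10 %) is provided as the alternative phrasing of the same idea; the top-k
intersection is the default path.

Tuning is a small documented grid (depth 2–3, η 0.1/0.3, 50/100 trees,
subsample 0.8/1.0) by mean 5-fold stratified CV AUC, refit on the full
training set. Evaluation computes AUC from predicted probabilities and the
confusion metrics at 0.5, with probability ties counting as positive. LOO
evaluation aggregates all out-of-sample probabilities before computing a
single AUC/confusion table (not a per-fold average). Leakage is prevented by
construction — selection and tuning see only the training partition — and
tested: corrupting held-out rows cannot change training-side importances.

## Problem sizes in tests and the acceptance script

The test suite runs the statistical experiments at reduced but adequately
powered sizes chosen once: 40/group with 50 noise features and 40 resampling
iterations for planted-channel recovery (20 seeds); 20 permutations for the
null-AUC band; 200 iterations on a 200-feature matrix for the selection
plumbing check; 5–6 subjects/group, 30 s recordings on a reduced mass grid for
the end-to-end pipeline. The acceptance script simulates 20 full one-minute
recordings at default noise for the cycle-count bound and one noise-free
drifted recording for the calibration bound.

## Known limitations

- No isotope deconvolution of overlapping peaks and no cross-day drift
  correction; alignment assumes one acquisition context.
- The simulator's breath waveform, duty cycle and VOC kinetics are
  conventions, not physiological claims; absolute intensities are arbitrary.
- Fisher's exact test on tables larger than 2×2 relies on the exact network
  algorithm in SciPy and can be slow for large tables.
- The BDR model's near-perfect synthetic AUC reflects the planted effect
  sizes; it says nothing about clinical transportability.
- Propensity-score matching and covariate-adjusted regressions are not
  implemented.
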