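# Methods

This note documents the models, parameter choices and numerical decisions
behind `ramcal`, and what the synthetic study can and cannot demonstrate.

## The calibration problem

Raman spectra of cell-culture samples superimpose weak analyte bands on a
large water band (~1650 cm⁻¹) and a fluorescence background that grows as
the culture ages. A calibration model maps the pre-treated spectrum to one
analyte concentration. Two properties of fed-batch data make this hard:

1. **Collinearity with batch age.** Glucose falls while titer rises, so a
   naive model can "predict" glucose from the titer bands or from the
   fluorescence level. Such a model collapses as soon as the process
   changes. Spiking individual analytes into samples breaks these
   correlations and widens the calibration range.
2. **Narrow native ranges.** Glutamine and glutamate only span ~1.5 g/L
   over a run; relative to reference-assay noise that is a small signal,
   and models built on unspiked samples alone predict poorly. Spiking to
   ~6 g/L is what makes these analytes calibratable — the central
   qualitative claim the acceptance checks reproduce.

## Study design (experiment_design)

* 24 vessels: 16 DoE rows drawn deterministically (seeded) from the
  2⁴ factorial over inoculation density, glucose feed target, pH and DO
  setpoints, plus 8 identical control vessels. The specific factor values
  are placeholders — only the varied-vs-constant structure matters
  downstream.
* Sampling: one unspiked sample per vessel per day for 14 days; a spiked
  sample additionally on days 6–13. 24 × (14 + 8) = 528 scheduled spectra;
  48 samples on a spiking day. Day 14 carries no spike: the total of 528
  fixes the spiking window to eight days.
* Spike mass balance, with V_eff = V_nominal + pipette offset:

      c_spiked = (c_unspiked·V_sample + c_stock·V_eff) / (V_sample + V_eff)

  a convex combination of sample and stock concentration, monotone in both
  stock concentration and volume. The pipette offset defaults to 0 and can
  be supplied per volume.
* Spike scheme: a deterministic rotation over (analyte × stock level ×
  volume) cells across vessels and days, seeded, guaranteeing that every
  analyte receives low and high stock spikes at several volumes in several
  vessels. The per-analyte stock pairs default to glucose 16/32, lactate
  12/24, glutamine 8/16, glutamate 8/16, titer 10/20 g/L — inside the
  4–32 g/L envelope; the titer pair is set high relative to the ~3.5 g/L
  end-of-run titer so that spiking visibly extends the normalized range.
* Acquisition bookkeeping: each 1-minute sub-spectrum is an average of
  `round(60 s / I_t)` exposures (I_t = 0.2 s → 300, 1 s → 60), and five
  sub-spectra form one sample measurement.

## Synthetic data (synthetic_data)

The generator emulates the statistical structure the analysis assumes —
not CHO biochemistry.

* **Trajectories.** VCD follows a Gaussian-in-time bump (peak 13.8×10⁶
  cells/mL, day 8, width 4.5 d; per-vessel perturbations put the maximum
  near 14.5×10⁶). "Metabolic activity" is VCD relative to peak. Glucose is
  consumed proportionally to activity (1.25 g/L/day at peak) and re-fed by
  a capped daily bolus toward the vessel's DoE target from day 3 — the
  feed-to-target rule keeps every vessel inside the 2–8 g/L envelope,
  which fixed boluses do not (drift integrates over 14 days). Lactate is
  produced until day 7 and consumed after (the metabolic shift); glutamine
  decays (first-order chemical degradation plus uptake); glutamate slowly
  accumulates; titer accumulates with integrated VCD and is normalized to
  the run maximum. Per-vessel multiplicative factors derive from the DoE
  factors plus a 3% lognormal jitter. Defaults were calibrated once so
  pooled unspiked ranges sit inside the study envelopes (glucose 2–8,
  lactate 1.5–11, glutamine 1–2.5, glutamate 0.5–2.5 g/L, titer 0–1).
* **Spectra.** Intensity = gain · [Σ c_a·profile_a + water band +
  fluorescence(ν, day)] + detector noise, on a 200–3300 cm⁻¹ axis at
  2 cm⁻¹. Analyte profiles are Gaussian band sets at literature-typical
  positions (glucose ≈ 1125, lactate ≈ 830 cm⁻¹, …); their exact positions
  are configuration — the analysis only requires that band sets are not
  scalar multiples of each other and that the region table matches the
  library. The water band (1650 cm⁻¹, σ 42, amplitude 60 counts) dominates;
  fluorescence is a spectrally decaying exponential whose amplitude grows
  linearly with batch age (4 counts at day 0, +30%/day); gain jitter is
  lognormal (σ = 5%, shared by the five replicates of one sample);
  detector noise is i.i.d. Gaussian per channel and replicate
  (σ = 0.05 counts). Reference readings add 2% relative noise; titer
  references exist only on even days and for titer-spiked samples
  (emulating a slower offline assay cadence). An optional mixing-bias
  factor (default 1 = homogeneous) perturbs only the spectral, not the
  reference, concentration of spiked samples.
* **Artifacts.** "Empty chamber" multiplies a record by 10⁻⁴. "Bubble"
  applies a water-band-centred attenuation (deepest at 1650 cm⁻¹, fading
  to 1 at the spectral edges), because a bubble displaces the aqueous phase
  from the laser focus; a *flat* attenuation would be cancelled exactly by
  water-band normalization and is therefore not a usable artifact model.
  Strong bubbles (attenuation ≤ ~0.05) fail the raw water-band screen;
  mild ones survive it and must be caught by the PCA diagnostics.

**What passing tests do not show.** The spectra are exactly linear in
concentration, bands do not shift with temperature or matrix, fluorescence
has a fixed shape, and reference noise is uncorrelated. Model metrics are
therefore optimistic (Q² ≈ 0.99 versus ~0.9 on real instrument data); only
the *orderings* (spiked > unspiked for narrow-range analytes; lactate
gains nothing from spiking) and the machinery are transferable claims.

## Pre-treatment (preprocessing)

Order fixed as: screen raw → average replicates → AsLS baseline →
water-band normalization; region selection happens at model-fit time so a
single pre-treatment pass serves all five analytes. Screening operates on
the replicate-averaged raw spectrum (the artifacts modeled here affect
whole records, so per-replicate screening would add nothing).

* **Raw screen.** Fail `empty_chamber` if total intensity < 1000 counts;
  fail `weak_water_band` if the water-band statistic relative to the
  spectrum median < 1.05.
* **AsLS.** Eilers-type iteratively reweighted penalized least squares:
  solve (W + λ D₂ᵀD₂) z = W y, weights p above / 1−p below the baseline.
  Defaults λ = 1e5, p = 0.001, 10 iterations — standard settings that
  recover an injected Gaussian peak on a smooth background to within 5%.
  Implemented with sparse banded solves; cost ~5 ms per 1551-channel
  spectrum.
* **Water-band normalization.** Divide by the trapezoidal band area over
  1650 ± 50 cm⁻¹ (height optional). Exactly cancels multiplicative
  disturbances: scale-invariant, idempotent, removes gain jitter to
  machine precision. Computed after baseline correction.
* SNV + first derivative is available as an alternative toggle but off by
  default.
* Residual imperfection: day-varying fluorescence is removed by AsLS only
  down to ~10⁻³ of the signal scale at non-analyte channels; the
  orthogonal OPLS components absorb what remains.

## Outlier screening (outlier_detection)

PCA on the pre-treated matrix; component count = smallest number
explaining ≥ 99% of variance, capped at 10. The 99% (not 95%) rule is
deliberate: fluorescence and water dominate total variance, and at 95% the
model omits the rare spike-band directions, flagging exactly the
range-extending spiked samples — the opposite of the study's observation
that spiking produces no extra outliers.

Diagnostics per row: Hotelling's T² over the retained scores with the
F-boundary A(n−1)/(n−A)·F₁₋α(A, n−A) (α = 0.05), and DmodX = residual sd
after projection / pooled training residual sd. A row is **flagged** when
(a) it exceeds the T² boundary *and* DmodX > 2 (candidate confirmed), or
(b) DmodX > 3 alone, or (c) T² > 5× the boundary (action limit).
T²-candidates without DmodX confirmation are logged, not flagged: with
structured (non-Gaussian) score clouds the 95% ellipse alone would discard
5–9% of legitimate samples. After the first pass the PCA is refit on the
unflagged rows and all rows re-scored once — a cluster of similar
artifacts otherwise contributes its own principal component and masks
itself. Flags are reversible: flagged rows are excluded from calibration
but kept in the dataset and the log records which limit fired.

## OPLS (chemometrics)

Conventions: X mean-centered (no channel scaling); y centered and scaled
to unit variance; both stored in the model for exact inversion.

Trygg–Wold construction with a single predictive component: w ∝ Xᵀy;
repeatedly take the loading p of t = Xw, split off its part orthogonal to
w (w_o ∝ p − (wᵀp)w), deflate X by the component t_o p_oᵀ; finally regress
y on the last predictive score. Numerical safeguards: w is refreshed from
the deflated X each round (identical in exact arithmetic, keeps orthogonal
scores y-uncorrelated to machine precision), and w_o is re-orthogonalized
against w before and after normalization (cancellation is amplified when
the orthogonal part is small). NIPALS tolerance 1e-10; every fit asserts
|t_oᵀy| < 1e-8·‖t_o‖·‖y‖. Degenerate inputs (constant y, no residual
covariance, n_ortho beyond the data rank) raise.

PLS1 (closed-form NIPALS deflation for a single response) serves as the
independent oracle: OPLS(n_o) and PLS1(1+n_o) predict identically — the
orthogonal split buys interpretability, not accuracy.

Component selection: for n_ortho = 0…6, leave-vessel-out CV; choose the
Q²-maximizing count subject to R² − Q² ≤ 0.3 (ties toward fewer
components); if every candidate violates the guard, return the
smallest-gap candidate flagged as overfit.

## Validation (validation)

Vessels are dealt round-robin (sorted by id; optionally seeded-shuffled)
into k = 4 balanced groups; all samples of a vessel share a group, and
every split asserts train/test vessel disjointness. Q² and RMSEcv are
computed from the *pooled* cross-validation predictions (one prediction
per sample from the fold that held it out), not from per-fold averages.
Titer models run on the normalized 0–1 scale end to end. The reported
model is refit on all usable samples. `holdout_trajectory` excludes one
vessel completely and predicts its daily series — the monitoring scenario.

## Problem sizes

The default study (24 vessels × 14 days, 528 records × 5 replicates ×
1551 channels) runs end to end — generation, pre-treatment, screening and
ten cross-validated calibrations — in roughly 10–15 s on one CPU; the test
suite adds smaller six- and twelve-vessel variants of the same study.

## Known limitations

* One response per model (PLS1/OPLS); no multi-y OPLS, O2PLS or kernel
  variants; no VIP-based variable selection beyond the fixed region table.
* Spectral regions and band positions are self-consistent stand-ins, not
  instrument-validated assignments.
* Dark subtraction exists but is off by default (the generator emits net
  spectra); no cosmic-ray despiking or wavelength/intensity calibration.
* The outlier thresholds (α, DmodX limits, action factor) are heuristics
  in the SIMCA tradition, exposed as configuration; no claim of optimality.
* No plotting layer: the tabular outputs (report.csv, trajectory.csv,
  parity and trajectory series) are the interface; figures are left to the
  analyst.
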