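# Methods

## Problem and scope

`respwatch` re-creates, as a tested pipeline, the external-validation
workflow for continuous-monitoring risk models of respiratory failure
leading to emergent (unplanned) intubation in ICU patients: reconstruction
of mechanical-ventilation epochs from sparse flowsheet charting,
extraction of cardiorespiratory-dynamics predictors in overlapping 30-min
windows, logistic modelling with relative-risk output, and the full
evaluation suite (event-aligned trajectories, signed-rank lag tests,
window-dependent AUC with admission-level bootstrap, decile calibration).
No patient-level data from such studies are publicly deposited, so the
pipeline runs end-to-end on a synthetic cohort whose generator is itself a
first-class, tested component.  The numbers the pipeline produces
therefore validate the *machinery* — that each stage implements its
contract and that the whole chain detects exactly the signal that was
programmed in, and nothing when none was — not any historical model
weights, which were never published.

## Ventilation-epoch reconstruction

Respiratory therapists chart the ventilator respiratory rate every few
hours.  Ventilation is taken to span the first to the last such entry in a
run; runs are split where consecutive entries are **more than 16 h** apart
(strictly: a gap of exactly 16 h merges), and an isolated entry opens a
1 h epoch.  Verified emergent-intubation times are then reconciled so that
every event starts an epoch exactly at the event time; when an event falls
inside a reconstructed epoch, the preceding charting entry is read as the
extubation time.  Epoch membership is closed on both ends, so a feature
window stamped exactly at an extubation is still censored (conservative
exclusion of ventilated data).  Overlaps arising from reconciliation are
merged with ties broken toward longer censoring.

Two edge cases are worth noting.  An event falling exactly at an epoch's
last entry re-opens ventilation from the event time (the preceding entry
becomes the extubation).  And re-applying the rule to an output's own
boundary entries is a fixed point *except* when two isolated entries lie
between 16 h and 16 h + 2·(isolated duration) apart — their synthesized
1 h ends can close the gap back under the threshold; this marginal band is
inherent to the rule, not an implementation artifact.

## Predictors

Features are computed in 30-min windows stepped every 15 min (50% overlap)
and stamped at the window end:

* per-channel sample mean and SD (ddof = 1) of heart rate, respiratory
  rate, SpO2 and systolic blood pressure on the per-minute grid;
* zero-lag Pearson cross-correlation for each of the six channel pairs
  over pairwise-complete samples (the original implementation's exact
  estimator is unpublished; zero-lag Pearson is this package's documented
  choice);
* **SDNN**: sample SD of the RR intervals in the window (ms);
* **COSEn** = SampEn(m, r) + ln(2r) − ln(mean RR), with m = 1 and
  r = 30 ms by default (a conventional tolerance; configurable and recorded
  in model metadata).  SampEn = −ln(A/B) with Chebyshev distance, where A
  counts matching non-self template pairs of length m+1 and B of length m,
  each count running over *all valid start positions for its own template
  length*.  Under this convention the short templates at the record's end
  enter B only, so a constant series yields A/B < 1 rather than exactly 1;
  the exhaustive-enumeration oracle in the tests uses the same convention.
* **DFA variance slope**: the mean-subtracted intervals are integrated,
  partitioned into non-overlapping boxes of n ∈ {4, 8, 16, 32, 64} beats
  from both ends of the record, each box linearly detrended, and the slope
  of log F²(n) on log n returned.  Regressing the *variance* (F²) makes the
  iid-noise reference slope 1.0, i.e. twice the conventional scaling
  exponent α = 0.5; a switch (`dfa_use_squared=False`) regresses log F
  instead for the α convention.

Windows with fewer than 10 vital-sign samples or fewer than 100 beats
yield missing values rather than unstable estimates.  Missing features are
imputed with medians computed on the development split (standing in for
the original development-cohort medians), with per-feature imputation
flags retained.

## Risk models

All models are binary logistic regressions on the imputed features,
differing in basis and horizon: a linear-basis model with a 24 h horizon
(optionally built by forward stepwise selection on AIC, entering features
while ΔAIC < 0; off by default), and two restricted-cubic-spline models
(3 knots per feature at the 10th/50th/90th development percentiles,
Harrell truncated-power form, linear beyond the boundary knots) with 4 h
and 6 h horizons.  A window is labelled positive when
0 < event_time − window_end ≤ horizon (open at zero).  Fitting maximizes
the Bernoulli likelihood with a weak ridge penalty (λ = 1e−6, slopes only)
that stabilizes complete separation; with zero predictors the intercept is
the closed-form logit of prevalence.  Output is *relative risk*: predicted
probability divided by the development-set mean predicted probability, a
fold-increase over the average patient whose development-set mean is 1 by
construction (a consequence of the logistic score equations, verified in
tests).  Relative risks are uncapped by default; a cap option exists
because such models tend to overestimate in the highest decile.

Development and validation halves are disjoint admission sets (stratified
by event status, deterministic under the run seed), emulating external
validation with independent admissions from the same generator.

## Evaluation

* **Event-aligned trajectory**: risk series of event admissions are
  aligned on the intubation time, snapped to the 15-min grid; per offset
  the mean over populated cells is reported with a normal-approximation
  95% ribbon (mean ± 1.96·SD/√n; the ribbon method in the original figures
  is unstated, and a bootstrap option exists).
* **Signed-rank lag test**: at each offset, a one-sided (greater) Wilcoxon
  signed-rank test of the null that risk equals the same patient's risk
  12 h earlier; zero differences dropped; offsets with fewer than 5 pairs
  untested; no multiple-testing correction (matching the per-offset 0.05
  convention).  For n ≤ 25 pairs the p-value is exact, computed by dynamic
  programming over the doubled midranks (so tied magnitudes are handled
  exactly — the reason this is not delegated to `scipy.stats.wilcoxon`,
  whose exact method does not support ties); beyond that, a normal
  approximation with tie correction and continuity correction.
* **AUC versus event window**: for window widths 4–24 h (every 2 h by
  default), epochs within the window before an event are positive;
  controls are all epochs of never-intubated admissions plus far-from-event
  epochs of event admissions; ventilated and DNI epochs are excluded
  everywhere.  95% CIs are percentile intervals over 200 bootstrap
  resamples drawn over *hospital admissions* (all epochs of a sampled
  admission enter together), preserving within-patient correlation;
  single-class replicates are redrawn and counted.
* **Decile calibration**: uncensored measurements ranked by predicted
  relative risk (stable sort on value, admission, time, so the partition is
  reproducible) and cut into 10 equal-count groups; per decile, observed
  relative risk = (fraction of measurements within 12 h of an event) /
  (development mean event probability).  The group-weighted mean of
  observed decile risks equals the overall observed relative risk by
  construction.

## Synthetic cohort: what it emulates and what it does not

Defaults (the study conditions of this artifact, chosen once):

| parameter | default | rationale |
| --- | --- | --- |
| admissions | 150 | desk-scale; ~50 events supports event-aligned averaging |
| event fraction | 1/3 | enriched relative to real ICU incidence (~2%), which would need ~10⁴ admissions for 50 events |
| DNI fraction | 0.05 | exercises the exclusion path |
| stay duration | lognormal, median 48 h, σ_log 0.35, min 30 h | every event admission observed ≥ 24 h pre-event |
| event time | uniform on [24 h, stay − 1 h] | guarantees a pre-event observation day |
| ramp | linear, final 12 h | the slowly-progressive multi-hour deterioration the models target |
| effect sizes | HR +15 bpm, RR +10 /min, SpO2 −6%, SBP −15 mmHg | clinically plausible decompensation magnitudes |
| RR variability | mean 800 ms, SD 50 ms, shrinking ×0.4 at event | loss of heart-rate variability/complexity before deterioration |
| vitals noise | AR(1), lag-1 0.9, marginal SDs 3/2/1/6 | persistent minute-scale physiological noise |
| flowsheet gaps | uniform 1–6 h | typical charting frequency during ventilation |
| missingness | 2% random per-channel dropout | exercises median imputation |

Vitals are sampled at 1/min; RR intervals beat by beat (independent normal
draws, clipped at a 200 ms floor, with the SD ramping down
multiplicatively over the deterioration).  Post-event ventilation runs
24 h or to discharge.  Controls are never ventilated unless
`control_vent_fraction` is set; one event per admission unless
`allow_multiple_events`.

The generator deliberately omits much of real monitoring data: no
waveform-level artifact or ectopy, no circadian or treatment-driven
nonstationarity in controls (the AR(1) choice is a stand-in, not an
inference about any real cohort), no informative missingness, no
admission-level heterogeneity in baselines, and deterioration that is a
clean linear ramp rather than a stuttering decline.  Passing tests
therefore show that the pipeline recovers programmed structure and emits
calibrated null behavior — not that the models would achieve any
particular performance on real patients.

Because the trailing 30-min windows saturate once the ramp completes, the
event-aligned mean trajectory plateaus over roughly the final two hours;
monotonicity checks therefore run on 2 h-binned means from ramp start to
−2 h.

## Numerical and design choices

* Natural logarithms throughout; sample SDs use ddof = 1.
* Cross-correlations are clipped into [−1, 1] against rounding; zero
  variance or < 10 overlapping samples give a missing value.
* The m = 1 sample-entropy counts use a sorted sweep that only visits
  first-component matches (numba-compiled, with a pure-numpy fallback);
  it is exactly equivalent to the O(N²) enumeration and is tested so.
* Degenerate spline knots (heavily tied features) are spread by 1e−9 to
  keep the basis well-defined.
* The single run seed fans out to stages via
  `numpy.random.SeedSequence([seed, stage_index])`; identical config and
  seed give byte-identical CSV outputs (tested).  CSV readers parse floats
  in round-trip mode so tables reload exactly.
* Joint statistical assertions (all 10 calibration deciles, all AUC
  windows of the null cohort) use Bonferroni-adjusted per-comparison bands
  (≈99.5%) so the family-wise level is ~95%; applying a per-comparison 95%
  band jointly to tens of correlated checks would reject correct behavior
  by construction.
* The null-cohort "no signal" check uses the admission-level bootstrap SE
  around 0.5 rather than an iid (Hanley-type) band: epochs within an
  admission are strongly autocorrelated and an iid band would be
  anticonservative.

## Problem sizes

The default analysis run uses 150 admissions (~26,000 uncensored 15-min
epochs); the null control 200 admissions with shorter stays (~28,000
epochs); the oracle-equivalence checks run at N ≤ 200 (exact), the DFA
reference at 100×2,000 beats, parameter recovery and calibration at
50,000 epochs.  These sizes are the package's chosen study conditions for
a desk-scale validation; scaling them up changes precision, not structure.

## Known limitations

* The exact cross-correlation estimator, DFA regression variable (F vs
  F²), sample-entropy tolerance and spline knot placement of the original
  proprietary implementation are unpublished; each is a documented,
  configurable choice here, and conclusions about the original system
  cannot be drawn from this re-creation.
* Multi-event admissions are supported only minimally (a second event may
  be drawn after extubation); events without intervening flowsheet entries
  can collapse the earlier epoch fragment.
* Chart review, event adjudication and tracheostomy identification are out
  of scope; the generator's event times are exact by construction.
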