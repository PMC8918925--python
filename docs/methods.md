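# Methods

`afhf` re-implements, as a tested pipeline over synthetic data, a
beat-to-beat analysis that discriminates patients whose heart failure
was induced by atrial fibrillation (AF-HF) from AF patients without
heart failure, using only RR-interval statistics from long-term ECG.

## Data model and segmentation

The unit of raw data is a per-patient stream of consecutive RR
intervals (ms) with a clock time for the first beat (default 08:00,
matching the 8 a.m.–8 a.m. convention of 24-h Holter recordings).
Beat onset times are the cumulative sums of the intervals, so the
stream fully determines timing; no waveform processing is performed
(QRS detection and artifact screening are upstream of this package).

Streams are cut into non-overlapping windows of 5 min of *cumulative
RR time* (not wall clock), the standard short-term HRV segment length.
A beat belongs to the window containing its onset; the trailing
partial window is discarded. Windows with fewer than `min_beats = 100`
beats are dropped as artifact-dominated (100 beats in 5 min means a
mean RR of 3 s — far outside plausible AF ventricular rates). Window
membership is computed in milliseconds so integer-ms streams segment
exactly. Each window is tagged *day* if its start clock lies in
[08:00, 22:00) and *night* otherwise; windows straddling a boundary
follow their start time (half-open convention, unambiguous at the
boundaries).

The relative RR series is `relRR_n = 100 · RR_n / RR_{n-1}` (ratio
convention, the package default). The symmetrised variant
`200·(RR_n − RR_{n-1})/(RR_n + RR_{n-1})` used elsewhere in the AF
literature is available as `relrr_mode="symmetric"`.

## The 14 features

Per segment, for both the RR and relRR series unless noted:

* **mean, SD, RMSSD** — SD uses the n−1 denominator; RMSSD is the root
  mean square of successive differences.
* **Deceleration/acceleration capacity (DC/AC, RR only)** —
  phase-rectified signal averaging. Anchors are beats longer (DC) or
  shorter (AC) than their predecessor; beat-to-beat changes above
  `anchor_limit = 0.20` (20%) are excluded as likely artifacts, as are
  anchors without `L = 2` beats of context on each side. With the
  anchor-aligned average X(k), capacity = (X(0)+X(1)−X(−1)−X(−2))/4.
  L = 2 is the minimum that forms this quadruple; both knobs are
  configurable. An empty anchor set yields an undefined value.
* **Deceleration reserve (DR, RR only)** — DR = DC + AC. AC is
  negative for roughly stationary series, so DR measures the asymmetry
  between decelerating and accelerating excursions; a time-reversible
  series gives DR = 0 exactly (when the anchor limit is disabled; the
  limit itself is not reversal-symmetric).
* **Shannon entropy** — histogram entropy (bits) with 16 equal-width
  bins spanning the segment's own min–max, hence scale-free; constant
  segments give 0 by convention. Bin count configurable.
* **Sample entropy** — m = 2, Chebyshev distance, tolerance
  r = 0.2·SD of the segment (field-standard defaults); self-matches
  excluded, both template lengths drawn from the common index range so
  the conditional probability is well defined. No matches at either
  length yields an undefined value rather than ±∞.
* **Spectral entropy** — normalised entropy of the raw periodogram of
  the mean-subtracted, beat-indexed tachogram (AF tachograms are
  conventionally analysed per beat index, not per unit time). The DC
  bin is dropped, the positive-frequency power is normalised to a
  probability vector, and the entropy is divided by log2 K so the
  value lies in [0, 1]: 0 for a single spectral line, 1 for a flat
  spectrum. A Welch option exists behind the config for long segments.

Undefined features propagate as NaN; model-fitting code drops segments
with NaN in the candidate features and logs the count (decision trees
cannot consume missingness flags).

## Synthetic cohort generator

No patient data ships with the package, so the pipeline is exercised
on a generator that emulates two-class 24-h AF Holter cohorts at the
beat-to-beat statistical level:

    RR_n = (60000 / HR(t_n)) · exp(ε_n)

with ε a stationary AR(1) process in log space and HR(t) a per-patient
base rate times a sinusoidal circadian profile peaking at 15:00.
Defaults are the study conditions: 26 patients per class; 24-h class
mean heart rates 91.6 bpm (AF-HF) and 78.7 bpm (control); RR
coefficient of variation 0.15 vs 0.21 (HF patients slightly less
irregular); log-RR lag-1 autocorrelation 0.5 vs 0.0 — higher
autocorrelation concentrates spectral power at low frequencies and is
the one-knob control of spectral entropy, the direction of the class
difference being lower spectral complexity in AF-HF; circadian
modulation depth 0.04 vs 0.10 (blunted circadian variation in heart
failure). Patients are not clones of their class: besides the base-HR
spread (SD 4 bpm), each patient carries a random offset in RR
coefficient of variation (SD 0.035) and in log-RR autocorrelation
(SD 0.15). This between-patient nuisance variation is what makes the
classification problem non-trivial — without it, every segment-level
feature separates the classes almost perfectly and patient-grouped
cross-validation would have nothing to guard against. Artifact gaps
arrive at 0.2/h, each deleting 30–120 s of
beats; the interval after a gap absorbs the deleted time, so beat
timing stays exact and gap-polluted windows are handled downstream by
`min_beats` and the PRSA anchor limit, emulating unscreened recording
dropouts.

Two deliberate calibration choices:

* **Controlled class means.** Between-patient base-HR heterogeneity
  (SD 4 bpm) is drawn centred per class, so the cohort-level class
  mean heart rate equals its target exactly rather than wandering by
  the sampling error of 26 draws. The 4 bpm SD is intentionally
  smaller than the between-patient spread of a real cohort; it is the
  within-class nuisance scale against which the class effects above
  are calibrated.
* **Day-specific class effects.** `night_attenuation = 0.6` shrinks
  the between-class gaps in mean HR, cv and autocorrelation toward the
  two-class midpoint during 22:00–08:00, emulating the compression of
  autonomic class differences during sleep; the daytime HR gap is
  widened correspondingly so each class's 24-h mean heart rate stays
  exactly on target. This is what makes a day-trained classifier
  degrade on night segments, the circadian performance asymmetry the
  analysis probes. Setting it to 0 gives clock-stationary class
  effects.

What the generator does *not* model: ECG morphology, AV-nodal
conduction, ectopy, ventricular response dynamics, medication effects,
or any within-patient non-stationarity beyond the circadian sinusoid
and AR(1) noise. Passing tests on this cohort therefore demonstrate
that the pipeline recovers planted beat-to-beat statistical structure
under realistic sample sizes and nuisance variation — not that the
specific features separate real AF-HF patients.

## Selection, classification, evaluation

**Split plan.** Patients (never segments) are randomly assigned, class
balanced: at the 52-patient study size, 6+6 held-out test patients and
five validation folds of 8 over the remaining 40 (train 32 /
validation 8 per fold); other cohort sizes scale the test fraction
proportionally. The SHA-256 hash of the test segment ids is computed
before selection and re-checked immediately before the single final
test evaluation.

**Greedy forward selection.** Starting from the empty set, each
iteration evaluates every remaining feature whose absolute Pearson
correlation with each already-selected feature — computed on the
pooled training segments — is below the 0.6 gate, by the mean
validation accuracy over the five folds of a tree trained on
selected ∪ {candidate}; the best candidate is accepted only if that
accuracy strictly increases (no epsilon threshold). Ties break toward
the candidate with lower mean |r| to the selected set, then by feature
name, making selection deterministic. Pearson (not Spearman) is
assumed, and accuracy is segment-weighted. A zero-variance feature has
undefined correlations and is treated as gated (conservative).

**Classifier.** CART decision tree (scikit-learn), Gini impurity,
uniform class priors via inverse-frequency class weights, no depth
cap, `min_samples_leaf = 5`, seeded. The final model is retrained on
all 40 non-test patients with the selected features and evaluated
exactly once on the test set; single-feature baselines reuse the same
split and retraining protocol.

**Metrics.** AF-HF is the positive class: ACC, sensitivity,
specificity and PPV from segment-level confusion counts, asserted
against a recount identity on every evaluation. Per-patient accuracy
ACC_i is the fraction of a test patient's segments classified
correctly; a patient is called by majority vote of segment
predictions, with an exact 50/50 tie going to AF-HF (screening
posture: prefer sensitivity) and flagged. Feature-level class
differences use the one-tailed Wilcoxon rank-sum test (default
direction: AF-HF lower); fully tied data return p = 0.5 with a
degeneracy flag.

## Shapley importance

The explained quantity is the tree's AF-HF probability. For each of
`n_runs` resampling runs, `n_samples` segments are drawn with
replacement and used as both explicand and background set; exact
interventional Shapley values are computed by enumerating all
coalitions of the features the tree actually splits on (features the
tree never uses receive exactly zero), with v(S) the background mean
of the tree output when the coalition's features come from the
explicand. Because the per-run computation is exact, the reported SD
across runs measures sampling variability only, not estimator noise.
Local accuracy (values sum to prediction minus background mean) holds
to machine precision and is asserted in the tests. The analysis
driver uses 1,000 runs of 100 segments.

## Problem sizes and numerical choices

The shipped analyses and tests run the pipeline at reduced recording
lengths — 4-h day-window recordings for the 52-patient classification
study and 16-h (08:00–24:00) recordings for the circadian-transfer
study — which preserve the per-segment feature distributions and the
patient-grouped protocol while keeping a full run in the minutes
range on one CPU. Monte-Carlo checks use 5–20 seeds as noted per
test. Feature computations are tested against independent naive
reference implementations at 1e-9 relative tolerance; float
comparisons elsewhere use the tolerances stated in the tests.

## Known limitations

* DR = DC + AC is this package's declared definition of deceleration
  reserve; published PRSA variants differ in windowing and parameters,
  and `prsa_half_width`, `anchor_limit` and the DR strategy are
  exposed in the config for that reason.
* Entropy estimators are sensitive to their hyperparameters (bins, m,
  r); the defaults are field-standard but not universal.
* The WFDB annotation format is not read directly; convert beat
  annotations to the CSV dialect (`patient_id,label,rr_ms[,clock_time]`)
  first.
* Patient-level calls assume enough segments per patient for a
  meaningful majority; very short recordings make the vote noisy.
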