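# Methods

`eegdem` implements a complete resting-state EEG biomarker pipeline for
degenerative dementia: a synthetic-cohort generator, signal cleaning,
six feature families, three-level HC/MCI/AD classification, group and
correlation statistics, and random-forest regression of cognitive and
disease-course measures. This note records the models, the tunable
parameters that matter, and the design choices made where the design was
genuinely open.

## The synthetic cohort model

Real clinical EEG with matched CSF and neuropsychology is not
redistributable, so the package ships a generator whose outputs carry the
statistical structure the downstream analysis is designed to detect. Every
quantitative claim made by the test suite is therefore a statement about
*parameter recovery* on simulated data, not about patients.

**Latent severity.** Each subject carries a scalar disease severity
`s in [0, 1]` drawn as group mean + Gaussian jitter (defaults: HC 0.10,
MCI 0.45, AD 0.80, DLB 0.75, FTD 0.70, VCI 0.65; SD 0.08, clipped to
[0.02, 0.98]). Severity drives both the EEG signal parameters and the
clinical table, which is the simplest mechanism that produces group
separation and brain-cognition-CSF correlations simultaneously. Two
pathway latents (theta, mobility) equal severity plus small jitter
(SD 0.03), so the two EEG effects are correlated but not identical.

**Signal model.** Each channel is a sum of

* a fixed 1/f background (FFT-shaped Gaussian noise, power exponent 1.3,
  6 µV RMS);
* an alpha oscillator (8-12 Hz filtered noise), posterior-dominant
  (6 / 3 / 1.5 µV RMS posterior / central / frontal), half of its power
  drawn from a source shared across channels so the data has a stable
  dominant topography; amplitude scales by `1 - 0.35 * s` posteriorly;
* a theta oscillator (4-8 Hz filtered noise, 3 µV RMS) whose posterior
  amplitude scales by `1 + 2.0 * t` with the theta latent `t` — the
  generator's first planted marker;
* a slow-wave component (also 4-8 Hz filtered noise, RMS
  `3 µV * 1.0 * u` at posterior channels) driven by the mobility latent
  `u`: extra low-frequency power lowers the signal's RMS frequency and
  hence Hjorth mobility — the generator's second planted marker. Both
  dials modulate theta-band power because increased slow activity and
  reduced mobility are two views of the same cortical slowing; keeping
  the slowing dials narrowband (rather than, say, tilting the whole 1/f
  spectrum) confines the planted signal to the theta-power and mobility
  feature families instead of spreading it across every band;
* a white-noise floor (1.5 µV RMS), optionally scaled by an entropy
  slope (default 0: complexity effects emerge from the spectral changes
  rather than being dialed in separately);
* optional spike artifacts: Poisson-placed Hann pulses of 50-200 ms at
  8-12x the channel SD on all channels, with the expected corrupted-sample
  fraction equal to `artifact_rate`; the generator records the exact
  corrupted mask as ground truth.

Slopes are *fractional changes over the full severity range* and each
effect carries a per-channel weight vector; the defaults confine the
planted effects to the parieto-occipital channels, where slowing is most
pronounced in degenerative dementia. A `null_config()` preset zeroes every
slope and coupling for chance-level testing.

**Clinical table.** Per-group means and SDs for age, sex ratio, MMSE,
MoCA, disease course (COD), CSF analytes (Aβ42, Aβ40, t-tau, p-tau) and
APOE ε4 carrier fraction are configuration data; age of onset is derived
as `age - COD`, which keeps `ADO <= age` by construction. Scores are
clipped to [0, 30] and rounded; analytes are floored at small positive
values. CSF and APOE are generated only for MCI/AD subjects, with
configurable ascertainment fractions (default 1.0: complete
ascertainment, because desk-scale cohorts of 30/group would otherwise
fall below the regression stage's 20-subject eligibility floor; partial
ascertainment is one config field away).

**Planted couplings.** Four correlations are planted within the combined
MCI+AD pool by default: theta-pathway vs p-tau (+0.442), theta vs Aβ42
(−0.358), mobility vs MMSE (+0.44), mobility vs MoCA (+0.44). For a
coupled column the generator draws
`V = mu_g + beta * (X - E[X|g]) + sigma_res_g * eps`, where `X` is the
pathway variable — the total posterior theta-band power multiplier
`(1 + 2.0 t)^2 + (1.0 u)^2`, or its negation for mobility couplings so
that "higher mobility = higher score" — and
`sigma_res_g` keeps the within-group SD at its configured value. The
loading `beta` is solved by root-finding the pooled Pearson correlation of
large fixed-seed simulated draws *including the validity truncation*,
so the correlation among the published values matches the target; a purely
analytic solution is biased by up to ~0.06 by score clipping and analyte
floors. Two properties of this construction are worth knowing:

* with strongly separated group means, the between-group component alone
  can exceed the target, in which case the solved within-group loading is
  negative — the solver plants whatever within-group structure makes the
  pooled correlation come out right;
* the calibration draws use an internal fixed seed, so the solved loadings
  depend only on the configuration, never on the user seed.

Determinism: subject metadata and each recording use children of a single
`SeedSequence` keyed by the config seed and subject index, so identical
configs reproduce bit-identical cohorts and the table does not depend on
how many recordings are later materialized.

## Preprocessing

Fixed stage order: band-pass 1-55 Hz (zero-phase Butterworth, order 4
effective) → 50 Hz notch (zero-phase IIR, Q=30) → common average
reference → artifact census → epoching. The artifact rule flags a sample
when any channel exceeds `min(100 µV, 6 x 1.4826 x MAD)` for that channel;
the census uses consecutive non-overlapping 25-s windows (the last window
truncated, so every sample belongs to a window) and excludes windows with
more than 30% flagged samples. Epochs are 5 s (1000 samples at 200 Hz),
non-overlapping, cut independently within each maximal run of retained
windows, so no epoch straddles an exclusion; remainders are discarded,
giving exactly `floor(retained_seconds / 5)` epochs per retained segment.
The amplitude rule and the non-overlapping window reading are declared
package choices: they are robust, deterministic, and catch the spike
artifacts the generator plants.

## Features

All features are computed per 5-s epoch; subject-level matrices are
NaN-aware means over a subject's epochs. Columns are named
`family/band/channel`.

* **Band powers**: Welch PSD (1-s Hann windows, 50% overlap) integrated
  over delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz;
  relative powers divide by the five-band sum (and so sum to 1 per
  channel). 80 + 80 columns.
* **Hjorth parameters** on the broadband signal, with derivatives as
  first differences (the original discrete definition): activity
  (variance), mobility `sqrt(var(dx)/var(x))`, complexity
  `mobility(dx)/mobility(x)`. A constant signal returns activity 0 and a
  degeneracy flag. 48 columns.
* **Sample entropy** SampEn(m=2, r=0.2 SD), Chebyshev distance,
  self-matches excluded, computed by a compiled O(N²) kernel; undefined
  values (no matches) are NaN sentinels excluded from aggregation and
  counted in the log. 16 columns.
* **STFT summaries**: spectrogram with 1-s Hann windows, 50% overlap;
  per band, the channel-mean band power per frame is summarized by its
  temporal mean and SD (10 columns). The exact statistic is a declared
  package choice.
* **Microstates**: polarity-invariant ("modified") k-means with k=4 and
  10 restarts on global-field-power peak maps; the template update is the
  dominant eigenvector of the assigned maps; every sample is back-fit to
  the template with the highest absolute spatial correlation, with no
  temporal smoothing. Per-state mean lifetime (ms) and occurrence (1/s)
  plus one global converting rate (transitions/s) give 9 columns; a state
  absent from an epoch contributes lifetime 0 and occurrence 0, which
  keeps matrices finite and preserves the coverage identity
  `sum_s occurrence_s x lifetime_s = 1`. Models are fit per subject
  across all of that subject's epochs.

Total: 243 columns.

## Classification

Ordinal class codes HC=1, MCI=2, AD=3. Features are ranked by |Pearson r|
against the code vector (ties keep column order; constant columns get
r=0 with a warning). Forward selection grows the ranked prefix, scoring
each prefix by mean 5-fold stratified CV accuracy of a
standardize-then-classify pipeline (z-scores fit per training fold)
inside an 80% stratified training split; the optimal set is the first
accuracy maximum. The untouched 20% test split is evaluated once with the
selected set. Classifiers: LDA and linear-kernel SVM with default
regularization. Metrics come from one-vs-rest confusion counts — recall
TP/(TP+FN), precision TP/(TP+FP), F1 the harmonic mean, accuracy the
fraction correct; three-class recall/precision/F1 are macro averages.

Samples are epochs by default, which reproduces the common (leaky)
protocol in which one subject's epochs can land on both sides of the
split; a subject-grouped mode is provided and every report records which
mode produced it. Ranking uses the training split only by default
(`rank_on="all"` mirrors the leakier whole-data variant). The ranked-
prefix evaluation is capped (`max_features`, default 40 in the pipeline)
to bound runtime; the accuracy curve length equals the number of prefixes
evaluated.

## Group statistics

ANCOVA is the linear model `feature ~ group + age` with an F test on the
group dummies (statsmodels OLS); a constant age column drops the
covariate with a warning. Post hoc comparisons are Tukey HSD on
age-adjusted values (feature minus the age-only regression component),
the standard ANCOVA follow-up; Benjamini-Hochberg adjustment is applied
across the pairwise family within a feature and again across features,
and both layers are stored. Note that BH re-application is *not* a no-op
in general (adjusted values fed back through the step-up rule can
increase), so the implementation adjusts raw p values exactly once per
family. Brain-cognition-CSF correlations are Pearson r over the combined
MCI+AD pool, pairwise-complete in the presence of missing CSF, with
cells under 3 complete pairs reported as missing. Under the default
generator the expected sign pattern is: theta power negative with Aβ42,
positive with p-tau; mobility positive with MMSE and MoCA.

## Prediction

Random-forest regression (500 trees, unrestricted depth, default split
criterion, seeded) of MMSE, MoCA, ADO and COD from three feature sets:
the selected EEG features; CSF/APOE (Aβ42, Aβ40, Aβ42/40, t-tau, p-tau,
ε4 carrier); and hybrid (EEG ∪ CSF/APOE ∪ {sex, age}). The protocol is
repeated random subsampling — ten independent 80/20 splits of the
eligible MCI+AD subjects, validation predictions pooled across splits,
metrics on the pooled pairs only (training pairs never enter a metric);
a partitioned 10-fold variant sits behind `scheme="kfold"`. Missing
feature values are imputed with training-fold medians. Two R² variants
are reported: the model-sum-of-squares ratio MSS/TSS (non-negative,
unbounded above — e.g. truth (0,1) with predictions (−1,2) gives 9.0)
and the standard 1−RSS/TSS companion; MAE applies the absolute value to
each residual. Trees are invariant to monotone feature scaling, so no
standardization is applied before the forest.

## Numerical choices and degenerate inputs

* All signal amplitudes are microvolts; time indices 0-based, intervals
  half-open; adjacent frequency bands share edge frequencies and band
  integration includes both edges, so the five bands tile 1-45 Hz.
* Ties everywhere resolve to the first occurrence; every stochastic step
  descends from one master seed.
* Degenerate inputs fail loudly (empty evaluation vectors, constant
  regression targets, all-zero band powers, single-channel re-referencing)
  or return flagged sentinels where the pipeline must continue (constant
  epochs in Hjorth, match-free sample entropy).
* Microstate fitting accepts k=1 (principal topography, constant labels)
  even though the clinical parameterization is k=4.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the full pipeline completes in minutes on one CPU: 30 subjects per
HC/MCI/AD group with 60-s recordings for classification, and 150 MCI +
150 AD for correlation and regression recovery (the planted-correlation
checks need ~300 subjects for usefully narrow confidence intervals). The
generator's clinical defaults describe 10-min recordings; only the
duration is reduced for testing, which raises per-subject feature noise
but leaves every planted effect recoverable.

## What passing tests do and do not show

The generator emulates group-wise spectral slowing, a posterior-dominant
alpha topography, planted brain-cognition-CSF correlations, score/analyte
distributions with realistic truncation, spike artifacts, and CSF/APOE
missingness. It does not emulate volume conduction or a forward head
model, channel-correlated broadband noise, non-stationarity (drowsiness,
eye movements), subtype-specific electrophysiology for DLB/FTD/VCI, or
measurement error in the clinical covariates. Passing tests therefore
demonstrate that the pipeline recovers known planted structure at the
stated sizes — they say nothing about diagnostic performance on real
patients, and the epoch-level split in particular is known to flatter
accuracy whenever subject identity leaks across the split.
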