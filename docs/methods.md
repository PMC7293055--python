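# Methods notes

This note records the modelling choices behind `phenomarker`: what the
synthetic cohort emulates, how each biomarker family is estimated, how the
stacked ensemble and the validity statistics are put together, and where
design decisions were genuinely open.

## Synthetic cohort

The generator produces, per participant, a latent standardized severity
z ~ N(0,1) and derives every observable from it.

**Self-reports.** SIAS = round(29.1 + 9.4 z) clipped to [0, 80], matching
the marginal distribution the generator emulates (sample mean ≈ 29.1,
SD ≈ 9.4, verified on n = 2000 cohorts). DASS-21 depression and PANAS
negative/positive affect follow a one-factor Gaussian model
(measure = ρ·z + √(1−ρ²)·ε, then rescaled and discretized to their score
ranges) with default target correlations ρ = 0.45 / 0.45 / −0.30. The
one-factor construction is positive semidefinite for any |ρ| ≤ 1; the
config still runs an eigenvalue check and rejects invalid targets with a
diagnostic. Missingness is completely at random at 5% / 14% / 14%
(depression / NA / PA) — MCAR is the assumption under which the
multiple-imputation stage is consistent.

**Accelerometer.** A 1 Hz magnitude channel (single channel because
magnitude is rotation-invariant and standard for phone-in-pocket data):
gravity baseline 9.81 m/s² with 0.08 m/s² jitter, an alternating
rest/movement renewal process (mean bout 8 min, active fraction 0.25),
and within bouts a gait sinusoid at period 6.35 s with amplitude
max(0, 0.6 − 0.2 z) m/s² — less anxious participants oscillate with
larger amplitude — plus 0.35 m/s² motion noise. The gait phase is
coherent per participant (one walker, one stride phase). App dropouts
appear as ~1.5 recording gaps per day of 2–10 min. By default one day of
accelerometer is emitted per participant (86,400 samples); the
`accel_full_length` flag restores the full window. Duration is drawn
from N(16.41, 2.69²) days.

**Communication.** Events arrive as thinned Poisson processes per contact
(1 + Poisson(6) contacts, Dirichlet rate shares) with total incoming rate
`comm_rate_base`·exp(comm_rate_slope·z) per day, 78% texts. Incoming
texts draw a log-normal reply latency whose log-mean shifts by
`reply_delay_slope`·z; incoming calls are missed with probability
sigmoid(logit(0.25) + `missed_call_slope`·z), and missed calls trigger a
delayed call-back. Default slopes (−0.15, +0.4, +0.5) make anxious
participants less active, slower to reply, and likelier to miss calls.
The phone-idle flag is Bernoulli(0.4), severity-independent.

**What the generator does not emulate:** real Android sensor quirks
(clock drift, duty cycling), diurnal/weekly rhythms, content or
social-graph structure, non-random missingness, and measurement models of
the questionnaires (no item-level data). Passing tests therefore show
that the *pipeline machinery* recovers planted structure under its own
assumptions — not that real cohorts carry signal of this strength.

## Accelerometer biomarkers

**Distribution family (109 features).** Moment-based Fisher skewness and
excess kurtosis (normal → 0), both defined as 0 for zero-variance input;
population SD; RMSSD at lag k = √mean((x[t+k]−x[t])²); quantiles with
linear interpolation. The mode of continuous data is the midpoint of the
densest Freedman–Diaconis bin (raw-value mode is degenerate for floats);
ties resolve to the lowest bin. These conventions keep every feature
defined and bounded: min ≤ q01 ≤ … ≤ q99 ≤ max and mode ∈ [min, max] are
asserted properties.

**Varying-coefficient dynamics.** The model links each sample to its own
lagged values through a coefficient that is a smooth function of the time
difference: y_t ≈ f₁(TD)·y_{t−TD}, all integer lags TD = 1…60 s stacked.
Because TD is discrete, the stacked least-squares problem collapses to
per-lag sufficient statistics (Σx², Σxy per lag), making the fit exact
and O(lags × samples). f₁ is a penalized natural-cubic smoothing spline
over the lag axis; the smoothing parameter is chosen by weighted GCV *at
the lag level* (60 per-lag OLS slopes with precision weights Σx²). GCV
over the raw stacked rows is uninformative — the roughness penalty barely
moves the row-level residual sum — and over-smooths, which biases the
lag-1 coefficient; the lag-level criterion keeps the estimate within
±0.05 of the OLS lag-1 slope on AR(1) test data while still suppressing
lag-to-lag noise (white-noise coefficients stay below 0.05 in absolute
value). A 60 s maximum lag bounds cost while covering ~9 gait periods;
"all possible lags" at 10⁶ samples is neither feasible nor informative
beyond the correlation length. Estimation subsamples up to 40 seeded
10-minute windows per participant (series shorter than two windows are
used whole); constant series yield zero coefficients with a warning code
rather than an error.

**Spectral family.** Welch PSD with Hann taper and 50% overlap; the
feature grid is the segment's positive FFT frequencies, identical across
participants. The default 4096 s segment yields 2048 features, which the
ensemble chunks into blocks of 1000; a 512 s segment (256 features) is
the reduced preset for fast end-to-end runs. The density normalization
satisfies Parseval (integrated power = variance within 2% on white
noise). Segments never span a sampling gap larger than 5 s: the series is
split into contiguous runs, Welch runs per segment-eligible run, and the
per-run densities are pooled weighted by segment count. Log10(power +
1e−12) is taken before modelling, since band powers vary over decades.
Distribution features, by contrast, always use every sample.

## Communication biomarkers

Gap features use the same 109-feature distribution summary applied to
inter-event times. Per-contact summaries require at least two events for
a contact (one gap), computed under relaxed rules (features undefined at
that length are NaN); the across-contact variability is the population
(divide-by-n) SD, so a single contact gives exactly zero — the natural
"no between-contact variation" answer. Gap vectors with fewer than three
gaps produce MISSING (NaN) features rather than silent zeros, and
participants with zero calls get MISSING proportions; the boosted trees
route NaN natively, so no feature-level imputation is ever performed.
All functions sort events internally; input order cannot change any
biomarker.

## Stacked ensemble

Lower-level learners are XGBoost regressors with fixed hyperparameters:
depth 3, learning rate 0.1, 200 rounds, subsample 0.8, and column
subsampling 0.25 on the feature blocks (a standard p ≫ n device that also
bounds the cost of ~500 leave-one-out refits of 1000-column blocks). No
hyperparameter search is performed. Every lower-level prediction is
out-of-sample by construction: participant i's value comes from a model
fitted to the other n−1 rows.

The meta-learner stacks the block-prediction matrix with the same
settings except column subsampling, which is disabled there: the meta
matrix has one column per block, and a tree that sees only a random
quarter of ~5 columns allocates gain essentially at random between
near-collinear block predictions, which destroys the interpretability of
block importance. The meta level reuses the lower-level out-of-sample
predictions for its own LOO loop rather than running a fully nested
double-LOO; the known slight optimism of this shortcut is accepted
deliberately — it mirrors how such stacked LOO designs are run in
practice — and all validity statistics are computed on these meta-level
LOO predictions. Predictions are not clipped to [0, 80]; evaluation uses
correlation, which is shift/scale-invariant.

**Importance** follows the ensemble's two-level structure: the meta
model's total gain (summed over splits, averaged over LOO refits) ranks
blocks; within a block, the refit-averaged total gain ranks features; the
final score is (block share of meta gain) × (feature share of block
gain), so the top-ranked feature is the top feature of the most
influential lower-order model. Spectral features carry a period
annotation 1/f in seconds.

**Embedding.** t-SNE (3 components, exact method, PCA initialization,
perplexity min(30, (n−1)/3), seeded) of the block-prediction rows, with a
plotting helper coloring points by observed severity.

## Validity statistics

* Fisher-z CI: tanh(atanh r ± z₀.₉₇₅/√(n−3)), reported to 3 decimals.
* Steiger's (1980) pooled Z for two dependent correlations sharing the
  predicted score, with the correlation-matrix PSD checked first. The
  statistic is antisymmetric in its first two arguments and grows as √n.
* Multiple imputation: scikit-learn's chained-equation imputer with
  posterior sampling, m = 20 completed datasets by default, correlations
  pooled on the Fisher-z scale by Rubin's rules (within-imputation
  variance 1/(n−3), Barnard–Rubin degrees of freedom). Zero missingness
  reduces exactly to the complete-data estimate. CIs use n = 59-style
  observed sample size throughout.
* Partial correlation: residual-on-residual correlation after linear
  adjustment, CI on n−3−k effective observations; pooled over the same
  imputations when controls are incomplete. A variable fully explained by
  the controls has partial correlation 0 by convention.
* Cutoff shares use ≥ for both 34 and 36, following the cutoffs'
  validation literature.
* p-values are two-sided with no multiplicity correction (the report
  makes three planned comparisons).
* Reports refuse predictions not flagged out-of-sample.

## The spectral-only configuration

`pipeline.spectral_only_config()` builds a cohort in which the 6.35 s
oscillation is the *only* severity-coded signal, used to verify that the
importance-to-period mapping recovers the planted period. Designing this
took care, because an amplitude-modulated oscillation naturally leaks
into every feature family: variance and kurtosis (distribution block),
and the autocovariance at every lag (dynamics block). The configuration
therefore: holds total in-bout variance constant (amplitude up, noise
down); makes movement continuous; gives each participant a
severity-*independent* random motion-noise smoothness (AR(1) coefficient
uniform in 0.45–0.75), which dominates and decorrelates the short-lag
dynamics and RMSSD channels; and lets the gait phase drift with a ~25 s
coherence time, which damps the long-lag autocovariance signature. The
drifting line is wider than a fine frequency grid would resolve, so this
configuration pairs with 64 s spectral segments, keeping the line inside
a single bin. Under these conditions the top-ranked feature is the
gait-band spectral bin, annotated with a period within one bin of 6.35 s,
in 10 of 10 test seeds.

## Problem sizes and determinism

Default test/acceptance runs use n = 59 participants with one day of
accelerometer each and the 512 s spectral preset — sizes chosen so a full
pipeline run takes ~30 s on one core and multi-seed robustness checks
remain routine; the full-length configuration scales linearly. All
randomness flows from a single root seed split into named substreams
(cohort, dtvem windows, model, imputation, t-SNE); a rerun with the same
config reproduces every CSV/JSON artifact bit for bit (floats are written
with round-trip repr and parsed with round-trip precision).

## Known limitations

* The meta-LOO reuses lower-level predictions (slight optimism, see
  above); with n = 59 the LOO permutation null also shows the familiar
  small negative bias of cross-validated predictions.
* The generator's effect sizes are deliberately strong; observed
  correlations on synthetic cohorts (~0.9) exceed what real sensing data
  support, and no claim about real-data effect sizes follows from them.
* DTVEM-style estimation assumes local stationarity within sampled
  windows; heavy non-stationarity would call for time-varying extensions.
* The Steiger tests use pooled imputed correlations with the full-sample
  n rather than propagating imputation uncertainty into the Z itself.
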