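# Methods notes

This note records the modelling assumptions, parameter choices and
numerical conventions behind `schemarsa`, and what the synthetic-data
tests do and do not establish about recorded data.

## Design and conventions

The condition space is the full factorial fragment grid: `n_scenes_per_type`
indoor + outdoor scenes × `n_vertical` × `n_horizontal` fragment positions
(default 3/3/2 → 36 conditions). The canonical order is scene-major
(indoor scenes first), vertical before horizontal; vertical is coded
1 = top … 3 = bottom and horizontal 1 = left, 2 = right. These codes are
arbitrary but fixed, and every matrix in the package is index-aligned to
them — a single ordering convention is the cheapest insurance against
silent misalignment between neural and model RDMs.

RDM diagonals are stored as NaN, never 0: the self-dissimilarity is
undefined, and a 0 would silently survive vectorization bugs.
Vectorization takes the lower off-diagonal triangle in row-major order;
masked analyses drop excluded pairs from criterion and predictors alike,
and z-scoring is computed on the retained entries only (the masked vector
is the criterion that enters the regression).

## Cross-validated correlation RDMs (fMRI)

"All possible splits" is implemented as all unordered equal partitions of
the runs (10 for 6 runs). Per split, both within-condition correlations
(i↔i and j↔j across halves) and both between-condition directions (i↔j,
j↔i) are averaged; this symmetric reading guarantees an exactly symmetric
RDM. Correlations are Fisher-transformed per split and then averaged
across splits. Correlations are clipped to |r| ≤ 1 − 1e−12 before the
transform because noise-free synthetic patterns can reach r = 1, whose
arctanh is infinite. A zero-variance pattern yields correlation 0 with a
warning instead of NaN, so degenerate inputs never abort a batch run.
Trial-pattern extraction takes the volume at the TR closest to onset plus
a 3-TR shift by default (6 s hemodynamic delay; sweepable 0–5), and
per-run demeaning subtracts each voxel's mean across conditions.

## Pairwise decoding RDMs (EEG)

Folds pair the k-th trial of each condition: the training set is all but
one trial per condition, the held-out pair is tested, and this repeats
until every trial has been left out once (n folds for n repetitions, 2n
test evaluations). The LDA uses the pooled within-class covariance of the
training trials with fixed shrinkage 0.05 toward a scaled identity; with
17 channels and few trials the raw covariance can be singular, and the
exact regularization of common MVPA toolboxes is undocumented, so the
conclusion-bearing results should be (and are, in tests) robust to the
coefficient. With one training trial per class the covariance is void and
the classifier degrades to the nearest-class-mean rule (identity
covariance). Unequal trial counts are not silently rebalanced — the study
design has equal repetitions — but `balance=True` subsamples to the
minimum count. Decoding contains no randomness; identical inputs give
identical RDMs.

The implementation computes all folds of all pairs by rank-one
leave-one-out downdates of the per-condition means and scatter matrices
and batches the resulting 17×17 solves, which makes a full 630-pair ×
201-time-point series tractable on one core. Tests verify it against an
explicit fold-by-fold enumeration and against per-fold scikit-learn LDA.

Preprocessing follows the usual order: per-trial per-channel baseline
subtraction over the pre-stimulus window, then decimation by boxcar
averaging of consecutive samples (the least surprising anti-alias choice
at this scale; the original rate must be an integer multiple of the
target, e.g. 1000 → 200 Hz giving 5 ms steps).

## GLM and residualization

The criterion (neural vector) is z-scored by default; predictors stay in
raw binary form. Z-scoring rescales all betas by one common positive
factor and changes no sign or t statistic (tested), so standardizing
predictors as well would not alter any conclusion. An intercept is always
included. Rank-deficient user-supplied designs raise an error naming the
dependent predictors.

Covariate control is two-step: the covariate bank (plus intercept) is
projected out of the criterion **and** the predictors before the OLS fit.
By the Frisch–Waugh theorem this equals one joint GLM with the bank as
nuisance regressors. Residualizing only the criterion — the naive reading
of "using the residuals as the regression criterion" — is available via
`residualize_predictors=False`, but it cannot cleanly attribute shared
structure: the projection of the vertical predictor onto the bank span
re-enters the category column, so a bank that fully spans the category RDM
would still leave a nonzero category beta of the order of the
vertical–category design correlation. Under the default two-step scheme a
predictor the bank spans exactly becomes the zero vector; its beta is
reported as 0 with a warning — its structure has been fully attributed to
the covariates — rather than raising the collinearity error reserved for
malformed user designs.

Under the cross-scene-type restriction (324 indoor×outdoor pairs) every
retained pair stems from different scenes, so a category predictor is
constant and cannot be modelled; requesting it raises.

## Group statistics

fMRI betas are tested with one-tailed one-sample t-tests (greater than
zero) and Bonferroni correction across ROIs (default m = 3). EEG beta
time courses use 1-D TFCE with E = 0.5, H = 2 and dh = max(t)/100 —
standard values from the TFCE literature — over adjacent-sample
connectivity (the electrode dimension is already collapsed by the
decoder); negative t contributes nothing (one-tailed use). The
sign-permutation null flips each subject's whole time course with
probability ½ per iteration (default 10,000), records the maximum
enhanced statistic per iteration (max-statistic FWER control), and
converts the observed enhanced map to z via the null's mean/SD; an
empirical-quantile conversion is available and agrees on clear effects.
The significance threshold is Z > 1.64 (p < 0.05 one-tailed). Onset is
defined as the first sample of the earliest suprathreshold run, the peak
as the argmax of the group t map; their reliability is estimated by
bootstrapping subjects with replacement, with draws lacking any
significant sample reported as an undefined-onset rate. Note that
bootstrap resampling duplicates subjects and therefore fattens the tails
of the resampled t distribution; null-data onset rates are only ≈ 1 for
strict significance criteria.

## Synthetic data

The generators plant known structure so recovery is checkable:

- **fMRI** (`simulate_fmri`): per subject, each condition's mean pattern
  is a weighted sum of a shared per-vertical-level component, a
  per-horizontal-level component, a per-scene component and a
  condition-unique component, all i.i.d. unit Gaussian across voxels and
  drawn fresh per subject (the analysis is within-subject; patterns are
  never aligned across subjects). Runs add i.i.d. Gaussian noise.
  Defaults mirror the study: 30 subjects, 6 runs with every condition in
  every run (4 repetitions per run upstream of averaging), 100 voxels.
- **EEG** (`simulate_eeg`): the same component construction over channels,
  multiplied by an effect time course that is zero before 50 ms, ramps
  linearly to a peak at 200 ms and decays exponentially (τ = 200 ms) —
  mimicking the morphology of early visual decoding effects — plus
  i.i.d. trial noise (optional AR(1)). Defaults: 20 subjects, 40
  repetitions, 17 posterior channels, −200…800 ms at 200 Hz.
- **Features** (`simulate_features`): 18 layers by default; layer *l*
  mixes i.i.d. noise with per-scene prototype activations at a coefficient
  growing linearly to `category_gradient`, so the final layer of a
  gradient-1 bank is a pure function of the scene and its RDM separates
  same-scene from different-scene pairs perfectly. (Its Spearman
  correlation with the *binary* category RDM is capped well below 1 by the
  ties of the binary matrix; rank equivalence is therefore asserted as
  perfect separation, not as ρ ≈ 1.)

Default effect weights (vertical 1, horizontal 0, category 1, unique 1)
and noise SD 5 were chosen once to give peak pairwise decoding around
0.65–0.75 and clearly positive but noisy single-subject betas — the
regime in which the inference machinery is actually exercised — and are
not tuned against any test outcome.

What the generators do **not** emulate: hemodynamic convolution beyond a
fixed pattern-per-condition abstraction, temporal autocorrelation (unless
enabled), eye movements and artifacts, spatial channel correlations,
subject-level effect heterogeneity beyond pattern resampling, and any
realistic forward model. Passing recovery tests therefore demonstrates
the correctness of the estimators and inference chain, not that effects
of a given size are detectable in recorded data.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at reduced scale chosen as the package's own
trade-off between statistical resolution and turnaround: null calibration
uses 500 units (t-test) and 50–100 simulated experiments at 1,000
permutation iterations (TFCE/FWER); fMRI recovery uses 30–50 simulations
of 20 subjects × 100 voxels; EEG recovery uses a reduced 12-condition
grid, 6 repetitions and a −100…400 ms epoch so the decoding stage stays
in the seconds range per simulated study. Null-calibration inputs enter
at the RDM-vector stage (noise RDMs through the real GLM → inference
path): under the null the RDM constructors yield exchangeable noise, and
regenerating raw multichannel data per unit would add cost without adding
coverage of the stages being calibrated.

## Known limitations

- The cross-validated correlation distance is unbiased around zero but
  not a metric; MDS visualization shifts negative values by the frame
  minimum, which distorts large negative excursions.
- TFCE z-conversion via null moments assumes the null maxima are roughly
  Gaussian; the empirical-quantile option avoids this at the cost of
  resolution limited by the iteration count.
- The LDA pairing of held-out trials (k-th with k-th) is one of several
  defensible leave-one-trial-out conventions; with exchangeable trials it
  does not affect expected accuracy.
- `extract_trial_patterns` assumes onsets aligned to the volume grid to
  within rounding; no slice-time or jitter model is applied.
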