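# Methods

This note documents the modeling conventions, numerical choices and known
limitations of mvpdkit. It describes what the code computes; every empirical
claim here is one the test suite or `scripts/acceptance.py` computes itself.

## Data model and voxel bookkeeping

All analysis operates on `voxels × timepoints` matrices extracted from 4D
NIfTI functionals through 3D binary masks. A mask is flattened to a voxel
list in ascending linear-index order with the **first spatial axis varying
fastest** (Fortran order, the NIfTI on-disk layout); this linearization is
single-sourced in `io_volumes.mask_linear_indices` and shared by
extraction, map writing and the synthetic materializer, so element `j` of
any per-voxel vector always refers to the same voxel. Affines are passed
through untouched and no resampling is performed — masks must already live
on the functional grid, because registration and denoising are upstream
concerns. Non-finite values inside a mask are an error, never imputed.
An optional switch removes predictor voxels from the target mask (off by
default; useful when the target is a whole-cortex mask containing the
seed).

## Cross-validation

Folds are leave-k-run-out: every size-k combination of runs serves once as
the test set (lexicographic order; k=1 gives the classic leave-one-run-out
scheme). Training runs are concatenated along time. Runs are the unit of
splitting because BOLD timeseries are temporally autocorrelated: within-run
splits would leak information between temporally adjacent train and test
samples. Fitting functions accept only training-fold data by signature, so
test leakage is structurally impossible rather than merely discouraged.

## Linear models

Ridge solves `min ||Y − BX||²_F + λ||B||²_F` with the intercept always
fitted and never penalized (implemented by centering; BOLD baselines are
arbitrary, so penalizing the intercept would be meaningless). There is no
`1/T` factor on the penalty — documented so λ values can be mapped from
other software. λ=0 falls back to a least-squares solver that returns the
minimum-norm solution on rank-deficient designs. Because an explicit
pre-centering step changes nothing once the intercept is unpenalized, no
separate centering switch is exposed. Lasso uses the coordinate-descent
objective `1/(2T)·||Y − BX||²_F + λ||B||₁` per target voxel
(scikit-learn's convention), with non-convergence raised as an error.
All target voxels share one design matrix, so the multi-output system is
solved jointly; this is mathematically identical to independent per-voxel
solves.

Nested-CV ridge runs an inner leave-one-run-out loop over the *training*
runs only, scores each candidate strength by mean inner-fold prediction
MSE, and refits on all training runs at the winner. MSE (not varExpl) is
the inner criterion: it is monotone-friendly in the strength and avoids
divide-by-variance instabilities on low-variance voxels; exact ties go to
the smallest strength, the conservative (most-regularized-of-equals is not
wanted here; smallest keeps the default 0.001 preferred) and reproducible
choice. With a single training run the inner loop is impossible and the
error message directs users to a fixed strength.

## Dimensionality reduction

PCA and ICA (FastICA) reduce the predictor before fitting; timepoints are
samples, voxels variables. Reducers are fitted on the training fold only
and applied with the frozen training mean and basis to held-out data. The
component count is user-chosen (default 3); automatic selection is a
plug-in point, not built in. ICA is capped at 1000 iterations with
tolerance 1e-4 and a fixed seed; non-convergence is an error. Optionally
the *target* may be reduced as well, in which case predictions are
back-projected to voxel space before evaluation — varExpl is defined
voxelwise, so models are always scored in voxel space. Whether to reduce
the target is left off by default.

## Linear-activation networks

`nn_standard` chains affine layers input → hidden^L → output;
`nn_dense` concatenates the raw input and all earlier hidden outputs into
each layer, so hidden layer ℓ has input width `n_X + (ℓ−1)·h` and the
output layer `n_X + L·h`. No nonlinear activations anywhere: each network
is algebraically one affine map, and its training accuracy can never exceed
the MSE-optimal linear map's (asserted as a test). The architectures differ
only in how SGD parameterizes that space.

Normalization: a non-affine batch-norm stage (standardize to batch mean
0 / variance 1, ε=1e-5) precedes **every** affine layer including the
first, which is what lets raw BOLD-scale inputs train at learning rate
0.001. The scale/shift parameters of a conventional batch norm are omitted
because the following affine layer absorbs them exactly when no
nonlinearity intervenes. Running statistics (momentum 0.1) are accumulated
during training and frozen at prediction time, so a column's prediction is
independent of the batch it arrives in; predicting with a never-trained
batch-norm network is an error.

Training is SGD with classical momentum and an L2 weight-decay gradient
term. The optimized objective **sums** squared error over target voxels and
averages over batch timepoints. This choice matters: averaging over voxels
as well would scale every per-voxel gradient by `1/n_Y`, silently dividing
the effective learning rate by the target-region size and leaving
large-baseline targets unconverged at standard learning rates within any
reasonable epoch budget. The recorded `loss_history` is nevertheless the
per-element mean squared error (the same quantity divided by `n_Y`), so
histories are comparable across region sizes.

Batches realize a replay-memory idea: each epoch draws a seeded permutation
of all training timepoints and slices it into `⌈T/batch⌉` chunks, so
batches mix timepoints from across runs and are non-consecutive in
acquisition time, weakening within-batch temporal dependence; sampling with
replacement is available as an option. Weight initialization is a seeded
uniform fan-in scheme (`U(±1/√fan_in)` per layer, drawn in a fixed order),
so identical seeds give bitwise-identical parameters before and after
training. Defaults: hidden width 100, batch 32, lr 0.001, momentum 0.9, no
weight decay, 100 epochs (the epoch count is a package default, logged
prominently in every run).

Practical note on batch statistics: with small batches the normalization
injects an irreducible noise floor into the training loss (batch mean/std
fluctuate at `O(1/√batch)`), so tests that require the loss to collapse on
noiseless data use larger batches; held-out varExpl is much less sensitive
because prediction uses the frozen running statistics.

## Variance explained

`varExpl(j) = 1 − mean[(Y_test(j) − Ŷ_test(j))²] / var[Y_test(j)]`, with
the population (divide-by-T) variance in the denominator. The numerator is
the **uncentered** mean squared residual by default. The two candidate
conventions genuinely differ: under a centered numerator a prediction that
matches the pattern but misses the mean has a constant residual with zero
variance, hence varExpl = 1; under the uncentered convention it is heavily
negative (and 0 after thresholding) while its Pearson correlation with the
target is 1. The uncentered convention is the default because treating a
missed baseline as explained variance would overstate dependence; the
centered variant is available via `convention="centered"` and the choice is
logged. Consequently varExpl is invariant to shifting target and prediction
together but not to shifting the prediction alone.

Thresholding clips negatives to zero (idempotent), reading a failed
prediction as zero explained variance. Target voxels with zero test
variance have an undefined ratio; they are flagged, excluded from all
averages and counted in the log — not silently zeroed. Aggregation averages
per voxel across folds first, then across voxels, which makes the scalar
independent of unequal fold lengths; a voxel undefined in some folds is
averaged over the folds where it is defined.

## Model comparison

Per-subject scalar summaries of two models are differenced and tested with
a one-sample one-tailed t-test (df = n_subjects − 1), Bonferroni-multiplied
by the number of comparisons — by default all `k(k−1)` ordered pairs, since
one-tailed tests count both directions. Zero-variance differences are
reported as t = ±∞ with a note (t = 0 when all differences vanish). The
best-model map labels each voxel by the model with the highest subject-mean
varExpl (ties to the lowest model index) and attaches the minimum, across
competitors, of the paired t statistic best-minus-competitor — a
conservative margin. Voxel-level group inference (permutation / FWE
mapping) is intentionally not reimplemented: per-subject difference maps
are exported as NIfTI for the established external tools.

## Synthetic data

The generator plants `Y = B·S + c + noise` on AR(1) predictor signal with
stationary unit marginal variance (so the AR coefficient shapes temporal
autocorrelation without touching SNR), Gaussian baselines of magnitude 100
on both regions to emulate raw BOLD offsets, and a rank-controllable `B`
with unit row norms — making the theoretical per-voxel varExpl the closed
form `1/(1 + noise_sd²)`, so `noise_sd = 1` plants exactly 50% explainable
variance and `noise_sd = 0` plants 100%. Defaults (20 → 30 voxels, 4 runs
× 400 timepoints, AR 0.5) are a desk-scale analogue of a multi-run fMRI
session: large enough for stable estimates, small enough that the full test
suite runs in seconds. Seeds are split per run and per component
(signal/noise) via `SeedSequence.spawn`, so single runs regenerate in
isolation. Not emulated: hemodynamic convolution, physiological/motion
artifacts, spatial autocorrelation — passing tests validate the estimation
machinery, not robustness to real fMRI noise structure.

`materialize_as_volumes` writes the dataset as float64 NIfTI (predictor and
target occupying disjoint voxel blocks of a minimal cubic grid), chosen so
a reload through the standard extraction path reproduces the matrices
bit-exactly.

## Workflow, logging, determinism

An analysis is a YAML file with `inputinfo` (paths) and `params`
(everything else). Input files are checked for existence before any
computation. Results land in `maps/` (per-fold and mean varExpl volumes,
written **uncompressed** so repeated runs are byte-identical), `tables/`
(scalar summary JSON/CSV), `checkpoints/` (network weights and loss
histories), and a `<TIMESTAMP>_log.txt` recording paths, every parameter,
all derived seeds, fold definitions and the toolbox version — the log alone
suffices to re-run the analysis. The master seed derives stage seeds by
fixed offsets (reducer +1, network +2, mod 2³¹). `mvpdkit selfcheck` runs
the five example model types on a deterministic synthetic fixture and
correlates each mean varExpl map against shipped references (themselves
synthetic, generated by this package at packaging time), failing any model
below r = 0.95 and isolating failures per model.

## Known limitations

* Output maps are 32-bit float; values round accordingly.
* No lagged predictors: the mapping is simultaneous in time.
* No searchlight mode — use a whole-brain target mask instead.
* Automatic component-count selection and nonlinear architectures are
  extension points, not features.
* The Bonferroni/paired-t machinery covers scalar summaries; voxelwise
  group inference requires external nonparametric software.
* Thresholded varExpl values violate the assumptions of standard t-tests;
  for inference prefer unthresholded values or differences between models.
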