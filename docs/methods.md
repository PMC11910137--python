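# Methods

This note documents the models, defaults and design choices behind
`ramantax`, and what the synthetic-data experiments do and do not show.

## The classification problem

A single-cell Raman spectrum is a vector of scattering intensities over a
wavenumber grid (here 600–1800 cm⁻¹, the biological fingerprint region).
Spectra carry both *taxonomic* signal (which bands an organism's biomolecular
makeup produces) and *physiological* signal (how band intensities shift with
growth stage). The package treats taxonomy identification as supervised
classification over preprocessed spectra, with growth stage either ignored
(T-only), conditioned on as ground truth (T/G), or recovered by a first-stage
classifier (G-T).

## Synthetic spectra generator

The generator emulates the statistical structure of a duo-labelled reference
library — by default 36 strains, 16 genera, 4 phyla, 4 growth stages,
120 spectra per strain per stage (17,280 spectra; real libraries of this kind
run to ~17k spectra with >100 per strain and stage).

Each spectrum is a sum of Gaussian bands plus nuisance terms:

- **Shared peaks** (12): generic biomass bands common to all organisms,
  amplitudes U(0.3, 1) a.u., widths U(8, 25) cm⁻¹.
- **Genus peaks** (6) and **strain peaks** (4): amplitudes U(0.15, 0.5) and
  U(0.1, 0.4) scaled by `taxon_separation` (default 1). At separation 0 all
  taxon-specific bands vanish and every strain is spectrally identical.
- **Stage signal**: a global per-stage multiplier pattern
  exp(stage_separation · N(0, 0.25)) on the shared peaks, identical across
  taxa (so stage is recognizable irrespective of organism), a weaker
  per-strain modulation N(0, 0.15) on taxon peaks, and 2 stage-specific
  extra bands. At `stage_separation = 0` a stage classifier performs at
  chance, which the tests verify against a binomial confidence interval.
- **Within-stage jitter**: multiplicative amplitude noise per spectrum;
  defaults Exp 6%, S1 2%, S2 5%, S3 8%. S1 is deliberately the most
  internally consistent stage, the synthetic analogue of early stationary
  phase being the most informative sampling point; this is a default, not a
  hard-coded property.
- **Nuisance**: a random polynomial baseline of degree ≤ 3 (coefficients
  U(−0.15, 0.15) on a normalized axis) and i.i.d. Gaussian noise
  (sd 0.02 a.u.).
- **Environmental mode**: a broad fluorescence hump (center U(1100, 1600),
  width U(150, 300) cm⁻¹) and ~10% multiplicative intensity jitter, both
  scaled by `env_strength` — emulating the background fluorescence and
  cellular alteration a FISH-labelling step introduces. At strength 0 the
  output is bit-identical to the clean generator.

Two strains of the first multi-strain genus have their strain-specific bands
attenuated (×0.3), designating a closely-related "confusable pair" that
dominates the confusion structure, as a pair of congeneric species would.

Randomness: one master seed; every strain × stage block draws from its own
`default_rng([seed, stream, strain, stage])` substream, so datasets are
bit-identical given the config and invariant to generation order.

*What passing tests show*: that the pipeline recovers planted structure at
realistic effect sizes and degrades to chance when structure is absent. They
do **not** show instrument-level realism — there is no instrument response
function, cosmic-ray spikes, detector nonlinearity or real band physics, and
the effect sizes are free parameters, not estimates from real spectra.

## Preprocessing

Background subtraction, Savitzky–Golay smoothing (default window 11,
polyorder 3), asymmetric-least-squares (ALS) baseline estimation, and
per-spectrum normalization, with pipeline order background → smooth →
baseline → normalize. ALS (smoothness weight λ = 1e5, asymmetry p = 0.01,
10 reweighting iterations) is the standard default where a protocol names
"baseline correction" without equations; both parameters are exposed.
Resampling is linear interpolation and refuses to extrapolate; assembling
spectra from per-file exports with differing grids is an error, never a
silent resample.

## Dimensionality reduction

- `NONE` is a first-class method (classifiers see full spectra), so the
  benchmark grid treats "no DR" uniformly.
- `PCA`/`KPCA` delegate to scikit-learn; KPCA uses an RBF kernel with the
  median pairwise-distance heuristic for the kernel scale unless given.
- `LDA` solves the generalized eigenproblem eigh(S_b, S_w) directly on
  between/within scatter (each /n), with a relative ridge 1e-8·tr(S_w)/p on
  S_w for numerical safety. Output dimensionality is bounded by
  n_classes − 1 (3 for the 4-stage task) and the bound is enforced with an
  explicit error.
- `SUP_PCA` is the label-kernel-weighted covariance construction: top
  eigenvectors of X_cᵀ (H Y)(H Y)ᵀ X_c with a one-hot label kernel. With a
  delta kernel its rank is at most n_classes; requested dimensions beyond
  that are the deterministic near-null eigh completion.
- `ISM_SDR` is an iterative supervised kernel dimension reduction: starting
  from the SUP_PCA subspace, it alternates (a) eigendecomposition of the
  dependence-weighted scatter Xᵀ(Ψ ∘ K)X, where Ψ is the centered label
  kernel and K an RBF kernel in the current subspace, with (b) a median-
  heuristic kernel-scale update in that subspace; convergence when the
  largest principal angle between successive subspaces is < 1e-6 (cap 100
  iterations). Component signs are fixed so the largest-magnitude loading is
  positive. This is our documented variant of the iterative-spectral family;
  numerical equality with other implementations is not claimed.

Default output dimensionality: 35 for taxonomy tasks, 3 for the stage task;
the benchmark runner shrinks infeasible requests (LDA's class bound, the
channel count) per method and task rather than failing the grid.

## Classifiers

scikit-learn estimators behind one registry: GNB; KNN with K = 10; LDA; LR
(multinomial, L2, C = 1 — no tuning is specified for it); RF with 100 trees;
linear and RBF SVMs at C = 1; CV-tuned SVM variants with candidate grids
C ∈ {0.01, 0.1, 1, 10, 100} and RBF scale σ ∈ {0.01, 0.1, 1, 10} × the
median-distance heuristic; and an MLP (one hidden layer of 128 units, early
stopping, ≤ 200 epochs — a CPU-scale default, as the architecture is a free
choice). SVMs are one-vs-rest; ties break by decision margin, then sorted
label order. Every stochastic method consumes an explicit seed.

## Cross-validation and the benchmark grid

Outer (evaluation) CV: stratified 10-fold by default — nine splits train,
one tests, each split tests once; fold accuracies are aggregated by an
unweighted mean. Stratification uses the task's own label (strain for
taxonomy, stage for the G-step); when a stratum is smaller than the fold
count the engine warns and degrades to unstratified shuffled folds.

Inner (optimization) CV: when a classifier carries a grid, the outer
training data is re-split (default 5 inner folds — the re-split granularity
is a convention here, as only "re-splitting the training folds" is specified)
and candidates are scored by mean inner accuracy; exact ties keep the first
candidate in declared grid order. The DR is fitted once per outer training
split and candidates are scored on those reduced features; the outer test
split is untouched throughout, which the no-leakage test verifies by hashing
every fitted model under permuted test labels.

The default grid is 6 DR × 9 classifiers = 54 models; the MLP is excluded by
default and enabled with a flag, since neural networks warrant separate
treatment (training cost, capacity) from the classical grid. A failing
combination is recorded and the run continues.

`dim_sweep` scans output dimensionalities and selects the best mean accuracy,
ties to the smaller dimensionality; infeasible dimensionalities are skipped
with a warning.

`extend_reference` merges two libraries and re-balances at genus level to an
exact per-genus quota (without replacement; with replacement plus a warning
when a genus is short), the procedure for extending a pure-culture reference
toward environmental targets.

## The G-T ensemble

`train_gt` fits the G-step on all stage-labelled rows and one T-step model
per stage. The open choice — train T-step models on ground-truth or on
predicted stage partitions — defaults to ground truth with a
`train_on_predicted` flag, since truth partitions make the oracle-gating
equivalence exact: with routing forced to the true stage, the ensemble
reproduces the stage-conditioned CV fold accuracies bit-for-bit (a tested
identity). `evaluate_gt` shares one fold split (stratified on
strain × stage) between both steps so the joint accuracy is well-defined per
fold, and reports G-step accuracy, joint accuracy, oracle-gated accuracy,
per-stage accuracies and the stage confusion matrix. Defaults for the two
steps are NONE+SVM_RBF_CV (G) and LDA+LR (T), both overridable.

## BEST model comparison

Each model's per-fold accuracies are modelled as Normal(mean, sd) with
normal priors; a joint random-walk Metropolis–Hastings chain samples
(mean_A, sd_A, mean_B, sd_B) for 11,000 iterations, discarding the first
1,000 as burn-in (automated rather than inspected; diagnostics surface
pathology). Defaults, all exposed in `BESTConfig`:

- priors centred on the pooled sample mean/sd with weakly informative
  spread 0.5 (sd prior truncated positive);
- proposal steps auto-scaled to the within-group posterior scale
  (mean within-group sd / √n) — the pooled spread would overshoot when the
  groups are far apart;
- the null region is |mean_A − mean_B| ≤ 0.005 (half an accuracy percentage
  point), a region of practical equivalence: `p_null` is its posterior mass,
  so the null can be *accepted*, not merely non-rejected. The ROPE width is
  a genuine free choice and results are sensitive to it, hence it is logged
  with every result.
- both groups constant and equal (or unequal) is decided analytically
  (p_null 1 or 0) rather than sampled.

Multiple comparisons use Benjamini–Hochberg FDR at 0.05 (statsmodels).
Calibration is tested empirically: for two groups drawn from one
distribution, p_null exceeds 0.05 in ≥ 90% of 200 seeded simulations.
Diagnostics flag acceptance rates outside [0.1, 0.7].

## Problem sizes used in tests and the acceptance script

Test fixtures scale the library down (4–12 strains, 10–50 spectra per
strain × stage, 60–300 channels) so the full suite runs in well under a
minute of compute per file; the acceptance script uses an 8-genus /
10-strain library (800 spectra × 150 channels) for the 54-model grid and an
18-genus / 38-strain library for the environmental-transfer case. At these
sizes several top models saturate at 100% fold accuracy — scaled-down
synthetic regimes are easier than a 17k-spectrum real library, and the
reported numbers characterize the synthetic conditions only.

## Known limitations

- Synthetic effect sizes are conventions, not estimates; absolute accuracies
  on synthetic data say nothing quantitative about real spectra.
- SUP_PCA beyond the label-kernel rank appends near-null directions.
- The ALS baseline under broad peaks biases peak heights slightly downward
  (tested to < 5% on a simulated known-truth case).
- BEST's Gaussian likelihood is thin-tailed; accuracy distributions truncated
  near 1.0 are approximated, not modelled exactly.
- The G-T engine does hard routing only; probability-weighted soft routing is
  deliberately out of scope.
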