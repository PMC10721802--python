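# Methods

`mcifmri` re-implements, as a tested library, a resting-state fMRI analysis
for separating mild cognitive impairment (MCI) from healthy controls (HC):
three voxel-based metrics are computed from denoised BOLD series, averaged
over a 132-region atlas into subject feature vectors, submitted to wrapper
feature selection under five search strategies, and evaluated with
cross-validated SVM / random-forest classifiers. Because the original
scanner cohorts are access-controlled, a synthetic-data generator with known
ground truth stands in for them; everything below is the package's own
account of the model, its parameters and its limitations.

## Voxel metrics

All three metrics are ratio- or correlation-based and therefore invariant to
positive rescaling of any voxel's time series.

**fALFF** (fractional amplitude of low-frequency fluctuations). Per voxel,
the sum of Fourier amplitudes over the low-frequency band divided by the sum
over all positive frequencies (DC excluded); values in [0, 1]. The band
defaults to 0.008–0.09 Hz. fALFF is computed on confound-regressed but
*unfiltered* series: after band-pass filtering the ratio is degenerately ≈ 1,
so the metric requires the full spectrum. Zero-variance voxels are assigned
0 and counted in a log warning.

**LCOR** (local correlation). Per voxel, the Gaussian-distance-weighted mean
Pearson correlation with in-mask neighbours within a truncation radius of
2 × kernel, values in [−1, 1]. The kernel parameter is 25 mm and is
interpreted as the FWHM of the Gaussian (σ = FWHM / 2√(2 ln 2) ≈ 10.6 mm);
the toolbox convention behind the published analysis does not state whether
25 mm is FWHM or σ, so σ-parameterisation is selectable (`kernel_is_sigma`).
Distances are measured in millimetres using the voxel geometry.

**ICC** (intrinsic connectivity). Per voxel, a summary of connectivity to
all other in-mask voxels. The default "power" variant is the mean squared
correlation, in [0, 1]; for independent Gaussian series its null expectation
is 1/(T−1), which the tests use as a closed-form oracle. A thresholded
"degree" variant (fraction of voxels with r above a threshold, default 0.25)
is also implemented, since the source analysis is ambiguous between the two
readings. Computation is blockwise so memory stays bounded.

**Temporal preprocessing.** Band-pass filtering is a hard FFT-domain mask
(bins with low ≤ f ≤ high retained) after linear detrending — exactly
reproducible and exactly matched to the band edges. Confound regression is
ordinary least squares of each voxel on the confound columns plus an
intercept; residuals are returned, and a rank-deficient design is rejected
with the collinear columns named. Only these two denoising steps are in
scope: realignment, slice-timing, scrubbing, normalisation and smoothing are
expected to have been applied upstream by whatever toolchain produced the
input volumes.

## Parcellation

An atlas is an integer label volume (0 = background, 1..R). Each region's
feature is the arithmetic mean of the metric map over the region's in-mask
voxels; empty regions are an error. Columns are ordered metric-major and
named `<metric>__<region_index>__<region_name>`, so three metrics over 132
regions give the canonical 396-column table. The package ships no anatomical
atlas: the default fixture is a deterministic box tiling of the synthetic
grid (trivially hand-checkable), and users supply real label volumes as
NIfTI. No resampling is performed — maps and atlas must share the grid.

## Wrapper feature selection

Candidate solutions are boolean masks over the feature columns; the fitness
of a mask is the mean fold accuracy P of the chosen classifier under
stratified k-fold CV (k = 10) restricted to the masked columns. The combined
objective trades error against parsimony:

    f(x) = α (1 − P) + (1 − α) · N_selected / N_total,  lower is better.

α defaults to 0.9 (classification error weighted an order of magnitude above
parsimony); it was not stated by the source analysis and is config-exposed.

Per-method criteria follow the published protocol: GA, SA and SFFS maximise
accuracy; PSO minimises f; NSGA-II minimises the pair (N_selected, f) and
reports a Pareto front, with the designated solution the front member of
minimal f (ties → fewer features). Hyperparameters were unreported and are
the package's own defaults, all config-exposed:

* **GA** — population 20, tournament size 3, uniform crossover (rate 0.9),
  per-bit mutation 1/N, elitism 1, 24 generations.
* **NSGA-II** — same variation operators; fast non-dominated sort and
  crowding distance; binary tournament on (rank, crowding).
* **PSO** — continuous positions binarised by the sigmoid transfer at
  threshold 0.5 (equivalently x > 0); constriction parameters w = 0.729,
  c1 = c2 = 1.49445, velocity clamp ±4. Positions are initialised well away
  from the threshold and velocities small so the sparse start survives the
  first update.
* **SA** — Metropolis acceptance on accuracy, T₀ = 1.0, geometric cooling
  ×0.95 per step, 300 steps. The default proposal draws a fresh random
  subset each iteration; a one-bit-flip neighbourhood is selectable, but on
  accuracy plateaus the flip walk accepts neutral ON-flips indefinitely and
  drifts toward very large masks, which matches neither reading of the
  original description.
* **SFFS** — classic sequential floating forward selection: best single
  addition (ties → lowest column index), followed by conditional exclusion
  while it improves the best value recorded for the smaller subset size;
  stops when no addition improves the criterion or a size cap is reached.

Masks are initialised sparsely (each bit set with probability
`init_density` = 0.08). With ~400 columns and an accuracy-only criterion,
dense random masks (density 0.5) reach ceiling accuracy immediately and
never shrink, which makes the selected-feature frequency report
uninformative; a sparse prior keeps subset sizes in the regime where
selection pressure operates. Any proposal with zero bits is repaired by
setting one uniformly random bit. All methods are reproducible from the
objective seed; mask evaluations are cached within a run.

An exhaustive oracle enumerates every nonempty mask for tables of ≤ 20
features (deterministic tie-breaks: fewest features, then smallest integer
encoding) and is the reference the metaheuristics are validated against.

## Evaluation

Folds are stratified (per-fold class counts within one of proportionality);
stratification is a deviation-by-necessity from the unstated original
protocol, because unstratified tenfold on 32 MCI subjects risks class-empty
test folds. k = n is treated as leave-one-out. Features are z-scored with
training-fold statistics only. Classifiers: linear SVM (C = 1) and random
forest (500 trees, √N features per split, seeded); forest size is reduced
(`rf_trees`, default 128) inside grid runs purely for wall-time.

The headline numbers are computed from the fold-pooled confusion matrix in
the reference-HC-row orientation [[TN, FP], [FN, TP]]. Accuracy is
(TP+TN)/total. Sensitivity and specificity are reported in *both*
conventions: the published result tables score HC as the positive class
(`sens_hc_pos` = TN/(TN+FP), `spec_hc_pos` = TP/(TP+FN)), which reproduces
their printed percentages, while `sens_std`/`spec_std` are the standard
MCI-positive values; the two are mirror images. The printed formula with an
FN denominator in sensitivity is inconsistent with every printed table and
is treated as a typographical error. ROC-AUC is the mean of per-fold AUCs
from decision scores; single-class test folds are skipped with a warning.

Two evaluation modes exist. **Faithful** mode reports metrics on the same
tenfold CV the selector optimised — the original protocol, optimistically
biased by construction (the null-calibration test quantifies this: faithful
accuracy on no-effect data sits well above 0.5, honest accuracy does not).
**Honest** mode wraps selection in an outer CV (default 5 folds): masks are
chosen on the outer-training portion only and scored once on the held-out
fold. Acceptance-style comparisons use faithful mode because that is what
the published numbers are.

## Synthetic cohorts

The generator emulates the study design, not scanner physics. Defaults
mirror the local arm (46 HC / 32 MCI, TR = 2 s, 300 volumes, 132 regions);
86/69 gives the consortium-style arm.

At **feature level**, uninformative columns are N(0,1) in both groups and
planted columns are mean-shifted by `effect_size` for MCI — exact Cohen's d
in expectation, exchangeable groups at d = 0.

At **image level**, every region r carries a unit-variance latent signal
s_r(t) (six sinusoids with frequencies drawn in 0.008–0.09 Hz,
subject-specific phases) and voxel v in r observes
A_{s,r}·s_r(t) + B_{s,r}·σ·ε_v(t) with white noise ε. A and B vary between
subjects (SD 0.15); MCI subjects in informative regions get A raised (moves
fALFF and ICC) and B lowered (raises within-region coherence, moves LCOR),
each channel independently configurable. Channel gains (0.6 amplitude, 1.0
coherence) and the default 10 mm voxel spacing were calibrated by Monte-Carlo
so the mean standardized difference of the planted ROI features across the
three metrics matches the configured effect size (measured 1.50 for a
configured 1.5); the 10 mm spacing keeps the 25 mm LCOR kernel local
relative to region size, emulating real data where atlas regions are large
compared with the kernel. All randomness flows from one seed through fixed
per-subject substreams, so cohorts are bit-reproducible.

What the generator does **not** emulate: spatial autocorrelation beyond
region boundaries, head motion, physiological noise spectra, scanner drift,
anatomical variability, atlas misregistration. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's machinery, not
expected performance on clinical data.

## Problem sizes and numerical choices

Default search budgets (population 20 × 24 iterations; SA 300 steps; SFFS
capped only by the column count) are sized so that a five-selector SVM
battery on the 78 × 396 table finishes in about a minute per run; grid runs
with the forest use the reduced `rf_trees`. The recovery experiment pools
the selector battery over three independent run seeds on one cohort before
ranking region frequencies — single-battery counts on an easily separable
cohort are too noisy to rank regions stably, because ceiling accuracy makes
many small subsets equivalent. Tests and the acceptance script use reduced
grids (fewer regions, subjects or volumes) chosen to keep each Monte-Carlo
within minutes; the sizes are stated in each test.

Degenerate inputs are handled by convention rather than NaN: zero-variance
series have correlation 0 and fALFF 0 (logged); empty regions, empty masks,
rank-deficient confounds and out-of-Nyquist bands are errors.

## Known limitations

* The five selectors' hyperparameters are this package's choices; no claim
  is made that they match the unreported originals, so absolute accuracy
  values on synthetic cohorts are not comparable to the published ones.
* Greedy SFFS can miss the exhaustive optimum when no small separating
  subset exists; the oracle-equivalence guarantee is established on tables
  with strongly separating planted features.
* ICC is quadratic in voxel count per block; the image path targets the
  small synthetic grids, not whole-brain volumes.
* Honest mode nests selection inside the outer CV but does not additionally
  tune classifier hyperparameters (no nested tuning).
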