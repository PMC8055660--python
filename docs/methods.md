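# Methods

This note documents the models and procedures implemented in
`falff_prognosis`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic cohorts do and do not
establish about behavior on real data.

## The analysis in one paragraph

Post-stroke aphasia patients are treated for one impairment (anomia,
agrammatism, or dysgraphia) and assessed before and after therapy on a
treatment-specific measure (TSM), a bounded score in [0, 1]. The pipeline
predicts the post-treatment TSM from the pre-treatment TSM plus one of two
feature families: a 27-measure behavioral language battery, or 20
resting-state fMRI features obtained by decomposing all subjects' BOLD
series with group spatial ICA and summarizing each subject-component time
course by its fractional amplitude of low-frequency fluctuations (fALFF).
Prediction uses elastic-net regression with leave-one-out cross-validation
(LOOCV) throughout; performance is judged by median absolute deviation
(MAD), a paired Wilcoxon comparison against a chance model, and squared
Pearson correlation (R²) with a correlation test.

## Quality control (qc)

Scan quality is summarized by slice-wise temporal SNR: per voxel, the
temporal mean over the temporal standard deviation (n−1 denominator);
per axial slice (third array axis), the mean over in-mask voxels; per
scan, the slice values averaged with brain-voxel-count weights. Scans with
weighted tSNR below 100 are excluded; among repeated runs the highest-tSNR
run is kept (ties keep the earliest). The slice statistic admits a second
reading — the spatially averaged slice time course's mean over its
standard deviation — which is available as `method="pooled"`; the
voxel-mean reading is the default because it is standard practice and
robust to within-slice intensity gradients. tSNR is computed on the scan
as given (no despiking or motion correction precedes it here; those stages
wrap external tools and are out of scope).

## Group ICA (ica)

Temporal-concatenation group spatial ICA:

1. **Subject reduction.** Each subject's in-mask (t × V) matrix is
   voxel-wise centered and reduced along time by PCA to
   k = ⌈1.5 · n_components⌉ rows (clipped to the subject's temporal rank).
2. **Group reduction and whitening.** Reduced subjects are stacked,
   row-centered over voxels, and eigendecomposed; the top `n_components`
   directions are kept and scaled so the output rows have identity
   covariance over voxels. Requesting more components than the group rank
   is an error.
3. **InfoMax unmixing.** Full-batch natural-gradient ascent with the
   logistic nonlinearity: `W ← W + lr·(I + (1 − 2g(WY))(WY)ᵀ/V)·W`.
   The learning rate (initial 0.05) halves whenever successive updates
   oscillate; iteration stops at relative update norm < 1e−7 or 1000
   iterations (with a warning). The seed draws the initial unmixing
   matrix. The logistic score suits spatially sparse (super-Gaussian)
   sources, which both real component maps and the synthetic blobs are.
4. **Ordering and sign.** Components are ordered by descending mixing
   energy in the whitened group space; each map's sign is fixed so its
   maximum-magnitude voxel is positive.
5. **Back-projection.** Dual regression: subject time courses are the
   least-squares regression of the subject's centered data on the group
   maps; subject maps are the regression of the data on those time
   courses. This is a deliberate, self-contained substitute for toolbox
   PCA-based back-reconstruction; numerical identity with GIFT is not
   claimed.
6. **Stability.** InfoMax is rerun under distinct seeds (100 by default at
   the CLI; smaller in desk-scale runs); each restart's source maps are
   greedily matched to the first restart's by absolute spatial
   correlation, and a component's stability index is the mean matched
   |correlation| — 1.0 means every restart found the same component.

Cohorts with mixed repetition times are decomposed together; TR matters
only at the fALFF stage.

## fALFF features (falff)

For one time course: linear detrend (which also removes the mean), an
unpadded, untapered periodogram via the discrete Fourier transform, and
the ratio of summed power at frequencies 0.01 ≤ f ≤ 0.08 Hz (inclusive
edges) to summed power over all positive frequencies. The band must lie
below Nyquist = 1/(2·TR). "Power" means squared spectral magnitude, per
the ratio-of-power definition; the amplitude convention of the original
low-frequency-fluctuation literature is available as `mode="amplitude"`.
A constant series is reported as 0 with a warning. Each subject's
per-component values are then standardized to sum to one, making the
feature vector a relative power profile invariant to global per-subject
power scaling. fALFF is itself invariant to amplitude scaling and mean
offsets of the time course, so whether time courses were variance
normalized upstream is immaterial.

## Prognostic model (model)

Elastic net on z-scored predictors with unpenalized intercept, objective

    (1/2n)·Σᵢ (yᵢ − β₀ − xᵢβ)² + λ·(α·‖β‖₁ + (1−α)/2·‖β‖₂²),

fit by scikit-learn's coordinate descent (identical parameterization);
λ = 0 is solved directly as least squares. Standardization uses the
training rows only (n−1 denominator); constant training columns are
dropped with a log entry, never an exception.

Hyperparameters are chosen by LOOCV mean squared error over a grid of
α ∈ {0.1, 0.325, 0.55, 0.775, 1.0} and, per α, a 25-point log-spaced λ
path from λ_max (the smallest penalty that zeroes all coefficients) down
four decades. Ties prefer the larger λ, then the smaller α. Out-of-sample
predictions come from an outer LOOCV loop that is **fully nested** by
default: standardization, tuning, and fitting for subject i all exclude
subject i. Nesting avoids the optimistic bias of tuning on the full
sample; a non-nested mode exists behind a flag for comparison. Predictions
are clamped to the measure's dynamic range ([0, 1] by default).

Missing behavioral cells are filled by iterative random-forest imputation
(scikit-learn `IterativeImputer` with a 100-tree forest per incomplete
column, up to 10 rounds) using predictor columns only — outcomes are
excluded so imputation cannot leak the prediction target. An imputation
ensemble repeats impute-then-LOOCV with distinct seeds and aggregates
per-subject predictions and per-predictor coefficients by the elementwise
median, recording coefficient min/max across imputations. With no missing
data every imputation is identical, so a single run stands for the
ensemble. An optional sweep selects the forest size minimizing imputation
variance across seeded repeats.

## Evaluation (evaluation)

* **MAD**: median of |predicted − actual| (midpoint convention at even n).
* **Chance comparison**: per-subject absolute model deviations are paired
  with the zero-order deviations |actualᵢ − mean(actual)| — the error of a
  model that predicts the sample mean for everyone — and tested with a
  one-sided Wilcoxon signed-rank (alternative: model deviations smaller).
  The zero-order description admits a second reading (deviations of
  predictions from their own mean); that literal variant is available via
  `zero_order_of="predicted"`, with the true chance model as default.
* **Signed-rank p-values**: zeros are handled by the Pratt method and ties
  by average ranks. For n ≤ 25 the p-value is computed from the exact
  sign-flip permutation distribution (dynamic programming over doubled
  ranks — equal to full 2^m enumeration, and valid under ties and zeros,
  which clamped predictions routinely produce); beyond that, the normal
  approximation with continuity and tie correction.
* **R²**: squared Pearson correlation between predicted and actual, with
  the one-sided test t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.
  Note that R² defined this way is sign-blind: a perfectly
  anti-correlated prediction also has R² = 1, which the one-sided
  correlation test (not the R² value) exposes. Constant vectors are
  reported as R² = 0 with p = 1 and a warning.
* **Confidence intervals**: case-resampling percentile bootstrap (2000
  replicates, seeded). Replicates on which a metric is undefined (e.g. a
  constant resample under correlation) are skipped; more than 20%
  degenerate replicates is an error. The construction behind published
  intervals for these metrics is not standardized; the percentile
  bootstrap is this package's choice. In ensemble mode, intervals are
  computed on the median-aggregated predictions.
* **Treatment effect**: one-sided Wilcoxon signed-rank of post vs pre
  (alternative: post greater).

## Battery structure (battery)

Pairwise Kendall tau-b (standard tie correction) over pairwise-complete
observations, computed within each impairment group and averaged cell-wise
across groups with equal weight — balancing unequal group sizes. Cells
with fewer than 3 complete pairs in a group are excluded from that group's
contribution rather than zero-filled. Correlation distance is 1 − tau by
default; the 1 − |tau| variant is selectable because the two appear
interchangeably in descriptions of this analysis, and the package
surfaces rather than silently resolves that discrepancy. Clustering is
UPGMA (average linkage) via scipy, with Newick export; merge heights are
nondecreasing and ultrametric inputs are reproduced exactly in cophenetic
distance.

## Synthetic cohorts (synthetic)

The generator plants known ground truth for every downstream stage:

* **Sources.** Gaussian-smoothed white-noise fields thresholded to their
  top 10% of voxels give compact graded blobs (component maps in this
  regime need not resemble canonical language networks). Accepted blobs
  are then exactly decorrelated (symmetric whitening) and rotated to the
  empirical InfoMax independence optimum. The rotation perturbs each blob
  only slightly (correlation with the raw blob typically > 0.99) but makes
  the planted maps the *exactly identifiable* sources of any noiseless
  mixture built from them; without it, ground truth would be defined only
  up to a finite-sample rotation that no decomposition could resolve, and
  recovery checks would conflate that ambiguity with algorithmic error.
* **Time courses.** Sums of random-phase cosines at DFT-bin frequencies
  strictly inside 0.01–0.08 Hz and strictly above 0.09 Hz,
  amplitude-ratioed so the realized band-power fraction hits the
  per-subject, per-source target (within ±0.02; bin-centered tones make
  the control essentially exact), plus a 10⁻³ white-noise floor.
* **Scans.** `Σ_k timecourse_k ⊗ map_k` plus i.i.d. Gaussian noise
  (default sd 0.1 against unit-variance time courses) and a constant
  baseline offset of 1000 so tSNR behaves realistically.
* **Battery.** A common-factor model: every measure loads a general
  language-ability factor (loading 0.55) and one of three block factors
  (loading 0.6), plus unique noise — giving the global positive
  multicollinearity and stronger within-assessment correlation real
  batteries show. Default measure names follow the standard 27-measure
  aphasia battery roster. Missing cells are injected completely at random
  (MCAR, rate 0.033) into baseline battery cells only; outcome columns are
  never masked. MCAR is an assumption of convenience — only the rate, not
  the mechanism, is specified by the emulated study design.
* **Outcomes.** pre ~ U(0.2, 0.8);
  `post = clamp₍₀,₁₎(0.5·pre + Σ_k w_k·falffnorm_k + ε)` with ε ~ N(0, 0.03²),
  where `falffnorm` is the planted fALFF profile standardized to sum to
  one — the same standardization the measured features receive, so the
  planted signal lives in the space the model sees. Default weights
  (1.0, −0.4, 0.8, 0.7, −0.2) have mixed signs and a positive sum, so
  cohorts show a significant pre→post treatment gain as treated cohorts
  do. The weights are free parameters of the simulation: no published
  component-level effect sizes exist to calibrate them.
* **Seeding.** One integer seed fans out through fixed
  `numpy.random.SeedSequence` spawn keys (one domain per ingredient, one
  stream per subject × source), so cohorts are bit-reproducible and
  per-subject streams are stable under reordering.

Default problem sizes are desk-scale: a 12 × 12 × 8 grid, 120 timepoints,
TR 2 s, 5 sources, 30 subjects. The full 210-volume, 20-component regime
is supported by configuration; the defaults keep a complete pipeline run
plus nested LOOCV in the tens of seconds and the full test suite in
minutes.

### What the synthetic cohorts do not emulate

Hemodynamic response shapes, scanner drift and spike artifacts, motion,
physiological (cardiac/respiratory) structured noise, lesions and their
effect on source topography, site differences, and any nonlinear or
interaction structure in outcomes. Passing the recovery tests shows the
chain is *correct* — it recovers planted structure through QC, ICA, fALFF
and regularized regression without leakage — not that real BOLD data
contain such recoverable structure; on real data the components reflect
whatever independent structure is present, including physiological
signal.

## Numerical choices and degenerate inputs

Rank decisions use a relative eigenvalue tolerance of 1e−10. Whitening is
checked to identity covariance within 1e−6. Elastic-net fits warm-start
down a short penalty path to the target λ (pathwise coordinate descent, as
glmnet does): a cold start at λ_max/10⁴ on a collinear design can take
orders of magnitude longer to satisfy the duality-gap criterion. Final
fits target tolerance 1e−6; on near-singular designs at tiny penalties
the duality gap can stall with the solution long since settled, so fits
are retried over a tolerance ladder (1e−6, 1e−4, 1e−3) and, inside
cross-validation loops, a stalled-but-finite solution is accepted with a
warning rather than aborting the analysis (the low-level fitting function
raises by default). The CV path used for hyperparameter *ranking* runs at
tolerance 1e−5 with a 1000-iteration cap — selection only compares
candidates, and the tens of milliseconds saved per path dominate the
runtime of nested LOOCV. Zero-variance voxels,
slices and columns are excluded with warnings rather than raised, except
where the result would be meaningless (all scans failing QC, all-zero
fALFF vectors, rank-deficient back-projection), which raise. Degenerate
bootstrap replicates are skipped and counted. UPGMA tie-breaks follow
scipy's deterministic nearest-neighbor-chain order; merge heights, leaf
partitions and cophenetic distances are invariant to input order.

## Known limitations

Only linear prognostic models with convex regularization are provided (by
design: the modeled regime has more predictors than subjects). Change
scores (post − pre) are deliberately not modeled. The InfoMax
implementation targets super-Gaussian sources; strongly sub-Gaussian
sources would need an extended variant. Group demographics testing,
lesion analysis, spatial normalization and artifact-component labeling
are out of scope.
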