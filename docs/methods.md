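# Methods

## Scope and model

The package analyzes the resting-state functional network of the
structurally intact (contralesional) hemisphere in glioma patients and asks
whether its remodeling signature predicts malignancy grade (low-grade vs
high-grade, LGG/HGG).  The measurement model is deliberately minimal: a
subject is a matrix of N parcel time series; statistical dependence between
parcels (Pearson correlation, variance-stabilized by Fisher's Z) defines
the network; everything downstream — binary graph topology, feature
screening, classification — operates on those Z values.  No volumetric
processing is performed: inputs are assumed already parcellated (the
upstream steps — realignment, normalization with tumor cost-function
masking, smoothing, atlas parcellation — require image-domain tooling and
raw scans and are out of scope).

## Synthetic cohorts

Because no patient data are distributable, the generator produces cohorts
whose statistical structure matches what the analysis assumes, with ground
truth attached:

- **Time series** are zero-mean multivariate normal draws; group covariance
  matrices are correlation matrices equal to the identity except on a
  *planted* edge set, where the HGG matrix is shifted by ±`effect_size`.
  If a shift breaks positive definiteness the matrix is re-projected to the
  nearest positive-definite correlation matrix (Higham alternating
  projection, via statsmodels `corr_nearest`, tolerance 1e-8); a spec whose
  projection still fails is rejected with the offending edges named.
- **Demography**: ages are normal per group, truncated at 18 years (adult
  cohort); defaults follow the clinical groups the pipeline targets
  (LH: 36 LGG aged 38.54 ± 10.88 vs 44 HGG aged 45.06 ± 13.21;
  RH: 32 LGG 39.48 ± 10.46 vs 14 HGG 51.25 ± 17.81), with matching sex
  ratios.  Cohort generation is a pure function of the spec, seed included.
- **Effect-size calibration.** `effect_size_for_separation(s)` converts a
  target two-sample separation of the *downstream* Fisher-Z edge feature
  (in pooled-SD units) into a correlation shift, accounting for the
  degrees of freedom the band-pass leaves behind: an ideal filter keeping m
  positive-frequency bins leaves ≈ 2m effective samples, so the null Z SD
  is ≈ 1/√(2m−3) and δ = tanh(s/√(2m−3)).  At T = 230, TR = 2 s, band
  0.01–0.08 Hz this gives δ ≈ 0.13 per 1 SD of separation.  The realized
  separation is verified empirically in the tests.
- The default planted shift is positive on every planted edge (sign
  configurable per edge).  Positive shifts are what the upper-tail
  candidate rule (below) is designed to detect; topological group
  differences are *not* planted separately — they arise from the same
  covariance difference, as in the real analysis.

What the generator does **not** emulate: hemodynamic response functions,
scanner noise spectra, motion artifacts beyond the synthetic nuisance
regressors, spatial autocorrelation of real parcellations, and realistic
background connectivity (the base correlation is the identity).  Passing
tests therefore demonstrate correctness and calibration of the *procedure*,
not clinical effect sizes.

## Time-series cleaning

Order is fixed: detrend → nuisance regression → band-pass.  The three steps
are linear, and detrending is absorbed by the regression intercept, so the
composite is insensitive to the detrend/regression order; fixing one order
keeps runs bit-reproducible.  Nuisance regression is OLS against an
intercept plus the Friston-24 motion expansion ([m, m_lag1, m², m_lag1²]
per parameter, lag zero-padded); rank-deficient designs are rejected with
the collinear rows named.  The band-pass is an ideal rectangular FFT filter
(bins outside [0.01, 0.08] Hz zeroed, DC removed) — exact in-band
passthrough makes the filter testable to machine precision and matches
common resting-state practice.

## Connectivity

Correlations are clipped to |r| ≤ 1 − 1e-7 before `atanh`, so degenerate
perfectly-correlated pairs map to a large finite Z (≈ 8.06) instead of
infinity.  The diagonal is fixed at 0 (self-connections are not features).
Edges are vectorized in row-major upper-triangle order; the "i_j" edge ids
are the canonical feature ids everywhere downstream.  Negative correlations
are retained as signed Z values.

## Graph topology

- **Binarization** keeps the E = round(s·N(N−1)/2) strongest edges by
  *signed* Z (standard sparsity thresholding; negative edges enter only
  when E exceeds the positive-edge count), with lexicographic (i, j)
  tie-breaks and half-away-from-zero rounding for bit-exact edge counts.
- **Metrics.**  Cp is the mean local clustering (0 for degree < 2); Lp
  averages shortest-path lengths over *connected* ordered pairs, with a
  disconnection flag recorded (exclusion distorts least and keeps the
  value finite at sparse thresholds where isolates are routine); Eg counts
  unreachable pairs as efficiency 0; Eloc is the mean over nodes of the
  neighbor-subgraph global efficiency.  Nodal: unnormalized Brandes
  betweenness (scale is irrelevant after AUC integration and model
  standardization), degree, NEg = mean inverse distance to the other
  N−1 nodes, NEloc as above.  Implementation uses `scipy.sparse.csgraph`
  BFS distances and adjacency algebra; betweenness uses networkx's Brandes
  implementation.  All metrics are verified against naive brute-force
  oracles (queue BFS, triple enumeration, exhaustive shortest-path
  enumeration) on graphs ≤ 15 nodes.
- **Small-world nulls** are Maslov–Sneppen double-edge swaps (default 10
  proposals per edge, 20 nulls per sparsity; Monte-Carlo error of γ/λ
  shrinks as 1/√n_null).  Degenerate ratios: when Cp and ⟨Cp_null⟩ are both
  zero (sparse graphs without triangles) γ is defined as 1 — the graph is
  exactly as clustered as its null; a positive Cp over a zero null mean is
  returned as NaN and interpolated from the nearest finite curve points
  before integration (a subject with no finite points anywhere is
  rejected).
- **AUC over sparsity** is a trapezoidal integral over the 0.01–0.34 grid.
  The trapezoid is exact for linear curves; rectangle sums would differ by
  O(step), which matters to nobody downstream but is documented for
  reproducibility.

## Feature selection

Per inner fold, every feature is scored by its single-feature ROC AUC
(tie-corrected Mann–Whitney rank statistic; a numba kernel makes the
10-folds × repetitions × 7,503-features loop tractable, cross-checked
against scikit-learn).  A normal distribution is fitted to the AUC vector
by sample mean/SD (method of moments) and the candidate threshold is
mean + z(ci)·sd.

Two design points were genuinely open:

- **Direction handling.**  Candidates are taken from the *upper tail* of
  the raw AUC distribution: features must discriminate in the "high value
  → HGG" direction.  The alternative — folding AUCs to max(a, 1−a) so
  anti-correlated features score symmetrically — is available
  (`fold_auc=True`) but is not the default, because folded null AUCs are
  half-normal rather than normal and the one-sided-CI threshold then no
  longer controls the candidate rate at 1 − ci (the null fraction above
  mean + z·sd of a half-normal is 2Φ(−(0.798 + 0.603 z)), e.g. ≈ 7% at
  ci = 95%).  With the unfolded rule the null candidate fraction matches
  1 − ci to binomial accuracy, which the tests verify.  `feature_auc`
  itself reports the folded value, which is the natural screening summary.
- **Predictive quota.**  The top-percent threshold applies to the
  *candidate pool* (features selected at least once), not to the full
  feature list: predictive features are "top x% of the candidates".  On a
  7,503-edge hemisphere at ci = 99.6% this yields models of ~15–25
  features rather than 376, which is both the behavior that makes the
  selection meaningful and the scale of predictive sets this family of
  analyses reports.  Ties in frequency break by canonical feature order;
  zero-count features are never promoted.

Frequencies are counted per inner fold (repetitions × k draws) — finer
grained than per repetition and less tie-prone; the inner train-test fifth
plays no role in selection (the procedure bases selection on train-train
AUCs alone) and is deliberately left unused.  Age and sex can be screened
with the same AUC operator; age is force-included in the final model, sex
and other covariates stay behind a config switch.

## Classification and validation

Outer stratified 10-fold CV; *everything* adaptive happens inside the
training portion of each fold: selection, SMOTE, standardization, fitting.
SMOTE interpolates minority points toward their k = 5 nearest minority
neighbors (k reduced when the class is smaller) until classes balance
exactly; originals are preserved.  The logistic model is fitted on
z-scored features with ridge 1e-4 (intercept unpenalized; scikit-learn
lbfgs, checked against a textbook IRLS oracle to 1e-6) — SMOTE-balanced
high-AUC feature sets are frequently separable and the penalty keeps
coefficients finite.  The scaler is learned on the SMOTE-augmented training
data and frozen in the model so fold models transport unchanged to other
cohorts.

Hemisphere specificity: every fold model is scored on the entire
opposite-hemisphere table; same-group vs cross-group AUC vectors are
compared by two-tailed t-tests with Benjamini–Hochberg adjustment.  A
label-permutation sentinel test confirms the pipeline carries no leakage
(validation AUC at chance when labels are shuffled upstream).

## Problem sizes

Test and reproduction runs use hemisphere-scale cohorts (123 nodes, 230
timepoints, 80 and 46 subjects) with inner-CV repetitions at 25 (production
default 100) and seed sweeps of 10 (test suite) or 3 (acceptance script);
selection frequencies are stable at 125 draws per fold, and the seed sweeps
put Monte-Carlo error on reported means well inside the asserted bands.
Topology profiles in the structural checks run 1–2 nulls per sparsity;
γ/λ accuracy claims are tested separately at n_null = 5 on small graphs.

## Known limitations

- Identity background connectivity makes the synthetic screening problem
  easier than real connectomes, where correlated edges inflate the
  variance of selection frequencies; calibration claims are exact only
  under the generator's independence structure.
- Lp's connected-pairs convention and the γ degenerate-case rules are
  conventions, not estimates; other toolboxes make different choices and
  their threshold-integrated values differ accordingly.
- The classifier family is logistic regression only; no nonlinear models,
  no LASSO/wrapper selection.
- Reported AUCs on synthetic cohorts characterize the procedure under
  planted effects, not clinical performance.
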