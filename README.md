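# gliomanet

Functional-network analysis of the contralesional (tumor-free) hemisphere for
predicting glioma malignancy grade — a tested, reusable reimplementation of
the full resting-state pipeline: node time series → Fisher-Z connectome →
sparsity-integrated graph topology → repeated-CV feature selection →
SMOTE-balanced logistic classification, with cross-hemisphere transfer
validation.

## Who this is for

Researchers working with parcellated resting-state fMRI who want a
reproducible, leak-free implementation of the "AUC-threshold + frequency
ranking" feature-selection family and threshold-free graph metrics, and a
synthetic-cohort generator with planted ground truth to validate every stage
without patient data.

## The analysis

**Connectome.** Per subject, node time series (123 parcels per hemisphere,
230 volumes at TR = 2 s) are detrended, nuisance-regressed (Friston-24
motion expansion), band-pass filtered (0.01–0.08 Hz, ideal FFT filter), and
correlated: `Z_ij = atanh(r_ij)` gives a 123 × 123 Fisher-Z matrix whose
upper triangle (7,503 edges) is the FC feature vector.

**Topology.** The weighted matrix is binarized at sparsities 0.01–0.34
(step 0.01, strongest edges first).  At each sparsity: clustering
coefficient Cp, characteristic path length Lp, global/local efficiency
Eg/Eloc, and small-world ratios γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩,
σ = γ/λ against degree-preserving (Maslov–Sneppen) nulls, plus nodal
betweenness Bc, degree Dc, and nodal efficiencies NEg/NEloc.  Each metric
curve is integrated over the sparsity grid (trapezoid), yielding 7 global +
4 × 123 = 492 nodal threshold-free features per subject.

**Selection.** Inside the training data, stratified inner 5-fold CV scores
every feature by single-feature ROC AUC on the train-train portion; a normal
fit to all AUCs plus a one-sided confidence level (default 99.6%) yields an
upper-tail candidate threshold.  Repetitions (default 100; studies here use
25) with fresh fold randomizations produce per-feature selection
frequencies; the top percent (default 5%) of the candidate pool becomes the
predictive feature set.

**Classification.** Per outer stratified 10-fold CV fold: selection on the
training portion only → SMOTE balancing of the training classes →
standardized logistic regression (ridge 1e-4) over predictive features +
age → ROC AUC on the training and held-out portions.  Fold models can be
transported to the opposite-hemisphere cohort to quantify hemisphere
specificity (two-tailed t-test, Benjamini–Hochberg FDR).

**Synthetic cohorts.** Groups (LGG/HGG) are multivariate-normal time series
whose correlation matrices differ on a configurable planted edge set;
class-specific age distributions and sex ratios follow the clinical
demography the pipeline was designed around (LH group 36 LGG / 44 HGG, RH
group 32 LGG / 14 HGG).  `effect_size_for_separation()` converts a target
per-edge two-sample separation (in SD units of the band-passed Fisher-Z
feature) into a correlation shift.

## Worked example

```python
import numpy as np
from gliomanet import (
    lh_cohort_spec, generate_cohort, effect_size_for_separation,
    SelectionConfig, outer_cv_evaluate,
)
from gliomanet.pipeline import fc_feature_table

delta = effect_size_for_separation(1.5)          # 1.5-SD planted separation
spec = lh_cohort_spec(
    planted_edges=tuple((2 * k, 2 * k + 1) for k in range(10)),
    effect_size=delta, seed=3,
)
table = fc_feature_table(generate_cohort(spec).subjects)
cfg = SelectionConfig(ci_level=0.996, top_pct=0.05, n_repetitions=25, seed=1)
ev = outer_cv_evaluate(table, cfg, cv_folds=10, seed=1)
print(f"train      AUC {ev.train.mean:.3f} ± {ev.train.sd:.3f}")
print(f"validation AUC {ev.validation.mean:.3f} ± {ev.validation.sd:.3f}")
print(f"features per fold ~{np.mean([len(f) for f in ev.selected_features]):.0f}")
```

prints

```
train      AUC 1.000 ± 0.000
validation AUC 1.000 ± 0.000
features per fold ~19
```

i.e. with ten edges planted at 1.5-SD separation plus the age gap, the
selected ~19-feature logistic model separates held-out subjects essentially
perfectly, while the same pipeline on a null cohort (no planted effect,
equal ages) stays at chance (validation AUC ≈ 0.5) — see the tests.

A YAML-driven CLI covers the same flow stage by stage:

```bash
gliomanet run-all --config config.yaml --seed 7 --out results/
gliomanet sweep   --config config.yaml --seed 7 --out results/  # CI × top-% grid
```

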