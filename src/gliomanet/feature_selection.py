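"""Repeated cross-validated AUC screening with frequency-ranked selection.

The selection procedure works in three steps.  (1) Inside the training
data, a stratified inner k-fold split (default 5) defines train-train /
train-test subsets; on each train-train subset the discriminative power of
every single feature is scored by its ROC AUC (Mann-Whitney rank statistic,
ties counted 1/2).  (2) A normal distribution is fitted to the vector of
all per-feature AUCs (sample mean and SD) and a one-sided confidence level
turns it into an upper-tail threshold mean + z(ci) * sd; features above the
threshold become *candidates* for that fold.  (3) The inner CV is repeated
(default 100 times with fresh fold randomizations) and each feature's
selection frequency across all repetitions x folds is recorded; the
top-percent most frequently selected features (default top 5%) are the
*predictive* features.

Direction handling: by default candidates are taken from the upper tail of
the raw (unfolded) AUC distribution — features that discriminate in either
direction can be screened symmetrically by setting ``fold_auc=True``, which
folds AUCs to max(a, 1-a) before thresholding; note that folding makes the
null candidate rate exceed 1 - ci_level, since folded null AUCs are
half-normal rather than normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary labels (LGG=0, HGG=1)."""

    X: np.ndarray
    feature_ids: list[str]
    labels: np.ndarray
    subject_ids: list[str]
    age: np.ndarray | None = None
    sex: np.ndarray | None = None  # 1 = male, 0 = female

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D [subjects x features]")
        n, f = self.X.shape
        if len(self.feature_ids) != f:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.feature_ids)) != f:
            raise ValueError("feature_ids must be unique")
        if self.labels.shape != (n,) or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix has non-finite entries")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (n,):
                raise ValueError("age length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X[idx],
            feature_ids=self.feature_ids,
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(idx)],
            age=None if self.age is None else self.age[idx],
            sex=None if self.sex is None else self.sex[idx],
        )


@dataclass(frozen=True)
class SelectionConfig:
    ci_level: float = 0.996
    top_pct: float = 0.05
    n_repetitions: int = 100
    k_inner: int = 5
    seed: int = 0
    fold_auc: bool = False

    def __post_init__(self) -> None:
        if not (0.95 <= self.ci_level <= 0.999):
            raise ValueError("ci_level must lie in [0.95, 0.999]")
        if not (0.01 <= self.top_pct <= 0.20):
            raise ValueError("top_pct must lie in [0.01, 0.20]")
        if self.n_repetitions < 1 or self.k_inner < 2:
            raise ValueError("need n_repetitions >= 1 and k_inner >= 2")


@dataclass
class FrequencyTable:
    counts: np.ndarray
    feature_ids: list[str]
    total_draws: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.feature_ids):
            raise ValueError("counts/feature_ids length mismatch")
        if np.any(self.counts < 0) or np.any(self.counts > self.total_draws):
            raise ValueError("counts must lie in [0, total_draws]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "count": self.counts,
             "frequency": self.counts / self.total_draws}
        )


# ---------------------------------------------------------------------------
# Per-feature AUC (the hot loop of the whole procedure)


@njit(cache=True)
def _auc_columns_kernel(Xt, y):  # pragma: no cover - exercised via wrapper
    """Raw Mann-Whitney AUC per feature; Xt is [features x subjects] C-order."""
    f, n = Xt.shape
    n1 = 0
    for i in range(n):
        n1 += y[i]
    n0 = n - n1
    out = np.empty(f, dtype=np.float64)
    for j in range(f):
        order = np.argsort(Xt[j])
        r1 = 0.0
        i = 0
        while i < n:
            k = i + 1
            while k < n and Xt[j, order[k]] == Xt[j, order[i]]:
                k += 1
            avg_rank = 0.5 * (i + k + 1)  # ranks i+1 .. k averaged
            for t in range(i, k):
                if y[order[t]] == 1:
                    r1 += avg_rank
            i = k
        out[j] = (r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    return out


def feature_auc_matrix(X: np.ndarray, labels: np.ndarray, fold: bool = False) -> np.ndarray:
    """Vectorized single-feature ROC AUCs (tie-corrected rank statistic)."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    Xt = np.ascontiguousarray(X.T)
    aucs = _auc_columns_kernel(Xt, labels)
    if fold:
        aucs = np.maximum(aucs, 1.0 - aucs)
    return aucs


def feature_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Folded single-feature AUC in [0.5, 1] (direction-symmetric screen)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    return float(feature_auc_matrix(values, labels, fold=True)[0])


def auc_threshold(aucs: np.ndarray, ci_level: float) -> float:
    """Upper one-sided threshold mean + z(ci) * sd of the fitted normal."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size < 2:
        raise ValueError("need at least 2 AUC values")
    mean = float(aucs.mean())
    sd = float(aucs.std(ddof=1))
    if sd == 0:
        return mean  # degenerate: no spread to threshold on
    return mean + float(stats.norm.ppf(ci_level)) * sd


def candidates_one_fold(
    X: np.ndarray, labels: np.ndarray, ci_level: float, fold_auc: bool = False
) -> np.ndarray:
    """Boolean candidate mask: features whose AUC exceeds the fitted threshold."""
    aucs = feature_auc_matrix(X, labels, fold=fold_auc)
    return aucs > auc_threshold(aucs, ci_level)


def repeated_selection(table: FeatureTable, cfg: SelectionConfig) -> FrequencyTable:
    """Selection frequency over n_repetitions x k_inner candidate draws."""
    y = table.labels
    min_class = int(np.bincount(y).min())
    if min_class < cfg.k_inner:
        raise ValueError(
            f"minority class ({min_class}) too small for stratified {cfg.k_inner}-fold CV"
        )
    counts = np.zeros(table.n_features, dtype=np.int64)
    for rep in range(cfg.n_repetitions):
        rs = (cfg.seed * 1_000_003 + rep) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=cfg.k_inner, shuffle=True, random_state=rs)
        for tt_idx, _tt_test in skf.split(table.X, y):
            # train-train portion drives selection; the held-in train-test
            # fifth is reserved (unused by the written procedure)
            mask = candidates_one_fold(
                table.X[tt_idx], y[tt_idx], cfg.ci_level, fold_auc=cfg.fold_auc
            )
            counts += mask
    total = cfg.n_repetitions * cfg.k_inner
    assert counts.max(initial=0) <= total
    return FrequencyTable(counts=counts, feature_ids=table.feature_ids, total_draws=total)


def pick_predictive(freq: FrequencyTable, top_pct: float) -> list[str]:
    """Top-percent most frequently selected candidate features.

    The quota is ceil(top_pct * n_candidates), where the candidate pool is
    the set of features selected at least once across the repeated inner CV
    — predictive features are drawn from the candidates, not from the full
    feature list, so the model stays small even when the feature space is
    huge.  Ties in count break by canonical feature order; zero-count
    features are never returned.
    """
    if len(freq.feature_ids) == 0:
        raise ValueError("empty frequency table")
    n_candidates = int(np.count_nonzero(freq.counts))
    if n_candidates == 0:
        return []
    n_top = math.ceil(top_pct * n_candidates)
    order = np.lexsort((np.arange(len(freq.counts)), -freq.counts))
    picked = [i for i in order[:n_top] if freq.counts[i] > 0]
    return [freq.feature_ids[i] for i in picked]


def demographic_screen(table: FeatureTable) -> dict[str, float]:
    """Folded AUC of the demographic covariates (age, sex) on their own."""
    out: dict[str, float] = {}
    if table.age is not None:
        out["age"] = feature_auc(table.age, table.labels)
    if table.sex is not None:
        out["sex"] = feature_auc(np.asarray(table.sex, dtype=float), table.labels)
    return out


# ---------------------------------------------------------------------------
# I/O


def write_selection_report(
    path, cfg: SelectionConfig, freq: FrequencyTable, predictive: list[str],
    demographics: dict[str, float] | None = None,
) -> None:
    import json

    payload = dict(
        config=dict(
            ci_level=cfg.ci_level, top_pct=cfg.top_pct,
            n_repetitions=cfg.n_repetitions, k_inner=cfg.k_inner,
            seed=cfg.seed, fold_auc=cfg.fold_auc,
        ),
        total_draws=freq.total_draws,
        counts={fid: int(c) for fid, c in zip(freq.feature_ids, freq.counts) if c > 0},
        predictive_features=predictive,
        demographic_auc=demographics or {},
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_ranked_tsv(path, freq: FrequencyTable) -> None:
    df = freq.as_frame().sort_values(["count", "feature_id"], ascending=[False, True])
    df.to_csv(path, sep="\t", index=False)


def build_feature_table(
    feature_df: pd.DataFrame, labels_by_subject: dict[str, int],
    ages: dict[str, float] | None = None, sexes: dict[str, int] | None = None,
) -> FeatureTable:
    """Assemble a FeatureTable from a subject-indexed feature frame."""
    ids = list(feature_df.index)
    return FeatureTable(
        X=feature_df.to_numpy(dtype=float),
        feature_ids=list(feature_df.columns),
        labels=np.array([labels_by_subject[s] for s in ids]),
        subject_ids=ids,
        age=None if ages is None else np.array([ages[s] for s in ids]),
        sex=None if sexes is None else np.array([sexes[s] for s in ids]),
    )
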