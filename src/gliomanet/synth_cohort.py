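"""Synthetic resting-state cohorts with planted connectivity group differences.

The generator emulates the statistical structure the downstream analysis
assumes: two diagnostic classes (low-grade vs high-grade glioma, LGG/HGG)
whose parcellated node time series are draws from zero-mean multivariate
normals that differ on a configurable *planted* subset of inter-node
correlations, plus class-specific age distributions.  Ground truth (the
planted edge set and both group covariance matrices) is carried along so
that feature-recovery and classifier-calibration tests have an oracle.

No scanner physics, hemodynamics or tumor mass effect is simulated — the
time series are stationary Gaussian processes on the correlation structure.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.correlation_tools import corr_nearest

GROUP_LGG = "LGG"
GROUP_HGG = "HGG"

#: minimum eigenvalue for a covariance to count as positive definite
_PD_TOL = 1e-8

# Adult glioma cohort: ages are truncated below at 18 years.
ADULT_AGE_FLOOR = 18.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic hemisphere cohort.

    Defaults mirror the left-hemisphere (LH) group of the motivating
    acquisition: 123 parcels per hemisphere, 230 retained volumes at
    TR = 2 s (240 acquired minus 10 discarded), LGG/HGG age distributions
    and sex ratios as observed clinically.

    ``effect_size`` is the correlation shift applied to each planted edge in
    the HGG group (sign per edge via ``planted_signs``, default all +).  It
    is a free simulation parameter, not an estimate of any clinical effect;
    use :func:`effect_size_for_separation` to target a given per-edge
    two-sample separation of the downstream Fisher-Z features.
    """

    n_lgg: int
    n_hgg: int
    n_nodes: int = 123
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    hemisphere: str = "LH"
    age_lgg: tuple[float, float] = (38.54, 10.88)
    age_hgg: tuple[float, float] = (45.06, 13.21)
    male_frac_lgg: float = 20 / 36
    male_frac_hgg: float = 28 / 44
    planted_edges: tuple[tuple[int, int], ...] = ()
    planted_signs: tuple[int, ...] | None = None
    effect_size: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lgg < 2 or self.n_hgg < 2:
            raise ValueError("each class needs at least 2 subjects")
        if self.n_nodes < 2 or self.n_timepoints < 3:
            raise ValueError("need n_nodes >= 2 and n_timepoints >= 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative (use planted_signs for direction)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        norm_edges = []
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) is a self-loop")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"planted edge ({i},{j}) out of range for {self.n_nodes} nodes")
            norm_edges.append((min(i, j), max(i, j)))
        if len(set(norm_edges)) != len(norm_edges):
            raise ValueError("planted_edges contains duplicate unordered pairs")
        object.__setattr__(self, "planted_edges", tuple(norm_edges))
        if self.planted_signs is not None:
            if len(self.planted_signs) != len(self.planted_edges):
                raise ValueError("planted_signs must match planted_edges in length")
            if any(s not in (-1, 1) for s in self.planted_signs):
                raise ValueError("planted_signs entries must be +1 or -1")

    @property
    def n_subjects(self) -> int:
        return self.n_lgg + self.n_hgg

    @property
    def signs(self) -> tuple[int, ...]:
        if self.planted_signs is None:
            return tuple(1 for _ in self.planted_edges)
        return self.planted_signs


@dataclass
class Subject:
    """One participant: metadata plus the node-by-time series matrix."""

    id: str
    group: str
    hemisphere: str
    age: float
    sex: str
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in (GROUP_LGG, GROUP_HGG):
            raise ValueError(f"unknown group {self.group!r}")
        if self.hemisphere not in ("LH", "RH"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not np.all(np.isfinite(self.timeseries)):
            raise ValueError(f"subject {self.id}: non-finite time series entries")

    @property
    def label(self) -> int:
        """Binary class label: LGG=0, HGG=1."""
        return 0 if self.group == GROUP_LGG else 1


@dataclass
class GroundTruth:
    planted_edges: tuple[tuple[int, int], ...]
    signs: tuple[int, ...]
    effect_size: float
    cov_lgg: np.ndarray
    cov_hgg: np.ndarray
    seed: int


@dataclass
class Cohort:
    subjects: list[Subject]
    spec: CohortSpec
    ground_truth: GroundTruth

    def __post_init__(self) -> None:
        n_lgg = sum(1 for s in self.subjects if s.group == GROUP_LGG)
        n_hgg = sum(1 for s in self.subjects if s.group == GROUP_HGG)
        if (n_lgg, n_hgg) != (self.spec.n_lgg, self.spec.n_hgg):
            raise ValueError("cohort class counts do not match the spec")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=np.int64)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)


def _check_pd(mat: np.ndarray) -> float:
    """Smallest eigenvalue of a symmetric matrix."""
    return float(np.linalg.eigvalsh(mat)[0])


def build_group_covariances(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Construct the two group correlation matrices.

    The LGG matrix is the identity (uncorrelated background); the HGG matrix
    shifts each planted edge by ``sign * effect_size``.  If the shifted
    matrix is not positive definite it is re-projected to the nearest
    positive-definite correlation matrix (Higham alternating projection);
    failure after projection rejects the spec, naming the offending edges.
    """
    n = spec.n_nodes
    cov_lgg = np.eye(n)
    cov_hgg = np.eye(n)
    for (i, j), s in zip(spec.planted_edges, spec.signs):
        val = s * spec.effect_size
        if abs(val) >= 1.0:
            raise ValueError(
                f"planted correlation {val:+.3f} at edge ({i},{j}) is outside (-1, 1)"
            )
        cov_hgg[i, j] = cov_hgg[j, i] = val
    if _check_pd(cov_hgg) <= _PD_TOL:
        cov_hgg = corr_nearest(cov_hgg, threshold=1e-8, n_fact=200)
        cov_hgg = (cov_hgg + cov_hgg.T) / 2.0
        if _check_pd(cov_hgg) <= 0:
            raise ValueError(
                "group covariance not positive definite even after projection; "
                f"offending planted edges: {list(spec.planted_edges)}"
            )
    return cov_lgg, cov_hgg


def sample_subject_timeseries(cov: np.ndarray, n_timepoints: int, seed: int) -> np.ndarray:
    """Draw a [n_nodes x n_timepoints] matrix from N(0, cov), reproducibly."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue {_check_pd(cov):.3e})"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((cov.shape[0], n_timepoints))
    return chol @ z


def synth_motion_params(
    n_timepoints: int, seed: int, amplitude: float = 0.05
) -> np.ndarray:
    """Six smooth low-amplitude random-walk nuisance series (shape 6 x T).

    Emulates rigid-body head-motion estimates (3 translations, 3 rotations)
    well enough to exercise nuisance regression; units are arbitrary.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((6, n_timepoints)) / math.sqrt(n_timepoints)
    walk = np.cumsum(steps, axis=1)
    # light smoothing keeps the walks slow, like real motion drift
    kernel = np.array([0.25, 0.5, 0.25])
    smooth = np.apply_along_axis(
        lambda r: np.convolve(np.pad(r, 1, mode="edge"), kernel, mode="valid"), 1, walk
    )
    return amplitude * smooth


def _truncated_ages(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    a = (ADULT_AGE_FLOOR - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _sexes(n: int, male_frac: float) -> list[str]:
    n_male = int(round(male_frac * n))
    return ["M"] * n_male + ["F"] * (n - n_male)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: a pure function of the spec (incl. seed)."""
    cov_lgg, cov_hgg = build_group_covariances(spec)
    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    plan = [
        (GROUP_LGG, spec.n_lgg, spec.age_lgg, spec.male_frac_lgg, cov_lgg),
        (GROUP_HGG, spec.n_hgg, spec.age_hgg, spec.male_frac_hgg, cov_hgg),
    ]
    for group, n, (age_mu, age_sd), male_frac, cov in plan:
        ages = _truncated_ages(rng, age_mu, age_sd, n)
        sexes = _sexes(n, male_frac)
        for k in range(n):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            ts = sample_subject_timeseries(cov, spec.n_timepoints, sub_seed)
            if spec.noise_sd > 0:
                noise_rng = np.random.default_rng(sub_seed + 1)
                ts = ts + spec.noise_sd * noise_rng.standard_normal(ts.shape)
            subjects.append(
                Subject(
                    id=f"sub-{spec.hemisphere}{group}{k:03d}",
                    group=group,
                    hemisphere=spec.hemisphere,
                    age=float(ages[k]),
                    sex=sexes[k],
                    timeseries=ts,
                )
            )
    gt = GroundTruth(
        planted_edges=spec.planted_edges,
        signs=spec.signs,
        effect_size=spec.effect_size,
        cov_lgg=cov_lgg,
        cov_hgg=cov_hgg,
        seed=spec.seed,
    )
    return Cohort(subjects=subjects, spec=spec, ground_truth=gt)


def effect_size_for_separation(
    separation: float,
    n_timepoints: int = 230,
    tr_seconds: float = 2.0,
    band: tuple[float, float] | None = (0.01, 0.08),
) -> float:
    """Correlation shift giving a target two-sample separation of Z features.

    The per-edge Fisher-Z feature of a null edge has SD ~ 1/sqrt(dof - 3),
    where dof is the effective number of independent samples after the
    cleaning band-pass: an ideal filter keeping m positive-frequency bins
    leaves ~2m real degrees of freedom.  The planted edge shifts the Z mean
    by atanh(effect_size), so a separation of ``separation`` SDs needs
    effect_size = tanh(separation / sqrt(dof - 3)).
    """
    if band is None:
        dof = n_timepoints
    else:
        freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
        kept = np.sum((freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12))
        dof = 2 * int(kept)
    if dof <= 3:
        raise ValueError("too few effective degrees of freedom in the pass band")
    return float(np.tanh(separation / math.sqrt(dof - 3)))


def lh_cohort_spec(**overrides) -> CohortSpec:
    """Left-hemisphere-group defaults: 36 LGG / 44 HGG, LH demographics."""
    base = dict(
        n_lgg=36,
        n_hgg=44,
        hemisphere="LH",
        age_lgg=(38.54, 10.88),
        age_hgg=(45.06, 13.21),
        male_frac_lgg=20 / 36,
        male_frac_hgg=28 / 44,
    )
    base.update(overrides)
    return CohortSpec(**base)


def rh_cohort_spec(**overrides) -> CohortSpec:
    """Right-hemisphere-group defaults: 32 LGG / 14 HGG, RH demographics."""
    base = dict(
        n_lgg=32,
        n_hgg=14,
        hemisphere="RH",
        age_lgg=(39.48, 10.46),
        age_hgg=(51.25, 17.81),
        male_frac_lgg=16 / 32,
        male_frac_hgg=8 / 14,
    )
    base.update(overrides)
    return CohortSpec(**base)


# ---------------------------------------------------------------------------
# I/O: one TSV per subject + manifest CSV + ground-truth JSON


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        ts_path = ts_dir / f"{sub.id}.tsv"
        np.savetxt(ts_path, sub.timeseries, delimiter="\t", fmt="%.10g")
        rows.append(
            dict(
                id=sub.id,
                group=sub.group,
                hemisphere=sub.hemisphere,
                age=sub.age,
                sex=sub.sex,
                timeseries_path=str(ts_path.relative_to(out)),
            )
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    gt = cohort.ground_truth
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            dict(
                planted_edges=[list(e) for e in gt.planted_edges],
                signs=list(gt.signs),
                effect_size=gt.effect_size,
                seed=gt.seed,
            ),
            fh,
            indent=2,
        )
    return manifest


def read_cohort_manifest(manifest_path: str | Path) -> list[Subject]:
    """Load subjects from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    subjects = []
    for row in df.itertuples(index=False):
        ts = np.loadtxt(manifest_path.parent / row.timeseries_path, delimiter="\t")
        subjects.append(
            Subject(
                id=str(row.id),
                group=str(row.group),
                hemisphere=str(row.hemisphere),
                age=float(row.age),
                sex=str(row.sex),
                timeseries=np.atleast_2d(ts),
            )
        )
    return subjects
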