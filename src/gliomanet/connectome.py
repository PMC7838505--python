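"""Time-series cleaning and Fisher-Z functional-connectivity construction.

Cleaning follows the standard resting-state recipe for already-parcellated
node signals: removal of the per-node linear trend, ordinary-least-squares
regression of nuisance variables (Friston-24 motion expansion plus any
extra regressors), and ideal (rectangular FFT) band-pass filtering in the
low-frequency band 0.01-0.08 Hz.  A hemisphere of N parcels then yields an
N x N symmetric matrix of Fisher-Z-transformed Pearson correlations, whose
upper triangle (N(N-1)/2 edges; 7,503 for the 123-parcel hemisphere) is the
per-subject functional-connectivity feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

#: correlations are clipped to |r| <= 1 - R_CLIP before atanh
R_CLIP = 1e-7


@dataclass
class FCMatrix:
    """Symmetric Fisher-Z connectivity matrix with zero diagonal."""

    values: np.ndarray
    node_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("FC matrix is not symmetric to 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("FC matrix diagonal must be exactly 0")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle FC values in canonical row-major (i < j) order."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.edge_index):
            raise ValueError("values and edge_index length mismatch")


def default_node_labels(n: int) -> list[str]:
    return [f"node{i:03d}" for i in range(n)]


def edge_feature_ids(n_nodes: int) -> list[str]:
    """Canonical FC feature ids 'i_j' in row-major upper-triangle order."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return [f"{i}_{j}" for i, j in zip(iu, ju)]


# ---------------------------------------------------------------------------
# Cleaning


def remove_linear_trend(ts: np.ndarray) -> np.ndarray:
    """Subtract the per-node least-squares line (intercept + slope * t)."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[-1] < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    return sp_signal.detrend(ts, axis=-1, type="linear")


def friston24_expand(motion: np.ndarray) -> np.ndarray:
    """Expand 6 motion parameters into the 24-regressor Friston set.

    For each parameter m: [m(t), m(t-1), m(t)^2, m(t-1)^2], with the lag-1
    series zero-padded at t = 0.  Rows are grouped per parameter.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError(f"expected a 6 x T motion matrix, got shape {motion.shape}")
    lag = np.zeros_like(motion)
    lag[:, 1:] = motion[:, :-1]
    rows = []
    for p in range(6):
        rows.extend([motion[p], lag[p], motion[p] ** 2, lag[p] ** 2])
    return np.vstack(rows)


def regress_nuisance(ts: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Replace each node series by its OLS residual against [1; regressors]."""
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[-1]
    if regressors is None or np.size(regressors) == 0:
        return ts - ts.mean(axis=-1, keepdims=True)
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    K = regressors.shape[0]
    if K >= T:
        raise ValueError(f"{K} regressors for {T} timepoints: design is overdetermined")
    design = np.vstack([np.ones(T), regressors]).T  # T x (K+1)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name collinear rows: those whose removal restores full column rank
        bad = [
            k
            for k in range(K)
            if np.linalg.matrix_rank(np.delete(design, k + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient nuisance design; collinear regressor rows: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return ts - (design @ beta).T


def bandpass_filter(ts: np.ndarray, tr: float, low: float, high: float) -> np.ndarray:
    """Ideal rectangular FFT band-pass: zero all bins outside [low, high] Hz."""
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist {nyquist} Hz")
    T = ts.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    spec = np.fft.rfft(ts, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


@dataclass(frozen=True)
class CleaningConfig:
    """Which cleaning steps to run, in the fixed order detrend -> nuisance -> band-pass."""

    detrend: bool = True
    band: tuple[float, float] | None = (0.01, 0.08)
    use_friston24: bool = True


def clean_timeseries(
    ts: np.ndarray,
    tr: float,
    motion: np.ndarray | None = None,
    extra_regressors: np.ndarray | None = None,
    config: CleaningConfig = CleaningConfig(),
) -> np.ndarray:
    """Composite cleaning: detrend, nuisance regression, band-pass."""
    out = np.asarray(ts, dtype=float)
    if config.detrend:
        out = remove_linear_trend(out)
    regs = []
    if motion is not None and config.use_friston24:
        regs.append(friston24_expand(motion))
    elif motion is not None:
        regs.append(np.atleast_2d(motion))
    if extra_regressors is not None and np.size(extra_regressors):
        regs.append(np.atleast_2d(extra_regressors))
    if regs:
        out = regress_nuisance(out, np.vstack(regs))
    if config.band is not None:
        out = bandpass_filter(out, tr, config.band[0], config.band[1])
    return out


# ---------------------------------------------------------------------------
# Connectivity


def pearson_fc(
    ts: np.ndarray,
    node_labels: Sequence[str] | None = None,
    subject_id: str = "",
) -> FCMatrix:
    """Pearson correlations between node series, Fisher-Z transformed.

    Correlations are clipped to |r| <= 1 - 1e-7 before atanh so perfectly
    (anti)correlated pairs map to a large finite Z (~8.06) rather than
    infinity; the diagonal is fixed at 0 (self-connections are not features).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a 2-D [nodes x timepoints] matrix with T >= 3")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node series at indices {dead.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    labels = list(node_labels) if node_labels is not None else default_node_labels(ts.shape[0])
    return FCMatrix(values=z, node_labels=labels, subject_id=subject_id)


def vectorize_edges(fc: FCMatrix) -> EdgeVector:
    """Flatten the upper triangle in row-major order (invertible)."""
    n = fc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    return EdgeVector(values=fc.values[iu, ju].copy(), edge_index=list(zip(iu.tolist(), ju.tolist())))


def devectorize_edges(ev: EdgeVector, n_nodes: int, node_labels: Sequence[str] | None = None,
                      subject_id: str = "") -> FCMatrix:
    """Inverse of :func:`vectorize_edges`."""
    expected = n_nodes * (n_nodes - 1) // 2
    if len(ev.values) != expected:
        raise ValueError(f"edge vector length {len(ev.values)} != N(N-1)/2 = {expected}")
    mat = np.zeros((n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    mat[iu, ju] = ev.values
    mat = mat + mat.T
    labels = list(node_labels) if node_labels is not None else default_node_labels(n_nodes)
    return FCMatrix(values=mat, node_labels=labels, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Cohort-level helpers and I/O


def cohort_fc_matrices(
    subjects,
    tr: float,
    config: CleaningConfig = CleaningConfig(),
    motions: dict[str, np.ndarray] | None = None,
) -> list[FCMatrix]:
    """FC matrix per subject after cleaning (order preserved)."""
    out = []
    for sub in subjects:
        motion = motions.get(sub.id) if motions else None
        cleaned = clean_timeseries(sub.timeseries, tr, motion=motion, config=config)
        out.append(pearson_fc(cleaned, subject_id=sub.id))
    return out


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.values, columns=fc.node_labels).to_csv(path, sep="\t", index=False)


def read_fc_matrix(path: str | Path, subject_id: str = "") -> FCMatrix:
    df = pd.read_csv(path, sep="\t")
    return FCMatrix(values=df.to_numpy(dtype=float), node_labels=list(df.columns),
                    subject_id=subject_id)


def write_edge_feature_csv(fcs: Sequence[FCMatrix], path: str | Path) -> None:
    """One row per subject: subject_id then edge columns 'i_j'."""
    if not fcs:
        raise ValueError("no FC matrices to write")
    ids = edge_feature_ids(fcs[0].n_nodes)
    rows = {fc.subject_id: vectorize_edges(fc).values for fc in fcs}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    df.index.name = "subject_id"
    df.to_csv(path)
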