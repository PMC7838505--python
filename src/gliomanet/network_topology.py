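"""Graph-theoretical network metrics integrated over the sparsity range.

A weighted Fisher-Z connectivity matrix is thresholded into binary
undirected graphs across a grid of sparsities (default 0.01..0.34, step
0.01, i.e. the strongest 1%..34% of possible edges).  At each sparsity the
module computes the standard small-world battery — clustering coefficient
Cp, characteristic path length Lp, global/local efficiency Eg/Eloc, and the
normalized ratios gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma =
gamma/lambda against degree-preserving (Maslov-Sneppen) random nulls — plus
four nodal metrics: betweenness centrality Bc (unnormalized, Brandes),
degree centrality Dc, nodal global efficiency NEg and nodal local
efficiency NEloc.  Each metric's curve over sparsity is then collapsed to a
single threshold-free value by trapezoidal integration ("AUC over
sparsity"), yielding 7 global and 4N nodal features per subject.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import FCMatrix

GLOBAL_METRIC_NAMES = ("aGamma", "aLambda", "aSigma", "aCp", "aLp", "aEg", "aEloc")
NODAL_METRIC_NAMES = ("aBc", "aDc", "aNEg", "aNEloc")

DEFAULT_SPARSITIES = tuple(round(k / 100, 2) for k in range(1, 35))


@dataclass
class BinaryGraph:
    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity must lie in (0, 1)")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class MetricCurve:
    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sparsities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("sparsities and values must be matching 1-D arrays")
        if s.size >= 2 and np.any(np.diff(s) <= 0):
            raise ValueError("sparsities must be strictly increasing")
        self.sparsities, self.values = s, v


@dataclass
class TopologyProfile:
    """AUC-integrated global (7) and nodal (4 x N) topology features."""

    global_values: dict[str, float]
    nodal_values: dict[str, np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if set(self.global_values) != set(GLOBAL_METRIC_NAMES):
            raise ValueError("expected exactly the 7 global metrics")
        if set(self.nodal_values) != set(NODAL_METRIC_NAMES):
            raise ValueError("expected exactly the 4 nodal metric vectors")
        if not all(np.isfinite(v) for v in self.global_values.values()):
            raise ValueError("non-finite global metric value")
        for name, vec in self.nodal_values.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite entries in {name}")
        if np.any(self.nodal_values["aDc"] < 0):
            raise ValueError("aDc entries must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.nodal_values["aDc"])

    def feature_ids(self) -> list[str]:
        ids = list(GLOBAL_METRIC_NAMES)
        for name in NODAL_METRIC_NAMES:
            ids.extend(f"{name}_{i}" for i in range(self.n_nodes))
        return ids

    def feature_vector(self) -> np.ndarray:
        parts = [np.array([self.global_values[k] for k in GLOBAL_METRIC_NAMES])]
        parts.extend(self.nodal_values[k] for k in NODAL_METRIC_NAMES)
        return np.concatenate(parts)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def binarize_at_sparsity(fc: FCMatrix, sparsity: float) -> BinaryGraph:
    """Keep the E = round(s * N(N-1)/2) strongest (signed) edges.

    Ranking is on signed Z — strongest positive first — so negative edges
    enter only once all positive edges are used; ties break by (i, j)
    lexicographic order for bit-exact reproducibility.
    """
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must lie in (0, 1)")
    n = fc.n_nodes
    m = n * (n - 1) // 2
    n_edges = _round_half_away(sparsity * m)
    if n_edges == 0:
        raise ValueError(f"sparsity {sparsity} keeps zero edges on {n} nodes")
    iu, ju = np.triu_indices(n, k=1)
    w = fc.values[iu, ju]
    order = np.lexsort((ju, iu, -w))[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj += adj.T
    return BinaryGraph(adjacency=adj, sparsity=sparsity)


# ---------------------------------------------------------------------------
# Metrics


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", directed=False, unweighted=True)


def _pair_efficiency(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    triangles = np.diag(a @ a @ a) / 2.0
    k = adj.sum(axis=0).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * triangles / denom
    c[denom <= 0] = 0.0
    return c


def _subgraph_efficiency(adj: np.ndarray, nodes: np.ndarray) -> float:
    """Global efficiency of the induced subgraph (0 for < 2 nodes)."""
    k = nodes.size
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nodes, nodes)]
    inv = _pair_efficiency(_distances(sub))
    return float(inv.sum() / (k * (k - 1)))


def _nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = _subgraph_efficiency(adj, np.flatnonzero(adj[i]))
    return out


def global_metrics(g: BinaryGraph) -> dict:
    """Cp, Lp, Eg, Eloc (plus a flag when the graph is disconnected).

    Lp averages shortest-path lengths over connected ordered pairs only;
    Eg counts unreachable pairs as efficiency 0.
    """
    adj = np.asarray(g.adjacency, dtype=np.int8)
    n = g.n_nodes
    if g.n_edges == 0:
        return dict(Cp=0.0, Lp=0.0, Eg=0.0, Eloc=0.0, disconnected=True)
    dist = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    disconnected = bool(finite.sum() < off.sum())
    lp = float(dist[finite].mean()) if finite.any() else 0.0
    inv = _pair_efficiency(dist)
    eg = float(inv.sum() / (n * (n - 1)))
    neloc = _nodal_local_efficiency(adj)
    return dict(
        Cp=float(_clustering(adj).mean()),
        Lp=lp,
        Eg=eg,
        Eloc=float(neloc.mean()),
        disconnected=disconnected,
    )


def nodal_metrics(g: BinaryGraph) -> dict:
    """Per-node Bc (unnormalized Brandes), Dc, NEg, NEloc."""
    adj = np.asarray(g.adjacency, dtype=np.int8)
    n = g.n_nodes
    G = nx.from_numpy_array(adj)
    bc_map = nx.betweenness_centrality(G, normalized=False)
    bc = np.array([bc_map[i] for i in range(n)])
    dc = adj.sum(axis=0).astype(float)
    inv = _pair_efficiency(_distances(adj))
    neg = inv.sum(axis=1) / (n - 1)
    neloc = _nodal_local_efficiency(adj)
    return dict(Bc=bc, Dc=dc, NEg=neg, NEloc=neloc)


def degree_preserving_null(g: BinaryGraph, n_swaps: int, seed: int) -> BinaryGraph:
    """Maslov-Sneppen double-edge-swap randomization (degree sequence kept)."""
    if n_swaps <= 0 or g.n_edges < 2:
        return BinaryGraph(adjacency=g.adjacency.copy(), sparsity=g.sparsity)
    G = nx.from_numpy_array(g.adjacency)
    try:
        nx.double_edge_swap(G, nswap=n_swaps, max_tries=100 * n_swaps + 100, seed=seed)
    except nx.NetworkXAlgorithmError:
        pass  # exhausted proposals (e.g. rigid graphs like complete graphs)
    adj = nx.to_numpy_array(G, nodelist=range(g.n_nodes), dtype=np.int8)
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def small_world_indices(
    g: BinaryGraph, n_null: int, seed: int, swap_factor: int = 10
) -> dict:
    """gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda.

    Averages run over ``n_null`` degree-preserving nulls (swap budget
    ``swap_factor`` proposals per edge).  When both numerator and null mean
    are zero the ratio is defined as 1 (the graph is exactly as clustered /
    as short as its null); a positive numerator over a zero null mean is
    undefined and returned as NaN for upstream imputation or rejection.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    base = global_metrics(g)
    rng = np.random.default_rng(seed)
    cps, lps = [], []
    for _ in range(n_null):
        null = degree_preserving_null(
            g, n_swaps=swap_factor * g.n_edges, seed=int(rng.integers(0, 2**31 - 1))
        )
        m = global_metrics(null)
        cps.append(m["Cp"])
        lps.append(m["Lp"])
    cp_null = float(np.mean(cps))
    lp_null = float(np.mean(lps))

    def _ratio(num: float, den: float) -> float:
        if den > 0:
            return num / den
        return 1.0 if num == 0 else float("nan")

    gamma = _ratio(base["Cp"], cp_null)
    lam = _ratio(base["Lp"], lp_null)
    sigma = gamma / lam if (np.isfinite(gamma) and np.isfinite(lam) and lam != 0) else float("nan")
    return dict(gamma=gamma, **{"lambda": lam}, sigma=sigma)


def auc_over_sparsity(curve: MetricCurve) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    if curve.sparsities.size < 2:
        raise ValueError("need at least 2 points to integrate")
    bad = np.flatnonzero(~np.isfinite(curve.values))
    if bad.size:
        levels = curve.sparsities[bad].tolist()
        raise ValueError(f"non-finite metric values at sparsities {levels}")
    return float(np.trapezoid(curve.values, curve.sparsities))


@dataclass(frozen=True)
class TopologyConfig:
    sparsities: tuple[float, ...] = DEFAULT_SPARSITIES
    n_null: int = 20
    swap_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sparsities) < 2:
            raise ValueError("need at least 2 sparsity levels")
        if np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsities must be strictly increasing")


def _interpolate_flagged(values: np.ndarray) -> np.ndarray:
    """Replace NaN curve points by nearest-finite interpolation along the grid."""
    v = values.copy()
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("metric curve has no finite points")
    idx = np.arange(v.size)
    v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v


def compute_topology_profile(fc: FCMatrix, config: TopologyConfig = TopologyConfig()) -> TopologyProfile:
    """Full threshold-integrated topology profile of one FC matrix.

    Deterministic given (fc, config): the per-sparsity null seeds are
    derived from config.seed and the sparsity level.
    """
    spars = np.asarray(config.sparsities, dtype=float)
    n = fc.n_nodes
    glob_curves = {k: [] for k in GLOBAL_METRIC_NAMES}
    nodal_curves = {k: [] for k in NODAL_METRIC_NAMES}
    for s_idx, s in enumerate(spars):
        g = binarize_at_sparsity(fc, float(s))
        gm = global_metrics(g)
        nm = nodal_metrics(g)
        sw = small_world_indices(
            g, n_null=config.n_null, seed=(config.seed * 1009 + s_idx) % (2**31 - 1),
            swap_factor=config.swap_factor,
        )
        glob_curves["aGamma"].append(sw["gamma"])
        glob_curves["aLambda"].append(sw["lambda"])
        glob_curves["aSigma"].append(sw["sigma"])
        glob_curves["aCp"].append(gm["Cp"])
        glob_curves["aLp"].append(gm["Lp"])
        glob_curves["aEg"].append(gm["Eg"])
        glob_curves["aEloc"].append(gm["Eloc"])
        nodal_curves["aBc"].append(nm["Bc"])
        nodal_curves["aDc"].append(nm["Dc"])
        nodal_curves["aNEg"].append(nm["NEg"])
        nodal_curves["aNEloc"].append(nm["NEloc"])
    global_values = {}
    for name, vals in glob_curves.items():
        v = _interpolate_flagged(np.asarray(vals, dtype=float))
        global_values[name] = auc_over_sparsity(MetricCurve(spars, v))
    nodal_values = {}
    for name, vals in nodal_curves.items():
        arr = np.asarray(vals, dtype=float)  # [n_sparsities x N]
        nodal_values[name] = np.array(
            [auc_over_sparsity(MetricCurve(spars, arr[:, i])) for i in range(n)]
        )
    return TopologyProfile(global_values=global_values, nodal_values=nodal_values,
                           subject_id=fc.subject_id)


def topology_feature_table(profiles) -> "pd.DataFrame":
    """Per-cohort TF feature frame: 7 global then 4N nodal columns."""
    import pandas as pd

    if not profiles:
        raise ValueError("no profiles")
    ids = profiles[0].feature_ids()
    data = {p.subject_id: p.feature_vector() for p in profiles}
    df = pd.DataFrame.from_dict(data, orient="index", columns=ids)
    df.index.name = "subject_id"
    return df
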