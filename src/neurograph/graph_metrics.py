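"""Binary-graph topology, degree-preserving null models, and AUC curves.

Global measures: global efficiency Eg, local efficiency Eloc, mean
clustering coefficient Cp, characteristic path length Lp, and their
null-normalized forms gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>,
sigma = gamma / lambda (small-worldness; sigma > 1 indicates small-world
organization).  Nodal measures: nodal efficiency Ne and degree centrality
Dc.  Null networks are Maslov-Sneppen double-edge-swap rewirings that
preserve the degree sequence exactly.

Distances are unweighted shortest paths (hops).  On disconnected graphs Lp
is the mean over finite-distance pairs, with the finite fraction reported
alongside; efficiency metrics handle disconnection natively (1/inf = 0).

Every metric curve can be integrated over a sparsity grid by the
trapezoidal rule, giving the threshold-free AUC summaries used for group
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network_construction import BinaryNetwork, ConnectivityMatrix, binarize_at_sparsity

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("Ne", "Dc")


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    connected_fraction: float
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None

    def as_dict(self) -> dict:
        d = {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "Eg": self.Eg,
            "Eloc": self.Eloc,
            "connected_fraction": self.connected_fraction,
        }
        if self.gamma is not None:
            d.update({"gamma": self.gamma, "lambda": self.lam, "sigma": self.sigma})
        return d


@dataclass(frozen=True)
class NullEnsembleConfig:
    """Maslov-Sneppen ensemble: 100 nulls, 10 attempted swaps per edge."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def validate_for_normalization(self) -> None:
        if self.n_nulls < 10:
            raise ValueError("need at least 10 nulls for normalization")


@dataclass
class MetricCurve:
    """Per-threshold global and nodal metrics plus their trapezoidal AUCs."""

    grid: np.ndarray
    global_curves: pd.DataFrame  # index threshold, columns metric names
    nodal_curves: dict[str, np.ndarray]  # metric -> (n_thresholds, n_nodes)
    auc: dict[str, float] = field(default_factory=dict)
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)
    entity_id: str | None = None


def _as_adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=bool)


def degree_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Dc_i = number of edges incident to node i."""
    return _as_adjacency(net).sum(axis=1).astype(float)


def clustering_coefficients(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """C_i = 2 t_i / (k_i (k_i - 1)); 0 for degree < 2."""
    a = _as_adjacency(net).astype(float)
    k = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def mean_clustering(net: BinaryNetwork | np.ndarray) -> float:
    return float(clustering_coefficients(net).mean())


def shortest_path_lengths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs hop distances (BFS); unreachable pairs are infinity."""
    a = _as_adjacency(net)
    if not a.any():
        d = np.full(a.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def characteristic_path_length(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> tuple[float, float]:
    """(Lp, connected_fraction): mean finite off-diagonal distance and the
    share of node pairs at finite distance."""
    d = shortest_path_lengths(net) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_off = n * (n - 1)
    if not finite.any():
        raise ValueError("no finite-distance pairs; Lp undefined on an empty graph")
    return float(d[finite].mean()), float(finite.sum() / n_off)


def global_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Eg = mean over ordered pairs of 1/d(i,j), with 1/inf = 0."""
    d = shortest_path_lengths(net) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off, 1.0 / d, 0.0)
    return float(inv[off].mean())


def nodal_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> np.ndarray:
    """Ne_i = mean over j != i of 1/d(i,j)."""
    d = shortest_path_lengths(net) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off, 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's neighbor subgraph."""
    a = _as_adjacency(net)
    n = a.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        eff[i] = global_efficiency(sub)
    return float(eff.mean())


def global_metrics(net: BinaryNetwork | np.ndarray) -> GlobalMetrics:
    """Raw (un-normalized) global measures of one binary network."""
    d = shortest_path_lengths(net)
    lp, cf = characteristic_path_length(net, d)
    return GlobalMetrics(
        Cp=mean_clustering(net),
        Lp=lp,
        Eg=global_efficiency(net, d),
        Eloc=local_efficiency(net),
        connected_fraction=cf,
    )


@njit(cache=False)
def _rewire_kernel(adj: np.ndarray, edges: np.ndarray, n_attempts: int, seed: int) -> int:
    """Maslov-Sneppen double-edge swaps in place; returns successful swap count."""
    np.random.seed(seed)
    m = edges.shape[0]
    n_ok = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c  # c/d may have been flipped above
        edges[e2, 1] = b
        n_ok += 1
    return n_ok


def rewire_null(
    net: BinaryNetwork | np.ndarray, cfg: NullEnsembleConfig
) -> list[np.ndarray]:
    """Degree-preserving rewired ensemble (boolean adjacency matrices).

    Each null starts from the observed network and applies
    ``swaps_per_edge * n_edges`` attempted double-edge swaps, rejecting any
    swap that would create a self-loop or a multi-edge.  The degree sequence
    is preserved exactly.  Seeded and deterministic.
    """
    a = _as_adjacency(net)
    iu, ju = np.triu_indices(a.shape[0], k=1)
    sel = a[iu, ju]
    base_edges = np.stack([iu[sel], ju[sel]], axis=1).astype(np.int64)
    m = base_edges.shape[0]
    if m < 2:
        warnings.warn("fewer than 2 edges: rewiring impossible, returning copies", stacklevel=2)
        return [a.copy() for _ in range(cfg.n_nulls)]
    n_attempts = cfg.swaps_per_edge * m
    # spawn one independent 32-bit seed per null from the ensemble seed
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_nulls)
    nulls = []
    total_ok = 0
    for s in seeds:
        adj = a.copy()
        edges = base_edges.copy()
        total_ok += _rewire_kernel(adj, edges, n_attempts, int(s % (2**31 - 1)))
        nulls.append(adj)
    if total_ok == 0:
        warnings.warn(
            "no swap was accepted in any null; graph is effectively unrewireable",
            stacklevel=2,
        )
    return nulls


def small_world(
    net: BinaryNetwork | np.ndarray, cfg: NullEnsembleConfig
) -> GlobalMetrics:
    """Global metrics plus gamma, lambda, sigma against the rewired ensemble."""
    cfg.validate_for_normalization()
    gm = global_metrics(net)
    null_cp = np.empty(cfg.n_nulls)
    null_lp = np.empty(cfg.n_nulls)
    for i, adj in enumerate(rewire_null(net, cfg)):
        null_cp[i] = mean_clustering(adj)
        null_lp[i], _ = characteristic_path_length(adj)
    mean_cp, mean_lp = null_cp.mean(), null_lp.mean()
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("null ensemble mean Cp or Lp is zero; normalization undefined")
    gm.gamma = gm.Cp / mean_cp
    gm.lam = gm.Lp / mean_lp
    gm.sigma = gm.gamma / gm.lam
    return gm


def auc_trapezoid(values: np.ndarray, grid: np.ndarray) -> float | np.ndarray:
    """Trapezoidal integral of a metric curve over the sparsity grid.

    For a constant curve c over [a, b] this is c * (b - a).  ``values`` may
    be (n_thresholds,) or (n_thresholds, n_nodes).
    """
    values = np.asarray(values, dtype=float)
    return np.trapezoid(values, x=np.asarray(grid, dtype=float), axis=0)


def metric_curves(
    cm: ConnectivityMatrix,
    grid: np.ndarray,
    null_cfg: NullEnsembleConfig | None = None,
    rank_absolute: bool = False,
) -> MetricCurve:
    """Binarize at every grid sparsity, compute all metrics, integrate AUCs.

    Null-normalized metrics (gamma/lambda/sigma) are computed when
    ``null_cfg`` is given; per-threshold null seeds derive from
    ``null_cfg.seed`` so the whole curve is reproducible.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array of >= 2 values")
    rows = []
    ne = np.empty((grid.size, cm.n_nodes))
    dc = np.empty((grid.size, cm.n_nodes))
    for t, s in enumerate(grid):
        try:
            net = binarize_at_sparsity(cm, s, rank_absolute=rank_absolute)
            if null_cfg is not None:
                cfg_t = NullEnsembleConfig(
                    n_nulls=null_cfg.n_nulls,
                    swaps_per_edge=null_cfg.swaps_per_edge,
                    seed=null_cfg.seed + t,
                )
                gm = small_world(net, cfg_t)
            else:
                gm = global_metrics(net)
            d = shortest_path_lengths(net)
            ne[t] = nodal_efficiency(net, d)
            dc[t] = degree_centrality(net)
        except ValueError as err:
            raise ValueError(f"metric computation failed at sparsity {s:.2f}: {err}") from err
        rows.append({"threshold": s, **gm.as_dict()})
    global_curves = pd.DataFrame(rows).set_index("threshold")
    auc = {c: float(auc_trapezoid(global_curves[c].to_numpy(), grid)) for c in global_curves}
    nodal = {"Ne": ne, "Dc": dc}
    nodal_auc = {k: np.asarray(auc_trapezoid(v, grid)) for k, v in nodal.items()}
    return MetricCurve(
        grid=grid,
        global_curves=global_curves,
        nodal_curves=nodal,
        auc=auc,
        nodal_auc=nodal_auc,
        entity_id=cm.entity_id,
    )
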