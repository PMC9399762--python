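"""Weighted association matrices and sparsity-threshold binarization.

Structural covariance networks are group-level: edge (i, j) is the Pearson
correlation of region-i and region-j kurtosis values across the subjects of
one group.  Functional networks are subject-level: Pearson correlation of
the two regions' time series, optionally Fisher-z transformed (the z
transform is strictly increasing, so the binarized network is identical
either way).

Binarization keeps the top floor(s * N(N-1)/2) positive weights at sparsity
s.  Negative correlations are excluded from edge candidacy by default
(binary small-world metrics assume positive connectivity); absolute-value
ranking is available via ``rank_absolute=True``.  Ties at the cutoff are
broken by ascending (i, j) node index and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nodes import N_REGIONS
from .synthetic_cohort import RegionalChannelTable, RoiTimeSeries

FISHER_CLIP = 1.0 - 1e-7

STRUCTURAL_GRID = (0.06, 0.40)  # sparsity range for gray-matter networks
FUNCTIONAL_GRID = (0.10, 0.40)  # sparsity range for functional networks
GRID_STEP = 0.01


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted association matrix over the 90 AAL nodes."""

    weights: np.ndarray
    node_labels: list[str]
    kind: str  # "structural_group" | "functional_subject"
    channel: str | None = None
    entity_id: str | None = None  # group name or subject id
    fisher_z: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_labels), len(self.node_labels)):
            raise ValueError("weights shape does not match node labels")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric within 1e-12")
        np.fill_diagonal(w, 0.0)  # diagonal ignored by contract
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency at a stated sparsity, no self-loops."""

    adjacency: np.ndarray
    sparsity: float
    node_labels: list[str] = field(default_factory=list)
    tie_note: str | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _check_columns_nonconstant(values: np.ndarray, labels: list[str], what: str) -> None:
    sd = values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [labels[i] for i in bad[:5]]
        raise ValueError(f"constant {what} column(s): {names}")


def build_structural_network(table: RegionalChannelTable) -> ConnectivityMatrix:
    """Group-level structural covariance matrix (Pearson r across subjects)."""
    values = table.values.to_numpy(dtype=float)
    labels = list(table.values.columns)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects to correlate across individuals")
    _check_columns_nonconstant(values, labels, "region")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        weights=r,
        node_labels=labels,
        kind="structural_group",
        channel=table.channel,
        entity_id=table.group,
        fisher_z=False,
    )


def build_functional_network(
    ts: RoiTimeSeries,
    node_labels: list[str],
    apply_fisher: bool = True,
) -> ConnectivityMatrix:
    """Subject-level functional connectivity (Pearson r over time, optional Fisher z)."""
    x = ts.series
    _check_columns_nonconstant(x, node_labels, "region time-series")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if apply_fisher:
        if np.any(np.abs(r) >= FISHER_CLIP):
            warnings.warn(
                f"|r| >= {FISHER_CLIP} encountered for subject {ts.subject_id}; "
                "clipped before Fisher z to keep atanh finite",
                stacklevel=2,
            )
        r = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
        np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        weights=r,
        node_labels=node_labels,
        kind="functional_subject",
        entity_id=ts.subject_id,
        fisher_z=apply_fisher,
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """z = atanh(r) with clipping at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def binarize_at_sparsity(
    cm: ConnectivityMatrix, sparsity: float, rank_absolute: bool = False
) -> BinaryNetwork:
    """Keep the top floor(sparsity * n_pairs) weights as undirected edges.

    Candidate edges are the strictly positive upper-triangle weights
    (absolute values when ``rank_absolute``).  Ranking ties at the cutoff
    are broken by ascending (i, j) lexicographic node order; any such tie
    is recorded in ``tie_note``.  If fewer candidates exist than requested,
    all of them are kept and a warning is issued.
    """
    if not (0 < sparsity <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = cm.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = cm.weights[iu, ju]
    rank_w = np.abs(w) if rank_absolute else w
    candidates = np.flatnonzero(rank_w > 0)
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(sparsity * n_pairs))
    tie_note = None
    if candidates.size < k:
        warnings.warn(
            f"only {candidates.size} positive weights available for "
            f"{k} requested edges at sparsity {sparsity:.2f}; keeping all",
            stacklevel=2,
        )
        keep = candidates
    else:
        # sort by descending weight, then ascending (i, j): lexsort keys are
        # least significant first
        order = np.lexsort((ju[candidates], iu[candidates], -rank_w[candidates]))
        ranked = candidates[order]
        keep = ranked[:k]
        if 0 < k < ranked.size and rank_w[ranked[k - 1]] == rank_w[ranked[k]]:
            w_cut = rank_w[ranked[k - 1]]
            n_tied = int(np.sum(rank_w[candidates] == w_cut))
            tie_note = (
                f"{n_tied} candidate edges tied at cutoff weight {w_cut:.6g}; "
                "kept by ascending (i, j) node order"
            )
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, sparsity=sparsity, node_labels=cm.node_labels, tie_note=tie_note
    )


def sparsity_grid(kind: str) -> np.ndarray:
    """Sparsity grids: 0.06-0.40 (structural) or 0.10-0.40 (functional), step 0.01."""
    if kind == "structural_group":
        lo, hi = STRUCTURAL_GRID
    elif kind == "functional_subject":
        lo, hi = FUNCTIONAL_GRID
    else:
        raise ValueError(f"unknown network kind: {kind!r}")
    # integer arithmetic avoids float accumulation over the grid
    return np.arange(round(lo * 100), round(hi * 100) + 1) / 100.0


def max_edges(n_nodes: int = N_REGIONS) -> int:
    return n_nodes * (n_nodes - 1) // 2
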