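"""Global efficiency of weighted directed brain graphs.

Each subject's connectivity matrix defines a weighted directed graph whose
edge weights are directed-influence magnitudes. Edges are mapped to lengths
by ℓ = 1/w (stronger influence = shorter path), shortest directed path
lengths d_ij come from Dijkstra's algorithm, and global efficiency is the
mean inverse shortest path length over ordered node pairs,

    GE = 1/(n(n−1)) · Σ_{i≠j} 1/d_ij,

with unreachable pairs contributing zero. Subnetwork efficiency applies the
same measure to the subgraph induced by one resting-state network's nodes;
paths may not detour through nodes outside the subnetwork.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .exceptions import ShapeError, UndefinedMetricError
from .parcellation import RSN_LABELS


def build_graph(matrix: np.ndarray) -> np.ndarray:
    """Validate a connectivity matrix as a weighted directed graph.

    Returns the weight array with self-loops removed; entry [i, j] is the
    weight of the directed edge i -> j.
    """
    w = np.asarray(matrix, dtype=float).copy()
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError("connectivity matrix must be square")
    if not np.all(np.isfinite(w)):
        raise ShapeError("connectivity matrix contains non-finite entries")
    if np.any(w < 0):
        raise ShapeError("edge weights must be nonnegative")
    np.fill_diagonal(w, 0.0)
    return w


def _inverse_shortest_paths(weights: np.ndarray) -> np.ndarray:
    """Matrix of 1/d_ij for the length mapping ℓ = 1/w (0 where unreachable)."""
    n = weights.shape[0]
    rows, cols = np.nonzero(weights)
    lengths = csr_matrix((1.0 / weights[rows, cols], (rows, cols)), shape=(n, n))
    d = dijkstra(lengths, directed=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(weights: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    w = build_graph(weights)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMetricError("global efficiency needs at least 2 nodes")
    inv = _inverse_shortest_paths(w)
    return float(inv.sum() / (n * (n - 1)))


def subnetwork_efficiency(
    weights: np.ndarray, parcellation: pd.DataFrame
) -> dict[str, float]:
    """Global efficiency of each RSN-induced subgraph, keyed by RSN label.

    The subgraph keeps only edges between that network's nodes, so shortest
    paths cannot leave the subnetwork.
    """
    w = build_graph(weights)
    if len(parcellation) != w.shape[0]:
        raise ShapeError("parcellation rows must match graph nodes")
    out: dict[str, float] = {}
    labels = np.asarray(parcellation["rsn_label"])
    present = [r for r in RSN_LABELS if r in labels]
    for rsn in present:
        idx = np.flatnonzero(labels == rsn)
        if idx.size < 2:
            raise UndefinedMetricError(
                f"RSN {rsn!r} has {idx.size} node(s); efficiency undefined"
            )
        out[rsn] = global_efficiency(w[np.ix_(idx, idx)])
    return out


def efficiency_report(
    subject_id: str, weights: np.ndarray, parcellation: pd.DataFrame | None = None
) -> dict:
    """Whole-brain plus per-RSN efficiency for one subject as a flat record
    (columns ge_whole, ge_visual, ..., ge_default_mode)."""
    record = {"subject_id": subject_id, "ge_whole": global_efficiency(weights)}
    if parcellation is not None:
        for rsn, value in subnetwork_efficiency(weights, parcellation).items():
            record[f"ge_{rsn}"] = value
    return record
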