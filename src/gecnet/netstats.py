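"""Graph statistics contrasting positive and negative effective connections.

Modularity uses Newman's spectral algorithm (leading-eigenvector
bipartitioning with Kernighan-Lin refinement, applied recursively through the
generalized modularity matrix); the clustering coefficient is the binary
topological form C_i = 2 t_i / (k_i (k_i - 1)).  Sign-class graphs are built
from the absolute weights of each sign separately, since Newman's quality
function assumes nonnegative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphPartition:
    """Community labels together with the modularity Q they achieve."""

    labels: np.ndarray
    q: float


@dataclass(frozen=True)
class SignedEdgeSummary:
    """Weight, length, modularity and clustering profiles of each sign class.

    Negative-side fields are ``None`` when the matrix has no negative edges.
    """

    fraction_negative: float
    mean_abs_weight_pos: float | None
    mean_abs_weight_neg: float | None
    mean_length_pos: float | None
    mean_length_neg: float | None
    modularity_pos: float | None
    modularity_neg: float | None
    clustering_pos: float | None
    clustering_neg: float | None


def _partition_q(adj: np.ndarray, labels: np.ndarray) -> float:
    k = adj.sum(axis=1)
    two_m = adj.sum()
    same = labels[:, None] == labels[None, :]
    return float(((adj - np.outer(k, k) / two_m) * same).sum() / two_m)


def _kl_refine(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement of a bipartition sign vector.

    Repeatedly sweeps: move each vertex exactly once in order of greatest
    gain, keep the best intermediate state; stop when a sweep no longer
    improves the objective s^T B s.
    """
    n = s.size
    best = s.copy()
    best_obj = best @ bg @ best
    improved = True
    while improved:
        improved = False
        s_work = best.copy()
        obj = best_obj
        moved = np.zeros(n, dtype=bool)
        trail = []
        for _ in range(n):
            # gain of flipping i: -4 s_i (B[i] @ s) + 4 B_ii
            gains = -4.0 * s_work * (bg @ s_work) + 4.0 * np.diag(bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            s_work[i] = -s_work[i]
            moved[i] = True
            obj = obj + gains[i]
            trail.append((obj, s_work.copy()))
        sweep_best_obj, sweep_best = max(trail, key=lambda t: t[0])
        if sweep_best_obj > best_obj + 1e-12:
            best_obj, best = sweep_best_obj, sweep_best
            improved = True
    return best


def _divide(bg: np.ndarray, nodes: np.ndarray, labels: np.ndarray,
            next_label: list[int], two_m: float) -> None:
    eigval, eigvec = np.linalg.eigh(bg)
    lead = eigvec[:, -1]
    if eigval[-1] <= 1e-12 or np.all(lead >= 0) or np.all(lead <= 0):
        return  # indivisible
    s = np.where(lead >= 0, 1.0, -1.0)
    s = _kl_refine(bg, s)
    delta_q = (s @ bg @ s) / (4.0 * two_m)
    if delta_q <= 1e-12 or np.all(s == s[0]):
        return
    for sign in (1.0, -1.0):
        group = np.nonzero(s == sign)[0]
        if sign == -1.0:
            next_label[0] += 1
            labels[nodes[group]] = next_label[0]
        sub = bg[np.ix_(group, group)].copy()
        sub[np.diag_indices_from(sub)] -= bg[group].sum(axis=1)
        _divide(sub, nodes[group], labels, next_label, two_m)


def modularity(adjacency: np.ndarray) -> GraphPartition:
    """Newman spectral community detection on a symmetric nonnegative matrix."""
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(adj < 0):
        raise ValueError("pass |weights| of one sign class; weights must be nonnegative")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    two_m = adj.sum()
    if two_m == 0.0:
        raise ValueError("empty graph")
    k = adj.sum(axis=1)
    b = adj - np.outer(k, k) / two_m
    n = adj.shape[0]
    labels = np.zeros(n, dtype=int)
    _divide(b, np.arange(n), labels, [0], two_m)
    # compact label ids
    _, labels = np.unique(labels, return_inverse=True)
    return GraphPartition(labels=labels, q=_partition_q(adj, labels))


def clustering_coefficient(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary clustering coefficient per node and its mean.

    Edges are binarized at nonzero; nodes of degree < 2 get C_i = 0.
    """
    adj = np.asarray(adjacency, dtype=float)
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    binary = (adj != 0.0).astype(float)
    np.fill_diagonal(binary, 0.0)
    g = nx.from_numpy_array(binary)
    per_node = np.array([nx.clustering(g, i) for i in range(binary.shape[0])])
    return per_node, float(per_node.mean())


def signed_edge_summary(gec, coords: np.ndarray | None = None) -> SignedEdgeSummary:
    """Split a fitted GEC by edge sign and profile each class.

    Accepts a :class:`~gecnet.gec.GECResults` or a raw matrix.  An asymmetric
    GEC is symmetrized by averaging before the graph statistics (logged).
    Lengths are Euclidean distances between region centroids.
    """
    from gecnet.gec import GECResults

    if isinstance(gec, GECResults):
        matrix, mask = gec.gec, gec.mask
    else:
        matrix = np.asarray(gec, dtype=float)
        mask = matrix != 0.0
        np.fill_diagonal(mask, False)
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        logger.info("symmetrizing an asymmetric GEC for graph statistics")
    sym = 0.5 * (matrix + matrix.T)
    sym_mask = mask | mask.T
    n_masked = int(np.count_nonzero(mask))
    if n_masked == 0:
        raise ValueError("empty mask")
    fraction_negative = float(np.count_nonzero(matrix[mask] < 0) / n_masked)

    dist = None
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))

    def _profile(sign: int):
        sel = sym_mask & ((sym > 0) if sign > 0 else (sym < 0))
        if not np.any(sel):
            return None, None, None, None
        weights = np.where(sel, np.abs(sym), 0.0)
        iu = np.triu_indices_from(sym, k=1)
        edge_sel = sel[iu]
        mean_w = float(np.abs(sym[iu][edge_sel]).mean())
        mean_len = float(dist[iu][edge_sel].mean()) if dist is not None else None
        try:
            q = modularity(weights).q
        except ValueError:
            q = None
        _, clust = clustering_coefficient(weights)
        return mean_w, mean_len, q, clust

    wp, lp, qp, cp = _profile(+1)
    wn, ln, qn, cn = _profile(-1)
    return SignedEdgeSummary(
        fraction_negative=fraction_negative,
        mean_abs_weight_pos=wp, mean_abs_weight_neg=wn,
        mean_length_pos=lp, mean_length_neg=ln,
        modularity_pos=qp, modularity_neg=qn,
        clustering_pos=cp, clustering_neg=cn,
    )
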