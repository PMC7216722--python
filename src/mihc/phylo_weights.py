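"""Phylogeny-derived OTU weights for the weighted higher criticism test.

OTUs are partitioned into phylogenetically close clusters by PAM
(k-medoids) on the cophenetic distance matrix, with the cluster count
chosen to maximize the average silhouette width (searched up to 30
clusters).  Within the cluster containing OTU j, the weight

    w_j = [ sum_{j' != j} |Z_{j'}| / D_{j,j'} ] / [ sum_{j' != j} 1 / D_{j,j'} ] + 1

is the inverse-distance-weighted mean of the neighbours' absolute score
statistics plus one, so OTUs whose close relatives carry strong signals
are up-weighted.  Clusters depend on the tree only; weights are
recomputed for every (permuted) Z vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

ZERO_DIST_FLOOR = 1e-10


@dataclass
class PhyloWeights:
    """Cluster assignment and weight machinery derived from a tree."""

    D: np.ndarray          # (m, m) cophenetic distances
    clusters: np.ndarray   # (m,) cluster labels 0..C-1
    C: int
    _M: np.ndarray = None  # row-normalized within-cluster 1/D matrix

    def __post_init__(self):
        if self._M is None:
            self._M = _weight_operator(self.clusters, self.D)

    def weights(self, Z: np.ndarray) -> np.ndarray:
        """Eq.-style weights for one Z vector or a batch (..., m) of them."""
        return np.abs(Z) @ self._M.T + 1.0


def cophenetic_matrix(tree, otu_ids=None) -> np.ndarray:
    """Pairwise path lengths between leaves (branch-length units).

    D[j, j'] is the total branch length from leaf j up to the most recent
    common ancestor and back down to leaf j'.  Computed in one postorder
    sweep: D[a, b] = depth(a) + depth(b) - 2 depth(mrca(a, b)).

    Parameters
    ----------
    tree : dendropy.Tree
    otu_ids : sequence of str, optional
        Row/column order; defaults to the tree's leaf order.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    if otu_ids is None:
        otu_ids = labels
    pos = {lab: i for i, lab in enumerate(otu_ids)}
    missing = [lab for lab in otu_ids if lab not in set(labels)]
    if missing:
        raise ValueError(f"tree is missing leaves: {missing}")
    m = len(otu_ids)
    D = np.zeros((m, m))

    # node depth from root
    depth = {}
    for nd in tree.preorder_node_iter():
        el = nd.edge.length or 0.0
        depth[nd] = (depth[nd.parent_node] + el) if nd.parent_node else 0.0

    leaf_depth = np.zeros(m)
    for lf in leaves:
        if lf.taxon.label in pos:
            leaf_depth[pos[lf.taxon.label]] = depth[lf]

    # postorder: merge child leaf-sets, filling cross-child blocks
    below = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            below[nd] = [pos[lab]] if lab in pos else []
            continue
        groups = [below.pop(ch) for ch in nd.child_nodes()]
        merged = []
        for gi, g in enumerate(groups):
            for h in groups[gi + 1:]:
                if g and h:
                    ia, ib = np.asarray(g), np.asarray(h)
                    val = leaf_depth[ia][:, None] + leaf_depth[ib][None, :] - 2.0 * depth[nd]
                    D[np.ix_(ia, ib)] = val
                    D[np.ix_(ib, ia)] = val.T
            merged.extend(g)
        below[nd] = merged
    return D


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: medoids minimizing total nearest distance."""
    m = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    d1 = D[:, first].copy()
    for _ in range(1, k):
        gain = np.maximum(d1[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        d1 = np.minimum(d1, D[:, nxt])
    return np.array(medoids)


def _pam_swap(D: np.ndarray, medoids: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """SWAP phase: exchange (medoid, non-medoid) pairs while cost drops.

    The cost change of every (medoid i, candidate h) pair is evaluated at
    once: for points owned by i the new service cost is min(D[., h], d2),
    for the rest it can only improve to min(D[., h], d1).
    """
    m = D.shape[0]
    medoids = medoids.copy()
    k = len(medoids)
    for _ in range(max_iter):
        dm = D[:, medoids]                     # (m, k)
        order = np.argsort(dm, axis=1)
        near = order[:, 0]
        d1 = dm[np.arange(m), near]
        d2 = dm[np.arange(m), order[:, 1]] if k > 1 else np.full(m, np.inf)
        T_keep = np.minimum(D - d1[:, None], 0.0)          # point not owned by i
        T_lose = np.minimum(D, d2[:, None]) - d1[:, None]  # point owned by i
        owns = np.zeros((m, k))
        owns[np.arange(m), near] = 1.0
        delta = owns.T @ (T_lose - T_keep) + T_keep.sum(axis=0)  # (k, m)
        delta[:, medoids] = np.inf
        i, h = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, h] >= -1e-12:
            break
        medoids[i] = int(h)
    return medoids


def pam(D: np.ndarray, k: int) -> np.ndarray:
    """k-medoids labels for a precomputed distance matrix (deterministic)."""
    medoids = _pam_swap(D, _pam_build(D, k))
    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)             # medoids own themselves
    return labels


def average_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width for a precomputed distance matrix.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to own
    cluster (excluding self) and b_i the smallest mean distance to any
    other cluster; points in singleton clusters score 0.
    """
    m = D.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    onehot = np.zeros((m, k))
    onehot[np.arange(m), inv] = 1.0
    counts = onehot.sum(axis=0)
    dsum = D @ onehot                              # (m, k)
    own = counts[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = dsum[np.arange(m), inv] / np.maximum(own - 1.0, 1.0)
        mean_other = dsum / counts[None, :]
        mean_other[np.arange(m), inv] = np.inf
        b = mean_other.min(axis=1)
        s = (b - a) / np.maximum(a, b)
    s[own == 1] = 0.0
    s[~np.isfinite(s)] = 0.0
    return float(s.mean())


def cluster_otus(D: np.ndarray, k_max: int = 30):
    """Select the cluster count maximizing average silhouette width.

    Searches k = 2 .. min(k_max, m-1); ties go to the smaller k.  With
    fewer than 3 OTUs the silhouette is undefined and all OTUs form one
    cluster.

    Returns
    -------
    (labels, C) : (ndarray of int, int)
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if m < 3:
        logger.info("m=%d < 3: single cluster (silhouette undefined)", m)
        return np.zeros(m, dtype=np.int64), 1
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(2, min(k_max, m - 1) + 1):
        labels = pam(D, k)
        if len(np.unique(labels)) < 2:
            continue
        sil = average_silhouette(D, labels)
        if sil > best_sil + 1e-12:             # ties break toward smaller k
            best_k, best_sil, best_labels = k, sil, labels
    return best_labels, best_k


def _weight_operator(clusters: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Row-normalized within-cluster inverse-distance matrix M.

    w = M |Z| + 1; rows of singleton clusters are all-zero, giving w = 1.
    """
    inv = 1.0 / np.maximum(D, ZERO_DIST_FLOOR)
    same = clusters[:, None] == clusters[None, :]
    np.fill_diagonal(same, False)
    M = np.where(same, inv, 0.0)
    rs = M.sum(axis=1, keepdims=True)
    return np.divide(M, rs, out=np.zeros_like(M), where=rs > 0)


def compute_weights(Z: np.ndarray, clusters: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Weights for one Z vector given fixed clusters and distances."""
    return np.abs(Z) @ _weight_operator(clusters, D).T + 1.0


def build_weights(tree=None, D=None, otu_ids=None, k_max: int = 30) -> PhyloWeights:
    """Cluster a tree (or a precomputed distance matrix) into a PhyloWeights."""
    if D is None:
        if tree is None:
            raise ValueError("need a tree or a distance matrix")
        D = cophenetic_matrix(tree, otu_ids)
    clusters, C = cluster_otus(D, k_max=k_max)
    logger.info("PAM/silhouette selected C=%d clusters", C)
    return PhyloWeights(D=D, clusters=clusters, C=C)
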