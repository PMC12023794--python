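"""Tree-derived distances, Brownian-motion covariance, and genome clustering.

The comparative analyses downstream of genome curation all consume one of two
tree-derived matrices: the cophenetic (patristic) distance matrix, used to
group genomes into taxa by hierarchical clustering, and the Brownian-motion
covariance matrix, used as the residual correlation structure of the
phylogenetic linear model.  For an ultrametric tree of height ``h`` the two are
linked by ``d(i, j) = 2 * (h - V[i, j])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "load_tree",
    "tip_labels",
    "cophenetic_distances",
    "bm_covariance",
    "hierarchical_cluster",
    "select_k",
    "ClusterAssignment",
    "KSelection",
]

VALID_LINKAGES = ("complete", "average", "single")


def load_tree(path: str) -> dendropy.Tree:
    """Read a rooted newick tree whose tips are genome ids."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    _check_tips(tree)
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _check_tips(tree: dendropy.Tree) -> list[str]:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return labels


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic distance matrix: sum of branch lengths on each tip-tip path."""
    labels = _check_tips(tree)
    if len(labels) < 2:
        raise ValueError("need at least 2 tips for a distance matrix")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
    return pd.DataFrame(d, index=labels, columns=labels)


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance: V[i, j] = depth of the MRCA of tips i and j.

    The diagonal holds root-to-tip depths; for an ultrametric tree the matrix
    satisfies ``cophenetic = 2 * (height - V)`` off the diagonal.
    """
    labels = _check_tips(tree)
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # node depths from the root; the root's own edge (if any) is ignored
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        elen = node.edge.length or 0.0
        depth[id(node)] = depth[id(node.parent_node)] + elen

    # tips below each node, accumulated postorder; cross-child pairs share
    # this node as their MRCA
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
            below[id(node)] = [i]
            continue
        kids = [below.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        V[i, j] = V[j, i] = d
        below[id(node)] = [i for k in kids for i in k]
    return pd.DataFrame(V, index=labels, columns=labels)


@dataclass
class ClusterAssignment:
    """Result of cutting a hierarchical clustering into ``k`` groups."""

    labels: pd.Series  # genome id -> 1..k
    k: int
    silhouettes: pd.Series
    mean_silhouette: float


@dataclass
class KSelection:
    k_best: int
    mean_silhouettes: dict[int, float] = field(default_factory=dict)
    gap: dict[int, float] = field(default_factory=dict)


def _as_square(dist: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ids = list(dist.index)
    if list(dist.columns) != ids:
        raise ValueError("distance matrix rows and columns disagree")
    d = np.asarray(dist, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    return d, ids


def hierarchical_cluster(
    dist: pd.DataFrame, k: int, linkage: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering of a distance matrix cut into ``k`` groups."""
    d, ids = _as_square(dist)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if linkage not in VALID_LINKAGES:
        raise ValueError(f"linkage must be one of {VALID_LINKAGES}")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = scipy_linkage(squareform(d, checks=False), method=linkage)
        raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    lab = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        lab[i] = remap.setdefault(c, len(remap) + 1)
    sil = _silhouettes(d, lab)
    return ClusterAssignment(
        labels=pd.Series(lab, index=ids, name="cluster"),
        k=int(lab.max()),
        silhouettes=pd.Series(sil, index=ids, name="silhouette"),
        mean_silhouette=float(np.mean(sil)),
    )


def _silhouettes(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouettes on a precomputed distance matrix.

    Singleton clusters score 0 (standard convention); k=1 and k=n are
    degenerate and score 0 everywhere.
    """
    k = len(np.unique(labels))
    n = len(labels)
    if k < 2 or k >= n:
        return np.zeros(n)
    return silhouette_samples(d, labels, metric="precomputed")


def select_k(
    dist: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    linkage: str = "complete",
    n_ref: int = 10,
    seed: int = 0,
) -> KSelection:
    """Choose the cluster number maximizing the mean silhouette.

    A gap statistic is reported alongside for diagnostics: the clustering is
    re-run on ``n_ref`` uniform resamples of the bounding box of a principal
    coordinate embedding of the distances, and gap(k) is the difference in
    log within-cluster dispersion between reference and observed data.
    """
    d, ids = _as_square(dist)
    n = len(ids)
    if not (2 <= k_min < k_max <= n - 1):
        raise ValueError(f"require 2 <= k_min < k_max <= n-1 (n={n})")
    if np.allclose(d, 0.0):
        raise ValueError("degenerate all-zero distance matrix")

    sils: dict[int, float] = {}
    obs_logw: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        ca = hierarchical_cluster(dist, k, linkage=linkage)
        sils[k] = ca.mean_silhouette
        obs_logw[k] = np.log(_within_dispersion(d, ca.labels.to_numpy()))

    # reference distribution: uniform over the PCoA bounding box
    from .ordination import pcoa  # local import; ordination does not import phylo

    rng = np.random.default_rng(seed)
    coords = pcoa(pd.DataFrame(d, index=ids, columns=ids)).coordinates.to_numpy()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    ref_logw: dict[int, list[float]] = {k: [] for k in sils}
    for _ in range(n_ref):
        pts = rng.uniform(lo, hi, size=coords.shape)
        dref = squareform(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)), checks=False)
        Z = scipy_linkage(dref, method=linkage)
        dref_sq = squareform(dref, checks=False)
        for k in sils:
            labs = fcluster(Z, t=k, criterion="maxclust")
            ref_logw[k].append(np.log(_within_dispersion(dref_sq, labs)))
    gap = {k: float(np.mean(ref_logw[k]) - obs_logw[k]) for k in sils}
    k_best = max(sils, key=lambda k: (sils[k], -k))
    return KSelection(k_best=k_best, mean_silhouettes=sils, gap=gap)


def _within_dispersion(d: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of (sum of pairwise d^2) / (2 n_r)."""
    total = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        total += (sub**2).sum() / (2.0 * len(idx))  # double sum over ordered pairs
    return max(total, 1e-300)
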