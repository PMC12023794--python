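"""Gene-content ordination and group comparison.

Bray-Curtis dissimilarities over ortholog counts feed three analyses:
principal coordinates (Gower double-centering + eigendecomposition),
PERMANOVA (permutational multivariate ANOVA on the distance matrix), and
distance-based redundancy analysis (RDA of the PCoA coordinates on group
indicators), which together quantify how much of the gene-content variation
habitat or host type explains.  Univariate genome summaries (COG richness,
genome size, GC content) are compared across habitats by ANOVA with Tukey HSD
and reported as compact-letter displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .enrichment import bh_fdr

__all__ = [
    "bray_curtis",
    "richness",
    "pcoa",
    "permanova",
    "dbrda",
    "permanova_dbrda",
    "compare_groups",
    "genome_summary_compare",
    "compact_letters",
    "PCoAResult",
    "OrdinationResult",
    "GroupComparison",
]


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)


@dataclass
class OrdinationResult:
    constrained_R2: float  # between-group share of total inertia
    F: float
    p: float
    n_perm: int
    dbrda_R2: float = np.nan
    eigenvalues: np.ndarray | None = None
    coordinates: pd.DataFrame | None = None


@dataclass
class GroupComparison:
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, p, q
    letters: dict[str, str]
    group_means: pd.Series


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between genomes: sum|u-v| / sum(u+v).

    ``counts`` is genes x genomes (non-negative).  A pair of all-zero
    genomes has an undefined dissimilarity and raises.
    """
    x = counts.to_numpy(dtype=float).T  # genomes x genes
    if (x < 0).any():
        raise ValueError("negative counts")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(counts.columns[zero])
        raise ValueError(f"Bray-Curtis undefined between all-zero genomes: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def richness(counts: pd.DataFrame, presence_min: int = 1) -> pd.Series:
    """Number of gene orthologs present (count >= presence_min) per genome."""
    return (counts >= presence_min).sum(axis=0).rename("richness")


def pcoa(dissim: pd.DataFrame) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering.

    Axes with negative eigenvalues (non-Euclidean input) are reported in the
    eigenvalue spectrum but dropped from the coordinates.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, U = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > 1e-10 * max(abs(w[0]), 1.0)
    coords = U[:, pos] * np.sqrt(w[pos])
    cols = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dissim.index, columns=cols),
        eigenvalues=w,
    )


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dissim: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "auto",
) -> OrdinationResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    F = (SS_between/(k-1)) / (SS_within/(N-k)); the p-value counts
    permutations with F at least as large as observed, including the
    observed labeling (so p >= 1/(n_perm+1)).  ``method`` "exact"
    enumerates all distinct label permutations (small N only);
    "auto" uses Monte Carlo sampling under ``seed``.
    """
    ids = list(dissim.index)
    lab = pd.Series(labels).reindex(ids)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    codes, levels = pd.factorize(lab)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 members")
    d2 = np.asarray(dissim, dtype=float) ** 2
    N = len(ids)

    def f_stat(g: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2, g)
        ss_between = ss_total - ss_within
        F = (ss_between / (k - 1)) / (ss_within / (N - k))
        return F, ss_between / ss_total

    F_obs, r2 = f_stat(codes)
    if method == "exact":
        seen = set()
        count = 0
        total = 0
        for perm in _permutations(range(N)):
            key = tuple(codes[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if f_stat(np.array(key))[0] >= F_obs - 1e-12:
                count += 1
        p = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 1  # the observed labeling
        for _ in range(n_perm):
            g = codes[rng.permutation(N)]
            if f_stat(g)[0] >= F_obs - 1e-12:
                count += 1
        p = count / (n_perm + 1)
        n_used = n_perm
    return OrdinationResult(
        constrained_R2=float(r2), F=float(F_obs), p=float(p), n_perm=n_used
    )


def dbrda(dissim: pd.DataFrame, labels: dict[str, str] | pd.Series) -> OrdinationResult:
    """Distance-based RDA: constrain PCoA coordinates on group indicators.

    The constrained R^2 is the fraction of PCoA inertia captured by the
    group-fitted coordinates; constrained axes come from the eigenanalysis
    of the fitted values.
    """
    res = pcoa(dissim)
    Y = res.coordinates.to_numpy()
    ids = list(dissim.index)
    lab = pd.Series(labels).reindex(ids)
    X = pd.get_dummies(lab, dtype=float).to_numpy()
    X = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    XtX_inv = np.linalg.pinv(X.T @ X)
    fitted = X @ (XtX_inv @ (X.T @ Yc))
    total_inertia = (Yc**2).sum()
    constrained = (fitted**2).sum()
    # constrained axes: eigen-structure of the fitted matrix
    Uf, sf, _ = np.linalg.svd(fitted, full_matrices=False)
    keep = sf**2 > 1e-12 * max(total_inertia, 1.0)
    axes = pd.DataFrame(
        Uf[:, keep] * sf[keep],
        index=ids,
        columns=[f"dbRDA{i + 1}" for i in range(int(keep.sum()))],
    )
    return OrdinationResult(
        constrained_R2=float(constrained / total_inertia),
        F=np.nan,
        p=np.nan,
        n_perm=0,
        dbrda_R2=float(constrained / total_inertia),
        eigenvalues=sf[keep] ** 2,
        coordinates=axes,
    )


def permanova_dbrda(
    dissim: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """PERMANOVA inference plus dbRDA constrained inertia and axes."""
    perm = permanova(dissim, labels, n_perm=n_perm, seed=seed)
    rda = dbrda(dissim, labels)
    perm.dbrda_R2 = rda.dbrda_R2
    perm.eigenvalues = rda.eigenvalues
    perm.coordinates = rda.coordinates
    return perm


def compact_letters(
    groups: list[str], q: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact-letter display: groups share a letter iff pairwise q >= alpha.

    Letters are the maximal cliques of the not-significantly-different graph,
    ordered for stable output.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if q.loc[a, b] >= alpha:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: (sorted(groups).index(min(c)), -len(c)))
    letters: dict[str, str] = {grp: "" for grp in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        for grp in clique:
            letters[grp] += alphabet[idx % len(alphabet)]
    return {grp: "".join(sorted(s)) for grp, s in letters.items()}


def compare_groups(
    values: pd.Series, labels: pd.Series, alpha: float = 0.05
) -> GroupComparison:
    """ANOVA + Tukey HSD (Tukey-Kramer for unbalanced groups) + letters.

    Pairwise Tukey p-values are additionally BH-FDR adjusted, and the
    compact-letter display is computed from the adjusted values.
    """
    labels = labels.reindex(values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    samples = [values[labels == g].to_numpy(dtype=float) for g in groups]
    F, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values.to_numpy(dtype=float), labels.to_numpy(), alpha=alpha)
    # pairs appear in combinations order over the sorted unique groups
    from itertools import combinations

    pairs = list(combinations(tk.groupsunique, 2))
    pw = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "diff": tk.meandiffs,
            "p": tk.pvalues,
        }
    )
    pw["q"] = bh_fdr(pw["p"].to_numpy())
    qmat = pd.DataFrame(1.0, index=groups, columns=groups)
    for _, row in pw.iterrows():
        qmat.loc[row["group_a"], row["group_b"]] = row["q"]
        qmat.loc[row["group_b"], row["group_a"]] = row["q"]
    letters = compact_letters(groups, qmat, alpha=alpha)
    return GroupComparison(
        anova_F=float(F),
        anova_p=float(p),
        pairwise=pw,
        letters=letters,
        group_means=values.groupby(labels).mean(),
    )


def genome_summary_compare(
    records: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> dict[str, GroupComparison]:
    """Habitat comparison of genome size and GC content with letter groups.

    ``records`` must carry ``genome_size`` and ``gc_content`` columns indexed
    by genome id.
    """
    out = {}
    for col in ("genome_size", "gc_content"):
        if col not in records.columns:
            raise ValueError(f"records table lacks {col!r}")
        out[col] = compare_groups(records[col].astype(float), labels, alpha=alpha)
    return out
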