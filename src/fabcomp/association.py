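"""Habitat-association scoring of gene orthologs.

Presence/absence association is tested per (gene, habitat) cell with the
upper-tail hypergeometric test — drawing the habitat's genomes from the pool
and asking whether they carry the gene more often than chance — and with the
odds ratio on the corresponding 2x2 table, whose one-sided Fisher exact
p-value coincides with the hypergeometric tail.  The "hypergeometric score"
reported alongside is -log10 of the upper-tail p.  A gene is called
habitat-specific when either FDR-corrected test clears the significance
threshold (disjunction rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = [
    "hypergeom_test",
    "odds_ratio_test",
    "cpt_transform",
    "associate_all",
    "call_specific_genes",
]


def _check_margins(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent margins N={N}, K={K}, n={n}, k={k}")
    if k < max(0, n + K - N):
        raise ValueError(f"k={k} below the feasible minimum {max(0, n + K - N)}")


def hypergeom_test(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Upper-tail hypergeometric p-value and its -log10 score.

    X ~ Hypergeometric(N population, K marked, n drawn); p = P(X >= k),
    evaluated through the log survival function so extreme tails keep
    precision, with the score taken directly on the log scale.
    """
    _check_margins(N, K, n, k)
    if k <= max(0, n + K - N):
        return 1.0, 0.0
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    p = float(np.exp(logp))
    score = float(-logp / np.log(10.0))
    return min(p, 1.0), max(score, 0.0)


def odds_ratio_test(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Odds ratio of the 2x2 presence table and one-sided Fisher p.

    Table: [[k, n-k], [K-k, (N-n)-(K-k)]].  The Haldane-Anscombe +0.5
    correction is applied only when some cell is zero.  The one-sided
    (enrichment) Fisher exact p equals the hypergeometric upper tail.
    """
    _check_margins(N, K, n, k)
    a, b = k, n - k
    c, d = K - k, (N - n) - (K - k)
    if min(a, b, c, d) == 0:
        orx = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orx = (a * d) / (b * c)
    fisher_p, _ = hypergeom_test(N, K, n, k)
    return float(orx), fisher_p


def cpt_transform(
    counts_by_habitat: pd.DataFrame, n_genomes_by_habitat: pd.Series
) -> pd.DataFrame:
    """Counts per thousand genomes: 1000 * count / habitat genome tally.

    Normalizes absolute gene (or category) counts for unequal habitat sample
    sizes; columns are habitats.
    """
    n = n_genomes_by_habitat.reindex(counts_by_habitat.columns)
    if n.isna().any() or (n <= 0).any():
        bad = list(n.index[n.isna() | (n <= 0)])
        raise ValueError(f"habitats without genomes: {bad}")
    return 1000.0 * counts_by_habitat.div(n, axis=1)


def associate_all(
    counts: pd.DataFrame,
    habitats: dict[str, str],
    presence_min: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric + odds-ratio association for every (gene, habitat).

    ``counts`` is genes x genomes; a gene is present in a genome when its
    count >= ``presence_min``.  Returns a long table with p, q (BH across
    genes within each habitat), score, odds ratio, and the specificity call.
    """
    genomes = list(counts.columns)
    missing = [g for g in genomes if g not in habitats]
    if missing:
        raise ValueError(f"no habitat for genomes: {missing[:5]}")
    present = counts.to_numpy() >= presence_min  # genes x genomes
    hab = np.array([habitats[g] for g in genomes])
    N = len(genomes)
    K_all = present.sum(axis=1)
    rows = []
    for h in sorted(set(hab)):
        mask = hab == h
        n_h = int(mask.sum())
        k_h = present[:, mask].sum(axis=1)
        for j, gene in enumerate(counts.index):
            p, score = hypergeom_test(N, int(K_all[j]), n_h, int(k_h[j]))
            orx, fisher_p = odds_ratio_test(N, int(K_all[j]), n_h, int(k_h[j]))
            rows.append(
                {
                    "gene": gene,
                    "habitat": h,
                    "N": N,
                    "K": int(K_all[j]),
                    "n": n_h,
                    "k": int(k_h[j]),
                    "hyper_p": p,
                    "hyper_score": score,
                    "odds_ratio": orx,
                    "fisher_p": fisher_p,
                }
            )
    out = pd.DataFrame(rows)
    out["q_hyper"] = np.nan
    out["q_fisher"] = np.nan
    for h in out["habitat"].unique():
        m = out["habitat"] == h
        out.loc[m, "q_hyper"] = bh_fdr(out.loc[m, "hyper_p"].to_numpy())
        out.loc[m, "q_fisher"] = bh_fdr(out.loc[m, "fisher_p"].to_numpy())
    out["specific"] = (out["q_hyper"] < alpha) | (out["q_fisher"] < alpha)
    return out


def call_specific_genes(
    results: pd.DataFrame, alpha: float = 0.05
) -> dict[str, set[str]]:
    """Per-habitat sets of genes specific by either corrected test."""
    required = {"gene", "habitat", "q_hyper", "q_fisher"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table missing columns {required - set(results.columns)}")
    spec = results[(results["q_hyper"] < alpha) | (results["q_fisher"] < alpha)]
    out: dict[str, set[str]] = {h: set() for h in results["habitat"].unique()}
    for h, sub in spec.groupby("habitat"):
        out[h] = set(sub["gene"])
    return out
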