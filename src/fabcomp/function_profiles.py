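"""Pathway completeness and CAZyme substrate profiling.

A pathway (e.g., one ABC transporter system) is complete in a genome only
when every required gene is present; its copy number is the minimum copy
count over the required genes, so incompleteness gives zero and the value
counts fully stocked pathway instances.  Copy-number frequencies are compared
across habitats by Pearson chi-squared with BH-FDR over pathways.

CAZyme annotations are consensus-filtered (kept only when supported by at
least two of the annotation algorithms), collated into family x genome
counts, rolled up to substrates through a family-to-substrate map (a family
serving two substrates contributes its full count to both), and compared
between fungal host guilds (ectomycorrhizal vs saprotrophic) by two-sided
rank-sum tests with BH-FDR over substrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = [
    "PathwayDef",
    "pathway_copy_number",
    "pathway_copy_table",
    "pathway_habitat_comparison",
    "cazy_consensus_filter",
    "family_counts",
    "substrate_profile",
]


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    required_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"pathway {self.pathway_id} has no required genes")


def pathway_copy_number(gene_counts: Mapping[str, int], pathway: PathwayDef) -> int:
    """Copies of a complete pathway: min count over required genes, 0 if any absent."""
    counts = [int(gene_counts.get(g, 0)) for g in pathway.required_genes]
    if any(c < 0 for c in counts):
        raise ValueError("negative gene count")
    return min(counts)


def pathway_copy_table(
    counts: pd.DataFrame, pathways: Sequence[PathwayDef]
) -> pd.DataFrame:
    """Genome x pathway copy-number table from a genes x genomes count matrix."""
    out = {}
    for pw in pathways:
        present = [g for g in pw.required_genes if g in counts.index]
        if len(present) < len(pw.required_genes):
            out[pw.pathway_id] = np.zeros(counts.shape[1], dtype=int)
            continue
        out[pw.pathway_id] = counts.loc[present].min(axis=0).astype(int).to_numpy()
    return pd.DataFrame(out, index=counts.columns)


def _bin_copies(copies: np.ndarray, mode: str) -> np.ndarray:
    if mode == "categories":
        return np.minimum(copies, 2)  # 0, 1, >=2
    if mode == "presence":
        return (copies > 0).astype(int)
    raise ValueError("mode must be 'categories' or 'presence'")


def pathway_habitat_comparison(
    copy_table: pd.DataFrame,
    habitats: dict[str, str],
    mode: str = "categories",
    yates: bool = False,
) -> pd.DataFrame:
    """Chi-squared comparison of pathway copy-number frequencies across habitats.

    Copy numbers are binned as {0, 1, >=2} ("categories") or presence/absence
    ("presence"); bins empty in every habitat are dropped.  A pathway present
    in exactly one habitat is flagged exclusive.
    """
    hab = pd.Series({g: habitats[g] for g in copy_table.index})
    levels = sorted(hab.unique())
    rows = []
    for pw in copy_table.columns:
        binned = _bin_copies(copy_table[pw].to_numpy(), mode)
        table = pd.crosstab(binned, hab.to_numpy())
        table = table.loc[table.sum(axis=1) > 0, :]
        present_in = [
            h for h in levels if (copy_table.loc[hab.index[hab == h], pw] > 0).any()
        ]
        if table.shape[0] < 2 or table.shape[1] < 2:
            chi2, p, dof = 0.0, 1.0, 0
        else:
            chi2, p, dof, _ = stats.chi2_contingency(
                table.to_numpy(), correction=yates
            )
        rows.append(
            {
                "pathway": pw,
                "chi2": float(chi2),
                "df": int(dof),
                "p": float(p),
                "exclusive": len(present_in) == 1,
                "exclusive_habitat": present_in[0] if len(present_in) == 1 else "",
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def cazy_consensus_filter(
    annotations: pd.DataFrame, min_algorithms: int = 2
) -> pd.DataFrame:
    """Keep annotation rows supported by at least ``min_algorithms`` algorithms.

    The ``algorithms`` column holds '+'-joined algorithm names; row order is
    preserved and the filter is idempotent.
    """
    if annotations.empty:
        return annotations.copy()
    n_alg = annotations["algorithms"].map(
        lambda s: len([a for a in str(s).split("+") if a])
    )
    return annotations.loc[n_alg >= min_algorithms].copy()


def family_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Collate annotations into a family x genome domain-count matrix."""
    if annotations.empty:
        return pd.DataFrame()
    return pd.crosstab(annotations["family"], annotations["genome_id"])


def substrate_profile(
    annotations: pd.DataFrame,
    substrate_map: Mapping[str, Iterable[str]],
    genome_guilds: Mapping[str, str],
    min_algorithms: int = 2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substrate-level CAZyme comparison between fungal host guilds.

    Returns (substrate x genome counts, per-substrate test table).  Genomes
    without a guild label are excluded from the test but kept in the counts.
    Substrates whose families are absent from the data appear with zero
    counts and a missing test result.
    """
    filtered = cazy_consensus_filter(annotations, min_algorithms=min_algorithms)
    fam = family_counts(filtered)
    genomes = list(fam.columns) if not fam.empty else []
    sub_counts = pd.DataFrame(
        0, index=list(substrate_map.keys()), columns=genomes, dtype=int
    )
    for substrate, fams in substrate_map.items():
        fams_here = [f for f in fams if f in fam.index]
        if fams_here:
            sub_counts.loc[substrate] = fam.loc[fams_here].sum(axis=0)

    guild = pd.Series({g: genome_guilds.get(g) for g in genomes})
    ecto = guild.index[guild == "ectomycorrhizal"]
    sapro = guild.index[guild == "saprotrophic"]
    rows = []
    for substrate in sub_counts.index:
        a = sub_counts.loc[substrate, ecto].to_numpy(dtype=float)
        b = sub_counts.loc[substrate, sapro].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0 or (a.sum() + b.sum()) == 0:
            rows.append(
                {"substrate": substrate, "mean_ecto": np.nan, "mean_sapro": np.nan,
                 "statistic": np.nan, "p": np.nan}
            )
            continue
        try:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:  # all values identical
            u, p = np.nan, 1.0
        rows.append(
            {"substrate": substrate, "mean_ecto": float(a.mean()),
             "mean_sapro": float(b.mean()), "statistic": u, "p": p}
        )
    tests = pd.DataFrame(rows)
    ok = tests["p"].notna()
    tests["q"] = np.nan
    if ok.any():
        tests.loc[ok, "q"] = bh_fdr(tests.loc[ok, "p"].to_numpy())
    tests["starred"] = tests["q"] < alpha
    return sub_counts, tests
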