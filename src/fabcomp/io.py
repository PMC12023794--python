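"""Readers, writers, validation, and the end-to-end pipeline driver.

All tabular interchange is TSV with a header line ('#' starts a comment),
trees are newick, and configuration (pathway definitions, substrate maps)
is YAML.  ``read_tables`` cross-validates id sets (tree tips vs metadata vs
count columns) before any stage runs; ``run_pipeline`` executes the stages in
the analysis order — curation, clustering, enrichment, association,
function profiles, ordination — writing each stage's outputs before the next
starts and a run manifest (config hash, per-file checksums) last.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import association, curation, enrichment, function_profiles, ordination, phylo
from .curation import ANIPair, GenomeRecord
from .function_profiles import PathwayDef

__all__ = [
    "read_metadata",
    "write_metadata",
    "read_counts",
    "write_counts",
    "read_ani_pairs",
    "write_ani_pairs",
    "read_cazymes",
    "write_cazymes",
    "read_pathways",
    "write_pathways",
    "read_substrate_map",
    "write_substrate_map",
    "read_tables",
    "write_dataset",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]

_META_COLUMNS = [
    "genome_id", "habitat", "host_type", "species", "isolation_site_known",
    "completeness", "contamination", "coding_fraction", "single_copy_hits",
    "guild", "genome_size", "gc_content",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err


def read_metadata(path: str | Path) -> list[GenomeRecord]:
    df = _read_tsv(path, dtype={"genome_id": str})
    missing = [c for c in _META_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"{path}: duplicate genome ids {dup[:5]}")
    records = []
    for _, row in df.iterrows():
        records.append(
            GenomeRecord(
                genome_id=row["genome_id"],
                habitat=row["habitat"],
                host_type=row["host_type"],
                species=row["species"],
                isolation_site_known=_as_bool(row["isolation_site_known"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                coding_fraction=float(row["coding_fraction"]),
                single_copy_hits=int(row["single_copy_hits"]),
                guild=_opt(row.get("guild")),
                genome_size=_opt_float(row.get("genome_size")),
                gc_content=_opt_float(row.get("gc_content")),
            )
        )
    return records


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("1", "true", "yes")


def _opt(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("", "nan"):
        return None
    return str(v)


def _opt_float(v) -> Optional[float]:
    s = _opt(v)
    return None if s is None else float(s)


def write_metadata(records: list[GenomeRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene-count TSV: genes as rows (first column 'gene'), genomes as columns."""
    # pandas silently renames duplicate columns, so check the raw header
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValueError(f"{path}: empty count table")
    cols = pd.Index(header[1:])
    if cols.duplicated().any():
        dup = list(cols[cols.duplicated()])
        raise ValueError(f"{path}: duplicated genome columns {dup[:5]}")
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated gene ids")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_ani_pairs(path: str | Path) -> list[ANIPair]:
    df = _read_tsv(path, dtype={"query": str, "subject": str})
    need = {"query", "subject", "ani", "af"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: ANI table needs columns {sorted(need)}")
    return [
        ANIPair(genome_a=r["query"], genome_b=r["subject"], ani=float(r["ani"]), af=float(r["af"]))
        for _, r in df.iterrows()
    ]


def write_ani_pairs(pairs: list[ANIPair], path: str | Path) -> None:
    pd.DataFrame(
        [{"query": p.genome_a, "subject": p.genome_b, "ani": p.ani, "af": p.af} for p in pairs]
    ).to_csv(path, sep="\t", index=False)


def read_cazymes(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    need = {"protein_id", "genome_id", "family", "algorithms"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: CAZyme table needs columns {sorted(need)}")
    return df


def write_cazymes(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> list[PathwayDef]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        PathwayDef(pathway_id=k, name=v.get("name", k), required_genes=frozenset(v["genes"]))
        if isinstance(v, dict)
        else PathwayDef(pathway_id=k, name=k, required_genes=frozenset(v))
        for k, v in raw.items()
    ]


def write_pathways(pathways: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in pathways.items()}, fh)


def read_substrate_map(path: str | Path) -> dict[str, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: list(v) for k, v in raw.items()}


def write_substrate_map(smap: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in smap.items()}, fh)


def read_tables(
    metadata: str | Path,
    counts: str | Path,
    tree: Optional[str | Path] = None,
    ani: Optional[str | Path] = None,
) -> dict:
    """Load and cross-validate the core inputs.

    Tree tips, metadata genome ids, and count-matrix columns must agree as
    sets; orphans on any side are reported in the error.
    """
    records = read_metadata(metadata)
    count_df = read_counts(counts)
    meta_ids = {r.genome_id for r in records}
    count_ids = set(count_df.columns)
    problems = []
    if meta_ids != count_ids:
        problems.append(
            f"metadata vs counts mismatch: only-metadata={sorted(meta_ids - count_ids)[:5]}, "
            f"only-counts={sorted(count_ids - meta_ids)[:5]}"
        )
    tree_obj = None
    if tree is not None:
        tree_obj = phylo.load_tree(tree)
        tips = set(phylo.tip_labels(tree_obj))
        if tips != meta_ids:
            problems.append(
                f"tree vs metadata mismatch: only-tree={sorted(tips - meta_ids)[:5]}, "
                f"only-metadata={sorted(meta_ids - tips)[:5]}"
            )
    if problems:
        raise ValueError("; ".join(problems))
    pairs = read_ani_pairs(ani) if ani is not None else []
    return {"records": records, "counts": count_df, "tree": tree_obj, "ani_pairs": pairs}


def write_dataset(dataset, outdir: str | Path) -> dict[str, str]:
    """Serialize a SimulatedDataset to plain-text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "counts": out / "gene_counts.tsv",
        "ani": out / "ani_pairs.tsv",
        "cazymes": out / "cazymes.tsv",
        "pathway_content": out / "pathway_counts.tsv",
        "category_map": out / "category_map.tsv",
        "truth": out / "truth.json",
    }
    dataset.tree.write(path=str(paths["tree"]), schema="newick")
    write_metadata(dataset.records, paths["metadata"])
    write_counts(dataset.counts, paths["counts"])
    write_ani_pairs(dataset.ani_pairs, paths["ani"])
    write_cazymes(dataset.cazyme_annotations, paths["cazymes"])
    write_counts(dataset.pathway_content, paths["pathway_content"])
    dataset.category_map.rename_axis("gene").to_frame().to_csv(
        paths["category_map"], sep="\t"
    )
    with open(paths["truth"], "w") as fh:
        json.dump(_jsonable(dataset.truth), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _key(k):
    return "|".join(map(str, k)) if isinstance(k, tuple) else str(k)


@dataclass
class PipelineConfig:
    metadata: str
    counts: str
    tree: str
    outdir: str
    ani: Optional[str] = None
    cazymes: Optional[str] = None
    pathways: Optional[str] = None
    pathway_counts: Optional[str] = None  # defaults to the main count table
    substrate_map: Optional[str] = None
    category_map: Optional[str] = None
    stages: tuple[str, ...] = (
        "curation", "clustering", "enrichment", "association", "profiles", "ordination",
    )
    seed: int = 0
    k_range: tuple[int, int] = (2, 8)
    lam: float = 1.0
    alpha: float = 0.05
    n_perm: int = 999


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in analysis order and write a manifest."""
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        version=__version__,
        config_hash=cfg_hash,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    data = read_tables(config.metadata, config.counts, tree=config.tree, ani=config.ani)
    records, counts, tree = data["records"], data["counts"], data["tree"]

    def record_stage(name: str, outputs: dict[str, Path]) -> None:
        manifest.stages.append(
            {"stage": name, "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                                        for k, p in outputs.items()}}
        )

    if "curation" in config.stages:
        kept, report = curation.curate(records, data["ani_pairs"], seed=config.seed)
        kept_ids = [r.genome_id for r in kept]
        p = out / "curation_report.json"
        with open(p, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        pk = out / "kept_ids.txt"
        pk.write_text("\n".join(kept_ids) + "\n")
        record_stage("curation", {"report": p, "kept_ids": pk})
        records = kept
        counts = counts[kept_ids]
        tree = tree.extract_tree_with_taxa_labels(kept_ids)
    else:
        manifest.warnings.append("curation disabled: downstream stages use the unfiltered set")

    habitats = {r.genome_id: r.habitat for r in records}
    hab_series = pd.Series(habitats)

    if "clustering" in config.stages:
        dist = phylo.cophenetic_distances(tree)
        sel = phylo.select_k(dist, k_min=config.k_range[0],
                             k_max=min(config.k_range[1], dist.shape[0] - 1),
                             seed=config.seed)
        ca = phylo.hierarchical_cluster(dist, sel.k_best)
        p1 = out / "distances.tsv"
        dist.to_csv(p1, sep="\t")
        p2 = out / "clusters.tsv"
        pd.DataFrame({"cluster": ca.labels, "silhouette": ca.silhouettes}).rename_axis(
            "genome_id"
        ).to_csv(p2, sep="\t")
        p3 = out / "k_selection.json"
        with open(p3, "w") as fh:
            json.dump({"k_best": sel.k_best,
                       "mean_silhouettes": {str(k): v for k, v in sel.mean_silhouettes.items()},
                       "gap": {str(k): v for k, v in sel.gap.items()}}, fh, indent=1)
        record_stage("clustering", {"distances": p1, "clusters": p2, "k_selection": p3})

    V = phylo.bm_covariance(tree)

    if "enrichment" in config.stages:
        cats = None
        if config.category_map:
            cats = _read_tsv(config.category_map).set_index("gene").iloc[:, 0]
        tables = enrichment.enrich_all(
            counts, habitats, V, category_map=cats, lam=config.lam, alpha=config.alpha
        )
        p1 = out / "enrichment_genes.tsv"
        tables.gene_table.to_csv(p1, sep="\t", index=False)
        p2 = out / "enrichment_categories.tsv"
        tables.category_medians.to_csv(p2, sep="\t")
        record_stage("enrichment", {"genes": p1, "categories": p2})

    if "association" in config.stages:
        res = association.associate_all(counts, habitats, alpha=config.alpha)
        p1 = out / "association.tsv"
        res.to_csv(p1, sep="\t", index=False)
        record_stage("association", {"association": p1})

    if "profiles" in config.stages and config.pathways:
        pwdefs = read_pathways(config.pathways)
        pw_counts = read_counts(config.pathway_counts) if config.pathway_counts else counts
        pw_counts = pw_counts[[g for g in pw_counts.columns if g in habitats]]
        copy_tab = function_profiles.pathway_copy_table(pw_counts, pwdefs)
        comp = function_profiles.pathway_habitat_comparison(copy_tab, habitats)
        p1 = out / "pathways.tsv"
        comp.to_csv(p1, sep="\t", index=False)
        outputs = {"pathways": p1}
        if config.cazymes and config.substrate_map:
            ann = read_cazymes(config.cazymes)
            smap = read_substrate_map(config.substrate_map)
            guilds = {r.genome_id: r.guild for r in records if r.guild}
            sub_counts, tests = function_profiles.substrate_profile(ann, smap, guilds)
            p2 = out / "substrates.tsv"
            tests.to_csv(p2, sep="\t", index=False)
            outputs["substrates"] = p2
        record_stage("profiles", outputs)

    if "ordination" in config.stages:
        bc = ordination.bray_curtis(counts)
        res = ordination.permanova_dbrda(
            bc, hab_series, n_perm=config.n_perm, seed=config.seed
        )
        p1 = out / "bray_curtis.tsv"
        bc.to_csv(p1, sep="\t")
        p2 = out / "ordination_stats.json"
        with open(p2, "w") as fh:
            json.dump(
                {"R2": res.constrained_R2, "dbrda_R2": res.dbrda_R2, "F": res.F,
                 "p": res.p, "n_perm": res.n_perm, "seed": config.seed}, fh, indent=1)
        outputs = {"bray_curtis": p1, "stats": p2}
        if res.coordinates is not None:
            p3 = out / "dbrda_coordinates.tsv"
            res.coordinates.to_csv(p3, sep="\t")
            outputs["coordinates"] = p3
        record_stage("ordination", outputs)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    return manifest
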