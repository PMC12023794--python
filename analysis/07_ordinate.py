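#!/usr/bin/env python
"""Gene-content ordination and genome summary comparisons.

Builds the Bray-Curtis dissimilarity over ortholog counts, runs PERMANOVA
and dbRDA on habitat and host-type labels, compares COG richness and genome
size / GC content across habitats (ANOVA + Tukey HSD with compact letters).
Writes results/ordination/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from fabcomp.io import read_counts, read_metadata
from fabcomp.ordination import (
    bray_curtis,
    compare_groups,
    genome_summary_compare,
    permanova_dbrda,
    richness,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main() -> None:
    kept = (ROOT / "curation" / "kept_ids.txt").read_text().split()
    counts = read_counts(ROOT / "data" / "gene_counts.tsv")[kept]
    records = read_metadata(ROOT / "data" / "metadata.tsv")
    by_id = {r.genome_id: r for r in records}
    habitat = pd.Series({g: by_id[g].habitat for g in kept})
    host_type = pd.Series({g: by_id[g].host_type for g in kept})

    bc = bray_curtis(counts)
    out = ROOT / "ordination"
    out.mkdir(parents=True, exist_ok=True)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")

    stats = {}
    for name, labels in [("habitat", habitat), ("host_type", host_type)]:
        res = permanova_dbrda(bc, labels, n_perm=999, seed=SEED)
        stats[name] = {"R2": res.constrained_R2, "dbrda_R2": res.dbrda_R2,
                       "F": res.F, "p": res.p, "n_perm": res.n_perm}
        print(f"{name}: PERMANOVA R2={res.constrained_R2:.3f} "
              f"F={res.F:.2f} p={res.p:.3g}; dbRDA R2={res.dbrda_R2:.3f}")
        if res.coordinates is not None:
            res.coordinates.to_csv(out / f"dbrda_{name}.tsv", sep="\t")
    with open(out / "permanova.json", "w") as fh:
        json.dump({**stats, "seed": SEED}, fh, indent=1)

    rich = richness(counts)
    rcmp = compare_groups(rich.astype(float), habitat)
    rich.rename_axis("genome_id").to_frame().assign(habitat=habitat).to_csv(
        out / "richness.tsv", sep="\t"
    )
    print("\nCOG richness by habitat (mean, letter):")
    for h in sorted(rcmp.group_means.index):
        print(f"  {h}: {rcmp.group_means[h]:.1f} {rcmp.letters[h]}")

    meta = pd.DataFrame(
        {"genome_size": [by_id[g].genome_size for g in kept],
         "gc_content": [by_id[g].gc_content for g in kept]},
        index=kept,
    )
    summaries = genome_summary_compare(meta, habitat)
    rows = []
    for var, cmp_ in summaries.items():
        for h in sorted(cmp_.group_means.index):
            rows.append({"variable": var, "habitat": h,
                         "mean": cmp_.group_means[h], "letters": cmp_.letters[h]})
    pd.DataFrame(rows).to_csv(out / "genome_summaries.tsv", sep="\t", index=False)
    print("\ngenome size / GC letters:",
          {v: c.letters for v, c in summaries.items()})


if __name__ == "__main__":
    sys.exit(main())
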