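#!/usr/bin/env python
"""Habitat association of gene orthologs by hypergeometric and odds-ratio tests.

Scores every (gene, habitat) presence pattern, normalizes per-habitat gene
tallies to counts per thousand genomes (CPT), and calls habitat-specific
genes by the either-test FDR rule.  Writes results/association/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from fabcomp.association import associate_all, call_specific_genes, cpt_transform
from fabcomp.io import read_counts, read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    kept = (ROOT / "curation" / "kept_ids.txt").read_text().split()
    counts = read_counts(ROOT / "data" / "gene_counts.tsv")[kept]
    records = read_metadata(ROOT / "data" / "metadata.tsv")
    habitats = {r.genome_id: r.habitat for r in records if r.genome_id in set(kept)}

    res = associate_all(counts, habitats)
    out = ROOT / "association"
    out.mkdir(parents=True, exist_ok=True)
    res.to_csv(out / "association.tsv", sep="\t", index=False)

    # CPT: presence tallies per habitat scaled to 1000 genomes
    hab = pd.Series(habitats)
    present = (counts >= 1).T.groupby(hab).sum().T
    n_by_hab = hab.value_counts()
    cpt = cpt_transform(present, n_by_hab)
    cpt.to_csv(out / "gene_cpt.tsv", sep="\t")

    sets = call_specific_genes(res)
    sim = json.load(open(ROOT / "data" / "simulation_config.json"))
    planted = set(sim["specific_genes"])
    print("habitat-specific gene calls:")
    for h in sorted(sets):
        overlap = len(sets[h] & planted)
        note = f" ({overlap} of {len(planted)} planted fungi-specific genes)" if h == "fungi" else ""
        print(f"  {h}: {len(sets[h])}{note}")


if __name__ == "__main__":
    sys.exit(main())
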