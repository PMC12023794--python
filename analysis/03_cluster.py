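#!/usr/bin/env python
"""Cluster the curated genomes from cophenetic tree distances.

Converts the phylogeny to a patristic distance matrix, scans cluster numbers
k by mean silhouette (gap statistic reported for diagnostics), and writes the
chosen assignment under results/clustering/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from fabcomp.phylo import cophenetic_distances, hierarchical_cluster, load_tree, select_k

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main() -> None:
    tree = load_tree(ROOT / "data" / "tree.nwk")
    kept = (ROOT / "curation" / "kept_ids.txt").read_text().split()
    tree = tree.extract_tree_with_taxa_labels(kept)
    dist = cophenetic_distances(tree)
    sel = select_k(dist, 2, 8, seed=SEED)
    ca = hierarchical_cluster(dist, sel.k_best)
    out = ROOT / "clustering"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cluster": ca.labels, "silhouette": ca.silhouettes}).rename_axis(
        "genome_id"
    ).to_csv(out / "clusters.tsv", sep="\t")
    with open(out / "k_selection.json", "w") as fh:
        json.dump({"k_best": sel.k_best,
                   "mean_silhouettes": {str(k): v for k, v in sel.mean_silhouettes.items()},
                   "gap": {str(k): v for k, v in sel.gap.items()}}, fh, indent=1)
    print(f"{len(kept)} genomes; k_best={sel.k_best} "
          f"(mean silhouette {ca.mean_silhouette:.3f})")
    for k in sorted(sel.mean_silhouettes):
        print(f"  k={k}: silhouette {sel.mean_silhouettes[k]:.3f} "
              f"gap {sel.gap[k]:.3f}")


if __name__ == "__main__":
    sys.exit(main())
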