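#!/usr/bin/env python
"""Generate the ground-truthed synthetic genome collection.

Emulates the layout of a five-habitat comparative genome set: an ultrametric
phylogeny of 150 genomes, Poisson ortholog counts with Brownian phylogenetic
signal and planted fungi-habitat enrichments, QC metadata with designed
failures for every filtration rule, four injected near-clone genome pairs,
dbCAN-style CAZyme annotations with an ectomycorrhizal guild effect, and
pathway gene content with one fungi-exclusive transporter pathway.
Writes all tables (plus the truth record) under results/data/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from fabcomp.io import write_dataset, write_pathways, write_substrate_map
from fabcomp.synthetic import (
    DEFAULT_PATHWAYS,
    DEFAULT_SUBSTRATE_MAP,
    SimulationConfig,
    simulate_dataset,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20240901

EFFECT_GENES = [f"COG{g:04d}" for g in range(1, 13)]  # planted fungi enrichment
#: rare accessory genes with a planted fungi presence/absence signal
SPECIFIC_GENES = [f"COG{g:04d}" for g in range(13, 19)]


def main() -> None:
    effects = {(g, "fungi"): 1.2 for g in EFFECT_GENES}
    effects.update({(g, "fungi"): 4.5 for g in SPECIFIC_GENES})
    cfg = SimulationConfig(
        n_tips=150,
        n_habitats=5,
        n_genes=200,
        baseline_log_mean=float(np.log(5.0)),
        baseline_overrides={g: float(np.log(0.05)) for g in SPECIFIC_GENES},
        bm_sigma2=0.2,
        effect_table=effects,
        n_duplicates=4,
        qc_fail_spec={
            "missing_site": 2, "completeness": 3, "contamination": 2,
            "single_copy": 2, "coding_fraction": 2,
        },
        seed=SEED,
    )
    ds = simulate_dataset(cfg)
    paths = write_dataset(ds, OUT)
    write_pathways(DEFAULT_PATHWAYS, OUT / "pathways.yaml")
    write_substrate_map(DEFAULT_SUBSTRATE_MAP, OUT / "substrate_map.yaml")
    with open(OUT / "simulation_config.json", "w") as fh:
        json.dump(
            {"n_tips": cfg.n_tips, "n_habitats": cfg.n_habitats,
             "n_genes": cfg.n_genes, "bm_sigma2": cfg.bm_sigma2,
             "planted_effect": 1.2, "effect_genes": EFFECT_GENES,
             "specific_genes": SPECIFIC_GENES,
             "n_duplicates": cfg.n_duplicates, "seed": SEED},
            fh, indent=1,
        )
    print(f"wrote {len(paths)} tables to {OUT}")
    print(f"  genomes: {len(ds.records)} (incl. {cfg.n_duplicates} near-clones)")
    print(f"  genes: {ds.counts.shape[0]}; planted fungi effect on {len(EFFECT_GENES)}")
    print(f"  designed QC failures: {sum(cfg.qc_fail_spec.values())}")


if __name__ == "__main__":
    sys.exit(main())
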