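#!/usr/bin/env python
"""Pathway completeness and CAZyme substrate profiles across habitats.

Counts complete transporter pathways per genome (min-rule copy number),
compares copy-number frequencies across habitats by chi-squared with FDR,
then consensus-filters CAZyme annotations and compares substrate-level
enzyme counts between fungal host guilds.  Writes results/profiles/.
"""

import json
import sys
from pathlib import Path

from fabcomp.function_profiles import (
    pathway_copy_table,
    pathway_habitat_comparison,
    substrate_profile,
)
from fabcomp.io import (
    read_cazymes,
    read_counts,
    read_metadata,
    read_pathways,
    read_substrate_map,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    kept = set((ROOT / "curation" / "kept_ids.txt").read_text().split())
    records = read_metadata(ROOT / "data" / "metadata.tsv")
    habitats = {r.genome_id: r.habitat for r in records if r.genome_id in kept}

    pw_counts = read_counts(ROOT / "data" / "pathway_counts.tsv")
    pw_counts = pw_counts[[g for g in pw_counts.columns if g in kept]]
    defs = read_pathways(ROOT / "data" / "pathways.yaml")
    copy_tab = pathway_copy_table(pw_counts, defs)
    comp = pathway_habitat_comparison(copy_tab, habitats)

    out = ROOT / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    copy_tab.rename_axis("genome_id").to_csv(out / "pathway_copies.tsv", sep="\t")
    comp.to_csv(out / "pathway_tests.tsv", sep="\t", index=False)

    truth = json.load(open(ROOT / "data" / "truth.json"))
    print("pathway habitat comparison:")
    for _, row in comp.iterrows():
        marker = " *exclusive*" if row["exclusive"] else ""
        print(f"  {row['pathway']}: chi2={row['chi2']:.1f} q={row['q']:.2g}{marker}")
    print(f"planted exclusive pathway: {truth['pathway_exclusive']}")

    ann = read_cazymes(ROOT / "data" / "cazymes.tsv")
    ann = ann[ann["genome_id"].isin(kept)]
    smap = read_substrate_map(ROOT / "data" / "substrate_map.yaml")
    guilds = {r.genome_id: r.guild for r in records if r.guild and r.genome_id in kept}
    sub_counts, tests = substrate_profile(ann, smap, guilds)
    sub_counts.rename_axis("substrate").to_csv(out / "substrate_counts.tsv", sep="\t")
    tests.to_csv(out / "substrate_tests.tsv", sep="\t", index=False)
    print("\nsubstrate comparison (ectomycorrhizal vs saprotrophic hosts):")
    for _, row in tests.iterrows():
        star = " *" if row["starred"] else ""
        print(f"  {row['substrate']}: ecto {row['mean_ecto']:.1f} vs "
              f"sapro {row['mean_sapro']:.1f}, q={row['q']:.2g}{star}")


if __name__ == "__main__":
    sys.exit(main())
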