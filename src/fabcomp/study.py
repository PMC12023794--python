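"""Published design constants of the comparative study this pipeline mirrors.

The curated analysis set comprised 1211 bacterial genomes spanning five
habitats; the per-habitat tallies below are the study's reported inputs and
are used for genome accounting, CPT normalization examples, and the analysis
drivers' narrative output.  They are inputs, not results of this package.
"""

from __future__ import annotations

#: Genomes per habitat in the curated analysis set.
HABITAT_GENOME_COUNTS: dict[str, int] = {
    "fungi": 163,
    "plants": 316,
    "humans": 212,
    "soil": 284,
    "water": 236,
}

#: Fungus-associated genomes by host fungal guild (subset of "fungi").
FUNGAL_GUILD_COUNTS: dict[str, int] = {
    "ectomycorrhizal": 39,
    "saprotrophic": 17,
}


def curated_total() -> int:
    """Size of the curated analysis set implied by the per-habitat tallies."""
    return sum(HABITAT_GENOME_COUNTS.values())
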