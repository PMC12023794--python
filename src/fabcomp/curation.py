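"""Genome selection and filtration.

Five rules, applied in a fixed order so every removal is attributed to exactly
one cause:

1. genomes with missing or ambiguous isolation sites are discarded;
2. genomes less than 95% complete are removed;
3. genomes with more than 5% contamination are removed, as are genomes
   carrying fewer than 90% of the 92 single-copy marker genes (>= 83 after
   ceiling, since gene tallies are integers);
4. genomes with less than 85% protein-coding sequence are discarded;
5. within each (species, habitat) group, up to 5 genomes are kept at random;
   then genome pairs with ANI > 99.995% and alignment fraction > 90% are
   marked redundant and one representative per redundancy group is kept.

Thresholds follow the wording literally: "less than" / "more than" /
"exceeded" / "greater than" are strict on the failing side, so a genome at
exactly 95% completeness or exactly 5% contamination passes, and a pair at
exactly ANI 99.995% is not redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GenomeRecord",
    "ANIPair",
    "CurationReport",
    "filter_quality",
    "subsample_species",
    "deduplicate_ani",
    "curate",
    "SINGLE_COPY_TOTAL",
    "SINGLE_COPY_MIN",
]

HABITATS = ("fungi", "plants", "humans", "soil", "water")
GUILDS = ("ectomycorrhizal", "saprotrophic", "other")

SINGLE_COPY_TOTAL = 92
#: 90% of the 92 single-copy marker genes, rounded up: integers of genes
SINGLE_COPY_MIN = int(np.ceil(0.9 * SINGLE_COPY_TOTAL))  # = 83

RULE_ORDER = (
    "missing_site",
    "completeness",
    "contamination",
    "single_copy",
    "coding_fraction",
    "subsample",
    "dedup",
)


@dataclass
class GenomeRecord:
    genome_id: str
    habitat: str
    host_type: str = "host_associated"
    species: str = ""
    isolation_site_known: bool = True
    completeness: float = 100.0
    contamination: float = 0.0
    coding_fraction: float = 90.0
    single_copy_hits: int = SINGLE_COPY_TOTAL
    guild: Optional[str] = None
    genome_size: Optional[float] = None  # bp
    gc_content: Optional[float] = None  # percent

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination", "coding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.genome_id}: {name}={v} outside [0, 100]")
        if not 0 <= self.single_copy_hits <= SINGLE_COPY_TOTAL:
            raise ValueError(
                f"{self.genome_id}: single_copy_hits={self.single_copy_hits} "
                f"outside [0, {SINGLE_COPY_TOTAL}]"
            )


@dataclass
class ANIPair:
    genome_a: str
    genome_b: str
    ani: float  # fraction in [0, 1]
    af: float  # alignment fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError(f"self-pair {self.genome_a}")
        for name in ("ani", "af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pair {self.genome_a}-{self.genome_b}: {name}={v}")


@dataclass
class CurationReport:
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    kept_ids: list[str] = field(default_factory=list)
    seed: Optional[int] = None

    def reconciles(self) -> bool:
        return self.n_input == len(self.kept_ids) + sum(self.removed.values())

    def to_dict(self) -> dict:
        return asdict(self)


def filter_quality(records: Sequence[GenomeRecord]) -> tuple[list[GenomeRecord], CurationReport]:
    """Apply the per-genome QC rules; attribute each removal to its first failing rule."""
    if not records:
        raise ValueError("no genome records given")
    removed = {r: 0 for r in RULE_ORDER[:5]}
    kept = []
    for rec in records:
        rule = _first_failing_rule(rec)
        if rule is None:
            kept.append(rec)
        else:
            removed[rule] += 1
    report = CurationReport(
        n_input=len(records), removed=removed, kept_ids=[r.genome_id for r in kept]
    )
    return kept, report


def _first_failing_rule(rec: GenomeRecord) -> Optional[str]:
    if not rec.isolation_site_known:
        return "missing_site"
    if rec.completeness < 95.0:
        return "completeness"
    if rec.contamination > 5.0:
        return "contamination"
    if rec.single_copy_hits < SINGLE_COPY_MIN:
        return "single_copy"
    if rec.coding_fraction < 85.0:
        return "coding_fraction"
    return None


def subsample_species(
    records: Sequence[GenomeRecord], max_per: int = 5, seed: int = 0
) -> list[GenomeRecord]:
    """Keep at most ``max_per`` genomes per (species, habitat) group, at random.

    Order of the output follows the input order of the kept records.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.species, rec.habitat), []).append(i)
    keep_idx: set[int] = set()
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) <= max_per:
            keep_idx.update(idx)
        else:
            keep_idx.update(rng.choice(idx, size=max_per, replace=False).tolist())
    return [rec for i, rec in enumerate(records) if i in keep_idx]


def deduplicate_ani(
    records: Sequence[GenomeRecord],
    ani_pairs: Iterable[ANIPair],
    ani_thr: float = 0.99995,
    af_thr: float = 0.90,
    seed: int = 0,
) -> tuple[list[GenomeRecord], list[tuple[str, str]]]:
    """Collapse near-identical genomes to one representative per redundancy group.

    Pairs with ani > ani_thr and af > af_thr (both strict) form edges of a
    redundancy graph; within each connected component one genome is retained
    at random and the rest removed.  Components handle transitive chains
    (A~B, B~C) deterministically, which pairwise random removal would not.
    """
    ids = {r.genome_id for r in records}
    g = nx.Graph()
    redundant_pairs: list[tuple[str, str]] = []
    for pair in ani_pairs:
        if pair.genome_a not in ids or pair.genome_b not in ids:
            raise ValueError(
                f"ANI pair references unknown genome: {pair.genome_a}, {pair.genome_b}"
            )
        if pair.ani > ani_thr and pair.af > af_thr:
            g.add_edge(pair.genome_a, pair.genome_b)
            redundant_pairs.append((pair.genome_a, pair.genome_b))
    rng = np.random.default_rng(seed)
    drop: set[str] = set()
    for comp in sorted(nx.connected_components(g), key=min):
        members = sorted(comp)
        winner = members[rng.integers(len(members))]
        drop.update(m for m in members if m != winner)
    kept = [r for r in records if r.genome_id not in drop]
    return kept, redundant_pairs


def curate(
    records: Sequence[GenomeRecord],
    ani_pairs: Iterable[ANIPair] = (),
    max_per_species: int = 5,
    ani_thr: float = 0.99995,
    af_thr: float = 0.90,
    seed: int = 0,
) -> tuple[list[GenomeRecord], CurationReport]:
    """Full curation chain: QC rules, species subsampling, ANI deduplication."""
    kept, report = filter_quality(records)
    n_qc = len(kept)
    kept = subsample_species(kept, max_per=max_per_species, seed=seed)
    report.removed["subsample"] = n_qc - len(kept)
    kept_ids = {r.genome_id for r in kept}
    usable_pairs = [
        p for p in ani_pairs if p.genome_a in kept_ids and p.genome_b in kept_ids
    ]
    n_sub = len(kept)
    kept, _ = deduplicate_ani(kept, usable_pairs, ani_thr=ani_thr, af_thr=af_thr, seed=seed)
    report.removed["dedup"] = n_sub - len(kept)
    report.kept_ids = [r.genome_id for r in kept]
    report.seed = seed
    assert report.reconciles()
    return kept, report
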