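import dendropy
import numpy as np
import pandas as pd
import pytest

from fabcomp import phylo
from fabcomp.curation import ANIPair, GenomeRecord
from fabcomp.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_tree():
    """((A:1,B:1):1,C:2); — the worked three-tip example."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def four_taxon_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — balanced ultrametric quartet."""
    return dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")


@pytest.fixture(scope="session")
def small_dataset():
    """A complete synthetic dataset reused across modules (seeded)."""
    cfg = SimulationConfig(
        n_tips=40,
        n_genes=60,
        n_habitats=5,
        habitat_mode="random",
        n_duplicates=3,
        qc_fail_spec={
            "missing_site": 1,
            "completeness": 2,
            "contamination": 1,
            "single_copy": 1,
            "coding_fraction": 1,
        },
        seed=101,
    )
    return simulate_dataset(cfg)


def make_record(genome_id="G1", **kw):
    """A GenomeRecord passing every QC rule unless overridden."""
    base = dict(
        genome_id=genome_id,
        habitat="fungi",
        species=f"sp_{genome_id}",
        isolation_site_known=True,
        completeness=98.0,
        contamination=1.0,
        coding_fraction=90.0,
        single_copy_hits=90,
    )
    base.update(kw)
    return GenomeRecord(**base)


@pytest.fixture(scope="session")
def curation_fixture():
    """One designed failure per QC rule plus six clean passes.

    Hand enumeration: F1 missing site, F2 completeness 94.9, F3 contamination
    5.1, F4 single-copy 82, F5 coding 84.9 are each removed by exactly one
    rule; P1..P6 pass (P1 sits exactly on every passing boundary).
    """
    records = [
        make_record("F1", isolation_site_known=False),
        make_record("F2", completeness=94.9),
        make_record("F3", contamination=5.1),
        make_record("F4", single_copy_hits=82),
        make_record("F5", coding_fraction=84.9),
        make_record("P1", completeness=95.0, contamination=5.0,
                    single_copy_hits=83, coding_fraction=85.0),
        make_record("P2"),
        make_record("P3", habitat="soil"),
        make_record("P4", habitat="water"),
        make_record("P5", habitat="plants"),
        make_record("P6", habitat="humans"),
    ]
    kept_expected = {"P1", "P2", "P3", "P4", "P5", "P6"}
    return records, kept_expected
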