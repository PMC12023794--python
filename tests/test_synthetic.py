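"""Generator contracts: determinism, ultrametricity, planted truth."""

import numpy as np
import pytest
from scipy import stats

from fabcomp import phylo
from fabcomp.synthetic import (
    SimulationConfig,
    assign_habitats,
    simulate_clade_tree,
    simulate_dataset,
    simulate_gene_counts,
    simulate_tree,
)


class TestSimulateTree:
    def test_single_tip_degenerate(self):
        tree = simulate_tree(1)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 1
        assert leaves[0].distance_from_root() == 0.0

    def test_invalid_tip_count(self):
        with pytest.raises(ValueError):
            simulate_tree(0)

    def test_topology_and_ultrametricity(self):
        tree = simulate_tree(50, seed=3)
        leaves = list(tree.leaf_node_iter())
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 50
        assert len(internal) == 49
        depths = [lf.distance_from_root() for lf in leaves]
        assert max(depths) - min(depths) < 1e-9
        lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
        assert min(lengths) > 0

    def test_seeded_determinism(self):
        a = simulate_tree(20, seed=7).as_string(schema="newick")
        b = simulate_tree(20, seed=7).as_string(schema="newick")
        assert a == b
        c = simulate_tree(20, seed=8).as_string(schema="newick")
        assert a != c


class TestAssignHabitats:
    def test_single_habitat_all_same(self):
        tree = simulate_tree(10, seed=1)
        # n_habitats=1 is below the config minimum but valid for assignment
        hab = assign_habitats(tree, 1, "random", seed=0)
        assert len(set(hab.values())) == 1

    def test_more_habitats_than_tips(self):
        tree = simulate_tree(3, seed=1)
        with pytest.raises(ValueError):
            assign_habitats(tree, 5, "random")

    def test_clade_confounded_two_habitats_is_root_split(self):
        tree = simulate_tree(8, seed=5)
        hab = assign_habitats(tree, 2, "clade_confounded", seed=0)
        kids = tree.seed_node.child_nodes()
        left = {lf.taxon.label for lf in kids[0].leaf_iter()}
        labels_left = {hab[t] for t in left}
        labels_right = {hab[t] for t in hab if t not in left}
        assert len(labels_left) == 1 and len(labels_right) == 1
        assert labels_left != labels_right

    def test_clade_confounded_clades_are_connected(self):
        tree = simulate_tree(30, seed=2)
        hab = assign_habitats(tree, 4, "clade_confounded", seed=0)
        assert len(set(hab.values())) == 4
        # each habitat's tips form a clade: their MRCA contains no other habitat
        pdm_labels = {h: [t for t, hh in hab.items() if hh == h] for h in set(hab.values())}
        taxa = {t.label: t for t in tree.taxon_namespace}
        for h, tips in pdm_labels.items():
            mrca = tree.mrca(taxa=[taxa[t] for t in tips])
            under = {lf.taxon.label for lf in mrca.leaf_iter()}
            assert under == set(tips)

    def test_random_mode_exchangeable_wrt_root_split(self):
        """Label-clade association should reject at ~5% under random labels."""
        tree = simulate_tree(100, seed=42)
        left = {lf.taxon.label for lf in tree.seed_node.child_nodes()[0].leaf_iter()}
        rejections = 0
        reps = 1000
        for rep in range(reps):
            hab = assign_habitats(tree, 2, "random", seed=rep)
            table = np.zeros((2, 2))
            for tip, h in hab.items():
                table[0 if tip in left else 1, 0 if h == "fungi" else 1] += 1
            p = stats.chi2_contingency(table, correction=False)[1]
            rejections += p < 0.05
        # 99% binomial band around 0.05 at 1000 reps
        assert 0.032 <= rejections / reps <= 0.068


class TestSimulateGeneCounts:
    def test_poisson_mean_without_signal(self):
        """With no BM signal and no effects, mean count concentrates at e^mu."""
        tree = simulate_tree(200, seed=9)
        hab = assign_habitats(tree, 2, "random", seed=9)
        cfg = SimulationConfig(
            n_tips=200, n_habitats=2, n_genes=5,
            baseline_log_mean=float(np.log(5.0)), bm_sigma2=0.0, seed=9,
        )
        counts, _ = simulate_gene_counts(tree, hab, cfg)
        means = counts.mean(axis=1)
        assert ((means > 4.0) & (means < 6.0)).all()

    def test_planted_effect_raises_habitat_mean(self):
        for seed in range(30):
            tree = simulate_tree(100, seed=seed)
            hab = assign_habitats(tree, 2, "random", seed=seed)
            cfg = SimulationConfig(
                n_tips=100, n_habitats=2, n_genes=2, bm_sigma2=0.1,
                effect_table={("COG0001", "fungi"): 2.0}, seed=seed,
            )
            counts, truth = simulate_gene_counts(tree, hab, cfg)
            in_h = [g for g, h in hab.items() if h == "fungi"]
            out_h = [g for g, h in hab.items() if h != "fungi"]
            assert counts.loc["COG0001", in_h].mean() > counts.loc["COG0001", out_h].mean()

    def test_zero_genes_preserves_genomes(self):
        tree = simulate_tree(10, seed=1)
        hab = assign_habitats(tree, 2, "random", seed=1)
        cfg = SimulationConfig(n_tips=10, n_habitats=2, n_genes=0, seed=1)
        counts, _ = simulate_gene_counts(tree, hab, cfg)
        assert counts.shape == (0, 10)
        assert list(counts.columns) == [lf.taxon.label for lf in tree.leaf_node_iter()]

    def test_unknown_effect_key_rejected(self):
        tree = simulate_tree(10, seed=1)
        hab = assign_habitats(tree, 2, "random", seed=1)
        cfg = SimulationConfig(
            n_tips=10, n_habitats=2, n_genes=2,
            effect_table={("COG9999", "fungi"): 1.0}, seed=1,
        )
        with pytest.raises(ValueError):
            simulate_gene_counts(tree, hab, cfg)


class TestSimulateDataset:
    def test_designed_qc_failures(self, small_dataset):
        recs = small_dataset.records
        assert sum(1 for r in recs if r.completeness < 95) == 2
        assert sum(1 for r in recs if not r.isolation_site_known) == 1
        assert sum(1 for r in recs if r.contamination > 5) == 1
        assert sum(1 for r in recs if r.single_copy_hits < 83) == 1
        assert sum(1 for r in recs if r.coding_fraction < 85) == 1

    def test_duplicate_pairs_exceed_thresholds(self, small_dataset):
        redundant = [
            p for p in small_dataset.ani_pairs if p.ani > 0.99995 and p.af > 0.90
        ]
        assert len(redundant) == 3
        assert len(small_dataset.truth["duplicates"]) == 3

    def test_id_consistency(self, small_dataset):
        tips = sorted(lf.taxon.label for lf in small_dataset.tree.leaf_node_iter())
        assert tips == sorted(small_dataset.counts.columns)
        assert tips == sorted(r.genome_id for r in small_dataset.records)

    def test_same_seed_identical_serialization(self, tmp_path):
        from fabcomp.io import write_dataset

        cfg = SimulationConfig(n_tips=12, n_genes=10, n_duplicates=1, seed=5)
        p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for key in p1:
            with open(p1[key]) as f1, open(p2[key]) as f2:
                assert f1.read() == f2.read(), key


class TestSimulateCladeTree:
    def test_separation_ratio_holds(self):
        tree, truth = simulate_clade_tree(40, 4, separation=5.0, seed=0)
        dist = phylo.cophenetic_distances(tree)
        labels = {t: truth[t] for t in dist.index}
        within = max(
            dist.loc[a, b]
            for a in dist.index
            for b in dist.index
            if a < b and labels[a] == labels[b]
        )
        between = min(
            dist.loc[a, b]
            for a in dist.index
            for b in dist.index
            if labels[a] != labels[b]
        )
        assert between / within >= 5.0
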