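"""Bray-Curtis, PCoA, PERMANOVA/dbRDA, and group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabcomp.ordination import (
    bray_curtis,
    compact_letters,
    compare_groups,
    dbrda,
    genome_summary_compare,
    pcoa,
    permanova,
    permanova_dbrda,
    richness,
)


def frame(arrs, ids=None):
    ids = ids or [f"G{i}" for i in range(len(arrs))]
    return pd.DataFrame(np.array(arrs, dtype=float).T, columns=ids)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        bc = bray_curtis(frame([[5, 0], [5, 0], [0, 5]], ids=["u", "u2", "v"]))
        assert bc.loc["u", "u2"] == pytest.approx(0.0)
        assert bc.loc["u", "v"] == pytest.approx(1.0)

    def test_worked_example(self):
        bc = bray_curtis(frame([[6, 2], [2, 2]], ids=["a", "b"]))
        assert bc.loc["a", "b"] == pytest.approx(4 / 12)

    def test_two_all_zero_genomes_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(frame([[0, 0], [0, 0]], ids=["a", "b"]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.poisson(3, size=(8, 5)) + np.eye(8, 5, dtype=int))
        bc = bray_curtis(counts).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0)
        assert (bc >= 0).all() and (bc <= 1 + 1e-12).all()


class TestRichness:
    def test_counting(self):
        counts = frame([[0, 3, 1, 0], [0, 0, 0, 0]], ids=["a", "b"])
        r = richness(counts)
        assert r["a"] == 2 and r["b"] == 0


class TestPcoa:
    def test_three_equidistant_points(self):
        """The unit simplex: two equal positive eigenvalues, third ~ 0."""
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        w = res.eigenvalues
        assert w[0] == pytest.approx(w[1], rel=1e-9)
        assert abs(w[2]) < 1e-12
        assert res.coordinates.shape == (3, 2)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        res = pcoa(pd.DataFrame(d, index=ids, columns=ids))
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(d, d2, atol=1e-8)

    def test_duplicated_sample_coincident(self):
        counts = frame([[3, 1], [3, 1], [0, 4]], ids=["a", "a2", "b"])
        res = pcoa(bray_curtis(counts))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["a2"], atol=1e-9)

    def test_matches_scikit_bio(self):
        """Independent cross-check of the Gower-centered eigendecomposition."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(4, size=(12, 9)).astype(float))
        bc = bray_curtis(counts)
        ours = pcoa(bc)
        theirs = skbio_pcoa(bc.to_numpy(), number_of_dimensions=3)
        npos = min(3, ours.coordinates.shape[1])
        for ax in range(npos):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)


class TestPermanova:
    def test_identical_groups_no_signal(self):
        """Two groups made of the same four profiles: no between-group inertia."""
        profiles = [[5, 1, 2], [1, 4, 0], [2, 2, 2], [0, 1, 6]]
        counts = frame(profiles + profiles, ids=[f"g{i}" for i in range(8)])
        labels = pd.Series(["x"] * 4 + ["y"] * 4, index=counts.columns)
        res = permanova(bray_curtis(counts), labels, n_perm=199, seed=0)
        assert res.constrained_R2 < 0.05
        assert res.p > 0.5

    def test_small_group_rejected(self):
        counts = frame([[1, 2], [2, 1], [3, 1]], ids=list("abc"))
        labels = pd.Series({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError):
            permanova(bray_curtis(counts), labels)

    def test_r2_decomposition(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(5, size=(20, 12)).astype(float))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
        d2 = bray_curtis(counts).to_numpy() ** 2
        from fabcomp.ordination import _permanova_ss

        codes = np.array([0] * 6 + [1] * 6)
        ss_total, ss_within = _permanova_ss(d2, codes)
        assert ss_total == pytest.approx(ss_within + (ss_total - ss_within), abs=1e-10)
        res = permanova(bray_curtis(counts), labels, n_perm=49, seed=1)
        assert 0 <= res.constrained_R2 <= 1

    def test_exact_enumeration_matches_monte_carlo(self):
        """Full enumeration on N=8 agrees with sampling within its noise."""
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(6, size=(15, 8)).astype(float))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
        bc = bray_curtis(counts)
        exact = permanova(bc, labels, method="exact")
        mc = permanova(bc, labels, n_perm=4999, seed=2)
        assert abs(exact.p - mc.p) < 3 * np.sqrt(exact.p * (1 - exact.p) / 5000) + 1e-3
        assert exact.F == pytest.approx(mc.F)

    def test_matches_scikit_bio(self):
        """Cross-check pseudo-F against the reference implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(rng.poisson(5, size=(18, 12)).astype(float))
        labels = ["a"] * 6 + ["b"] * 6
        bc = bray_curtis(counts)
        ours = permanova(bc, pd.Series(labels, index=counts.columns), n_perm=99, seed=0)
        dm = skbio.DistanceMatrix(bc.to_numpy(), ids=[str(c) for c in bc.index])
        theirs = skbio.stats.distance.permanova(dm, labels, permutations=99)
        assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_null_calibration_and_planted_separation(self):
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(60):
            counts = pd.DataFrame(rng.poisson(5, size=(25, 24)).astype(float))
            labels = pd.Series(["a", "b", "c"] * 8, index=counts.columns)
            ps.append(permanova(bray_curtis(counts), labels, n_perm=99, seed=rep).p)
        assert 0.40 <= np.mean(ps) <= 0.60
        # strongly separated groups reach the permutation floor
        base = rng.poisson(5, size=(25, 12)).astype(float)
        shifted = base + 30.0
        counts = pd.DataFrame(np.hstack([base, shifted]),
                              columns=[f"g{i}" for i in range(24)])
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=counts.columns)
        res = permanova(bray_curtis(counts), labels, n_perm=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)


class TestDbrda:
    def test_constrained_r2_bounds_and_separation(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(5, size=(25, 10)).astype(float)
        shifted = base + 20.0
        counts = pd.DataFrame(np.hstack([base, shifted]),
                              columns=[f"g{i}" for i in range(20)])
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        res = dbrda(bray_curtis(counts), labels)
        assert 0.5 < res.dbrda_R2 <= 1.0
        assert res.coordinates is not None

    def test_combined_runner(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(5, size=(15, 12)).astype(float))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
        res = permanova_dbrda(bray_curtis(counts), labels, n_perm=99, seed=0)
        assert np.isfinite(res.F) and np.isfinite(res.dbrda_R2)
        assert 1 / 100 <= res.p <= 1.0


class TestGroupComparisons:
    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(0, 1, 60))
        labels = pd.Series(["a", "b", "c"] * 20)
        cmp_ = compare_groups(vals, labels)
        letters = set(cmp_.letters.values())
        assert len(letters) == 1

    def test_shifted_group_gets_unique_letter(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                               rng.normal(9, 1, 30)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        cmp_ = compare_groups(pd.Series(vals), labels)
        assert set(cmp_.letters["c"]).isdisjoint(set(cmp_.letters["a"]))
        assert set(cmp_.letters["a"]) & set(cmp_.letters["b"])

    def test_letters_partition_property(self):
        """Two groups share a letter iff their pairwise q >= alpha."""
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(i * 2.0, 1, 25) for i in range(4)])
        labels = pd.Series(sum([[g] * 25 for g in "abcd"], []))
        cmp_ = compare_groups(pd.Series(vals), labels)
        q = {(r["group_a"], r["group_b"]): r["q"] for _, r in cmp_.pairwise.iterrows()}
        for (a, b), qv in q.items():
            share = bool(set(cmp_.letters[a]) & set(cmp_.letters[b]))
            assert share == (qv >= 0.05), (a, b, qv, cmp_.letters)

    def test_genome_summary_compare(self, small_dataset):
        meta = pd.DataFrame(
            {"genome_size": [r.genome_size for r in small_dataset.records],
             "gc_content": [r.gc_content for r in small_dataset.records]},
            index=[r.genome_id for r in small_dataset.records],
        )
        labels = pd.Series({r.genome_id: r.habitat for r in small_dataset.records})
        out = genome_summary_compare(meta, labels)
        assert set(out) == {"genome_size", "gc_content"}
        for cmp_ in out.values():
            assert set(cmp_.letters) == set(labels.unique())

    def test_single_group_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            compare_groups(vals, pd.Series(["a", "a", "a"]))
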