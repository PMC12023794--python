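"""Phylogenetic linear model: GLS algebra, calibration, FDR, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabcomp import phylo
from fabcomp.enrichment import (
    bh_fdr,
    enrich_all,
    one_vs_rest_design,
    phylolm_fit,
    phylolm_fit_batch,
    standardize_counts,
)
from fabcomp.synthetic import assign_habitats, simulate_bm_traits, simulate_tree


class TestStandardizeCounts:
    def test_hand_computed_zscores(self):
        counts = pd.DataFrame([[0, 0, 4, 4]], index=["g1"], columns=list("abcd"))
        z, excluded = standardize_counts(counts)
        assert np.allclose(z.loc["g1"], [-1, -1, 1, 1])
        assert excluded == []
        z1, _ = standardize_counts(counts, ddof=1)
        assert np.allclose(z1.loc["g1"], np.array([-1, -1, 1, 1]) * np.sqrt(3 / 4))

    def test_constant_gene_excluded(self):
        counts = pd.DataFrame(
            [[3, 3, 3], [1, 2, 3]], index=["flat", "ok"], columns=list("abc")
        )
        z, excluded = standardize_counts(counts)
        assert excluded == ["flat"]
        assert list(z.index) == ["ok"]

    def test_centering_identity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(4, (10, 30)))
        z, _ = standardize_counts(counts)
        assert np.abs(z.mean(axis=1)).max() < 1e-12

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            standardize_counts(pd.DataFrame([[1]], columns=["a"]))


class TestPhyloLMFit:
    def test_star_tree_equals_ols(self):
        """V proportional to I whitens by a scalar: GLS == OLS exactly."""
        rng = np.random.default_rng(1)
        n = 30
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        V = 2.5 * np.eye(n)
        fit = phylolm_fit(y, X, V)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        s2 = resid @ resid / (n - 2)
        se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.beta, beta_ols, atol=1e-10)
        assert np.allclose(fit.se, se_ols, atol=1e-10)

    def test_four_taxon_explicit_matrix_oracle(self, four_taxon_tree):
        """Direct V^-1 arithmetic on the balanced quartet fixture."""
        V = phylo.bm_covariance(four_taxon_tree).loc[list("ABCD"), list("ABCD")]
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        Vinv = np.linalg.inv(V.to_numpy())
        beta_oracle = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        resid = y - X @ beta_oracle
        s2_oracle = (resid @ Vinv @ resid) / (4 - 2)
        se_oracle = np.sqrt(np.diag(s2_oracle * np.linalg.inv(X.T @ Vinv @ X)))
        fit = phylolm_fit(y, X, V.to_numpy())
        assert np.allclose(fit.beta, beta_oracle, atol=1e-10)
        assert np.allclose(fit.se, se_oracle, atol=1e-10)
        assert fit.sigma2 == pytest.approx(s2_oracle)

    def test_batch_matches_single_fits(self):
        tree = simulate_tree(25, seed=5)
        V = phylo.bm_covariance(tree)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((25, 7))
        X = np.column_stack([np.ones(25), rng.integers(0, 2, 25).astype(float)])
        batch = phylolm_fit_batch(Y, X, V.to_numpy())
        for j in range(7):
            fit = phylolm_fit(Y[:, j], X, V.to_numpy())
            assert np.allclose(batch["beta"][:, j], fit.beta, atol=1e-10)
            assert np.allclose(batch["p"][:, j], fit.p, atol=1e-10)

    def test_singular_design_raises(self):
        n = 10
        X = np.ones((n, 2))  # duplicated intercept
        with pytest.raises(ValueError):
            phylolm_fit(np.arange(n, dtype=float), X, np.eye(n))

    def test_type_i_error_controlled_under_clade_confounding(self):
        """BM nulls with clade-confounded labels: GLS calibrated, OLS inflated."""
        tree = simulate_tree(150, seed=11)
        habitats = assign_habitats(tree, 2, "clade_confounded", seed=11)
        V = phylo.bm_covariance(tree)
        genomes = list(V.index)
        Y = simulate_bm_traits(tree, 1.0, 300, seed=3, V=V).loc[genomes].to_numpy()
        Y = (Y - Y.mean(0)) / Y.std(0)
        X = one_vs_rest_design(genomes, habitats, "fungi").to_numpy()
        gls = phylolm_fit_batch(Y, X, V.to_numpy())
        ols = phylolm_fit_batch(Y, X, np.eye(len(genomes)))
        rej_gls = (gls["p"][1] < 0.05).mean()
        rej_ols = (ols["p"][1] < 0.05).mean()
        # 99% binomial band around 0.05 at 300 genes
        assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / 300) <= rej_gls
        assert rej_gls <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 300)
        assert rej_ols > 0.15

    def test_lambda_ml_recovers_boundaries(self):
        """Traits simulated at lambda=1 (BM) and lambda=0 (iid) pick the right end."""
        hits1 = hits0 = 0
        reps = 20
        for seed in range(reps):
            tree = simulate_tree(120, seed=seed + 50)
            V = phylo.bm_covariance(tree)
            n = V.shape[0]
            rng = np.random.default_rng(seed)
            y_bm = simulate_bm_traits(tree, 1.0, 1, seed=seed, V=V).iloc[:, 0]
            y_iid = rng.standard_normal(n)
            X = np.ones((n, 1))
            # "at the boundary" = within one grid step of the truth
            hits1 += phylolm_fit(y_bm, X, V.to_numpy(), lambda_mode="ml").lam >= 0.95
            hits0 += phylolm_fit(y_iid, X, V.to_numpy(), lambda_mode="ml").lam <= 0.05
        assert hits1 >= 0.9 * reps
        assert hits0 >= 0.9 * reps


class TestBhFdr:
    def test_hand_computed_stepup(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_stepup_properties(self, pvals):
        q = bh_fdr(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def planted():
    from fabcomp.synthetic import SimulationConfig, simulate_gene_counts

    tree = simulate_tree(120, seed=77)
    habitats = assign_habitats(tree, 3, "random", seed=77)
    V = phylo.bm_covariance(tree)
    n_genes = 60
    genes = [f"COG{g:04d}" for g in range(1, n_genes + 1)]
    cats = pd.Series(
        ["G"] * 12 + ["N"] * 24 + ["S"] * 24, index=genes, name="category"
    )
    # strong positive fungi effect planted on every category-G gene;
    # counts carry genuine phylogenetic signal matching V
    cfg = SimulationConfig(
        n_tips=120, n_habitats=3, n_genes=n_genes, bm_sigma2=0.2, seed=77,
        effect_table={(g, "fungi"): 1.5 for g in genes[:12]},
    )
    counts, _ = simulate_gene_counts(tree, habitats, cfg)
    return counts, habitats, V, cats


class TestEnrichAll:
    def test_planted_category_cell_detected(self, planted):
        """Poisson sampling noise on top of BM calls for lambda-ML fits."""
        counts, habitats, V, cats = planted
        tables = enrich_all(counts, habitats, V, category_map=cats, lambda_mode="ml")
        assert tables.category_medians.loc["G", "fungi"] > 0
        g_fungi = tables.gene_table.query("habitat == 'fungi' and category == 'G'")
        assert (g_fungi["q"] < 0.05).all()
        null_cells = tables.gene_table.query("habitat != 'fungi' and category == 'S'")
        assert (null_cells["q"] < 0.05).mean() < 0.2

    def test_genome_order_invariance(self, planted):
        counts, habitats, V, cats = planted
        t1 = enrich_all(counts, habitats, V, category_map=cats)
        perm = list(np.random.default_rng(1).permutation(counts.columns))
        t2 = enrich_all(counts[perm], habitats, V.loc[perm, perm], category_map=cats)
        a = t1.gene_table.set_index(["gene", "habitat"]).sort_index()
        b = t2.gene_table.set_index(["gene", "habitat"]).sort_index()
        assert np.allclose(a["beta"], b["beta"], atol=1e-9)
        assert np.allclose(a["q"], b["q"], atol=1e-9)

    def test_unmapped_genes_fall_into_unknown_bucket(self, planted):
        counts, habitats, V, cats = planted
        tables = enrich_all(counts, habitats, V, category_map=cats.iloc[:30])
        assert "Unknown function" in tables.category_medians.index
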