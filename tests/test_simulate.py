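import numpy as np
import pytest

from mihc.phylo_weights import cophenetic_matrix
from mihc.simulate import (DmParams, SimScenario, default_dm_params,
                           estimate_dm, estimate_rejection_rate,
                           generate_dm_counts, generate_phenotype,
                           generate_random_tree, select_associated)


class TestDmParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            DmParams(pi=np.array([0.5, 0.6]), theta=0.1)
        with pytest.raises(ValueError):
            DmParams(pi=np.array([0.5, 0.5]), theta=1.0)

    def test_default_profile_is_constant_and_long_tailed(self):
        a, b = default_dm_params(100), default_dm_params(100)
        np.testing.assert_array_equal(a.pi, b.pi)
        assert a.pi.sum() == pytest.approx(1.0)
        assert (np.diff(a.pi) <= 0).all()            # sorted, abundant first
        assert a.pi[0] / a.pi[-1] > 10               # long tail


class TestEstimateDm:
    def test_multinomial_gives_zero_theta(self):
        params = DmParams(pi=np.full(10, 0.1), theta=0.0)
        counts = generate_dm_counts(params, n=400, depth=2000, seed=1)
        est = estimate_dm(counts)
        assert est.theta < 0.01
        np.testing.assert_allclose(est.pi, 0.1, atol=0.01)

    def test_identical_rows_truncate_to_zero(self):
        counts = np.tile(np.array([10, 20, 30]), (5, 1))
        assert estimate_dm(counts).theta == 0.0

    def test_dispersion_recovery(self):
        """Moment estimator recovers theta = 0.1 within 0.02 at n = 500."""
        true = DmParams(pi=default_dm_params(50).pi, theta=0.10)
        counts = generate_dm_counts(true, n=500, depth=1000, seed=3)
        est = estimate_dm(counts)
        assert abs(est.theta - 0.10) <= 0.02

    def test_single_otu_rejected(self):
        with pytest.raises(ValueError):
            estimate_dm(np.ones((5, 1)))


class TestGenerateCounts:
    def test_row_sums_equal_depth(self):
        counts = generate_dm_counts(default_dm_params(30), n=20, depth=777,
                                    seed=2)
        assert (counts.sum(axis=1) == 777).all()

    def test_deterministic(self):
        p = default_dm_params(20)
        np.testing.assert_array_equal(generate_dm_counts(p, 5, 100, seed=9),
                                      generate_dm_counts(p, 5, 100, seed=9))

    def test_multinomial_column_means(self):
        p = DmParams(pi=np.array([0.5, 0.5]), theta=0.0)
        counts = generate_dm_counts(p, n=5000, depth=1000, seed=4)
        se = np.sqrt(0.5 * 0.5 / 1000 / 5000) * 1000
        assert abs(counts[:, 0].mean() - 500) < 5 * se


class TestRandomTree:
    def test_binary_rooted_arithmetic(self):
        tree = generate_random_tree(25, seed=6)
        leaves = [nd for nd in tree if nd.is_leaf()]
        internal = [nd for nd in tree if not nd.is_leaf()]
        assert len(leaves) == 25
        assert len(internal) == 24
        assert all(len(nd.child_nodes()) == 2 for nd in internal)

    def test_branch_lengths_in_unit_interval(self):
        tree = generate_random_tree(15, seed=7)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert 0.0 < edge.length < 1.0

    def test_four_point_condition(self):
        """Cophenetic distances from the tree are additive: the two largest
        of the three quartet sums coincide."""
        tree = generate_random_tree(12, seed=8)
        D = cophenetic_matrix(tree)
        rng = np.random.default_rng(0)
        for _ in range(30):
            i, j, k, l = rng.choice(12, size=4, replace=False)
            sums = sorted([D[i, j] + D[k, l], D[i, k] + D[j, l],
                           D[i, l] + D[j, k]])
            assert sums[2] - sums[1] < 1e-9


class TestSelectAssociated:
    def test_counts(self):
        assert len(select_associated("random", 0.02, 100, seed=1)) == 2
        assert len(select_associated("random", 1.0, 50, seed=1)) == 50
        assert len(select_associated("random", 0.001, 100, seed=1)) == 1

    def test_phylo_close_nearest_neighbors(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                                 schema="newick")
        D = cophenetic_matrix(tree, ["A", "B", "C", "D"])
        lam = select_associated("phylo_close", 0.5, 4, D=D, seed=0)
        assert len(lam) == 2
        # whatever the anchor, its sibling is the closest neighbor
        assert tuple(lam) in {(0, 1), (2, 3)}

    def test_phylo_close_requires_distances(self):
        with pytest.raises(ValueError, match="cophenetic"):
            select_associated("phylo_close", 0.1, 10, seed=0)


class TestPhenotype:
    def test_null_independent_of_otus(self):
        O = np.random.default_rng(1).dirichlet(np.ones(5), size=50)
        y1, X1 = generate_phenotype(O, [], 0.0, seed=5)
        y2, X2 = generate_phenotype(np.roll(O, 1, axis=0), [], 0.0, seed=5)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(X1, X2)
        assert X1.shape == (50, 3)

    def test_variance_decomposition(self):
        """Var(y) = 0.25 + 0.25 + 1 + beta^2 Var(sum of scaled signals)."""
        rng = np.random.default_rng(2)
        n, beta = 10_000, 0.7
        O = rng.dirichlet(np.ones(20), size=n)
        lam = [0, 3, 7]
        y, _ = generate_phenotype(O, lam, beta, seed=6)
        s = np.zeros(n)
        for j in lam:
            col = O[:, j]
            s += (col - col.mean()) / col.std(ddof=1)
        expect = 0.25 + 0.25 + 1.0 + beta ** 2 * s.var(ddof=1)
        assert y.var(ddof=1) == pytest.approx(expect, rel=0.06)

    def test_constant_column_contributes_zero(self, caplog):
        O = np.full((30, 3), 1.0 / 3)
        O[:, 0] = np.linspace(0.1, 0.5, 30)
        O[:, 2] = 1.0 - O[:, 0] - O[:, 1]
        with caplog.at_level("WARNING"):
            y1, _ = generate_phenotype(O, [1], 2.0, seed=3)
        y0, _ = generate_phenotype(O, [], 0.0, seed=3)
        np.testing.assert_array_equal(y1, y0)
        assert "constant" in caplog.text


class TestRejectionRate:
    def test_alpha_one_rejects_everything(self):
        sc = SimScenario(n=20, m=25, depth=400, beta=0.0)
        r = estimate_rejection_rate(sc, n_reps=2, alpha=1.0, B=100, seed=1,
                                    dm_params=default_dm_params(25))
        assert (r.rates == 1.0).all()

    def test_saturated_power_for_large_effect(self):
        """A huge sparse effect (beta = 5 on 2% of OTUs) is always detected.

        Sparsity matters even in the large-effect limit: as beta grows the
        phenotype becomes proportional to the sum of the associated scaled
        OTUs, so each marginal statistic plateaus at a level set by how many
        OTUs share the effect.  At 2% the plateau is far past any threshold."""
        sc = SimScenario(n=50, m=100, beta=5.0, fraction=0.02, mode="random")
        r = estimate_rejection_rate(sc, n_reps=10, B=200, seed=2)
        assert r.rates["MiHC"] >= 0.9

    def test_pvalue_dump_shape_and_ci(self):
        sc = SimScenario(n=20, m=25, depth=400, beta=0.0)
        r = estimate_rejection_rate(sc, n_reps=3, B=100, seed=3,
                                    dm_params=default_dm_params(25))
        assert r.pvalues.shape == (3, 14)     # 5 uHC + 5 wHC + Simes + 3 omnibus
        lo, hi = r.confidence_interval("MiHC")
        assert 0.0 <= lo <= hi <= 1.0
        frame = r.to_frame()
        assert set(frame.columns) >= {"test", "rate", "ci_low", "ci_high"}

    def test_deterministic(self):
        sc = SimScenario(n=20, m=20, depth=300, beta=0.0)
        a = estimate_rejection_rate(sc, n_reps=2, B=100, seed=5,
                                    dm_params=default_dm_params(20))
        b = estimate_rejection_rate(sc, n_reps=2, B=100, seed=5,
                                    dm_params=default_dm_params(20))
        assert a.pvalues.equals(b.pvalues)

    def test_dm_histogram_fit(self):
        """Counts regenerated from estimated parameters reproduce the pooled
        nonzero relative-abundance distribution (two-sample KS)."""
        from scipy import stats

        src = generate_dm_counts(default_dm_params(60), n=80, depth=1000,
                                 seed=11)
        est = estimate_dm(src)
        rep = generate_dm_counts(est, n=80, depth=1000, seed=12)
        a = (src / 1000.0).ravel()
        b = (rep / 1000.0).ravel()
        assert stats.ks_2samp(a[a > 0], b[b > 0]).pvalue > 0.001
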