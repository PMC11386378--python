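import numpy as np
import pytest
from scipy.spatial.distance import squareform

import granulecology as g
from tests.conftest import relative


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        m = g.CountMatrix(["A", "B"], ["s"], np.array([[6], [4]]))
        out = g.rarefy(m, 10, seed=0)
        assert np.array_equal(out.counts, m.counts)

    def test_single_taxon_forced(self):
        m = g.CountMatrix(["A", "B"], ["s"], np.array([[10], [0]]))
        out = g.rarefy(m, 5, seed=0)
        assert np.array_equal(out.counts[:, 0], [5, 0])

    def test_shallow_sample_dropped_with_warning(self):
        m = g.CountMatrix(["A"], ["s1", "s2"], np.array([[10, 3]]))
        with pytest.warns(UserWarning, match="s2"):
            out = g.rarefy(m, 5, seed=0)
        assert out.sample_ids == ["s1"]

    def test_mean_matches_hypergeometric_expectation(self):
        counts = np.array([[50], [30], [20]])
        m = g.CountMatrix(["A", "B", "C"], ["s"], counts)
        draws = np.array(
            [g.rarefy(m, 40, seed=k).counts[:, 0] for k in range(200)]
        )
        total = 100
        expect = 40 * counts[:, 0] / total
        var = (40 * (counts[:, 0] / total) * (1 - counts[:, 0] / total)
               * (total - 40) / (total - 1))
        se = np.sqrt(var / 200)
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se)


class TestAlphaMetrics:
    def test_chao1_bias_corrected_formula(self):
        # S_obs=10, F1=4 singletons, F2=2 doubletons -> 10 + 4*3/(2*3) = 12
        col = [1, 1, 1, 1, 2, 2, 3, 3, 3, 3]
        assert g.chao1(col) == pytest.approx(12.0)

    def test_chao1_no_singletons_is_richness(self):
        assert g.chao1([2, 2, 5]) == pytest.approx(3.0)

    def test_chao1_no_doubletons(self):
        # S_obs=5, F1=3, F2=0 -> 5 + 3*2/2 = 8
        assert g.chao1([1, 1, 1, 3, 4]) == pytest.approx(8.0)

    def test_shannon_uniform_maximum(self):
        assert g.shannon([1] * 8) == pytest.approx(np.log(8))

    def test_shannon_single_taxon_zero(self):
        assert g.shannon([5, 0, 0]) == pytest.approx(0.0)

    def test_shannon_mixed(self):
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert g.shannon([1, 1, 2]) == pytest.approx(expected)

    def test_shannon_zero_column_rejected(self):
        with pytest.raises(ValueError):
            g.shannon([0, 0])


class TestGroupAnova:
    def test_star_convention(self):
        assert g.stars(0.004) == "**"
        assert g.stars(0.04) == "*"
        assert g.stars(0.0004) == "***"
        assert g.stars(0.2) == ""

    def test_degenerate_equal_groups(self):
        p, table = g.group_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert p == pytest.approx(1.0)
        assert (table["p"] == 1.0).all()

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        p, table = g.group_anova(vals, ["a"] * 10 + ["b"] * 10)
        assert p < 0.001
        assert table.loc[0, "stars"] == "***"

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            g.group_anova([1, 2, 3], ["a", "a", "a"])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        r = relative([[1, 1], [3, 3]])
        assert np.allclose(g.bray_curtis(r), [[0, 0], [0, 0]])

    def test_disjoint_supports_one(self):
        r = relative([[1, 0], [0, 1]])
        d = g.bray_curtis(r)
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        r = relative([[0.2, 0.5], [0.8, 0.5]])
        assert g.bray_curtis(r)[0, 1] == pytest.approx(0.3)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(1)
        r = relative(rng.lognormal(0, 1, (30, 10)))
        d = g.bray_curtis(r)
        assert d.min() >= 0 and d.max() <= 1
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestPcoa:
    def test_equilateral_triangle_two_equal_axes(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = g.pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[0] > 0

    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 2.5, 4.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = g.pcoa(d)
        recon = np.abs(res.coordinates[:, 0][:, None]
                       - res.coordinates[:, 0][None, :])
        assert np.allclose(recon, d, atol=1e-8)

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
        res = g.pcoa(d)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(2)
        r = relative(rng.lognormal(0, 1, (20, 8)))
        d = g.bray_curtis(r)
        mine = g.pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d))
        k = min(3, mine.coordinates.shape[1])
        assert np.allclose(
            np.sort(mine.eigenvalues[:k]),
            np.sort(ref.eigvals.to_numpy()[:k][::-1]),
            atol=1e-8,
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            g.pcoa(np.array([[0, 1], [2, 0]], dtype=float))


class TestPermanova:
    def test_separated_blocks_hit_floor(self):
        # 8+8 so that label permutations recreating the block partition
        # (which tie the observed F) are rarer than 1/n_perm
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.01, (8, 5)) + np.array([10, 0, 0, 0, 0])
        b = rng.normal(0, 0.01, (8, 5)) + np.array([0, 10, 0, 0, 0])
        pts = np.vstack([a, b])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        f, p = g.permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        r = relative(rng.lognormal(0, 1, (20, 12)))
        d = g.bray_curtis(r)
        groups = np.array(["a", "b", "c"] * 4)
        f1, _ = g.permanova(d, groups, n_perm=99, seed=0)
        perm = rng.permutation(12)
        f2, _ = g.permanova(d[np.ix_(perm, perm)], groups[perm],
                            n_perm=99, seed=0)
        assert f1 == pytest.approx(f2)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(5)
        r = relative(rng.lognormal(0, 1, (25, 12)))
        d = g.bray_curtis(r)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        f, _ = g.permanova(d, groups, n_perm=99, seed=0)
        ref = skbio_permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(12)]), list(groups),
            permutations=99,
        )
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_all_singletons_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            g.permanova(d, ["a", "b", "c"], n_perm=99, seed=0)
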