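from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.stats.distance import anosim as skbio_anosim

from deepamend import (
    RelativeAbundanceTable,
    ValidationError,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    one_way_anova,
    simper,
    variance_ratio_test,
)
from tests.conftest import random_relative_table


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0, 3], [0, 2, 0]) == 1.0

    def test_hand_example(self):
        assert bray_curtis([1, 0, 3], [0, 2, 1]) == pytest.approx(5 / 7)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            u, v = rng.gamma(1.0, size=(2, 12))
            assert bray_curtis(u, v) == pytest.approx(scipy_braycurtis(u, v))

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_is_symmetric_zero_diagonal_unit_interval(self):
        rng = np.random.default_rng(1)
        dm = bray_curtis_matrix(random_relative_table(rng, 10, 8))
        d = dm.data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestAnosim:
    def _separated_matrix(self):
        # two tight clusters: every between distance exceeds every within distance
        d = np.full((6, 6), 0.9)
        for i, j in combinations(range(3), 2):
            d[i, j] = d[j, i] = 0.1
            d[i + 3, j + 3] = d[j + 3, i + 3] = 0.1
        np.fill_diagonal(d, 0)
        return d

    def test_perfect_separation_gives_r_of_one(self):
        res = anosim(self._separated_matrix(), ["a"] * 3 + ["b"] * 3)
        assert res.R == pytest.approx(1.0)

    def test_constant_distances_give_r_of_zero(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0)
        res = anosim(d, ["a"] * 3 + ["b"] * 3)
        assert res.R == pytest.approx(0.0)

    def test_exhaustive_p_matches_manual_enumeration(self):
        # 6 samples, 2 groups of 3: 20 distinct relabelings
        rng = np.random.default_rng(5)
        x = rng.gamma(1.0, size=(6, 5))
        dm = bray_curtis_matrix(
            RelativeAbundanceTable(
                pd.DataFrame(
                    x / x.sum(1, keepdims=True), index=[f"s{i}" for i in range(6)]
                )
            )
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = anosim(dm, labels)
        assert res.exhaustive and res.n_permutations == 20

        # independent oracle: rank once, enumerate all C(6,3) relabelings
        d = dm.data
        ii, jj = np.triu_indices(6, k=1)
        ranks = sps.rankdata(d[ii, jj])

        def r_stat(lab):
            within = lab[ii] == lab[jj]
            return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)

        r_obs = r_stat(labels)
        r_all = []
        for grp_a in combinations(range(6), 3):
            lab = np.ones(6, dtype=int)
            lab[list(grp_a)] = 0
            r_all.append(r_stat(lab))
        p_expected = sum(r >= r_obs - 1e-12 for r in r_all) / len(r_all)
        assert res.R == pytest.approx(r_obs)
        assert res.p == pytest.approx(p_expected)

    def test_r_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        dm = bray_curtis_matrix(random_relative_table(rng, 12, 8))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = anosim(dm, groups, seed=0, exhaustive_limit=0)
        ref = skbio_anosim(dm, grouping=groups, permutations=99)
        assert mine.R == pytest.approx(ref["test statistic"])

    def test_group_of_one_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            anosim(d, ["a", "a", "b"])

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        dm = bray_curtis_matrix(random_relative_table(rng, 14, 6))
        groups = ["a"] * 7 + ["b"] * 7
        r1 = anosim(dm, groups, seed=11)
        r2 = anosim(dm, groups, seed=11)
        assert (r1.R, r1.p) == (r2.R, r2.p)


class TestSimper:
    def test_duplicated_samples_give_zero_dissimilarity(self):
        row = np.array([0.5, 0.3, 0.2])
        rel = RelativeAbundanceTable(
            pd.DataFrame([row, row, row, row], index=list("abcd"))
        )
        res = simper(rel, ["g1", "g1", "g2", "g2"])
        assert res.overall_dissimilarity == 0.0
        assert np.allclose(res.contributions, 0.0)

    def test_decomposition_identity_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rel = random_relative_table(rng, 8, 10)
            groups = ["a"] * 4 + ["b"] * 4
            res = simper(rel, groups)
            d = bray_curtis_matrix(rel).data
            between = d[np.ix_(range(4), range(4, 8))].mean()
            assert res.contributions.sum() == pytest.approx(between, abs=1e-9)
            assert res.table["percent"].sum() == pytest.approx(100, abs=1e-6)

    def test_hand_computed_two_by_two(self):
        rel = RelativeAbundanceTable(
            pd.DataFrame(
                [[0.6, 0.4], [0.5, 0.5], [0.2, 0.8], [0.1, 0.9]],
                index=list("abcd"),
                columns=["x", "y"],
            )
        )
        res = simper(rel, ["g1", "g1", "g2", "g2"])
        # four between pairs, each with denominator 2 (rows sum to 1)
        exp_x = (0.4 + 0.5 + 0.3 + 0.4) / 4 / 2
        exp_y = exp_x  # two-part compositions are symmetric
        assert res.contributions == pytest.approx([exp_x, exp_y])

    def test_multi_group_dispatches_all_pairs(self):
        rng = np.random.default_rng(2)
        rel = random_relative_table(rng, 9, 5)
        out = simper(rel, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(2)
        rel = random_relative_table(rng, 4, 5)
        with pytest.raises(ValidationError):
            simper(rel, ["a", "a", "a", "a"])


class TestAnova:
    def test_hand_computed_example(self):
        f, p = one_way_anova([1, 2, 3, 7, 8, 9], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(54.0)
        assert p < 0.01

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        f, p = one_way_anova(x, groups)
        ref = sps.f_oneway(x[:5], x[5:10], x[10:])
        assert f == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_null_draw_is_insignificant(self):
        rng = np.random.default_rng(123)
        x = np.concatenate([rng.normal(size=10), rng.normal(size=10)])
        f, p = one_way_anova(x, ["a"] * 10 + ["b"] * 10)
        assert p > 0.05

    def test_p_uniform_under_null(self):
        # 1,000 null datasets; KS test against Uniform(0,1) at alpha = 0.01
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=18)
            pvals.append(one_way_anova(x, ["a", "b", "c"] * 6)[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([1, 1, 1, 1], ["a", "a", "b", "b"])


class TestVarianceRatio:
    def test_identical_samples(self):
        f, p = variance_ratio_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert f == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_scale_property(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        f1, _ = variance_ratio_test(x, y)
        f2, _ = variance_ratio_test(3 * x, y)
        assert f2 == pytest.approx(9 * f1)

    def test_rejection_rate_matches_analytic_power(self):
        # variance ratio 4, n = 30 per sample, alpha = 0.05, 500 replicates
        n, ratio, alpha = 30, 4.0, 0.05
        f_hi = sps.f.ppf(1 - alpha / 2, n - 1, n - 1)
        f_lo = sps.f.ppf(alpha / 2, n - 1, n - 1)
        power = sps.f.sf(f_hi / ratio, n - 1, n - 1) + sps.f.cdf(
            f_lo / ratio, n - 1, n - 1
        )
        rng = np.random.default_rng(15)
        rejections = 0
        for _ in range(500):
            x = rng.normal(scale=2.0, size=n)
            y = rng.normal(scale=1.0, size=n)
            rejections += variance_ratio_test(x, y)[1] < alpha
        assert abs(rejections / 500 - power) < 0.05

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValidationError):
            variance_ratio_test([1.0, 2.0], [3.0, 3.0])
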