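"""Rank-test checks: Kruskal-Wallis, Dunn's post-hoc, selection, Spearman."""

import numpy as np
import pytest
from scipy import stats as sps

from vmdoc.features import FeatureTable
from vmdoc.stats import (dunn_posthoc, kruskal_wallis, select_features,
                         spearman_corr)


def make_table(values, labels, crs_r=None, gcs=None):
    values = np.asarray(values, float)
    return FeatureTable(values=values,
                        feature_names=[f"f{i}" for i in range(values.shape[1])],
                        labels=list(labels),
                        subject_ids=[f"s{i}" for i in range(values.shape[0])],
                        crs_r=crs_r, gcs=gcs)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # mean ranks 2, 5, 8; H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2)
        assert h == pytest.approx(7.2, abs=1e-9)
        assert 0 < p < 0.05

    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([[1, 2, 3]] * 3)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_constant_data(self):
        assert kruskal_wallis([[2, 2], [2, 2]]) == (0.0, 1.0)

    def test_two_groups_equal_rank_sum_oracle(self, rng):
        # no ties: H equals the squared standardized Mann-Whitney statistic
        x = rng.permutation(20)[:8].astype(float)
        y = rng.permutation(40)[20:32].astype(float) + 0.5
        h, _ = kruskal_wallis([x, y])
        n1, n2 = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        r1 = ranks[:n1].sum()
        u = r1 - n1 * (n1 + 1) / 2
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z ** 2, rel=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(loc, 1, 10) for loc in (0, 1, 2)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunnPosthoc:
    def test_extreme_pair_has_smallest_p(self):
        p = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert p[(0, 2)] == min(p.values())

    def test_identical_pair_z_zero(self):
        p = dunn_posthoc([[1, 2, 3], [1, 2, 3], [10, 11, 12]])
        assert p[(0, 1)] == pytest.approx(1.0)

    def test_bonferroni_never_smaller(self):
        groups = [[1, 2, 3], [2, 3, 5], [7, 8, 9]]
        raw = dunn_posthoc(groups)
        adj = dunn_posthoc(groups, adjust="bonferroni")
        for pair in raw:
            assert adj[pair] >= raw[pair] - 1e-15
            assert adj[pair] <= 1.0

    def test_against_permutation_oracle(self):
        # seeded permutation distribution of the mean-rank difference
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 6), rng.normal(0.8, 1, 6), rng.normal(2.0, 1, 6)]
        p_dunn = dunn_posthoc(groups)[(0, 1)]
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        obs = abs(ranks[:6].mean() - ranks[6:12].mean())
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm = rng.permutation(ranks)
            if abs(perm[:6].mean() - perm[6:12].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_dunn == pytest.approx(p_perm, abs=0.08)


class TestSelectFeatures:
    def test_null_noise_selection_near_alpha(self):
        rng = np.random.default_rng(99)
        n_feat = 200
        table = make_table(rng.standard_normal((45, n_feat)),
                           ["coma"] * 15 + ["UWS"] * 15 + ["MCS"] * 15)
        res = select_features(table, alpha=0.05)
        rate = res.n_selected / n_feat
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_feat)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_strong_effect_selected(self, rng):
        base = rng.standard_normal((45, 3))
        base[15:30, 0] += 2.0
        base[30:, 0] += 4.0
        table = make_table(base, ["coma"] * 15 + ["UWS"] * 15 + ["MCS"] * 15)
        res = select_features(table)
        assert res.selected[0]

    def test_alpha_zero_selects_nothing(self, rng):
        table = make_table(rng.standard_normal((30, 10)),
                           ["UWS"] * 15 + ["MCS"] * 15)
        assert select_features(table, alpha=0.0).n_selected == 0

    def test_small_class_raises(self, rng):
        table = make_table(rng.standard_normal((4, 3)),
                           ["UWS", "UWS", "UWS", "MCS"])
        with pytest.raises(ValueError, match="< 2 subjects"):
            select_features(table)

    def test_spearman_attached_for_selected(self, rng):
        vals = rng.standard_normal((45, 2))
        vals[:, 0] += np.repeat([0.0, 2.0, 4.0], 15)
        crs = np.repeat([1.0, 5.0, 15.0], 15) + rng.uniform(0, 1, 45)
        table = make_table(vals, ["coma"] * 15 + ["UWS"] * 15 + ["MCS"] * 15,
                           crs_r=crs, gcs=crs)
        res = select_features(table)
        name = res.selected_names[0]
        assert name in res.rho_crsr and abs(res.rho_crsr[name]) > 0.5
        assert name in res.dunn_p and len(res.dunn_p[name]) == 3


class TestScoreCorrelations:
    def test_selected_vmd_features_correlate_moderately_with_crsr(self, protocol_result):
        # on the default cohort most selected features should show the
        # moderate |rho| vs CRS-R typical of EEG markers
        assert protocol_result["vmd_rho_in_band"] >= 0.40


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_rank_formula_example(self):
        rho, _ = spearman_corr([1, 2, 3, 4, 5], [5, 6, 4, 8, 7])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert spearman_corr(x, -y)[0] == pytest.approx(-spearman_corr(x, y)[0])

    def test_zero_variance_sentinel(self):
        rho, p = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)
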