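"""Univariate tests, BH adjustment, volcano calls, OPLS-DA VIP, AUC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmpanel import diff_stats as ds
from prmpanel.diff_stats import (
    VolcanoThresholds,
    autoscale,
    benjamini_hochberg,
    fold_change,
    mann_whitney_u,
    opls_da,
    univariate_auc,
    volcano_classify,
    welch_t_test,
)


def mw_exact_p_enumeration(x, y):
    """Oracle: two-sided exact P by enumerating all group relabelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(sample_x, sample_y):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in sample_x for b in sample_y
        )

    u_obs = u_of(x, y)
    n0 = len(y)
    mean_u = n1 * n0 / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.100, abs=1e-12)

    def test_identical_multisets(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n0 = rng.integers(2, 7), rng.integers(2, 7)
            # distinct values: stay in the exact regime
            vals = rng.permutation(100)[: n1 + n0].astype(float)
            x, y = vals[:n1], vals[n1:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mw_exact_p_enumeration(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(1, 1, size=25)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_both_groups_flagged(self):
        res = welch_t_test([2, 2, 2], [5, 5, 5])
        assert res.degenerate
        assert res.p == 1.0

    def test_null_type_i_error(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1000, 15))
        y = rng.normal(size=(1000, 15))
        from scipy.stats import ttest_ind

        p = ttest_ind(x, y, axis=1, equal_var=False).pvalue
        # consistency of our wrapper with the vectorized call on one row
        assert welch_t_test(x[0], y[0]).p == pytest.approx(p[0])
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(3.0, 1.0, size=20)
        y = rng.normal(0.0, 1.0, size=20)
        assert welch_t_test(x, y).p < 1e-6


def bh_stepup_oracle(p):
    """Direct step-up definition: q(i) = min_{j>=i} m p(j)/j on sorted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q_sorted, 0, 1)
    return out


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_stepup_oracle(p), atol=1e-12
            )

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(6)
        p = rng.random(25)
        perm = rng.permutation(25)
        adjusted = benjamini_hochberg(p)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), adjusted[perm])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_values_monotone_in_raw_p(self, p):
        adj = benjamini_hochberg(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestFoldChange:
    def test_mean_ratio(self):
        fc, l2 = fold_change([3.0, 3.0], [1.5, 1.5])
        assert fc == pytest.approx(2.0)
        assert l2 == pytest.approx(1.0)

    def test_equal_groups(self):
        fc, l2 = fold_change([2, 4], [4, 2])
        assert fc == pytest.approx(1.0)
        assert l2 == pytest.approx(0.0)

    def test_reciprocity(self):
        rng = np.random.default_rng(7)
        x, y = rng.lognormal(size=20), rng.lognormal(size=20)
        fc_xy, _ = fold_change(x, y)
        fc_yx, _ = fold_change(y, x)
        assert fc_xy * fc_yx == pytest.approx(1.0, rel=1e-12)

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0])


class TestVolcano:
    def test_hand_classified_table(self):
        table = pd.DataFrame(
            {
                "log2_fc": [0.9, 0.3, -0.7, -0.5, 1.2, 0.0],
                "p": [0.001, 0.0001, 0.002, 0.2, 0.06, 0.5],
                "adj_p": [0.01, 0.001, 0.02, 0.4, 0.12, 0.7],
            },
            index=[f"F{i}" for i in range(6)],
        )
        serum = volcano_classify(table, VolcanoThresholds.serum())
        assert list(serum) == ["up", "ns", "down", "ns", "ns", "ns"]
        tissue = volcano_classify(table, VolcanoThresholds.tissue())
        assert list(tissue) == ["ns", "ns", "ns", "ns", "ns", "ns"]
        # tissue cutoff |log2FC| >= 1 with raw p: only F4 passes FC but p=0.06
        table.loc["F4", "p"] = 0.01
        assert volcano_classify(table, VolcanoThresholds.tissue())["F4"] == "up"

    def test_serum_cutoff_is_1p5_fold(self):
        assert VolcanoThresholds.serum().log2_fc_cutoff == pytest.approx(0.585, abs=5e-4)
        assert VolcanoThresholds.serum().neg_log10_p_cutoff == pytest.approx(1.301, abs=5e-4)


class TestOplsDa:
    @staticmethod
    def _planted(n=60, p=10, d=2.0, seed=8):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        X = rng.standard_normal((n, p))
        X[y == 1, 0] += d
        Xs, _, _ = autoscale(X)
        return Xs, y

    def test_informative_column_attains_max_vip(self):
        Xs, y = self._planted()
        model = opls_da(Xs, y, n_orthogonal=1)
        assert int(np.argmax(model.vip)) == 0
        assert model.vip[0] > 1.0

    def test_duplicated_columns_share_vip(self):
        Xs, y = self._planted()
        Xdup = np.hstack([Xs, Xs[:, [0]]])
        model = opls_da(Xdup, y, n_orthogonal=1)
        assert model.vip[0] == pytest.approx(model.vip[-1], abs=1e-9)

    def test_vip_squared_mean_is_one(self):
        Xs, y = self._planted(p=17)
        for n_ortho in (0, 1, 2):
            model = opls_da(Xs, y, n_orthogonal=n_ortho)
            assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-6)

    def test_zero_orthogonal_reduces_to_pls1_vip(self):
        Xs, y = self._planted(p=6)
        model = opls_da(Xs, y, n_orthogonal=0)
        w = Xs.T @ (y - y.mean())
        w /= np.linalg.norm(w)
        vip_oracle = np.sqrt(6) * np.abs(w)
        np.testing.assert_allclose(model.vip, vip_oracle, atol=1e-10)

    def test_single_class_rejected(self):
        Xs, _ = self._planted()
        with pytest.raises(ValueError):
            opls_da(Xs, np.ones(Xs.shape[0]))

    def test_constant_column_removed_with_warning(self):
        Xs, y = self._planted()
        Xc = Xs.copy()
        Xc[:, 3] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            model = opls_da(Xc, y)
        assert model.vip[3] == 0.0


class TestUnivariateAuc:
    def test_perfect_separation(self):
        assert univariate_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties(self):
        assert univariate_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            v = rng.integers(0, 6, size=n).astype(float)  # force ties
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            pos, neg = v[y], v[~y]
            brute = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in pos for b in neg
            ])
            assert univariate_auc(v, y) == pytest.approx(brute, abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=40)
        y = rng.integers(0, 2, size=40).astype(bool)
        assert univariate_auc(v, y) + univariate_auc(-v, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_auc([1, 2], [1, 1])


class TestFeatureStatsTable:
    def test_columns_and_consistency(self):
        from prmpanel import pipeline, prm_quant, syndata

        cfg = syndata.SynConfig(
            n_features=20, n_proteins=16, group_sizes={"NC": 25, "UR": 13, "R": 12},
            n_batches=2, qc_per_batch=2, n_heavy_refs=4,
            planted_ia={"F010": 1.5}, seed=21,
        )
        matrix, _, _ = syndata.generate_cohort(cfg)
        norm = prm_quant.normalize_two_step(prm_quant.log10_transform(matrix))
        labels = pipeline.contrast_labels(norm.sample_meta, "IA_vs_NC")
        stats = ds.compute_feature_stats(
            norm.light[labels.index], labels, protein_of=norm.feature_meta["protein"]
        )
        assert {"protein", "fc", "log2_fc", "p", "vip", "auc", "adj_p", "direction"} <= set(stats.columns)
        assert np.all(stats["adj_p"] >= stats["p"] - 1e-15)
        assert np.all((stats["auc"] >= 0) & (stats["auc"] <= 1))
        np.testing.assert_allclose(stats["log2_fc"], np.log2(stats["fc"]), atol=1e-12)
        assert np.mean(stats["vip"] ** 2) == pytest.approx(1.0, abs=1e-6)
        # the planted feature should dominate
        assert stats.loc["F010", "p"] == stats["p"].min()
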