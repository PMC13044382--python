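"""Descriptives, symptom importance, outcome regressions, EM, MCAR test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import panelnet as pn
from panelnet.clinical import em_mvnorm
from tests.conftest import panel_from_items


class TestDescriptives:
    def test_two_point_arithmetic(self):
        # totals (2, 4) pre and (1, 3) post: mean diff 1, pooled sd sqrt(2)
        pre = np.zeros((2, 20), int)
        pre[0, 0], pre[0, 1] = 1, 1
        pre[1, :4] = 1
        post = np.zeros((2, 20), int)
        post[0, 0] = 1
        post[1, :3] = 1
        panel = panel_from_items(pre, post)
        d = pn.descriptives(panel)
        assert d["total_pre_mean"] == 3.0
        assert d["paired_d_ptss"] == pytest.approx(1 / np.sqrt(2))

    def test_identical_waves_zero_effect(self, small_panel):
        same = panel_from_items(small_panel.items_pre, small_panel.items_pre)
        d = pn.descriptives(same)
        assert d["paired_d_ptss"] == 0
        assert d["variability_t"] == 0

    def test_positive_shift_gives_positive_d(self):
        hits = 0
        for seed in range(20):
            truth = pn.make_ground_truth(seed=seed)
            panel = pn.simulate_panel(truth, n=652, seed=seed + 3000)
            hits += pn.descriptives(panel)["paired_d_ptss"] > 0
        assert hits == 20

    def test_change_score_conservation(self, default_panel):
        """Summed per-symptom changes equal the change in totals, exactly."""
        change = default_panel.items_post - default_panel.items_pre
        assert np.array_equal(
            change.sum(axis=1),
            default_panel.totals("post") - default_panel.totals("pre"))


class TestSymptomImportance:
    def test_two_symptom_symmetry(self):
        rng = np.random.default_rng(0)
        pre = rng.integers(0, 5, (100, 3))
        post = rng.integers(0, 5, (100, 3))
        tab = pn.symptom_importance(panel_from_items(pre, post))
        # p=2 case embedded: correlation of s with the single remaining
        # change is symmetric; with 3 nodes just check validity instead
        assert len(tab) == 3
        assert tab["importance_r"].between(-1, 1).all()

    def test_common_factor_gives_high_importance(self):
        rng = np.random.default_rng(1)
        n = 400
        factor = rng.standard_normal(n)
        pre = np.full((n, 20), 2, dtype=int)
        post = np.clip(np.round(2 + factor[:, None]
                                + 0.25 * rng.standard_normal((n, 20))), 0, 4).astype(int)
        tab = pn.symptom_importance(panel_from_items(pre, post))
        assert (tab["importance_r"] > 0.8).all()

    def test_independent_symptom_has_null_importance(self):
        rng = np.random.default_rng(2)
        n = 2000
        factor = rng.standard_normal(n)
        post = np.clip(np.round(2 + factor[:, None]
                                + 0.3 * rng.standard_normal((n, 20))), 0, 4).astype(int)
        post[:, 0] = rng.integers(0, 5, n)  # decoupled symptom
        pre = np.full((n, 20), 2, dtype=int)
        tab = pn.symptom_importance(panel_from_items(pre, post))
        assert abs(tab["importance_r"].iloc[0]) < 3 / np.sqrt(n)

    def test_zero_variance_change_warns(self):
        pre = np.full((50, 20), 2, dtype=int)
        post = pre.copy()
        post[:, 1:] += np.random.default_rng(0).integers(-1, 2, (50, 19))
        post = np.clip(post, 0, 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            tab = pn.symptom_importance(panel_from_items(pre, post))
        assert np.isnan(tab["importance_r"].iloc[0])

    def test_ordering_invariance(self, default_panel):
        tab = pn.symptom_importance(default_panel)
        perm = np.random.default_rng(3).permutation(20)
        shuffled = dataclasses.replace(
            default_panel,
            items_pre=default_panel.items_pre[:, perm],
            items_post=default_panel.items_post[:, perm],
            node_labels=tuple(default_panel.node_labels[i] for i in perm))
        tab2 = pn.symptom_importance(shuffled)
        merged = tab.merge(tab2, on="node", suffixes=("_a", "_b"))
        assert np.allclose(merged["importance_r_a"], merged["importance_r_b"])


class TestImportanceRegression:
    def test_exact_linear_construction(self):
        """importance built as 0.1 + 0.07 * EI_z recovers B = 0.07 exactly."""
        rng = np.random.default_rng(4)
        ei_z = pn.zscore(rng.standard_normal(20))
        tab = pd.DataFrame({
            "node": [f"V{i}" for i in range(20)],
            "baseline_mean": rng.uniform(0.5, 2.5, 20),
            "importance_r": 0.1 + 0.07 * ei_z,
            "ei_z": ei_z,
        })
        rep = pn.centrality_importance_regression(tab, "ei_z")
        assert rep.coef("ei_z") == pytest.approx(0.07, abs=1e-10)
        assert rep.coef("baseline_mean") == pytest.approx(0.0, abs=1e-10)

    def test_shuffled_centrality_is_null(self, default_panel):
        net = pn.estimate_network(default_panel, "pre")
        ei_z = pn.expected_influence(net).ei_z
        tab = pn.symptom_importance(default_panel, {"ei_z": ei_z})
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            t2 = tab.copy()
            t2["ei_z"] = rng.permutation(t2["ei_z"].to_numpy())
            rep = pn.centrality_importance_regression(t2, "ei_z")
            tval = rep.table.loc[rep.table["term"] == "ei_z", "t"].iloc[0]
            hits += abs(tval) < 2
        assert hits >= 45

    def test_collinear_predictors_rejected(self):
        tab = pd.DataFrame({
            "node": [f"V{i}" for i in range(20)],
            "baseline_mean": np.arange(20.0),
            "importance_r": np.random.default_rng(0).uniform(0, 1, 20),
            "ei_z": np.arange(20.0),  # duplicate of severity
        })
        with pytest.raises(ValueError, match="collinear"):
            pn.centrality_importance_regression(tab, "ei_z")


class TestOutcomeRegression:
    def test_fiml_equals_ols_without_missingness(self):
        truth = pn.make_ground_truth(
            seed=2, missing_rate={"rate_pre": 0, "rate_post": 0})
        panel = pn.simulate_panel(truth, n=400, seed=2)
        ols = pn.core_peripheral_outcome_regression(panel, truth.central_mask,
                                                    "ols_complete")
        em = pn.core_peripheral_outcome_regression(panel, truth.central_mask,
                                                   "fiml_em", n_boot_se=20, seed=0)
        assert np.allclose(ols.table["B"], em.table["B"], atol=1e-6)
        assert em.estimator == "fiml_em"

    def test_flag_requirements(self, default_panel):
        with pytest.raises(ValueError, match="central"):
            pn.core_peripheral_outcome_regression(
                default_panel, np.zeros(20, bool), "ols_complete")
        with pytest.raises(ValueError, match="central"):
            pn.core_peripheral_outcome_regression(
                default_panel, np.ones(20, bool), "ols_complete")

    def test_report_invariants(self, default_panel, default_truth):
        rep = pn.core_peripheral_outcome_regression(
            default_panel, default_truth.central_mask, "fiml_em",
            n_boot_se=25, seed=3)
        t = rep.table
        assert np.allclose(t["t"], t["B"] / t["SE"])
        assert rep.n_used == default_panel.n
        # reproducibility of bootstrap SEs
        rep2 = pn.core_peripheral_outcome_regression(
            default_panel, default_truth.central_mask, "fiml_em",
            n_boot_se=25, seed=3)
        assert np.array_equal(rep.table["SE"], rep2.table["SE"])


class TestEmMvnorm:
    def test_complete_data_matches_sample_moments(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 4))
        mu, Sigma, ll, n_iter = em_mvnorm(X)
        assert np.allclose(mu, X.mean(0))
        assert np.allclose(Sigma, np.cov(X.T, bias=True), atol=1e-8)

    def test_recovers_under_mcar(self):
        rng = np.random.default_rng(1)
        C = np.array([[1, .6, .3], [.6, 1, .4], [.3, .4, 1.]])
        X = rng.multivariate_normal([0, 1, 2], C, size=4000)
        mask = rng.random(X.shape) < 0.3
        mask[:, 0] = False
        Xm = X.copy()
        Xm[mask] = np.nan
        mu, Sigma, _, _ = em_mvnorm(Xm)
        assert np.abs(mu - [0, 1, 2]).max() < 0.1
        assert np.abs(Sigma - C).max() < 0.12


class TestLittleMcar:
    def test_single_pattern_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        with pytest.raises(ValueError, match="patterns"):
            pn.little_mcar_test(X)

    def test_df_formula(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 4))
        X[:100, 1] = np.nan  # two patterns: full (4 obs) and missing-one (3)
        res = pn.little_mcar_test(X)
        assert res["df"] == (4 + 3) - 4
        assert res["n_patterns"] == 2

    def test_mnar_detected(self):
        rng = np.random.default_rng(3)
        C = np.array([[1, .5], [.5, 1.]])
        X = rng.multivariate_normal([0, 0], C, size=1000)
        miss = rng.random(1000) < 1 / (1 + np.exp(-2.5 * X[:, 1]))
        X[miss, 1] = np.nan
        res = pn.little_mcar_test(X)
        assert res["p"] < 0.05
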