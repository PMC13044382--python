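"""Generator: determinism, limiting cases, marginal fidelity, MAR structure."""

import dataclasses

import numpy as np
import pytest

import panelnet as pn
from panelnet.synthetic import simulate_panel


def test_ground_truth_deterministic():
    a = pn.make_ground_truth(p=20, edge_density=0.2, seed=1)
    b = pn.make_ground_truth(p=20, edge_density=0.2, seed=1)
    assert np.array_equal(a.precision_pre, b.precision_pre)
    assert np.array_equal(a.lagged, b.lagged)
    iu = np.triu_indices(20, 1)
    nz = a.partials_pre[iu][a.partials_pre[iu] != 0]
    assert np.mean(np.abs(nz)) == np.mean(np.abs(b.partials_pre[iu][b.partials_pre[iu] != 0]))


def test_empty_graph_limit():
    truth = pn.make_ground_truth(p=20, edge_density=0.0, seed=3)
    off = truth.partials_pre[np.triu_indices(20, 1)]
    assert np.all(off == 0)


def test_zero_crosslag_sd_gives_diagonal_transition():
    truth = pn.make_ground_truth(crosslag_sd=0.0, seed=5)
    assert np.array_equal(truth.lagged, np.diag(np.diag(truth.lagged)))


def test_partials_match_precision_definition():
    truth = pn.make_ground_truth(seed=2)
    K = truth.precision_pre
    d = np.sqrt(np.diag(K))
    expected = -K / np.outer(d, d)
    np.fill_diagonal(expected, 0)
    assert np.allclose(truth.partials_pre, expected)
    assert np.linalg.eigvalsh(K).min() > 0
    assert np.all(np.diff(truth.thresholds, axis=1) > 0)


def test_panel_bit_identical_for_fixed_seed(default_truth):
    a = simulate_panel(default_truth, n=120, seed=9)
    b = simulate_panel(default_truth, n=120, seed=9)
    assert np.array_equal(a.items_pre, b.items_pre)
    assert np.array_equal(a.items_post, b.items_post)
    assert np.array_equal(a.age, b.age)
    assert np.array_equal(a.outcome_post, b.outcome_post, equal_nan=True)


def test_small_n_refused(default_truth):
    with pytest.raises(ValueError, match="n >= 50"):
        simulate_panel(default_truth, n=10, seed=0)


def test_misordered_thresholds_rejected():
    truth = pn.make_ground_truth(seed=0)
    bad = truth.thresholds.copy()
    bad[0] = bad[0][::-1]
    with pytest.raises(ValueError, match="increasing"):
        dataclasses.replace(truth, thresholds=bad)


def test_zero_missing_rate_gives_complete_outcome(default_truth):
    truth = dataclasses.replace(
        default_truth, missing_rate={"rate_pre": 0.0, "rate_post": 0.0})
    panel = simulate_panel(truth, n=300, seed=4)
    assert not np.isnan(panel.outcome_post).any()
    assert not np.isnan(panel.outcome_pre).any()


def test_mean_shift_reduces_wave2_totals(default_truth):
    panel = simulate_panel(default_truth, n=652, seed=21)
    assert panel.totals("post").mean() < panel.totals("pre").mean()


def test_zero_lagged_gives_null_cross_wave_correlation():
    """With no transition and independent innovations, cross-wave item
    correlations are centred on zero (Monte Carlo over replicates)."""
    truth = pn.make_ground_truth(autoreg_mean=0.0, autoreg_sd=0.0,
                                 crosslag_sd=0.0, mean_shift=0.0, seed=13)
    assert np.all(truth.lagged == 0)
    n = 400
    rs = []
    for rep in range(30):
        panel = simulate_panel(truth, n=n, seed=rep)
        for j in range(0, 20, 4):
            rs.append(np.corrcoef(panel.items_pre[:, j], panel.items_post[:, j])[0, 1])
    assert abs(np.mean(rs)) < 3 / np.sqrt(n)


def test_marginal_fidelity_all_categories_used():
    """Each item uses all five categories at n=500 in nearly every seed."""
    ok = 0
    for seed in range(20):
        truth = pn.make_ground_truth(seed=seed)
        panel = simulate_panel(truth, n=500, seed=seed + 1000)
        full = all(len(np.unique(panel.items_pre[:, j])) == 5 for j in range(20))
        ok += full
    assert ok >= 19


def test_missingness_is_mar_not_mnar(default_truth):
    """The missingness indicator of the post outcome is driven by observed
    wave-1 severity, not by the masked value beyond it: in a logistic fit on
    (severity, masked true value) the severity dominates."""
    truth = dataclasses.replace(
        default_truth,
        missing_rate={"rate_pre": 0.0, "rate_post": 0.5,
                      "beta_total": 0.8, "beta_age": 0.0})
    # regenerate with and without masking from identical streams
    complete = simulate_panel(dataclasses.replace(
        truth, missing_rate={"rate_pre": 0.0, "rate_post": 0.0}), n=4000, seed=6)
    masked = simulate_panel(truth, n=4000, seed=6)
    assert np.array_equal(complete.items_pre, masked.items_pre)
    miss = np.isnan(masked.outcome_post).astype(float)
    import statsmodels.api as sm
    zt = (complete.totals("pre") - complete.totals("pre").mean()) / complete.totals("pre").std()
    zy = (complete.outcome_post - complete.outcome_post.mean()) / complete.outcome_post.std()
    fit = sm.Logit(miss, sm.add_constant(np.column_stack([zt, zy]))).fit(disp=0)
    # conditional on severity, the true (masked) value carries no signal
    assert abs(fit.params[2]) < 3 * fit.bse[2]
    assert fit.params[1] > 3 * fit.bse[1]


def test_csv_round_trip(tmp_path, default_panel):
    path = tmp_path / "panel.csv"
    default_panel.to_csv(path)
    back = pn.SymptomPanel.from_csv(path)
    assert np.array_equal(back.items_pre, default_panel.items_pre)
    assert np.array_equal(back.items_post, default_panel.items_post)
    assert np.allclose(back.outcome_post, default_panel.outcome_post, equal_nan=True)


def test_truth_json_round_trip(tmp_path, default_truth):
    path = tmp_path / "truth.json"
    default_truth.to_json(path)
    back = pn.SyntheticTruth.from_json(path)
    assert np.allclose(back.precision_pre, default_truth.precision_pre)
    assert np.allclose(back.lagged, default_truth.lagged)
    assert back.seed == default_truth.seed
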