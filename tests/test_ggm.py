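"""Correlation input handling and EBIC-glasso selection behavior."""

import numpy as np
import pytest

import panelnet as pn
from panelnet._glasso import glasso
from panelnet.ggm import correlation_matrix, ebic_glasso
from tests.conftest import panel_from_items


def brute_force_glasso(S, lam, eps=1e-12):
    """Independent oracle: generic quasi-Newton minimization of the
    penalized negative log-likelihood over symmetric matrices (smoothed L1
    on the off-diagonal, barrier against indefiniteness)."""
    from scipy.optimize import minimize
    p = S.shape[0]
    iu = np.triu_indices(p)
    offd = ~np.eye(p, dtype=bool)

    def unpack(v):
        Th = np.zeros((p, p))
        Th[iu] = v
        return Th + Th.T - np.diag(np.diag(Th))

    def obj_grad(v):
        Th = unpack(v)
        vals = np.linalg.eigvalsh(Th)
        if vals.min() <= 1e-10:
            return 1e10 - vals.min(), np.zeros_like(v)
        inv = np.linalg.inv(Th)
        sm = np.sqrt(Th ** 2 + eps)
        f = -np.linalg.slogdet(Th)[1] + (S * Th).sum() + lam * sm[offd].sum()
        G = -inv + S + lam * np.where(offd, Th / sm, 0.0)
        return f, np.where(np.eye(p, dtype=bool), G, 2 * G)[iu]

    x0 = np.diag(1.0 / np.diag(S))[iu]
    res = minimize(obj_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-12})
    return unpack(res.x)


class TestCorrelationMatrix:
    def test_duplicate_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 5, size=(100, 20))
        items[:, 1] = items[:, 0]
        R = correlation_matrix(panel_from_items(items), "pre")
        assert R[0, 1] == pytest.approx(1.0)

    def test_constant_column_raises_naming_symptom(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 5, size=(100, 20))
        items[:, 3] = 2
        with pytest.raises(ValueError, match="B4"):
            correlation_matrix(panel_from_items(items), "pre")

    def test_independent_columns_have_small_correlations(self):
        rng = np.random.default_rng(1)
        items = rng.integers(0, 5, size=(5000, 20))
        R = correlation_matrix(panel_from_items(items), "pre")
        off = np.abs(R[np.triu_indices(20, 1)])
        assert np.mean(off < 0.05) >= 0.95

    def test_spearman_on_monotone_data_matches_pearson_of_ranks(self):
        rng = np.random.default_rng(2)
        items = rng.integers(0, 5, size=(300, 20))
        R = correlation_matrix(panel_from_items(items), "pre", method="spearman")
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)


class TestEbicGlasso:
    def test_identity_input_gives_empty_network(self):
        net = ebic_glasso(np.eye(20), n=500)
        assert net.n_edges == 0

    def test_two_node_toy_recovers_correlation(self):
        # with p=2 the partial correlation equals the correlation
        r = 0.6
        S = np.array([[1.0, r], [r, 1.0]])
        net = ebic_glasso(S, n=10_000, n_lambda=100)
        assert net.n_edges == 1
        assert net.weights[0, 1] == pytest.approx(r, abs=0.05)

    def test_gamma_monotone_in_sparsity(self, small_panel):
        R = correlation_matrix(small_panel, "pre")
        e_low = ebic_glasso(R, small_panel.n, gamma=0.25).n_edges
        e_high = ebic_glasso(R, small_panel.n, gamma=1.0).n_edges
        assert e_high <= e_low

    def test_nonpsd_input_rejected(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.9
        S[1, 2] = S[2, 1] = 0.9
        S[0, 2] = S[2, 0] = -0.9
        with pytest.raises(ValueError, match="positive semidefinite"):
            ebic_glasso(S, n=100)

    def test_weights_are_valid_partials(self, small_panel):
        net = pn.estimate_network(small_panel, "pre")
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert np.abs(net.weights).max() <= 1
        iu = np.triu_indices(net.p, 1)
        assert net.n_edges == np.count_nonzero(net.weights[iu])

    @pytest.mark.parametrize("p,lam", [(3, 0.05), (3, 0.2), (4, 0.05), (4, 0.2)])
    def test_solver_matches_brute_force_oracle(self, p, lam):
        rng = np.random.default_rng(p * 100 + int(lam * 100))
        A = rng.standard_normal((80, p))
        A[:, 0] += 0.6 * A[:, -1]
        S = np.corrcoef(A.T)
        Theta = glasso(S, lam, max_iter=2000, tol=1e-9)
        Theta_bf = brute_force_glasso(S, lam)
        assert np.abs(Theta - Theta_bf).max() < 1e-4

    def test_solver_matches_sklearn(self):
        """Cross-check against the independent reference implementation."""
        from sklearn.covariance import graphical_lasso
        rng = np.random.default_rng(3)
        A = rng.standard_normal((300, 8))
        A[:, 1] += 0.5 * A[:, 0]
        S = np.corrcoef(A.T)
        for lam in (0.02, 0.1):
            ours = glasso(S, lam, max_iter=2000, tol=1e-9)
            _, ref = graphical_lasso(S, alpha=lam, max_iter=2000, tol=1e-10)
            assert np.abs(ours - ref).max() < 1e-4


def test_network_json_round_trip(tmp_path, small_panel):
    net = pn.estimate_network(small_panel, "pre")
    path = tmp_path / "net.json"
    net.to_json(path)
    back = pn.WeightedNetwork.from_json(path)
    assert np.array_equal(back.weights, net.weights)
    assert back.lambda_selected == net.lambda_selected
    assert back.n_edges == net.n_edges
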