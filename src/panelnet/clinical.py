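"""Linking network centrality to clinical change.

Covers the outcome-facing half of the analysis: paired-change descriptives,
the symptom-importance index (how much each symptom's change co-occurs
with change in the remaining symptoms), regressions of that index on
centrality, the core-vs-peripheral outcome regression with likelihood-based
missing-data handling, and Little's MCAR diagnostic.

Missing data are handled by an EM algorithm for the multivariate-normal
mean and covariance of all model variables; regression coefficients are
derived from the converged covariance (the maximum-likelihood estimates
under MAR), with standard errors from a nonparametric subject bootstrap.
With no missingness this reduces exactly to complete-data OLS, which is
checked internally.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import ConvergenceError, RegressionReport, SymptomPanel

OUTCOME_TERMS = ("outcome_pre", "baseline_total", "age", "sex", "race",
                 "maltreatment", "peripheral_change", "core_change")


# ---------------------------------------------------------------------------
# descriptives

def _paired_cohen_d(pre: np.ndarray, post: np.ndarray) -> float:
    """(mean_pre - mean_post) / pooled sd of the pre and post scores."""
    pooled = np.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2.0)
    if pooled == 0:
        return np.nan
    return float((pre.mean() - post.mean()) / pooled)


def descriptives(panel: SymptomPanel) -> dict:
    """Totals, paired effect sizes and within-person symptom variability.

    Within-person variability is the per-subject standard deviation across
    the symptom scores at each wave, compared pre vs post by paired t-test.
    """
    tot_pre = panel.totals("pre").astype(float)
    tot_post = panel.totals("post").astype(float)
    d_ptss = _paired_cohen_d(tot_pre, tot_post)
    if np.isnan(d_ptss):
        warnings.warn("zero pooled sd for symptom totals; d undefined")
    both = ~np.isnan(panel.outcome_pre) & ~np.isnan(panel.outcome_post)
    d_outcome = (_paired_cohen_d(panel.outcome_pre[both], panel.outcome_post[both])
                 if both.sum() >= 2 else np.nan)
    var_pre = panel.items_pre.std(axis=1, ddof=1)
    var_post = panel.items_post.std(axis=1, ddof=1)
    if np.allclose(var_pre, var_post):
        t_var, p_var = 0.0, 1.0
    else:
        t_var, p_var = stats.ttest_rel(var_pre, var_post)
    return {
        "n": panel.n,
        "total_pre_mean": float(tot_pre.mean()),
        "total_pre_sd": float(tot_pre.std(ddof=1)),
        "total_post_mean": float(tot_post.mean()),
        "total_post_sd": float(tot_post.std(ddof=1)),
        "paired_d_ptss": d_ptss,
        "paired_d_outcome": float(d_outcome) if np.isfinite(d_outcome) else None,
        "n_outcome_pairs": int(both.sum()),
        "variability_pre_mean": float(var_pre.mean()),
        "variability_pre_sd": float(var_pre.std(ddof=1)),
        "variability_post_mean": float(var_post.mean()),
        "variability_post_sd": float(var_post.std(ddof=1)),
        "variability_t": float(t_var),
        "variability_p": float(p_var),
        "cohen_d_formula": "pooled pre/post sd",
    }


# ---------------------------------------------------------------------------
# symptom importance

def symptom_importance(panel: SymptomPanel,
                       centrality_z: dict | None = None) -> pd.DataFrame:
    """Per-symptom importance of change in the broader change process.

    For symptom s, ``importance_r`` is the Pearson correlation across
    subjects between s's change score and the *sum* of the remaining
    symptoms' change scores. Zero-variance change vectors give a missing
    entry with a warning. Optional ``centrality_z`` columns (e.g. pre_ei_z)
    are merged in for downstream regressions.
    """
    change = panel.items_post.astype(float) - panel.items_pre.astype(float)
    total_change = change.sum(axis=1)
    rows = []
    for s, lab in enumerate(panel.node_labels):
        rest = total_change - change[:, s]
        if change[:, s].std() == 0 or rest.std() == 0:
            warnings.warn(f"zero-variance change for symptom {lab}; "
                          "importance undefined")
            r = np.nan
        else:
            r = float(np.corrcoef(change[:, s], rest)[0, 1])
        rows.append({"node": lab, "baseline_mean": float(panel.items_pre[:, s].mean()),
                     "importance_r": r})
    tab = pd.DataFrame(rows)
    for col, vec in (centrality_z or {}).items():
        tab[col] = np.asarray(vec, dtype=float)
    return tab


def centrality_importance_regression(tab: pd.DataFrame,
                                     centrality_col: str) -> RegressionReport:
    """OLS of importance_r on one centrality column plus baseline severity.

    Also reports the zero-order correlation between the centrality and
    baseline severity (the usual confounding check).
    """
    use = tab.dropna(subset=["importance_r", centrality_col, "baseline_mean"])
    if len(use) < 3:
        raise ValueError("need at least 3 non-missing symptom rows")
    X = use[[centrality_col, "baseline_mean"]].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(use)), X])) < 3:
        raise ValueError("collinear predictors in importance regression")
    model = sm.OLS(use["importance_r"].to_numpy(), sm.add_constant(X)).fit()
    terms = ["intercept", centrality_col, "baseline_mean"]
    table = pd.DataFrame({
        "term": terms, "B": model.params, "SE": model.bse,
        "t": model.tvalues, "p": model.pvalues,
    })
    r, rp = stats.pearsonr(use[centrality_col], use["baseline_mean"])
    return RegressionReport(
        table=table.reset_index(drop=True), n_used=len(use), estimator="ols",
        meta={"df_resid": int(model.df_resid),
              "r_centrality_severity": float(r),
              "p_centrality_severity": float(rp)},
    )


# ---------------------------------------------------------------------------
# EM for the multivariate normal with missing values

def em_mvnorm(X: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
              ridge: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float, int]:
    """EM estimates of (mu, Sigma) for rows with arbitrary missingness.

    Convergence is declared when the relative change in the observed-data
    log-likelihood falls below ``tol``; failure raises ConvergenceError.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError("need n > p for covariance estimation")
    obs_mask = ~np.isnan(X)
    if (~obs_mask.any(axis=1)).any():
        raise ValueError("rows with no observed values are not allowed")
    mu = np.nanmean(X, axis=0)
    diff = np.where(obs_mask, X - mu, 0.0)
    Sigma = (diff.T @ diff) / n + np.eye(p) * 1e-3
    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(obs_mask[i].tobytes(), []).append(i)
    patterns = {k: np.array(v) for k, v in patterns.items()}
    prev_ll = -np.inf
    for it in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for key, idx in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            Xo = X[np.ix_(idx, o)]
            So = Sigma[np.ix_(o, o)] + np.eye(o.sum()) * ridge
            So_inv = np.linalg.inv(So)
            dev = Xo - mu[o]
            sign, logdet = np.linalg.slogdet(So)
            ll += (-0.5 * len(idx) * (o.sum() * np.log(2 * np.pi) + logdet)
                   - 0.5 * np.einsum("ij,jk,ik->", dev, So_inv, dev))
            Ex = np.repeat(mu[None, :], len(idx), axis=0)
            Ex[:, o] = Xo
            cond_cov = np.zeros((p, p))
            if m.any():
                Smo = Sigma[np.ix_(m, o)]
                B = Smo @ So_inv
                Ex[:, m] = mu[m] + dev @ B.T
                cc = Sigma[np.ix_(m, m)] - B @ Smo.T
                cond_cov[np.ix_(m, m)] = cc
            sum_x += Ex.sum(axis=0)
            sum_xx += Ex.T @ Ex + len(idx) * cond_cov
        mu = sum_x / n
        Sigma = sum_xx / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            return mu, Sigma, ll, it + 1
        prev_ll = ll
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations (rel. tol {tol})")


def _regression_from_moments(mu: np.ndarray, Sigma: np.ndarray,
                             y_idx: int, x_idx: list[int]) -> np.ndarray:
    """[intercept, slopes] of y on x implied by an MVN mean/covariance."""
    Sxx = Sigma[np.ix_(x_idx, x_idx)]
    sxy = Sigma[np.ix_(x_idx, [y_idx])].ravel()
    beta = np.linalg.solve(Sxx, sxy)
    intercept = mu[y_idx] - beta @ mu[x_idx]
    return np.concatenate([[intercept], beta])


def _core_peripheral_matrix(panel: SymptomPanel,
                            central_flags: np.ndarray) -> np.ndarray:
    change = panel.items_post.astype(float) - panel.items_pre.astype(float)
    central = np.asarray(central_flags, dtype=bool)
    core = change[:, central].mean(axis=1)
    peripheral = change[:, ~central].mean(axis=1)
    return np.column_stack([
        panel.outcome_post, panel.outcome_pre,
        panel.totals("pre").astype(float), panel.age.astype(float),
        panel.sex.astype(float), panel.race.astype(float),
        panel.maltreatment.astype(float), peripheral, core,
    ])


def core_peripheral_outcome_regression(panel: SymptomPanel,
                                       central_flags: np.ndarray,
                                       estimator: str = "ols_complete",
                                       n_boot_se: int = 200,
                                       seed: int = 0) -> RegressionReport:
    """Regress the post outcome on core vs peripheral symptom change.

    Predictors: pre outcome, baseline symptom total, age, sex, race,
    maltreatment-index indicator, mean peripheral change and mean core
    change (core = flagged central symptoms). ``estimator='fiml_em'`` uses
    the EM mean/covariance under missingness with bootstrap standard
    errors; ``'ols_complete'`` is listwise-complete OLS.
    """
    central = np.asarray(central_flags, dtype=bool)
    if central.sum() < 1 or (~central).sum() < 1:
        raise ValueError("need at least one central and one peripheral symptom")
    M = _core_peripheral_matrix(panel, central)
    terms = ["intercept"] + list(OUTCOME_TERMS)
    x_idx = list(range(1, M.shape[1]))
    complete = ~np.isnan(M).any(axis=1)

    def _ols(Mc: np.ndarray):
        model = sm.OLS(Mc[:, 0], sm.add_constant(Mc[:, 1:])).fit()
        return model

    if estimator == "ols_complete":
        model = _ols(M[complete])
        table = pd.DataFrame({"term": terms, "B": model.params, "SE": model.bse,
                              "t": model.tvalues, "p": model.pvalues})
        return RegressionReport(
            table=table.reset_index(drop=True), n_used=int(complete.sum()),
            estimator="ols_complete",
            meta={"reference": f"t({int(model.df_resid)})"},
        )
    if estimator != "fiml_em":
        raise ValueError(f"unknown estimator {estimator!r}")
    mu, Sigma, _, _ = em_mvnorm(M)
    B = _regression_from_moments(mu, Sigma, 0, x_idx)
    if complete.all():
        ols_B = np.asarray(_ols(M).params)
        if not np.allclose(B, ols_B, atol=1e-6):
            raise AssertionError(
                "EM with complete data disagrees with OLS; internal error")
    n = M.shape[0]
    draws = np.empty((n_boot_se, len(B)))
    for d in range(n_boot_se):
        rng = np.random.default_rng([int(seed), d])
        idx = rng.integers(0, n, size=n)
        Md = M[idx]
        if complete.all():
            draws[d] = np.asarray(_ols(Md).params)
        else:
            mu_d, Sig_d, _, _ = em_mvnorm(Md)
            draws[d] = _regression_from_moments(mu_d, Sig_d, 0, x_idx)
    SE = draws.std(axis=0, ddof=1)
    df = n - len(B)
    t = B / SE
    p = 2 * stats.t.sf(np.abs(t), df=df)
    table = pd.DataFrame({"term": terms, "B": B, "SE": SE, "t": t, "p": p})
    return RegressionReport(
        table=table, n_used=n, estimator="fiml_em",
        meta={"reference": f"t({df})", "n_boot_se": n_boot_se, "seed": seed,
              "se_method": "nonparametric bootstrap"},
    )


# ---------------------------------------------------------------------------
# Little's MCAR test

def little_mcar_test(X: np.ndarray, ridge: float = 1e-8) -> dict:
    """Little's chi-square test of missing completely at random.

    Compares each missingness pattern's observed-variable means with the EM
    grand estimates: d2 = sum_k n_k (ybar_k - mu_k)' Sigma_k^{-1}
    (ybar_k - mu_k) on the observed coordinates, with df =
    sum_k p_k - p. Requires at least two distinct patterns.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs_mask = ~np.isnan(X)
    keep = obs_mask.any(axis=1)
    X, obs_mask = X[keep], obs_mask[keep]
    pattern_keys = {obs_mask[i].tobytes() for i in range(X.shape[0])}
    if len(pattern_keys) < 2:
        raise ValueError("need at least 2 distinct missingness patterns")
    mu, Sigma, _, _ = em_mvnorm(X)
    d2 = 0.0
    df = -p
    groups: dict[bytes, list[int]] = {}
    for i in range(X.shape[0]):
        groups.setdefault(obs_mask[i].tobytes(), []).append(i)
    for key, idx in groups.items():
        o = np.frombuffer(key, dtype=bool)
        k = int(o.sum())
        df += k
        ybar = X[np.ix_(idx, o)].mean(axis=0)
        So = Sigma[np.ix_(o, o)]
        try:
            So_inv = np.linalg.inv(So)
        except np.linalg.LinAlgError:
            warnings.warn("singular pattern submatrix; ridge repair applied")
            So_inv = np.linalg.inv(So + np.eye(k) * ridge)
        dev = ybar - mu[o]
        d2 += len(idx) * float(dev @ So_inv @ dev)
    return {"chi2": float(d2), "df": int(df),
            "p": float(stats.chi2.sf(d2, df)) if df > 0 else np.nan,
            "n_patterns": len(groups)}
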