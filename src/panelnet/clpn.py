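"""Cross-lagged panel network estimation via node-wise regularized regression.

Each wave-2 symptom is regressed on all 20 standardized wave-1 symptoms
(optionally plus demographic covariates) with an L1 penalty chosen by
k-fold cross-validated mean squared error (CV-minimum rule). Column j of
the coefficient matrix ``b`` collects the symptom coefficients of outcome
j, so ``b[i, j]`` is the standardized effect of wave-1 symptom i on wave-2
symptom j and the diagonal holds autoregressive effects. Covariate
coefficients are reported in a side table and never enter the network.

Standardization uses full-sample means and standard deviations computed
before the cross-validation split: simpler and deterministic, at the cost
of a slight optimism in fold errors (documented in the methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .types import DirectedNetwork, SymptomPanel

COVARIATE_GETTERS = {
    "age": lambda p: p.age.astype(float),
    "sex": lambda p: p.sex.astype(float),
    "race": lambda p: p.race.astype(float),
    "maltreatment": lambda p: p.maltreatment.astype(float),
}


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        dead = np.where(sd == 0)[0]
        raise ValueError(f"zero-variance predictor column(s): {dead.tolist()}")
    return (X - mu) / sd


def fit_clpn(panel: SymptomPanel, k_folds: int = 10,
             covariates: list[str] | None = None, seed: int = 0,
             n_alphas: int = 100, penalize_covariates: bool = True,
             ) -> DirectedNetwork:
    """Estimate the directed wave-1 -> wave-2 network.

    ``covariates`` names any of age / sex / race / maltreatment; by default
    they enter the penalized design matrix alongside the symptom predictors
    (set ``penalize_covariates=False`` to partial them out unpenalized
    first). Fold assignment is deterministic from ``seed`` with subjects as
    the sampling unit, and the same split is reused for every outcome.
    """
    covariates = list(covariates or [])
    p = panel.p
    n = panel.n
    if n <= 5 * (p + len(covariates)):
        raise ValueError(
            f"need n > 5*(p + #covariates) = {5 * (p + len(covariates))}, got {n}")
    if not 2 <= k_folds <= 20:
        raise ValueError(f"k_folds must lie in [2, 20], got {k_folds}")
    for c in covariates:
        if c not in COVARIATE_GETTERS:
            raise ValueError(f"unknown covariate {c!r}")
    Xs = _standardize(panel.items_pre.astype(float))
    Ys = _standardize(panel.items_post.astype(float))
    C = None
    first_stage = None
    if covariates:
        C = _standardize(np.column_stack(
            [COVARIATE_GETTERS[c](panel) for c in covariates]))
        if not penalize_covariates:
            # partial covariates out of predictors and outcomes, unpenalized
            proj = C @ np.linalg.lstsq(C, Xs, rcond=None)[0]
            first_stage = np.linalg.lstsq(C, Ys, rcond=None)[0]
            Xs = Xs - proj
            Ys = Ys - C @ first_stage
            C = None
    design = Xs if C is None else np.column_stack([Xs, C])
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**31))
    b = np.zeros((p, p))
    alphas = np.zeros(p)
    cov_rows = []
    for j in range(p):
        model = LassoCV(cv=cv, alphas=n_alphas, fit_intercept=False,
                        max_iter=50_000)
        model.fit(design, Ys[:, j])
        if not np.isfinite(model.coef_).all():
            raise RuntimeError(
                f"LASSO failed to converge for outcome {panel.node_labels[j]}")
        b[:, j] = model.coef_[:p]
        alphas[j] = model.alpha_
        for ci, cname in enumerate(covariates):
            coef = (float(model.coef_[p + ci]) if C is not None
                    else float(first_stage[ci, j]))
            cov_rows.append({"outcome": panel.node_labels[j],
                             "covariate": cname, "coef": coef})
    cov_table = pd.DataFrame(cov_rows, columns=["outcome", "covariate", "coef"]) \
        if covariates else None
    return DirectedNetwork(
        node_labels=panel.node_labels, b=b, alphas=alphas, k_folds=k_folds,
        covariate_adjusted=bool(covariates), seed=int(seed),
        covariate_coefs=cov_table,
    )


def strong_edges(net: DirectedNetwork, threshold: float = 0.10) -> pd.DataFrame:
    """Off-diagonal cells with |b| > threshold, strongest first.

    Ties are broken by (source, target) label order so output is stable.
    """
    rows = []
    for i in range(net.p):
        for j in range(net.p):
            if i != j and abs(net.b[i, j]) > threshold:
                rows.append({
                    "source": net.node_labels[i],
                    "target": net.node_labels[j],
                    "weight": float(net.b[i, j]),
                })
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    if len(df):
        df = df.sort_values(
            by=["weight", "source", "target"],
            key=lambda s: -s.abs() if s.name == "weight" else s,
        ).reset_index(drop=True)
    return df


def autoregressive_contrast(net: DirectedNetwork) -> dict:
    """Contrast autoregressive against cross-lagged coefficient size.

    Summaries of the diagonal and off-diagonal cells, plus a paired t-test
    across the p symptoms of (autoregressive_i - mean outgoing cross-lagged
    coefficient of symptom i), df = p - 1. A zero-variance difference vector
    is flagged degenerate (t reported as +/-inf, p = 0).
    """
    b = net.b
    p = net.p
    if p < 2:
        raise ValueError("need at least 2 nodes")
    diag = np.diag(b)
    off_mask = ~np.eye(p, dtype=bool)
    off = b[off_mask]
    row_cross = (b.sum(axis=1) - diag) / (p - 1)   # outgoing means
    d = diag - row_cross
    sd_d = d.std(ddof=1)
    # float-noise guard: a constant difference vector is degenerate even if
    # summation order leaves an O(eps) residual spread
    degenerate = sd_d <= 1e-12 * max(1.0, abs(float(d.mean())))
    if degenerate:
        if d.mean() == 0:
            t = 0.0
            pval = 1.0
        else:
            t = float(np.sign(d.mean()) * np.inf)
            pval = 0.0
    else:
        t = float(d.mean() / (sd_d / np.sqrt(p)))
        pval = float(2 * stats.t.sf(abs(t), df=p - 1))
    return {
        "mean_auto": float(diag.mean()), "sd_auto": float(diag.std(ddof=1)),
        "mean_cross": float(off.mean()), "sd_cross": float(off.std(ddof=1)),
        "t_stat": t, "df": p - 1, "p": pval, "degenerate": bool(degenerate),
    }
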