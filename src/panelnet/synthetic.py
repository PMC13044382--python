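"""Synthetic two-wave ordinal symptom panels with known network structure.

The generator emulates the statistical shape of a pre/post treatment PTSD
symptom panel: wave-1 latents from a sparse Gaussian graphical model,
wave-2 latents from a strong-diagonal / weak-off-diagonal lagged transition
plus their own sparse innovation GGM, discretization to 0-4 Likert scores
through right-skewed thresholds, demographic covariates matched to the
study-population margins, an outcome total (0-40) linearly coupled to
change in the generating network's central symptoms, and a logistic
missing-at-random mask on the outcome.

Every quantity that downstream estimators try to recover is recorded in the
returned :class:`~panelnet.types.SyntheticTruth`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .types import (DEFAULT_NODE_LABELS, GenerationError, SymptomPanel,
                    SyntheticTruth)

#: default latent cutpoints: right-skewed category usage (clinical symptom
#: scales pile up at the low end); category probabilities under N(0,1) are
#: about .31/.31/.20/.13/.04.
DEFAULT_THRESHOLDS = (-0.5, 0.3, 1.0, 1.8)

#: outcome-model coefficients (0-40 total difficulties scale). core_change is
#: the generating coefficient the outcome-regression recovery tests target.
DEFAULT_OUTCOME_BETAS = {
    "intercept": 4.0,
    "outcome_pre": 0.6,
    "baseline_total": 0.05,
    "age": -0.15,
    "sex": 0.0,
    "race": 0.0,
    "maltreatment": 0.0,
    "peripheral_change": 0.3,
    "core_change": 1.0,
    "sigma": 3.0,
}

#: logistic MAR mechanism on the outcome: probability depends on the wave-1
#: symptom total and age only (both always observed), never on the masked
#: value itself. Default post rate kept at .50 so estimation stays well-posed
#: (the motivating study lost most parent reports, ~.76).
DEFAULT_MISSING_RATE = {"rate_pre": 0.25, "rate_post": 0.50,
                        "beta_total": 0.6, "beta_age": 0.3}


def _sparse_precision(p: int, edge_density: float, rng: np.random.Generator,
                      partial_low: float = 0.15, partial_high: float = 0.40,
                      positive_frac: float = 0.8, max_repair: int = 50,
                      min_eig: float = 0.3,
                      seed_label: int | None = None) -> np.ndarray:
    """Sparse SPD precision matrix with unit diagonal and controlled partials.

    Off-diagonal entries start at -(target partial correlation); if the
    smallest eigenvalue falls below ``min_eig`` the off-diagonals are shrunk
    by 10% steps (a repair that preserves support and signs). The eigenvalue
    floor keeps the implied latent correlations in the moderate range seen
    in real symptom inventories; a near-singular precision would imply
    inter-item correlations approaching 1.
    """
    K = np.eye(p)
    iu = np.triu_indices(p, k=1)
    support = rng.random(len(iu[0])) < edge_density
    vals = rng.uniform(partial_low, partial_high, size=len(iu[0]))
    signs = np.where(rng.random(len(iu[0])) < positive_frac, 1.0, -1.0)
    partials = np.where(support, vals * signs, 0.0)
    K[iu] = -partials
    K.T[iu] = -partials
    for _ in range(max_repair):
        if np.linalg.eigvalsh(K).min() > min_eig:
            return K
        off = K - np.diag(np.diag(K))
        K = np.eye(p) + 0.9 * off
    raise GenerationError(
        f"could not repair precision matrix to SPD (seed={seed_label})")


def make_ground_truth(p: int = 20, edge_density: float = 0.2,
                      autoreg_mean: float = 0.15, crosslag_sd: float = 0.01,
                      seed: int = 0, *, autoreg_sd: float = 0.07,
                      crosslag_mean: float = 0.01, crosslag_density: float = 0.5,
                      mean_shift: float | np.ndarray = 0.29,
                      thresholds: np.ndarray | None = None,
                      outcome_betas: dict | None = None,
                      missing_rate: dict | None = None,
                      node_labels=None) -> SyntheticTruth:
    """Build the generating quantities for a two-wave panel.

    The lagged matrix has a strong diagonal near ``autoreg_mean`` (spread
    ``autoreg_sd``) and sparse off-diagonals near ``crosslag_mean`` with
    spread ``crosslag_sd``; ``crosslag_sd = 0`` disables cross-lagged paths
    entirely (exactly diagonal transition).
    """
    if not 0 <= edge_density < 1:
        raise ValueError("edge_density must lie in [0, 1)")
    if p < 3:
        raise ValueError("need p >= 3")
    rng = np.random.default_rng(seed)
    K_pre = _sparse_precision(p, edge_density, rng, seed_label=seed)
    K_inn = _sparse_precision(p, edge_density, rng, seed_label=seed)
    diag = autoreg_mean + autoreg_sd * rng.standard_normal(p)
    L = np.diag(diag)
    if crosslag_sd > 0:
        off_mask = (rng.random((p, p)) < crosslag_density)
        np.fill_diagonal(off_mask, False)
        off_vals = crosslag_mean + crosslag_sd * rng.standard_normal((p, p))
        L = L + np.where(off_mask, off_vals, 0.0)
    if thresholds is None:
        thresholds = np.tile(DEFAULT_THRESHOLDS, (p, 1))
    shift = np.broadcast_to(np.asarray(mean_shift, dtype=float), (p,)).copy()
    labels = tuple(node_labels) if node_labels is not None else (
        DEFAULT_NODE_LABELS if p == 20 else tuple(f"V{i+1}" for i in range(p)))
    return SyntheticTruth(
        precision_pre=K_pre, lagged=L, innovation_precision=K_inn,
        thresholds=np.asarray(thresholds, dtype=float), mean_shift=shift,
        outcome_betas=dict(outcome_betas or DEFAULT_OUTCOME_BETAS),
        missing_rate=dict(missing_rate or DEFAULT_MISSING_RATE),
        seed=int(seed), node_labels=labels,
    )


def _corr_from_precision(K: np.ndarray) -> np.ndarray:
    C = np.linalg.inv(K)
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    return (R + R.T) / 2.0


def _discretize(Z: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    items = np.empty(Z.shape, dtype=int)
    for j in range(Z.shape[1]):
        items[:, j] = np.searchsorted(thresholds[j], Z[:, j], side="left")
    return items


def _calibrated_intercept(lin: np.ndarray, rate: float) -> float:
    """Intercept b0 with mean(sigmoid(b0 + lin)) = rate on this sample."""
    if rate <= 0:
        return -np.inf

    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lin))))) - rate

    return brentq(gap, -30.0, 30.0)


def simulate_panel(truth: SyntheticTruth, n: int, seed: int = 0) -> SymptomPanel:
    """Draw a two-wave panel of n subjects from the generating model.

    Wave-1 latents are multivariate normal with the correlation implied by
    ``truth.precision_pre``; wave-2 latents are ``lagged.T @ z1`` plus scaled
    innovations minus ``mean_shift``, so post scores sit lower on the same
    thresholds. The outcome is built from the generating core/peripheral
    change split and masked missing-at-random.
    """
    if n < 50:
        raise ValueError("need n >= 50 for downstream estimation")
    rng = np.random.default_rng(seed)
    p = truth.p
    R1 = _corr_from_precision(truth.precision_pre)
    Z1 = rng.multivariate_normal(np.zeros(p), R1, size=n, method="cholesky")
    items_pre = _discretize(Z1, truth.thresholds)
    # the lagged coefficients are standardized effects of *observed* wave-1
    # scores (the estimand of the node-wise regressions), so the transition
    # acts on the standardized discretized scores, not the latents
    X1 = items_pre.astype(float)
    X1s = (X1 - X1.mean(axis=0)) / X1.std(axis=0)
    pred = X1s @ truth.lagged
    pred_var = pred.var(axis=0)
    resid_sd = np.sqrt(np.clip(1.0 - pred_var, 0.1, None))
    Rinn = _corr_from_precision(truth.innovation_precision)
    E = rng.multivariate_normal(np.zeros(p), Rinn, size=n, method="cholesky")
    Z2 = pred + E * resid_sd - truth.mean_shift
    items_post = _discretize(Z2, truth.thresholds)

    # covariates: study-population margins (age truncated normal on [7, 18])
    a, b = (7.0 - 12.47) / 3.12, (18.0 - 12.47) / 3.12
    age = stats.truncnorm.rvs(a, b, loc=12.47, scale=3.12, size=n, random_state=rng)
    sex = (rng.random(n) < 0.575).astype(int)
    race = (rng.random(n) < 0.219).astype(int)
    maltreatment = (rng.random(n) < 0.5).astype(int)

    # outcome coupled to central-symptom change on the observed score scale
    betas = truth.outcome_betas
    central = truth.central_mask
    if not central.any():          # degenerate truth: fall back to top node
        central = np.zeros(p, dtype=bool)
        central[np.argmax(truth.partials_pre.sum(axis=1))] = True
    change = items_post.astype(float) - items_pre.astype(float)
    core_change = change[:, central].mean(axis=1)
    peripheral_change = change[:, ~central].mean(axis=1) if (~central).any() \
        else np.zeros(n)
    baseline_total = items_pre.sum(axis=1).astype(float)
    outcome_pre = np.clip(np.round(
        14.0 + 0.15 * (baseline_total - baseline_total.mean())
        + 4.0 * rng.standard_normal(n)), 0, 40)
    lin = (betas["intercept"]
           + betas["outcome_pre"] * outcome_pre
           + betas["baseline_total"] * baseline_total
           + betas["age"] * age
           + betas["sex"] * sex
           + betas["race"] * race
           + betas["maltreatment"] * maltreatment
           + betas["peripheral_change"] * peripheral_change
           + betas["core_change"] * core_change)
    outcome_post = np.clip(np.round(lin + betas["sigma"] * rng.standard_normal(n)),
                           0, 40)

    # MAR mask. The post outcome goes missing as a function of wave-1 total
    # severity and age; the pre outcome then goes missing as a function of
    # the *observed* post value (plus severity), emulating administrative
    # inconsistency that tracks family difficulty. Both steps condition
    # only on observed quantities, so the mechanism is missing-at-random,
    # yet listwise deletion selects on an outcome-correlated variable and
    # is genuinely biased where likelihood-based estimation is not.
    mr = truth.missing_rate
    zt = (baseline_total - baseline_total.mean()) / (baseline_total.std() + 1e-12)
    za = (age - age.mean()) / (age.std() + 1e-12)
    rate_post = float(mr.get("rate_post", 0.0))
    if rate_post > 0:
        lin_post = mr.get("beta_total", 0.6) * zt + mr.get("beta_age", 0.3) * za
        b0 = _calibrated_intercept(lin_post, rate_post)
        miss = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + lin_post)))
        outcome_post[miss] = np.nan
    rate_pre = float(mr.get("rate_pre", 0.0))
    if rate_pre > 0:
        obs_post = np.where(np.isnan(outcome_post), np.nanmean(outcome_post),
                            outcome_post)
        zp = (obs_post - obs_post.mean()) / (obs_post.std() + 1e-12)
        lin_pre = mr.get("beta_outcome", 1.0) * zp + 0.3 * zt
        b0 = _calibrated_intercept(lin_pre, rate_pre)
        miss = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + lin_pre)))
        outcome_pre[miss] = np.nan

    return SymptomPanel(
        subject_id=np.arange(1, n + 1),
        items_pre=items_pre, items_post=items_post,
        age=age, sex=sex, race=race, maltreatment=maltreatment,
        outcome_pre=outcome_pre, outcome_post=outcome_post,
        node_labels=truth.node_labels,
    )
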