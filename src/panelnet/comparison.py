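"""Permutation tests for equality of two symptom networks.

Two statistics are tested, each with full network re-estimation inside
every permutation:

* structure invariance ``M`` -- the maximum absolute edge difference, and
* global strength ``S`` -- the absolute difference of the summed absolute
  edge weights.

The paired test swaps each subject's wave labels independently with
probability 1/2 (the within-subject exchangeability scheme); the
independent-groups test permutes group labels across the pooled subjects.
p-values use the add-one convention (1 + #{perm >= obs}) / (1 + n_perm),
so they are always in (0, 1].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ggm import estimate_network
from .types import SymptomPanel

logger = logging.getLogger(__name__)


@dataclass
class NCTResult:
    m_observed: float
    s_observed: float
    m_pvalue: float
    s_pvalue: float
    n_perm: int
    paired: bool
    m_perm: np.ndarray
    s_perm: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "m_observed": self.m_observed, "s_observed": self.s_observed,
            "m_pvalue": self.m_pvalue, "s_pvalue": self.s_pvalue,
            "n_perm": self.n_perm, "paired": self.paired, "seed": self.seed,
            "pvalue_rule": "add-one: (1 + #{perm >= obs}) / (1 + n_perm)",
            "m_perm": np.asarray(self.m_perm).tolist(),
            "s_perm": np.asarray(self.s_perm).tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def network_statistics(w_a: np.ndarray, w_b: np.ndarray) -> tuple[float, float]:
    """(M, S): max absolute edge difference and |global strength difference|."""
    p = w_a.shape[0]
    iu = np.triu_indices(p, k=1)
    m = float(np.abs(w_a[iu] - w_b[iu]).max())
    s = float(abs(np.abs(w_a[iu]).sum() - np.abs(w_b[iu]).sum()))
    return m, s


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Family-wise adjusted per-test level for k comparisons."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def _pvalue(perm: np.ndarray, observed: float) -> float:
    return float((1 + np.count_nonzero(perm >= observed)) / (1 + perm.size))


def _estimate_weights(items: np.ndarray, labels, cfg: dict) -> np.ndarray:
    panel_like = _ItemsView(items, labels)
    return estimate_network(panel_like, "pre", **cfg).weights


class _ItemsView:
    """Minimal panel facade over a raw item matrix, for re-estimation loops."""

    def __init__(self, items: np.ndarray, labels):
        self.items_pre = np.asarray(items)
        self.node_labels = tuple(labels)
        self.n = self.items_pre.shape[0]
        self.p = self.items_pre.shape[1]

    def items(self, wave: str) -> np.ndarray:
        return self.items_pre


def nct_paired(panel: SymptomPanel, estimator_config: dict | None = None,
               n_perm: int = 1000, seed: int = 0,
               max_redraw_factor: int = 3) -> NCTResult:
    """Paired network comparison test between the two waves of one panel."""
    cfg = dict(estimator_config or {})
    labels = panel.node_labels
    w_pre = _estimate_weights(panel.items_pre, labels, cfg)
    w_post = _estimate_weights(panel.items_post, labels, cfg)
    m_obs, s_obs = network_statistics(w_pre, w_post)
    n = panel.n
    m_perm = np.empty(n_perm)
    s_perm = np.empty(n_perm)
    n_failed = 0
    attempt = 0
    for b in range(n_perm):
        while True:
            rng = np.random.default_rng([int(seed), attempt])
            attempt += 1
            swap = rng.random(n) < 0.5
            a_items = np.where(swap[:, None], panel.items_post, panel.items_pre)
            b_items = np.where(swap[:, None], panel.items_pre, panel.items_post)
            try:
                wa = _estimate_weights(a_items, labels, cfg)
                wb = _estimate_weights(b_items, labels, cfg)
            except (ValueError, RuntimeError) as exc:
                n_failed += 1
                logger.warning("paired NCT permutation redrawn: %s", exc)
                if n_failed > 0.05 * n_perm:
                    raise RuntimeError("more than 5% of NCT permutations failed")
                if attempt > max_redraw_factor * n_perm:
                    raise RuntimeError("NCT permutation redraw budget exhausted")
                continue
            m_perm[b], s_perm[b] = network_statistics(wa, wb)
            break
    return NCTResult(
        m_observed=m_obs, s_observed=s_obs,
        m_pvalue=_pvalue(m_perm, m_obs), s_pvalue=_pvalue(s_perm, s_obs),
        n_perm=n_perm, paired=True, m_perm=m_perm, s_perm=s_perm, seed=seed,
    )


def nct_independent(panel_a: SymptomPanel, panel_b: SymptomPanel, wave: str,
                    estimator_config: dict | None = None, n_perm: int = 1000,
                    seed: int = 0, max_redraw_factor: int = 3) -> NCTResult:
    """Independent-groups network comparison test at one wave."""
    cfg = dict(estimator_config or {})
    if panel_a.node_labels != panel_b.node_labels:
        raise ValueError("panels must share node labels")
    labels = panel_a.node_labels
    p = panel_a.p
    n_small = min(panel_a.n, panel_b.n)
    if n_small < p:
        raise ValueError(
            f"smallest group ({n_small}) below the node count ({p}); aborting")
    if n_small < 3 * p:
        warnings.warn(
            f"smallest group ({n_small}) below 3x node count; estimation unstable")
    items_a = panel_a.items(wave)
    items_b = panel_b.items(wave)
    w_a = _estimate_weights(items_a, labels, cfg)
    w_b = _estimate_weights(items_b, labels, cfg)
    m_obs, s_obs = network_statistics(w_a, w_b)
    pooled = np.vstack([items_a, items_b])
    na = items_a.shape[0]
    n_tot = pooled.shape[0]
    m_perm = np.empty(n_perm)
    s_perm = np.empty(n_perm)
    n_failed = 0
    attempt = 0
    for b in range(n_perm):
        while True:
            rng = np.random.default_rng([int(seed), attempt])
            attempt += 1
            order = rng.permutation(n_tot)
            try:
                wa = _estimate_weights(pooled[order[:na]], labels, cfg)
                wb = _estimate_weights(pooled[order[na:]], labels, cfg)
            except (ValueError, RuntimeError) as exc:
                n_failed += 1
                logger.warning("independent NCT permutation redrawn: %s", exc)
                if n_failed > 0.05 * n_perm:
                    raise RuntimeError("more than 5% of NCT permutations failed")
                if attempt > max_redraw_factor * n_perm:
                    raise RuntimeError("NCT permutation redraw budget exhausted")
                continue
            m_perm[b], s_perm[b] = network_statistics(wa, wb)
            break
    return NCTResult(
        m_observed=m_obs, s_observed=s_obs,
        m_pvalue=_pvalue(m_perm, m_obs), s_pvalue=_pvalue(s_perm, s_obs),
        n_perm=n_perm, paired=False, m_perm=m_perm, s_perm=s_perm, seed=seed,
    )
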