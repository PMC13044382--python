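"""Bootstrap accuracy and stability for networks and centrality.

Implements the standard descriptive toolkit for regularized symptom
networks: nonparametric subject bootstrap for edge-weight confidence
intervals, bootstrapped difference tests between parameters of the same
network, and the case-dropping bootstrap behind the correlation-stability
(CS) coefficient -- the largest proportion of cases that can be dropped
while, with 95% probability, subset centrality still correlates >= 0.7
with the full-sample centrality.

Per-draw random streams are derived from the master seed and the draw
index, so results are reproducible and order-independent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import directed_expected_influence, expected_influence
from .ggm import estimate_network
from .types import SymptomPanel

logger = logging.getLogger(__name__)


@dataclass
class EdgeBootstrap:
    """Nonparametric bootstrap of one wave's network edges (and EI)."""

    node_labels: tuple[str, ...]
    edges: list[tuple[int, int]]        # upper-triangle (i, j) pairs, i < j
    point_estimate: np.ndarray          # full-sample edge weights
    samples: np.ndarray                 # n_ok x n_edges bootstrap draws
    ei_point: np.ndarray
    ei_samples: np.ndarray
    n_boot: int
    seed: int
    n_failed: int = 0

    @property
    def boot_mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def ci_low(self) -> np.ndarray:
        return np.percentile(self.samples, 2.5, axis=0)

    @property
    def ci_high(self) -> np.ndarray:
        return np.percentile(self.samples, 97.5, axis=0)

    @property
    def mean_ci_width(self) -> float:
        return float((self.ci_high - self.ci_low).mean())

    @property
    def sd_ci_width(self) -> float:
        return float((self.ci_high - self.ci_low).std(ddof=1))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_i": [self.node_labels[i] for i, _ in self.edges],
            "node_j": [self.node_labels[j] for _, j in self.edges],
            "point": self.point_estimate,
            "boot_mean": self.boot_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })

    def to_csv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, index=False)


@dataclass
class StabilityProfile:
    """Case-dropping bootstrap profile and the derived CS-coefficient."""

    metric: str
    drop_proportions: np.ndarray
    correlations: dict                  # proportion -> array of correlations
    cs_value: float
    cor_threshold: float = 0.7
    coverage: float = 0.95
    n_boot: int = 0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metric": self.metric,
            "drop_proportions": np.asarray(self.drop_proportions).tolist(),
            "correlations": {f"{k:.2f}": np.asarray(v).tolist()
                             for k, v in self.correlations.items()},
            "cs_value": self.cs_value,
            "cor_threshold": self.cor_threshold,
            "coverage": self.coverage,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _draw_rng(seed: int, draw: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(draw)])


def bootstrap_edges(panel: SymptomPanel, wave: str,
                    estimator_config: dict | None = None,
                    n_boot: int = 1000, seed: int = 0) -> EdgeBootstrap:
    """Resample subjects with replacement and re-estimate the full network.

    Draws where estimation fails (e.g. a zero-variance resampled column)
    are skipped and counted; more than 5% failures aborts.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot={n_boot} below the minimum of 100")
    cfg = dict(estimator_config or {})
    net = estimate_network(panel, wave, **cfg)
    p = panel.p
    iu, ju = np.triu_indices(p, k=1)
    edges = list(zip(iu.tolist(), ju.tolist()))
    point = net.weights[iu, ju]
    ei_point = expected_influence(net).ei_raw
    n = panel.n
    samples, ei_samples, n_failed = [], [], 0
    for d in range(n_boot):
        rng = _draw_rng(seed, d)
        idx = rng.integers(0, n, size=n)
        try:
            bnet = estimate_network(panel.subset(idx), wave, **cfg)
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.debug("bootstrap draw %d failed: %s", d, exc)
            if n_failed > 0.05 * n_boot:
                raise RuntimeError(
                    f"more than 5% of bootstrap draws failed ({n_failed})")
            continue
        samples.append(bnet.weights[iu, ju])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ei_samples.append(expected_influence(bnet).ei_raw)
    return EdgeBootstrap(
        node_labels=panel.node_labels, edges=edges, point_estimate=point,
        samples=np.array(samples), ei_point=ei_point,
        ei_samples=np.array(ei_samples), n_boot=n_boot, seed=seed,
        n_failed=n_failed,
    )


def difference_test(boot: EdgeBootstrap, a: int, b: int,
                    kind: str = "edge") -> dict:
    """Bootstrapped difference test between two edges or two EI values.

    Significant iff the 95% percentile CI of (value_a - value_b) excludes 0.
    """
    if a == b:
        raise ValueError("a and b must differ")
    mats = {"edge": boot.samples, "ei": boot.ei_samples}
    if kind not in mats:
        raise ValueError(f"kind must be 'edge' or 'ei', got {kind!r}")
    M = mats[kind]
    k = M.shape[1]
    if not (0 <= a < k and 0 <= b < k):
        raise IndexError(f"index out of range for {kind} bootstrap of size {k}")
    diff = M[:, a] - M[:, b]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return {
        "significant": bool(lo > 0 or hi < 0),
        "ci_of_difference": (float(lo), float(hi)),
        "mean_difference": float(diff.mean()),
    }


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; degenerate (zero-variance) vectors count as 0."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


DEFAULT_DROP_GRID = np.round(np.arange(0.05, 0.751, 0.05), 2)


def cs_coefficient(panel: SymptomPanel, wave: str, metric: str = "ei",
                   drop_grid: np.ndarray | None = None, n_boot: int = 250,
                   cor_threshold: float = 0.7, coverage: float = 0.95,
                   seed: int = 0, estimator_config: dict | None = None,
                   clpn_config: dict | None = None) -> StabilityProfile:
    """Correlation-stability coefficient via the case-dropping bootstrap.

    ``metric='ei'`` re-estimates the cross-sectional network of ``wave`` in
    each subset; ``'in_ei'``/``'out_ei'`` re-estimate the cross-lagged panel
    network (both waves, ``wave`` ignored).
    """
    from .clpn import fit_clpn  # deferred: clpn does not depend on resampling

    if metric not in ("ei", "in_ei", "out_ei"):
        raise ValueError(f"unknown centrality metric {metric!r}")
    grid = DEFAULT_DROP_GRID if drop_grid is None else np.asarray(drop_grid, float)
    if grid.max() > 0.75:
        raise ValueError("largest drop proportion must be <= 0.75")
    cfg = dict(estimator_config or {})
    ccfg = dict(clpn_config or {})

    def _centrality(sub: SymptomPanel, sub_seed: int) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if metric == "ei":
                return expected_influence(estimate_network(sub, wave, **cfg)).ei_raw
            net = fit_clpn(sub, seed=sub_seed, **ccfg)
            tab = directed_expected_influence(net)
            return tab.in_ei_raw if metric == "in_ei" else tab.out_ei_raw

    full = _centrality(panel, seed)
    n = panel.n
    correlations: dict[float, np.ndarray] = {}
    for gi, prop in enumerate(grid):
        m = int(round((1.0 - prop) * n))
        cors = []
        for d in range(n_boot):
            rng = _draw_rng(seed, gi * n_boot + d)
            if m < panel.p + 2:
                logger.debug("subset of %d too small at proportion %.2f", m, prop)
                continue
            idx = rng.choice(n, size=m, replace=False)
            try:
                sub_c = _centrality(panel.subset(idx), seed)
            except (ValueError, RuntimeError) as exc:
                logger.debug("case-drop draw failed at %.2f: %s", prop, exc)
                continue
            cors.append(_pearson_or_zero(sub_c, full))
        correlations[float(prop)] = np.array(cors)
    cs = 0.0
    for prop in sorted(correlations):
        cors = correlations[prop]
        if cors.size and np.mean(cors >= cor_threshold) >= coverage:
            cs = max(cs, prop)
    return StabilityProfile(
        metric=metric, drop_proportions=grid, correlations=correlations,
        cs_value=cs, cor_threshold=cor_threshold, coverage=coverage,
        n_boot=n_boot, seed=seed,
    )
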