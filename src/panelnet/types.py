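"""Core containers for two-wave symptom-panel network analysis.

The objects here are deliberately thin: validated numpy/pandas state plus
round-tripping readers and writers for the plain-text formats the pipeline
exchanges (wide panel CSV, edge-list CSV, JSON documents). All estimation
lives in the sibling modules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: DSM-5 PTSD symptom codes in instrument order: intrusion (B1-B5),
#: avoidance (C1-C2), negative alterations in cognitions and mood (D1-D7),
#: arousal and reactivity (E1-E6).
DEFAULT_NODE_LABELS: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "B5",
    "C1", "C2",
    "D1", "D2", "D3", "D4", "D5", "D6", "D7",
    "E1", "E2", "E3", "E4", "E5", "E6",
)

COVARIATE_COLUMNS = ("age", "sex", "race", "maltreat")


def zscore(values: np.ndarray) -> np.ndarray:
    """Population (n-denominator) z-scores; all-equal input maps to zeros.

    The degenerate case is flagged with a warning rather than an error so
    that empty networks (all centralities zero) flow through reporting.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std()  # population sd, ddof=0
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("all values equal; z-scores undefined, returning zeros")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


class GenerationError(RuntimeError):
    """Raised when a synthetic ground truth cannot be made positive definite."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge."""


@dataclass
class SymptomPanel:
    """Two-wave ordinal symptom panel with covariates and optional outcome.

    ``items_pre``/``items_post`` are n x p integer matrices of 0-4 symptom
    frequency ratings; ``outcome_pre``/``outcome_post`` are 0-40 totals with
    NaN marking missing values. Symptom waves themselves are required to be
    complete (the network sample is listwise complete).
    """

    subject_id: np.ndarray
    items_pre: np.ndarray
    items_post: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    race: np.ndarray
    maltreatment: np.ndarray
    outcome_pre: np.ndarray
    outcome_post: np.ndarray
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS

    def __post_init__(self) -> None:
        self.items_pre = np.asarray(self.items_pre, dtype=int)
        self.items_post = np.asarray(self.items_post, dtype=int)
        self.node_labels = tuple(self.node_labels)
        n, p = self.items_pre.shape
        if self.items_post.shape != (n, p):
            raise ValueError("items_pre and items_post shapes differ")
        if len(self.node_labels) != p:
            raise ValueError(f"{p} item columns but {len(self.node_labels)} node labels")
        if len(set(self.node_labels)) != p:
            raise ValueError("node labels must be unique")
        for name in ("items_pre", "items_post"):
            arr = getattr(self, name)
            if arr.min() < 0 or arr.max() > 4:
                raise ValueError(f"{name} entries must lie in 0..4")
        for name in ("subject_id", "age", "sex", "race", "maltreatment",
                     "outcome_pre", "outcome_post"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n={n}")
            setattr(self, name, arr)
        self.outcome_pre = np.asarray(self.outcome_pre, dtype=float)
        self.outcome_post = np.asarray(self.outcome_post, dtype=float)
        for name in ("outcome_pre", "outcome_post"):
            arr = getattr(self, name)
            obs = arr[~np.isnan(arr)]
            if obs.size and (obs.min() < 0 or obs.max() > 40):
                raise ValueError(f"{name} observed values must lie in [0, 40]")

    @property
    def n(self) -> int:
        return self.items_pre.shape[0]

    @property
    def p(self) -> int:
        return self.items_pre.shape[1]

    def items(self, wave: str) -> np.ndarray:
        if wave not in ("pre", "post"):
            raise ValueError(f"wave must be 'pre' or 'post', got {wave!r}")
        return self.items_pre if wave == "pre" else self.items_post

    def totals(self, wave: str) -> np.ndarray:
        return self.items(wave).sum(axis=1)

    def subset(self, mask: np.ndarray) -> "SymptomPanel":
        mask = np.asarray(mask)
        return SymptomPanel(
            subject_id=self.subject_id[mask],
            items_pre=self.items_pre[mask],
            items_post=self.items_post[mask],
            age=self.age[mask],
            sex=self.sex[mask],
            race=self.race[mask],
            maltreatment=self.maltreatment[mask],
            outcome_pre=self.outcome_pre[mask],
            outcome_post=self.outcome_post[mask],
            node_labels=self.node_labels,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": self.subject_id}
        for j, lab in enumerate(self.node_labels):
            cols[f"pre_{lab}"] = self.items_pre[:, j]
        for j, lab in enumerate(self.node_labels):
            cols[f"post_{lab}"] = self.items_post[:, j]
        cols.update(
            age=self.age, sex=self.sex, race=self.race,
            maltreat=self.maltreatment,
            sdq_pre=self.outcome_pre, sdq_post=self.outcome_post,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS,
                       ) -> "SymptomPanel":
        labels = tuple(node_labels)
        for lab in labels:
            for prefix in ("pre", "post"):
                col = f"{prefix}_{lab}"
                if col not in df.columns:
                    raise ValueError(f"panel is missing symptom column {col!r}")
        for col in ("id", "age", "sex", "race", "maltreat"):
            if col not in df.columns:
                raise ValueError(f"panel is missing column {col!r}")
        pre = df[[f"pre_{lab}" for lab in labels]].to_numpy()
        post = df[[f"post_{lab}" for lab in labels]].to_numpy()
        if np.isnan(pre).any() or np.isnan(post).any():
            raise ValueError("symptom waves must be complete (no missing entries)")
        nan_col = np.full(len(df), np.nan)
        return cls(
            subject_id=df["id"].to_numpy(),
            items_pre=pre.astype(int),
            items_post=post.astype(int),
            age=df["age"].to_numpy(dtype=float),
            sex=df["sex"].to_numpy(dtype=int),
            race=df["race"].to_numpy(dtype=int),
            maltreatment=df["maltreat"].to_numpy(dtype=int),
            outcome_pre=df["sdq_pre"].to_numpy(dtype=float) if "sdq_pre" in df else nan_col,
            outcome_post=df["sdq_post"].to_numpy(dtype=float) if "sdq_post" in df else nan_col.copy(),
            node_labels=labels,
        )

    @classmethod
    def from_csv(cls, path: str | Path,
                 node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS) -> "SymptomPanel":
        return cls.from_dataframe(pd.read_csv(path), node_labels)


@dataclass
class SyntheticTruth:
    """Generating quantities behind a synthetic panel; the recovery oracle.

    ``lagged[i, j]`` is the standardized effect of symptom i at wave 1 on
    symptom j at wave 2; the diagonal holds autoregressive effects.
    """

    precision_pre: np.ndarray
    lagged: np.ndarray
    innovation_precision: np.ndarray
    thresholds: np.ndarray          # p x 4 increasing latent cutpoints
    mean_shift: np.ndarray          # per-item latent reduction at wave 2, >= 0
    outcome_betas: dict
    missing_rate: dict
    seed: int
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS

    def __post_init__(self) -> None:
        self.precision_pre = np.asarray(self.precision_pre, dtype=float)
        self.lagged = np.asarray(self.lagged, dtype=float)
        self.innovation_precision = np.asarray(self.innovation_precision, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.mean_shift = np.asarray(self.mean_shift, dtype=float)
        p = self.precision_pre.shape[0]
        for name in ("precision_pre", "innovation_precision"):
            K = getattr(self, name)
            if not np.allclose(K, K.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(K).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.lagged.shape != (p, p):
            raise ValueError("lagged matrix shape mismatch")
        if self.thresholds.shape != (p, 4):
            raise ValueError("thresholds must be p x 4")
        if not (np.diff(self.thresholds, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly increasing within each item")
        if (self.mean_shift < 0).any():
            raise ValueError("mean_shift must be nonnegative")

    @property
    def p(self) -> int:
        return self.precision_pre.shape[0]

    @property
    def partials_pre(self) -> np.ndarray:
        """Partial correlations implied by the wave-1 precision matrix."""
        K = self.precision_pre
        d = np.sqrt(np.diag(K))
        R = -K / np.outer(d, d)
        np.fill_diagonal(R, 0.0)
        return R

    @property
    def central_mask(self) -> np.ndarray:
        """Nodes whose generating expected influence has z > 1 (core set)."""
        ei = self.partials_pre.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return zscore(ei) > 1.0

    def to_json(self, path: str | Path) -> None:
        doc = {
            "precision_pre": self.precision_pre.tolist(),
            "lagged": self.lagged.tolist(),
            "innovation_precision": self.innovation_precision.tolist(),
            "thresholds": self.thresholds.tolist(),
            "mean_shift": self.mean_shift.tolist(),
            "outcome_betas": self.outcome_betas,
            "missing_rate": self.missing_rate,
            "seed": int(self.seed),
            "node_labels": list(self.node_labels),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            precision_pre=np.array(doc["precision_pre"]),
            lagged=np.array(doc["lagged"]),
            innovation_precision=np.array(doc["innovation_precision"]),
            thresholds=np.array(doc["thresholds"]),
            mean_shift=np.array(doc["mean_shift"]),
            outcome_betas=doc["outcome_betas"],
            missing_rate=doc["missing_rate"],
            seed=doc["seed"],
            node_labels=tuple(doc["node_labels"]),
        )


@dataclass
class WeightedNetwork:
    """Symmetric regularized partial-correlation network (one wave)."""

    node_labels: tuple[str, ...]
    weights: np.ndarray
    lambda_selected: float
    gamma: float
    n: int
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = tuple(self.node_labels)
        W = self.weights
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(W)).max() > 0:
            raise ValueError("diagonal must be exactly zero")
        if np.abs(W).max() > 1 + 1e-9:
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def global_strength(self) -> float:
        iu = np.triu_indices(self.p, k=1)
        return float(np.abs(self.weights[iu]).sum())

    def to_edge_csv(self, path: str | Path) -> None:
        iu, ju = np.triu_indices(self.p, k=1)
        rows = [
            {"node_i": self.node_labels[i], "node_j": self.node_labels[j],
             "weight": self.weights[i, j]}
            for i, j in zip(iu, ju) if self.weights[i, j] != 0
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "node_labels": list(self.node_labels),
            "weights": self.weights.tolist(),
            "lambda_selected": self.lambda_selected,
            "gamma": self.gamma,
            "n": int(self.n),
            "n_edges": self.n_edges,
            "correlation_method": self.correlation_method,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightedNetwork":
        doc = json.loads(Path(path).read_text())
        return cls(
            node_labels=tuple(doc["node_labels"]),
            weights=np.array(doc["weights"]),
            lambda_selected=doc["lambda_selected"],
            gamma=doc["gamma"],
            n=doc["n"],
            correlation_method=doc["correlation_method"],
        )


@dataclass
class DirectedNetwork:
    """Cross-lagged panel network: b[i, j] = standardized effect of wave-1
    symptom i on wave-2 symptom j; the diagonal holds autoregressive effects."""

    node_labels: tuple[str, ...]
    b: np.ndarray
    alphas: np.ndarray              # per-outcome selected penalty
    k_folds: int
    covariate_adjusted: bool
    seed: int
    covariate_coefs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.node_labels = tuple(self.node_labels)
        if not np.isfinite(self.b).all():
            raise ValueError("all coefficients must be finite")
        if self.b.shape[0] != self.b.shape[1]:
            raise ValueError("b must be square")

    @property
    def p(self) -> int:
        return self.b.shape[0]

    @property
    def autoregressive(self) -> np.ndarray:
        return np.diag(self.b).copy()

    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for i in range(self.p):
            for j in range(self.p):
                if self.b[i, j] != 0:
                    rows.append({
                        "source": self.node_labels[i],
                        "target": self.node_labels[j],
                        "weight": self.b[i, j],
                        "is_autoregressive": i == j,
                    })
        pd.DataFrame(rows, columns=["source", "target", "weight", "is_autoregressive"]
                     ).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "node_labels": list(self.node_labels),
            "b": self.b.tolist(),
            "alphas": np.asarray(self.alphas).tolist(),
            "k_folds": int(self.k_folds),
            "covariate_adjusted": bool(self.covariate_adjusted),
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DirectedNetwork":
        doc = json.loads(Path(path).read_text())
        return cls(
            node_labels=tuple(doc["node_labels"]),
            b=np.array(doc["b"]),
            alphas=np.array(doc["alphas"]),
            k_folds=doc["k_folds"],
            covariate_adjusted=doc["covariate_adjusted"],
            seed=doc["seed"],
        )


@dataclass
class CentralityTable:
    """Per-node expected influence (signed one-step), z-scores and core flags.

    For directed networks the in/out variants are populated instead of ``ei``.
    z-scores use the population standard deviation across nodes (recorded in
    ``meta``); nodes with z > cutoff are flagged central.
    """

    node_labels: tuple[str, ...]
    ei_raw: np.ndarray | None = None
    ei_z: np.ndarray | None = None
    is_central: np.ndarray | None = None
    in_ei_raw: np.ndarray | None = None
    in_ei_z: np.ndarray | None = None
    in_is_central: np.ndarray | None = None
    out_ei_raw: np.ndarray | None = None
    out_ei_z: np.ndarray | None = None
    out_is_central: np.ndarray | None = None
    meta: dict = field(default_factory=lambda: {"z_sd": "population", "z_cutoff": 1.0})

    def metric(self, name: str) -> np.ndarray:
        """Raw centrality vector by name: 'ei', 'in_ei' or 'out_ei'."""
        vec = {"ei": self.ei_raw, "in_ei": self.in_ei_raw, "out_ei": self.out_ei_raw}.get(name)
        if vec is None:
            raise KeyError(f"metric {name!r} not available in this table")
        return vec

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for metric in ("ei", "in_ei", "out_ei"):
            raw = getattr(self, f"{metric}_raw" if metric == "ei" else f"{metric}_raw")
            if raw is None:
                continue
            z = getattr(self, f"{metric}_z")
            flag = getattr(self, "is_central" if metric == "ei" else f"{metric.split('_')[0]}_is_central")
            for lab, r, zz, fl in zip(self.node_labels, raw, z, flag):
                rows.append({"node": lab, "metric": metric, "raw": r, "z": zz,
                             "is_central": bool(fl)})
        return pd.DataFrame(rows, columns=["node", "metric", "raw", "z", "is_central"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class RegressionReport:
    """Rows of {term, B, SE, t, p} plus estimation metadata."""

    table: pd.DataFrame
    n_used: int
    estimator: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"term", "B", "SE", "t", "p"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"report table must have columns {sorted(required)}")
        ok = np.isfinite(self.table["SE"]) & (self.table["SE"] > 0)
        ratio = self.table.loc[ok, "B"] / self.table.loc[ok, "SE"]
        if not np.allclose(ratio, self.table.loc[ok, "t"], atol=1e-10):
            raise ValueError("t must equal B/SE")

    def coef(self, term: str) -> float:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["B"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
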