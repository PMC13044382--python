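"""End-to-end orchestration of the two-wave network analysis.

``run_pipeline`` reproduces the full analysis sequence on a panel CSV or
in-memory panel: descriptives -> pre/post networks with EI, edge bootstraps
and CS profiles -> paired NCT -> cross-lagged panel network (unadjusted and
covariate-adjusted) with in/out EI and stability -> symptom importance and
centrality regressions -> core-vs-peripheral outcome regressions. All
artifacts land in a run directory as CSV/JSON and are fully re-derivable
from the config plus the master seed: each stage draws its randomness from
a seed hashed out of (master_seed, stage name), so adding a stage never
perturbs earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import directed_expected_influence, expected_influence
from .clinical import (core_peripheral_outcome_regression, descriptives,
                       centrality_importance_regression, little_mcar_test,
                       symptom_importance)
from .clpn import autoregressive_contrast, fit_clpn, strong_edges
from .comparison import nct_independent, nct_paired
from .ggm import estimate_network
from .resampling import bootstrap_edges, cs_coefficient
from .types import DEFAULT_NODE_LABELS, SymptomPanel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis settings; defaults mirror the standard reporting conventions
    (gamma .5, 1,000 bootstrap samples, 1,000 permutations, 10 folds,
    z > 1.0 central, display threshold 0.10, CS correlation 0.7)."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"
    n_boot: int = 1000
    n_perm: int = 1000
    k_folds: int = 10
    ei_z_cutoff: float = 1.0
    display_threshold: float = 0.10
    drop_grid: tuple = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))
    cs_threshold: float = 0.7
    outcome_estimator: str = "fiml_em"
    n_boot_se: int = 200
    cs_n_boot: int | None = None
    master_seed: int = 0
    covariates: tuple = ("age", "sex", "race", "maltreatment")
    item_to_symptom_map: str | None = None

    @property
    def estimator_config(self) -> dict:
        return {"gamma": self.gamma, "n_lambda": self.n_lambda,
                "lambda_min_ratio": self.lambda_min_ratio,
                "method": self.correlation_method}

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2**31, independent across stages."""
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["drop_grid"] = list(doc["drop_grid"])
        doc["covariates"] = list(doc["covariates"])
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_grid" in doc:
            doc["drop_grid"] = tuple(doc["drop_grid"])
        if "covariates" in doc:
            doc["covariates"] = tuple(doc["covariates"])
        return cls(**doc)


def load_panel(path: str | Path, mapping_path: str | Path | None = None,
               node_labels=DEFAULT_NODE_LABELS) -> SymptomPanel:
    """Read a wide panel CSV, optionally collapsing instrument items first.

    ``mapping_path`` names a two-column CSV (item, symptom); mapped item
    columns (pre_<item>/post_<item>) are aggregated to symptom scores by
    the max rule before validation.
    """
    df = pd.read_csv(path)
    if mapping_path is not None:
        mapping = pd.read_csv(mapping_path)
        if not {"item", "symptom"}.issubset(mapping.columns):
            raise ValueError("mapping file needs 'item' and 'symptom' columns")
        for prefix in ("pre", "post"):
            for symptom, grp in mapping.groupby("symptom"):
                cols = [f"{prefix}_{it}" for it in grp["item"]]
                missing = [c for c in cols if c not in df.columns]
                if missing:
                    raise ValueError(f"mapped item column(s) absent: {missing}")
                df[f"{prefix}_{symptom}"] = df[cols].max(axis=1)
    return SymptomPanel.from_dataframe(df, node_labels)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=float))


def run_pipeline(panel: SymptomPanel | str | Path, config: PipelineConfig,
                 outdir: str | Path) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    if not isinstance(panel, SymptomPanel):
        panel = load_panel(panel, config.item_to_symptom_map)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    log_lines = [f"panelnet {__version__}",
                 f"numpy {np.__version__}, pandas {pd.__version__}",
                 f"n={panel.n} p={panel.p} master_seed={config.master_seed}"]
    results: dict = {}
    cfg = config.estimator_config

    # descriptives ---------------------------------------------------------
    desc = descriptives(panel)
    results["descriptives"] = desc
    _json_dump(desc, out / "descriptives.json")
    log_lines.append("descriptives: done")

    # cross-sectional networks + EI ---------------------------------------
    nets, eis = {}, {}
    for wave in ("pre", "post"):
        net = estimate_network(panel, wave, **cfg)
        tab = expected_influence(net, config.ei_z_cutoff)
        nets[wave], eis[wave] = net, tab
        net.to_edge_csv(out / f"network_{wave}_edges.csv")
        net.to_json(out / f"network_{wave}.json")
        tab.to_csv(out / f"centrality_{wave}.csv")
        log_lines.append(f"network_{wave}: lambda={net.lambda_selected:.5f} "
                         f"edges={net.n_edges}")
    results["networks"] = nets
    results["centrality"] = eis

    # bootstrap accuracy + stability --------------------------------------
    boots = {}
    for wave in ("pre", "post"):
        seed = config.stage_seed(f"bootstrap_{wave}")
        eb = bootstrap_edges(panel, wave, cfg, n_boot=config.n_boot, seed=seed)
        boots[wave] = eb
        eb.to_csv(out / f"edge_bootstrap_{wave}.csv")
        log_lines.append(f"bootstrap_{wave}: seed={seed} "
                         f"mean_ci_width={eb.mean_ci_width:.4f}")
    results["edge_bootstraps"] = boots
    profiles = {}
    for wave in ("pre", "post"):
        seed = config.stage_seed(f"cs_{wave}")
        prof = cs_coefficient(panel, wave, "ei", np.asarray(config.drop_grid),
                              n_boot=config.cs_n_boot or config.n_boot,
                              cor_threshold=config.cs_threshold, seed=seed,
                              estimator_config=cfg)
        profiles[f"ei_{wave}"] = prof
        prof.to_json(out / f"stability_ei_{wave}.json")
        log_lines.append(f"cs_ei_{wave}: seed={seed} cs={prof.cs_value}")

    # paired NCT -----------------------------------------------------------
    seed = config.stage_seed("nct_paired")
    nct = nct_paired(panel, cfg, n_perm=config.n_perm, seed=seed)
    results["nct_paired"] = nct
    nct.to_json(out / "nct_paired.json")
    log_lines.append(f"nct_paired: seed={seed} M={nct.m_observed:.4f} "
                     f"S={nct.s_observed:.4f} pM={nct.m_pvalue:.4f} "
                     f"pS={nct.s_pvalue:.4f}")

    # CLPN ----------------------------------------------------------------
    clpn_seed = config.stage_seed("clpn")
    clpn = fit_clpn(panel, k_folds=config.k_folds, seed=clpn_seed)
    clpn_adj = fit_clpn(panel, k_folds=config.k_folds, seed=clpn_seed,
                        covariates=list(config.covariates))
    results["clpn"] = clpn
    results["clpn_adjusted"] = clpn_adj
    for name, net in (("clpn", clpn), ("clpn_adjusted", clpn_adj)):
        net.to_json(out / f"{name}.json")
        net.to_long_csv(out / f"{name}_edges.csv")
    if clpn_adj.covariate_coefs is not None:
        clpn_adj.covariate_coefs.to_csv(out / "clpn_covariate_coefs.csv",
                                        index=False)
    strong_edges(clpn, config.display_threshold).to_csv(
        out / "clpn_strong_edges.csv", index=False)
    dir_tab = directed_expected_influence(clpn, config.ei_z_cutoff)
    results["clpn_centrality"] = dir_tab
    dir_tab.to_csv(out / "centrality_clpn.csv")
    contrast = autoregressive_contrast(clpn)
    results["autoregressive_contrast"] = contrast
    _json_dump(contrast, out / "autoregressive_contrast.json")
    log_lines.append(f"clpn: seed={clpn_seed} mean_auto={contrast['mean_auto']:.4f} "
                     f"mean_cross={contrast['mean_cross']:.4f}")
    for metric in ("in_ei", "out_ei"):
        seed = config.stage_seed(f"cs_{metric}")
        prof = cs_coefficient(panel, "pre", metric,
                              np.asarray(config.drop_grid),
                              n_boot=config.cs_n_boot or config.n_boot,
                              cor_threshold=config.cs_threshold, seed=seed,
                              clpn_config={"k_folds": config.k_folds})
        profiles[metric] = prof
        prof.to_json(out / f"stability_{metric}.json")
        log_lines.append(f"cs_{metric}: seed={seed} cs={prof.cs_value}")
    results["stability"] = profiles

    # importance + centrality regressions ---------------------------------
    imp = symptom_importance(panel, centrality_z={
        "pre_ei_z": eis["pre"].ei_z,
        "in_ei_z": dir_tab.in_ei_z,
        "out_ei_z": dir_tab.out_ei_z,
    })
    results["importance"] = imp
    imp.to_csv(out / "importance.csv", index=False)
    reg_results = {}
    for col in ("pre_ei_z", "in_ei_z", "out_ei_z"):
        rep = centrality_importance_regression(imp, col)
        reg_results[col] = rep
        rep.to_csv(out / f"importance_regression_{col}.csv")
        log_lines.append(f"importance_regression_{col}: "
                         f"B={rep.coef(col):.4f}")
    results["importance_regressions"] = reg_results

    # outcome regressions --------------------------------------------------
    M_vars = np.column_stack([panel.outcome_pre, panel.outcome_post,
                              panel.totals("pre").astype(float),
                              panel.age.astype(float)])
    try:
        mcar = little_mcar_test(M_vars)
    except ValueError:
        mcar = {"chi2": None, "df": None, "p": None, "n_patterns": 1}
    results["mcar"] = mcar
    _json_dump(mcar, out / "little_mcar.json")
    outcome_reports = {}
    flag_sets = {"ei": eis["pre"].is_central, "in_ei": dir_tab.in_is_central}
    for name, flags in flag_sets.items():
        if flags.sum() < 1 or (~flags).sum() < 1:
            log_lines.append(f"outcome_regression_{name}: skipped (no core set)")
            continue
        seed = config.stage_seed(f"outcome_{name}")
        rep = core_peripheral_outcome_regression(
            panel, flags, estimator=config.outcome_estimator,
            n_boot_se=config.n_boot_se, seed=seed)
        outcome_reports[name] = rep
        rep.to_csv(out / f"outcome_regression_{name}.csv")
        log_lines.append(f"outcome_regression_{name}: seed={seed} "
                         f"B(core)={rep.coef('core_change'):.4f}")
    results["outcome_regressions"] = outcome_reports

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def subgroup_runs(panel: SymptomPanel | str | Path, split_var: str,
                  config: PipelineConfig, outdir: str | Path) -> dict:
    """Per-subgroup networks/EI/paired NCT plus between-group NCT per wave.

    ``split_var`` is one of sex / race / maltreatment / age_median.
    Groups smaller than the node count are skipped with a warning.
    """
    if not isinstance(panel, SymptomPanel):
        panel = load_panel(panel, config.item_to_symptom_map)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if split_var == "age_median":
        med = np.median(panel.age)
        values = (panel.age > med).astype(int)
    elif split_var in ("sex", "race"):
        values = getattr(panel, split_var)
    elif split_var == "maltreatment":
        values = panel.maltreatment
    else:
        raise ValueError(f"unknown split variable {split_var!r}")
    cfg = config.estimator_config
    groups: dict[int, SymptomPanel] = {}
    results: dict = {"groups": {}, "between": {}}
    for g in np.unique(values):
        sub = panel.subset(values == g)
        if sub.n < panel.p:
            warnings.warn(f"group {split_var}={g} has only {sub.n} subjects; skipped")
            continue
        groups[int(g)] = sub
        gdir = out / f"{split_var}_{g}"
        gdir.mkdir(exist_ok=True)
        gres = {}
        for wave in ("pre", "post"):
            net = estimate_network(sub, wave, **cfg)
            tab = expected_influence(net, config.ei_z_cutoff)
            net.to_edge_csv(gdir / f"network_{wave}_edges.csv")
            tab.to_csv(gdir / f"centrality_{wave}.csv")
            gres[f"network_{wave}"] = net
            gres[f"centrality_{wave}"] = tab
        seed = config.stage_seed(f"subgroup_nct_{split_var}_{g}")
        nct = nct_paired(sub, cfg, n_perm=config.n_perm, seed=seed)
        nct.to_json(gdir / "nct_paired.json")
        gres["nct_paired"] = nct
        results["groups"][int(g)] = gres
    keys = sorted(groups)
    if len(keys) == 2:
        a, b = keys
        for wave in ("pre", "post"):
            seed = config.stage_seed(f"between_nct_{split_var}_{wave}")
            nct = nct_independent(groups[a], groups[b], wave, cfg,
                                  n_perm=config.n_perm, seed=seed)
            nct.to_json(out / f"between_nct_{wave}.json")
            results["between"][wave] = nct
    return results
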