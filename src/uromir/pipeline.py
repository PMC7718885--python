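"""End-to-end orchestration: configured multi-stage runs with provenance.

A run is described by a single TOML config (stage list plus per-stage
sections); every output file records the package version, a hash of the
config, and the seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .datasets import load_discovery_derivatives
from .diagnostics import percent, sens_spec_at_cutoff
from .expression import read_expression_matrix, screen_differential
from .panel import (
    DEFAULT_CUTOFF,
    SEVEN_PARAM_SUBSET,
    PanelModel,
    fit_panel,
    panel_sum,
    score_cohort,
    search_best_panel,
)
from .prioritize import (
    ScoreWeights,
    breakdowns_to_frame,
    compute_marker_score,
    profiles_from_bank,
    rank_markers,
)
from .qpcr import consolidate_table
from .simulate import default_cohort_spec, simulate_urinary_cohort

log = logging.getLogger("uromir")

__all__ = ["run_pipeline", "reproduce_discovery", "load_config", "write_tsv"]

KNOWN_STAGES = ("simulate", "screen", "rank", "qpcr", "panel-fit", "panel-score", "roc")


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    cfg["_config_hash"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
    return cfg


def _provenance(cfg: dict) -> dict:
    return {
        "uromir_version": __version__,
        "config_hash": cfg.get("_config_hash", "none"),
        "seed": cfg.get("seed", None),
    }


def write_tsv(df: pd.DataFrame, path, cfg: Optional[dict] = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in _provenance(cfg or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj: dict, path, cfg: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = {"provenance": _provenance(cfg or {}), **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def reproduce_discovery(cutoff: float = DEFAULT_CUTOFF) -> dict:
    """Re-derive the headline panel numbers from the packaged fixtures.

    Sums the packaged derivative matrix over the seven-parameter panel
    and evaluates it at the given cutoff; returns AUC, sensitivity and
    specificity with exact 95% CIs.
    """
    derivs = load_discovery_derivatives()
    scores = panel_sum(derivs, SEVEN_PARAM_SUBSET)
    case = (derivs.groups == "ccRCC").to_numpy()
    m = sens_spec_at_cutoff(scores.to_numpy(), case, cutoff=cutoff)
    return {
        "subset": list(SEVEN_PARAM_SUBSET),
        "cutoff": cutoff,
        "auc": round(m.auc, 2),
        "auc_p": m.auc_p,
        "sensitivity_pct": percent(m.sensitivity),
        "specificity_pct": percent(m.specificity),
        "sensitivity_ci_pct": [percent(x) for x in m.sensitivity_ci],
        "specificity_ci_pct": [percent(x) for x in m.specificity_ci],
        "confusion": {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn},
    }


def run_pipeline(cfg: dict, base_dir=".") -> dict:
    """Execute the configured stages in order and return a run report."""
    base = Path(base_dir)
    stages = cfg.get("stages", [])
    report: dict = {"stages_run": [], **_provenance(cfg)}
    if not stages:
        log.warning("empty stage list: nothing to do")
        report["warning"] = "empty stage list"
        return report
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; expected {KNOWN_STAGES}")

    for stage in stages:
        sec = cfg.get(stage.replace("-", "_"), {})
        log.info("stage %s: %s", stage, sec)
        if stage == "simulate":
            spec = default_cohort_spec(
                n_case=sec.get("n_case", 13),
                n_control=sec.get("n_control", 14),
                seed=sec.get("seed", cfg.get("seed", 0)),
            )
            cohort = simulate_urinary_cohort(spec)
            write_tsv(cohort, base / sec.get("out", "cohort.tsv"), cfg)
        elif stage == "screen":
            expr = read_expression_matrix(base / sec["matrix"], base / sec["annotations"])
            res = screen_differential(
                expr,
                case_tissue=sec.get("case", "ccRCC_kidney"),
                control_tissue=sec.get("control", "kidney"),
                up_threshold=sec.get("up", 1.73),
                down_threshold=sec.get("down", 0.77),
                alpha=sec.get("alpha", 0.05),
            )
            write_tsv(res, base / sec.get("out", "screen.tsv"), cfg, index=False)
            report["screen_overexpressed"] = int((res["classification"] == "overexpressed").sum())
        elif stage == "rank":
            expr = read_expression_matrix(base / sec["matrix"], base / sec["annotations"])
            weights = ScoreWeights(**sec.get("weights", {}))
            ranked = rank_markers(
                [
                    compute_marker_score(p, weights, sec.get("sex", "male"))
                    for p in profiles_from_bank(expr)
                ]
            )
            write_tsv(breakdowns_to_frame(ranked), base / sec.get("out", "ranking.tsv"), cfg, index=False)
            report["top_marker"] = ranked[0].mirna
        elif stage == "qpcr":
            table = pd.read_csv(base / sec["in"], sep="\t", comment="#")
            cons = consolidate_table(table, mode=sec.get("mode", "urine"))
            write_tsv(cons, base / sec.get("out", "consensus.tsv"), cfg)
        elif stage == "panel-fit":
            cohort = pd.read_csv(base / sec["ct"], sep="\t", comment="#", index_col=0)
            model, result, _ = fit_panel(cohort, cutoff=sec.get("cutoff"))
            out = base / sec.get("out", "model.json")
            out.parent.mkdir(parents=True, exist_ok=True)
            out.write_text(model.to_json(**_provenance(cfg)))
            report["panel_subset"] = list(result.subset)
            report["panel_auc"] = result.metrics.auc
        elif stage == "panel-score":
            cohort = pd.read_csv(base / sec["ct"], sep="\t", comment="#", index_col=0)
            model = PanelModel.from_json((base / sec["model"]).read_text())
            scored = score_cohort(model, cohort)
            write_tsv(scored, base / sec.get("out", "scores.tsv"), cfg)
        elif stage == "roc":
            scored = pd.read_csv(base / sec["scores"], sep="\t", comment="#", index_col=0)
            case = (scored["group"] == "ccRCC").to_numpy()
            m = sens_spec_at_cutoff(
                scored["score"].to_numpy(), case, cutoff=sec.get("cutoff", DEFAULT_CUTOFF)
            )
            write_json({"metrics": m.as_dict()}, base / sec.get("out", "metrics.json"), cfg)
            report["auc"] = m.auc
            report["sensitivity_pct"] = percent(m.sensitivity)
            report["specificity_pct"] = percent(m.specificity)
        report["stages_run"].append(stage)
    return report
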