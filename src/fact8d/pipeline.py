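"""End-to-end orchestration: design -> simulate/ingest -> QC -> fits ->
raking -> value set -> scoring, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DCEDesign
from .estimation import ConditionalLogitQALY, compare_fits
from .qc import build_qc_report
from .raking import Raker, variance_inflation
from .simulate import default_true_parameters, simulate_cohort
from .valueset import MonotonicConditionalLogit, preference_weights, score_factg_file

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "fact8d_run",
    "n_respondents": 2054,
    "design": {"n_candidates": 50},
    "truth": {"alpha": 0.4, "noise_scale": 1.0},
    "pathologies": {"all_A_fraction": 0.0, "all_B_fraction": 0.0, "fast_random_fraction": 0.0},
    "weighting": {"enabled": True, "threshold": 0.02},
    "qc": {"n_deciles": 10},
    "score_responses": None,  # optional path to a FACT-G responses CSV
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config=None) -> Path:
    """Run every stage under one seed and write artifacts plus a manifest.

    Outputs (CSV/JSON, all deterministic given the seed): the design and
    its generator sidecar, simulated choices and demographics, raking
    weights, QC report, the four fits (Models 1 and 2, unweighted and
    weighted), the recommended value set, and optionally scored FACT-G
    responses.
    """
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- design ---------------------------------------------------------
    design = DCEDesign.build(seed=seed, n_candidates=int(cfg["design"]["n_candidates"]))
    design.to_csv(out / "design.csv")
    design.write_sidecar(out / "design.json")

    # --- simulate -------------------------------------------------------
    truth = default_true_parameters(
        alpha=float(cfg["truth"]["alpha"]), noise_scale=float(cfg["truth"]["noise_scale"])
    )
    cohort = simulate_cohort(
        design.choice_sets,
        n_respondents=int(cfg["n_respondents"]),
        params=truth,
        seed=seed,
        **{k: float(v) for k, v in cfg["pathologies"].items()},
    )
    cohort.choices.to_csv(out / "choices.csv", index=False)
    cohort.demographics.to_csv(out / "demographics.csv")
    cohort.targets.to_csv(out / "targets.csv", index=False)
    truth_record = {
        "alpha": truth.alpha,
        "noise_scale": truth.noise_scale,
        "beta": {f"{d}_L{l}": v for (d, l), v in truth.beta.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth_record, indent=2, sort_keys=True))

    # --- qc -------------------------------------------------------------
    report = build_qc_report(
        cohort.choices, cohort.completion_times, n_deciles=int(cfg["qc"]["n_deciles"])
    )
    (out / "qc.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    if report.decile_table is not None:
        report.decile_table.to_csv(out / "qc_deciles.csv", index=False)

    # --- raking ---------------------------------------------------------
    weights = None
    if cfg["weighting"]["enabled"]:
        raker = Raker(
            targets=cohort.targets, threshold=float(cfg["weighting"]["threshold"])
        ).fit(cohort.demographics)
        weights = raker.weights_
        weights.rename("weight").to_csv(out / "weights.csv")

    # --- fits: (Model 1, Model 2) x (unweighted, weighted) --------------
    fits: dict[str, object] = {}
    m1u = ConditionalLogitQALY().fit(cohort.choices)
    fits["model1_unweighted"] = m1u
    m2u = MonotonicConditionalLogit().fit(cohort.choices)
    fits["model2_unweighted"] = m2u.fit_
    if weights is not None:
        m1w = ConditionalLogitQALY().fit(cohort.choices, sample_weight=weights)
        fits["model1_weighted"] = m1w
        m2w = MonotonicConditionalLogit().fit(cohort.choices, sample_weight=weights)
        fits["model2_weighted"] = m2w.fit_
        recommended = m2w.fit_
    else:
        recommended = m2u.fit_
    for name, fit in fits.items():
        (out / f"fit_{name}.json").write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))

    diagnostics = {
        "model2_vs_model1_unweighted": {
            k: v for k, v in compare_fits(m1u, m2u.fit_).items() if np.isscalar(v)
        }
    }
    if weights is not None:
        vi = variance_inflation(m1u, fits["model1_weighted"])
        diagnostics["weighting_variance_inflation_mean_pct"] = vi["mean_pct"]
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, sort_keys=True))

    # --- value set ("recommended" preset: weighted + constrained) -------
    vs = preference_weights(recommended)
    vs.to_csv(out / "valueset.csv")

    # --- scoring --------------------------------------------------------
    if cfg.get("score_responses"):
        score_factg_file(cfg["score_responses"], vs, out / "utilities.csv")

    # --- manifest -------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "artifact_hashes": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
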