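"""End-to-end pipeline: design -> responses -> models -> post-hoc -> mixing.

Configuration is a nested mapping (usually loaded from YAML).  Every stage
writes delimited-text or JSON artifacts into the output directory and one
structured log line; given fixed seeds the numeric outputs are
deterministic, byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import design as dz
from . import io as pio
from . import posthoc, rsm, synth
from .mixing import build_geometry, simulate_mixing

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Pipeline defaults: analyse the packaged study fixture."""
    return {
        "seed": 0,
        "data": {"source": "fixture"},
        "design": {
            "factors": {
                "frr": {"low": 1.0, "high": 12.0, "decimals": 1},
                "tfr": {"low": 3.0, "high": 18.0, "decimals": 1},
            },
            "cube_reps": 3, "axial_reps": 3, "center_reps": 5,
        },
        "analysis": {
            "alpha": 0.05,
            "responses": ["z_average_nm", "pdi", "zeta_mv"],
            "optimize": {
                "response": "z_average_nm", "sense": "min",
                "bounds": {"frr": [1.0, 12.0], "tfr": [3.0, 18.0]},
            },
            "tukey": ["pdi", "zeta_mv"],
        },
        "mixing": {"enabled": False, "tfr": 18.0, "frr_values": [1.0, 3.0],
                   "n_obstacles": 8, "cells_across": 30},
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _design_spec(cfg: Mapping, seed: int) -> dz.DesignSpec:
    d = cfg["design"]
    factors = tuple(
        dz.FactorSpec(name, float(f["low"]), float(f["high"]),
                      int(f.get("decimals", 1)))
        for name, f in d["factors"].items()
    )
    return dz.DesignSpec(
        factors=factors, cube_reps=int(d["cube_reps"]),
        axial_reps=int(d["axial_reps"]), center_reps=int(d["center_reps"]),
        seed=seed,
    )


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: Mapping | str | Path | None = None,
                 outdir: str | Path = "pdmix_out") -> dict:
    """Run the full analysis and write a report bundle to ``outdir``.

    ``config`` may be a mapping, a YAML path, or None for the defaults;
    partial configurations are merged over :func:`default_config`.
    Returns a summary dictionary (also written as ``summary.json``).
    """
    if isinstance(config, (str, Path)):
        config = pio.load_config(config)
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **info):
        line = f"{stage}: " + ", ".join(f"{k}={v}" for k, v in info.items())
        logger.info(line)
        log_lines.append(line)

    seed = int(cfg["seed"])
    summary: dict[str, Any] = {"seed": seed}

    try:
        spec = _design_spec(cfg, seed)
        table = dz.build_cccr_design(spec)
        pio.save_run_table(table, outdir / "design.csv")
        log("design", runs=len(table), alpha=round(spec.alpha, 2), seed=seed)

        source = cfg["data"]["source"]
        if source == "fixture":
            runs = pio.load_study_runs()
        elif source == "synthetic":
            truth = synth.TruthSpec(**cfg["data"].get("noise", {}))
            runs = synth.generate_run_table(table, truth, seed=seed)
        else:
            runs = pio.load_run_table(source)
        pio.save_run_table(runs, outdir / "runs.csv")
        log("responses", source=source, runs=len(runs))

        alpha = float(cfg["analysis"]["alpha"])
        models: dict[str, rsm.SurfaceModel] = {}
        for resp in cfg["analysis"]["responses"]:
            model, report = rsm.reduce_model(runs, resp, alpha=alpha)
            models[resp] = model
            (outdir / f"model_{resp}.txt").write_text(report.to_text() + "\n")
            anova = {
                "response": resp,
                "terms": model.terms,
                "coefficients": list(model.coefficients),
                "significant": model.significant,
                "r2_percent": 100 * report.r2,
                "r2_adj_percent": 100 * report.r2_adj,
                "r2_pred_percent": 100 * report.r2_pred,
                "f_model": report.f_model,
                "p_model": report.p_model,
            }
            with open(outdir / f"model_{resp}.json", "w") as fh:
                json.dump(anova, fh, indent=1, default=_json_default)
            summary[f"model_{resp}"] = anova
            log("fit", response=resp, terms="+".join(model.terms),
                r2=f"{100 * report.r2:.2f}%")

        opt_cfg = cfg["analysis"].get("optimize")
        if opt_cfg:
            model = models[opt_cfg["response"]]
            if model.significant:
                bounds = {k: tuple(map(float, v))
                          for k, v in opt_cfg["bounds"].items()}
                opt = rsm.optimize_response(model, bounds,
                                            sense=opt_cfg.get("sense", "min"))
                opt_d = {
                    "response": opt_cfg["response"], "sense": opt.sense,
                    "settings": opt.settings, "predicted": opt.predicted,
                    "se_fit": opt.se_fit, "ci95": list(opt.ci95),
                    "at_boundary": opt.at_boundary,
                }
                with open(outdir / "optimum.json", "w") as fh:
                    json.dump(opt_d, fh, indent=1, default=_json_default)
                summary["optimum"] = opt_d
                log("optimize", response=opt_cfg["response"],
                    predicted=f"{opt.predicted:.2f}")

        condition = runs["frr"].astype(str) + "/" + runs["tfr"].astype(str)
        for resp in cfg["analysis"].get("tukey", []):
            grouping = posthoc.tukey_letters(runs[resp], condition, alpha=alpha)
            grouping.table.to_csv(outdir / f"tukey_{resp}.csv", index=False)
            summary[f"tukey_{resp}"] = {
                "n_classes": grouping.n_classes,
                "isolated": grouping.isolated(),
            }
            log("tukey", response=resp, classes=grouping.n_classes)

        mix = cfg["mixing"]
        if mix.get("enabled"):
            geom = build_geometry(
                n_obstacles=int(mix.get("n_obstacles", 8)))
            for frr in mix["frr_values"]:
                result = simulate_mixing(
                    geom, float(mix["tfr"]), float(frr),
                    cells_across=int(mix.get("cells_across", 30)))
                tag = f"{float(frr):g}".replace(".", "p")
                result.profile.to_csv(outdir / f"mixing_frr_{tag}.csv")
                log("simulate", frr=frr,
                    outlet_me=f"{result.profile.me[-1]:.1f}%")
    except Exception as exc:
        log("failed", error_type=type(exc).__name__, error=str(exc))
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
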