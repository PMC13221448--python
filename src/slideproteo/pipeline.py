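"""End-to-end pipeline orchestration.

Runs the stages simulate -> calibrate -> qc -> score -> diff -> gsea in
dependency order from one configuration, writing TSV tables plus a JSON
summary into an output directory. Every table carries a provenance
header (package version, seed, config hash) and the whole run is
deterministic given the seed: rerunning with the same configuration
produces byte-identical tables. Completed stages are skipped on rerun
when their outputs are newer than their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibrate, differential, gsea, io, normalize, qc, signatures
from .errors import ConfigurationError
from .simulate import SimConfig, simulate_cohort, simulate_hela_series

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "qc", "score", "diff", "gsea")

DEFAULT_CONFIG: dict[str, Any] = {
    "out_dir": "pipeline_out",
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},  # SimConfig field overrides
    "calibrate": {
        "hela_amounts": [10, 25, 50, 100, 200, 350, 500, 700],
        "hela_cv": 0.05,
    },
    "qc": {"top_n": 20},
    "score": {"min_coverage": 0.5},
    "diff": {"stratify_by": "PTPRC"},
    "gsea": {"n_perm": 1000, "weight": 1.0, "min_size": 5, "max_size": 500},
    "inputs": {},  # external file paths when the simulate stage is off
}


def load_config(
    source: str | Path | Mapping[str, Any] | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Merge a YAML file or mapping over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    user: Mapping[str, Any] = {}
    if isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    elif source:
        user = source
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    return cfg


def _config_hash(cfg: Mapping[str, Any]) -> str:
    # hash the analysis parameters, not where the outputs land
    payload = {k: v for k, v in cfg.items() if k != "out_dir"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _header(cfg: Mapping[str, Any]) -> str:
    return (
        f"slideproteo {__version__}\nseed={cfg['seed']}\nconfig_hash={_config_hash(cfg)}"
    )


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    out_mtime = min(p.stat().st_mtime for p in outputs)
    in_mtime = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return out_mtime >= in_mtime


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    force: bool = True,
) -> dict[str, Any]:
    """Execute the configured stages; return the run summary.

    With ``force=False``, a stage whose outputs already exist and are
    newer than its inputs is skipped.
    """
    cfg = load_config(config, seed=seed, out_dir=out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = _header(cfg)
    stages = list(cfg["stages"])

    paths = {
        "precursors": out / "precursors.tsv",
        "quant": out / "quant.tsv",
        "quant_imputed": out / "quant_imputed.tsv",
        "tic": out / "tic.tsv",
        "meta": out / "meta.tsv",
        "truth": out / "truth.json",
        "hela": out / "hela_standards.tsv",
        "estimates": out / "estimates.tsv",
        "qc": out / "qc_report.tsv",
        "qc_json": out / "qc_summary.json",
        "scores": out / "scores.tsv",
        "histology": out / "histology_scores.tsv",
        "coverage": out / "coverage.json",
        "tertiles": out / "tertiles.tsv",
        "diff": out / "diff.tsv",
        "gsea": out / "gsea.tsv",
    }
    # when simulation is off, the remaining stages read external inputs
    if "simulate" not in stages:
        for key, val in cfg["inputs"].items():
            paths[key] = Path(val)
        needed = [k for k in ("precursors", "quant", "quant_imputed", "tic", "meta", "hela")]
        missing = [str(paths[k]) for k in needed if not paths[k].exists()]
        if missing:
            raise ConfigurationError(f"missing input file(s): {missing}")

    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "stages_run": [],
    }
    sigs = io.packaged_signatures()

    def stage_enabled(name: str, outputs: list[Path], inputs: list[Path]) -> bool:
        if name not in stages:
            return False
        if not force and _fresh(outputs, inputs):
            logger.info("stage %s: outputs up to date, skipped", name)
            return False
        logger.info("stage %s: running", name)
        summary["stages_run"].append(name)
        return True

    if stage_enabled("simulate", [paths["precursors"], paths["quant"]], []):
        sim_cfg = SimConfig(seed=cfg["seed"], **cfg["simulate"])
        cohort = simulate_cohort(sim_cfg)
        io.write_precursor_table(cohort.precursors, paths["precursors"], header)
        io.write_quant_matrix(cohort.quant, paths["quant"], header)
        io.write_quant_matrix(cohort.quant_imputed, paths["quant_imputed"], header)
        io.write_tic_traces(cohort.tic, paths["tic"], header)
        io.write_sample_meta(cohort.meta, paths["meta"], header)
        io.write_sim_truth(cohort.truth, paths["truth"])
        hela = simulate_hela_series(
            cfg["calibrate"]["hela_amounts"],
            curve_truth=sim_cfg.curve_truth,
            cv=cfg["calibrate"]["hela_cv"],
            seed=cfg["seed"] + 101,
        )
        io._write_tsv(hela, paths["hela"], header, index=False)

    precursors = io.read_precursor_table(paths["precursors"])
    quant = io.read_quant_matrix(paths["quant"], imputed=False)
    quant_imputed = io.read_quant_matrix(paths["quant_imputed"], imputed=True)
    tic = io.read_tic_traces(paths["tic"])

    if stage_enabled("calibrate", [paths["estimates"]], [paths["precursors"], paths["hela"]]):
        standards = pd.read_csv(paths["hela"], sep="\t", comment="#")
        model = calibrate.fit_standard_curve(standards)
        totals = calibrate.total_ms1_by_sample(precursors)
        est = calibrate.estimate_amounts(model, totals)
        est["planned_astral_ng"] = [
            calibrate.plan_injection(e, 0.10, "astral") for e in est["estimate_ng"]
        ]
        est["planned_timstof_ng"] = [
            calibrate.plan_injection(e, 0.10, "timstof") for e in est["estimate_ng"]
        ]
        io._write_tsv(est, paths["estimates"], header, index=False)
        summary["calibration"] = {
            "coefficients": list(model.coefficients),
            "residual_sd": model.fit_residual_sd,
            "n_standards": model.n_standards,
        }

    if stage_enabled("qc", [paths["qc"]], [paths["precursors"], paths["quant"], paths["tic"]]):
        report = qc.qc_report(
            precursors, quant, tic, sigs["SKIN_KERATINS"],
            complexes=[sigs["MCM_COMPLEX"]], top_n=cfg["qc"]["top_n"],
        )
        io._write_tsv(report.reset_index(), paths["qc"], header, index=False)
        rho, p, method = qc.metric_depth_correlation(
            report["keratin_fraction"], report["id_count"]
        )
        qc_summary = {
            "keratin_vs_depth": {"rho": rho, "p": p, "method": method},
            "n_depth_outliers": int(report["depth_outlier"].sum()),
            "outlier_method": qc.OUTLIER_METHOD,
        }
        paths["qc_json"].write_text(json.dumps(qc_summary, indent=1, sort_keys=True))
        summary["qc"] = qc_summary

    norm_imp = normalize.median_normalize_log2(quant_imputed)
    scaled = normalize.scale_per_protein(norm_imp)

    if stage_enabled("score", [paths["scores"]], [paths["quant_imputed"]]):
        score_frames = [
            signatures.signature_score(scaled, sigs["TIS"], cfg["score"]["min_coverage"]),
            signatures.signature_score(
                scaled, sigs["IMMUNE_CELL_MARKERS_SYNTHETIC"], cfg["score"]["min_coverage"]
            ),
        ]
        scores = pd.concat(score_frames, ignore_index=True)
        io._write_tsv(scores, paths["scores"], header, index=False)
        hist = signatures.histology_score(
            norm_imp, sigs["AC_MARKERS"], sigs["SCC_MARKERS"]
        )
        io._write_tsv(
            hist.rename_axis("sample_id").reset_index(), paths["histology"], header, index=False
        )
        coverage = {}
        for panel in ("TIS", "LUNG_ACTIONABLE_MARKERS_SYNTHETIC", "IMMUNE_CELL_MARKERS_SYNTHETIC"):
            pct, _ = signatures.list_coverage(quant, sigs[panel])
            coverage[panel] = pct
        paths["coverage"].write_text(json.dumps(coverage, indent=1, sort_keys=True))
        summary["coverage_pct"] = coverage

    if stage_enabled("diff", [paths["diff"]], [paths["quant_imputed"], paths["precursors"]]):
        marker = cfg["diff"]["stratify_by"]
        if marker not in norm_imp.index:
            raise ConfigurationError(f"diff stage: stratification marker {marker!r} not in matrix")
        labels = differential.stratify_tertiles(norm_imp.loc[marker])
        io._write_tsv(
            labels.rename_axis("sample_id").reset_index(), paths["tertiles"], header, index=False
        )
        counts = differential.median_precursor_counts(precursors)
        result = differential.moderated_test(norm_imp, labels, counts)
        io._write_tsv(result.reset_index(), paths["diff"], header, index=False)
        summary["diff"] = {
            "stratify_by": marker,
            "tertile_sizes": differential.tertile_sizes(labels),
            "d0": float(result["df_prior"].iloc[0]),
            "n_significant": int((result["adj_p_value"] < 0.05).sum()),
        }

    if stage_enabled("gsea", [paths["gsea"]], [paths["diff"]]):
        diff_table = pd.read_csv(paths["diff"], sep="\t", comment="#", index_col=0)
        ranking = diff_table["logFC"].dropna()
        gsea_sets = [
            sigs[name]
            for name in (
                "IFNG_RESPONSE_SYNTHETIC",
                "INFLAMMATORY_RESPONSE_SYNTHETIC",
                "IMMUNE_CELL_MARKERS_SYNTHETIC",
            )
        ]
        enr = gsea.preranked_gsea(
            ranking,
            gsea_sets,
            weight=cfg["gsea"]["weight"],
            n_perm=cfg["gsea"]["n_perm"],
            seed=cfg["seed"] + 202,
            min_size=cfg["gsea"]["min_size"],
            max_size=cfg["gsea"]["max_size"],
        )
        io._write_tsv(enr.reset_index(), paths["gsea"], header, index=False)
        summary["gsea"] = {
            name: {"nes": float(row["nes"]), "p": float(row["p_value"])}
            for name, row in enr.iterrows()
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    with open(out / "run.log", "a") as fh:
        fh.write(f"run seed={cfg['seed']} stages={summary['stages_run']}\n")
    return summary
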