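"""Pipeline plumbing: stage orchestration, provenance, file formats.

Stages run in dependency order — simulate (optional) -> code -> fit ->
persons -> diagnose — each reading the previous stage's CSV outputs.  Every
run writes a run-report JSON carrying package/library versions, the seed,
household counts, accumulated warnings and a SHA-256 hash of the resolved
configuration, so outputs are attributable to an exact configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cml import ItemParameters, fit_cml, report_eta_beta
from .coding import BinaryResponseMatrix, build_binary_matrix
from .diagnostics import graphical_model_check, icc, outfit, plot_icc, plot_model_check
from .errors import UserInputError
from .persons import district_summary, score_households
from .simulate import SimulationConfig, simulate, simulate_misfit

logger = logging.getLogger("fsrasch")

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_STAGES = ("code", "fit", "persons", "diagnose")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def write_sidecar(path, config: dict) -> None:
    """Provenance sidecar <path>.meta.json with the config hash."""
    write_json(
        str(path) + ".meta.json",
        {"fsrasch_version": __version__, "config_hash": config_hash(config)},
    )


class PipelineConfig:
    """Resolved configuration for a multi-stage run.

    Built from a YAML mapping with keys ``stages`` (list), ``outdir``,
    ``seed`` and per-stage option mappings ``simulate``, ``code``, ``fit``,
    ``persons``, ``diagnose``.  Unknown stages are rejected up front.
    """

    KNOWN_STAGES = ("simulate",) + DEFAULT_STAGES

    def __init__(self, mapping: dict):
        self.raw = dict(mapping)
        self.stages = list(mapping.get("stages", DEFAULT_STAGES))
        unknown = [s for s in self.stages if s not in self.KNOWN_STAGES]
        if unknown:
            raise UserInputError(f"unknown pipeline stages: {unknown}")
        self.outdir = Path(mapping.get("outdir", "."))
        self.seed = int(mapping.get("seed", 0))
        self.options = {
            s: dict(mapping.get(s, {})) for s in self.KNOWN_STAGES
        }
        self.input = mapping.get("input")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "outdir": str(self.outdir),
            "seed": self.seed,
            "input": self.input,
            "options": self.options,
        }


def _simulate_stage(cfg: PipelineConfig, report: dict) -> BinaryResponseMatrix:
    opt = cfg.options["simulate"]
    seed = int(opt.get("seed", cfg.seed))
    if "preset" in opt and opt["preset"]:
        sim_cfg = SimulationConfig.from_preset(opt["preset"], seed=seed, n=opt.get("n"))
    else:
        beta = opt.get("beta")
        if beta is None:
            raise UserInputError("simulate needs a preset or an explicit beta vector")
        if isinstance(beta, str):
            beta = pd.read_csv(beta)["beta"].to_numpy()
        sim_cfg = SimulationConfig(
            n=int(opt.get("n", 500)),
            beta=np.asarray(beta, dtype=float),
            mu=float(opt.get("mu", 0.0)),
            sigma=float(opt.get("sigma", 1.0)),
            seed=seed,
        )
    misfit = opt.get("misfit_items")
    ds = (
        simulate_misfit(sim_cfg, misfit, float(opt.get("slope", 1.0)))
        if misfit
        else simulate(sim_cfg)
    )
    out = cfg.outdir / "sim.csv"
    ds.matrix.to_csv(out)
    write_json(cfg.outdir / "truth.json", ds.truth_dict())
    write_sidecar(out, cfg.to_dict())
    report["counts"]["simulated_households"] = ds.matrix.n
    report["outputs"] += [str(out), str(cfg.outdir / "truth.json")]
    logger.info("simulate: wrote %s (n=%d)", out, ds.matrix.n)
    return ds.matrix


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    cfg = config
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "fsrasch_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg.to_dict()),
        "stages": cfg.stages,
        "counts": {},
        "warnings": [],
        "outputs": [],
    }

    matrix: BinaryResponseMatrix | None = None
    params: ItemParameters | None = None
    scores = None

    if "simulate" in cfg.stages:
        matrix = _simulate_stage(cfg, report)

    if "code" in cfg.stages:
        opt = cfg.options["code"]
        if matrix is not None:
            raw = matrix.to_frame()  # simulated data is already binary: no-op pass
        else:
            path = opt.get("input", cfg.input)
            if path is None:
                raise UserInputError("code stage needs an input CSV")
            raw = pd.read_csv(path, dtype=str)
        level_map = opt.get("level_map")
        if isinstance(level_map, str):
            with open(level_map) as fh:
                level_map = yaml.safe_load(fh)
        matrix, log = build_binary_matrix(
            raw,
            dk_policy=opt.get("dk_policy", "as_negative"),
            level_map=level_map,
        )
        out = cfg.outdir / "binary.csv"
        matrix.to_csv(out)
        write_json(cfg.outdir / "coding_log.json", log.to_dict())
        write_sidecar(out, cfg.to_dict())
        report["counts"]["households"] = matrix.n
        report["counts"]["items"] = matrix.k
        report["warnings"] += log.warnings
        report["outputs"] += [str(out), str(cfg.outdir / "coding_log.json")]

    if matrix is None:
        if cfg.input is None:
            raise UserInputError("no input: provide a simulate/code stage or an input path")
        matrix = BinaryResponseMatrix.from_csv(cfg.input)
        report["counts"]["households"] = matrix.n

    if "fit" in cfg.stages:
        fit = fit_cml(matrix)
        params = fit.params
        out = cfg.outdir / "params.csv"
        params.to_csv(out)
        write_json(cfg.outdir / "fit.json", fit.to_report())
        write_sidecar(out, cfg.to_dict())
        report["counts"]["n_used_calibration"] = fit.n_used
        report["counts"]["households"] = int(fit.score_freqs.sum())
        rep = report_eta_beta(params)
        report["beta_first_from_eta"] = rep["beta_first_from_eta"]
        report["outputs"] += [str(out), str(cfg.outdir / "fit.json")]
        logger.info("fit: converged in %d iterations", fit.n_iter)

    if "persons" in cfg.stages:
        if params is None:
            p = cfg.options["persons"].get("params")
            if p is None:
                raise UserInputError("persons stage needs fitted params")
            params = ItemParameters.from_csv(p)
        scores = score_households(
            matrix, params, cfg.options["persons"].get("extreme_policy", "exclude")
        )
        out = cfg.outdir / "persons.csv"
        scores.to_csv(out)
        summary = district_summary(scores)
        write_json(cfg.outdir / "summary.json", summary.to_dict())
        write_sidecar(out, cfg.to_dict())
        report["counts"]["n_scored"] = scores.n_used
        cl = scores.frame["classification"]
        report["counts"]["secure"] = int((cl == "secure").sum())
        report["counts"]["insecure"] = int((cl == "insecure").sum())
        report["outputs"] += [str(out), str(cfg.outdir / "summary.json")]

    if "diagnose" in cfg.stages:
        if params is None or scores is None:
            raise UserInputError("diagnose stage needs fit and persons stages")
        opt = cfg.options["diagnose"]
        stats = outfit(matrix, params, scores)
        stats.to_csv(cfg.outdir / "itemfit.csv")
        check = graphical_model_check(matrix, alpha=float(opt.get("alpha", 0.05)))
        write_json(cfg.outdir / "model_check.json", check.to_dict())
        curves = icc(params)
        curves.to_csv(cfg.outdir / "icc.csv")
        report["counts"]["lr_p_value"] = check.p_value
        report["outputs"] += [
            str(cfg.outdir / "itemfit.csv"),
            str(cfg.outdir / "model_check.json"),
            str(cfg.outdir / "icc.csv"),
        ]
        if opt.get("plots"):
            pdir = Path(opt["plots"])
            pdir.mkdir(parents=True, exist_ok=True)
            plot_model_check(check, pdir / "model_check.png")
            plot_icc(curves, pdir / "icc.png")
            report["outputs"] += [str(pdir / "model_check.png"), str(pdir / "icc.png")]

    write_json(cfg.outdir / "run_report.json", report)
    return report
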