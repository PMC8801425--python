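"""Configuration-driven analysis pipeline.

Stages (in execution order): simulate, fit-eins, fit-mspf, partition,
fit-qens, composition, report.  The configuration is a YAML mapping
validated before any stage runs; identical configuration + seeds produce
byte-identical result tables (no timestamps in outputs; provenance is the
configuration hash, the seed and the package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, composition, heterogeneity, io, synthetic
from .eins import fit_series
from .exceptions import ConfigError, IncoscatError
from .qens import fit_resolution, global_fit

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("incoscat")

STAGES = ("simulate", "fit-eins", "fit-mspf", "partition", "fit-qens",
          "composition", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: str
    stages: tuple[str, ...] = STAGES
    preset: str = "LP60"
    seed: int | None = None
    eins_noise: float = 0.01
    eins_n_q: int = 30
    qens_noise: float = 0.02
    qens_n_omega: int = 111
    vanadium_noise: float = 0.005
    width_law: str = "jump_diffusion"
    n_starts: int = 3
    validity_limit: float = 2.4
    bounds: tuple[float, float] = heterogeneity.DEFAULT_BOUNDS
    n_residues: float = heterogeneity.HEWL_RESIDUES
    nonexchangeable_h: int = composition.HEWL_NONEXCHANGEABLE_H
    ladder_temperature: float = 306.0
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_mapping(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError("configuration must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "outdir" not in doc:
            raise ConfigError("configuration requires 'outdir'")
        cfg = cls(**doc)  # type: ignore[arg-type]
        cfg.raw = dict(doc)
        cfg.stages = tuple(cfg.stages)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad} (choose from {STAGES})")
        if "simulate" in cfg.stages and cfg.seed is None:
            raise ConfigError("stage 'simulate' requires an explicit 'seed'")
        if cfg.preset not in synthetic.GLOBAL_FIT_PRESETS:
            raise ConfigError(f"unknown preset {cfg.preset!r}")
        if cfg.width_law not in ("jump_diffusion", "constant_width"):
            raise ConfigError(f"unknown width_law {cfg.width_law!r}")
        for name in ("eins_noise", "qens_noise", "vanadium_noise"):
            if getattr(cfg, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        b = tuple(float(x) for x in cfg.bounds)
        if len(b) != 2 or not (0 < b[0] < b[1]):
            raise ConfigError("bounds must be two increasing positive r^2 values")
        cfg.bounds = b
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_mapping(doc or {})

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _float_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report dictionary.

    Result tables and the human-readable report are written under
    `config.outdir`.  Any stage failure raises with the stage name; partial
    outputs written by earlier stages are retained.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "provenance": {"config_hash": config.config_hash(),
                       "seed": config.seed, "version": __version__},
        "stages": {},
    }
    eins_dir = os.path.join(config.outdir, "eins")
    qens_dir = os.path.join(config.outdir, "qens")
    vana_dir = os.path.join(config.outdir, "vanadium")

    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            if stage == "simulate":
                truth = synthetic.eins_truth_preset(noise=config.eins_noise,
                                                    n_q=config.eins_n_q)
                series = synthetic.generate_eins_series(truth, seed=config.seed)
                io.write_series(series, eins_dir, sample=config.preset)
                qtruth = synthetic.qens_truth_preset(
                    config.preset, noise=config.qens_noise,
                    n_omega=config.qens_n_omega)
                vana = synthetic.generate_vanadium_spectrum(
                    qtruth.resolution_map(), noise=config.vanadium_noise,
                    seed=config.seed + 1, n_omega=config.qens_n_omega)
                io.save_qens_dataset(vana, vana_dir, sample="vanadium")
                data = synthetic.generate_qens_dataset(qtruth,
                                                       seed=config.seed + 2)
                io.save_qens_dataset(data, qens_dir, sample=config.preset)
                report["stages"]["simulate"] = {
                    "eins_dir": eins_dir, "qens_dir": qens_dir,
                    "vanadium_dir": vana_dir}

            elif stage in ("fit-eins", "fit-mspf"):
                series = io.read_series(eins_dir)
                table = fit_series(series, validity_limit=config.validity_limit)
                cols = (["temperature", "u2", "u2_err", "q_max_used"]
                        if stage == "fit-eins" else
                        ["temperature", "r2", "r2_err", "beta", "beta_err",
                         "gaussian_indistinguishable"])
                name = "eins_msd.tsv" if stage == "fit-eins" else "eins_mspf.tsv"
                path = os.path.join(config.outdir, name)
                _float_table(table[cols], path)
                report["stages"][stage] = {"table": path,
                                           "n_temperatures": len(table)}
                if stage == "fit-mspf":
                    report["_mspf_table"] = table

            elif stage == "partition":
                table = report.get("_mspf_table")
                if table is None:
                    series = io.read_series(eins_dir)
                    table = fit_series(series,
                                       validity_limit=config.validity_limit)
                parts, ladder = heterogeneity.partition_series(
                    table.itertuples(), bounds=config.bounds,
                    n_residues=config.n_residues,
                    ladder_temperature=config.ladder_temperature)
                path = os.path.join(config.outdir, "partition.tsv")
                _float_table(heterogeneity.partition_table(parts), path)
                entry = {"table": path}
                if ladder is not None:
                    entry["ladder"] = {"temperature": ladder.temperature,
                                       "dG_SM_kJ_mol": ladder.dG_SM,
                                       "dG_ML_kJ_mol": ladder.dG_ML}
                report["stages"]["partition"] = entry

            elif stage == "fit-qens":
                data = io.load_qens_dataset(qens_dir)
                if os.path.isdir(vana_dir):
                    vana = io.load_qens_dataset(vana_dir)
                    data = data.with_resolution(fit_resolution(vana))
                fit = global_fit(data, width_law=config.width_law,
                                 n_starts=config.n_starts,
                                 seed=0 if config.seed is None else config.seed)
                path = os.path.join(config.outdir, "qens_fit.json")
                doc = {
                    "model": fit.model_tag,
                    "chi2": fit.chi2,
                    "p0": fit.params.p0, "p0_err": fit.errors.get("p0"),
                    "a_A": fit.params.a, "a_err": fit.errors.get("a"),
                    "tau_ps": fit.params.tau, "tau_err": fit.errors.get("tau"),
                    "D_1e-8_cm2_s": fit.params.d_1e8_cm2_s,
                    "D_err": fit.errors.get("d8"),
                    "s": fit.params.s, "t": fit.params.t,
                    "scale": list(fit.params.scale),
                    "flags": list(fit.flags),
                }
                with open(path, "w", encoding="utf-8") as fh:
                    json.dump(doc, fh, indent=1, sort_keys=True)
                report["stages"]["fit-qens"] = doc | {"table": path}

            elif stage == "composition":
                budget = composition.cross_section_budget()
                entry = {"protein_sigma_cm2": budget.protein_sigma,
                         "water_sigma_cm2": budget.water_sigma,
                         "protein_fraction_pct": budget.protein_fraction}
                p0 = report["stages"].get("fit-qens", {}).get("p0")
                if p0 is not None:
                    h, res = composition.immobile_hydrogen_count(
                        min(max(p0, 0.0), 1.0),
                        nonexchangeable_h=config.nonexchangeable_h)
                    entry |= {"immobile_hydrogens": h, "immobile_residues": res}
                report["stages"]["composition"] = entry

            elif stage == "report":
                path = os.path.join(config.outdir, "report.txt")
                with open(path, "w", encoding="utf-8") as fh:
                    fh.write(_format_report(report))
                report["stages"]["report"] = {"path": path}
        except IncoscatError as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    report.pop("_mspf_table", None)
    return report


def _format_report(report: dict) -> str:
    lines = ["incoscat pipeline report",
             f"config hash: {report['provenance']['config_hash']}",
             f"seed: {report['provenance']['seed']}",
             f"version: {report['provenance']['version']}", ""]
    for stage, entry in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in entry.items():
            if isinstance(val, float):
                val = f"{val:.6g}"
            lines.append(f"  {key}: {val}")
        lines.append("")
    return "\n".join(lines)
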