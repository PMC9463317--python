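"""End-to-end pipeline: simulate -> scan -> mediate -> inequality -> model-check.

A :class:`RunConfig` (loadable from YAML) selects stages and carries the
generator, solver and analysis settings.  Every run writes delimited output
tables plus a JSON manifest with content hashes, so a persisted config
re-executes to identical artifacts; each sample restriction (the
completed-fertility filter, RLRS exclusions) is logged with row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import selgen.inequality as ineq
import selgen.mediation as med
import selgen.model as mdl
import selgen.scan as scn
from selgen.simulate import ConfigError, GeneratorConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scan", "mediate", "inequality", "model-check")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "selgen_run"
    stages: tuple[str, ...] = STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_path: str | None = None  # use an existing cohort instead of simulating
    alpha: float = 0.05
    apply_completed_fertility_filter: bool = True
    n_boot: int = 100
    ci_level: float = 0.95
    mediation_seed: int = 0
    inequality_score: str | None = None  # default: first score column
    sweep: mdl.SweepConfig = field(default_factory=mdl.SweepConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage name(s): {sorted(unknown)}")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}

        def _tuplify(d: dict) -> dict:
            return {
                k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
            }

        gen_raw = _tuplify(raw.pop("generator", {}))
        mult = gen_raw.get("subgroup_multipliers")
        if isinstance(mult, dict):
            gen_raw["subgroup_multipliers"] = {k: tuple(v) for k, v in mult.items()}
        gen = GeneratorConfig(**gen_raw)
        sweep = mdl.SweepConfig(**_tuplify(raw.pop("sweep", {})))
        cfg = cls(generator=gen, sweep=sweep, **_tuplify(raw))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are listed in the manifest as partial.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": list(cfg.stages), "outputs": {}, "log": [], "partial": False}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"][name] = _sha256(path)

    table = None
    stage = None
    try:
        if "simulate" in cfg.stages:
            stage = "simulate"
            table = generate_cohort(cfg.generator)
            write_cohort(table, out / "cohort.csv")
            manifest["outputs"]["cohort.csv"] = _sha256(out / "cohort.csv")
            manifest["log"].append(f"simulate: generated {len(table)} rows")
        elif cfg.cohort_path:
            from selgen.simulate import read_cohort

            table = read_cohort(cfg.cohort_path)
            manifest["log"].append(f"input: read {len(table)} rows from {cfg.cohort_path}")

        needs_data = {"scan", "mediate", "inequality"} & set(cfg.stages)
        if needs_data and table is None:
            raise ConfigError("scan/mediate/inequality stages need a simulated or loaded cohort")

        if needs_data and cfg.apply_completed_fertility_filter:
            table, counts = scn.completed_fertility_filter(
                table, cfg.generator.reference_year
            )
            manifest["log"].append(
                f"completed-fertility filter: retained {counts['retained']}, "
                f"excluded {counts['excluded']}"
            )

        scan_report = None
        if "scan" in cfg.stages:
            stage = "scan"
            scan_report = scn.scan_all(table, alpha=cfg.alpha)
            _write(scan_report.to_frame(), "scan_overall.csv")
            for split in ("income", "education", "partners", "cohabiting", "aflb-terciles"):
                rep = scn.subgroup_scan(table, split, alpha=cfg.alpha)
                _write(rep.to_frame(), f"scan_{split.replace('-', '_')}.csv")
            manifest["log"].append(
                "scan: mean % change from weighting = "
                f"{scan_report.summary['mean_pct_change_from_weighting']:.1f}; "
                f"{scan_report.summary['n_significant_weighted']} significant (weighted)"
            )

        if "mediate" in cfg.stages:
            stage = "mediate"
            if scan_report is None:
                scan_report = scn.scan_all(table, alpha=cfg.alpha)
            results, summary = med.mediation_panel(
                table,
                scan_report,
                alpha=cfg.alpha,
                n_boot=cfg.n_boot,
                level=cfg.ci_level,
                seed=cfg.mediation_seed,
            )
            _write(med.panel_frame(results), "mediation.csv")
            manifest["log"].append(f"mediate: {summary}")

        if "inequality" in cfg.stages:
            stage = "inequality"
            score = cfg.inequality_score or [
                c for c in table.columns if c.startswith("pgs_")
            ][0]
            _write(ineq.child_mean_by_group(table, score), "inequality_groups.csv")
            panel = ineq.amplification_panel(table)
            _write(panel, "inequality_amplification.csv")
            manifest["log"].append(
                f"inequality: {panel.attrs['n_increased']}/{panel.attrs['n_stable']} "
                "score-income correlations amplified"
            )

        if "model-check" in cfg.stages:
            stage = "model-check"
            report = mdl.check_predictions(cfg.sweep)
            _write(report.to_frame(), "model_check_evaluations.csv")
            _write(report.summary_frame(), "model_check_summary.csv")
            manifest["log"].append(
                f"model-check: predictions passed = {report.passed}"
            )
    except Exception as exc:
        manifest["partial"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
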