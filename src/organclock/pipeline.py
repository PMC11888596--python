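"""Configured, logged pipeline: simulate -> score -> fit -> validate -> infer.

One run directory holds every stage artifact plus a manifest (serialized
config, seed, input hashes, package/library versions), so each numeric
artifact is reproducible from the manifest alone. Stages exchange the
long-format CSV registered in :mod:`organclock.columns`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

import organclock
from organclock import columns as C
from organclock.fem import FEMSpec, fit_fem, run_sensitivity_suite
from organclock.kdm import DEFAULT_PANELS, fit_kdm_all, score_dataset
from organclock.lifestyle import FactorDefinitions, build_hli_records, categorize_change
from organclock.qgc import QGCSpec, fit_qgc
from organclock.synthetic import CohortConfig, demo_config, generate_cohort, write_cohort
from organclock.validation import validate_panels

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class StageToggles(BaseModel):
    simulate: bool = True
    lifestyle: bool = True
    kdm: bool = True
    validation: bool = True
    fem: bool = True
    qgc: bool = True
    report: bool = True


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 1
    n_individuals: int = 2000
    profile: str = "demo"               # "demo" (high-signal) | "study" conditions
    input_csv: Optional[str] = None     # skip simulation, read this table
    use_ca_anchor: bool = True
    bootstrap_reps: int = 0
    force_unvalidated: bool = False
    stages: StageToggles = Field(default_factory=StageToggles)
    exposure_modes: list[str] = Field(
        default_factory=lambda: ["five-factors-joint", "hli-continuous", "hli-binary"])
    sensitivity: bool = False


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the artifact directory.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "versions": {
            "organclock": organclock.__version__,
            "pandas": pd.__version__,
        },
        "stages_run": [],
        "inputs": {},
    }

    def stage(name):
        manifest["stages_run"].append(name)
        log.info("stage: %s", name)

    try:
        if config.input_csv:
            stage("load")
            data = pd.read_csv(config.input_csv)
            manifest["inputs"]["cohort_csv"] = _hash_file(Path(config.input_csv))
        elif config.stages.simulate:
            stage("simulate")
            if config.profile == "demo":
                cc = demo_config(config.n_individuals, config.seed)
            else:
                cc = CohortConfig(n_individuals=config.n_individuals, seed=config.seed)
            data, truth = generate_cohort(cc)
            write_cohort(data, truth, out)
            manifest["inputs"]["cohort_csv"] = _hash_file(out / "cohort.csv")
        else:
            raise PipelineError("no input: provide input_csv or enable simulate")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage simulate/load failed: {e}") from e

    try:
        stage("lifestyle")
        hli = build_hli_records(data, FactorDefinitions())
        changes = categorize_change(hli)
        hli.to_csv(out / "hli_records.csv", index=False)
        changes.to_csv(out / "change_records.csv", index=False)
    except Exception as e:
        raise PipelineError(f"stage lifestyle failed: {e}") from e

    try:
        stage("kdm")
        params = fit_kdm_all(data, DEFAULT_PANELS)
        (out / "kdm_params.json").write_text(json.dumps(
            {f"{p}/{s}": kp.to_dict() for (p, s), kp in params.items()}, indent=1))
        ba = score_dataset(data, params, use_ca_anchor=config.use_ca_anchor)
        ba.to_csv(out / "ba_results.csv", index=False)
    except Exception as e:
        raise PipelineError(f"stage kdm failed: {e}") from e

    validated: list[str] = []
    if config.stages.validation:
        try:
            stage("validate")
            table, validated, unvalidatable = validate_panels(data, ba, hli)
            table.to_csv(out / "validation_report.csv", index=False)
            (out / "validated_panels.json").write_text(json.dumps(
                {"validated": validated, "unvalidatable": unvalidatable}))
        except Exception as e:
            raise PipelineError(f"stage validate failed: {e}") from e
    elif config.force_unvalidated:
        validated = [p for p in DEFAULT_PANELS if p != "renal"]
    else:
        raise PipelineError(
            "stage fem refused: validation disabled and force_unvalidated not set")

    fem_tables = []
    if config.stages.fem:
        try:
            stage("fem")
            for panel in validated:
                for mode in config.exposure_modes:
                    spec = FEMSpec(outcome_panel=panel, exposure_mode=mode)
                    fem_tables.append(fit_fem(data, ba, changes, spec))
                if config.sensitivity:
                    sens = run_sensitivity_suite(
                        data, ba, FEMSpec(outcome_panel=panel))
                    sens.to_csv(out / f"sensitivity_{panel}.csv", index=False)
            fem_table = pd.concat(fem_tables, ignore_index=True)
            fem_table.to_csv(out / "fem_results.csv", index=False)
        except Exception as e:
            raise PipelineError(f"stage fem failed: {e}") from e

    qgc_out = {}
    if config.stages.qgc:
        try:
            stage("qgc")
            from organclock.fem import build_difference_frame
            for panel in validated:
                spec = FEMSpec(outcome_panel=panel, exposure_mode="five-factors-joint")
                frame = build_difference_frame(data, ba, changes, spec)
                res = fit_qgc(frame, QGCSpec(bootstrap_reps=config.bootstrap_reps,
                                             seed=config.seed))
                qgc_out[panel] = {
                    "psi": res.psi, "se": res.se,
                    "ci": [res.ci_low, res.ci_high],
                    "coefficients": res.coefficients,
                    "weights_negative": res.weights_negative,
                    "weights_positive": res.weights_positive,
                    "n": res.n,
                }
            (out / "qgc_results.json").write_text(json.dumps(qgc_out, indent=1))
        except Exception as e:
            raise PipelineError(f"stage qgc failed: {e}") from e

    if config.stages.report:
        try:
            stage("report")
            _write_report(out, validated, fem_tables, qgc_out)
        except Exception as e:
            raise PipelineError(f"stage report failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _write_report(out: Path, validated, fem_tables, qgc_out) -> None:
    lines = ["# Lifestyle change and biological-age acceleration", ""]
    lines.append(f"Validated panels: {', '.join(validated) or 'none'}")
    if fem_tables:
        fem = pd.concat(fem_tables, ignore_index=True)
        lines += ["", "## Fixed-effects estimates (years of BA acceleration)", ""]
        lines.append("| panel | exposure | beta | 95% CI | n |")
        lines.append("|---|---|---|---|---|")
        for _, r in fem.iterrows():
            lines.append(
                f"| {r['panel']} | {r['term']} | {r['beta']:.3f} "
                f"| ({r['ci_low']:.3f}, {r['ci_high']:.3f}) | {r['n']} |")
    if qgc_out:
        lines += ["", "## Mixture analysis (negative-direction weights)", ""]
        lines.append("| panel | psi | factor weights |")
        lines.append("|---|---|---|")
        for panel, res in qgc_out.items():
            w = ", ".join(f"{k.removeprefix('d_')}: {v:.2f}"
                          for k, v in res["weights_negative"].items())
            lines.append(f"| {panel} | {res['psi']:.3f} | {w} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")
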