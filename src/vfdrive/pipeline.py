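"""End-to-end pipeline: simulate → integrate → drive metrics → analyze.

A single YAML-serializable config drives the whole run; every artifact
carries the config hash and master seed, and a rerun with the same config
is byte-identical (floats printed at fixed precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .analysis import fit_vehicle_control_model, group_comparisons
from .binocular import integrate_fields
from .driving import LIMIT_55_MPS, LIMIT_60_MPS, compute_drive_metrics, simulate_telemetry
from .geometry import DEFAULT_RING_BOUNDARIES
from .io import FLOAT_FORMAT, write_binocular_field, write_monocular_field, write_telemetry
from .synthetic import CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("vfdrive")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class PipelineConfig(BaseModel):
    """Complete configuration of one pipeline run; runnable with defaults."""

    pattern: str = "24-2"
    ring_boundaries: tuple[float, float, float, float] = DEFAULT_RING_BOUNDARIES
    logit_eps: float = 0.005
    limit_55_mps: float = LIMIT_55_MPS
    limit_60_mps: float = LIMIT_60_MPS
    n_glaucoma: int = Field(default=25, ge=1)
    n_suspect: int = Field(default=18, ge=1)
    drives_per_subject: int = Field(default=2, ge=1)
    residual_sd: float = Field(default=0.35, gt=0)
    subject_sd: float = Field(default=0.30, ge=0)
    telemetry_duration_s: float = Field(default=60.0, gt=0)
    telemetry_sample_rate_hz: float = Field(default=60.0, gt=0)
    outcomes: tuple[str, ...] = ("steering_sd", "lat_accel_sd")
    exposure: str = "logit_ou"
    seed: int = Field(default=0, ge=0)
    out_dir: str = "vfdrive_run"

    @field_validator("exposure")
    @classmethod
    def _check_exposure(cls, v: str) -> str:
        if v not in ("logit_ou", "group"):
            raise ValueError("exposure must be 'logit_ou' or 'group'")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True))
        return path

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = json.loads(self.model_dump_json())
        payload.pop("out_dir", None)
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return a manifest of artifacts.

    Stages: (1) simulate a cohort with visual fields and planted drive
    outcomes; (2) integrate an example field pair and write the binocular
    table; (3) materialize telemetry per subject-drive whose variability
    matches the planted outcomes and recompute drive metrics from it;
    (4) fit the multivariable vehicle-control models and write Table-style
    results.  Partial artifacts are preserved if a later stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "artifacts": {},
    }
    logger.info("run start: config %s seed %d vfdrive %s", chash, config.seed, __version__)
    config.to_yaml(out / "config.yaml")
    manifest["artifacts"]["config"] = "config.yaml"

    cohort, fields = _simulate(config)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False, float_format=FLOAT_FORMAT)
    manifest["artifacts"]["cohort"] = cohort_path.name

    first = cohort["subject_id"].iloc[0]
    left, right = fields[first]
    write_monocular_field(left, out / "example_field_OS.csv")
    write_monocular_field(right, out / "example_field_OD.csv")
    binoc = _integrate(left, right, config)
    write_binocular_field(binoc, out / "example_binocular.csv", out / "example_binocular.json")
    manifest["artifacts"]["example_binocular"] = "example_binocular.csv"

    metrics = _metrics(cohort, config, out)
    metrics_path = out / "drive_metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format=FLOAT_FORMAT)
    manifest["artifacts"]["drive_metrics"] = metrics_path.name

    results = _analyze(cohort, config)
    results_path = out / "model_results.csv"
    results.to_csv(results_path, index=False, float_format=FLOAT_FORMAT)
    manifest["artifacts"]["model_results"] = results_path.name

    comparisons = group_comparisons(cohort)
    comp_path = out / "group_comparisons.csv"
    comparisons.to_csv(comp_path, index=False, float_format=FLOAT_FORMAT)
    manifest["artifacts"]["group_comparisons"] = comp_path.name

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("run complete: %s", out)
    return manifest


@_stage("simulate")
def _simulate(config: PipelineConfig):
    spec = CohortSpec(
        n_glaucoma=config.n_glaucoma,
        n_suspect=config.n_suspect,
        drives_per_subject=config.drives_per_subject,
        residual_sd=config.residual_sd,
        subject_sd=config.subject_sd,
        logit_eps=config.logit_eps,
        seed=config.seed,
    )
    return simulate_cohort(spec, return_fields=True)


@_stage("integrate")
def _integrate(left, right, config: PipelineConfig):
    return integrate_fields(left, right, ring_boundaries=config.ring_boundaries)


@_stage("metrics")
def _metrics(cohort: pd.DataFrame, config: PipelineConfig, out: Path) -> pd.DataFrame:
    telem_dir = out / "telemetry"
    telem_dir.mkdir(exist_ok=True)
    rows = []
    base = np.random.SeedSequence([config.seed, 0x7E1E])
    children = base.spawn(len(cohort))
    for (idx, row), child in zip(cohort.iterrows(), children):
        trace = simulate_telemetry(
            duration=config.telemetry_duration_s,
            sample_rate=config.telemetry_sample_rate_hz,
            steering_sd=row["steering_sd"],
            lat_accel_sd=row["lat_accel_sd"],
            seed=child,
        )
        if idx == 0:
            write_telemetry(trace, telem_dir / f"{row['subject_id']}_drive{int(row['drive'])}.csv")
        m = compute_drive_metrics(trace, config.limit_55_mps, config.limit_60_mps)
        rec = {"subject_id": row["subject_id"], "drive": int(row["drive"])}
        rec.update(m.as_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


@_stage("analyze")
def _analyze(cohort: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    frames = []
    for outcome in config.outcomes:
        res = fit_vehicle_control_model(
            cohort, outcome=outcome, exposure=config.exposure, logit_eps=config.logit_eps
        )
        res.insert(0, "outcome", outcome)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
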