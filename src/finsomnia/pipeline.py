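"""End-to-end orchestration: config validation, staged execution, reports.

A single human-editable YAML config drives the run.  Every default that
affects the result (speed threshold, windows, photoperiod) is serialized
into the output directory's provenance manifest, so no analysis parameter
is ever left unrecorded.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .cells import DetectionParams, load_stack, quantify_stack
from .errors import ConfigError, PipelineError
from .qpcr import quantify as qpcr_quantify
from .scoring import ScoringParams, score_cohort
from .stats import anova_table, holm_sidak, pairwise_contrasts, two_way_anova
from .trajectory import PhotoperiodSpec


class ScoringCfg(BaseModel):
    speed_threshold: float = Field(4.0, ge=0)
    smooth_window_s: float = Field(1.0, ge=0)
    min_sleep_s: float = Field(60.0, gt=0)
    min_interrupt_s: float = Field(1.0, ge=0)
    fill_max_gap_s: float = Field(1.0, ge=0)
    windows: Literal["total", "day_night"] = "total"
    bin_minutes: int = Field(60, gt=0)

    def to_params(self) -> ScoringParams:
        return ScoringParams(
            self.speed_threshold, self.smooth_window_s,
            self.min_sleep_s, self.min_interrupt_s,
        )


class PhotoperiodCfg(BaseModel):
    lights_on_zt: float = Field(0.0, ge=0)
    lights_off_zt: float = Field(14.0, gt=0)
    period: float = Field(24.0, gt=0)

    def to_spec(self) -> PhotoperiodSpec:
        return PhotoperiodSpec(self.lights_on_zt, self.lights_off_zt, self.period)


class ContrastCfg(BaseModel):
    metric: str
    a: dict
    b: dict
    method: Literal["t_unpaired", "rank_nonparametric"] = "t_unpaired"


class StatsCfg(BaseModel):
    metrics: list[str] = ["total_sleep_min", "bout_count", "mean_bout_s", "waking_mm_s"]
    contrasts: list[ContrastCfg] = []


class QpcrCfg(BaseModel):
    path: str
    calibrator_group: str
    calibrator_sample: Optional[str] = None
    efficiency: float = Field(1.0, gt=0.8, le=1.2)


_DET = DetectionParams()


class CellsCfg(BaseModel):
    manifest: str  # CSV: file, brain_id, population, treatment
    threshold_k: float = Field(_DET.threshold_k, gt=0)
    min_area: int = Field(_DET.min_area, gt=0)
    max_area: int = Field(_DET.max_area, gt=0)
    min_separation: int = Field(_DET.min_separation, gt=0)
    dilate_px: int = Field(3, ge=0)


class RunConfig(BaseModel):
    """Declarative description of a full pipeline run."""

    manifest: str
    output_dir: str = "results"
    seed: int = 0
    scoring: ScoringCfg = ScoringCfg()
    photoperiod: PhotoperiodCfg = PhotoperiodCfg()
    stats: StatsCfg = StatsCfg()
    qpcr: Optional[QpcrCfg] = None
    cells: Optional[CellsCfg] = None


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config, reporting every error at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unreadable config: {exc}") from exc
    try:
        return RunConfig.model_validate(raw or {})
    except pydantic.ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError(
            f"invalid config ({len(msgs)} error(s)): " + "; ".join(msgs), errors=msgs
        ) from exc


def _write_provenance(config: RunConfig, outdir: Path, extra: dict) -> None:
    dump = config.model_dump()
    blob = json.dumps(dump, sort_keys=True).encode()
    prov = {
        "config": dump,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": __version__,
        "seed": config.seed,
        **extra,
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))


def _figures(metrics: pd.DataFrame, outdir: Path, bin_minutes: int) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    total = metrics[metrics["window"] == "total"]
    prof_cols = sorted(c for c in total.columns if c.startswith("profile_bin_"))
    groups = total.groupby(["population", "treatment"], observed=True)
    if prof_cols:
        fig, ax = plt.subplots(figsize=(7, 4))
        hours = (np.arange(len(prof_cols)) + 0.5) * bin_minutes / 60.0
        for (pop, treat), sub in groups:
            ax.plot(hours, sub[prof_cols].mean(axis=0), label=f"{pop}/{treat}")
        ax.set_xlabel("hours from recording start")
        ax.set_ylabel(f"sleep (min / {bin_minutes} min bin)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "sleep_profiles.png", dpi=120)
        plt.close(fig)
        made.append("sleep_profiles.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    means = groups["total_sleep_min"].mean()
    sems = groups["total_sleep_min"].sem()
    labels = ["/".join(map(str, k)) for k in means.index]
    ax.bar(labels, means.to_numpy(), yerr=sems.to_numpy(), capsize=3)
    ax.set_ylabel("total sleep (min)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(outdir / "total_sleep_bars.png", dpi=120)
    plt.close(fig)
    made.append("total_sleep_bars.png")
    return made


def run_stats(metrics: pd.DataFrame, stats_cfg: StatsCfg):
    """ANOVA effects table (per metric) plus the explicit contrast family."""
    total = metrics[metrics["window"] == "total"]
    effects_frames = []
    for metric in stats_cfg.metrics:
        if metric not in total.columns:
            continue
        sub = total.dropna(subset=[metric])
        if sub["population"].nunique() < 2 or sub["treatment"].nunique() < 2:
            continue
        results = two_way_anova(sub, response=metric)
        tbl = anova_table(results)
        tbl.insert(0, "metric", metric)
        effects_frames.append(tbl)
    effects = pd.concat(effects_frames, ignore_index=True) if effects_frames else pd.DataFrame()
    if len(effects):
        effects["p_adj"] = holm_sidak(effects["p_raw"].to_numpy())

    contrast_frames = []
    for c in stats_cfg.contrasts:
        contrast_frames.append(
            pairwise_contrasts(total, c.metric, [(c.a, c.b)], method=c.method)
        )
    if contrast_frames:
        contrasts = pd.concat(contrast_frames, ignore_index=True)
        contrasts["p_adj"] = holm_sidak(contrasts["p_raw"].to_numpy())
    else:
        contrasts = pd.DataFrame()
    return effects, contrasts


def run_pipeline(config: RunConfig, base_dir=None) -> dict:
    """Execute the configured stages; returns a map of output names to paths.

    Stages run in order scoring -> stats -> (qpcr) -> (cells); any stage
    failure halts the run with the stage name and offending inputs.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    outdir = base / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    try:
        metrics, failures = score_cohort(
            base / config.manifest,
            config.scoring.to_params(),
            fill_max_gap_s=config.scoring.fill_max_gap_s,
            windows=config.scoring.windows,
            photoperiod=config.photoperiod.to_spec(),
            bin_minutes=config.scoring.bin_minutes,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'score' failed: {exc}") from exc
    metrics.to_csv(outdir / "metrics.csv", index=False)
    failures.to_csv(outdir / "failures.csv", index=False)
    outputs["metrics"] = outdir / "metrics.csv"
    outputs["failures"] = outdir / "failures.csv"

    try:
        effects, contrasts = run_stats(metrics, config.stats)
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc
    effects.to_csv(outdir / "effects.csv", index=False)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    outputs["effects"] = outdir / "effects.csv"
    outputs["contrasts"] = outdir / "contrasts.csv"

    if config.qpcr is not None:
        try:
            plate = pd.read_csv(base / config.qpcr.path)
            folds = qpcr_quantify(
                plate,
                calibrator_group=config.qpcr.calibrator_group,
                calibrator_sample=config.qpcr.calibrator_sample,
                efficiency=config.qpcr.efficiency,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'qpcr' failed on {config.qpcr.path}: {exc}") from exc
        folds.to_csv(outdir / "qpcr_folds.csv", index=False)
        outputs["qpcr_folds"] = outdir / "qpcr_folds.csv"

    if config.cells is not None:
        try:
            cell_rows, count_rows = [], []
            stack_manifest = pd.read_csv(base / config.cells.manifest)
            det = DetectionParams(
                threshold_k=config.cells.threshold_k,
                min_area=config.cells.min_area,
                max_area=config.cells.max_area,
                min_separation=config.cells.min_separation,
            )
            for _, row in stack_manifest.iterrows():
                stack = load_stack(base / row["file"])
                records, count = quantify_stack(
                    stack, det, dilate_px=config.cells.dilate_px
                )
                for rec in records:
                    cell_rows.append(
                        {"brain_id": row["brain_id"],
                         "population": row.get("population"),
                         "treatment": row.get("treatment"), **rec}
                    )
                count_rows.append(
                    {"brain_id": row["brain_id"],
                     "population": row.get("population"),
                     "treatment": row.get("treatment"), "n_cells": count}
                )
        except Exception as exc:
            raise PipelineError(f"stage 'cells' failed: {exc}") from exc
        pd.DataFrame(cell_rows).to_csv(outdir / "cells.csv", index=False)
        pd.DataFrame(count_rows).to_csv(outdir / "cell_counts.csv", index=False)
        outputs["cells"] = outdir / "cells.csv"
        outputs["cell_counts"] = outdir / "cell_counts.csv"

    try:
        for name in _figures(metrics, outdir, config.scoring.bin_minutes):
            outputs[name] = outdir / name
    except Exception as exc:
        raise PipelineError(f"stage 'figures' failed: {exc}") from exc

    _write_provenance(
        config, outdir,
        {"n_fish_scored": int(metrics["subject_id"].nunique()) if len(metrics) else 0,
         "n_failures": int(len(failures))},
    )
    outputs["provenance"] = outdir / "provenance.json"
    return outputs
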