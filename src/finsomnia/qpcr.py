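"""Relative transcript quantification from qPCR Ct tables (ΔΔCt method).

Input is a long-format table with one row per technical replicate:
``sample_id, group, run_id, gene, ct`` where ``gene`` is ``"target"`` or
``"reference"`` (the reference being a housekeeping gene such as *gapdh*).

The workflow is:

1. ``collapse_replicates`` — arithmetic mean Ct per sample x gene, with the
   replicate SD reported and samples above a quality cutoff flagged.
2. ``interrun_calibrate`` — a per-run, per-gene additive Ct offset computed
   from a shared calibrator sample so that the calibrator reads identically
   in every run (fold changes are invariant to the anchor run).
3. ``relative_expression`` — ΔCt = Ct_target − Ct_reference per sample,
   ΔΔCt = ΔCt − mean ΔCt of the designated calibrator group, and
   fold = (1 + efficiency)^(−ΔΔCt); at 100% amplification efficiency this is
   the textbook 2^(−ΔΔCt).  Anchoring on the calibrator group's arithmetic
   mean ΔCt makes the geometric mean fold of that group exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

PLATE_COLUMNS = ("sample_id", "group", "run_id", "gene", "ct")
GENES = ("target", "reference")

#: Replicate-SD above which a sample is flagged (cycles); flags, never drops.
REPLICATE_SD_CUTOFF = 0.5


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format plate table; returns it with normalized dtypes."""
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValidationError(f"plate missing columns {missing}")
    plate = plate.copy()
    plate["ct"] = pd.to_numeric(plate["ct"], errors="coerce")
    if plate["ct"].isna().any() or not plate["ct"].between(0, 45, inclusive="neither").all():
        raise ValidationError("all Ct values must be finite and in (0, 45)")
    bad_gene = set(plate["gene"]) - set(GENES)
    if bad_gene:
        raise ValidationError(f"unknown gene labels {sorted(bad_gene)}; expected {GENES}")
    per_sample = plate.groupby("sample_id")["gene"].agg(set)
    incomplete = [s for s, genes in per_sample.items() if genes != set(GENES)]
    if incomplete:
        raise ValidationError(
            f"samples missing a gene (need both target and reference): {incomplete}"
        )
    return plate


def collapse_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per sample x gene.

    Returns columns ``sample_id, group, run_id, gene, ct_mean, ct_sd,
    n_replicates, flagged`` where ``flagged`` marks replicate SD above
    :data:`REPLICATE_SD_CUTOFF` cycles.
    """
    plate = validate_plate(plate)
    out = (
        plate.groupby(["sample_id", "group", "run_id", "gene"], as_index=False)
        .agg(ct_mean=("ct", "mean"), ct_sd=("ct", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
             n_replicates=("ct", "size"))
    )
    out["flagged"] = out["ct_sd"] > REPLICATE_SD_CUTOFF
    return out.sort_values(["sample_id", "gene"], kind="stable").reset_index(drop=True)


def interrun_calibrate(
    mean_ct: pd.DataFrame, calibrator_sample: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove per-run Ct offsets using a sample shared across all runs.

    For each gene, the offset of a run is the calibrator's mean Ct in that
    run minus its Ct in the anchor run (the first run in sorted order); the
    offset is subtracted from every Ct of that run.  Returns
    ``(adjusted table, offsets table)``.  Raises if any run lacks the shared
    calibrator.
    """
    runs = sorted(mean_ct["run_id"].unique())
    cal = mean_ct[mean_ct["sample_id"] == calibrator_sample]
    missing = [r for r in runs if r not in set(cal["run_id"])]
    if missing:
        raise ValidationError(
            f"runs {missing} lack the shared calibrator sample {calibrator_sample!r}"
        )
    anchor = runs[0]
    cal_ct = cal.set_index(["run_id", "gene"])["ct_mean"]
    offsets = []
    for run in runs:
        for gene in GENES:
            offsets.append(
                {
                    "run_id": run,
                    "gene": gene,
                    "offset": float(cal_ct.loc[(run, gene)] - cal_ct.loc[(anchor, gene)]),
                }
            )
    offsets = pd.DataFrame(offsets)
    adjusted = mean_ct.merge(offsets, on=["run_id", "gene"], how="left")
    adjusted["ct_mean"] = adjusted["ct_mean"] - adjusted["offset"]
    return adjusted.drop(columns="offset"), offsets


def relative_expression(
    mean_ct: pd.DataFrame, calibrator_group: str, efficiency: float = 1.0
) -> pd.DataFrame:
    """ΔΔCt fold changes relative to the calibrator group.

    Returns columns ``sample_id, group, delta_ct, delta_delta_ct, fold``.
    The calibrator group's arithmetic-mean ΔCt anchors ΔΔCt, so the
    geometric mean fold of that group is exactly 1.
    """
    if not (0.8 < efficiency <= 1.2):
        raise ValidationError(f"efficiency must be in (0.8, 1.2], got {efficiency}")
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct_mean"
    ).reset_index()
    if "target" not in wide or "reference" not in wide or wide[list(GENES)].isna().any().any():
        raise ValidationError("every sample needs a mean Ct for both genes")
    wide["delta_ct"] = wide["target"] - wide["reference"]
    cal = wide.loc[wide["group"] == calibrator_group, "delta_ct"]
    if cal.empty:
        raise ValidationError(f"calibrator group {calibrator_group!r} is empty")
    wide["delta_delta_ct"] = wide["delta_ct"] - cal.mean()
    wide["fold"] = (1.0 + efficiency) ** (-wide["delta_delta_ct"])
    out = wide[["sample_id", "group", "delta_ct", "delta_delta_ct", "fold"]]
    return out.sort_values("sample_id", kind="stable").reset_index(drop=True)


def quantify(
    plate: pd.DataFrame,
    calibrator_group: str,
    calibrator_sample: str | None = None,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Full workflow: collapse replicates, optional inter-run calibration,
    then ΔΔCt fold changes."""
    mean_ct = collapse_replicates(plate)
    if calibrator_sample is not None and mean_ct["run_id"].nunique() > 1:
        mean_ct, _ = interrun_calibrate(mean_ct, calibrator_sample)
    return relative_expression(mean_ct, calibrator_group, efficiency)
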