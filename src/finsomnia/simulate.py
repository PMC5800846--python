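"""Synthetic study generator: activity traces, qPCR plates, image stacks.

Every generator is fully deterministic given ``(params, seed)`` and records
its ground truth, so the scoring, statistics and image pipelines can be
validated by parameter recovery.

Activity traces follow a two-state semi-Markov model: the fish alternates
between wake and rest bouts with exponentially distributed durations
(truncated at one frame).  During wake, per-frame speeds are drawn from a
gamma distribution and the fish performs a bounded correlated random walk in
the arena; during rest the position jitters around an anchor with small
Gaussian noise.  A rest bout of at least 60 s is, by the behavioural
definition, a sleep bout; the emergent sleep fraction of the model is

    sleep_fraction = mu_s / (mu_s + mu_w) * exp(-60/mu_s) * (1 + 60/mu_s)

for mean rest/wake bout durations ``mu_s``/``mu_w`` (the second factor is
the time-weighted probability that a rest bout reaches 60 s under the
exponential law).

Presets encode the qualitative phenotypes the pipeline must resolve: the
cave morph sleeps a small fraction of what the surface morph does, and
orexin-receptor antagonist treatment (like starvation or lateral-line
ablation) restores cavefish sleep — via shorter wake bouts *and* longer rest
bouts, so both bout number and bout duration increase — while leaving the
surface morph unchanged.  The numbers are plausibility anchors for testing,
not estimates of real fish.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError
from .trajectory import Trajectory, write_tracking
from .cells import ImageStack
from .scoring import SLEEP, WAKE

POPULATION_LABELS = ("surface", "cavefish")
TREATMENT_LABELS = ("control", "antagonist", "starved", "ablated")


@dataclass(frozen=True)
class ActivitySimParams:
    """Two-state semi-Markov activity model parameters."""

    mean_sleep_bout_s: float = 200.0
    mean_wake_bout_s: float = 250.0
    wake_speed_shape: float = 4.0  # gamma shape; mean speed = shape*scale mm/s
    wake_speed_scale: float = 5.0
    rest_jitter_sd: float = 0.05  # mm positional noise during rest
    duration_h: float = 24.0
    frame_rate: float = 15.0
    arena_mm: tuple = (300.0, 150.0)
    heading_sd: float = 0.4  # rad/frame heading diffusion during wake
    seed: int = 0

    def __post_init__(self):
        for name in ("mean_sleep_bout_s", "mean_wake_bout_s", "wake_speed_shape",
                     "wake_speed_scale", "duration_h", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.rest_jitter_sd < 0:
            raise ConfigError("rest_jitter_sd must be >= 0")


@dataclass
class GroundTruth:
    """True bout structure of a simulated recording."""

    intervals: list  # (start_s, end_s, label) partitioning the recording
    sleep_fraction: float  # time in rest bouts >= min_sleep_s / total
    params: ActivitySimParams = None
    seed: int = 0
    min_sleep_s: float = 60.0


def expected_sleep_fraction(params: ActivitySimParams, min_sleep_s: float = 60.0) -> float:
    """Analytic sleep fraction of the exponential bout model."""
    mu_s, mu_w = params.mean_sleep_bout_s, params.mean_wake_bout_s
    rest_frac = mu_s / (mu_s + mu_w)
    qualifying = math.exp(-min_sleep_s / mu_s) * (1 + min_sleep_s / mu_s)
    return rest_frac * qualifying


def simulate_activity(
    params: ActivitySimParams,
    seed: int | None = None,
    subject_id: str = "sim",
    population: str = "surface",
    treatment: str = "control",
    zt_start: float = 0.0,
    min_sleep_s: float = 60.0,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one recording; identical (params, seed) gives identical output."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    fr = params.frame_rate
    n = int(round(params.duration_h * 3600.0 * fr))
    dt = 1.0 / fr

    # alternating wake/rest bout durations in frames (truncated at 1 frame)
    total_mu = params.mean_sleep_bout_s + params.mean_wake_bout_s
    est = max(int(2.5 * params.duration_h * 3600.0 / total_mu) + 16, 16)
    states, frames = [], []
    acc = 0
    awake = True
    while acc < n:
        durs_w = rng.exponential(params.mean_wake_bout_s, size=est)
        durs_s = rng.exponential(params.mean_sleep_bout_s, size=est)
        for dw, ds in zip(durs_w, durs_s):
            for dur, st in ((dw, True), (ds, False)) if awake else ((ds, False), (dw, True)):
                f = max(int(round(dur * fr)), 1)
                states.append(st)
                frames.append(f)
                acc += f
            if acc >= n:
                break
    frames = np.asarray(frames)
    states = np.asarray(states, dtype=bool)
    # truncate to exactly n frames
    cum = np.cumsum(frames)
    keep = np.searchsorted(cum, n, side="left") + 1
    frames, states = frames[:keep].copy(), states[:keep]
    frames[-1] -= cum[keep - 1] - n

    wake_frame = np.repeat(states, frames)  # True during wake

    # wake kinematics: correlated random walk with gamma speeds
    n_wake = int(wake_frame.sum())
    steps = np.zeros((n, 2))
    if n_wake:
        speeds = rng.gamma(params.wake_speed_shape, params.wake_speed_scale, size=n_wake)
        headings = np.cumsum(rng.normal(0.0, params.heading_sd, size=n_wake))
        headings += rng.uniform(0, 2 * np.pi)
        steps[wake_frame, 0] = speeds * dt * np.cos(headings)
        steps[wake_frame, 1] = speeds * dt * np.sin(headings)
    start = rng.uniform([0.25, 0.25], [0.75, 0.75]) * np.asarray(params.arena_mm)
    base = start + np.cumsum(steps, axis=0)
    # reflect into the arena by triangle-wave folding
    for k, L in enumerate(params.arena_mm):
        base[:, k] = L - np.abs(np.mod(base[:, k], 2 * L) - L)
    pos = base
    if params.rest_jitter_sd > 0:
        n_rest = n - n_wake
        if n_rest:
            jitter = rng.normal(0.0, params.rest_jitter_sd, size=(n_rest, 2))
            pos[~wake_frame] += jitter
            for k, L in enumerate(params.arena_mm):
                np.clip(pos[:, k], 0.0, L, out=pos[:, k])

    traj = Trajectory(
        subject_id=subject_id,
        population=population,
        treatment=treatment,
        t=np.arange(n) / fr,
        x=pos[:, 0],
        y=pos[:, 1],
        frame_rate=fr,
        zt_start=zt_start,
        missing=np.zeros(n, dtype=bool),
    )

    # ground-truth partition: rest runs >= min_sleep_s are sleep
    bounds = np.concatenate(([0], np.cumsum(frames)))
    intervals = []
    sleep_s = 0.0
    for st, s, e in zip(states, bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        dur = (e - s) / fr
        if (not st) and dur >= min_sleep_s - 1e-9:
            label = SLEEP
            sleep_s += dur
        else:
            label = WAKE
        if intervals and intervals[-1][2] == label == WAKE:
            intervals[-1] = (intervals[-1][0], e / fr, WAKE)
        else:
            intervals.append((s / fr, e / fr, label))
    truth = GroundTruth(
        intervals=intervals,
        sleep_fraction=sleep_s / (n / fr),
        params=params,
        seed=seed,
        min_sleep_s=min_sleep_s,
    )
    return traj, truth


#: Preset (mean rest bout s, mean wake bout s) per (population, treatment).
#: Expected sleep fractions: surface ~0.46 everywhere; cavefish control
#: ~0.085 (>80% below surface); treated cavefish ~0.32.
_PRESET_BOUTS = {
    ("surface", "control"): (220.0, 240.0),
    ("cavefish", "control"): (45.0, 280.0),
    ("cavefish", "antagonist"): (90.0, 150.0),
    ("cavefish", "starved"): (90.0, 150.0),
    ("cavefish", "ablated"): (90.0, 150.0),
}


def preset(population: str, treatment: str, **overrides) -> ActivitySimParams:
    """Simulation parameters for a population x treatment condition.

    Surface fish are insensitive to the sleep-promoting treatments, so all
    surface presets equal the surface control; cavefish treatments raise
    sleep through shorter wake bouts and longer rest bouts.
    """
    if population not in POPULATION_LABELS:
        raise ConfigError(f"unknown population {population!r}")
    if treatment not in TREATMENT_LABELS:
        raise ConfigError(f"unknown treatment {treatment!r}")
    key = (population, treatment)
    if population == "surface":
        key = ("surface", "control")
    mu_s, mu_w = _PRESET_BOUTS[key]
    return ActivitySimParams(
        mean_sleep_bout_s=mu_s, mean_wake_bout_s=mu_w, **overrides
    )


def simulate_cohort(
    groups: list[tuple[str, str]],
    n_per_group: int = 12,
    duration_h: float = 24.0,
    seed: int = 0,
    zt_start: float = 0.0,
):
    """Simulate ``n_per_group`` fish per (population, treatment) condition.

    Returns a list of ``(Trajectory, GroundTruth)``; fish seeds are derived
    from ``seed`` deterministically.
    """
    out = []
    k = 0
    for population, treatment in groups:
        params = preset(population, treatment, duration_h=duration_h)
        for i in range(n_per_group):
            fish_seed = (int(seed) * 100_003 + k * 7919 + 1) & 0x7FFFFFFF
            traj, truth = simulate_activity(
                params,
                seed=fish_seed,
                subject_id=f"{population[:4]}_{treatment[:4]}_{i:02d}",
                population=population,
                treatment=treatment,
                zt_start=zt_start,
            )
            out.append((traj, truth))
            k += 1
    return out


def simulate_qpcr(
    group_delta_ct: dict,
    n_per_group: int = 4,
    n_replicates: int = 3,
    replicate_sd: float = 0.15,
    run_offsets: list | None = None,
    seed: int = 0,
    calibrator_sample: str = "irc",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format qPCR plate with known group ΔCt values.

    Reference-gene Cts are N(15, 0.2) per sample; the target Ct is the
    sample's reference level plus the group ΔCt, plus replicate noise and a
    per-run instrument offset (applied to both genes).  A shared calibrator
    sample appears in every run so inter-run calibration can recover the
    offsets.  Returns ``(plate, truth)`` with truth holding the ΔCt map,
    offsets and expected folds relative to any calibrator group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    offsets = list(run_offsets) if run_offsets else [0.0]
    rows = []
    sample_idx = 0
    irc_ref, irc_target = 15.0, 20.0
    for run_id, off in enumerate(offsets):
        for gene, base in (("reference", irc_ref), ("target", irc_target)):
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": calibrator_sample,
                        "group": "irc",
                        "run_id": run_id,
                        "gene": gene,
                        "ct": base + off + rng.normal(0, replicate_sd),
                    }
                )
    for group, dct in group_delta_ct.items():
        for i in range(n_per_group):
            run_id = sample_idx % len(offsets)
            off = offsets[run_id]
            ref_base = rng.normal(15.0, 0.2)
            for gene, level in (("reference", ref_base), ("target", ref_base + dct)):
                for _ in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": f"{group}_{i:02d}",
                            "group": group,
                            "run_id": run_id,
                            "gene": gene,
                            "ct": level + off + rng.normal(0, replicate_sd),
                        }
                    )
            sample_idx += 1
    truth = {
        "group_delta_ct": dict(group_delta_ct),
        "run_offsets": offsets,
        "expected_fold_vs": {
            cal: {g: 2.0 ** (-(d - group_delta_ct[cal])) for g, d in group_delta_ct.items()}
            for cal in group_delta_ct
        },
    }
    return pd.DataFrame(rows), truth


def simulate_stack(
    n_cells: int = 8,
    soma_radius_px: float = 4.0,
    intensity_mean: float = 50.0,
    background: float = 20.0,
    noise_sd: float = 2.5,
    min_separation_px: float = 24.0,
    size: tuple = (5, 128, 128),
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate a z-stack with Gaussian-profile somata of known truth.

    Somata are placed by rejection sampling honouring ``min_separation_px``
    (and an edge margin), each on one z-slice with a one-slice-sigma axial
    profile; per-cell peak amplitudes vary +/-20% around ``intensity_mean``.
    Gaussian noise of SD ``noise_sd`` approximates Poisson-like acquisition
    noise.  Truth records position, amplitude and the noise-free integrated
    intensity of each soma in the max projection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    nz, ny, nx = size
    sigma = soma_radius_px / 2.0
    margin = 3.0 * soma_radius_px
    centers = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 20_000:
            raise ConfigError(
                "could not place somata with the requested separation; "
                "reduce n_cells or min_separation_px"
            )
        cy = rng.uniform(margin, ny - margin)
        cx = rng.uniform(margin, nx - margin)
        if all(np.hypot(cy - y0, cx - x0) >= min_separation_px for y0, x0 in centers):
            centers.append((cy, cx))

    yy, xx = np.mgrid[0:ny, 0:nx]
    clean = np.zeros((nz, ny, nx))
    truth_rows = []
    for i, (cy, cx) in enumerate(centers):
        amp = intensity_mean * rng.uniform(0.8, 1.2)
        zc = int(rng.integers(0, nz))
        g2d = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        z_factor = 0.0
        for z in range(nz):
            zf = math.exp(-((z - zc) ** 2) / 2.0)
            clean[z] += g2d * zf
            z_factor += zf
        truth_rows.append(
            {
                "cell_id": i + 1,
                "y": cy,
                "x": cx,
                "z": zc,
                "amplitude": amp,
                # total noise-free signal of this soma across the stack
                "integrated_int": float(g2d.sum()) * z_factor,
            }
        )
    voxels = clean + background + rng.normal(0.0, noise_sd, size=(nz, ny, nx))
    np.clip(voxels, 0.0, None, out=voxels)
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "y", "x", "z", "amplitude", "integrated_int"]
    ).sort_values(["y", "x"], kind="stable").reset_index(drop=True)
    return ImageStack(voxels), truth


def simulate_study(
    outdir,
    groups: list[tuple[str, str]] | None = None,
    n_per_group: int = 12,
    duration_h: float = 2.0,
    seed: int = 0,
    n_stacks_per_group: int = 0,
) -> Path:
    """Write a complete synthetic study (manifest + trajectories + qPCR +
    optional stacks + ground-truth JSON) into a directory; returns its path."""
    outdir = Path(outdir)
    (outdir / "trajectories").mkdir(parents=True, exist_ok=True)
    groups = groups or [
        ("surface", "control"),
        ("surface", "antagonist"),
        ("cavefish", "control"),
        ("cavefish", "antagonist"),
    ]
    manifest_rows, truth_fish = [], {}
    for traj, truth in simulate_cohort(groups, n_per_group, duration_h, seed):
        rel = f"trajectories/{traj.subject_id}.csv"
        write_tracking(traj, outdir / rel)
        manifest_rows.append(
            {
                "file": rel,
                "subject_id": traj.subject_id,
                "population": traj.population,
                "treatment": traj.treatment,
                "zt_start": traj.zt_start,
                "calibration_mm_per_px": 1.0,
            }
        )
        truth_fish[traj.subject_id] = {
            "sleep_fraction": truth.sleep_fraction,
            "seed": truth.seed,
        }
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)

    # qPCR: cavefish control elevated ~3-fold vs surface control; the
    # sleep-promoting treatment restores surface-like expression in cavefish
    delta_ct = {
        "surface_control": 5.0,
        "surface_antagonist": 5.0,
        "cavefish_control": 5.0 - math.log2(3.0),
        "cavefish_antagonist": 5.0,
    }
    plate, qpcr_truth = simulate_qpcr(
        delta_ct, run_offsets=[0.0, 0.4], seed=seed + 101
    )
    plate.to_csv(outdir / "qpcr.csv", index=False)

    stack_meta = []
    if n_stacks_per_group:
        (outdir / "stacks").mkdir(exist_ok=True)
        for gi, (population, treatment) in enumerate(groups):
            n_cells = 18 if population == "cavefish" else 8
            for i in range(n_stacks_per_group):
                stack, struth = simulate_stack(
                    n_cells=n_cells, size=(5, 192, 192),
                    seed=seed + 1000 + gi * 37 + i,
                )
                name = f"stacks/{population[:4]}_{treatment[:4]}_{i:02d}.tif"
                tifffile.imwrite(outdir / name, stack.voxels.astype(np.float32))
                stack_meta.append(
                    {
                        "file": name,
                        "brain_id": f"{population[:4]}_{treatment[:4]}_{i:02d}",
                        "population": population,
                        "treatment": treatment,
                        "true_n_cells": n_cells,
                    }
                )
        pd.DataFrame(stack_meta).to_csv(outdir / "stacks.csv", index=False)

    truth = {
        "seed": seed,
        "groups": [list(g) for g in groups],
        "n_per_group": n_per_group,
        "duration_h": duration_h,
        "fish": truth_fish,
        "qpcr": {
            "group_delta_ct": qpcr_truth["group_delta_ct"],
            "run_offsets": qpcr_truth["run_offsets"],
        },
        "expected_sleep_fraction": {
            f"{p}/{t}": expected_sleep_fraction(preset(p, t)) for p, t in groups
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
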