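"""Sleep scoring: speed, immobility, bout detection and architecture metrics.

Sleep is scored behaviourally: a sleep bout is a maximal run of immobility
lasting at least ``min_sleep_s`` (default 60 s), the duration at which
immobility in this species correlates with an increased arousal threshold.
The scorer proceeds in four stages:

1. ``compute_speed`` — frame-to-frame Euclidean speed (mm/s) from the
   calibrated trajectory, median-smoothed to suppress single-frame tracker
   jitter.
2. ``classify_immobility`` — per-frame immobility call, ``speed <
   speed_threshold`` (strict inequality).
3. ``detect_bouts`` — run-length analysis.  Mobile runs shorter than
   ``min_interrupt_s`` flanked by immobility are absorbed (one noisy frame
   must not split a sleep bout); maximal immobility runs of at least
   ``min_sleep_s`` become sleep intervals; everything else is wake.  The
   result is an exact, gap-free partition of the recording.
4. ``summarize_sleep`` — per-fish architecture metrics: total sleep, bout
   count, mean bout duration, waking activity (mean speed over wake intervals
   only, which distinguishes genuine sleep increase from lethargy) and a
   binned 24-h sleep profile.

All conventions (strict threshold inequality, half-open frame-edge-aligned
intervals, window membership by bout midpoint) are fixed so that results are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ConfigError, PipelineError, ValidationError
from .trajectory import PhotoperiodSpec, Trajectory, fill_gaps, load_cohort

SLEEP = "sleep"
WAKE = "wake"


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the immobility-based sleep scorer.

    speed_threshold : mm/s
        Frames with smoothed speed strictly below this are immobile.  The
        value is not dictated by the behavioural definition itself; the
        default (4 mm/s, of order one body length per second for an adult
        *A. mexicanus*) is a configurable choice and is logged in every
        report.
    smooth_window_s : s
        Width of the rolling-median speed filter (1 s at 15 Hz spans 15
        frames).
    min_sleep_s : s
        Minimum immobility duration that counts as sleep (60 s).
    min_interrupt_s : s
        Mobile runs shorter than this do not terminate an immobility run.
        Set to 0 for the strictest reading (any supra-threshold frame ends
        a bout).
    """

    speed_threshold: float = 4.0
    smooth_window_s: float = 1.0
    min_sleep_s: float = 60.0
    min_interrupt_s: float = 1.0

    def __post_init__(self):
        if min(self.speed_threshold, self.smooth_window_s, self.min_interrupt_s) < 0:
            raise ConfigError("scoring parameters must be >= 0")
        if not self.min_sleep_s > 0:
            raise ConfigError("min_sleep_s must be > 0")


@dataclass
class BoutSeries:
    """Exhaustive sleep/wake partition of a recording.

    ``intervals`` is an ordered list of ``(start_s, end_s, label)`` tuples
    that tile ``[0, recording_span)`` exactly, with alternating labels; every
    sleep interval is at least ``min_sleep_s`` long.  Boundaries are
    frame-edge aligned (frame ``i`` covers ``[i/frame_rate, (i+1)/frame_rate)``).
    """

    intervals: list
    recording_span: float
    frame_rate: float
    min_sleep_s: float = 60.0

    def __post_init__(self):
        prev_end, prev_label = 0.0, None
        for start, end, label in self.intervals:
            if label not in (SLEEP, WAKE):
                raise ValidationError(f"unknown interval label {label!r}")
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValidationError("intervals must tile the recording without gaps")
            if label == prev_label:
                raise ValidationError("adjacent intervals must differ in label")
            if label == SLEEP and end - start < self.min_sleep_s - 1e-9:
                raise ValidationError("sleep interval shorter than min_sleep_s")
            prev_end, prev_label = end, label
        if self.intervals and not math.isclose(
            prev_end, self.recording_span, abs_tol=1e-9
        ):
            raise ValidationError("intervals must end at recording_span")

    @property
    def sleep_intervals(self):
        return [(s, e) for s, e, lab in self.intervals if lab == SLEEP]

    @property
    def total_sleep_s(self) -> float:
        return float(sum(e - s for s, e in self.sleep_intervals))


@dataclass
class SleepMetrics:
    """Per-fish sleep-architecture summary over one analysis window."""

    total_sleep_min: float
    sleep_bout_count: int
    mean_bout_duration_s: float  # NaN when no bouts
    waking_activity_mm_per_s: float
    profile: np.ndarray = field(default_factory=lambda: np.array([]))
    window: tuple = (0.0, 0.0)

    def to_dict(self) -> dict:
        d = {
            "total_sleep_min": self.total_sleep_min,
            "bout_count": self.sleep_bout_count,
            "mean_bout_s": self.mean_bout_duration_s,
            "waking_mm_s": self.waking_activity_mm_per_s,
        }
        for i, v in enumerate(self.profile):
            d[f"profile_bin_{i:02d}"] = v
        return d


def compute_speed(traj: Trajectory, smooth_window_s: float = 1.0) -> np.ndarray:
    """Per-frame speed (mm/s), NaN where undefined.

    ``speed[i]`` is the Euclidean displacement between consecutive *resolved*
    frames divided by their time difference, assigned to the later frame.
    The first resolved frame and all missing frames carry NaN.  A rolling
    median of width ``round(smooth_window_s * frame_rate)`` is applied along
    the resolved-frame sequence (width <= 1 is the identity).
    """
    resolved = ~traj.missing
    idx = np.flatnonzero(resolved)
    if idx.size < 2:
        raise ValidationError("need at least 2 resolved frames to compute speed")
    dt = np.diff(traj.t[idx])
    disp = np.hypot(np.diff(traj.x[idx]), np.diff(traj.y[idx]))
    vals = disp / dt
    width = int(round(smooth_window_s * traj.frame_rate))
    if width > 1:
        vals = median_filter(vals, size=width, mode="nearest")
    speed = np.full(traj.n_frames, np.nan)
    speed[idx[1:]] = vals
    return speed


def classify_immobility(speed: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Per-frame immobility calls: ``speed < speed_threshold`` (strict).

    Frames with no speed value inherit the preceding frame's call; leading
    undefined frames take the first defined call.
    """
    speed = np.asarray(speed, dtype=float)
    defined = np.isfinite(speed)
    if not defined.any():
        raise ValidationError("no defined speed values to classify")
    calls = np.where(defined, speed < params.speed_threshold, False)
    # forward-fill undefined frames from the last defined call
    last_def = np.maximum.accumulate(np.where(defined, np.arange(speed.size), -1))
    first = np.flatnonzero(defined)[0]
    last_def = np.where(last_def < 0, first, last_def)
    return calls[last_def]


def _runs(values: np.ndarray):
    """Run-length encode a boolean array -> (start_idx, length, value)."""
    values = np.asarray(values, dtype=bool)
    n = values.size
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, values[starts]


def detect_bouts(
    immobility: np.ndarray, frame_rate: float, params: ScoringParams
) -> BoutSeries:
    """Partition a recording into alternating sleep/wake intervals.

    Mobile runs strictly shorter than ``min_interrupt_s`` that are flanked by
    immobility on both sides are absorbed into the surrounding immobility
    (runs at the recording edges are never absorbed).  Maximal immobility
    runs of duration >= ``min_sleep_s`` become sleep; all remaining time is
    wake.  Intervals are frame-edge aligned and half-open.
    """
    immobility = np.asarray(immobility, dtype=bool)
    if immobility.size == 0:
        raise ValidationError("empty immobility series")
    starts, lengths, vals = _runs(immobility)

    if params.min_interrupt_s > 0 and starts.size > 2:
        # runs alternate, so an interior mobile run is always flanked by
        # immobility; absorb the short ones, then re-merge
        short = (~vals) & (lengths / frame_rate < params.min_interrupt_s)
        short[0] = short[-1] = False
        if short.any():
            merged = np.where(short, True, vals)
            expanded = np.repeat(merged, lengths)
            starts, lengths, vals = _runs(expanded)

    min_frames_ok = (lengths / frame_rate) >= params.min_sleep_s - 1e-9
    is_sleep = vals & min_frames_ok

    intervals = []
    span = immobility.size / frame_rate
    cursor = 0.0
    pending_wake_start = None
    for s, ln, sleep in zip(starts, lengths, is_sleep):
        start_s = s / frame_rate
        end_s = (s + ln) / frame_rate
        if sleep:
            if pending_wake_start is not None:
                intervals.append((pending_wake_start, start_s, WAKE))
                pending_wake_start = None
            elif intervals and not math.isclose(cursor, start_s, abs_tol=1e-12):
                intervals.append((cursor, start_s, WAKE))
            intervals.append((start_s, end_s, SLEEP))
            cursor = end_s
        else:
            if pending_wake_start is None:
                pending_wake_start = start_s
    if pending_wake_start is not None:
        intervals.append((pending_wake_start, span, WAKE))
    elif not intervals or intervals[-1][1] < span - 1e-12:
        if intervals:
            intervals.append((intervals[-1][1], span, WAKE))
        else:
            intervals.append((0.0, span, WAKE))
    # merge contiguous wake intervals produced around absorbed runs
    cleaned = []
    for iv in intervals:
        if cleaned and cleaned[-1][2] == WAKE and iv[2] == WAKE:
            cleaned[-1] = (cleaned[-1][0], iv[1], WAKE)
        else:
            cleaned.append(list(iv) if isinstance(iv, tuple) else iv)
    cleaned = [tuple(iv) for iv in cleaned]
    return BoutSeries(
        intervals=cleaned,
        recording_span=span,
        frame_rate=frame_rate,
        min_sleep_s=params.min_sleep_s,
    )


def _overlap(a0, a1, b0, b1):
    return max(0.0, min(a1, b1) - max(a0, b0))


def summarize_sleep(
    bouts: BoutSeries,
    speed: np.ndarray | None = None,
    window: tuple | None = None,
    bin_minutes: int = 60,
) -> SleepMetrics:
    """Architecture metrics over ``window = (start_s, end_s)``.

    Bouts straddling the window contribute only their overlapping portion to
    total sleep and the profile, but count once toward the bout count if
    their midpoint lies in the window (their full duration enters the mean).
    Waking activity is the time-weighted mean speed over wake intervals in
    the window; it is NaN when no wake frame has a speed value.
    """
    if window is None:
        window = (0.0, bouts.recording_span)
    w0, w1 = float(window[0]), float(window[1])
    if not (0.0 <= w0 < w1 <= bouts.recording_span + 1e-9):
        raise ValidationError(f"window {window} not within recording span")

    total_sleep_s = 0.0
    counted = []
    for s, e in bouts.sleep_intervals:
        total_sleep_s += _overlap(s, e, w0, w1)
        if w0 <= (s + e) / 2.0 < w1:
            counted.append(e - s)

    # profile: bins of bin_minutes from window start, last bin truncated
    bin_s = bin_minutes * 60.0
    n_bins = int(math.ceil((w1 - w0) / bin_s - 1e-12))
    profile = np.zeros(n_bins)
    for s, e in bouts.sleep_intervals:
        s_c, e_c = max(s, w0), min(e, w1)
        if e_c <= s_c:
            continue
        b0 = int((s_c - w0) // bin_s)
        b1 = min(int((e_c - w0) // bin_s), n_bins - 1)
        for b in range(b0, b1 + 1):
            lo = w0 + b * bin_s
            profile[b] += _overlap(s_c, e_c, lo, lo + bin_s) / 60.0

    waking = np.nan
    if speed is not None:
        speed = np.asarray(speed, dtype=float)
        fr = bouts.frame_rate
        n = speed.size
        # frame i has midpoint (i + 0.5)/fr; stamp wake intervals in O(n)
        delta = np.zeros(n + 1, dtype=np.int64)
        for s, e, lab in bouts.intervals:
            if lab == WAKE:
                i0 = min(max(int(math.ceil(s * fr - 0.5 - 1e-9)), 0), n)
                i1 = min(max(int(math.ceil(e * fr - 0.5 - 1e-9)), 0), n)
                delta[i0] += 1
                delta[i1] -= 1
        wake_mask = np.cumsum(delta[:-1]) > 0
        i0 = min(max(int(math.ceil(w0 * fr - 0.5 - 1e-9)), 0), n)
        i1 = min(max(int(math.ceil(w1 * fr - 0.5 - 1e-9)), 0), n)
        in_win = np.zeros(n, dtype=bool)
        in_win[i0:i1] = True
        sel = in_win & wake_mask & np.isfinite(speed)
        if sel.any():
            waking = float(speed[sel].mean())

    return SleepMetrics(
        total_sleep_min=total_sleep_s / 60.0,
        sleep_bout_count=len(counted),
        mean_bout_duration_s=float(np.mean(counted)) if counted else float("nan"),
        waking_activity_mm_per_s=waking,
        profile=profile,
        window=(w0, w1),
    )


def _summarize_union(bouts, speed, intervals, bin_minutes):
    """Metrics over a union of disjoint windows (used for day/night splits)."""
    parts = [summarize_sleep(bouts, speed, w, bin_minutes) for w in intervals]
    total = sum(p.total_sleep_min for p in parts)
    count = sum(p.sleep_bout_count for p in parts)
    durations = [
        p.mean_bout_duration_s * p.sleep_bout_count
        for p in parts
        if p.sleep_bout_count
    ]
    mean_bout = (sum(durations) / count) if count else float("nan")
    wak = [p.waking_activity_mm_per_s for p in parts if np.isfinite(p.waking_activity_mm_per_s)]
    spans = [
        w1 - w0
        for (w0, w1), p in zip(intervals, parts)
        if np.isfinite(p.waking_activity_mm_per_s)
    ]
    waking = float(np.average(wak, weights=spans)) if wak else float("nan")
    profile = np.concatenate([p.profile for p in parts]) if parts else np.array([])
    lo = min(w[0] for w in intervals) if intervals else 0.0
    hi = max(w[1] for w in intervals) if intervals else 0.0
    return SleepMetrics(total, count, mean_bout, waking, profile, (lo, hi))


def phase_intervals(
    zt_start: float, span_s: float, photoperiod: PhotoperiodSpec, phase: str
) -> list[tuple[float, float]]:
    """Recording-time intervals during which ZT falls in the given phase.

    ``phase`` is ``"light"`` or ``"dark"``; boundaries follow the half-open
    convention (lights-on = [on, off) in ZT).
    """
    pp = photoperiod
    want_light = phase == "light"
    # phase boundaries in recording seconds
    bounds = [0.0]
    for k in range(int(span_s / 3600 / pp.period) + 2):
        for zt_edge in (pp.lights_on_zt, pp.lights_off_zt):
            t_edge = ((zt_edge - zt_start) % pp.period + k * pp.period) * 3600.0
            if 0.0 < t_edge < span_s:
                bounds.append(t_edge)
    bounds.append(span_s)
    bounds = sorted(set(bounds))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        zt_mid = (zt_start + (a + b) / 2.0 / 3600.0) % pp.period
        if pp.is_light(zt_mid) == want_light:
            if out and math.isclose(out[-1][1], a, abs_tol=1e-9):
                out[-1] = (out[-1][0], b)
            else:
                out.append((a, b))
    return out


def score_trajectory(
    traj: Trajectory,
    params: ScoringParams,
    fill_max_gap_s: float = 1.0,
    windows: str = "total",
    photoperiod: PhotoperiodSpec | None = None,
    bin_minutes: int = 60,
):
    """Score one fish; returns ``{window_name: SleepMetrics}``.

    ``windows`` is ``"total"`` (full recording) or ``"day_night"`` (adds
    ZT light/dark splits).  Missing-frame gaps up to ``fill_max_gap_s`` are
    interpolated first.
    """
    pp = photoperiod or PhotoperiodSpec()
    traj = fill_gaps(traj, fill_max_gap_s)
    speed = compute_speed(traj, params.smooth_window_s)
    immob = classify_immobility(speed, params)
    bouts = detect_bouts(immob, traj.frame_rate, params)
    out = {"total": summarize_sleep(bouts, speed, None, bin_minutes)}
    if windows == "day_night":
        for phase, name in (("light", "day"), ("dark", "night")):
            ivs = phase_intervals(traj.zt_start, bouts.recording_span, pp, phase)
            if ivs:
                out[name] = _summarize_union(bouts, speed, ivs, bin_minutes)
    return out


def score_cohort(
    manifest,
    params: ScoringParams,
    base_dir=None,
    fill_max_gap_s: float = 1.0,
    windows: str = "total",
    photoperiod: PhotoperiodSpec | None = None,
    bin_minutes: int = 60,
):
    """Score every fish in a cohort manifest.

    Returns ``(metrics DataFrame, failures DataFrame)``: one metrics row per
    fish x window with population/treatment labels propagated; per-fish
    failures are recorded, never silently dropped.  Raises
    :class:`PipelineError` if every file fails.
    """
    rows, failures = [], []
    n_input = 0
    for row, traj, err in load_cohort(manifest, base_dir):
        n_input += 1
        if err is not None:
            failures.append(
                {"subject_id": row.get("subject_id"), "file": row.get("file"),
                 "error": str(err)}
            )
            continue
        try:
            per_window = score_trajectory(
                traj, params, fill_max_gap_s, windows, photoperiod, bin_minutes
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(
                {"subject_id": traj.subject_id, "file": row.get("file"),
                 "error": str(exc)}
            )
            continue
        for wname, metrics in per_window.items():
            rows.append(
                {
                    "subject_id": traj.subject_id,
                    "population": traj.population,
                    "treatment": traj.treatment,
                    "window": wname,
                    **metrics.to_dict(),
                }
            )
    if n_input and not rows:
        raise PipelineError(
            f"all {n_input} cohort files failed to score; first error: "
            f"{failures[0]['error'] if failures else 'unknown'}"
        )
    metrics_df = pd.DataFrame(rows).sort_values(
        ["subject_id", "window"], kind="stable"
    ).reset_index(drop=True) if rows else pd.DataFrame()
    return metrics_df, pd.DataFrame(failures)
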