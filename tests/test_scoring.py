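"""Sleep scoring: speed, immobility calls, bout detection, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finsomnia.errors import PipelineError, ValidationError
from finsomnia.scoring import (
    SLEEP,
    WAKE,
    ScoringParams,
    classify_immobility,
    compute_speed,
    detect_bouts,
    score_cohort,
    summarize_sleep,
)
from finsomnia.trajectory import Trajectory, write_tracking

FR = 15.0


def traj_of(x, y=None, missing=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float) if y is not None else np.zeros_like(x)
    return Trajectory("f", "surface", "control", t=np.arange(x.size) / FR,
                      x=x, y=y, frame_rate=FR, missing=missing)


def oracle_sleep_intervals(immob, fr, min_sleep_s=60.0, min_interrupt_s=0.0):
    """Brute-force run enumeration, independent of the implementation."""
    runs = []
    cur, ln = bool(immob[0]), 0
    for v in immob:
        v = bool(v)
        if v == cur:
            ln += 1
        else:
            runs.append([cur, ln])
            cur, ln = v, 1
    runs.append([cur, ln])
    if min_interrupt_s > 0:
        relabeled = []
        for i, (val, ln) in enumerate(runs):
            if (not val) and ln / fr < min_interrupt_s and 0 < i < len(runs) - 1:
                val = True
            if relabeled and relabeled[-1][0] == val:
                relabeled[-1][1] += ln
            else:
                relabeled.append([val, ln])
        runs = relabeled
    sleeps, pos = [], 0
    for val, ln in runs:
        if val and ln / fr >= min_sleep_s - 1e-9:
            sleeps.append((pos / fr, (pos + ln) / fr))
        pos += ln
    return sleeps


class TestComputeSpeed:
    def test_constant_position_zero_speed(self):
        speed = compute_speed(traj_of(np.full(100, 3.0)), 0.0)
        assert np.nanmax(speed) == 0.0

    def test_one_mm_per_frame_is_15_mm_s(self):
        speed = compute_speed(traj_of(np.arange(50, dtype=float)), 0.0)
        assert np.allclose(speed[1:], 15.0)

    def test_width_one_window_is_identity(self, rng):
        x = np.cumsum(rng.normal(size=300))
        y = np.cumsum(rng.normal(size=300))
        raw = compute_speed(traj_of(x, y), 0.0)
        smoothed = compute_speed(traj_of(x, y), 1.0 / FR)  # one-frame window
        assert np.array_equal(raw[1:], smoothed[1:])

    def test_missing_frames_carry_no_speed(self):
        x = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        speed = compute_speed(traj_of(x, missing=np.isnan(x)), 0.0)
        assert np.isnan(speed[0]) and np.isnan(speed[2])
        # displacement bridges the gap: 2 mm over 2 frames
        assert speed[3] == pytest.approx(15.0)

    def test_too_few_resolved_frames(self):
        x = np.array([1.0, np.nan, np.nan])
        with pytest.raises(ValidationError):
            compute_speed(traj_of(x, missing=np.isnan(x)), 0.0)


class TestClassifyImmobility:
    def test_all_zero_all_immobile(self, params_strict):
        calls = classify_immobility(np.zeros(100), params_strict)
        assert calls.all()

    def test_exactly_at_threshold_is_mobile(self, params_strict):
        calls = classify_immobility(np.full(10, 4.0), params_strict)
        assert not calls.any()

    def test_matches_elementwise_oracle(self, rng, params_strict):
        speed = rng.uniform(0, 8, size=1000)
        calls = classify_immobility(speed, params_strict)
        assert np.array_equal(calls, speed < 4.0)

    def test_nan_inherits_previous_call(self, params_strict):
        speed = np.array([np.nan, 1.0, np.nan, np.nan, 5.0, np.nan])
        calls = classify_immobility(speed, params_strict)
        assert calls.tolist() == [True, True, True, True, False, False]


class TestDetectBouts:
    def test_single_long_immobility_run(self, params_strict):
        immob = np.zeros(int(300 * FR), dtype=bool)
        immob[: int(120 * FR)] = True
        bouts = detect_bouts(immob, FR, params_strict)
        assert bouts.sleep_intervals == [(0.0, 120.0)]
        assert bouts.total_sleep_s == pytest.approx(120.0)

    def test_59s_run_is_not_sleep(self, params_strict):
        immob = np.zeros(int(300 * FR), dtype=bool)
        immob[: int(59 * FR)] = True
        bouts = detect_bouts(immob, FR, params_strict)
        assert bouts.sleep_intervals == []
        assert bouts.total_sleep_s == 0.0

    def test_exactly_60s_is_sleep(self, params_strict):
        immob = np.zeros(int(300 * FR), dtype=bool)
        immob[: int(60 * FR)] = True
        bouts = detect_bouts(immob, FR, params_strict)
        assert bouts.sleep_intervals == [(0.0, 60.0)]

    def test_matches_bruteforce_oracle(self, params_strict):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(100, 5000))
            flip = rng.random(n) < rng.uniform(0.0005, 0.02)
            immob = np.cumsum(flip) % 2 == 0
            bouts = detect_bouts(immob, FR, params_strict)
            expect = oracle_sleep_intervals(immob, FR, 60.0, 0.0)
            got = [(round(s, 9), round(e, 9)) for s, e in bouts.sleep_intervals]
            expect = [(round(s, 9), round(e, 9)) for s, e in expect]
            assert got == expect

    def test_interruption_absorption_matches_oracle(self):
        params = ScoringParams(min_interrupt_s=1.0, smooth_window_s=0.0)
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(500, 5000))
            flip = rng.random(n) < 0.01
            immob = np.cumsum(flip) % 2 == 0
            bouts = detect_bouts(immob, FR, params)
            expect = oracle_sleep_intervals(immob, FR, 60.0, 1.0)
            assert [(s, e) for s, e in bouts.sleep_intervals] == pytest.approx(expect)

    def test_short_interruption_bridges_bout(self):
        params = ScoringParams(min_interrupt_s=1.0, smooth_window_s=0.0)
        immob = np.ones(int(130 * FR), dtype=bool)
        mid = int(62 * FR)
        immob[mid : mid + 5] = False  # 1/3 s movement
        bouts = detect_bouts(immob, FR, params)
        assert bouts.sleep_intervals == [(0.0, 130.0)]
        # strictest reading: the same movement splits the run
        strict = detect_bouts(immob, FR, ScoringParams(min_interrupt_s=0.0))
        assert len(strict.sleep_intervals) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 3000))
        immob = np.cumsum(rng.random(n) < 0.01) % 2 == 0
        bouts = detect_bouts(immob, FR, ScoringParams())
        covered = sum(e - s for s, e, _ in bouts.intervals)
        assert covered == pytest.approx(n / FR, abs=1e-9)
        labels = [lab for _, _, lab in bouts.intervals]
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_monotone_in_min_sleep(self, rng):
        immob = np.cumsum(rng.random(20000) < 0.005) % 2 == 0
        prev_total, prev_count = np.inf, np.inf
        for min_sleep in (30.0, 60.0, 120.0, 240.0):
            b = detect_bouts(immob, FR, ScoringParams(min_sleep_s=min_sleep))
            assert b.total_sleep_s <= prev_total + 1e-9
            assert len(b.sleep_intervals) <= prev_count
            prev_total, prev_count = b.total_sleep_s, len(b.sleep_intervals)

    def test_monotone_in_speed_threshold(self, rng):
        speed = np.abs(np.cumsum(rng.normal(0, 0.5, size=20000)))
        prev = -1.0
        for thr in (1.0, 2.0, 4.0, 8.0, 16.0):
            p = ScoringParams(speed_threshold=thr, smooth_window_s=0.0)
            b = detect_bouts(classify_immobility(speed, p), FR, p)
            assert b.total_sleep_s >= prev - 1e-9
            prev = b.total_sleep_s


class TestSummarize:
    def _bouts_with(self, sleep_spans, span_s):
        immob = np.zeros(int(span_s * FR), dtype=bool)
        for s, e in sleep_spans:
            immob[int(s * FR) : int(e * FR)] = True
        return detect_bouts(immob, FR, ScoringParams(min_interrupt_s=0.0))

    def test_single_bout_in_24h(self):
        bouts = self._bouts_with([(1000.0, 1120.0)], 24 * 3600)
        m = summarize_sleep(bouts)
        assert m.total_sleep_min == pytest.approx(2.0)
        assert m.sleep_bout_count == 1
        assert m.mean_bout_duration_s == pytest.approx(120.0)
        assert len(m.profile) == 24

    def test_bout_split_across_bins(self):
        # 90 s bout placed 30 s before an hourly boundary: 0.5 + 1.0 min
        bouts = self._bouts_with([(3600.0 - 30.0, 3600.0 + 60.0)], 3 * 3600)
        m = summarize_sleep(bouts)
        assert m.profile[0] == pytest.approx(0.5)
        assert m.profile[1] == pytest.approx(1.0)

    def test_profile_sums_to_total(self, rng):
        immob = np.cumsum(rng.random(int(6 * 3600 * FR)) < 0.002) % 2 == 0
        bouts = detect_bouts(immob, FR, ScoringParams())
        m = summarize_sleep(bouts, bin_minutes=45)
        assert m.profile.sum() == pytest.approx(m.total_sleep_min, abs=1e-6)

    def test_total_recomputed_from_interval_list(self, rng):
        immob = np.cumsum(rng.random(int(2 * 3600 * FR)) < 0.003) % 2 == 0
        bouts = detect_bouts(immob, FR, ScoringParams())
        m = summarize_sleep(bouts)
        oracle = sum(e - s for s, e in bouts.sleep_intervals) / 60.0
        assert m.total_sleep_min == pytest.approx(oracle, abs=1e-9)

    def test_midpoint_rule_at_window_edge(self):
        bouts = self._bouts_with([(3550.0, 3680.0)], 2 * 3600)  # midpoint 3615
        left = summarize_sleep(bouts, window=(0.0, 3600.0))
        right = summarize_sleep(bouts, window=(3600.0, 7200.0))
        assert left.sleep_bout_count == 0
        assert right.sleep_bout_count == 1
        assert left.total_sleep_min == pytest.approx(50 / 60)
        assert right.total_sleep_min == pytest.approx(80 / 60)

    def test_no_bouts_mean_is_nan(self):
        bouts = self._bouts_with([], 600)
        m = summarize_sleep(bouts)
        assert m.sleep_bout_count == 0
        assert np.isnan(m.mean_bout_duration_s)

    def test_waking_activity_excludes_sleep(self):
        n = int(300 * FR)
        speed = np.full(n, 10.0)
        immob = np.zeros(n, dtype=bool)
        immob[: int(120 * FR)] = True
        speed[: int(120 * FR)] = 0.0
        bouts = detect_bouts(immob, FR, ScoringParams(min_interrupt_s=0.0))
        m = summarize_sleep(bouts, speed=speed)
        assert m.waking_activity_mm_per_s == pytest.approx(10.0)


class TestScoreCohort:
    def _write_cohort(self, tmp_path, n_fish=2, bad_file=False):
        from finsomnia.simulate import preset, simulate_activity
        import pandas as pd

        rows = []
        for i in range(n_fish):
            traj, _ = simulate_activity(
                preset("cavefish", "control", duration_h=0.25),
                seed=i, subject_id=f"fish_{i}", population="cavefish")
            write_tracking(traj, tmp_path / f"fish_{i}.csv")
            rows.append({"file": f"fish_{i}.csv", "subject_id": f"fish_{i}",
                         "population": "cavefish", "treatment": "control",
                         "zt_start": 0.0, "calibration_mm_per_px": 1.0})
        if bad_file:
            rows.append({"file": "nope.csv", "subject_id": "ghost",
                         "population": "cavefish", "treatment": "control",
                         "zt_start": 0.0, "calibration_mm_per_px": 1.0})
        mpath = tmp_path / "manifest.csv"
        pd.DataFrame(rows).to_csv(mpath, index=False)
        return mpath

    def test_two_fish_two_rows(self, tmp_path):
        mpath = self._write_cohort(tmp_path, 2)
        metrics, failures = score_cohort(mpath, ScoringParams())
        assert sorted(metrics["subject_id"]) == ["fish_0", "fish_1"]
        assert failures.empty

    def test_unreadable_file_recorded_not_dropped(self, tmp_path):
        mpath = self._write_cohort(tmp_path, 2, bad_file=True)
        metrics, failures = score_cohort(mpath, ScoringParams())
        assert len(metrics) == 2
        assert len(failures) == 1
        assert failures.iloc[0]["subject_id"] == "ghost"

    def test_all_fail_raises(self, tmp_path):
        import pandas as pd

        rows = [{"file": "gone.csv", "subject_id": "x", "population": "surface",
                 "treatment": "control", "zt_start": 0, "calibration_mm_per_px": 1}]
        mpath = tmp_path / "m.csv"
        pd.DataFrame(rows).to_csv(mpath, index=False)
        with pytest.raises(PipelineError):
            score_cohort(mpath, ScoringParams())

    def test_file_order_invariance(self, tmp_path):
        import pandas as pd

        mpath = self._write_cohort(tmp_path, 3)
        metrics_a, _ = score_cohort(mpath, ScoringParams())
        df = pd.read_csv(mpath).iloc[::-1]
        mpath2 = tmp_path / "rev.csv"
        df.to_csv(mpath2, index=False)
        metrics_b, _ = score_cohort(mpath2, ScoringParams())
        pd.testing.assert_frame_equal(metrics_a, metrics_b)
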