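"""Centroid tracking, epoch displacement, bouts, and firing-bout coupling."""

import numpy as np
import pandas as pd
import pytest

from quasormod.behavior import (
    EpochSchedule,
    bout_coupling_stats,
    detect_bouts,
    epoch_displacement,
    track_centroids,
)
from quasormod.simulate.behavior import simulate_behavior_traces


def _path_length(traj):
    ok = traj[traj["valid"]]
    return np.hypot(np.diff(ok["x_mm"]), np.diff(ok["y_mm"])).sum()


class TestSchedule:
    def test_default_protocol(self):
        s = EpochSchedule.default()
        assert s.blocks[0] == ("acclimation", 0.0, 300.0)
        assert len([b for b in s.blocks if b[0] == "dark"]) == 2
        assert s.end_s == 300.0 + 4 * 900.0

    def test_gaps_rejected(self):
        with pytest.raises(ValueError):
            EpochSchedule([("dark", 0, 10), ("light", 20, 30)])
        with pytest.raises(ValueError):
            EpochSchedule([("disco", 0, 10)])


class TestTracking:
    def test_stationary_jitter_collapses(self):
        """Jitter < 1 mm merges away: post-merge path < 5% of raw."""
        rng = np.random.default_rng(0)
        det = pd.DataFrame({
            "x_mm": 10 + rng.uniform(-0.3, 0.3, 120),
            "y_mm": 10 + rng.uniform(-0.3, 0.3, 120),
        })
        traj = track_centroids(detections=det, frame_rate_hz=1.0)
        raw_path = np.hypot(np.diff(det["x_mm"]), np.diff(det["y_mm"])).sum()
        assert _path_length(traj) < 0.05 * raw_path

    def test_straight_run_unchanged(self):
        """At 1 mm/s the 2 s window spans 2 mm > 1 mm: merge never triggers."""
        det = pd.DataFrame({"x_mm": np.arange(60, dtype=float), "y_mm": 0.0})
        traj = track_centroids(detections=det, frame_rate_hz=1.0)
        assert len(traj) == 60
        assert _path_length(traj) == pytest.approx(59.0)

    def test_merge_never_increases_path_length(self):
        rng = np.random.default_rng(1)
        det = pd.DataFrame({
            "x_mm": np.cumsum(rng.normal(0, 0.4, 200)),
            "y_mm": np.cumsum(rng.normal(0, 0.4, 200)),
        })
        raw_path = np.hypot(np.diff(det["x_mm"]), np.diff(det["y_mm"])).sum()
        traj = track_centroids(detections=det)
        assert _path_length(traj) <= raw_path + 1e-9

    def test_empty_frames_invalid(self):
        frames = np.zeros((5, 8, 8))
        traj = track_centroids(frames=frames)
        assert (~traj["valid"]).all()

    def test_frame_centroid_weighted(self):
        frames = np.zeros((1, 10, 10))
        frames[0, 3, 7] = 2.0
        traj = track_centroids(frames=frames, mm_per_px=0.5)
        assert traj["x_mm"].iloc[0] == pytest.approx(3.5)
        assert traj["y_mm"].iloc[0] == pytest.approx(1.5)


class TestEpochDisplacement:
    def _schedule(self):
        return EpochSchedule([("acclimation", 0, 60), ("dark", 60, 960), ("light", 960, 1860)])

    def test_constant_speed_arithmetic(self):
        """0.2 mm/s over a 900 s epoch -> 180 mm of path."""
        t = np.arange(0, 1860, 1.0)
        traj = pd.DataFrame({"t_s": t, "x_mm": 0.2 * t, "y_mm": 0.0, "valid": True})
        epochs, _ = epoch_displacement(traj, self._schedule())
        dark = epochs[epochs["label"] == "dark"]["displacement_mm"].iloc[0]
        assert dark == pytest.approx(180.0, rel=0.01)

    def test_zero_speed_epoch(self):
        t = np.arange(0, 1860, 1.0)
        x = np.where(t < 960, 0.1 * t, 0.1 * 960)
        traj = pd.DataFrame({"t_s": t, "x_mm": x, "y_mm": 0.0, "valid": True})
        epochs, _ = epoch_displacement(traj, self._schedule())
        light = epochs[epochs["label"] == "light"]["displacement_mm"].iloc[0]
        assert light == pytest.approx(0.0, abs=1e-9)

    def test_displacement_rotation_invariant(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 1860, 1.0)
        xy = np.cumsum(rng.normal(0, 0.2, (len(t), 2)), axis=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = pd.DataFrame({"t_s": t, "x_mm": xy[:, 0], "y_mm": xy[:, 1], "valid": True})
        b_xy = xy @ R.T
        b = pd.DataFrame({"t_s": t, "x_mm": b_xy[:, 0], "y_mm": b_xy[:, 1], "valid": True})
        ea, _ = epoch_displacement(a, self._schedule())
        eb, _ = epoch_displacement(b, self._schedule())
        np.testing.assert_allclose(ea["displacement_mm"], eb["displacement_mm"], rtol=1e-9)

    def test_missing_epoch_reported_not_zeroed(self):
        t = np.arange(0, 900, 1.0)
        traj = pd.DataFrame({"t_s": t, "x_mm": t, "y_mm": 0.0, "valid": True})
        epochs, _ = epoch_displacement(traj, self._schedule())
        light = epochs[epochs["label"] == "light"]
        assert light["missing"].iloc[0]
        assert np.isnan(light["displacement_mm"].iloc[0])

    def test_two_speed_schedule_ratio(self):
        """Generator truth: dark 0.1 vs light 0.3 mm/s -> displacement ratio 3."""
        sched = EpochSchedule([("acclimation", 0, 60), ("dark", 60, 960), ("light", 960, 1860)])
        sim = simulate_behavior_traces(
            sched, speeds_mm_s={"acclimation": 0.1, "dark": 0.1, "light": 0.3},
            rng=3,
        )
        epochs, _ = epoch_displacement(sim.trajectory, sched)
        dark = epochs[epochs["label"] == "dark"]["displacement_mm"].iloc[0]
        light = epochs[epochs["label"] == "light"]["displacement_mm"].iloc[0]
        assert light / dark == pytest.approx(3.0, rel=0.1)


class TestBouts:
    def test_boxcar_detected_exactly(self):
        t = np.arange(0, 60, 0.05)
        y = np.random.default_rng(4).normal(0, 0.02, len(t))
        y[(t >= 20) & (t < 25)] += 1.0
        bouts = detect_bouts(t, y)
        assert len(bouts) == 1
        assert bouts["start_s"].iloc[0] == pytest.approx(20.0, abs=0.1)
        assert bouts["end_s"].iloc[0] == pytest.approx(25.0, abs=0.1)

    def test_close_boxcars_fuse(self):
        t = np.arange(0, 30, 0.05)
        y = np.random.default_rng(5).normal(0, 0.02, len(t))
        y[(t >= 10) & (t < 12)] += 1.0
        y[(t >= 12.3) & (t < 14)] += 1.0
        bouts = detect_bouts(t, y)
        assert len(bouts) == 1

    def test_flat_trace_no_bouts(self):
        t = np.arange(0, 10, 0.1)
        assert len(detect_bouts(t, np.ones_like(t))) == 0

    def test_threshold_monotone(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 120, 0.05)
        y = rng.normal(0, 0.1, len(t))
        for b0 in (10, 40, 70, 100):
            y[(t >= b0) & (t < b0 + 3)] += rng.uniform(0.3, 1.0)
        counts = [len(detect_bouts(t, y, mad_multiplier=c)) for c in (2, 3, 5, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_noise_only_false_bout_rate(self):
        """Null calibration: < 0.1 false bouts per noise-only trace."""
        total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 120, 0.05)
            y = rng.normal(0, 0.1, len(t))
            total += len(detect_bouts(t, y))
        assert total / 50 < 0.1


class TestCoupling:
    def test_no_spikes_zero_rates(self):
        bouts = pd.DataFrame({"start_s": [100.0], "end_s": [105.0]})
        rep = bout_coupling_stats([np.array([])], [bouts], 600.0)
        assert rep["before_rate_per_bin"][0] == 0.0
        assert rep["overall_rate_per_bin"][0] == 0.0

    def test_truncated_window_flagged(self):
        bouts = pd.DataFrame({"start_s": [3.0], "end_s": [8.0]})
        rep = bout_coupling_stats([np.array([1.0])], [bouts], 600.0)
        assert rep["n_truncated_windows"] == 1

    def test_poisson_null_not_significant(self):
        """Homogeneous Poisson firing: before ~ overall, paired test n.s."""
        rng = np.random.default_rng(7)
        spikes_list, bouts_list = [], []
        for _ in range(20):
            spikes = np.sort(rng.uniform(0, 600, rng.poisson(120)))
            starts = np.sort(rng.uniform(20, 580, 8))
            bouts_list.append(pd.DataFrame({"start_s": starts, "end_s": starts + 5}))
            spikes_list.append(spikes)
        rep = bout_coupling_stats(spikes_list, bouts_list, 600.0)
        assert rep["wilcoxon"]["p_value"] > 0.05

    def test_coupled_scenario_before_exceeds_overall(self):
        """Generator truth: bursts lead bouts by 4 s -> 'before' rate wins
        in >= 90% of recordings."""
        wins = 0
        n_rec = 20
        for seed in range(n_rec):
            sched = EpochSchedule([("dark", 0.0, 600.0)])
            sim = simulate_behavior_traces(sched, rng=seed)
            rep = bout_coupling_stats(
                [sim.typeii_spikes], [sim.ib_bouts], 600.0
            )
            if rep["before_rate_per_bin"][0] > rep["overall_rate_per_bin"][0]:
                wins += 1
        assert wins >= 0.9 * n_rec

    def test_coupling_type_i_error_calibrated(self):
        """Independent spikes and bouts: Wilcoxon rejects ~5% of replicate
        cohorts at alpha = 0.05 (0.05 ± 0.02 over 1000 cohorts)."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_cohorts = 1000
        for _ in range(n_cohorts):
            before, overall = [], []
            for _ in range(15):
                spikes = np.sort(rng.uniform(0, 600, 120))
                starts = np.sort(rng.uniform(10, 580, 8))
                w = 0
                for b0 in starts:
                    w += ((spikes >= b0 - 8) & (spikes < b0)).sum()
                before.append(w / (len(starts) * 8.0) * 0.05)
                overall.append(len(spikes) / 600.0 * 0.05)
            from quasormod.stats import run_tests

            p = run_tests([np.array(before), np.array(overall)], "wilcoxon_signed_rank")["p_value"]
            rejections += p < 0.05
        assert rejections / n_cohorts == pytest.approx(0.05, abs=0.02)


class TestBehaviorSimulator:
    def test_zero_speed_zero_displacement(self):
        sched = EpochSchedule([("dark", 0.0, 120.0)])
        sim = simulate_behavior_traces(sched, speeds_mm_s={"dark": 0.0}, rng=9)
        assert _path_length(sim.trajectory) == pytest.approx(0.0, abs=1e-12)

    def test_intraburst_isi_respects_20hz_cap(self):
        """Intraburst intervals never drop below 50 ms (20 Hz cap)."""
        sched = EpochSchedule([("dark", 0.0, 600.0)])
        sim = simulate_behavior_traces(sched, burst_rate_hz=20.0, tonic_rate_hz=0.0, rng=10)
        isis = np.diff(sim.typeii_spikes)
        # spikes here are all intraburst (tonic off) except across-burst gaps
        intra = isis[isis < 1.0]
        assert len(intra) > 10
        assert intra.min() >= 0.05 - 1e-12

    def test_pre_bout_rate_exceeds_overall_by_construction(self):
        """Direct counting: 8 s pre-bout windows hold elevated firing."""
        sched = EpochSchedule([("dark", 0.0, 600.0)])
        sim = simulate_behavior_traces(sched, burst_lead_s=4.0, rng=11)
        spikes = sim.typeii_spikes
        pre_count = sum(
            ((spikes >= b - 8) & (spikes < b)).sum() for b in sim.ib_bouts["start_s"]
        )
        pre_time = 8.0 * len(sim.ib_bouts)
        if pre_time > 0:
            assert pre_count / pre_time > len(spikes) / 600.0

    def test_bout_detection_recovers_simulated_bouts(self):
        sched = EpochSchedule([("dark", 0.0, 600.0)])
        sim = simulate_behavior_traces(sched, rng=12, ib_noise_sd=0.05)
        bouts = detect_bouts(sim.ib_trace["t_s"].to_numpy(), sim.ib_trace["dff"].to_numpy())
        assert len(bouts) == len(sim.ib_bouts)
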