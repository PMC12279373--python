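"""Body velocities, swing/stance labeling, rotation events, turn metrics."""

import numpy as np
import pandas as pd
import pytest

from steerlab import legs as L
from steerlab.core import TimeSeries
from steerlab.synthetic import GaitConfig, TurnBias, simulate_gait

from conftest import make_ts


def mirror_track(p: L.PoseTrack) -> L.PoseTrack:
    """Reflect the arena left-right (y -> -y), swapping R and L legs."""
    frames = {}
    for part in ("head", "abdomen"):
        frames[f"{part}_x"] = p.frames[f"{part}_x"]
        frames[f"{part}_y"] = -p.frames[f"{part}_y"]
    for leg in L.LEGS:
        other = ("L" if leg[0] == "R" else "R") + leg[1]
        frames[f"{leg}_x"] = p.frames[f"{other}_x"]
        frames[f"{leg}_y"] = -p.frames[f"{other}_y"]
    return L.PoseTrack(pd.DataFrame(frames), p.rate, p.t0)


class TestBodyVelocities:
    def test_pure_translation_along_axis(self):
        rate = 200.0
        n = 400
        t = np.arange(n) / rate
        frames = {"head_x": 1.25 + 5.0 * t, "head_y": np.zeros(n),
                  "abdomen_x": -1.25 + 5.0 * t, "abdomen_y": np.zeros(n)}
        for leg in L.LEGS:
            frames[f"{leg}_x"] = 5.0 * t
            frames[f"{leg}_y"] = np.ones(n)
        bv = L.body_velocities(L.PoseTrack(pd.DataFrame(frames), rate))
        assert np.allclose(bv.forward_mm_s, 5.0, atol=1e-6)
        assert np.allclose(bv.sideways_mm_s, 0.0, atol=1e-6)
        assert np.allclose(bv.rotational_deg_s, 0.0, atol=1e-6)
        assert bv.kept.all()

    def test_pure_rotation_discarded_for_low_forward(self):
        rate = 200.0
        n = 400
        theta = np.radians(30.0) * np.arange(n) / rate
        frames = {"head_x": 1.25 * np.cos(theta), "head_y": 1.25 * np.sin(theta),
                  "abdomen_x": -1.25 * np.cos(theta), "abdomen_y": -1.25 * np.sin(theta)}
        for leg in L.LEGS:
            frames[f"{leg}_x"] = np.zeros(n)
            frames[f"{leg}_y"] = np.ones(n)
        bv = L.body_velocities(L.PoseTrack(pd.DataFrame(frames), rate))
        assert np.allclose(bv.rotational_deg_s, 30.0, atol=0.5)
        assert not bv.kept.any()

    def test_scripted_curvature_recovered(self):
        track = simulate_gait(GaitConfig(n_strides=10, turn=TurnBias(rot_deg_s=25.0)))
        bv = L.body_velocities(track)
        assert np.allclose(bv.rotational_deg_s, 25.0, rtol=0.05)


class TestSwingStance:
    def test_stationary_leg_is_all_stance(self):
        track = simulate_gait(GaitConfig(n_strides=4))
        frames = track.frames.copy()
        frames["R1_x"] = 0.0
        frames["R1_y"] = -1.0
        ep = L.label_swing_stance(L.PoseTrack(frames, track.rate))
        assert ep["R1"]["stance_mask"].all()

    def test_square_wave_speed_epochs_match_edges(self):
        rate = 200.0
        n = 1200
        # leg alternates: still 100 frames, moving at 30 mm/s for 100 frames
        x = np.zeros(n)
        moving = (np.arange(n) // 100) % 2 == 1
        x = np.cumsum(np.where(moving, 30.0 / rate, 0.0))
        frames = {"head_x": np.full(n, 1.25), "head_y": np.zeros(n),
                  "abdomen_x": np.full(n, -1.25), "abdomen_y": np.zeros(n)}
        for leg in L.LEGS:
            frames[f"{leg}_x"] = x
            frames[f"{leg}_y"] = np.ones(n)
        ep = L.label_swing_stance(L.PoseTrack(pd.DataFrame(frames), rate))
        starts = [e.start for e in ep["R2"]["epochs"] if e.kind == "swing"]
        expected = [100 * k for k in range(1, 12, 2)]
        assert len(starts) == len(expected)
        assert all(abs(a - b) <= 1 for a, b in zip(starts, expected))

    def test_time_reversal_reverses_labels(self):
        track = simulate_gait(GaitConfig(n_strides=4, seed=1))
        ep = L.label_swing_stance(track)
        rev = L.PoseTrack(track.frames.iloc[::-1].reset_index(drop=True), track.rate)
        ep_rev = L.label_swing_stance(rev)
        for leg in L.LEGS:
            np.testing.assert_array_equal(ep_rev[leg]["stance_mask"],
                                          ep[leg]["stance_mask"][::-1])


class TestRotationEvents:
    def test_flat_trace_has_no_events(self):
        assert L.detect_rotation_events(make_ts(np.zeros(1000), rate=200.0)) == []

    def test_single_excursion_window_offsets(self):
        rate = 200.0
        v = np.zeros(2000)
        v[1000:1100] = 40.0  # 0.5 s above threshold
        evs = L.detect_rotation_events(TimeSeries(v, rate))
        assert len(evs) == 1
        start, stop, idx = evs[0]
        assert idx == 1000
        assert start == pytest.approx(1000 / rate - 0.1)
        assert stop == pytest.approx(start + 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        rate = 200.0
        v = np.clip(np.cumsum(rng.standard_normal(4000)) * 0.8, 0, None)
        evs = L.detect_rotation_events(TimeSeries(v, rate))
        # literal re-scan
        hold = int(round(0.1 * rate))
        expected = []
        above = v > 20.0
        for i in range(v.size):
            crossing = above[i] and (i == 0 or not above[i - 1])
            if not crossing or i + hold > v.size or not above[i:i + hold].all():
                continue
            start = i / rate - 0.1
            if start < 0 or start + 0.5 > v.size / rate:
                continue
            expected.append(i)
        assert [e[2] for e in evs] == expected


class TestTurnMetrics:
    def test_symmetric_gait_hits_null_values(self):
        track = simulate_gait(GaitConfig(n_strides=6))
        m = L.turn_metrics(track, L.label_swing_stance(track), "right")
        assert m.stance_direction_deg == pytest.approx(0.0, abs=2.0)
        assert m.swing_direction_deg == pytest.approx(0.0, abs=2.0)
        assert m.swing_distance_ratio == pytest.approx(1.0, abs=0.05)
        assert m.stance_duration_ratio == pytest.approx(1.0, abs=0.05)
        assert m.swing_duration_s == pytest.approx(0.2, abs=0.02)

    def test_prolonged_inner_back_stance_ratio(self):
        track = simulate_gait(GaitConfig(n_strides=6,
                                         turn=TurnBias(stance_prolong_ib=1.5)))
        m = L.turn_metrics(track, L.label_swing_stance(track), "right")
        assert m.stance_duration_ratio == pytest.approx(1.5, abs=0.05)

    def test_direction_and_distance_biases_recovered(self):
        turn = TurnBias(stance_dir_deg=20.0, swing_dir_deg=-10.0,
                        outer_swing_scale=1.3)
        track = simulate_gait(GaitConfig(n_strides=6, turn=turn))
        m = L.turn_metrics(track, L.label_swing_stance(track), "right")
        assert m.stance_direction_deg == pytest.approx(20.0, abs=2.0)
        assert m.swing_direction_deg == pytest.approx(-10.0, abs=2.0)
        assert m.swing_distance_ratio == pytest.approx(1.3, abs=0.05)

    def test_missing_epoch_omits_metric_with_reason(self):
        track = simulate_gait(GaitConfig(n_strides=6))
        ep = L.label_swing_stance(track)
        # strip all complete swing epochs from the oM leg (L2 for a right turn)
        ep["L2"]["epochs"] = [e for e in ep["L2"]["epochs"]
                              if not (e.kind == "swing" and e.complete)]
        m = L.turn_metrics(track, ep, "right")
        assert m.swing_distance_ratio is None
        assert "oM" in m.omitted["swing_distance_ratio"]
        # metrics not involving oM swings are unaffected
        assert m.stance_duration_ratio is not None

    def test_mirror_symmetry(self):
        turn = TurnBias(stance_dir_deg=15.0, swing_dir_deg=5.0,
                        outer_swing_scale=1.2, stance_prolong_ib=1.4)
        track = simulate_gait(GaitConfig(n_strides=6, turn=turn))
        m = L.turn_metrics(track, L.label_swing_stance(track), "right")
        mirrored = mirror_track(track)
        mm = L.turn_metrics(mirrored, L.label_swing_stance(mirrored), "left")
        assert mm.stance_direction_deg == pytest.approx(-m.stance_direction_deg, abs=1e-6)
        assert mm.swing_direction_deg == pytest.approx(-m.swing_direction_deg, abs=1e-6)
        assert mm.swing_distance_ratio == pytest.approx(m.swing_distance_ratio, abs=1e-9)
        assert mm.stance_duration_ratio == pytest.approx(m.stance_duration_ratio, abs=1e-9)
        assert mm.swing_duration_s == pytest.approx(m.swing_duration_s, abs=1e-9)


class TestWindowGaitStats:
    def test_scripted_stride_recovered(self):
        cfg = GaitConfig(n_strides=20, stride_hz=10.0, step_len_mm=2.0, rate=400.0)
        gs = L.window_gait_stats(simulate_gait(cfg))
        assert gs.step_frequency_hz.mean() == pytest.approx(10.0, rel=0.02)
        assert gs.step_length_mm.mean() == pytest.approx(2.0, rel=0.02)
        assert gs.forward_mm_s.mean() == pytest.approx(cfg.forward_mm_s, rel=0.02)

    def test_faster_playback_scales_frequency_only(self):
        base = GaitConfig(n_strides=20, stride_hz=5.0, step_len_mm=2.0, rate=400.0)
        fast = GaitConfig(n_strides=20, stride_hz=10.0, step_len_mm=2.0, rate=400.0)
        g1 = L.window_gait_stats(simulate_gait(base))
        g2 = L.window_gait_stats(simulate_gait(fast))
        assert g2.step_frequency_hz.mean() / g1.step_frequency_hz.mean() == pytest.approx(2.0, rel=0.05)
        assert g2.step_length_mm.mean() == pytest.approx(g1.step_length_mm.mean(), rel=0.05)

    def test_window_without_complete_stride_omitted(self):
        # one slow stride per second: 0.5 s windows can't hold a full stride
        cfg = GaitConfig(n_strides=4, stride_hz=1.0, step_len_mm=4.0, rate=200.0)
        gs = L.window_gait_stats(simulate_gait(cfg))
        assert len(gs) == 0
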