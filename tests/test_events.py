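"""Transitions, event-triggered averaging, binned maps, tuning curves."""

import numpy as np
import pytest

from steerlab import events as E
from steerlab.core import TimeSeries

from conftest import make_ts


def brute_force_transitions(v, rate, threshold=75.0, window_s=0.75, consistency=0.9):
    """Literal window-scanning re-implementation of the transition rules."""
    w = int(round(window_s * rate))
    found = []
    for i in range(1, v.size):
        if not (v[i - 1] <= threshold < v[i]) and not (v[i - 1] > threshold >= v[i]):
            continue
        if i - w < 0 or i + w > v.size:
            continue
        pre, post = v[i - w:i], v[i:i + w]
        if v[i] > threshold:  # upward
            if (np.mean(pre <= threshold / 2) >= consistency
                    and np.mean(post > threshold) >= consistency):
                found.append(("start", i))
        else:
            if (np.mean(pre > threshold) >= consistency
                    and np.mean(post <= threshold / 2) >= consistency):
                found.append(("stop", i))
    return found


def bout_train(seed, n=4000, rate=100.0):
    """Random alternation of rest (~0) and walking (~150 deg/s) with noise."""
    rng = np.random.default_rng(seed)
    v = np.zeros(n)
    i, level = 0, 0.0
    while i < n:
        dur = int(rng.uniform(0.3, 3.0) * rate)
        v[i:i + dur] = level
        level = 150.0 if level == 0.0 else 0.0
        i += dur
    return np.clip(v + rng.standard_normal(n) * rng.uniform(2, 40), 0, None)


class TestDetectTransitions:
    def test_constant_zero_has_no_events(self):
        assert E.detect_transitions(make_ts(np.zeros(1000))) == []

    def test_clean_step_yields_one_start_at_crossing(self):
        v = np.zeros(400)
        v[200:] = 150.0
        evs = E.detect_transitions(make_ts(v))
        assert len(evs) == 1
        assert evs[0].kind == "start"
        assert evs[0].index == 200

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        v = bout_train(seed)
        got = [(e.kind, e.index) for e in E.detect_transitions(make_ts(v))]
        assert got == brute_force_transitions(v, 100.0)

    def test_translation_equivariance(self):
        v = bout_train(99)
        base = [(e.kind, e.index) for e in E.detect_transitions(make_ts(v))]
        pad = 250
        shifted = np.concatenate([np.zeros(pad), v])
        got = [(e.kind, e.index - pad) for e in E.detect_transitions(make_ts(shifted))]
        # events whose windows now fit (or no longer fit) at the edges may differ;
        # compare the common interior
        interior = [ev for ev in base if ev[1] > 100]
        assert [ev for ev in got if ev[1] > 100] == interior

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            E.detect_transitions(make_ts(np.zeros(50)))


class TestAlignAndAverage:
    def test_identical_experiments_average_to_signal_with_zero_sem(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        sigs = [make_ts(x.copy()) for _ in range(4)]
        times = [np.array([5.0, 12.0])] * 4
        out = E.align_and_average(sigs, times, (-0.5, 0.5))
        np.testing.assert_allclose(out.sem, 0.0, atol=1e-12)
        i = int(5.0 * 100) + int(-0.5 * 100)
        np.testing.assert_allclose(out.per_experiment[0],
                                   0.5 * (x[i:i + 100] + x[i + 700:i + 800]))

    def test_template_recovered_from_noisy_events(self):
        rng = np.random.default_rng(1)
        rate = 100.0
        template = np.exp(-0.5 * ((np.arange(100) - 50) / 10.0) ** 2)
        sigs, times = [], []
        for _ in range(6):
            x = rng.standard_normal(6000) * 0.3
            ev = []
            for t0 in (10.0, 25.0, 40.0):
                i = int(t0 * rate) - 50
                x[i:i + 100] += template
                ev.append(t0)
            sigs.append(make_ts(x))
            times.append(np.array(ev))
        out = E.align_and_average(sigs, times, (-0.5, 0.5))
        err = np.max(np.abs(out.mean - template))
        assert err < 4 * 0.3 / np.sqrt(18)

    def test_single_experiment_flags_sem(self):
        out = E.align_and_average([make_ts(np.zeros(1000))], [np.array([5.0])],
                                  (-0.1, 0.1))
        assert out.sem is None


class TestBinnedMap:
    def test_constant_behavior_fills_unmasked_bins(self):
        rng = np.random.default_rng(2)
        a = make_ts(rng.uniform(0, 50, 60_000))
        b = make_ts(rng.uniform(0, 50, 60_000))
        beh = make_ts(np.full(60_000, 3.3))
        m = E.binned_behavior_map(a, b, beh, min_count=5)
        vals = m.mean[~np.isnan(m.mean)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, 3.3)

    def test_difference_signal_maps_to_bin_center_difference(self):
        rng = np.random.default_rng(3)
        rate = 100.0
        n = 120_000
        a_raw = rng.uniform(0, 60, n // 5).repeat(5)  # constant per 50 ms window
        b_raw = rng.uniform(0, 60, n // 5).repeat(5)
        shift = int(0.150 * rate)
        beh = np.zeros(n)
        beh[shift:] = (a_raw - b_raw)[:-shift]
        m = E.binned_behavior_map(make_ts(a_raw), make_ts(b_raw), make_ts(beh),
                                  bin_width=10.0, min_count=3)
        ca = 0.5 * (m.edges_a[:-1] + m.edges_a[1:])
        cb = 0.5 * (m.edges_b[:-1] + m.edges_b[1:])
        for i in range(ca.size):
            for j in range(cb.size):
                if not np.isnan(m.mean[i, j]):
                    assert abs(m.mean[i, j] - (ca[i] - cb[j])) <= 10.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_rebinning(self, seed):
        rng = np.random.default_rng(seed)
        n = 5000
        a = make_ts(rng.uniform(0, 40, n))
        b = make_ts(rng.uniform(0, 40, n))
        beh = make_ts(rng.standard_normal(n) * 30)
        m = E.binned_behavior_map(a, b, beh, bin_width=10.0, min_count=1)
        # literal recomputation
        shift = 15
        w = 5
        av = E.window_means(E.shift_forward(a.values, shift), w)
        bv = E.window_means(E.shift_forward(b.values, shift), w)
        ev = E.window_means(beh.values, w)
        ok = np.isfinite(av)
        av, bv, ev = av[ok], bv[ok], ev[ok]
        for i in range(m.edges_a.size - 1):
            for j in range(m.edges_b.size - 1):
                lo_a, hi_a = m.edges_a[i], m.edges_a[i + 1]
                lo_b, hi_b = m.edges_b[j], m.edges_b[j + 1]
                last_a = i == m.edges_a.size - 2
                last_b = j == m.edges_b.size - 2
                sel = ((av >= lo_a) & ((av <= hi_a) if last_a else (av < hi_a))
                       & (bv >= lo_b) & ((bv <= hi_b) if last_b else (bv < hi_b)))
                assert m.count[i, j] == sel.sum()
                if sel.any():
                    assert np.isclose(m.mean[i, j], ev[sel].mean(), equal_nan=True)

    def test_count_weighted_bin_means_reconstruct_global_mean(self):
        rng = np.random.default_rng(7)
        n = 20_000
        a = make_ts(rng.uniform(0, 40, n))
        b = make_ts(rng.uniform(0, 40, n))
        beh = make_ts(rng.standard_normal(n) * 30)
        m = E.binned_behavior_map(a, b, beh, bin_width=10.0, min_count=1)
        shift, w = 15, 5
        ev = E.window_means(beh.values, w)
        av = E.window_means(E.shift_forward(a.values, shift), w)
        used = np.isfinite(av)
        total = np.nansum(m.mean * m.count)
        assert total / m.count.sum() == pytest.approx(ev[used].mean())


class TestRLDifferenceTuning:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        rate = 100.0
        n = 60_000
        left = rng.uniform(0, 60, n // 5).repeat(5)
        right = rng.uniform(0, 60, n // 5).repeat(5)
        shift = int(0.150 * rate)
        vr = np.zeros(n)
        vr[shift:] = 2.0 * (left - right)[:-shift]
        out = E.rl_difference_tuning(make_ts(left), make_ts(right), make_ts(vr))
        assert out.slope == pytest.approx(2.0, abs=1e-9)
        assert out.intercept == pytest.approx(0.0, abs=1e-6)

    def test_independent_rotation_slope_ci_covers_zero(self):
        rng = np.random.default_rng(5)
        n = 60_000
        left = make_ts(rng.uniform(0, 60, n))
        right = make_ts(rng.uniform(0, 60, n))
        vr = make_ts(rng.standard_normal(n) * 50)
        out = E.rl_difference_tuning(left, right, vr)
        assert abs(out.slope) < 2.5 * out.slope_stderr

    def test_seesaw_simulation_gives_monotone_curve(self, quiet_session):
        sess = quiet_session
        out = E.rl_difference_tuning(sess.true_rate["mono_L"], sess.true_rate["mono_R"],
                                     sess.kinematics.v_r, bin_width=5.0)
        good = out.bin_counts >= 200
        curve = out.bin_means[good]
        # monotone non-increasing trend: left-minus-right drive turns leftward
        diffs = np.diff(curve)
        assert (diffs <= 0).mean() >= 0.8
        assert out.slope < 0


def test_rate_lead_lag_recovers_known_shift():
    rng = np.random.default_rng(6)
    x = np.convolve(rng.standard_normal(4000), np.ones(20) / 20, mode="same")
    shifted = np.roll(x, 25)
    assert E.rate_lead_lag(x, shifted, 100.0) == pytest.approx(0.25, abs=0.01)
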