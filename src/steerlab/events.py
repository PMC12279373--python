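"""Event-triggered analyses.

Covers movement/immobility transition detection on total speed,
event-aligned averaging with two-level (within- then across-experiment)
statistics, 2-D binned behavior maps over two neural channels, and
right-left firing-rate-difference tuning of rotational velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TimeSeries

TRANSITION_THRESHOLD = 75.0   # deg/s on total speed
TRANSITION_WINDOW_S = 0.75
TRANSITION_CONSISTENCY = 0.90
NEURAL_SHIFT_S = 0.150        # behavior lags the neurons by ~150 ms
MAP_WINDOW_S = 0.050


@dataclass
class TransitionEvent:
    """A movement start or stop detected on the total-speed trace."""

    kind: str        # "start" | "stop"
    time: float      # threshold-crossing time, seconds
    index: int       # crossing sample index


def detect_transitions(total_speed: TimeSeries, threshold: float = TRANSITION_THRESHOLD,
                       window_s: float = TRANSITION_WINDOW_S,
                       consistency: float = TRANSITION_CONSISTENCY) -> list[TransitionEvent]:
    """Detect consistent movement starts and stops by threshold crossing.

    A *start* is an upward crossing of ``threshold`` where at least
    ``consistency`` of the samples in the ``window_s`` before the crossing
    are <= threshold/2 and at least ``consistency`` of the samples after
    are > threshold.  A *stop* is a downward crossing where the pre-window
    is consistently > threshold and the post-window consistently
    <= threshold/2.  Windows extending past the trace are discarded.
    """
    v = total_speed.values
    if v.size < int(2 * window_s * total_speed.rate):
        raise ValueError("trace shorter than twice the consistency window")
    w = int(round(window_s * total_speed.rate))
    above = v > threshold
    events: list[TransitionEvent] = []
    crossings_up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    crossings_down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    for i in crossings_up:
        if i - w < 0 or i + w > v.size:
            continue
        pre, post = v[i - w:i], v[i:i + w]
        if (np.mean(pre <= threshold / 2) >= consistency
                and np.mean(post > threshold) >= consistency):
            events.append(TransitionEvent("start", total_speed.t0 + i / total_speed.rate, i))
    for i in crossings_down:
        if i - w < 0 or i + w > v.size:
            continue
        pre, post = v[i - w:i], v[i:i + w]
        if (np.mean(pre > threshold) >= consistency
                and np.mean(post <= threshold / 2) >= consistency):
            events.append(TransitionEvent("stop", total_speed.t0 + i / total_speed.rate, i))
    events.sort(key=lambda e: e.time)
    return events


@dataclass
class AlignedAverage:
    """Two-level event-triggered average: within experiments, then across."""

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray | None     # None when only one experiment contributed
    per_experiment: np.ndarray  # (n_experiments, n_lags)
    n_events: list[int]


def align_and_average(signals: list[TimeSeries], event_times: list[np.ndarray],
                      span_s: tuple[float, float]) -> AlignedAverage:
    """Average signal snippets around events, within then across experiments.

    ``signals[k]`` and ``event_times[k]`` belong to experiment k.  Events
    whose window would extend past the signal are skipped.  The SEM is
    computed across experiment means; with a single experiment it is
    flagged None rather than raising.
    """
    if len(signals) != len(event_times):
        raise ValueError("one event list per signal required")
    rate = signals[0].rate
    lo = int(round(span_s[0] * rate))
    hi = int(round(span_s[1] * rate))
    lags = np.arange(lo, hi) / rate
    per_exp = []
    n_events = []
    for sig, times in zip(signals, event_times):
        snips = []
        for t in np.atleast_1d(times):
            i = int(round((t - sig.t0) * rate))
            if i + lo < 0 or i + hi > sig.n:
                continue
            snips.append(sig.values[i + lo:i + hi])
        n_events.append(len(snips))
        if snips:
            per_exp.append(np.mean(snips, axis=0))
    if not per_exp:
        raise ValueError("no event window fits inside any signal")
    per_exp = np.asarray(per_exp)
    mean = per_exp.mean(axis=0)
    sem = (per_exp.std(axis=0, ddof=1) / np.sqrt(per_exp.shape[0])
           if per_exp.shape[0] > 1 else None)
    return AlignedAverage(lags=lags, mean=mean, sem=sem,
                          per_experiment=per_exp, n_events=n_events)


def rate_lead_lag(mean_a: np.ndarray, mean_b: np.ndarray, rate: float) -> float:
    """Lag (s) at which trace a best leads trace b (cross-correlation peak).

    Positive values mean a leads b.
    """
    a = mean_a - mean_a.mean()
    b = mean_b - mean_b.mean()
    cc = np.correlate(b, a, mode="full")
    shift = int(np.argmax(cc)) - (a.size - 1)
    return shift / rate


def window_means(x: np.ndarray, w: int) -> np.ndarray:
    """Means over non-overlapping windows of w samples (tail remainder dropped)."""
    n = (x.size // w) * w
    return x[:n].reshape(-1, w).mean(axis=1)


def shift_forward(x: np.ndarray, shift_samples: int) -> np.ndarray:
    """Shift a neural trace forward in time (delay it) by whole samples."""
    if shift_samples == 0:
        return x.copy()
    out = np.full_like(x, np.nan)
    out[shift_samples:] = x[:-shift_samples]
    return out


@dataclass
class BinnedMap:
    """Behavior binned on a 2-D grid of two neural channels."""

    edges_a: np.ndarray
    edges_b: np.ndarray
    mean: np.ndarray     # (n_bins_a, n_bins_b), NaN where masked
    count: np.ndarray
    min_count: int

    @property
    def mask(self) -> np.ndarray:
        return self.count < self.min_count


def binned_behavior_map(rate_a: TimeSeries, rate_b: TimeSeries, behavior: TimeSeries,
                        shift_s: float = NEURAL_SHIFT_S, window_s: float = MAP_WINDOW_S,
                        bin_width: float = 10.0, min_count: int = 20) -> BinnedMap:
    """Bin behavior on the joint values of two neural channels.

    Neural traces are shifted forward by ``shift_s`` (at 100 Hz and 150 ms
    this is exactly 15 samples, no interpolation), all three series are
    reduced to non-overlapping ``window_s`` means, and window behavior
    means are accumulated on the 2-D grid of (rate_a, rate_b) window
    means.  Bins with fewer than ``min_count`` windows are masked (NaN).
    """
    if not (rate_a.rate == rate_b.rate == behavior.rate):
        raise ValueError("all series must share one rate")
    rate = behavior.rate
    shift = int(round(shift_s * rate))
    w = max(1, int(round(window_s * rate)))
    a = window_means(shift_forward(rate_a.values, shift), w)
    b = window_means(shift_forward(rate_b.values, shift), w)
    beh = window_means(behavior.values, w)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(beh)
    a, b, beh = a[ok], b[ok], beh[ok]
    edges_a = _grid_edges(a, bin_width)
    edges_b = _grid_edges(b, bin_width)
    res_mean = stats.binned_statistic_2d(a, b, beh, statistic="mean",
                                         bins=[edges_a, edges_b])
    res_cnt = stats.binned_statistic_2d(a, b, beh, statistic="count",
                                        bins=[edges_a, edges_b])
    count = res_cnt.statistic.astype(int)
    mean = np.where(count >= min_count, res_mean.statistic, np.nan)
    return BinnedMap(edges_a=edges_a, edges_b=edges_b, mean=mean,
                     count=count, min_count=min_count)


def _grid_edges(x: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(x.min() / width) * width
    hi = np.ceil(x.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


@dataclass
class DifferenceTuning:
    """Rotational velocity as a function of the right-left rate difference."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    slope: float          # OLS on unbinned pairs, deg/s per (spike/s)
    intercept: float
    slope_stderr: float


def rl_difference_tuning(rate_left: TimeSeries, rate_right: TimeSeries, v_r: TimeSeries,
                         shift_s: float = NEURAL_SHIFT_S, window_s: float = MAP_WINDOW_S,
                         bin_width: float = 10.0) -> DifferenceTuning:
    """Tuning of rotational velocity to the bilateral rate difference.

    The difference (left - right) is computed on window means after the
    forward shift; the binned curve shows the mean v_r per difference bin
    and the slope/intercept come from an OLS fit (with intercept) on the
    unbinned window pairs.
    """
    rate = v_r.rate
    shift = int(round(shift_s * rate))
    w = max(1, int(round(window_s * rate)))
    dl = window_means(shift_forward(rate_left.values, shift), w)
    dr = window_means(shift_forward(rate_right.values, shift), w)
    vr = window_means(v_r.values, w)
    ok = np.isfinite(dl) & np.isfinite(dr) & np.isfinite(vr)
    diff, vr = (dl - dr)[ok], vr[ok]
    edges = _grid_edges(diff, bin_width)
    means = stats.binned_statistic(diff, vr, statistic="mean", bins=edges).statistic
    counts = stats.binned_statistic(diff, vr, statistic="count", bins=edges).statistic
    res = stats.linregress(diff, vr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DifferenceTuning(bin_centers=centers, bin_means=means,
                            bin_counts=counts.astype(int), slope=float(res.slope),
                            intercept=float(res.intercept),
                            slope_stderr=float(res.stderr))
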