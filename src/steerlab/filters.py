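"""Linear (Wiener) filter estimation between firing rate and behavior.

The filter from an input signal to an output signal is estimated in the
frequency domain as the ratio of the averaged cross-spectrum to the
averaged input power spectrum,

    F(w) = < input*(w) . output(w) > / < input*(w) . input(w) >,

averaged over overlapping 4 s windows, then inverse-transformed to a
two-sided lag-domain filter and low-pass smoothed with a 0th-order Slepian
(DPSS) taper.  Behavior->neuron filters use a 6 Hz taper bandwidth,
neuron->behavior filters 15 Hz.

Filters are estimated on the first 20% of a session and predictions are
scored (R^2 against the observed trace) on the remaining 80%, with the
filter length used for prediction optimized on a grid between 100 ms and
4 s.  Filter sign convention: positive lag means the output follows the
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .core import TimeSeries

FILTER_LENGTH_BOUNDS_S = (0.1, 4.0)
BANDWIDTH_N2B_HZ = 15.0  # neuron -> behavior Slepian half-bandwidth
BANDWIDTH_B2N_HZ = 6.0   # behavior -> neuron Slepian half-bandwidth


@dataclass
class LinearFilter:
    """Two-sided lag-domain filter from an input channel to an output channel."""

    lags: np.ndarray          # seconds, symmetric about 0
    values: np.ndarray        # gain, out-units per in-unit per sample
    rate: float
    direction: str = "neuron->behavior"
    bandwidth_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("filter values must be finite")

    def truncated(self, length_s: float) -> "LinearFilter":
        """Filter restricted to |lag| <= length_s / 2."""
        keep = np.abs(self.lags) <= length_s / 2.0 + 1e-12
        return LinearFilter(self.lags[keep], self.values[keep], self.rate,
                            self.direction, self.bandwidth_hz, dict(self.meta))


@dataclass
class PredictionReport:
    """Outcome of behavior prediction from a filter."""

    r2: float
    filter_length_used_s: float
    train_fraction: float = 0.2
    test_fraction: float = 0.8
    candidate_r2: dict = field(default_factory=dict)


def slepian_taper(rate: float, bandwidth_hz: float) -> np.ndarray:
    """Unit-sum 0th-order DPSS taper with the given half-bandwidth (Hz).

    Taper length is rate / bandwidth samples; the time-half-bandwidth
    product is then NW = 1.
    """
    m = max(3, int(round(rate / bandwidth_hz)))
    w = signal.windows.dpss(m, NW=1.0)
    return w / w.sum()


def estimate_filter(input_ts: TimeSeries, output_ts: TimeSeries, window_s: float = 4.0,
                    hop: int | None = None, bandwidth_hz: float | None = BANDWIDTH_N2B_HZ,
                    direction: str = "neuron->behavior", demean: bool = True,
                    ridge_scale: float = 1e-6, segment_taper: str = "hann",
                    debias_lags: bool = True, debias_floor: float = 0.5) -> LinearFilter:
    """Estimate the lag-domain linear filter from input to output.

    Cross- and input power spectra are averaged over ``window_s`` windows
    advanced by ``hop`` samples (default window/4; ``hop=1`` gives the
    maximally overlapped exact mode, statistically equivalent but slow).
    Each segment is multiplied by a Hann taper before the FFT (standard
    Welch practice: locomotor signals have red spectra and untapered
    segments leak low-frequency power across bins, biasing the
    deconvolution; ``segment_taper="boxcar"`` disables this).  A ridge of
    ``ridge_scale`` x max input power regularizes the division; its
    activation is noted in the metadata.  The result is smoothed with a
    unit-sum 0th-order Slepian taper of half-bandwidth ``bandwidth_hz``
    (``None`` skips the final smoothing).

    Finite windows shrink the lag-domain filter at lag tau by the segment
    taper's normalized autocorrelation rho(tau) (the triangle 1 - |tau|/T
    for a boxcar); with ``debias_lags`` the filter is divided by
    max(rho, ``debias_floor``) to undo this, so kernel amplitudes are
    unbiased for supports short relative to the window.
    """
    if input_ts.rate != output_ts.rate:
        raise ValueError("input and output must share one sampling rate")
    x, y = input_ts.values, output_ts.values
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    if demean:
        x = x - x.mean()
        y = y - y.mean()
    rate = input_ts.rate
    nwin = int(round(window_s * rate))
    if nwin > n:
        raise ValueError("window longer than the signal span")
    hop = max(1, nwin // 4) if hop is None else int(hop)
    if segment_taper == "hann":
        seg_w = np.hanning(nwin)
    elif segment_taper == "boxcar":
        seg_w = np.ones(nwin)
    else:
        raise ValueError(f"unknown segment taper {segment_taper!r}")

    cross = np.zeros(nwin, dtype=complex)
    power = np.zeros(nwin)
    count = 0
    for start in range(0, n - nwin + 1, hop):
        fx = np.fft.fft(seg_w * x[start:start + nwin])
        fy = np.fft.fft(seg_w * y[start:start + nwin])
        cross += np.conj(fx) * fy
        power += (np.conj(fx) * fx).real
        count += 1
    cross /= count
    power /= count
    eps = ridge_scale * power.max()
    if eps <= 0:
        raise ValueError("input has no power; cannot estimate a filter")
    ridge_active = bool(np.any(power < eps))
    f_freq = cross / (power + eps)
    f_lag = np.fft.fftshift(np.fft.ifft(f_freq).real)
    lags = (np.arange(nwin) - nwin // 2) / rate
    if debias_lags:
        rho_full = np.correlate(seg_w, seg_w, "full") / np.dot(seg_w, seg_w)
        rho = rho_full[nwin - 1 - nwin // 2: nwin - 1 - nwin // 2 + nwin]
        f_lag = f_lag / np.maximum(rho, debias_floor)

    if bandwidth_hz is None:
        f_smooth = f_lag
    else:
        taper = slepian_taper(rate, bandwidth_hz)
        f_smooth = np.convolve(f_lag, taper, mode="same")
    return LinearFilter(lags, f_smooth, rate, direction, bandwidth_hz,
                        meta={"window_s": window_s, "hop": hop, "n_windows": count,
                              "segment_taper": segment_taper,
                              "ridge_eps": eps, "ridge_active": ridge_active})


def apply_filter(filt: LinearFilter, input_ts: TimeSeries) -> TimeSeries:
    """Convolve an input with a two-sided filter (discrete per-sample gains)."""
    x = input_ts.values
    vals = filt.values
    zero_idx = int(np.argmin(np.abs(filt.lags)))
    full = np.convolve(x, vals, mode="full")
    # align so lag 0 of the filter maps sample t of input to sample t of output
    out = full[zero_idx:zero_idx + x.size]
    return input_ts.with_values(out)


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """R^2 of the OLS regression (with intercept) of observed on predicted."""
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return 0.0
    res = stats.linregress(predicted, observed)
    return float(res.rvalue ** 2)


def predict_behavior(filt: LinearFilter, input_ts: TimeSeries, observed: TimeSeries,
                     length_bounds_s: tuple[float, float] = FILTER_LENGTH_BOUNDS_S,
                     length_grid_s: float = 0.1, eval_fraction: float = 0.8,
                     active_mask: np.ndarray | None = None) -> tuple[TimeSeries, PredictionReport]:
    """Predict behavior from an input signal; choose the best filter length.

    The filter is truncated to candidate (two-sided) lengths on a fixed
    grid within ``length_bounds_s``; for each candidate the prediction is
    convolved and scored by R^2 against the observed trace over the final
    ``eval_fraction`` of the session.  Samples where ``active_mask`` is
    False are excluded from scoring when a mask is given.
    """
    n = min(input_ts.n, observed.n)
    i0 = int(round((1.0 - eval_fraction) * n))
    lo, hi = length_bounds_s
    candidates = np.arange(lo, hi + 1e-9, length_grid_s)
    best = (-np.inf, lo, None)
    scores: dict[float, float] = {}
    for length in candidates:
        pred = apply_filter(filt.truncated(length), input_ts)
        p = pred.values[i0:n]
        o = observed.values[i0:n]
        if active_mask is not None:
            m = active_mask[i0:n]
            p, o = p[m], o[m]
        r2 = r_squared(p, o)
        scores[round(float(length), 3)] = r2
        if r2 > best[0]:
            best = (r2, float(length), pred)
    r2_best, length_best, pred_best = best
    report = PredictionReport(r2=r2_best, filter_length_used_s=length_best,
                              train_fraction=1.0 - eval_fraction,
                              test_fraction=eval_fraction, candidate_r2=scores)
    return pred_best, report


def dual_prediction(pred_left: TimeSeries, pred_right: TimeSeries,
                    active_mask: np.ndarray | None = None) -> TimeSeries:
    """Two-cell prediction: equal-weight sum of both single-cell predictions.

    If an activity mask is given, inactive samples are set to NaN so they
    drop out of downstream regressions.
    """
    if pred_left.n != pred_right.n:
        raise ValueError("predictions must share one time base")
    s = pred_left.values + pred_right.values
    if active_mask is not None:
        s = np.where(active_mask, s, np.nan)
    return pred_left.with_values(s)


def autocorrelation(x: TimeSeries, max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Biased normalized autocorrelation, exactly 1 at lag 0.

    Returns (lags in seconds from 0 to max_lag_s, values).
    """
    v = x.values - x.values.mean()
    n = v.size
    denom = float(np.dot(v, v))
    if denom == 0:
        raise ValueError("zero-variance input")
    nlag = min(n - 1, int(round(max_lag_s * x.rate)))
    full = signal.correlate(v, v, mode="full")
    acf = full[n - 1:n + nlag] / denom
    lags = np.arange(nlag + 1) / x.rate
    return lags, acf
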