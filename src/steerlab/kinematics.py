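"""Spherical-treadmill kinematics preprocessing.

The raw treadmill channels (rotational, sideways, forward velocity) carry
small sensor offsets and high-frequency noise.  The preprocessing chain is:

1. :func:`correct_offset` — remove the zero-point offset, estimated as the
   median over inactive samples (successive difference < 0.025 deg/s).
2. :func:`smooth_gaussian` — light smoothing with a 50 ms Gaussian kernel
   bounded at +/-3.5 sigma and renormalized to unit sum.
3. :func:`smooth_random_walk_map` — MAP smoothing under a Gaussian
   random-walk (local-level with drift) model, removing residual noise
   while preserving large excursions.

:func:`total_speed` gives the scalar activity index |v_r|+|v_s|+|v_f| and
:func:`classify_inactivity` the histogram-based movement/rest mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import KinematicsTrace, TimeSeries

OFFSET_DIFF_THRESHOLD = 0.025  # deg/s, successive-difference rule for rest


def bounded_gaussian_kernel(sigma_samples: float, bound_sigma: float = 3.5) -> np.ndarray:
    """Gaussian kernel truncated at +/-``bound_sigma`` and renormalized to unit sum."""
    if sigma_samples <= 0:
        raise ValueError("sigma must be positive")
    half = max(1, int(np.ceil(bound_sigma * sigma_samples)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_samples) ** 2)
    return k / k.sum()


def convolve_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length convolution with reflect padding at the edges."""
    half = len(kernel) // 2
    if half == 0:
        return x * kernel.sum()
    pad = min(half, len(x) - 1)
    xp = np.pad(x, half, mode="reflect") if pad == half else np.pad(x, half, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def correct_offset(x: TimeSeries, diff_threshold: float = OFFSET_DIFF_THRESHOLD) -> TimeSeries:
    """Subtract the zero-point offset estimated over inactive samples.

    Inactive samples are those whose absolute successive difference
    |x[i] - x[i-1]| is below ``diff_threshold`` (default 0.025 deg/s); the
    offset is the median of the signal over that index set and is removed
    globally.  If no sample qualifies the input is returned unchanged with
    ``meta["offset_warning"]`` set.
    """
    v = x.values
    if v.size < 2:
        raise ValueError("need at least 2 samples to estimate an offset")
    if np.all(np.isnan(v)):
        raise ValueError("all-NaN input")
    inactive = np.zeros(v.size, dtype=bool)
    inactive[1:] = np.abs(np.diff(v)) < diff_threshold
    if not inactive.any():
        out = x.copy()
        out.meta["offset_warning"] = "no inactive samples; offset not corrected"
        out.meta["offset"] = 0.0
        return out
    offset = float(np.median(v[inactive]))
    out = x.with_values(v - offset, offset=offset)
    return out


def smooth_gaussian(x: TimeSeries, width_s: float = 0.050, bound_sigma: float = 3.5) -> TimeSeries:
    """Smooth with a Gaussian kernel of full width ``width_s`` (FWHM).

    The kernel is truncated at +/-``bound_sigma`` standard deviations and
    renormalized to unit sum, so constants pass through exactly.  Edges are
    reflect-padded; output length equals input length.
    """
    sigma_samples = width_s * x.rate / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if width_s * x.rate <= 2:
        raise ValueError("kernel width must exceed 2 samples at this rate")
    k = bounded_gaussian_kernel(sigma_samples, bound_sigma)
    return x.with_values(convolve_reflect(x.values, k), gaussian_width_s=width_s)


@dataclass
class RandomWalkSmootherParams:
    """Parameters of the Gaussian random-walk (local-level + drift) smoother.

    The generative model for observations y and latent path z is

        z_i ~ Normal(z_{i-1} + mu, (1 - alpha) * sigma2)
        y_i ~ Normal(z_i,          alpha * sigma2)

    ``alpha`` splits the signal variance between observation noise
    (fraction alpha) and the random walk (fraction 1 - alpha); the study
    convention is alpha = 0.2.  ``mu`` (per-step drift) and ``sigma2`` are
    estimated from the data when left as None.
    """

    alpha: float = 0.2
    mu: float | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")


def _kalman_map_path(y: np.ndarray, alpha: float, mu: float, sigma2: float,
                     prior_var_scale: float = 1e6) -> np.ndarray:
    """MAP latent path of the local-level model via Kalman + RTS smoothing.

    The model is linear-Gaussian, so the MAP path equals the posterior
    mean, computed exactly by a forward Kalman filter and a backward
    Rauch-Tung-Striebel pass.  The first latent state has a diffuse prior
    z_1 ~ Normal(y_1, prior_var_scale * sigma2).
    """
    q = (1.0 - alpha) * sigma2  # state innovation variance
    r = alpha * sigma2          # observation noise variance
    n = y.size
    m_f = np.empty(n)  # filtered means
    p_f = np.empty(n)  # filtered variances
    m_p = np.empty(n)  # one-step predicted means
    p_p = np.empty(n)  # predicted variances

    m_p[0] = y[0]
    p_p[0] = prior_var_scale * sigma2
    for i in range(n):
        if i > 0:
            m_p[i] = m_f[i - 1] + mu
            p_p[i] = p_f[i - 1] + q
        k = p_p[i] / (p_p[i] + r)
        m_f[i] = m_p[i] + k * (y[i] - m_p[i])
        p_f[i] = (1.0 - k) * p_p[i]

    z = np.empty(n)
    z[-1] = m_f[-1]
    for i in range(n - 2, -1, -1):
        g = p_f[i] / p_p[i + 1]
        z[i] = m_f[i] + g * (z[i + 1] - (m_f[i] + mu))
    return z


def smooth_random_walk_map(x: TimeSeries,
                           params: RandomWalkSmootherParams | None = None) -> TimeSeries:
    """MAP estimate of the latent path under the random-walk model.

    Because the model is linear-Gaussian the MAP path coincides with the
    posterior mean and is computed in closed form by forward-backward
    (Kalman/RTS) smoothing; no iterative optimizer is needed.  The drift
    ``mu`` defaults to the mean first difference of the input (the MLE for
    this model) and ``sigma2`` to a moment-matching estimate from the
    first-difference variance, var(diff y) = (1 + alpha) * sigma2.  Note
    the smoothed path depends on sigma2 only through the diffuse prior; the
    Kalman gain is set by the ratio (1 - alpha)/alpha.

    The fitted ``mu`` and ``sigma2`` are reported in the output metadata.
    """
    if params is None:
        params = RandomWalkSmootherParams()
    y = x.values
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(y)
    mu = float(np.mean(d)) if params.mu is None else float(params.mu)
    if params.sigma2 is None:
        sigma2 = float(np.var(d - mu) / (1.0 + params.alpha))
    else:
        sigma2 = float(params.sigma2)
    if sigma2 <= 0:
        # constant (zero-variance) input: the MAP path is the input itself
        out = x.copy()
        out.meta.update(rw_mu=mu, rw_sigma2=0.0, rw_alpha=params.alpha)
        return out
    z = _kalman_map_path(y, params.alpha, mu, sigma2)
    return x.with_values(z, rw_mu=mu, rw_sigma2=sigma2, rw_alpha=params.alpha)


def total_speed(k: KinematicsTrace) -> TimeSeries:
    """Scalar activity index: |v_r| + |v_s| + |v_f|, all channels in deg/s."""
    v = np.abs(k.v_r.values) + np.abs(k.v_s.values) + np.abs(k.v_f.values)
    return k.v_r.with_values(v).copy(units="deg/s")


def _fd_modal_bin(v: np.ndarray) -> tuple[float, float]:
    """(modal value, bin half-width) under the Freedman-Diaconis rule.

    The modal value is the center of the highest-count FD bin, with count
    ties broken toward zero.  A degenerate (zero-IQR) channel returns a
    zero half-width.
    """
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    h = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    if h <= 0:
        return float(np.median(v)), 0.0
    edges = np.histogram_bin_edges(v, bins=max(1, int(np.ceil((v.max() - v.min()) / h))))
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = counts == counts.max()
    cand = centers[best]
    mode = float(cand[np.argmin(np.abs(cand))])
    return mode, h / 2.0


def classify_inactivity(k: KinematicsTrace) -> np.ndarray:
    """Histogram-based rest mask: True where the fly is inactive.

    For each channel, Freedman-Diaconis bins are centered on the modal
    value (rest sits in the modal bin because the fly is still most of the
    time near zero ball motion); a sample is inactive iff all three
    channels fall inside their modal bins.  Degenerate constant channels
    classify every sample as inside their bin, with a warning.
    """
    mask = np.ones(k.n, dtype=bool)
    for name, ch in k.channels().items():
        mode, half = _fd_modal_bin(ch.values)
        if half == 0.0:
            warnings.warn(f"channel {name} is degenerate (zero IQR); treated as inactive")
            continue
        mask &= np.abs(ch.values - mode) <= half
    return mask


def resample_neural_to_kinematics(x: TimeSeries, target_rate: float,
                                  upsample_factor: int = 4) -> TimeSeries:
    """Rational resampling to the kinematics rate via a polyphase FIR.

    The signal is upsampled by ``upsample_factor``, filtered with a
    linear-phase FIR anti-alias filter (delay compensated, so net group
    delay is zero), then decimated to ``target_rate``.  Output length is
    ceil(n * target / source).
    """
    frac = Fraction(target_rate).limit_denominator(10**6) / Fraction(x.rate).limit_denominator(10**6)
    up = frac.numerator * upsample_factor
    down = frac.denominator * upsample_factor
    y = signal.resample_poly(x.values, up, down)
    out = TimeSeries(y, rate=target_rate, t0=x.t0, units=x.units, meta=dict(x.meta))
    out.meta["resampled_from_hz"] = x.rate
    return out
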