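"""Synthetic-data generators for every pipeline stage.

Nothing downstream needs real recordings: this module emulates the
statistical structure the analyses assume.

* :func:`simulate_steering_session` — two bilateral descending-neuron
  (DN) pairs whose firing rates drive treadmill kinematics through known
  ground-truth linear kernels (one monophasic "low-gain" cell type, one
  biphasic "high-gain" type), with see-saw right-left anticorrelation,
  immobility bouts, inhomogeneous-Poisson spikes and raw voltage traces
  carrying a stereotyped spike waveform on a slow subthreshold potential.
* :func:`simulate_bump_movie` / :func:`simulate_bump_experiment` — a
  von-Mises-shaped fluorescence bump over 8 sectors following a heading
  trajectory, with scripted jumps, returns and fades.
* :func:`simulate_gait` — six-leg alternating-tripod stride trajectories
  with parameterized turning asymmetries, so each turning metric has a
  known ground truth.
* :func:`simulate_connectivity` — cell-type-labeled synapse tables.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import KinematicsTrace, TimeSeries
from .legs import LEGS, PoseTrack

# ---------------------------------------------------------------------------
# ground-truth steering kernels (defined on the kinematics time base)
# ---------------------------------------------------------------------------


def monophasic_kernel(rate: float = 100.0, peak_gain: float = 1.0,
                      tau_s: float = 0.15, support_s: float = 1.5) -> np.ndarray:
    """Causal single-lobed alpha kernel, peak ``peak_gain`` at lag ``tau_s``.

    Gain units: (deg/s) per (spike/s), per sample of the input.
    """
    t = np.arange(int(round(support_s * rate))) / rate
    return peak_gain * (t / tau_s) * np.exp(1.0 - t / tau_s)


def biphasic_kernel(rate: float = 100.0, peak_gain: float = 2.0,
                    tau1_s: float = 0.10, tau2_s: float = 0.35,
                    undershoot: float = 0.6, support_s: float = 2.0) -> np.ndarray:
    """Causal biphasic kernel: fast positive lobe, slower negative lobe."""
    t = np.arange(int(round(support_s * rate))) / rate
    lobe1 = (t / tau1_s) * np.exp(1.0 - t / tau1_s)
    lobe2 = (t / tau2_s) * np.exp(1.0 - t / tau2_s)
    return peak_gain * (lobe1 - undershoot * lobe2)


def spike_template(rate: float = 10000.0, amplitude_mv: float = 8.0) -> np.ndarray:
    """Stereotyped 2 ms biphasic spike waveform, peak at ``amplitude_mv``."""
    t = np.arange(int(round(0.002 * rate))) / rate * 1e3  # ms
    w = (np.exp(-((t - 0.5) / 0.30) ** 2)
         - 0.5 * np.exp(-((t - 1.2) / 0.45) ** 2))
    return amplitude_mv * w / w.max()


def default_ground_truth_filters(rate: float = 100.0) -> dict[tuple[str, str], np.ndarray]:
    """Default kernel map: a monophasic and a biphasic bilateral pair.

    Right cells push rotational velocity positive (rightward), left cells
    negative; the biphasic pair also drives sideways velocity and both
    right cells contribute a small same-sign forward component.
    """
    mono = monophasic_kernel(rate)
    bi = biphasic_kernel(rate)
    return {
        ("mono_R", "v_r"): mono,
        ("mono_L", "v_r"): -mono,
        ("bi_R", "v_r"): bi,
        ("bi_L", "v_r"): -bi,
        ("bi_R", "v_s"): 0.5 * mono,
        ("bi_L", "v_s"): -0.5 * mono,
        ("mono_R", "v_f"): 0.3 * mono,
        ("bi_R", "v_f"): 0.3 * mono,
    }


# ---------------------------------------------------------------------------
# steering-session simulator
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Conditions of a simulated steering session.

    ``ground_truth_filters`` maps (cell, axis) to a lag-indexed kernel on
    the kinematics time base; cell names ending in ``_R``/``_L`` form
    bilateral pairs.  ``seesaw_coupling`` sets the right-left drive
    anticorrelation (1 = perfect see-saw).  Immobility bouts gate the
    kinematic output to ~0 and suppress firing below baseline.
    """

    duration_s: float = 300.0
    kinematics_rate: float = 100.0
    voltage_rate: float = 10000.0
    ground_truth_filters: dict[tuple[str, str], np.ndarray] | None = None
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"v_r": 40.0, "v_s": 20.0, "v_f": 20.0})
    baseline_rate: float = 20.0       # spikes/s
    drive_gain: float = 8.0           # spikes/s per unit latent drive
    drive_tau_s: float = 0.5          # latent OU correlation time
    seesaw_coupling: float = 0.8      # in [0, 1]
    immobility_bout_rate_per_min: float = 2.0
    immobility_mean_s: float = 2.0
    immobility_rate_factor: float = 0.3
    refractory_s: float = 0.002
    spike_amplitude_mv: float = 8.0
    voltage_noise_mv: float = 1.0
    resting_potential_mv: float = -55.0
    voltage_drive_mv_per_hz: float = 0.3
    immobility_hyperpol_mv: float = 6.0
    make_voltage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ground_truth_filters is None:
            self.ground_truth_filters = default_ground_truth_filters(self.kinematics_rate)
        for name, val in (("duration_s", self.duration_s),
                          ("kinematics_rate", self.kinematics_rate),
                          ("voltage_rate", self.voltage_rate)):
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be positive and finite, got {val}")
        if not 0.0 <= self.seesaw_coupling <= 1.0:
            raise ValueError("seesaw_coupling must lie in [0, 1]")
        for (cell, axis), k in self.ground_truth_filters.items():
            k = np.asarray(k, dtype=float)
            if not np.all(np.isfinite(k)):
                raise ValueError(f"kernel ({cell}, {axis}) has non-finite values")
            if k.size / self.kinematics_rate > 4.0:
                raise ValueError(f"kernel ({cell}, {axis}) support exceeds 4 s")
            if k.size / self.kinematics_rate > self.duration_s:
                raise ValueError(f"kernel ({cell}, {axis}) support exceeds the duration")
            self.ground_truth_filters[(cell, axis)] = k

    @property
    def cells(self) -> list[str]:
        return sorted({cell for cell, _ in self.ground_truth_filters})


@dataclass
class SyntheticSession:
    """A simulated session with its full ground truth attached."""

    kinematics: KinematicsTrace
    voltage: dict[str, TimeSeries]          # per cell, mV (empty if not generated)
    true_spike_times: dict[str, np.ndarray]  # per cell, seconds
    true_rate: dict[str, TimeSeries]        # per cell, spikes/s on the kinematic base
    active_mask: np.ndarray                 # ground-truth movement gate
    truth: SimConfig


def _ou_process(n: int, dt: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck path sampled at dt."""
    a = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i]
    return x


def _immobility_gate(n: int, rate: float, bouts_per_min: float, mean_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Movement gate: 1 while active, 0 during immobility bouts."""
    gate = np.ones(n)
    if bouts_per_min <= 0:
        return gate
    t = 0.0
    duration = n / rate
    while True:
        t += rng.exponential(60.0 / bouts_per_min)
        if t >= duration:
            break
        bout = rng.exponential(mean_s)
        i0, i1 = int(t * rate), min(n, int((t + bout) * rate))
        gate[i0:i1] = 0.0
    return gate


def _poisson_spikes(rate_hz: np.ndarray, sample_rate: float, refractory_s: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning, then refractory thinning."""
    lam_max = float(rate_hz.max())
    if lam_max <= 0:
        return np.array([])
    duration = rate_hz.size / sample_rate
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    local = rate_hz[np.minimum((cand * sample_rate).astype(int), rate_hz.size - 1)]
    keep = rng.uniform(0.0, lam_max, size=n_cand) < local
    times = cand[keep]
    if refractory_s > 0 and times.size:
        out = [times[0]]
        for t in times[1:]:
            if t - out[-1] >= refractory_s:
                out.append(t)
        times = np.asarray(out)
    return times


def simulate_steering_session(config: SimConfig) -> SyntheticSession:
    """Generate a full synthetic session from a :class:`SimConfig`.

    One latent steering drive per cell-type pair (unit-variance OU
    process) sets the right cell's rate; the left cell receives the
    negated drive scaled by the see-saw coupling plus an independent
    residual, so the pair's anticorrelation equals the coupling.  Each
    kinematic axis is the sum over cells of (true kernel convolved with
    the baseline-subtracted rate) plus Gaussian noise, gated to ~0 during
    immobility bouts.  Spikes are an inhomogeneous Poisson process with a
    refractory period enforced by thinning; voltage is a spline-
    interpolated subthreshold potential plus a stereotyped spike waveform
    at each spike time plus white noise.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.kinematics_rate
    n = int(round(config.duration_s * rate))
    dt = 1.0 / rate

    pair_types = sorted({c.rsplit("_", 1)[0] for c in config.cells})
    drives: dict[str, np.ndarray] = {}
    c = config.seesaw_coupling
    for ptype in pair_types:
        d = _ou_process(n, dt, config.drive_tau_s, rng)
        d_ind = _ou_process(n, dt, config.drive_tau_s, rng)
        drives[f"{ptype}_R"] = d
        drives[f"{ptype}_L"] = -c * d + np.sqrt(max(0.0, 1.0 - c * c)) * d_ind

    gate = _immobility_gate(n, rate, config.immobility_bout_rate_per_min,
                            config.immobility_mean_s, rng)

    rates: dict[str, np.ndarray] = {}
    for cell in config.cells:
        drive = drives.get(cell, np.zeros(n))
        r_active = config.baseline_rate + config.drive_gain * drive
        r = gate * r_active + (1.0 - gate) * config.immobility_rate_factor * config.baseline_rate
        rates[cell] = np.clip(r, 0.0, None)

    axes: dict[str, np.ndarray] = {}
    for axis in ("v_r", "v_s", "v_f"):
        sig = np.zeros(n)
        for (cell, ax), kernel in config.ground_truth_filters.items():
            if ax != axis:
                continue
            centered = rates[cell] - config.baseline_rate
            sig += np.convolve(centered, kernel)[:n]
        noise = rng.standard_normal(n) * config.noise_sd.get(axis, 0.0)
        axes[axis] = gate * (sig + noise)

    kin = KinematicsTrace(
        v_r=TimeSeries(axes["v_r"], rate, units="deg/s"),
        v_s=TimeSeries(axes["v_s"], rate, units="deg/s"),
        v_f=TimeSeries(axes["v_f"], rate, units="deg/s"),
    )

    spike_times = {cell: _poisson_spikes(rates[cell], rate, config.refractory_s, rng)
                   for cell in config.cells}
    true_rate = {cell: TimeSeries(rates[cell], rate, units="spikes/s")
                 for cell in config.cells}

    voltage: dict[str, TimeSeries] = {}
    if config.make_voltage:
        vrate = config.voltage_rate
        nv = int(round(config.duration_s * vrate))
        tv = np.arange(nv) / vrate
        tk = np.arange(n) / rate
        template = spike_template(vrate, config.spike_amplitude_mv)
        for cell in config.cells:
            sub = (config.resting_potential_mv
                   + config.voltage_drive_mv_per_hz * (rates[cell] - config.baseline_rate)
                   - config.immobility_hyperpol_mv * (1.0 - gate))
            v = CubicSpline(tk, sub)(np.clip(tv, tk[0], tk[-1]))
            for t_sp in spike_times[cell]:
                i0 = int(round(t_sp * vrate))
                i1 = min(nv, i0 + template.size)
                v[i0:i1] += template[:i1 - i0]
            v += rng.standard_normal(nv) * config.voltage_noise_mv
            voltage[cell] = TimeSeries(v, vrate, units="mV")

    return SyntheticSession(kinematics=kin, voltage=voltage,
                            true_spike_times=spike_times, true_rate=true_rate,
                            active_mask=gate > 0, truth=config)


# ---------------------------------------------------------------------------
# heading-bump simulator
# ---------------------------------------------------------------------------

_N_SECTORS = 8


def simulate_bump_movie(heading: TimeSeries, jumps: list[tuple[float, float]] | None = None,
                        width_sectors: float = 1.2, amplitude: float = 1.0,
                        baseline: float = 0.1, noise_sd: float = 0.0,
                        seed: int = 0, hold_s: float = 1.5, return_s: float = 1.0,
                        amplitude_profile: np.ndarray | None = None
                        ) -> tuple[np.ndarray, dict]:
    """Sector fluorescence movie of a von-Mises bump following a heading.

    The bump center is heading/45 deg plus the summed jump offsets; each
    (time, offset-in-sectors) jump holds for ``hold_s`` then is steered
    back to zero linearly over ``return_s`` (the return).  Each frame is
    ``amplitude * exp(kappa * (cos(theta_k - theta_c) - 1)) + baseline``
    plus Gaussian noise, clipped at zero (clipping is flagged in the
    returned info dict).  ``amplitude_profile`` optionally modulates the
    bump amplitude per frame (used to script fades).

    Returns (8 x T sector matrix, info dict with the true center trace).
    """
    if width_sectors <= 0:
        raise ValueError("width must be positive")
    h = heading.values
    if not np.all(np.isfinite(h)):
        raise ValueError("heading must be finite")
    rng = np.random.default_rng(seed)
    n = h.size
    t = heading.t
    offset = np.zeros(n)
    for t_j, off in (jumps or []):
        ramp = np.clip((t - (t_j + hold_s)) / max(return_s, 1e-9), 0.0, 1.0)
        offset += np.where(t >= t_j, off * (1.0 - ramp), 0.0)
    center = h / 45.0 + offset
    kappa = 1.0 / (width_sectors * (2.0 * np.pi / _N_SECTORS)) ** 2
    theta_k = 2.0 * np.pi * np.arange(_N_SECTORS) / _N_SECTORS
    theta_c = 2.0 * np.pi * center / _N_SECTORS
    amp = amplitude * (np.ones(n) if amplitude_profile is None else amplitude_profile)
    movie = amp * np.exp(kappa * (np.cos(theta_k[:, None] - theta_c[None, :]) - 1.0))
    movie = movie + baseline
    if noise_sd > 0:
        movie = movie + rng.standard_normal(movie.shape) * noise_sd
    clipped = bool((movie < 0).any())
    movie = np.clip(movie, 0.0, None)
    return movie, {"center_sectors": center % _N_SECTORS, "offset": offset,
                   "clipped_negative": clipped}


#: scripted trial kinds cycled by simulate_bump_experiment
BUMP_TRIAL_KINDS = ("jump_ccw", "jump_cw", "no_jump", "jump_ccw", "faded")


def simulate_bump_experiment(n_trials: int = 50, rate: float = 12.0, seed: int = 0,
                             trial_s: float = 14.0, pre_s: float = 2.0,
                             jump_sectors: float = 2.5, hold_s: float = 2.0,
                             return_s: float = 1.2, amplitude: float = 1.0,
                             baseline: float = 0.1, noise_sd: float = 0.02,
                             kinds: list[str] | None = None
                             ) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Scripted bump-jump experiment with ground-truth trial labels.

    Trials are concatenated ``trial_s`` blocks with the puff ``pre_s``
    into each block.  Kinds cycle through ``BUMP_TRIAL_KINDS`` unless
    given: ``jump_ccw``/``jump_cw`` jump by +/-``jump_sectors``, hold,
    return and dwell (include=True; the return path is opposite to the
    jump direction); ``no_jump`` trials have no offset; ``faded`` trials
    have the bump amplitude collapsed for 2 s after the puff.

    Returns (8 x T raw movie, puff times, per-trial truth dicts with keys
    kind / include / reason / jump_sign / return_path).
    """
    rng = np.random.default_rng(seed)
    n_frames_trial = int(round(trial_s * rate))
    n = n_trials * n_frames_trial
    t = np.arange(n) / rate
    heading_sectors = np.repeat(rng.uniform(0, _N_SECTORS, size=n_trials), n_frames_trial)
    heading = TimeSeries(heading_sectors * 45.0, rate, units="deg")

    kinds = list(kinds) if kinds is not None else [
        BUMP_TRIAL_KINDS[i % len(BUMP_TRIAL_KINDS)] for i in range(n_trials)]
    if len(kinds) != n_trials:
        raise ValueError("one kind per trial required")

    jumps: list[tuple[float, float]] = []
    amp_profile = np.ones(n)
    puffs = np.empty(n_trials)
    truth: list[dict] = []
    for k, kind in enumerate(kinds):
        t0 = k * trial_s
        puff = t0 + pre_s
        puffs[k] = puff
        entry = {"kind": kind, "include": False, "reason": "", "jump_sign": 0,
                 "return_path": "none"}
        if kind in ("jump_ccw", "jump_cw"):
            sign = 1.0 if kind == "jump_ccw" else -1.0
            jumps.append((puff, sign * jump_sectors))
            entry.update(include=True, jump_sign=int(sign),
                         return_path="clockwise" if sign > 0 else "counterclockwise")
        elif kind == "no_jump":
            entry["reason"] = "no-jump"
        elif kind == "faded":
            i0 = int(round((puff + 0.5) * rate))
            i1 = min(n, i0 + int(round(2.0 * rate)))
            amp_profile[i0:i1] = 0.02
            entry["reason"] = "faded"
        else:
            raise ValueError(f"unknown trial kind {kind!r}")
        truth.append(entry)

    movie, _ = simulate_bump_movie(heading, jumps=jumps, amplitude=amplitude,
                                   baseline=baseline, noise_sd=noise_sd, seed=seed + 1,
                                   hold_s=hold_s, return_s=return_s,
                                   amplitude_profile=amp_profile)
    return movie, puffs, truth


# ---------------------------------------------------------------------------
# gait simulator
# ---------------------------------------------------------------------------


@dataclass
class TurnBias:
    """Turning asymmetries of the synthetic gait, each with a known truth.

    ``stance_prolong_ib`` multiplies the inner-back stance duration (the
    pivot); ``stance_dir_deg``/``swing_dir_deg`` rotate stance and swing
    directions (positive stance = rightward of backward, positive swing =
    leftward of forward, matching the metric conventions);
    ``outer_swing_scale``/``inner_swing_scale`` scale swing distances per
    side; ``rot_deg_s`` curves the body path.
    """

    turn_side: str = "right"
    stance_prolong_ib: float = 1.0
    stance_dir_deg: float = 0.0
    swing_dir_deg: float = 0.0
    outer_swing_scale: float = 1.0
    inner_swing_scale: float = 1.0
    rot_deg_s: float = 0.0


@dataclass
class GaitConfig:
    """Alternating-tripod gait conditions."""

    n_strides: int = 10
    stride_hz: float = 2.5
    step_len_mm: float = 2.0
    rate: float = 200.0
    duty: float = 0.5             # stance fraction of the cycle
    body_len_mm: float = 2.5
    turn: TurnBias = field(default_factory=TurnBias)
    jitter_mm: float = 0.0        # Gaussian keypoint noise
    seed: int = 0

    @property
    def forward_mm_s(self) -> float:
        """Body speed making stance tarsi stationary in the world frame."""
        return self.step_len_mm * self.stride_hz / self.duty


#: neutral tarsus positions in the body frame (x forward, y left), mm
_NEUTRAL = {"R1": (1.0, -1.0), "R2": (0.0, -1.2), "R3": (-1.0, -1.0),
            "L1": (1.0, 1.0), "L2": (0.0, 1.2), "L3": (-1.0, 1.0)}
_TRIPOD_A = {"R1", "R3", "L2"}  # phase 0; the other tripod is anti-phase


def _leg_body_track(cfg: GaitConfig, leg: str, n: int) -> np.ndarray:
    """Body-frame tarsus trajectory of one leg over n frames."""
    turn = cfg.turn
    inner = "R" if turn.turn_side == "right" else "L"
    is_inner = leg.startswith(inner)
    role_ib = leg == f"{inner}3"

    rate = cfg.rate
    period = 1.0 / cfg.stride_hz
    stance_s = cfg.duty * period * (turn.stance_prolong_ib if role_ib else 1.0)
    swing_s = (1.0 - cfg.duty) * period
    stance_f = max(2, int(round(stance_s * rate)))
    swing_f = max(2, int(round(swing_s * rate)))

    # stance displacement keeps the tarsus world-fixed while the body advances
    l_st = cfg.forward_mm_s * stance_f / rate
    a_st = np.radians(turn.stance_dir_deg)
    d_st = l_st * np.array([-np.cos(a_st), -np.sin(a_st)])
    scale = turn.inner_swing_scale if is_inner else turn.outer_swing_scale
    l_sw = cfg.step_len_mm * scale
    a_sw = np.radians(turn.swing_dir_deg)
    d_sw = l_sw * np.array([np.cos(a_sw), np.sin(a_sw)])

    pos = np.array(_NEUTRAL[leg], dtype=float)
    track = np.empty((n, 2))
    in_stance = leg in _TRIPOD_A
    i = 0
    # start mid-phase so tripods alternate
    left = stance_f // 2 if in_stance else swing_f // 2
    while i < n:
        dur = left if left else (stance_f if in_stance else swing_f)
        step = (d_st if in_stance else d_sw) / (stance_f if in_stance else swing_f)
        for _ in range(dur):
            if i >= n:
                break
            pos = pos + step
            track[i] = pos
            i += 1
        in_stance = not in_stance
        left = 0
    return track


def simulate_gait(config: GaitConfig | None = None, **overrides) -> PoseTrack:
    """Six-leg alternating-tripod keypoint table with scripted turn biases.

    The body translates at the speed that keeps stance tarsi stationary in
    the camera frame and rotates at ``turn.rot_deg_s``; leg trajectories
    are scripted in the body frame from the :class:`TurnBias` parameters
    and transformed to the camera frame, so each turning metric has an
    exact ground truth.
    """
    cfg = config or GaitConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a GaitConfig or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.n_strides / cfg.stride_hz * cfg.rate))
    t = np.arange(n) / cfg.rate

    theta = np.radians(cfg.turn.rot_deg_s) * t
    step = cfg.forward_mm_s / cfg.rate
    heading = np.column_stack([np.cos(theta), np.sin(theta)])
    centroid = np.vstack([[0.0, 0.0], np.cumsum(heading[:-1] * step, axis=0)])

    rot = np.empty((n, 2, 2))
    rot[:, 0, 0] = np.cos(theta)
    rot[:, 0, 1] = -np.sin(theta)
    rot[:, 1, 0] = np.sin(theta)
    rot[:, 1, 1] = np.cos(theta)

    def to_cam(body_xy: np.ndarray) -> np.ndarray:
        return centroid + np.einsum("nij,nj->ni", rot, body_xy)

    half = cfg.body_len_mm / 2.0
    cols = {}
    head = to_cam(np.tile([half, 0.0], (n, 1)))
    abd = to_cam(np.tile([-half, 0.0], (n, 1)))
    cols["head_x"], cols["head_y"] = head.T
    cols["abdomen_x"], cols["abdomen_y"] = abd.T
    for leg in LEGS:
        cam = to_cam(_leg_body_track(cfg, leg, n))
        if cfg.jitter_mm > 0:
            cam = cam + rng.standard_normal(cam.shape) * cfg.jitter_mm
        cols[f"{leg}_x"], cols[f"{leg}_y"] = cam.T
    return PoseTrack(pd.DataFrame(cols), rate=cfg.rate)


# ---------------------------------------------------------------------------
# synapse-table simulator
# ---------------------------------------------------------------------------


def simulate_connectivity(spec: list[dict], seed: int = 0) -> pd.DataFrame:
    """Cell-type-labeled synapse table from a connection spec.

    Each spec entry is a dict with keys ``pre_type``, ``post_type``,
    ``n_per_side`` (cells of each type per hemisphere) and ``synapses``
    (an int for a fixed unitary count, or a (low, high) tuple for a
    uniform integer draw per unitary connection).  Every presynaptic cell
    contacts every same-side postsynaptic cell.  An empty spec yields an
    empty (but schema-complete) table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for entry in spec:
        pre_t, post_t = entry["pre_type"], entry["post_type"]
        n_side = int(entry.get("n_per_side", 1))
        syn = entry["synapses"]
        for side in ("L", "R"):
            for i in range(n_side):
                for j in range(n_side):
                    if isinstance(syn, (tuple, list)):
                        count = int(rng.integers(syn[0], syn[1] + 1))
                    else:
                        count = int(syn)
                    rows.append({
                        "pre_id": f"{pre_t}_{side}{i}", "pre_type": pre_t,
                        "pre_side": side,
                        "post_id": f"{post_t}_{side}{j}", "post_type": post_t,
                        "post_side": side, "synapses": count,
                    })
    return pd.DataFrame(rows, columns=["pre_id", "pre_type", "pre_side", "post_id",
                                       "post_type", "post_side", "synapses"])
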