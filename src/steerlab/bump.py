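"""Heading-bump (compass) analysis.

The ellipsoid-body compass population is imaged as 8 wedge-shaped sectors
(45 degrees each).  This module computes sector dF/F, tracks the activity
bump with a population vector average (PVA), and classifies bump-jump
trials: after a stimulus puff the bump should jump by at least half a
sector and later return to dwell near its initial position; trials where
the bump fades, is unstable before the puff, fails to jump, or fails to
return are excluded with explicit reason codes.

Sector convention: sectors are indexed 0-7 counterclockwise viewed from
the rear; increasing position is counterclockwise bump motion.  All sign
conventions are centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TimeSeries

N_SECTORS = 8
SECTOR_DEG = 360.0 / N_SECTORS  # 45 degrees per sector

# trial-inclusion constants
FADE_PERCENTILE = 7.0
FADE_MAX_S = 1.0
PRE_WINDOW_S = 1.0
PRE_STABILITY_SD_SECTORS = 1.5
MIN_JUMP_SECTORS = 0.5
DWELL_BAND_SECTORS = 0.5
DWELL_MIN_S = 0.5

# 3-frame Gaussian used to smooth the position derivative for return speed
_DERIV_KERNEL = np.array([0.25, 0.5, 0.25])


def _to_rad(sectors: np.ndarray | float) -> np.ndarray:
    return np.asarray(sectors, dtype=float) * (2.0 * np.pi / N_SECTORS)


def _to_sectors(rad: np.ndarray | float) -> np.ndarray:
    return np.asarray(rad, dtype=float) * (N_SECTORS / (2.0 * np.pi))


def circular_mean_sectors(pos: np.ndarray) -> float:
    """Circular mean of positions given in sectors, via the resultant vector."""
    a = _to_rad(pos)
    ang = np.angle(np.mean(np.exp(1j * a)))
    return float(_to_sectors(ang) % N_SECTORS)


def circular_std_sectors(pos: np.ndarray) -> float:
    """Circular standard deviation in sectors: sqrt(-2 ln R) on the resultant."""
    a = _to_rad(pos)
    r = np.abs(np.mean(np.exp(1j * a)))
    r = min(r, 1.0)
    if r <= 0:
        return float("inf")
    return float(_to_sectors(np.sqrt(-2.0 * np.log(r))))


def circular_diff_sectors(a, b) -> np.ndarray:
    """Signed shortest-arc difference a - b in sectors, in (-4, 4]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % N_SECTORS
    d = np.where(d > N_SECTORS / 2, d - N_SECTORS, d)
    return d


@dataclass
class SectorTrace:
    """dF/F of the 8 ellipsoid-body sectors over time."""

    dff: np.ndarray       # (8, T)
    rate: float           # frame rate, Hz (~12)
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2 or self.dff.shape[0] != N_SECTORS:
            raise ValueError(f"sector matrix must be ({N_SECTORS}, T)")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("sector trace must be finite")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate


def sector_dff(raw: np.ndarray, rate: float, t0: float = 0.0) -> SectorTrace:
    """Convert raw sector fluorescence to dF/F.

    The baseline F for each sector is the time-average of the lower half
    of that sector's raw values (samples at or below the sector median);
    dF/F = (raw - F) / F.  Scaling the raw trace leaves dF/F unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != N_SECTORS:
        raise ValueError(f"raw fluorescence must be ({N_SECTORS}, T)")
    dff = np.empty_like(raw)
    for k in range(N_SECTORS):
        row = raw[k]
        lower = row[row <= np.median(row)]
        f0 = float(np.mean(lower))
        if f0 <= 0:
            raise ValueError(f"non-positive baseline F in sector {k}")
        dff[k] = (row - f0) / f0
    return SectorTrace(dff=dff, rate=rate, t0=t0)


def pva(s: SectorTrace, undefined_tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Population vector average of the sector activity, per frame.

    Each sector contributes a unit vector at its center angle weighted by
    its dF/F (negative weights clipped to zero; the clipped mass is noted
    in the trace metadata).  Returns (position in sectors on [0, 8),
    magnitude); frames whose magnitude is ~0 get NaN position.
    """
    w = np.clip(s.dff, 0.0, None)
    clipped = float(np.sum(s.dff[s.dff < 0]))
    if clipped:
        s.meta["pva_clipped_negative_mass"] = clipped
    angles = _to_rad(np.arange(N_SECTORS))
    vec = (w * np.exp(1j * angles)[:, None]).sum(axis=0)
    magnitude = np.abs(vec)
    position = _to_sectors(np.angle(vec)) % N_SECTORS
    position = np.where(magnitude > undefined_tol, position, np.nan)
    return position, magnitude


@dataclass
class BumpTrial:
    """One puff trial with its inclusion decision and jump/return geometry."""

    puff_time: float
    include: bool
    reason: str = ""                       # non-empty whenever include is False
    initial_position: float | None = None  # sectors, circular
    jump_size: float | None = None         # signed sectors, + = counterclockwise
    return_path: str = "none"              # "clockwise" | "counterclockwise" | "none"
    alignment_time: float | None = None    # time of maximal return speed
    max_excursion_time: float | None = None


def classify_trials(s: SectorTrace, puff_times: np.ndarray,
                    trial_duration_s: float = 10.0,
                    pre_window_s: float = PRE_WINDOW_S) -> list[BumpTrial]:
    """Classify bump-jump trials, applying the inclusion rules in order.

    Per trial: (1) exclude if the PVA magnitude drops below the
    experiment-wide 7th percentile for more than 1 s during the trial
    ("faded"); (2) exclude if the circular SD of the bump position in the
    1 s pre-puff window exceeds 1.5 sectors ("unstable-pre"); (3) the
    initial position is the circular mean of that window; (4) exclude if
    the bump never moves at least 0.5 sectors from it ("no-jump");
    (5) exclude if the bump never dwells within 0.5 sectors of the initial
    position for at least 0.5 s after the jump ("no-return").  Survivors
    get the signed jump size (shortest arc at maximum excursion), the
    return direction, and the alignment time of maximal return speed
    (earlier frame on ties).
    """
    position, magnitude = pva(s)
    mag_thresh = float(np.percentile(magnitude, FADE_PERCENTILE))
    rate = s.rate
    trials: list[BumpTrial] = []
    for puff in np.atleast_1d(puff_times):
        i_puff = int(round((puff - s.t0) * rate))
        i_end = min(s.n_frames, i_puff + int(round(trial_duration_s * rate)))
        i_pre = max(0, i_puff - int(round(pre_window_s * rate)))
        if i_pre == i_puff or i_puff >= s.n_frames:
            trials.append(BumpTrial(puff, include=False, reason="outside-recording"))
            continue

        low = magnitude[i_puff:i_end] < mag_thresh
        if _longest_run(low) > FADE_MAX_S * rate:
            trials.append(BumpTrial(puff, include=False, reason="faded"))
            continue

        pre_pos = position[i_pre:i_puff]
        if np.any(np.isnan(pre_pos)) or circular_std_sectors(pre_pos) > PRE_STABILITY_SD_SECTORS:
            trials.append(BumpTrial(puff, include=False, reason="unstable-pre"))
            continue
        initial = circular_mean_sectors(pre_pos)

        disp = circular_diff_sectors(position[i_puff:i_end], initial)
        if np.any(np.isnan(disp)):
            trials.append(BumpTrial(puff, include=False, reason="faded"))
            continue
        i_max = int(np.argmax(np.abs(disp)))
        jump = float(disp[i_max])
        if abs(jump) < MIN_JUMP_SECTORS:
            trials.append(BumpTrial(puff, include=False, reason="no-jump"))
            continue

        in_band = np.abs(disp) <= DWELL_BAND_SECTORS
        dwell_start = _first_dwell(in_band, start=i_max, min_len=int(round(DWELL_MIN_S * rate)))
        if dwell_start is None:
            trials.append(BumpTrial(puff, include=False, reason="no-return"))
            continue

        # return period: maximum excursion -> re-entry into the dwell band
        seg = disp[i_max:dwell_start + 1]
        smooth = np.convolve(np.pad(seg, 1, mode="edge"), _DERIV_KERNEL, mode="valid")
        speed = np.abs(np.diff(smooth)) * rate
        i_align = i_max + (int(np.argmax(speed)) if speed.size else 0)
        net = disp[dwell_start] - disp[i_max]
        path = "counterclockwise" if net > 0 else "clockwise"
        trials.append(BumpTrial(
            puff_time=puff, include=True, initial_position=initial,
            jump_size=jump, return_path=path,
            alignment_time=s.t0 + (i_puff + i_align) / rate,
            max_excursion_time=s.t0 + (i_puff + i_max) / rate,
        ))
    return trials


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _first_dwell(in_band: np.ndarray, start: int, min_len: int) -> int | None:
    """First index >= start opening a run of >= min_len in-band frames."""
    n = in_band.size
    run = 0
    for i in range(start, n):
        run = run + 1 if in_band[i] else 0
        if run >= max(1, min_len):
            return i - run + 1
    return None


def align_trials_by_return(trials: list[BumpTrial], signals: list[TimeSeries],
                           span_s: tuple[float, float] = (-2.0, 2.0),
                           fly_ids: list | None = None) -> dict[str, dict]:
    """Average signals aligned to the maximal-return-speed time, per direction.

    ``signals[k]`` is the signal for ``trials[k]``.  Included trials are
    grouped by return direction (opposite directions are never mixed),
    aligned to their alignment time, averaged within fly and then across
    flies.  Returns {direction: {"lags", "mean", "per_fly", "n_trials"}}.
    """
    if len(trials) != len(signals):
        raise ValueError("one signal per trial required")
    fly_ids = fly_ids if fly_ids is not None else [0] * len(trials)
    out: dict[str, dict] = {}
    for direction in ("clockwise", "counterclockwise"):
        picks = [(tr, sig, fid) for tr, sig, fid in zip(trials, signals, fly_ids)
                 if tr.include and tr.return_path == direction]
        if not picks:
            continue
        rate = picks[0][1].rate
        lo, hi = (int(round(span_s[0] * rate)), int(round(span_s[1] * rate)))
        by_fly: dict = {}
        for tr, sig, fid in picks:
            i = int(round((tr.alignment_time - sig.t0) * rate))
            if i + lo < 0 or i + hi > sig.n:
                continue
            by_fly.setdefault(fid, []).append(sig.values[i + lo:i + hi])
        per_fly = np.asarray([np.mean(v, axis=0) for v in by_fly.values()])
        if per_fly.size == 0:
            continue
        out[direction] = {
            "lags": np.arange(lo, hi) / rate,
            "mean": per_fly.mean(axis=0),
            "per_fly": per_fly,
            "n_trials": len(picks),
        }
    return out
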