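"""Leg kinematics from pose-tracking keypoints.

Operates on per-frame keypoint tables with eight tracked body parts: the
head (anterior edge), the abdomen tip, and the six tarsi.  Provides body
velocities from the head-abdomen axis, swing/stance segmentation of each
leg (stance = smoothed tarsus speed < 8 mm/s), rotation-event detection,
the five turning metrics computed per event window, and windowed gait
statistics (step frequency, step length, forward velocity).

Conventions: legs are named by side and segment (R1/R2/R3 = right front/
middle/back, likewise L*).  For a turn, the inner side is the side the
fly turns toward, giving the roles iF, iM, iB, oF, oM, oB.  Stance
directions are measured relative to straight backward along the body axis
(0 deg), swing directions relative to straight forward; positive stance
direction = rightward, positive swing direction = leftward, so mirror
reflection negates both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeSeries

LEGS = ("R1", "R2", "R3", "L1", "L2", "L3")
STANCE_SPEED_THRESHOLD_MM_S = 8.0
MIN_FORWARD_MM_S = 2.0
WINDOW_S = 0.5
ROTATION_THRESHOLD_DEG_S = 20.0
ROTATION_MIN_HOLD_S = 0.1
ROTATION_PRE_S = 0.1

METRIC_LEGS = {
    "stance_direction": {"stance": ("oF", "iF", "iM")},
    "swing_direction": {"swing": ("oF", "iF", "iM")},
    "swing_distance_ratio": {"swing": ("oF", "oM", "iM", "iB")},
    "stance_duration_ratio": {"stance": ("iB", "iF", "oF", "oM", "oB")},
    "swing_duration": {"swing": ("iM", "iB")},
}


@dataclass
class PoseTrack:
    """Keypoint table: one row per frame, (x, y) in mm per body part."""

    frames: pd.DataFrame
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        needed = [f"{p}_{c}" for p in ("head", "abdomen") + LEGS for c in "xy"]
        missing = [c for c in needed if c not in self.frames.columns]
        if missing:
            raise ValueError(f"pose table missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.frames)

    def xy(self, part: str) -> np.ndarray:
        return self.frames[[f"{part}_x", f"{part}_y"]].to_numpy(dtype=float)

    def slice(self, start: int, stop: int) -> "PoseTrack":
        return PoseTrack(self.frames.iloc[start:stop].reset_index(drop=True),
                         self.rate, self.t0 + start / self.rate)


def leg_roles(turn_side: str) -> dict[str, str]:
    """Map turn-relative roles (iF..oB) to anatomical leg names."""
    if turn_side not in ("right", "left"):
        raise ValueError("turn_side must be 'right' or 'left'")
    inner, outer = ("R", "L") if turn_side == "right" else ("L", "R")
    return {"iF": f"{inner}1", "iM": f"{inner}2", "iB": f"{inner}3",
            "oF": f"{outer}1", "oM": f"{outer}2", "oB": f"{outer}3"}


def body_axis(p: PoseTrack) -> tuple[np.ndarray, np.ndarray]:
    """(unit axis vectors head-ward, axis angle in radians) per frame."""
    axis = p.xy("head") - p.xy("abdomen")
    angle = np.unwrap(np.arctan2(axis[:, 1], axis[:, 0]))
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    return axis / np.where(norm > 0, norm, 1.0), angle


def body_velocities(p: PoseTrack, window_s: float = WINDOW_S,
                    min_forward_mm_s: float = MIN_FORWARD_MM_S) -> pd.DataFrame:
    """Per-window body velocities from the head-abdomen vector.

    Forward velocity is the centroid velocity projected on the body axis
    (mm/s, signed); sideways speed is the magnitude of the orthogonal
    component; rotational speed is |d(axis angle)/dt| in deg/s.  Values
    are means over non-overlapping ``window_s`` windows; windows whose
    mean forward velocity is below ``min_forward_mm_s`` are flagged
    ``kept = False``.
    """
    unit, angle = body_axis(p)
    centroid = 0.5 * (p.xy("head") + p.xy("abdomen"))
    vel = np.gradient(centroid, axis=0) * p.rate
    forward = np.einsum("ij,ij->i", vel, unit)
    side = np.abs(vel[:, 0] * (-unit[:, 1]) + vel[:, 1] * unit[:, 0])
    rot = np.abs(np.gradient(angle) * p.rate) * 180.0 / np.pi
    w = max(1, int(round(window_s * p.rate)))
    n_win = p.n // w
    rows = []
    for k in range(n_win):
        sl = slice(k * w, (k + 1) * w)
        fwd = float(np.mean(forward[sl]))
        rows.append({
            "window": k,
            "t_start": p.t0 + k * w / p.rate,
            "forward_mm_s": fwd,
            "sideways_mm_s": float(np.mean(side[sl])),
            "rotational_deg_s": float(np.mean(rot[sl])),
            "kept": fwd >= min_forward_mm_s,
        })
    return pd.DataFrame(rows)


@dataclass
class LegEpoch:
    """A contiguous swing or stance epoch of one leg."""

    kind: str       # "stance" | "swing"
    start: int      # frame index, inclusive
    stop: int       # frame index, exclusive
    complete: bool  # False when clipped by the trace or window edge

    @property
    def n_frames(self) -> int:
        return self.stop - self.start


def limb_speed(p: PoseTrack, leg: str) -> np.ndarray:
    """Tarsus speed in the camera frame, smoothed over 3 consecutive frames."""
    pos = p.xy(leg)
    v = np.linalg.norm(np.gradient(pos, axis=0), axis=1) * p.rate
    k = np.ones(3) / 3.0
    return np.convolve(np.pad(v, 1, mode="edge"), k, mode="valid")


def label_swing_stance(p: PoseTrack,
                       threshold_mm_s: float = STANCE_SPEED_THRESHOLD_MM_S
                       ) -> dict[str, dict]:
    """Per-leg stance mask and swing/stance epoch lists.

    A leg is in stance when its 3-frame-smoothed camera-frame speed is
    below ``threshold_mm_s``, otherwise in swing.  Epochs touching the
    trace edges are flagged incomplete.
    """
    out: dict[str, dict] = {}
    for leg in LEGS:
        speed = limb_speed(p, leg)
        stance = speed < threshold_mm_s
        epochs: list[LegEpoch] = []
        i = 0
        while i < stance.size:
            j = i
            while j < stance.size and stance[j] == stance[i]:
                j += 1
            complete = i > 0 and j < stance.size
            epochs.append(LegEpoch("stance" if stance[i] else "swing", i, j, complete))
            i = j
        out[leg] = {"stance_mask": stance, "epochs": epochs}
    return out


def detect_rotation_events(rot_speed: TimeSeries,
                           threshold: float = ROTATION_THRESHOLD_DEG_S,
                           min_hold_s: float = ROTATION_MIN_HOLD_S,
                           window_s: float = WINDOW_S,
                           pre_s: float = ROTATION_PRE_S) -> list[tuple[float, float, int]]:
    """Body-rotation events: sustained excursions of rotational speed.

    A crossing where the speed rises above ``threshold`` and stays above
    it for at least ``min_hold_s`` opens a ``window_s`` analysis window
    starting ``pre_s`` before the crossing.  Returns (start time, stop
    time, crossing index) triples; windows extending past the trace are
    dropped.
    """
    v = rot_speed.values
    rate = rot_speed.rate
    hold = max(1, int(round(min_hold_s * rate)))
    above = v > threshold
    events = []
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    for i in crossings:
        if i + hold > v.size or not above[i:i + hold].all():
            continue
        start = rot_speed.t0 + i / rate - pre_s
        stop = start + window_s
        if start < rot_speed.t0 or stop > rot_speed.t0 + v.size / rate:
            continue
        events.append((start, stop, int(i)))
    return events


@dataclass
class TurnMetrics:
    """The five turning metrics of one rotation-event window.

    Any metric whose relevant legs lacked a complete epoch is None, with
    the explanation in ``omitted``.
    """

    stance_direction_deg: float | None
    swing_direction_deg: float | None
    swing_distance_ratio: float | None
    stance_duration_ratio: float | None
    swing_duration_s: float | None
    turn_side: str = ""
    omitted: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "stance_direction": self.stance_direction_deg,
            "swing_direction": self.swing_direction_deg,
            "swing_distance_ratio": self.swing_distance_ratio,
            "stance_duration_ratio": self.stance_duration_ratio,
            "swing_duration": self.swing_duration_s,
        }


def body_frame_positions(p: PoseTrack, part: str) -> np.ndarray:
    """Keypoint positions in the body frame (x forward, y left), per frame.

    The body frame is centered on the head-abdomen midpoint and rotated by
    the body-axis angle, so a world-fixed stance tarsus moves straight
    backward in it while the fly advances.
    """
    _, angle = body_axis(p)
    centroid = 0.5 * (p.xy("head") + p.xy("abdomen"))
    rel = p.xy(part) - centroid
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack([rel[:, 0] * ca + rel[:, 1] * sa,
                            -rel[:, 0] * sa + rel[:, 1] * ca])


def _epoch_stats(p: PoseTrack, leg: str, epochs: list[LegEpoch], kind: str) -> dict:
    """Direction, distance and duration of each complete epoch of one kind.

    Directions and distances are body-centric: computed on the tarsus
    trajectory in the moving body frame, so body translation and rotation
    drop out.
    """
    pos = body_frame_positions(p, leg)
    dirs, dists, durs = [], [], []
    for e in epochs:
        if e.kind != kind or not e.complete or e.n_frames < 2:
            continue
        d = pos[e.stop - 1] - pos[e.start]
        fwd, left = d
        if kind == "stance":
            direction = np.degrees(np.arctan2(-left, -fwd))  # + = rightward of backward
        else:
            direction = np.degrees(np.arctan2(left, fwd))    # + = leftward of forward
        dirs.append(direction)
        dists.append(float(np.hypot(*d)))
        durs.append(e.n_frames / p.rate)
    return {"directions": dirs, "distances": dists, "durations": durs}


def _circ_mean_deg(vals: list[float]) -> float:
    a = np.radians(vals)
    return float(np.degrees(np.angle(np.mean(np.exp(1j * a)))))


def turn_metrics(window: PoseTrack, epochs: dict[str, dict], turn_side: str) -> TurnMetrics:
    """Compute the five turning metrics for one event window.

    ``epochs`` is the :func:`label_swing_stance` output for the window.
    Each metric requires at least one complete relevant epoch from every
    leg it involves; otherwise that metric is omitted with a reason.
    """
    roles = leg_roles(turn_side)
    stats = {role: {kind: _epoch_stats(window, leg, epochs[leg]["epochs"], kind)
                    for kind in ("stance", "swing")}
             for role, leg in roles.items()}

    omitted: dict[str, str] = {}

    def check(metric: str) -> bool:
        for kind, legs_needed in METRIC_LEGS[metric].items():
            for role in legs_needed:
                if not stats[role][kind]["durations"]:
                    omitted[metric] = f"{role} has no complete {kind} epoch"
                    return False
        return True

    stance_dir = swing_dir = dist_ratio = dur_ratio = swing_dur = None
    if check("stance_direction"):
        dirs = sum((stats[r]["stance"]["directions"] for r in ("oF", "iF", "iM")), [])
        stance_dir = _circ_mean_deg(dirs)
    if check("swing_direction"):
        dirs = sum((stats[r]["swing"]["directions"] for r in ("oF", "iF", "iM")), [])
        swing_dir = _circ_mean_deg(dirs)
    if check("swing_distance_ratio"):
        outer = np.mean(sum((stats[r]["swing"]["distances"] for r in ("oF", "oM")), []))
        inner = np.mean(sum((stats[r]["swing"]["distances"] for r in ("iM", "iB")), []))
        dist_ratio = float(outer / inner) if inner > 0 else None
    if check("stance_duration_ratio"):
        ib = np.mean(stats["iB"]["stance"]["durations"])
        others = np.mean(sum((stats[r]["stance"]["durations"]
                              for r in ("iF", "oF", "oM", "oB")), []))
        dur_ratio = float(ib / others) if others > 0 else None
    if check("swing_duration"):
        swing_dur = float(np.mean(sum((stats[r]["swing"]["durations"]
                                       for r in ("iM", "iB")), [])))
    return TurnMetrics(stance_dir, swing_dir, dist_ratio, dur_ratio, swing_dur,
                       turn_side=turn_side, omitted=omitted)


def window_gait_stats(p: PoseTrack, window_s: float = WINDOW_S,
                      min_forward_mm_s: float = MIN_FORWARD_MM_S) -> pd.DataFrame:
    """Per-window step frequency, step length, and forward velocity.

    A stride runs from one stance onset to the next stance onset of the
    same leg; only strides complete within the window count.  Step
    frequency is the mean of 1/stride-duration across all complete
    strides of all six legs; step length is the mean body-centric distance
    the tarsus travels over each complete swing epoch (the stride's
    ground-gain, invariant to body translation).  Windows with no
    complete stride, or mean forward velocity below the threshold, are
    omitted.
    """
    bv = body_velocities(p, window_s, min_forward_mm_s)
    w = max(1, int(round(window_s * p.rate)))
    rows = []
    for _, win in bv.iterrows():
        if not win.kept:
            continue
        k = int(win.window)
        sl = p.slice(k * w, (k + 1) * w)
        ep = label_swing_stance(sl)
        freqs, lengths = [], []
        for leg in LEGS:
            onsets = [e.start for e in ep[leg]["epochs"] if e.kind == "stance" and e.complete]
            pos = body_frame_positions(sl, leg)
            for a, b in zip(onsets, onsets[1:]):
                dur = (b - a) / p.rate
                freqs.append(1.0 / dur)
            for e in ep[leg]["epochs"]:
                if e.kind == "swing" and e.complete and e.n_frames >= 2:
                    # extent along the swing's principal direction: robust to
                    # one-frame labeling blur at the epoch boundaries
                    seg = pos[e.start:e.stop]
                    d = seg[-1] - seg[0]
                    norm = np.linalg.norm(d)
                    if norm == 0:
                        continue
                    proj = seg @ (d / norm)
                    lengths.append(float(proj.max() - proj.min()))
        if not freqs or not lengths:
            continue
        rows.append({"window": k, "t_start": win.t_start,
                     "step_frequency_hz": float(np.mean(freqs)),
                     "step_length_mm": float(np.mean(lengths)),
                     "forward_mm_s": win.forward_mm_s})
    return pd.DataFrame(rows)
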