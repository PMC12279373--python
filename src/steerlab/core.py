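"""Core containers shared by every analysis stage.

All continuous signals travel through :class:`TimeSeries`, a uniformly
sampled array with an explicit rate and unit label.  Treadmill kinematics
are carried as a :class:`KinematicsTrace` holding the three fictive-path
channels (rotational, sideways, forward velocity, all in deg/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Spherical-treadmill ball radius used to convert deg/s to mm/s.
BALL_RADIUS_MM = 3.175

#: deg/s -> mm/s conversion factor for translational channels.
DEG_PER_S_TO_MM_PER_S = BALL_RADIUS_MM * np.pi / 180.0


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values
        Sample values, 1-D.
    rate
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample in seconds.
    units
        Free-form unit label (e.g. ``"deg/s"``, ``"mV"``).
    meta
        Optional processing metadata accumulated by pipeline stages.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"rate must be a positive finite number, got {self.rate}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.rate

    def copy(self, **changes) -> "TimeSeries":
        out = replace(self, values=self.values.copy(), meta=dict(self.meta))
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def with_values(self, values: np.ndarray, **meta) -> "TimeSeries":
        """New series sharing this time base but carrying ``values``."""
        out = self.copy()
        out.values = np.asarray(values, dtype=float)
        out.meta.update(meta)
        return out

    def slice_time(self, start: float, stop: float) -> "TimeSeries":
        """Samples with t in [start, stop)."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.n, int(np.ceil((stop - self.t0) * self.rate - 1e-9)))
        out = self.copy()
        out.values = self.values[i0:i1].copy()
        out.t0 = self.t0 + i0 / self.rate
        return out


@dataclass
class KinematicsTrace:
    """Aligned fictive-path velocities from the spherical treadmill.

    Channels share one time base.  All three are stored in deg/s; the
    translational channels can be viewed in mm/s via the ball radius.
    """

    v_r: TimeSeries
    v_s: TimeSeries
    v_f: TimeSeries

    def __post_init__(self) -> None:
        rates = {self.v_r.rate, self.v_s.rate, self.v_f.rate}
        if len(rates) != 1:
            raise ValueError("kinematic channels must share one rate")
        ns = {self.v_r.n, self.v_s.n, self.v_f.n}
        if len(ns) != 1:
            raise ValueError("kinematic channels must share one length")

    @property
    def rate(self) -> float:
        return self.v_r.rate

    @property
    def n(self) -> int:
        return self.v_r.n

    @property
    def t(self) -> np.ndarray:
        return self.v_r.t

    def channels(self) -> dict[str, TimeSeries]:
        return {"v_r": self.v_r, "v_s": self.v_s, "v_f": self.v_f}

    def v_s_mm(self) -> TimeSeries:
        return self.v_s.with_values(self.v_s.values * DEG_PER_S_TO_MM_PER_S).copy(units="mm/s")

    def v_f_mm(self) -> TimeSeries:
        return self.v_f.with_values(self.v_f.values * DEG_PER_S_TO_MM_PER_S).copy(units="mm/s")

    def map(self, fn) -> "KinematicsTrace":
        """Apply ``fn`` to each channel, returning a new trace."""
        return KinematicsTrace(v_r=fn(self.v_r), v_s=fn(self.v_s), v_f=fn(self.v_f))
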