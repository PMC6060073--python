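"""Electronic-rolling-shutter (ERS) timing and hyper-frame velocimetry.

Under an electronic rolling shutter each image row is exposed at its own
moment: row ``i`` starts ``i * dt`` after row 0, with ``dt`` a configurable
per-row offset.  Detections therefore carry a timestamp with sub-frame
granularity, and ``n`` exposure-distinct targets spread over a frame update
the scene information every ``1 / (n * f_P)`` seconds instead of the
global-shutter ``1 / f_P`` — down to the single-row interval ``dt`` when
every row holds a target.  Given a reference position for each particle,
its velocity follows from the finite difference of position over the row
timestamp difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExposureSchedule",
    "row_timestamp",
    "temporal_resolution",
    "ParticleTrack",
    "estimate_velocity",
    "hyperframe_velocities",
]


@dataclass(frozen=True)
class ExposureSchedule:
    """Per-row exposure timing of one frame.

    ``t0`` is the exposure start of row 0, ``dt`` the row-to-row offset,
    ``T_exp`` the exposure duration.  ``dt = 0`` degenerates to a global
    shutter (all rows simultaneous).  In seamless-readout mode the frame
    period equals the row offsets summed over the image: ``H * dt = 1/f_P``.
    """

    dt: float
    T_exp: float = 0.0
    t0: float = 0.0
    f_P: float | None = None
    H: int | None = None

    def __post_init__(self) -> None:
        if self.dt < 0:
            raise ValueError("row offset dt must be >= 0")
        if self.T_exp < 0:
            raise ValueError("exposure duration must be >= 0")

    @classmethod
    def seamless(cls, f_P: float, H: int, T_exp: float = 0.0,
                 t0: float = 0.0) -> "ExposureSchedule":
        """Schedule in which readout of frame k+1 starts as frame k ends."""
        return cls(dt=1.0 / (f_P * H), T_exp=T_exp, t0=t0, f_P=f_P, H=H)

    @classmethod
    def global_shutter(cls, f_P: float, T_exp: float = 0.0,
                       t0: float = 0.0) -> "ExposureSchedule":
        return cls(dt=0.0, T_exp=T_exp, t0=t0, f_P=f_P)

    @property
    def frame_period(self) -> float | None:
        return None if self.f_P is None else 1.0 / self.f_P


def row_timestamp(schedule: ExposureSchedule, i: float,
                  reference: str = "mid") -> float:
    """Exposure timestamp of row ``i`` (fractional rows allowed).

    ``reference='mid'`` (default) returns the exposure midpoint,
    ``'start'`` the exposure start.  Monotone non-decreasing in ``i``.
    """
    t = schedule.t0 + i * schedule.dt
    if reference == "mid":
        return t + schedule.T_exp / 2.0
    if reference == "start":
        return t
    raise ValueError("reference must be 'mid' or 'start'")


def temporal_resolution(f_P: float, n: int) -> tuple[float, float]:
    """Information-update intervals: global shutter vs hyper-frame.

    Returns ``(dT, dT_1D)`` where ``dT = 1/f_P`` is the frame-limited
    interval and ``dT_1D = dT / n`` the effective interval obtained from
    ``n`` exposure-distinct, evenly distributed targets in one ERS frame.
    """
    if f_P <= 0:
        raise ValueError("frame rate must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    dT = 1.0 / f_P
    return dT, dT / n


@dataclass
class ParticleTrack:
    """Velocity estimate of one particle relative to a reference epoch."""

    position: tuple[float, float]       # (x=row, y=col) at time t
    t: float
    reference: tuple[float, float]      # position at reference time t0
    t0: float
    velocity: tuple[float, float] | None  # (vx, vy) px/s; None if t == t0

    @property
    def defined(self) -> bool:
        return self.velocity is not None


def estimate_velocity(position, t: float, reference, t0: float
                      ) -> tuple[float, float] | None:
    """Finite-difference velocity; ``None`` when the epochs coincide."""
    dt = t - t0
    if dt == 0:
        return None
    return ((position[0] - reference[0]) / dt,
            (position[1] - reference[1]) / dt)


def hyperframe_velocities(observations, references) -> list[ParticleTrack]:
    """Per-particle velocities from ERS row timestamps.

    ``observations`` is a sequence of ``(x, y, t)`` detections (row, col,
    timestamp); ``references`` a sequence of ``(x, y, t0)`` reference
    positions — e.g. the detections of a previous frame, or the topmost
    particle's epoch.  Each observation is matched to the nearest
    reference by position.  A particle observed at its own reference epoch
    has an undefined velocity and is flagged, not dropped.
    """
    refs = np.asarray([(r[0], r[1]) for r in references], dtype=float)
    if refs.size == 0:
        raise ValueError("at least one reference position is required")
    tracks: list[ParticleTrack] = []
    for x, y, t in observations:
        d2 = (refs[:, 0] - x) ** 2 + (refs[:, 1] - y) ** 2
        k = int(np.argmin(d2))
        rx, ry, t0 = references[k]
        v = estimate_velocity((x, y), t, (rx, ry), t0)
        tracks.append(ParticleTrack(position=(x, y), t=t,
                                    reference=(rx, ry), t0=t0, velocity=v))
    return tracks
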