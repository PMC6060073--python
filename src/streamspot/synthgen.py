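"""Seeded synthetic scenes with the statistical structure of real sky tests.

Targets are Gaussian point-spread-function spots: a spot of total energy
``I0``, centre ``(x0, y0)`` and radius ``sigma`` contributes

    I(x, y) = I0 / (2 pi sigma^2) * exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2))

sampled at pixel centres (adequate for the ``sigma >= 0.5 px`` regime used
here; the sampled sum converges to ``I0`` as the patch grows).  Backgrounds
emulate the interference cases a night-sky detector must survive: a flat
floor, a clipped stray-light gradient, a low-frequency cloud field, and a
saturated-core disk ("moon") whose gray decays smoothly toward ~50 at the
rim.  Pixel defects are Bernoulli hot pixels, 3x3 dark (dead-pixel)
depressions, and additive Gaussian read noise; Poisson shot noise is not
modeled (a hook is left in :class:`NoiseSpec`).  All randomness comes from
the spec seed, so identical specs render byte-identical frames.

Axis convention: ``x`` is the row index, ``y`` the column index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .ers import ExposureSchedule

__all__ = [
    "PSFSpot",
    "NoiseSpec",
    "FlatBackground",
    "GradientBackground",
    "CloudBackground",
    "DiskBackground",
    "SceneSpec",
    "GroundTruth",
    "render_spot",
    "render_scene",
    "render_sequence",
]


@dataclass(frozen=True)
class PSFSpot:
    """One Gaussian-PSF target: total energy, sub-pixel centre, radius."""

    I0: float
    x0: float
    y0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.I0 <= 0 or self.sigma <= 0:
            raise ValueError("spot energy and sigma must be positive")

    @property
    def peak(self) -> float:
        """Gray value at the exact centre."""
        return self.I0 / (2.0 * math.pi * self.sigma ** 2)

    @classmethod
    def from_peak(cls, peak: float, x0: float, y0: float, sigma: float) -> "PSFSpot":
        return cls(I0=peak * 2.0 * math.pi * sigma ** 2, x0=x0, y0=y0, sigma=sigma)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise model: additive read noise plus impulse defects."""

    read_noise_sigma: float = 0.0
    hot_pixel_rate: float = 0.0
    hot_amplitude: float = 200.0
    dark_pixel_rate: float = 0.0
    dark_depth: float = 60.0
    dark_extent: int = 3          # dead points spread over dark_extent^2 pixels
    shot_noise: bool = False      # hook only; not modeled

    def __post_init__(self) -> None:
        for r in (self.hot_pixel_rate, self.dark_pixel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("impulse rates must lie in [0, 1]")
        if self.shot_noise:
            raise NotImplementedError("shot noise is a config hook only")


@dataclass(frozen=True)
class FlatBackground:
    level: float = 20.0


@dataclass(frozen=True)
class GradientBackground:
    """Clipped linear ramp (stray-light case), e.g. gray 120 -> 240."""

    low: float = 120.0
    high: float = 240.0
    axis: str = "y"  # ramp along columns by default

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("gradient axis must be 'x' or 'y'")


@dataclass(frozen=True)
class CloudBackground:
    """Seeded low-pass-filtered random field rescaled to a gray range."""

    low: float = 30.0
    high: float = 60.0
    scale_px: float = 24.0  # correlation length; >> L_bg so rows stay smooth


@dataclass(frozen=True)
class DiskBackground:
    """Saturated disk interferer with a smoothly decaying rim ("moon").

    Core at ``core_level`` (saturated), cosine decay to ``edge_level`` at
    radius ``radius``, then a soft roll-off to the ground level over
    ``soft_px`` pixels.  ``ground`` is the surrounding flat floor.
    """

    center: tuple[float, float] = (128.0, 128.0)  # (x=row, y=col)
    radius: float = 80.0
    core_level: float = 255.0
    edge_level: float = 50.0
    ground: float = 10.0
    core_fraction: float = 0.35
    soft_px: float = 6.0


Background = FlatBackground | GradientBackground | CloudBackground | DiskBackground


@dataclass(frozen=True)
class SceneSpec:
    """Generative description of one frame (or a static series)."""

    W: int = 128
    H: int = 128
    bitdepth: int = 8
    spots: tuple[PSFSpot, ...] = ()
    background: Background | tuple[Background, ...] = field(
        default_factory=FlatBackground)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.W < 1 or self.H < 1:
            raise ValueError("image dimensions must be positive")
        if self.bitdepth not in (8, 16):
            raise ValueError("bitdepth must be 8 or 16")
        for s in self.spots:
            if not (0 <= s.x0 < self.H and 0 <= s.y0 < self.W):
                raise ValueError("spot centres must lie inside the image")

    @property
    def saturation(self) -> int:
        return (1 << self.bitdepth) - 1

    @property
    def dtype(self):
        return np.uint8 if self.bitdepth == 8 else np.uint16


@dataclass
class GroundTruth:
    """What was actually rendered: spot table plus defect locations."""

    spots: pd.DataFrame            # spot_id, x, y, I0, sigma, peak
    hot_pixels: np.ndarray         # (k, 2) array of (row, col)
    dark_pixels: np.ndarray        # (k, 2) array of dark-patch centres


def render_spot(spot: PSFSpot, shape: tuple[int, int],
                radius_sigmas: float = 8.0) -> np.ndarray:
    """Render one spot into a float image of ``shape`` (H rows, W cols).

    The Gaussian is sampled at pixel centres within ``radius_sigmas *
    sigma`` of the centre; outside that window the contribution is
    negligible (the sampled sum over an 8-sigma window reproduces ``I0``
    to better than 0.1% for ``sigma >= 0.7``).
    """
    H, W = shape
    img = np.zeros((H, W), dtype=np.float64)
    r = radius_sigmas * spot.sigma
    x_lo = max(0, int(math.floor(spot.x0 - r)))
    x_hi = min(H, int(math.ceil(spot.x0 + r)) + 1)
    y_lo = max(0, int(math.floor(spot.y0 - r)))
    y_hi = min(W, int(math.ceil(spot.y0 + r)) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return img
    xs = np.arange(x_lo, x_hi, dtype=np.float64)[:, None]
    ys = np.arange(y_lo, y_hi, dtype=np.float64)[None, :]
    d2 = (xs - spot.x0) ** 2 + (ys - spot.y0) ** 2
    img[x_lo:x_hi, y_lo:y_hi] = spot.peak * np.exp(-d2 / (2.0 * spot.sigma ** 2))
    return img


def _render_background(bg: Background, shape: tuple[int, int],
                       rng: np.random.Generator) -> np.ndarray:
    H, W = shape
    if isinstance(bg, FlatBackground):
        return np.full(shape, float(bg.level))
    if isinstance(bg, GradientBackground):
        if bg.axis == "y":
            ramp = np.linspace(bg.low, bg.high, W)[None, :]
            return np.broadcast_to(ramp, shape).copy()
        ramp = np.linspace(bg.low, bg.high, H)[:, None]
        return np.broadcast_to(ramp, shape).copy()
    if isinstance(bg, CloudBackground):
        field_ = gaussian_filter(rng.standard_normal(shape), bg.scale_px,
                                 mode="nearest")
        lo, hi = field_.min(), field_.max()
        span = hi - lo if hi > lo else 1.0
        return bg.low + (field_ - lo) / span * (bg.high - bg.low)
    if isinstance(bg, DiskBackground):
        xs = np.arange(H, dtype=np.float64)[:, None]
        ys = np.arange(W, dtype=np.float64)[None, :]
        r = np.hypot(xs - bg.center[0], ys - bg.center[1])
        img = np.full(shape, float(bg.ground))
        r_core = bg.core_fraction * bg.radius
        rim = (r > r_core) & (r <= bg.radius)
        phase = (r[rim] - r_core) / (bg.radius - r_core)
        img[rim] = (bg.edge_level + (bg.core_level - bg.edge_level)
                    * 0.5 * (1.0 + np.cos(math.pi * phase)))
        img[r <= r_core] = bg.core_level
        soft = (r > bg.radius) & (r <= bg.radius + bg.soft_px)
        phase = (r[soft] - bg.radius) / bg.soft_px
        img[soft] = (bg.ground + (bg.edge_level - bg.ground)
                     * 0.5 * (1.0 + np.cos(math.pi * phase)))
        return img
    raise TypeError(f"unknown background spec: {bg!r}")


def render_scene(spec: SceneSpec,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame: background + spots + defects + read noise.

    Deterministic for a given ``(spec, seed)``; pass an external ``rng``
    to draw a frame series from one stream.  Returns the quantized frame
    (clamped to ``[0, saturation]``) and the ground truth.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    shape = (spec.H, spec.W)
    backgrounds = (spec.background if isinstance(spec.background, tuple)
                   else (spec.background,))
    img = np.zeros(shape, dtype=np.float64)
    for bg in backgrounds:
        img += _render_background(bg, shape, rng)
    for spot in spec.spots:
        img += render_spot(spot, shape)

    noise = spec.noise
    n_px = spec.H * spec.W
    hot = np.empty((0, 2), dtype=np.int64)
    dark = np.empty((0, 2), dtype=np.int64)
    if noise.hot_pixel_rate > 0:
        k = rng.binomial(n_px, noise.hot_pixel_rate)
        idx = rng.choice(n_px, size=k, replace=False)
        hot = np.column_stack(np.unravel_index(idx, shape))
        img[hot[:, 0], hot[:, 1]] += noise.hot_amplitude
    if noise.dark_pixel_rate > 0:
        k = rng.binomial(n_px, noise.dark_pixel_rate)
        idx = rng.choice(n_px, size=k, replace=False)
        dark = np.column_stack(np.unravel_index(idx, shape))
        half = noise.dark_extent // 2
        for r, c in dark:
            r0, r1 = max(0, r - half), min(spec.H, r + half + 1)
            c0, c1 = max(0, c - half), min(spec.W, c + half + 1)
            img[r0:r1, c0:c1] -= noise.dark_depth
    if noise.read_noise_sigma > 0:
        img += rng.normal(0.0, noise.read_noise_sigma, shape)

    frame = np.clip(np.rint(img), 0, spec.saturation).astype(spec.dtype)
    truth = GroundTruth(
        spots=pd.DataFrame(
            {"spot_id": np.arange(len(spec.spots)),
             "x": [s.x0 for s in spec.spots],
             "y": [s.y0 for s in spec.spots],
             "I0": [s.I0 for s in spec.spots],
             "sigma": [s.sigma for s in spec.spots],
             "peak": [s.peak for s in spec.spots]}),
        hot_pixels=hot,
        dark_pixels=dark,
    )
    return frame, truth


def _moving_spot(spot: PSFSpot, velocity: tuple[float, float],
                 frame_start: float, schedule: ExposureSchedule,
                 t_ref: float) -> tuple[PSFSpot, float]:
    """Position of a constant-velocity spot at its own row's exposure time.

    Under a rolling shutter the row that images the spot is itself a
    function of where the spot is when that row exposes; for linear motion
    the fixed point is closed-form:
    ``x* = (x0 + vx * (frame_start + T_exp/2 - t_ref)) / (1 - vx * dt)``.
    """
    vx, vy = velocity
    base = frame_start + schedule.T_exp / 2.0 - t_ref
    denom = 1.0 - vx * schedule.dt
    if denom <= 0:
        raise ValueError("spot outruns the rolling shutter (vx * dt >= 1)")
    x_star = (spot.x0 + vx * base) / denom
    t_star = frame_start + x_star * schedule.dt + schedule.T_exp / 2.0
    y_star = spot.y0 + vy * (t_star - t_ref)
    return replace(spot, x0=x_star, y0=y_star), t_star


def render_sequence(spec: SceneSpec, velocities, schedule: ExposureSchedule,
                    n_frames: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an ERS frame series with constant-velocity spots.

    ``velocities`` is one ``(vx, vy)`` pair (px/s) per spot in ``spec``;
    spot positions in ``spec`` are the true positions at the schedule
    epoch ``t0``.  Each spot is rendered where it stands at the exposure
    time of its own (fractional) row, so within a frame lower spots are
    displaced proportionally to their row index.  Returns the frame stack
    and a truth table with per-frame positions and row timestamps.
    """
    velocities = [tuple(v) for v in velocities]
    if len(velocities) != len(spec.spots):
        raise ValueError("need one velocity per spot")
    frame_period = (1.0 / schedule.f_P if schedule.f_P
                    else (schedule.H or spec.H) * schedule.dt)
    if frame_period <= 0:
        raise ValueError("schedule must define a positive frame period")
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((n_frames, spec.H, spec.W), dtype=spec.dtype)
    rows = []
    for k in range(n_frames):
        frame_start = schedule.t0 + k * frame_period
        moved = []
        for sid, (spot, v) in enumerate(zip(spec.spots, velocities)):
            mspot, t_star = _moving_spot(spot, v, frame_start, schedule,
                                         schedule.t0)
            moved.append(mspot)
            rows.append({"frame": k, "spot_id": sid, "x": mspot.x0,
                         "y": mspot.y0, "t": t_star, "vx": v[0], "vy": v[1]})
        frame_spec = replace(spec, spots=tuple(moved))
        frames[k], _ = render_scene(frame_spec, rng)
    return frames, pd.DataFrame(rows)
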