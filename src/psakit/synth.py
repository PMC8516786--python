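"""Synthetic gaze/pupil traces and rendered eye images with ground truth.

The trace generator emulates the standard PSA measurement: a luminance
stimulus modulated sinusoidally at 0.125 Hz drives the pupil diameter over a
160 s trial (20 cycles of 8 s) while the participant fixates, and the
recorded gaze deviation contains a component proportional to the
pupil-diameter change (the injected artefact slope, deg/mm) plus noise.
Blinks appear as Poisson-scheduled runs of missing data flanked by fast
linear pupil transients, which is what the velocity filter must remove.

The image renderer produces the kind of frame a pupil-minus-CR eye tracker
sees: a dark pupil disk on a mid-grey iris with bright corneal-reflection
spots (six by default, two rows of three, as produced by a six-LED
illuminator), anti-aliased by 4x supersampling, with exact sub-pixel ground
truth for every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import SignalTrace

__all__ = [
    "TraceGenConfig",
    "TraceGroundTruth",
    "ImageGenConfig",
    "ImageGroundTruth",
    "gen_trace",
    "gen_viewing_grid",
    "render_eye_image",
]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceGenConfig:
    """Study conditions for one synthetic PSA trial.

    Defaults mirror the measurement protocol: 1000 Hz sampling, 160 s
    presentation, 0.125 Hz sinusoidal pupil modulation between 2.5 and
    5.5 mm, gaze-deviation noise of 0.1 deg SD, and about twelve blinks per
    minute of 150 ms each with 15 mm/s pupil transients on both flanks.
    ``injected_slope`` (deg/mm) and ``injected_offset`` (deg) define the
    artefact to be recovered; the deviation is referenced to the pupil
    diameter ``d_ref`` (the calibration pupil).
    """

    rate: float = 1000.0  # Hz
    duration: float = 160.0  # s
    f_pupil: float = 0.125  # Hz
    pupil_mean: float = 4.0  # mm
    pupil_amp: float = 1.5  # mm
    injected_slope: float = -0.3  # deg/mm
    injected_offset: float = 0.0  # deg
    d_ref: float = 4.0  # mm
    noise_sd: float = 0.1  # deg
    blink_rate: float = 12.0  # per minute
    blink_duration: float = 150.0  # ms
    transient_slope: float = 15.0  # mm/s
    transient_depth: float = 1.0  # mm of pupil dip on each blink flank
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rate, self.duration, self.f_pupil) <= 0:
            raise ValueError("rate, duration and f_pupil must be positive")
        if self.pupil_mean - self.pupil_amp <= 0:
            raise ValueError("pupil_mean - pupil_amp must stay positive")
        if self.noise_sd < 0 or self.blink_rate < 0:
            raise ValueError("noise_sd and blink_rate must be non-negative")
        if self.blink_duration <= 0 or self.transient_slope <= 0:
            raise ValueError("blink_duration and transient_slope must be "
                             "positive")


@dataclass(frozen=True)
class TraceGroundTruth:
    """What the generator actually injected into one trace."""

    slope: float  # deg/mm
    offset: float  # deg
    d_ref: float  # mm
    blink_intervals: tuple[tuple[int, int], ...]  # [start, stop) sample idx
    transient_intervals: tuple[tuple[int, int], ...]  # incl. flanking ramps
    config: TraceGenConfig = field(repr=False, default=None)


def gen_trace(cfg: TraceGenConfig | None = None,
              ) -> tuple[SignalTrace, TraceGroundTruth]:
    """Generate one synthetic trial trace plus its ground-truth record.

    The pupil follows ``pupil_mean + pupil_amp * sin(2 pi f t)``; the
    horizontal deviation is ``offset + slope * (pupil - d_ref)`` plus white
    Gaussian noise (the vertical component is noise only).  Blinks are
    Poisson-scheduled gaps of ``blink_duration`` during which all channels
    are missing, flanked by linear pupil ramps of ``transient_depth`` mm at
    ``transient_slope`` mm/s.  Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or TraceGenConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    pupil = cfg.pupil_mean + cfg.pupil_amp * np.sin(2 * np.pi * cfg.f_pupil * t)
    dev_h = cfg.injected_offset + cfg.injected_slope * (pupil - cfg.d_ref)
    dev_v = np.zeros(n)
    if cfg.noise_sd > 0:
        dev_h = dev_h + rng.normal(0.0, cfg.noise_sd, n)
        dev_v = dev_v + rng.normal(0.0, cfg.noise_sd, n)

    valid = np.ones(n, dtype=bool)
    blink_iv: list[tuple[int, int]] = []
    trans_iv: list[tuple[int, int]] = []
    if cfg.blink_rate > 0:
        gap = int(round(cfg.blink_duration * cfg.rate / 1000.0))
        ramp = int(round(cfg.transient_depth / cfg.transient_slope * cfg.rate))
        n_blinks = rng.poisson(cfg.blink_rate * cfg.duration / 60.0)
        starts = np.sort(rng.uniform(0, cfg.duration, n_blinks))
        last_end = 0
        for s in starts:
            i0 = int(round(s * cfg.rate))
            if i0 - ramp <= last_end + 1 or i0 + gap + ramp >= n:
                continue  # drop blinks that would overlap or run off the end
            down = slice(i0 - ramp, i0)
            up = slice(i0 + gap, i0 + gap + ramp)
            k = np.arange(1, ramp + 1)
            pupil[down] = pupil[i0 - ramp - 1] - cfg.transient_slope * k / cfg.rate
            pupil[up] = pupil[i0 + gap + ramp] - cfg.transient_slope * k[::-1] / cfg.rate
            valid[i0:i0 + gap] = False
            blink_iv.append((i0, i0 + gap))
            trans_iv.append((i0 - ramp, i0 + gap + ramp))
            last_end = i0 + gap + ramp
    dev_h[~valid] = np.nan
    dev_v[~valid] = np.nan
    pupil[~valid] = np.nan

    trace = SignalTrace(t=t, dev_h=dev_h, dev_v=dev_v, pupil=pupil,
                        valid=valid, rate=cfg.rate, pupil_unit="mm")
    truth = TraceGroundTruth(slope=cfg.injected_slope,
                             offset=cfg.injected_offset,
                             d_ref=cfg.d_ref,
                             blink_intervals=tuple(blink_iv),
                             transient_intervals=tuple(trans_iv),
                             config=cfg)
    return trace, truth


def gen_viewing_grid(max_angle: float = 12.0, step: float = 3.0,
                     ) -> np.ndarray:
    """Viewing-direction grid: -max..max in ``step`` increments, 0 excluded.

    With the defaults this is the eight directions -12, -9, -6, -3, 3, 6, 9,
    12 degrees (the center direction is excluded because a frontally placed
    camera occludes it).
    """
    if max_angle <= 0 or step <= 0:
        raise ValueError("max_angle and step must be positive")
    grid = np.arange(-max_angle, max_angle + step / 2, step)
    return grid[np.abs(grid) > 1e-12]


# ---------------------------------------------------------------------------
# eye images
# ---------------------------------------------------------------------------


def _default_cr_positions(width: int, height: int,
                          pupil_center: tuple[float, float],
                          ) -> tuple[tuple[float, float], ...]:
    """Six CR spots in two rows of three, straddling the pupil center."""
    cx, cy = pupil_center
    dx = width * 0.12
    dy = height * 0.14
    return tuple((cx + j * dx, cy + i * dy)
                 for i in (-1, 1) for j in (-1, 0, 1))


@dataclass(frozen=True)
class ImageGenConfig:
    """Geometry and photometry of one rendered eye frame.

    The pupil must be darker than the iris and the corneal reflections
    brighter; intensities are 8-bit.  ``cr_positions=None`` places six spots
    in two rows of three around the pupil center.
    """

    width: int = 320
    height: int = 240
    iris_gray: int = 120
    pupil_gray: int = 20
    cr_gray: int = 250
    pupil_center: tuple[float, float] = (160.0, 120.0)
    pupil_radius: float = 40.0
    cr_positions: tuple[tuple[float, float], ...] | None = None
    cr_sigma: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.pupil_gray < self.iris_gray < self.cr_gray <= 255:
            raise ValueError("need pupil_gray < iris_gray < cr_gray in 0..255")
        if self.pupil_radius <= 0 or self.cr_sigma <= 0:
            raise ValueError("pupil_radius and cr_sigma must be positive")

    def resolved_cr_positions(self) -> tuple[tuple[float, float], ...]:
        if self.cr_positions is not None:
            return self.cr_positions
        return _default_cr_positions(self.width, self.height,
                                     self.pupil_center)


@dataclass(frozen=True)
class ImageGroundTruth:
    """Exact sub-pixel feature geometry of a rendered frame."""

    pupil_center: tuple[float, float]
    pupil_radius: float
    cr_centers: tuple[tuple[float, float], ...]
    config: ImageGenConfig = field(repr=False, default=None)


def render_eye_image(cfg: ImageGenConfig | None = None,
                     ) -> tuple[np.ndarray, ImageGroundTruth]:
    """Render one 8-bit grayscale eye frame plus its ground truth.

    The pupil disk is anti-aliased by 4x supersampling (each pixel averages a
    4x4 subgrid); CR spots have Gaussian profiles of ``cr_sigma`` px added on
    top, clipped to 8-bit; optional white pixel noise.  Pixel centers sit at
    integer coordinates, x rightward, y downward.  Deterministic for a given
    seed.

    Raises
    ------
    ValueError
        If the pupil or any CR lies (partly) outside the frame.
    """
    cfg = cfg or ImageGenConfig()
    cx, cy = cfg.pupil_center
    r = cfg.pupil_radius
    crs = cfg.resolved_cr_positions()
    if not (r <= cx <= cfg.width - 1 - r and r <= cy <= cfg.height - 1 - r):
        raise ValueError("pupil disk extends outside the frame")
    for x, y in crs:
        if not (0 <= x <= cfg.width - 1 and 0 <= y <= cfg.height - 1):
            raise ValueError("a CR position lies outside the frame")

    ss = 4
    # supersampled pixel-center coordinates: pixel i covers [i-0.5, i+0.5)
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(cfg.width)[:, None] + sub[None, :]).ravel()
    ys = (np.arange(cfg.height)[:, None] + sub[None, :]).ravel()
    inside = ((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) <= r * r
    cover = inside.reshape(cfg.height, ss, cfg.width, ss).mean(axis=(1, 3))
    img = cfg.iris_gray + (cfg.pupil_gray - cfg.iris_gray) * cover

    xg = np.arange(cfg.width)[None, :]
    yg = np.arange(cfg.height)[:, None]
    for x, y in crs:
        # specular highlight: blend towards cr_gray so the peak hits cr_gray
        # whether the spot falls on iris or pupil
        w = np.exp(-((xg - x) ** 2 + (yg - y) ** 2)
                   / (2.0 * cfg.cr_sigma ** 2))
        img = img + (cfg.cr_gray - img) * w
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = ImageGroundTruth(pupil_center=(float(cx), float(cy)),
                             pupil_radius=float(r),
                             cr_centers=tuple((float(x), float(y))
                                              for x, y in crs),
                             config=cfg)
    return img, truth
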