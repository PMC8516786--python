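"""Quantifying the pupil-size artefact from gaze/pupil time series.

The pupil-size artefact (PSA) is the apparent gaze deviation a pupil-based
eye tracker reports when the pupil changes size while the eye does not
rotate.  Given a trace of calibrated gaze deviation (degrees) and pupil
diameter recorded while a luminance stimulus slowly drives the pupil, the
artefact is summarised by

1. removing fast pupil episodes (blinks and their flanks) with a
   velocity-threshold filter,
2. subtracting the per-trial median deviation,
3. collapsing the (pupil, deviation) joint distribution onto seven points —
   the 2nd through 8th pupil-size deciles versus the mean deviation of the
   samples around each decile — and
4. fitting a line through those points.  The slope, in degrees per
   millimetre of pupil enlargement, is the PSA measure.

:class:`PSAModel` wraps steps 1-4 behind a ``fit()`` returning a
:class:`PSAResults`; every step is also available as a standalone function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

__all__ = [
    "SignalTrace",
    "FilterConfig",
    "FilterStats",
    "PsaCurve",
    "PSAModel",
    "PSAResults",
    "pupil_velocity",
    "mask_fast_segments",
    "filter_trace",
    "data_loss_proportion",
    "median_center",
    "decile_curve",
    "fit_slope",
    "convert_pupil_units",
    "foreshortening_factor",
    "pupil_underestimation_percent",
]

Component = Literal["horizontal", "vertical"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled gaze-deviation / pupil-size time series.

    Invalid samples (``valid == False``) carry NaN in ``dev_h``, ``dev_v``
    and ``pupil``.  ``pupil_unit`` is ``"mm"`` after conversion, otherwise
    ``"au"`` (arbitrary units).
    """

    t: np.ndarray  # seconds
    dev_h: np.ndarray  # degrees
    dev_v: np.ndarray  # degrees
    pupil: np.ndarray
    valid: np.ndarray  # bool
    rate: float  # Hz
    pupil_unit: str = "mm"
    # filter bookkeeping (pre-padding invalid core, threshold) so that
    # re-filtering an already-filtered trace is a no-op
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("dev_h", "dev_v", "pupil", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match t")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
                raise ValueError("t is not uniform at the stated rate")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples at the stated rate)."""
        return len(self) / self.rate

    @classmethod
    def from_arrays(cls, t, dev_h, dev_v, pupil, valid=None, rate=None,
                    pupil_unit="mm") -> "SignalTrace":
        t = np.asarray(t, dtype=float)
        dev_h = np.asarray(dev_h, dtype=float).copy()
        dev_v = np.asarray(dev_v, dtype=float).copy()
        pupil = np.asarray(pupil, dtype=float).copy()
        if valid is None:
            valid = ~(np.isnan(dev_h) | np.isnan(dev_v) | np.isnan(pupil))
        valid = np.asarray(valid, dtype=bool)
        if rate is None:
            if t.size < 2:
                raise ValueError("cannot infer rate from fewer than 2 samples")
            rate = 1.0 / float(np.median(np.diff(t)))
        for a in (dev_h, dev_v, pupil):
            a[~valid] = np.nan
        return cls(t=t, dev_h=dev_h, dev_v=dev_v, pupil=pupil, valid=valid,
                   rate=float(rate), pupil_unit=pupil_unit)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate: float | None = None,
                       pupil_unit: str = "mm") -> "SignalTrace":
        """Build a trace from a ``t_s, dev_h_deg, dev_v_deg, pupil, valid``
        DataFrame (the on-disk CSV layout)."""
        required = {"t_s", "dev_h_deg", "dev_v_deg", "pupil"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing trace columns: {sorted(missing)}")
        valid = (df["valid"].fillna(0).astype(float).to_numpy() > 0
                 if "valid" in df.columns else None)
        return cls.from_arrays(df["t_s"].to_numpy(float),
                               df["dev_h_deg"].to_numpy(float),
                               df["dev_v_deg"].to_numpy(float),
                               df["pupil"].to_numpy(float),
                               valid=valid, rate=rate, pupil_unit=pupil_unit)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "dev_h_deg": self.dev_h,
            "dev_v_deg": self.dev_v,
            "pupil": self.pupil,
            "valid": self.valid.astype(int),
        })

    def component(self, which: Component) -> np.ndarray:
        if which == "horizontal":
            return self.dev_h
        if which == "vertical":
            return self.dev_v
        raise ValueError("component must be 'horizontal' or 'vertical'")


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the fast-pupil-episode filter.

    ``velocity_window`` is the half-window (ms) of the difference-of-means
    differentiator; samples whose pupil velocity exceeds the mean by more
    than ``sd_multiplier`` standard deviations are invalidated, and every
    run of missing data is then widened by ``gap_pad`` ms on each side.
    """

    velocity_window: float = 20.0  # ms
    sd_multiplier: float = 2.0
    gap_pad: float = 20.0  # ms

    def __post_init__(self) -> None:
        if min(self.velocity_window, self.sd_multiplier, self.gap_pad) <= 0:
            raise ValueError("all filter parameters must be positive")

    def window_samples(self, rate: float) -> int:
        return max(1, int(round(self.velocity_window * rate / 1000.0)))

    def pad_samples(self, rate: float) -> int:
        return int(round(self.gap_pad * rate / 1000.0))


@dataclass(frozen=True)
class FilterStats:
    """Audit record of one filtering pass."""

    velocity_mean: float
    velocity_sd: float
    threshold: float
    n_masked_velocity: int
    n_masked_pad: int
    n_invalid_before: int
    n_invalid_after: int


@dataclass(frozen=True)
class PsaCurve:
    """Seven-point decile summary of deviation versus pupil size.

    ``decile_x`` holds the 2nd-8th pupil-size deciles (mm), ``mean_dev_y``
    the mean deviation (degrees) of the samples around each decile, and
    ``slope``/``intercept`` the least-squares line through the seven points.
    """

    decile_x: np.ndarray  # mm, 7 values, non-decreasing
    mean_dev_y: np.ndarray  # degrees, 7 values
    slope: float  # deg/mm
    intercept: float  # degrees

    def __post_init__(self) -> None:
        if self.decile_x.size != 7 or self.mean_dev_y.size != 7:
            raise ValueError("a PSA curve has exactly seven points")
        if np.any(np.diff(self.decile_x) < 0):
            raise ValueError("decile_x must be non-decreasing")

    def __len__(self) -> int:
        return 7


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def pupil_velocity(trace: SignalTrace,
                   cfg: FilterConfig | None = None) -> np.ndarray:
    """Pupil-size velocity by a difference-of-window-means differentiator.

    For window length ``w`` samples, the velocity at sample ``i`` is the mean
    pupil size over ``[i+1, i+w]`` minus the mean over ``[i-w, i-1]``,
    divided by the ``(w+1)/rate`` separation of the window centers.  Exact
    for linear ramps; attenuates high frequencies.  Missing input samples
    (and incomplete edge windows) yield NaN.
    """
    cfg = cfg or FilterConfig()
    w = cfg.window_samples(trace.rate)
    if len(trace) < 2 * w + 1:
        raise ValueError(f"trace shorter than the velocity window "
                         f"(need >= {2 * w + 1} samples)")
    p = pd.Series(trace.pupil)
    roll = p.rolling(window=w, min_periods=w).mean()
    before = roll.shift(1)
    after = roll.shift(-w)
    sep = (w + 1) / trace.rate
    v = ((after - before) / sep).to_numpy()
    v[np.isnan(trace.pupil)] = np.nan
    return v


def mask_fast_segments(trace: SignalTrace, velocity: np.ndarray,
                       cfg: FilterConfig | None = None,
                       threshold: float | None = None,
                       _stats_out: dict | None = None) -> SignalTrace:
    """Invalidate fast-pupil samples, then pad every missing-data run.

    First, samples whose velocity exceeds ``mean + sd_multiplier * SD``
    (strict; statistics over the defined velocities, or a pre-computed
    ``threshold``) are invalidated.  Second, each contiguous run of invalid
    samples is extended by ``gap_pad`` ms (rounded to whole samples) on each
    side — in that order.

    The pre-padding invalid core and the threshold are stored on the
    returned trace, so filtering an already-filtered trace with the stored
    threshold invalidates nothing further.
    """
    cfg = cfg or FilterConfig()
    if velocity.shape != trace.t.shape:
        raise ValueError("velocity is not aligned with the trace")
    defined = ~np.isnan(velocity)
    if threshold is None:
        if defined.any():
            mu = float(np.mean(velocity[defined]))
            sd = float(np.std(velocity[defined]))
        else:
            mu = sd = float("nan")
        threshold = mu + cfg.sd_multiplier * sd
    else:
        mu = sd = float("nan")
    with np.errstate(invalid="ignore"):
        fast = velocity > threshold  # strict; NaN compares False
    prior_core = trace.meta.get("core_invalid", ~trace.valid)
    core = prior_core | fast
    n_fast = int(np.count_nonzero(fast & trace.valid))
    pad = cfg.pad_samples(trace.rate)
    padded = binary_dilation(core, structure=np.ones(3, bool),
                             iterations=pad) if pad > 0 else core
    padded = padded | ~trace.valid
    if _stats_out is not None:
        _stats_out.update(velocity_mean=mu, velocity_sd=sd,
                          threshold=float(threshold),
                          n_masked_velocity=n_fast,
                          n_masked_pad=int(np.count_nonzero(
                              padded & ~core & trace.valid)),
                          n_invalid_before=int(np.count_nonzero(~trace.valid)),
                          n_invalid_after=int(np.count_nonzero(padded)))
    valid = ~padded
    out = {k: getattr(trace, k).copy() for k in ("dev_h", "dev_v", "pupil")}
    for a in out.values():
        a[padded] = np.nan
    return replace(trace, valid=valid,
                   meta={"core_invalid": core, "threshold": float(threshold)},
                   **out)


def filter_trace(trace: SignalTrace, cfg: FilterConfig | None = None,
                 ) -> tuple[SignalTrace, FilterStats]:
    """Velocity computation plus masking in one pass, with an audit record."""
    cfg = cfg or FilterConfig()
    v = pupil_velocity(trace, cfg)
    stats: dict = {}
    filtered = mask_fast_segments(trace, v, cfg, _stats_out=stats)
    return filtered, FilterStats(**stats)


def data_loss_proportion(trace: SignalTrace) -> float:
    """Fraction of invalid (empty) samples in the trace."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(np.count_nonzero(~trace.valid)) / len(trace)


def median_center(trace: SignalTrace) -> SignalTrace:
    """Subtract the median (over valid samples) from each deviation component.

    The pupil signal is untouched.  Traces recorded in separate trials become
    comparable once their median deviation is removed.
    """
    out = {}
    for name in ("dev_h", "dev_v"):
        a = getattr(trace, name).copy()
        if trace.valid.any():
            a = a - np.nanmedian(a[trace.valid])
        out[name] = a
    return replace(trace, **out)


# ---------------------------------------------------------------------------
# decile curve and slope
# ---------------------------------------------------------------------------


def fit_slope(x, y) -> tuple[float, float]:
    """Unweighted least-squares line through points; returns (slope, intercept).

    Units follow the inputs: deg/mm and degrees for a PSA curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points to fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def decile_curve(trace: SignalTrace,
                 component: Component = "horizontal") -> PsaCurve:
    """Seven-point decile summary of one deviation component.

    The x-values are the empirical 2nd-8th deciles of pupil size over the
    valid samples; each y-value is the mean deviation of the samples whose
    pupil size falls in the half-decile band around that decile, i.e. in
    ``[Q((k-0.5)/10), Q((k+0.5)/10))`` for decile ``k``.  Every sample
    between Q(0.15) and Q(0.85) therefore contributes to exactly one point.
    """
    if trace.pupil_unit != "mm":
        raise ValueError("pupil must be in mm; see convert_pupil_units")
    dev = trace.component(component)
    m = trace.valid & ~np.isnan(dev) & ~np.isnan(trace.pupil)
    p = trace.pupil[m]
    d = dev[m]
    if p.size < 20:
        raise ValueError("need at least 20 valid samples for a decile curve")
    ks = np.arange(2, 9)
    x = np.quantile(p, ks / 10.0)
    edges = np.quantile(p, (np.arange(2, 10) - 0.5) / 10.0)
    y = np.empty(7)
    for j, k in enumerate(ks):
        band = (p >= edges[j]) & (p < edges[j + 1])
        if not band.any():
            raise ValueError(f"empty pupil band for decile {k} "
                             f"([{edges[j]:.4g}, {edges[j + 1]:.4g}))")
        y[j] = d[band].mean()
    slope, intercept = fit_slope(x, y)
    return PsaCurve(decile_x=x, mean_dev_y=y, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# unit helpers
# ---------------------------------------------------------------------------


def convert_pupil_units(trace: SignalTrace, mm_per_unit: float) -> SignalTrace:
    """Scale the pupil signal to millimetres by an offline-calibrated ratio."""
    if mm_per_unit <= 0:
        raise ValueError("mm_per_unit must be positive")
    return replace(trace, pupil=trace.pupil * mm_per_unit, pupil_unit="mm")


def foreshortening_factor(angle_deg: float) -> float:
    """Pupil foreshortening factor 1/cos(angle) at a given viewing angle.

    The camera sees a pupil rotated by ``angle`` away from its axis
    foreshortened by cos(angle); multiplying the measured size by this factor
    undoes that.
    """
    return 1.0 / math.cos(math.radians(angle_deg))


def pupil_underestimation_percent(angle_deg: float) -> float:
    """Percent underestimation of pupil size, (1 - cos(angle)) * 100."""
    return (1.0 - math.cos(math.radians(angle_deg))) * 100.0


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PSAModel:
    """Pupil-size-artefact model for one gaze/pupil trace.

    Fits the linear deviation-versus-pupil-size relation through the
    standard pipeline: velocity filter, median centering, seven-point
    decile curve, least-squares slope.

    Parameters
    ----------
    trace
        The raw :class:`SignalTrace` (pupil in mm).
    component
        Which deviation component to quantify.
    filter_config
        Fast-episode filter settings; ``None`` uses the defaults
        (20 ms window, 2 SD, 20 ms pad).
    center
        Subtract the median deviation before building the curve.

    Examples
    --------
    >>> model = PSAModel(trace)           # doctest: +SKIP
    >>> res = model.fit()                 # doctest: +SKIP
    >>> print(res.summary())              # doctest: +SKIP
    """

    def __init__(self, trace: SignalTrace,
                 component: Component = "horizontal",
                 filter_config: FilterConfig | None = None,
                 center: bool = True):
        self.trace = trace
        self.component: Component = component
        self.filter_config = filter_config or FilterConfig()
        self.center = center

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate: float | None = None,
                       mm_per_unit: float | None = None,
                       **kwargs) -> "PSAModel":
        """Build the model from a trace DataFrame (CSV column layout);
        ``mm_per_unit`` applies the pupil unit conversion first."""
        unit = "mm" if mm_per_unit is None else "au"
        trace = SignalTrace.from_dataframe(df, rate=rate, pupil_unit=unit)
        if mm_per_unit is not None:
            trace = convert_pupil_units(trace, mm_per_unit)
        return cls(trace, **kwargs)

    def fit(self) -> "PSAResults":
        filtered, stats = filter_trace(self.trace, self.filter_config)
        if self.center:
            filtered = median_center(filtered)
        curve = decile_curve(filtered, self.component)
        return PSAResults(model=self, filtered_trace=filtered, curve=curve,
                          filter_stats=stats)


@dataclass
class PSAResults:
    """Fitted PSA estimate with diagnostics.

    Attributes
    ----------
    slope, intercept
        The PSA line through the decile curve (deg/mm, degrees).
    slope_se, intercept_se
        Standard errors from the residuals of the seven-point fit.
    data_loss
        Proportion of invalid samples after filtering.
    """

    model: PSAModel
    filtered_trace: SignalTrace
    curve: PsaCurve
    filter_stats: FilterStats
    _se: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def slope(self) -> float:
        return self.curve.slope

    @property
    def intercept(self) -> float:
        return self.curve.intercept

    def _standard_errors(self) -> tuple[float, float]:
        if self._se is None:
            x, y = self.curve.decile_x, self.curve.mean_dev_y
            resid = y - (self.curve.slope * x + self.curve.intercept)
            dof = x.size - 2
            s2 = float(resid @ resid) / dof
            sxx = float(np.sum((x - x.mean()) ** 2))
            slope_se = math.sqrt(s2 / sxx) if sxx > 0 else float("nan")
            int_se = (math.sqrt(s2 * (1.0 / x.size + x.mean() ** 2 / sxx))
                      if sxx > 0 else float("nan"))
            object.__setattr__(self, "_se", (slope_se, int_se))
        return self._se

    @property
    def slope_se(self) -> float:
        return self._standard_errors()[0]

    @property
    def intercept_se(self) -> float:
        return self._standard_errors()[1]

    @property
    def data_loss(self) -> float:
        return data_loss_proportion(self.filtered_trace)

    def summary(self) -> str:
        fs = self.filter_stats
        lines = [
            "Pupil-size artefact fit",
            "=" * 46,
            f"component        : {self.model.component}",
            f"samples          : {len(self.model.trace)} @ "
            f"{self.model.trace.rate:g} Hz",
            f"data loss        : {self.data_loss:.4f}",
            f"velocity thresh  : {fs.threshold:.6g} "
            f"(mean {fs.velocity_mean:.6g}, sd {fs.velocity_sd:.6g})",
            f"masked: velocity {fs.n_masked_velocity}, "
            f"pad {fs.n_masked_pad}",
            "",
            f"slope            : {self.slope:+.4f} deg/mm "
            f"(SE {self.slope_se:.4f})",
            f"intercept        : {self.intercept:+.4f} deg "
            f"(SE {self.intercept_se:.4f})",
            "",
            f"{'decile':>8} {'pupil [mm]':>12} {'deviation [deg]':>16}",
        ]
        for k, (x, y) in enumerate(zip(self.curve.decile_x,
                                       self.curve.mean_dev_y), start=2):
            lines.append(f"{k:>8d} {x:>12.4f} {y:>16.4f}")
        return "\n".join(lines)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "decile": np.arange(2, 9),
            "pupil_mm": self.curve.decile_x,
            "mean_deviation_deg": self.curve.mean_dev_y,
        })

    def plot(self, ax=None):
        """Decile curve with the fitted PSA line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.curve.decile_x, self.curve.mean_dev_y
        ax.plot(x, y, "o-", label="decile curve")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, self.slope * xs + self.intercept, "--",
                label=f"slope {self.slope:+.3f} deg/mm")
        ax.set_xlabel("pupil diameter [mm]")
        ax.set_ylabel(f"{self.model.component} deviation [deg]")
        ax.legend()
        return ax
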