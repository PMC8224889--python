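"""Time-series container and pre-treatment operations.

All estimation in this package operates on pairs of uniformly sampled,
real-valued signals (e.g. a neuronal calcium trace as input and a red
blood cell velocity trace as output). This module provides the immutable
:class:`TimeSeries` container and the pre-treatment steps applied before
transfer-function computation: cropping, median filtering (outlier
removal), Savitzky-Golay smoothing, linear resampling to a common
sampling interval, and boxcar stimulus construction.

Every operation returns a new series; inputs are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.signal

__all__ = [
    "TimeSeries",
    "PretreatmentConfig",
    "resample",
    "crop",
    "savgol_smooth",
    "median_filter",
    "boxcar",
    "pretreat",
]

#: Relative tolerance used to decide whether a time grid is uniform:
#: the maximum deviation of successive steps must be < UNIFORM_RTOL * dt.
UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """A real-valued signal sampled at strictly increasing time stamps.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing, length >= 2.
    values : array-like of float
        Signal values (arbitrary real units), same length as ``times``,
        all finite.

    Notes
    -----
    The arrays are copied and frozen (``writeable = False``) so a series
    can be shared safely between operations. ``dt`` is defined only when
    the grid is uniform within a relative tolerance of ``1e-6 * dt``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.array(self.times, dtype=np.float64, copy=True)
        v = np.array(self.values, dtype=np.float64, copy=True)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.shape != v.shape:
            raise ValueError(
                f"length mismatch: {t.size} times vs {v.size} values"
            )
        if t.size < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(t)):
            raise ValueError("time stamps must all be finite")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must all be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        t.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        """Total duration covered by the series, in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def is_uniform(self) -> bool:
        """True when successive steps agree within ``UNIFORM_RTOL``."""
        steps = np.diff(self.times)
        step = float(np.median(steps))
        return bool(np.max(np.abs(steps - step)) < UNIFORM_RTOL * step)

    @property
    def dt(self) -> Optional[float]:
        """Sampling interval in seconds, or None for non-uniform grids."""
        if not self.is_uniform:
            return None
        return float(np.median(np.diff(self.times)))

    def require_dt(self) -> float:
        """Return ``dt`` or raise if the grid is not uniform."""
        dt = self.dt
        if dt is None:
            raise ValueError(
                "series is not uniformly sampled; resample it to a fixed "
                "time interval first"
            )
        return dt


@dataclass(frozen=True)
class PretreatmentConfig:
    """Pre-treatment settings applied before TF computation.

    Steps run in the order crop -> median filter -> Savitzky-Golay ->
    resample, so that outliers are removed before smoothing and the
    filters see the raw sampling (interpolation comes last). Each step
    is optional; an unset field skips it.
    """

    dt: Optional[float] = None
    crop_start: Optional[float] = None
    crop_end: Optional[float] = None
    savgol_window: Optional[int] = None
    savgol_order: int = 2
    median_window: Optional[int] = None
    boxcar: Optional[Tuple[float, float]] = None  # (onset s, duration s)

    def __post_init__(self) -> None:
        if self.savgol_window is not None:
            if self.savgol_window % 2 == 0:
                raise ValueError("savgol_window must be odd")
            if self.savgol_order >= self.savgol_window:
                raise ValueError("savgol_order must be < savgol_window")
        if self.savgol_order < 0:
            raise ValueError("savgol_order must be >= 0")
        if self.median_window is not None and self.median_window % 2 == 0:
            raise ValueError("median_window must be odd")
        if self.crop_start is not None and self.crop_end is not None:
            if not self.crop_start < self.crop_end:
                raise ValueError("crop_start must be < crop_end")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


def resample(ts: TimeSeries, dt: float) -> TimeSeries:
    """Linearly interpolate a series onto a uniform grid of step ``dt``.

    The new grid starts at ``ts.times[0]`` and extends in exact steps of
    ``dt`` up to (at most) ``ts.times[-1]``. Linear interpolation is
    exact on straight-line signals and introduces no overshoot.

    If the series is already on a uniform grid with the requested step,
    it is returned unchanged (same sample values, bitwise).
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > ts.span:
        raise ValueError(
            f"dt={dt} exceeds the series span of {ts.span} s; "
            "resampling would leave fewer than 2 samples"
        )
    existing = ts.dt
    if existing is not None and abs(existing - dt) < UNIFORM_RTOL * dt:
        return TimeSeries(ts.times, ts.values)
    # +tiny guards against float drop-off when the span is an exact multiple
    n = int(np.floor(ts.span / dt * (1 + 1e-12))) + 1
    new_times = ts.times[0] + dt * np.arange(n)
    new_values = np.interp(new_times, ts.times, ts.values)
    return TimeSeries(new_times, new_values)


def crop(ts: TimeSeries, t0: float, t1: float) -> TimeSeries:
    """Keep the samples with ``t0 <= t <= t1`` (closed interval)."""
    if not t0 < t1:
        raise ValueError(f"invalid crop window: t0={t0} must be < t1={t1}")
    mask = (ts.times >= t0) & (ts.times <= t1)
    if int(mask.sum()) < 2:
        raise ValueError(
            f"crop window [{t0}, {t1}] retains {int(mask.sum())} sample(s) "
            f"of a series spanning [{ts.times[0]}, {ts.times[-1]}]; "
            "at least 2 are required"
        )
    return TimeSeries(ts.times[mask], ts.values[mask])


def savgol_smooth(ts: TimeSeries, window: int, order: int) -> TimeSeries:
    """Savitzky-Golay smoothing: local least-squares polynomial fits.

    Each value is replaced by the centre of a polynomial of degree
    ``order`` fitted over ``window`` samples. At the boundaries the
    window is truncated to the available one-sided samples and the same
    polynomial degree (capped at the truncated length minus one) is
    fitted, so the series length is preserved without fabricating data.

    Requires a uniform grid; a polynomial of degree >= ``order`` (e.g.
    a constant or a quadratic with ``order=2``) passes through unchanged
    up to numerical tolerance.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    if order < 0:
        raise ValueError("order must be >= 0")
    if not ts.is_uniform:
        raise ValueError(
            "Savitzky-Golay smoothing requires a uniform grid; "
            "resample the series first"
        )
    n = len(ts)
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")
    half = window // 2
    smoothed = scipy.signal.savgol_filter(
        ts.values, window_length=window, polyorder=order, mode="interp"
    )
    # Boundary samples: refit over the truncated window.
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi, dtype=float) - i  # centred for conditioning
        deg = min(order, hi - lo - 1)
        coeffs = np.polynomial.polynomial.polyfit(x, ts.values[lo:hi], deg)
        smoothed[i] = coeffs[0]  # polynomial value at the centre x = 0
    return TimeSeries(ts.times, smoothed)


def median_filter(ts: TimeSeries, window: int) -> TimeSeries:
    """Sliding-window median; the window shrinks symmetrically at edges."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    n = len(ts)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(ts.values[i - k : i + k + 1])
    return TimeSeries(ts.times, out)


def boxcar(onset: float, duration: float, dt: float, total: float) -> TimeSeries:
    """Rectangular 0/1 stimulus time course on a uniform grid.

    The value is 1 on the half-open interval ``[onset, onset + duration)``
    and 0 elsewhere, so that ``sum(values) * dt == duration`` whenever
    onset and duration are integer multiples of ``dt``. A boxcar can
    replace a recorded input signal when only stimulus timing is known.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    if onset < 0:
        raise ValueError(f"onset must be >= 0, got {onset}")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if onset + duration > total * (1 + 1e-12):
        raise ValueError(
            f"boxcar end {onset + duration} s exceeds total duration {total} s"
        )
    n = int(np.floor(total / dt * (1 + 1e-12))) + 1
    times = dt * np.arange(n)
    tol = 1e-9 * dt
    values = ((times >= onset - tol) & (times < onset + duration - tol)).astype(
        np.float64
    )
    return TimeSeries(times, values)


def pretreat(ts: TimeSeries, config: PretreatmentConfig) -> TimeSeries:
    """Apply the configured pre-treatment chain to a series.

    Order: crop -> median filter -> Savitzky-Golay -> resample. The
    ``boxcar`` field is not handled here — it replaces the input signal
    altogether and is resolved by the caller (see :mod:`tfkit.cli`).
    """
    out = ts
    if config.crop_start is not None or config.crop_end is not None:
        t0 = config.crop_start if config.crop_start is not None else out.times[0]
        t1 = config.crop_end if config.crop_end is not None else out.times[-1]
        out = crop(out, t0, t1)
    if config.median_window is not None:
        out = median_filter(out, config.median_window)
    if config.savgol_window is not None:
        out = savgol_smooth(out, config.savgol_window, config.savgol_order)
    if config.dt is not None:
        out = resample(out, config.dt)
    return out
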