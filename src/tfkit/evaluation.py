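"""Prediction by convolution and goodness-of-fit metrics.

A candidate transfer function is judged by convolving it with the input
signal and comparing the result to the observed output. Two metrics are
used: the Pearson product-moment coefficient, which focuses purely on
the dynamics (it is invariant to positive affine rescaling, allowing
comparisons across subjects), and the residual sum of squares, which
also penalises amplitude errors and serves as the optimizers' cost.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .signals import TimeSeries, UNIFORM_RTOL

__all__ = ["predict", "pearson", "rss"]

ArrayLike = Union[TimeSeries, np.ndarray]


def _values(x: ArrayLike) -> np.ndarray:
    return x.values if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)


def predict(input_ts: TimeSeries, tf: TimeSeries) -> TimeSeries:
    """Predicted output: causal discrete convolution scaled by dt.

    ``pred[i] = dt * sum_j input[i - j] * tf[j]`` — a Riemann
    approximation of the continuous convolution integral, so TF
    amplitudes are independent of the sampling step. The result is
    truncated to the input's length and carries its time stamps.

    Both series must share the same uniform sampling interval.
    """
    dt_in = input_ts.require_dt()
    dt_tf = tf.require_dt()
    if abs(dt_in - dt_tf) > UNIFORM_RTOL * dt_in:
        raise ValueError(
            f"sampling mismatch: input dt={dt_in} vs TF dt={dt_tf}; "
            "resample both to a common time interval first"
        )
    full = np.convolve(input_ts.values, tf.values)
    pred = full[: len(input_ts)] * dt_in
    return TimeSeries(input_ts.times, pred)


def pearson(pred: ArrayLike, obs: ArrayLike) -> float:
    """Pearson product-moment correlation between two equal-length series.

    Computed from the standard formula
    ``sum((x - mx)(y - my)) / sqrt(sum((x - mx)^2) sum((y - my)^2))``.
    Undefined (raises) when either series has zero variance.
    """
    x, y = _values(pred), _values(obs)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise ValueError(
            "pearson is undefined for a zero-variance (constant) series"
        )
    r = float(dx @ dy) / np.sqrt(sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def rss(pred: ArrayLike, obs: ArrayLike) -> float:
    """Residual sum of squares ``sum((pred - obs)^2)``."""
    x, y = _values(pred), _values(obs)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    r = x - y
    return float(r @ r)
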