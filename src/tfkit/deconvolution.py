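"""Direct transfer-function extraction by deconvolution.

Deconvolution inverts the convolution relation output = input * TF
without any assumption about the TF's shape — an unbiased estimate, at
the price of amplifying high-frequency noise (the central caveat of the
approach: training-set predictions look excellent while the kernel
itself is buried in noise and generalises poorly).

Two routes are provided:

* ``toeplitz_deconvolve`` — least squares on the causal lower-triangular
  Toeplitz (convolution) matrix built from the input, optionally ridge-
  regularised.
* ``fourier_deconvolve`` — spectral division with a water-level guard
  against near-zero input frequency bins.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import scipy.linalg

from .signals import TimeSeries, UNIFORM_RTOL

__all__ = ["toeplitz_deconvolve", "fourier_deconvolve", "convolution_matrix"]

logger = logging.getLogger("tfkit")


def _common_dt(input_ts: TimeSeries, output_ts: TimeSeries) -> float:
    dt_x = input_ts.require_dt()
    dt_y = output_ts.require_dt()
    if abs(dt_x - dt_y) > UNIFORM_RTOL * dt_x:
        raise ValueError(
            f"input dt={dt_x} and output dt={dt_y} differ; resample both "
            "to a common time interval first"
        )
    if len(input_ts) != len(output_ts):
        raise ValueError(
            f"input ({len(input_ts)}) and output ({len(output_ts)}) must "
            "have the same number of samples"
        )
    return dt_x


def convolution_matrix(x: np.ndarray, tf_len: int) -> np.ndarray:
    """Causal lower-triangular Toeplitz matrix A with A[i, j] = x[i - j].

    ``A @ h`` realises the first ``len(x)`` samples of the discrete
    convolution ``x * h`` for a kernel of ``tf_len`` taps. Causality
    (zero upper triangle) encodes that the system cannot anticipate its
    input.
    """
    x = np.asarray(x, dtype=float)
    return scipy.linalg.toeplitz(x, np.zeros(tf_len))


def toeplitz_deconvolve(
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    tf_len: int,
    ridge: float = 0.0,
) -> TimeSeries:
    """TF minimising ``||A h dt - y||^2 + ridge * ||h||^2``.

    Parameters
    ----------
    input_ts, output_ts : TimeSeries
        Equal-length signals on a common uniform grid.
    tf_len : int
        Number of kernel taps to estimate (kernel duration is
        ``(tf_len - 1) * dt``); must not exceed the signal length.
    ridge : float, default 0
        Tikhonov penalty. 0 reproduces plain least-squares
        deconvolution through a rank-revealing solver (the minimum-norm
        solution when A is rank deficient, with a conditioning warning
        in the log); larger values shrink the kernel toward zero, a
        practical handle on the method's ill-conditioning.

    Returns
    -------
    TimeSeries
        The estimated kernel on the grid ``0, dt, ..., (tf_len - 1) dt``.
    """
    dt = _common_dt(input_ts, output_ts)
    n = len(input_ts)
    if not 1 <= tf_len <= n:
        raise ValueError(
            f"tf_len ({tf_len}) must be between 1 and the signal length ({n})"
        )
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")
    A = convolution_matrix(input_ts.values, tf_len) * dt
    y = output_ts.values
    if ridge == 0.0:
        h, _, rank, _ = scipy.linalg.lstsq(A, y)
        if rank < tf_len:
            logger.warning(
                "Toeplitz system is rank deficient (rank %d < %d taps); "
                "returning the minimum-norm solution",
                rank,
                tf_len,
            )
    else:
        # Normal equations with Tikhonov term; tf_len x tf_len SPD solve.
        lhs = A.T @ A + ridge * np.eye(tf_len)
        h = scipy.linalg.solve(lhs, A.T @ y, assume_a="pos")
    return TimeSeries(dt * np.arange(tf_len), h)


def fourier_deconvolve(
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    eps: float = 1e-3,
    tf_len: Optional[int] = None,
) -> TimeSeries:
    """Frequency-domain deconvolution with a water-level regulariser.

    Computes ``H(f) = Y(f) conj(X(f)) / (|X(f)|^2 + (eps max|X|)^2)``,
    inverse-transforms, keeps the real part and scales by ``1/dt`` so
    the kernel is on the same continuous-convolution scale as
    :func:`toeplitz_deconvolve`. ``eps`` is the water level as a
    fraction of the input's peak spectral magnitude; ``eps = 0``
    requires every frequency bin of the input to be nonzero.

    The full signal-length kernel is computed; ``tf_len`` truncates the
    returned series to the first ``tf_len`` taps.
    """
    dt = _common_dt(input_ts, output_ts)
    n = len(input_ts)
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    X = np.fft.rfft(input_ts.values)
    Y = np.fft.rfft(output_ts.values)
    power = np.abs(X) ** 2
    if eps == 0.0 and np.any(power == 0.0):
        raise ZeroDivisionError(
            "the input spectrum has zero-magnitude frequency bins; "
            "use a water level eps > 0"
        )
    level = (eps * np.max(np.abs(X))) ** 2
    H = Y * np.conj(X) / (power + level)
    h = np.fft.irfft(H, n=n).real / dt
    if tf_len is not None:
        if not 1 <= tf_len <= n:
            raise ValueError(
                f"tf_len ({tf_len}) must be between 1 and the signal length ({n})"
            )
        h = h[:tf_len]
    return TimeSeries(dt * np.arange(len(h)), h)
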