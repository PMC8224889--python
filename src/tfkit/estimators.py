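"""Scikit-learn-style estimators for transfer-function extraction.

Each estimator is fitted on an ``(input, output)`` pair of
:class:`~tfkit.signals.TimeSeries` on a common uniform grid, exposes
the estimated kernel as the fitted attribute ``tf_``, predicts outputs
for new inputs by convolution, and scores predictions with the Pearson
coefficient. They follow the scikit-learn estimator protocol
(``get_params`` / ``set_params``, constructor stores hyperparameters
untouched, fitted state carries a trailing underscore), so they
compose with ``sklearn.base.clone`` and model-selection utilities.

Estimators
----------
ToeplitzDeconvolver, FourierDeconvolver
    Direct, assumption-free kernel extraction.
ParametricTFFitter
    Deterministic fit (Nelder-Mead simplex or quasi-Newton BFGS) of a
    parametric family, the one-Γ HRF by default.
AnnealingTFFitter
    A single seeded simulated-annealing run within parameter bounds.
AnnealingProtocol
    The full multi-run/iteration annealing workflow with
    biological-consistency selection.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import deconvolution, optimization
from .evaluation import pearson, predict, rss
from .models import GAMMA1, ParametricModel, get_model
from .signals import TimeSeries

__all__ = [
    "ToeplitzDeconvolver",
    "FourierDeconvolver",
    "ParametricTFFitter",
    "AnnealingTFFitter",
    "AnnealingProtocol",
]


def _as_series(obj, name: str) -> TimeSeries:
    if isinstance(obj, TimeSeries):
        return obj
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return TimeSeries(arr[:, 0], arr[:, 1])
    raise TypeError(
        f"{name} must be a TimeSeries or an (n, 2) array of (time, value) "
        f"rows, got shape {np.shape(obj)}"
    )


class _BaseTFEstimator(BaseEstimator):
    """Shared fit/predict/score plumbing; subclasses set ``tf_``."""

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        raise NotImplementedError

    def fit(self, X, y):
        X = _as_series(X, "X")
        y = _as_series(y, "y")
        self.tf_ = self._fit_tf(X, y)
        self.n_samples_ = len(X)
        self.dt_ = X.require_dt()
        return self

    def predict(self, X) -> TimeSeries:
        check_is_fitted(self, "tf_")
        return predict(_as_series(X, "X"), self.tf_)

    def score(self, X, y) -> float:
        """Pearson coefficient between prediction and observation."""
        return pearson(self.predict(X), _as_series(y, "y"))

    def residual(self, X, y) -> float:
        """Residual sum of squares between prediction and observation."""
        return rss(self.predict(X), _as_series(y, "y"))


class ToeplitzDeconvolver(_BaseTFEstimator):
    """Kernel estimation by (optionally ridge-regularised) least squares.

    Parameters
    ----------
    tf_duration : float, default 10.0
        Kernel duration in seconds; the number of estimated taps is
        ``floor(tf_duration / dt) + 1`` (capped at the signal length).
    ridge : float, default 0.0
        Tikhonov penalty; 0 gives plain deconvolution.

    Attributes
    ----------
    tf_ : TimeSeries
        Estimated kernel on the grid ``0, dt, ...``.
    """

    def __init__(self, tf_duration: float = 10.0, ridge: float = 0.0):
        self.tf_duration = tf_duration
        self.ridge = ridge

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        dt = X.require_dt()
        tf_len = min(int(np.floor(self.tf_duration / dt * (1 + 1e-12))) + 1, len(X))
        return deconvolution.toeplitz_deconvolve(X, y, tf_len, ridge=self.ridge)


class FourierDeconvolver(_BaseTFEstimator):
    """Kernel estimation by water-level-regularised spectral division.

    Parameters
    ----------
    eps : float, default 1e-3
        Water level as a fraction of the input's peak spectral
        magnitude.
    tf_duration : float, optional
        Truncate the kernel to this duration; None keeps the full
        signal-length kernel.
    """

    def __init__(self, eps: float = 1e-3, tf_duration: Optional[float] = None):
        self.eps = eps
        self.tf_duration = tf_duration

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        tf_len = None
        if self.tf_duration is not None:
            dt = X.require_dt()
            tf_len = min(
                int(np.floor(self.tf_duration / dt * (1 + 1e-12))) + 1, len(X)
            )
        return deconvolution.fourier_deconvolve(X, y, eps=self.eps, tf_len=tf_len)


class _ParametricBase(_BaseTFEstimator):
    def _model(self) -> ParametricModel:
        model = self.model
        if isinstance(model, str):
            model = get_model(model)
        return model

    def _init(self, model: ParametricModel) -> np.ndarray:
        if self.init is None:
            return model.defaults.copy()
        return np.asarray(self.init, dtype=float)


class ParametricTFFitter(_ParametricBase):
    """Deterministic parametric fit of a TF family.

    Parameters
    ----------
    model : str or ParametricModel, default "gamma1"
        The parametric family; the built-in ``"gamma1"`` is the one-Γ
        hemodynamic kernel.
    algorithm : {"simplex", "quasinewton"}, default "simplex"
        Nelder-Mead simplex or BFGS quasi-Newton (finite differences).
    init : sequence of float, optional
        Initial parameter values; defaults to the model's standard
        initial values (for gamma1, the canonical HRF peaking at 5 s).
    tf_duration : float, default 10.0
        Duration of the evaluated kernel in seconds.

    Attributes
    ----------
    tf_ : TimeSeries
        Fitted kernel.
    params_ : ndarray
        Fitted parameter vector.
    result_ : optimization.RunResult
        Full run record (residual, Pearson, consistency verdict).
    """

    def __init__(
        self,
        model="gamma1",
        algorithm: str = "simplex",
        init: Optional[Sequence[float]] = None,
        tf_duration: float = 10.0,
    ):
        self.model = model
        self.algorithm = algorithm
        self.init = init
        self.tf_duration = tf_duration

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        model = self._model()
        init = self._init(model)
        if self.algorithm == "simplex":
            result = optimization.optimize_simplex(
                model, init, X, y, tf_duration=self.tf_duration
            )
        elif self.algorithm == "quasinewton":
            result = optimization.optimize_quasinewton(
                model, init, X, y, tf_duration=self.tf_duration
            )
        else:
            raise ValueError(
                f"algorithm must be 'simplex' or 'quasinewton', got "
                f"{self.algorithm!r}"
            )
        if result.error is not None:
            raise RuntimeError(f"optimization failed: {result.error}")
        self.result_ = result
        self.params_ = result.params.copy()
        problem = optimization.FitProblem(
            model, X, y, tf_duration=self.tf_duration
        )
        return problem.tf_series(result.params)


class AnnealingTFFitter(_ParametricBase):
    """A single bounded simulated-annealing run (seeded, reproducible)."""

    def __init__(
        self,
        model="gamma1",
        init: Optional[Sequence[float]] = None,
        bounds: Optional[Sequence[Tuple[float, float]]] = None,
        seed: Optional[int] = None,
        maxfun: int = optimization.DEFAULT_MAXFUN,
        tf_duration: float = 10.0,
    ):
        self.model = model
        self.init = init
        self.bounds = bounds
        self.seed = seed
        self.maxfun = maxfun
        self.tf_duration = tf_duration

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        model = self._model()
        result = optimization.optimize_sim_annealing(
            model,
            self._init(model),
            self.bounds,
            X,
            y,
            seed=self.seed,
            tf_duration=self.tf_duration,
            maxfun=self.maxfun,
        )
        self.result_ = result
        self.params_ = result.params.copy()
        problem = optimization.FitProblem(
            model, X, y, tf_duration=self.tf_duration
        )
        return problem.tf_series(result.params)


class AnnealingProtocol(_ParametricBase):
    """Multi-run/iteration simulated-annealing protocol.

    Runs iterations of ``n_runs`` seeded annealing runs sharing initial
    values; each iteration keeps the lowest-residual biologically
    consistent run and warm-starts the next from it, stopping when the
    relative residual improvement drops below ``improvement_tol``.

    Attributes
    ----------
    tf_ : TimeSeries
        Kernel of the selected (final) run.
    params_ : ndarray
        Its parameter vector.
    protocol_result_ : optimization.ProtocolResult
        Every run of every iteration, the per-iteration bests and the
        stop reason.
    """

    def __init__(
        self,
        model="gamma1",
        n_runs: int = 50,
        max_iterations: int = 10,
        improvement_tol: float = 0.05,
        init: Optional[Sequence[float]] = None,
        bounds: Optional[Sequence[Tuple[float, float]]] = None,
        master_seed: int = 0,
        require_consistency: bool = True,
        maxfun_per_run: int = optimization.DEFAULT_MAXFUN,
        tf_duration: float = 10.0,
    ):
        self.model = model
        self.n_runs = n_runs
        self.max_iterations = max_iterations
        self.improvement_tol = improvement_tol
        self.init = init
        self.bounds = bounds
        self.master_seed = master_seed
        self.require_consistency = require_consistency
        self.maxfun_per_run = maxfun_per_run
        self.tf_duration = tf_duration

    def _config(self, model: ParametricModel) -> optimization.ProtocolConfig:
        init = self._init(model)
        bounds = self.bounds
        if bounds is not None:
            bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        return optimization.ProtocolConfig(
            n_runs=self.n_runs,
            max_iterations=self.max_iterations,
            improvement_tol=self.improvement_tol,
            bounds=bounds,
            init=tuple(float(v) for v in init),
            master_seed=self.master_seed,
            require_consistency=self.require_consistency,
            tf_duration=self.tf_duration,
            maxfun_per_run=self.maxfun_per_run,
        )

    def _fit_tf(self, X: TimeSeries, y: TimeSeries) -> TimeSeries:
        model = self._model()
        result = optimization.iterate_protocol(
            self._config(model), X, y, model=model
        )
        self.protocol_result_ = result
        self.params_ = result.final.params.copy()
        problem = optimization.FitProblem(
            model, X, y, tf_duration=self.tf_duration
        )
        return problem.tf_series(result.final.params)
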