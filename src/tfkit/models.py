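"""Parametric transfer-function families.

The workhorse is the one-Γ transfer function used throughout blood-flow
based neuroimaging to represent the hemodynamic response:

    TF(t; p1, p2, p3, p4)
        = H(t - p3) * p4 * (t - p3)^(p1 - 1) * p2^p1
          * exp(-p2 * (t - p3)) / Γ(p1)

where H is the Heaviside step. p1 is the dimensionless shape, p2 the
rate in 1/s, p3 a pure time shift in seconds (the onset delay of the
vascular response), and p4 an amplitude scale: because the underlying
Γ density integrates to one, the TF area converges to p4 as the
duration grows. The peak sits at ``p3 + (p1 - 1) / p2``.

Arbitrary user-defined parametric families are supported through
:class:`ParametricModel` and a plain-text model registry (JSON), so any
optimizer in :mod:`tfkit.optimization` can fit them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .signals import TimeSeries

__all__ = [
    "GammaTFParams",
    "ParametricModel",
    "gamma_tf_values",
    "evaluate_gamma_tf",
    "peak_time",
    "make_tf_grid",
    "make_custom_model",
    "get_model",
    "list_models",
    "save_model_registry",
    "load_model_registry",
    "GAMMA1",
]

#: Default transfer-function duration in seconds when none is given.
DEFAULT_TF_DURATION = 10.0


@dataclass(frozen=True)
class GammaTFParams:
    """Parameters of the one-Γ transfer function.

    p1 : shape (dimensionless), must be > 1 — for p1 < 1 the kernel
         diverges at t = p3 and for p1 = 1 it jumps discontinuously;
         plausible hemodynamic kernels rise smoothly from zero.
    p2 : rate in 1/s, must be > 0.
    p3 : onset time shift in seconds (may be negative for unconstrained
         fits, mirroring anticipatory shifts sometimes reported).
    p4 : amplitude/area scale in output-unit per input-unit seconds.
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        if not self.p1 > 1:
            raise ValueError(f"p1 (shape) must be > 1, got {self.p1}")
        if not self.p2 > 0:
            raise ValueError(f"p2 (rate) must be > 0, got {self.p2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)


def gamma_tf_values(theta: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Raw one-Γ kernel evaluation, total on any parameter vector.

    Used as the model evaluator by the optimizers, which may probe
    invalid regions (p1 <= 1, p2 <= 0); non-finite outputs there are
    turned into an infinite cost by the caller rather than raised here.
    The Heaviside gate uses H(0) = 1 (t = p3 belongs to the support).
    """
    p1, p2, p3, p4 = (float(x) for x in theta)
    t = np.asarray(t, dtype=float)
    s = t - p3
    out = np.zeros_like(t)
    pos = s > 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        logv = (
            (p1 - 1) * np.log(s[pos])
            + p1 * np.log(p2)
            - p2 * s[pos]
            - gammaln(p1)
        )
        out[pos] = p4 * np.exp(logv)
    # t == p3: with p1 > 1 the limit is 0, which the zeros already give;
    # H(0) = 1 only matters for families whose value at onset is nonzero.
    return out


def evaluate_gamma_tf(params: GammaTFParams, grid: TimeSeries | np.ndarray) -> TimeSeries:
    """Sample the one-Γ TF on a uniform grid starting at 0.

    Returns a :class:`TimeSeries` (a "TF series": times from 0, uniform
    step). Values are 0 for t < p3 and follow the scaled Γ density for
    t >= p3; with valid parameters every value is finite.
    """
    times = grid.times if isinstance(grid, TimeSeries) else np.asarray(grid, float)
    if times[0] != 0.0:
        raise ValueError("a TF grid must start at t = 0")
    values = gamma_tf_values(params.as_array(), times)
    if not np.all(np.isfinite(values)):
        raise ValueError("gamma TF evaluated to non-finite values")
    return TimeSeries(times, values)


def peak_time(params: GammaTFParams) -> float:
    """Time of the TF maximum: ``p3 + (p1 - 1) / p2`` (requires p1 > 1)."""
    return params.p3 + (params.p1 - 1.0) / params.p2


def make_tf_grid(duration: float = DEFAULT_TF_DURATION, dt: float = 0.05) -> np.ndarray:
    """Uniform TF time grid [0, duration] with step dt."""
    if not (duration > 0 and dt > 0):
        raise ValueError("duration and dt must be positive")
    n = int(np.floor(duration / dt * (1 + 1e-12))) + 1
    return dt * np.arange(n)


@dataclass(frozen=True)
class ParametricModel:
    """A named parametric TF family usable by every optimizer.

    ``evaluator(theta, t)`` maps a parameter vector and a time grid to
    TF values; it must be total on the bound box. ``onset_param`` names
    the index of a pure time-shift parameter when the family has one,
    letting the consistency screen read the onset delay directly from
    the parameters instead of estimating it from samples.
    """

    name: str
    param_names: tuple
    evaluator: Callable[[Sequence[float], np.ndarray], np.ndarray]
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    defaults: np.ndarray
    onset_param: Optional[int] = None
    expression: Optional[str] = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_bounds, dtype=float)
        hi = np.asarray(self.upper_bounds, dtype=float)
        d = np.asarray(self.defaults, dtype=float)
        k = len(self.param_names)
        if not (lo.size == hi.size == d.size == k):
            raise ValueError("bounds and defaults must match param_names length")
        if np.any(lo > d) or np.any(d > hi):
            raise ValueError(
                "bounds must satisfy lower <= default <= upper per parameter"
            )
        object.__setattr__(self, "param_names", tuple(self.param_names))
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        object.__setattr__(self, "defaults", d)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __call__(self, theta: Sequence[float], t: np.ndarray) -> np.ndarray:
        return self.evaluator(theta, t)


def _gamma1_model() -> ParametricModel:
    # Default initial values reproduce the standard one-Γ HRF peaking at
    # 5 s: p1=2, p2=0.2 /s, p3=0, p4=1 gives peak = (p1-1)/p2 = 5 s.
    # The bound box is generous: it covers kernels peaking anywhere from
    # ~0.1 s (fast microvascular coupling) to ~20 s.
    return ParametricModel(
        name="gamma1",
        param_names=("p1", "p2", "p3", "p4"),
        evaluator=gamma_tf_values,
        lower_bounds=np.array([1.0 + 1e-6, 1e-6, 0.0, -100.0]),
        upper_bounds=np.array([20.0, 20.0, 2.0, 100.0]),
        defaults=np.array([2.0, 0.2, 0.0, 1.0]),
        onset_param=2,
        expression=None,
    )


GAMMA1 = _gamma1_model()

_REGISTRY: Dict[str, ParametricModel] = {GAMMA1.name: GAMMA1}


class ModelRegistrationError(ValueError):
    """Raised when a custom model cannot be registered."""


def make_custom_model(
    name: str,
    param_names: Sequence[str],
    evaluator: Optional[Callable] = None,
    *,
    expression: Optional[str] = None,
    lower_bounds: Sequence[float],
    upper_bounds: Sequence[float],
    defaults: Sequence[float],
    onset_param: Optional[int] = None,
    overwrite: bool = False,
) -> ParametricModel:
    """Register a user-defined parametric TF family.

    Either a Python ``evaluator(theta, t)`` or a numpy ``expression``
    string (variables ``t`` and ``p[0]..p[k-1]``, numpy namespace ``np``)
    must be given. The evaluator is probed at the default parameters on
    a reference grid; non-finite output there aborts registration.
    """
    if name in _REGISTRY and not overwrite:
        raise ModelRegistrationError(f"a model named {name!r} already exists")
    if evaluator is None:
        if expression is None:
            raise ModelRegistrationError(
                "provide either an evaluator callable or an expression string"
            )
        evaluator = _compile_expression(expression)
    model = ParametricModel(
        name=name,
        param_names=tuple(param_names),
        evaluator=evaluator,
        lower_bounds=np.asarray(lower_bounds, float),
        upper_bounds=np.asarray(upper_bounds, float),
        defaults=np.asarray(defaults, float),
        onset_param=onset_param,
        expression=expression,
    )
    probe = model(model.defaults, make_tf_grid())
    if not np.all(np.isfinite(np.asarray(probe, float))):
        raise ModelRegistrationError(
            f"model {name!r} produced non-finite values at its default "
            "parameters; the evaluator must be total on the bound box"
        )
    _REGISTRY[name] = model
    return model


def get_model(name: str) -> ParametricModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_models() -> List[str]:
    return sorted(_REGISTRY)


def _compile_expression(expression: str) -> Callable:
    """Compile a numpy expression string into an evaluator(theta, t)."""
    code = compile(expression, "<tf-model>", "eval")

    def evaluator(theta, t):
        p = np.asarray(theta, dtype=float)
        env = {"np": np, "t": np.asarray(t, dtype=float), "p": p, "__builtins__": {}}
        with np.errstate(all="ignore"):
            out = eval(code, env)  # noqa: S307 - restricted namespace
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(t)).copy()

    return evaluator


def save_model_registry(path: str | Path, names: Optional[Sequence[str]] = None) -> None:
    """Persist expression-based models to a plain-text JSON registry.

    Only models registered with an ``expression`` can be persisted;
    callable-only models are skipped (they are not serialisable).
    """
    records = {}
    for name in names if names is not None else list_models():
        m = _REGISTRY[name]
        if m.expression is None:
            continue
        records[name] = {
            "param_names": list(m.param_names),
            "expression": m.expression,
            "lower_bounds": m.lower_bounds.tolist(),
            "upper_bounds": m.upper_bounds.tolist(),
            "defaults": m.defaults.tolist(),
            "onset_param": m.onset_param,
        }
    Path(path).write_text(json.dumps(records, indent=2))


def load_model_registry(path: str | Path, overwrite: bool = False) -> List[str]:
    """Load and register models from a JSON registry file."""
    records = json.loads(Path(path).read_text())
    loaded = []
    for name, rec in records.items():
        make_custom_model(
            name,
            rec["param_names"],
            expression=rec["expression"],
            lower_bounds=rec["lower_bounds"],
            upper_bounds=rec["upper_bounds"],
            defaults=rec["defaults"],
            onset_param=rec.get("onset_param"),
            overwrite=overwrite,
        )
        loaded.append(name)
    return loaded
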