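"""Parametric transfer-function fitting and the run/iteration protocol.

The cost of every optimizer is the residual sum of squares between the
convolution prediction and the observed output. The one-Γ family makes
this an ill-posed problem: p1, p2 and p4 all influence the kernel
amplitude, so the 4-D cost surface carries multiple local minima.

Three algorithm classes are provided:

* ``optimize_simplex`` — derivative-free Nelder-Mead; deterministic
  (same initial values, same result) but attracted to the nearest
  local minimum.
* ``optimize_quasinewton`` — BFGS with finite-difference gradients;
  deterministic and unconstrained, so it may return a negative time
  shift when that lowers the cost.
* ``optimize_sim_annealing`` — bounded generalized simulated
  annealing; non-deterministic across seeds, which is exactly what the
  multi-run protocol exploits to collect distinct local minima.

The protocol (``run_iteration`` / ``iterate_protocol``): an *iteration*
is an ensemble of seeded annealing *runs* sharing the same initial
values; the best biologically consistent run is kept, the next
iteration warm-starts from it, and the sequence stops when an iteration
brings no clear improvement (relative residual gain below a tolerance).
Starting deliberately far from the expected kernel — the standard HRF
peaking at 5 s, much slower than measured neurovascular kernels —
helps the run pool collect more distinct minima to choose from.
"""

from __future__ import annotations

import inspect
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .consistency import ConsistencyVerdict, is_biologically_consistent
from .evaluation import pearson, rss
from .models import GAMMA1, ParametricModel, make_tf_grid
from .signals import TimeSeries

__all__ = [
    "RunResult",
    "ProtocolConfig",
    "IterationResult",
    "ProtocolResult",
    "FitProblem",
    "optimize_simplex",
    "optimize_quasinewton",
    "optimize_sim_annealing",
    "run_iteration",
    "iterate_protocol",
    "recommend_method",
    "derive_run_seed",
]

logger = logging.getLogger("tfkit")

#: Default cap on cost evaluations per annealing run.
DEFAULT_MAXFUN = 20_000


@dataclass(frozen=True)
class RunResult:
    """Outcome of a single optimization run."""

    params: np.ndarray
    residual: float
    pearson: float
    consistent: bool
    algorithm: str
    seed: Optional[int] = None
    n_cost_evals: int = 0
    reasons: Tuple[str, ...] = ()
    error: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "params", np.asarray(self.params, dtype=float).copy()
        )
        if self.error is None:
            if not self.residual >= 0:
                raise ValueError("residual must be >= 0")
            if not -1.0 <= self.pearson <= 1.0:
                raise ValueError("pearson must lie in [-1, 1]")


class FitProblem:
    """Precomputed fitting context shared by all optimizers.

    Binds a parametric model to an (input, output) pair on a common
    uniform grid, exposes the residual-sum-of-squares cost, and scores
    parameter vectors into :class:`RunResult` records (residual,
    Pearson, biological-consistency verdict).
    """

    def __init__(
        self,
        model: ParametricModel,
        input_ts: TimeSeries,
        output_ts: TimeSeries,
        tf_duration: float = 10.0,
    ) -> None:
        dt = input_ts.require_dt()
        out_dt = output_ts.require_dt()
        if abs(dt - out_dt) > 1e-6 * dt:
            raise ValueError(
                "input and output must share the same sampling interval"
            )
        if len(input_ts) != len(output_ts):
            raise ValueError("input and output must have the same length")
        self.model = model
        self.input_ts = input_ts
        self.output_ts = output_ts
        self.dt = dt
        self.tf_times = make_tf_grid(tf_duration, dt)
        self._x = input_ts.values
        self._y = output_ts.values
        self._n = len(output_ts)
        self.n_cost_evals = 0

    def tf_values(self, theta: Sequence[float]) -> np.ndarray:
        return np.asarray(self.model(theta, self.tf_times), dtype=float)

    def tf_series(self, theta: Sequence[float]) -> TimeSeries:
        return TimeSeries(self.tf_times, self.tf_values(theta))

    def predict_values(self, h: np.ndarray) -> np.ndarray:
        return np.convolve(self._x, h)[: self._n] * self.dt

    def cost(self, theta: Sequence[float]) -> float:
        """RSS cost; +inf wherever the model or prediction is non-finite."""
        self.n_cost_evals += 1
        h = self.tf_values(theta)
        if not np.all(np.isfinite(h)):
            return np.inf
        r = self.predict_values(h) - self._y
        val = float(r @ r)
        return val if np.isfinite(val) else np.inf

    def score(
        self,
        theta: Sequence[float],
        algorithm: str,
        seed: Optional[int] = None,
        n_cost_evals: int = 0,
    ) -> RunResult:
        theta = np.asarray(theta, dtype=float)
        h = self.tf_values(theta)
        pred = self.predict_values(h)
        tf = TimeSeries(self.tf_times, h)
        onset = None
        if self.model.onset_param is not None:
            onset = float(theta[self.model.onset_param])
        verdict = is_biologically_consistent(tf, onset_delay=onset)
        return RunResult(
            params=theta,
            residual=rss(pred, self._y),
            pearson=pearson(pred, self._y),
            consistent=bool(verdict),
            algorithm=algorithm,
            seed=seed,
            n_cost_evals=n_cost_evals,
            reasons=tuple(verdict.reasons),
        )


def _as_problem(
    model: ParametricModel,
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    tf_duration: float,
) -> FitProblem:
    return FitProblem(model, input_ts, output_ts, tf_duration=tf_duration)


def _check_init(problem: FitProblem, init: np.ndarray) -> None:
    c0 = problem.cost(init)
    if not np.isfinite(c0):
        raise ValueError(
            f"cost is non-finite at the initial parameters {init.tolist()}"
        )


def optimize_simplex(
    model: ParametricModel,
    init: Sequence[float],
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    *,
    tf_duration: float = 10.0,
    maxfun: int = DEFAULT_MAXFUN,
) -> RunResult:
    """Nelder-Mead simplex minimisation of the RSS cost.

    Deterministic: repeated calls with the same initial values return
    bitwise-identical parameters. Bounds, if the model declares any,
    are advisory only (the method is unconstrained).
    """
    problem = _as_problem(model, input_ts, output_ts, tf_duration)
    init = np.asarray(init, dtype=float)
    _check_init(problem, init)
    res = scipy.optimize.minimize(
        problem.cost,
        init,
        method="Nelder-Mead",
        options={"maxfev": maxfun, "xatol": 1e-8, "fatol": 1e-10},
    )
    return problem.score(res.x, "simplex", n_cost_evals=res.nfev)


def optimize_quasinewton(
    model: ParametricModel,
    init: Sequence[float],
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    *,
    tf_duration: float = 10.0,
) -> RunResult:
    """BFGS quasi-Newton minimisation with finite-difference gradients.

    Deterministic and unconstrained — in particular the time-shift
    parameter of the one-Γ family may end up negative when the data
    favour it, something the bounded annealing runs cannot produce.
    A search that wanders into a non-finite cost region is reported as
    a failed run (``error`` set) rather than raised.
    """
    problem = _as_problem(model, input_ts, output_ts, tf_duration)
    init = np.asarray(init, dtype=float)
    _check_init(problem, init)
    with np.errstate(invalid="ignore", over="ignore"):
        res = scipy.optimize.minimize(problem.cost, init, method="BFGS")
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        logger.warning("quasi-Newton run failed: non-finite search point")
        return RunResult(
            params=init,
            residual=np.nan,
            pearson=np.nan,
            consistent=False,
            algorithm="quasinewton",
            n_cost_evals=res.nfev,
            error="non-finite cost during search",
        )
    return problem.score(res.x, "quasinewton", n_cost_evals=res.nfev)


def _dual_annealing_kwargs() -> dict:
    # scipy renamed `seed` to `rng`; support both without a warning.
    params = inspect.signature(scipy.optimize.dual_annealing).parameters
    return {"rng_key": "rng" if "rng" in params else "seed"}


_DA_RNG_KEY = None


def _run_dual_annealing(cost, bounds, x0, seed, maxfun):
    global _DA_RNG_KEY
    if _DA_RNG_KEY is None:
        _DA_RNG_KEY = _dual_annealing_kwargs()["rng_key"]
    kwargs = {_DA_RNG_KEY: seed}
    return scipy.optimize.dual_annealing(
        cost, bounds=bounds, x0=np.asarray(x0, dtype=float), maxfun=maxfun, **kwargs
    )


def optimize_sim_annealing(
    model: ParametricModel,
    init: Sequence[float],
    bounds: Optional[Sequence[Tuple[float, float]]],
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    seed: Optional[int] = None,
    *,
    tf_duration: float = 10.0,
    maxfun: int = DEFAULT_MAXFUN,
) -> RunResult:
    """Bounded simulated annealing (generalized annealing) run.

    The returned parameters always satisfy the bounds. With a fixed
    seed the run is reproducible; different seeds explore different
    trajectories and can settle in different minima of the ill-posed
    cost surface. The initial point is always evaluated, so the
    returned residual never exceeds the cost at ``init``.
    """
    problem = _as_problem(model, input_ts, output_ts, tf_duration)
    init = np.asarray(init, dtype=float)
    if bounds is None:
        bounds = list(zip(model.lower_bounds, model.upper_bounds))
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != len(init):
        raise ValueError("bounds length must match the parameter count")
    for j, ((lo, hi), v) in enumerate(zip(bounds, init)):
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError(
                f"annealing requires finite bounds; parameter {j} has ({lo}, {hi})"
            )
        if not lo <= v <= hi:
            raise ValueError(
                f"initial value {v} of parameter {j} lies outside its "
                f"bounds ({lo}, {hi})"
            )
    _check_init(problem, init)
    res = _run_dual_annealing(problem.cost, bounds, init, seed, maxfun)
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return problem.score(x, "annealing", seed=seed, n_cost_evals=res.nfev)


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the multi-run/iteration annealing protocol."""

    n_runs: int = 50
    max_iterations: int = 10
    improvement_tol: float = 0.05
    bounds: Optional[Tuple[Tuple[float, float], ...]] = None
    init: Optional[Tuple[float, ...]] = None
    master_seed: int = 0
    require_consistency: bool = True
    tf_duration: float = 10.0
    maxfun_per_run: int = DEFAULT_MAXFUN

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.improvement_tol < 0:
            raise ValueError("improvement_tol must be >= 0")


@dataclass(frozen=True)
class IterationResult:
    """All runs of one iteration plus the selected best."""

    runs: Tuple[RunResult, ...]
    best: RunResult
    no_consistent_run: bool = False


@dataclass(frozen=True)
class ProtocolResult:
    """Ordered iterations with the overall selected transfer function."""

    iterations: Tuple[IterationResult, ...]
    final: RunResult
    stop_reason: str  # converged | max_iterations | no_consistent_run

    @property
    def best_residuals(self) -> List[float]:
        return [it.best.residual for it in self.iterations]


def derive_run_seed(master_seed: int, iteration: int, run: int) -> int:
    """Deterministic per-run seed from the master seed (stays < 2^31)."""
    return (master_seed * 1_000_003 + iteration * 100_003 + run) % (2**31)


def run_iteration(
    config: ProtocolConfig,
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    model: ParametricModel = GAMMA1,
    init: Optional[Sequence[float]] = None,
    iteration: int = 0,
    incumbent: Optional[RunResult] = None,
) -> Tuple[List[RunResult], RunResult]:
    """One iteration: ``n_runs`` seeded annealing runs from a shared init.

    The best run is the lowest-residual one among those passing the
    biological-consistency screen (plus the incumbent best of a
    previous iteration, if given — the warm-start point every run
    evaluates, which keeps the selected residual non-increasing across
    iterations). If ``require_consistency`` is set and no run passes,
    the lowest-residual run overall is returned and the condition is
    logged; with ``require_consistency`` unset all runs compete.
    Individual run failures are recorded, not fatal.
    """
    if init is None:
        init = config.init if config.init is not None else model.defaults
    init = np.asarray(init, dtype=float)
    runs: List[RunResult] = []
    for r in range(config.n_runs):
        seed = derive_run_seed(config.master_seed, iteration, r)
        try:
            result = optimize_sim_annealing(
                model,
                init,
                config.bounds,
                input_ts,
                output_ts,
                seed=seed,
                tf_duration=config.tf_duration,
                maxfun=config.maxfun_per_run,
            )
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("annealing run %d failed: %s", r, exc)
            result = RunResult(
                params=init,
                residual=np.nan,
                pearson=np.nan,
                consistent=False,
                algorithm="annealing",
                seed=seed,
                error=str(exc),
            )
        runs.append(result)
    ok = [r for r in runs if r.error is None]
    if not ok:
        raise RuntimeError("every run of the iteration failed")
    if config.require_consistency:
        candidates = [r for r in ok if r.consistent]
    else:
        candidates = list(ok)
    if not candidates:
        logger.warning(
            "no run passed the biological-consistency screen; "
            "selecting the lowest-residual run overall"
        )
        candidates = list(ok)
    if incumbent is not None:
        candidates = candidates + [incumbent]
    best = min(candidates, key=lambda r: r.residual)
    return runs, best


def iterate_protocol(
    config: ProtocolConfig,
    input_ts: TimeSeries,
    output_ts: TimeSeries,
    model: ParametricModel = GAMMA1,
) -> ProtocolResult:
    """Run iterations until no clear improvement or the iteration cap.

    Iteration k+1 warm-starts from iteration k's best parameters. The
    sequence stops once the relative improvement of the selected best
    residual falls below ``improvement_tol`` (default 5%), quantifying
    the qualitative "no clear improvement" stopping rule.
    """
    init = (
        np.asarray(config.init, dtype=float)
        if config.init is not None
        else model.defaults.copy()
    )
    iterations: List[IterationResult] = []
    incumbent: Optional[RunResult] = None
    stop_reason = "max_iterations"
    for k in range(config.max_iterations):
        runs, best = run_iteration(
            config,
            input_ts,
            output_ts,
            model=model,
            init=init,
            iteration=k,
            incumbent=incumbent,
        )
        none_consistent = config.require_consistency and not any(
            r.consistent for r in runs if r.error is None
        )
        iterations.append(
            IterationResult(
                runs=tuple(runs), best=best, no_consistent_run=none_consistent
            )
        )
        if incumbent is not None:
            prev = incumbent.residual
            gain = (prev - best.residual) / prev if prev > 0 else 0.0
            if gain < config.improvement_tol:
                incumbent = best
                stop_reason = "converged"
                break
        incumbent = best
        init = best.params
    assert incumbent is not None
    consistent_bests = [
        it.best for it in iterations if it.best.consistent
    ]
    if consistent_bests:
        final = min(consistent_bests, key=lambda r: r.residual)
    else:
        final = incumbent
        stop_reason = "no_consistent_run"
    return ProtocolResult(
        iterations=tuple(iterations), final=final, stop_reason=stop_reason
    )


def recommend_method(
    has_shape_prior: bool,
    noise_level: str,
    need_dynamics: bool,
    time_budget: str,
) -> str:
    """Suggest a TF computation method from the dataset's features.

    Encodes the decision guidance: direct deconvolution when no shape
    prior is available and the goal is prediction quality within the
    training dataset; the annealing protocol when a shape prior exists
    and the kernel's dynamics (or robustness to noise) matter, at the
    cost of longer computation; a fast deterministic optimizer when a
    prior exists, noise is low and speed is the priority.
    """
    if noise_level not in ("low", "high"):
        raise ValueError("noise_level must be 'low' or 'high'")
    if time_budget not in ("fast", "slow"):
        raise ValueError("time_budget must be 'fast' or 'slow'")
    if not has_shape_prior:
        return "toeplitz"
    if need_dynamics or noise_level == "high" or time_budget == "slow":
        return "annealing_protocol"
    return "simplex"
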