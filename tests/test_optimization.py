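"""Optimizer contracts and the run/iteration annealing protocol.

Heavy parameter-recovery checks under the full study conditions live in
the acceptance suite; here the protocol runs with reduced budgets that
still exercise every contract.
"""

import numpy as np
import pytest

from tfkit import (
    GAMMA1,
    GammaTFParams,
    ProtocolConfig,
    TimeSeries,
    gen_dataset,
    gen_event_input,
    iterate_protocol,
    optimize_quasinewton,
    optimize_sim_annealing,
    optimize_simplex,
    recommend_method,
    run_iteration,
)
from tfkit.optimization import derive_run_seed

TRUE = GammaTFParams(2.5, 2.0, 0.2, 1.5)


@pytest.fixture(scope="module")
def small_pair():
    """A short noiseless pair for fast optimizer checks."""
    inp = gen_event_input(3, 0.5, [0.0, 1.5, 3.0], dt=0.05, total=10.0)
    inp, out, truth = gen_dataset(TRUE, inp, 0.0, tf_duration=6.0)
    return inp, out, truth


class TestDeterministicOptimizers:
    def test_descent_from_the_true_parameters(self, small_pair):
        inp, out, truth = small_pair
        res = optimize_simplex(
            GAMMA1, truth.params.as_array(), inp, out, tf_duration=6.0
        )
        assert res.residual < 1e-10

    @pytest.mark.parametrize("method", [optimize_simplex, optimize_quasinewton])
    def test_bitwise_reproducible(self, small_pair, method):
        inp, out, _ = small_pair
        init = np.array([2.0, 1.0, 0.1, 1.0])
        a = method(GAMMA1, init, inp, out, tf_duration=6.0)
        b = method(GAMMA1, init, inp, out, tf_duration=6.0)
        assert np.array_equal(a.params, b.params)
        assert a.residual == b.residual

    def test_convex_toy_recovery(self):
        # Single-parameter amplitude model: the cost is an exact parabola
        # in a with its minimum at the true amplitude 3.
        from tfkit.models import make_custom_model

        model = make_custom_model(
            "amp_toy", ["a"], expression="p[0] * np.exp(-t)",
            lower_bounds=[0.0], upper_bounds=[10.0], defaults=[1.0],
            overwrite=True,
        )
        dt = 0.05
        t = dt * np.arange(100)
        inp = TimeSeries(t, np.exp(-0.5 * t))
        tf_true = TimeSeries(t, 3.0 * np.exp(-t))
        from tfkit import predict

        out = predict(inp, tf_true)
        for method in (optimize_simplex, optimize_quasinewton):
            res = method(model, np.array([1.0]), inp, out, tf_duration=t[-1])
            assert res.params[0] == pytest.approx(3.0, rel=1e-4)

    def test_quasinewton_can_return_negative_time_shift(self):
        # Output built from a kernel with zero shift, input delayed after
        # the fact: the best unconstrained shift is negative.
        inp = gen_event_input(3, 0.5, [1.0, 3.0, 5.0], dt=0.05, total=12.0)
        _, out, _ = gen_dataset(
            GammaTFParams(2.5, 2.0, 1e-9, 1.5), inp, 0.0, tf_duration=6.0
        )
        shifted_in = TimeSeries(inp.times, np.roll(inp.values, 4))
        res = optimize_quasinewton(
            GAMMA1, np.array([2.5, 2.0, 0.1, 1.5]), shifted_in, out,
            tf_duration=6.0,
        )
        assert res.params[2] < 0.0

    def test_non_finite_initial_cost_rejected(self, small_pair):
        inp, out, _ = small_pair
        with pytest.raises(ValueError, match="non-finite"):
            optimize_simplex(
                GAMMA1, np.array([0.5, -1.0, 0.0, 1.0]), inp, out
            )


class TestAnnealing:
    def test_same_seed_is_identical(self, small_pair):
        inp, out, _ = small_pair
        kwargs = dict(tf_duration=6.0, maxfun=1500)
        a = optimize_sim_annealing(
            GAMMA1, GAMMA1.defaults, None, inp, out, seed=5, **kwargs
        )
        b = optimize_sim_annealing(
            GAMMA1, GAMMA1.defaults, None, inp, out, seed=5, **kwargs
        )
        assert np.array_equal(a.params, b.params)
        assert a.residual == b.residual

    def test_params_respect_bounds(self, small_pair):
        inp, out, _ = small_pair
        bounds = [(1.5, 3.0), (0.5, 4.0), (0.05, 1.0), (0.1, 5.0)]
        res = optimize_sim_annealing(
            GAMMA1, np.array([2.0, 1.0, 0.5, 1.0]), bounds, inp, out,
            seed=1, tf_duration=6.0, maxfun=1500,
        )
        for v, (lo, hi) in zip(res.params, bounds):
            assert lo <= v <= hi

    def test_init_outside_bounds_rejected(self, small_pair):
        inp, out, _ = small_pair
        with pytest.raises(ValueError, match="outside"):
            optimize_sim_annealing(
                GAMMA1, np.array([5.0, 1.0, 0.5, 1.0]),
                [(1.5, 3.0)] * 4, inp, out, seed=1,
            )

    def test_distinct_seeds_reach_distinct_optima(self, noisy_dataset):
        inp, out, _ = noisy_dataset
        results = [
            optimize_sim_annealing(
                GAMMA1, GAMMA1.defaults, None, inp, out, seed=s, maxfun=300
            )
            for s in range(8)
        ]
        unique = {tuple(np.round(r.params, 6)) for r in results}
        assert len(unique) >= 2


class TestProtocol:
    def test_single_run_iteration_equals_one_annealing_call(self, small_pair):
        inp, out, _ = small_pair
        cfg = ProtocolConfig(
            n_runs=1, master_seed=3, maxfun_per_run=1000, tf_duration=6.0
        )
        runs, best = run_iteration(cfg, inp, out)
        direct = optimize_sim_annealing(
            GAMMA1, GAMMA1.defaults, None, inp, out,
            seed=derive_run_seed(3, 0, 0), tf_duration=6.0, maxfun=1000,
        )
        assert np.array_equal(best.params, direct.params)
        assert best.residual == direct.residual

    def test_best_is_minimum_among_consistent_runs(self, small_pair):
        inp, out, _ = small_pair
        cfg = ProtocolConfig(
            n_runs=6, master_seed=7, maxfun_per_run=800, tf_duration=6.0
        )
        runs, best = run_iteration(cfg, inp, out)
        consistent = [r.residual for r in runs if r.consistent]
        if consistent:
            assert best.residual <= min(consistent)

    def test_single_iteration_protocol_matches_run_iteration(self, small_pair):
        inp, out, _ = small_pair
        cfg = ProtocolConfig(
            n_runs=3, max_iterations=1, master_seed=5,
            maxfun_per_run=800, tf_duration=6.0,
        )
        result = iterate_protocol(cfg, inp, out)
        runs, best = run_iteration(cfg, inp, out)
        assert len(result.iterations) == 1
        assert np.array_equal(result.iterations[0].best.params, best.params)

    def test_best_residual_non_increasing_across_iterations(self, noisy_dataset):
        inp, out, _ = noisy_dataset
        for seed in (0, 1, 2):
            cfg = ProtocolConfig(
                n_runs=4, max_iterations=3, improvement_tol=0.0,
                master_seed=seed, maxfun_per_run=500,
            )
            result = iterate_protocol(cfg, inp, out)
            residuals = result.best_residuals
            assert all(a >= b for a, b in zip(residuals, residuals[1:]))

    def test_converged_stop_reason_when_no_improvement(self, small_pair):
        inp, out, _ = small_pair
        cfg = ProtocolConfig(
            n_runs=2, max_iterations=6, improvement_tol=0.05,
            master_seed=9, maxfun_per_run=2000, tf_duration=6.0,
        )
        result = iterate_protocol(cfg, inp, out)
        assert result.stop_reason in ("converged", "max_iterations")
        assert len(result.iterations) <= 6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ProtocolConfig(n_runs=0)
        with pytest.raises(ValueError):
            ProtocolConfig(improvement_tol=-0.1)


class TestRecommendMethod:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((False, "low", False, "fast"), "toeplitz"),
            ((True, "high", True, "slow"), "annealing_protocol"),
            ((True, "low", False, "fast"), "simplex"),
            ((True, "low", True, "fast"), "annealing_protocol"),
            ((True, "high", False, "fast"), "annealing_protocol"),
        ],
    )
    def test_decision_tree(self, args, expected):
        assert recommend_method(*args) == expected

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            recommend_method(True, "medium", False, "fast")
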