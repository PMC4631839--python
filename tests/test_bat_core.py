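import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batecg.bat_core import (
    ConfigError,
    DimensionError,
    EvaluationError,
    SwarmConfig,
    decay_loudness,
    draw_frequency,
    grow_pulse_rate,
    init_swarm,
    local_search_ba,
    local_search_iba,
    rosenbrock,
    run_optimizer,
    step_ba,
    step_iba,
    update_loudness_iba,
    update_position,
    update_pulse_iba,
    update_velocity,
)

BOUNDS_2D = ((-5.0, 5.0), (-5.0, 5.0))


def quadratic(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestRosenbrock:
    def test_global_minimum(self):
        assert rosenbrock([1.0, 1.0, 1.0]) == 0.0

    def test_origin_2d(self):
        assert rosenbrock([0.0, 0.0]) == 1.0

    def test_hand_evaluated(self):
        # 100*(1 - 1.44)^2 + (-1.2 - 1)^2 = 19.36 + 4.84
        assert rosenbrock([-1.2, 1.0]) == pytest.approx(24.2)

    def test_dimension_error(self):
        with pytest.raises(DimensionError):
            rosenbrock([1.0])

    def test_batch_matches_rowwise(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        batch = rosenbrock(X)
        assert np.allclose(batch, [rosenbrock(row) for row in X])

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, xs):
        assert rosenbrock(xs) >= 0.0


class TestFrequency:
    @pytest.mark.parametrize("u,expected", [(0.0, 0.0), (1.0, 2.0), (0.5, 1.0)])
    def test_endpoints_and_midpoint(self, u, expected):
        assert draw_frequency(0.0, 2.0, u) == expected

    def test_order_error(self):
        with pytest.raises(ConfigError):
            draw_frequency(2.0, 0.0, 0.5)


class TestVelocityPosition:
    def test_best_bat_stationary(self):
        v = np.array([1.0, -2.0])
        x = np.array([0.5, 0.5])
        assert np.array_equal(update_velocity(v, x, x, 1.3), v)

    def test_hand_value(self):
        out = update_velocity(np.array([1.0]), np.array([2.0]), np.array([1.0]), 0.5)
        assert out == pytest.approx([1.5])

    def test_zero_frequency(self):
        v = np.array([0.3, 0.4])
        out = update_velocity(v, np.array([1.0, 2.0]), np.array([0.0, 0.0]), 0.0)
        assert np.array_equal(out, v)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            update_velocity(np.zeros(2), np.zeros(3), np.zeros(2), 1.0)

    def test_position_zero_velocity(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(update_position(x, np.zeros(2), BOUNDS_2D), x)

    def test_position_step(self):
        out = update_position(np.array([0.0]), np.array([1.0]), [(-5.0, 5.0)])
        assert out == pytest.approx([1.0])

    def test_position_clamps(self):
        out = update_position(np.array([4.0]), np.array([10.0]), [(-5.0, 5.0)])
        assert out == pytest.approx([5.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=2),
        st.lists(st.floats(-100, 100), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_position_always_in_bounds(self, x, v):
        out = update_position(np.array(x), np.array(v), BOUNDS_2D)
        assert np.all(out >= -5.0) and np.all(out <= 5.0)


class TestLocalSearchBA:
    def test_zero_epsilon(self):
        g = np.array([0.3, -0.2])
        assert np.array_equal(local_search_ba(g, 1.0, np.zeros(2)), g)

    def test_vanishing_loudness(self):
        g = np.array([0.3])
        assert local_search_ba(g, 1e-300, np.array([1.0])) == pytest.approx(g)

    def test_hand_value(self):
        out = local_search_ba(np.array([0.0]), 0.5, np.array([1.0]))
        assert out == pytest.approx([0.5])


class TestLoudnessPulse:
    def test_decay_paper_alpha(self):
        assert decay_loudness(1.0, 0.95) == pytest.approx(0.95)

    def test_decay_near_one(self):
        assert decay_loudness(2.0, 1 - 1e-12) == pytest.approx(2.0)

    def test_decay_repeated(self):
        a = 3.0
        for _ in range(10):
            a = decay_loudness(a, 0.95)
        assert a == pytest.approx(3.0 * 0.95**10)

    def test_decay_alpha_error(self):
        with pytest.raises(ConfigError):
            decay_loudness(1.0, 1.5)

    def test_pulse_zero_at_t0(self):
        assert grow_pulse_rate(0.2, 0.9, 0) == 0.0

    def test_pulse_asymptote(self):
        assert grow_pulse_rate(0.2, 0.9, 10_000) == pytest.approx(0.2)

    def test_pulse_hand_value(self):
        assert grow_pulse_rate(0.2, 0.9, 3) == pytest.approx(0.2 * (1 - math.exp(-2.7)))

    def test_pulse_monotone(self):
        vals = [grow_pulse_rate(0.2, 0.9, t) for t in range(10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_pulse_gamma_error(self):
        with pytest.raises(ConfigError):
            grow_pulse_rate(0.2, -1.0, 1)


class TestIBAPrimitives:
    def test_fully_blocked_keeps_self(self):
        # pulse rate 1 means the gate (rand > r) can never fire
        rng = np.random.default_rng(0)
        x = np.array([0.1, 0.2, 0.3])
        out, gates = local_search_iba(
            np.ones(3), x, np.full(3, 0.5), np.ones(3), 0.95, rng
        )
        assert not gates.any()
        assert np.array_equal(out, x)

    def test_fully_gated_copies_scaled_base(self):
        class ZeroEps:
            def random(self, shape):
                return np.full(shape, 0.5)  # above r=0, so every gate fires

            def uniform(self, lo, hi, size):
                return np.zeros(size)

        base = np.array([1.0, -2.0])
        out, gates = local_search_iba(
            base, np.zeros(2), np.ones(2), np.zeros(2), 1.0, ZeroEps()
        )
        assert gates.all()
        assert np.array_equal(out, base)

    def test_hand_value(self):
        class FixedEps:
            def random(self, shape):
                return np.full(shape, 0.5)

            def uniform(self, lo, hi, size):
                return np.full(size, 0.5)

        out, _ = local_search_iba(
            np.array([1.0]), np.array([0.0]), np.array([0.4]), np.array([0.0]),
            0.95, FixedEps(),
        )
        assert out == pytest.approx([1.15])

    def test_loudness_gated_and_not(self):
        assert update_loudness_iba(2.0, True, 0.95) == pytest.approx(1.9)
        assert update_loudness_iba(2.0, False, 0.95) == 2.0

    def test_loudness_repeated_gating_decreases(self):
        a = 1.0
        vals = []
        for _ in range(50):
            a = update_loudness_iba(a, True, 0.95)
            vals.append(a)
        assert all(b < a for a, b in zip(vals, vals[1:])) and vals[-1] > 0

    def test_pulse_gated_and_not(self):
        assert update_pulse_iba(0.07, False, 0.2, 0.9, 3) == 0.07
        assert update_pulse_iba(0.07, True, 0.2, 0.9, 0) == 0.0
        assert update_pulse_iba(0.07, True, 0.2, 0.9, 3) == pytest.approx(
            0.2 * (1 - math.exp(-2.7))
        )


class TestSwarmConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pop_size": 1},
            {"fmin": 3.0, "fmax": 1.0},
            {"alpha": 1.0},
            {"alpha": 0.0},
            {"gamma": 0.0},
            {"r0": 0.0},
            {"a_min": 0.0},
            {"a_min": 2.0, "a_max": 1.0},
            {"local_base": "other"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            SwarmConfig(bounds=BOUNDS_2D, **kwargs)

    def test_from_dict_rejects_unknown(self):
        with pytest.raises(ConfigError, match="unknown"):
            SwarmConfig.from_dict({"bounds": [[-1, 1]], "popsize": 3})

    def test_round_trip(self):
        cfg = SwarmConfig(bounds=BOUNDS_2D, pop_size=5, seed=3)
        assert SwarmConfig.from_dict(cfg.to_dict()) == cfg


def _cfg(**kw):
    base = dict(bounds=BOUNDS_2D, pop_size=25, generations=0, seed=0)
    base.update(kw)
    return SwarmConfig(**base)


class TestSteps:
    @pytest.mark.parametrize("mode,step", [("ba", step_ba), ("iba", step_iba)])
    def test_optimum_swarm_stays(self, mode, step):
        cfg = _cfg()
        rng = np.random.default_rng(0)
        swarm = init_swarm(cfg, rosenbrock, mode, rng)
        swarm.positions[:] = 1.0
        swarm.fitness[:] = 0.0
        swarm.best_position = np.ones(2)
        swarm.best_fitness = 0.0
        for _ in range(5):
            step(swarm, rosenbrock, cfg, rng)
        assert swarm.best_fitness == 0.0

    @pytest.mark.parametrize("mode,step", [("ba", step_ba), ("iba", step_iba)])
    def test_bitwise_determinism(self, mode, step):
        def run():
            cfg = _cfg(seed=11)
            rng = np.random.default_rng(cfg.seed)
            swarm = init_swarm(cfg, rosenbrock, mode, rng)
            for _ in range(20):
                step(swarm, rosenbrock, cfg, rng)
            return swarm

        a, b = run(), run()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.fitness, b.fitness)
        assert np.array_equal(a.loudness, b.loudness)
        assert np.array_equal(a.pulse, b.pulse)

    def test_ba_converges_fixed_seed(self):
        # reference value computed with this implementation before freezing
        cfg = _cfg(generations=1000, seed=2)
        result = run_optimizer(cfg, rosenbrock, mode="ba")
        assert result.best_fitness < 1e-2

    def test_non_finite_objective_reports_bat(self):
        cfg = _cfg(pop_size=3)
        with pytest.raises(EvaluationError, match="bat"):
            init_swarm(cfg, lambda x: float("nan"), "ba", np.random.default_rng(0))

    @pytest.mark.parametrize("mode", ["ba", "iba"])
    def test_dimension_collapse_converges(self, mode):
        # at D=1 the per-dimension machinery degenerates to scalars and
        # both variants still optimize a 1-D quadratic
        cfg = SwarmConfig(bounds=((-5.0, 5.0),), pop_size=10, generations=200, seed=4)
        result = run_optimizer(cfg, quadratic, mode=mode)
        assert result.best_fitness < 1e-3


class TestRunOptimizer:
    def test_zero_generations(self):
        cfg = _cfg(generations=0)
        result = run_optimizer(cfg, rosenbrock, mode="ba")
        assert len(result.trace) == 1
        assert result.best_fitness == pytest.approx(result.trace.best_fitness[0])

    @pytest.mark.parametrize("mode", ["ba", "iba"])
    def test_identical_traces_same_seed(self, mode):
        cfg = _cfg(generations=50, seed=9)
        t1 = run_optimizer(cfg, rosenbrock, mode=mode).trace
        t2 = run_optimizer(cfg, rosenbrock, mode=mode).trace
        assert t1.best_fitness == t2.best_fitness
        assert t1.mean_loudness == t2.mean_loudness
        assert t1.mean_pulse_rate == t2.mean_pulse_rate

    def test_missing_bounds(self):
        cfg = SwarmConfig(pop_size=5)
        with pytest.raises(ConfigError):
            run_optimizer(cfg, rosenbrock, mode="ba")

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            run_optimizer(_cfg(), rosenbrock, mode="xyz")


def check_step_invariants(mode, step, seed, generations=60):
    """Shared instrumented invariant check, reused by the acceptance suite."""
    cfg = _cfg(generations=generations, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(cfg, rosenbrock, mode, rng)
    lo, hi = cfg.bounds_arrays()
    prev_best = swarm.best_fitness
    for _ in range(generations):
        before = swarm.copy()
        step(swarm, rosenbrock, cfg, rng)
        accepted = swarm.last_accepted
        # best-so-far never worsens
        assert swarm.best_fitness <= prev_best
        prev_best = swarm.best_fitness
        # positions stay in the box
        assert np.all(swarm.positions >= lo) and np.all(swarm.positions <= hi)
        # loudness decays exactly on accepted (and, in IBA, gated) entries
        changed = swarm.loudness != before.loudness
        if mode == "ba":
            assert np.array_equal(changed, accepted)
            assert np.all(
                swarm.loudness[accepted]
                == pytest.approx(cfg.alpha * before.loudness[accepted])
            )
        else:
            assert not changed[~accepted].any()
            sel = changed
            assert np.all(
                swarm.loudness[sel] == pytest.approx(cfg.alpha * before.loudness[sel])
            )
        # pulse: changes only with acceptance, follows the saturating
        # schedule, and successive updates never decrease it
        pulse_changed = swarm.pulse != before.pulse
        if mode == "ba":
            assert not pulse_changed[~accepted].any()
            t_new = swarm.accept_counts[accepted]
            expect = cfg.r0 * (1.0 - np.exp(-cfg.gamma * t_new))
            assert swarm.pulse[accepted] == pytest.approx(expect)
        else:
            assert not pulse_changed[~accepted].any()
            for i in np.flatnonzero(accepted):
                t_new = swarm.accept_counts[i]
                expect = cfg.r0 * (1.0 - math.exp(-cfg.gamma * t_new))
                dims = np.flatnonzero(pulse_changed[i])
                assert swarm.pulse[i, dims] == pytest.approx(expect)
                # schedule value grows with the per-bat clock
                assert np.all(swarm.pulse[i, dims] >= before.pulse[i, dims] - cfg.r0 * math.exp(-cfg.gamma))
        assert np.all(swarm.pulse <= cfg.r0 + 1e-12)
        assert np.all(swarm.loudness <= before.loudness + 1e-12)
        # fitness bookkeeping: unaccepted bats untouched
        assert np.array_equal(swarm.fitness[~accepted], before.fitness[~accepted])


@pytest.mark.parametrize("mode,step", [("ba", step_ba), ("iba", step_iba)])
@pytest.mark.parametrize("seed", [0, 1])
def test_step_invariants(mode, step, seed):
    check_step_invariants(mode, step, seed)


def test_pulse_updates_non_decreasing_across_updates():
    """Successive accepted updates of one bat never lower its pulse rate."""
    cfg = _cfg(generations=200, seed=5)
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(cfg, rosenbrock, "ba", rng)
    history = [[] for _ in range(swarm.size)]
    for _ in range(cfg.generations):
        step_ba(swarm, rosenbrock, cfg, rng)
        for i in np.flatnonzero(swarm.last_accepted):
            history[i].append(float(swarm.pulse[i]))
    assert any(len(h) >= 2 for h in history)
    for h in history:
        assert all(b >= a for a, b in zip(h, h[1:]))
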