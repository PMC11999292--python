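"""Grey Wolf Optimizer: update rules, schedules, invariants."""

import numpy as np
import pytest

from gwoscreen.gwo import (GWOConfig, GreyWolfOptimizer, control_parameter,
                           encircle_coefficients, initialize_pack, optimize,
                           pounce_update, write_trace_csv)


def sphere(z):
    return float((z ** 2).sum())


def make_config(**kw):
    base = dict(n_wolves=5, dim=2, max_iters=10, lower_bounds=-1.0,
                upper_bounds=1.0, seed=0)
    base.update(kw)
    return GWOConfig(**base)


class FakeRng:
    """Deterministic stand-in yielding preset uniform vectors."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, dim):
        return np.full(dim, self.values.pop(0))


class TestConfig:
    def test_fewer_than_three_wolves_rejected(self):
        with pytest.raises(ValueError, match="n_wolves"):
            make_config(n_wolves=2)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower_bounds"):
            make_config(lower_bounds=2.0, upper_bounds=1.0)

    def test_scalar_bounds_broadcast(self):
        cfg = make_config(dim=3)
        assert cfg.lower_bounds.shape == (3,)


class TestInitialization:
    def test_constant_objective_ties_break_by_index(self):
        cfg = make_config(n_wolves=3, dim=1, lower_bounds=0.0, upper_bounds=1.0)
        pack = initialize_pack(cfg, lambda z: 7.0)
        assert np.all(pack.fitness == 7.0)
        assert pack.leaders == (0, 1, 2)

    def test_positions_inside_box_and_alpha_is_min(self):
        cfg = make_config(n_wolves=30, dim=2, lower_bounds=-5.0, upper_bounds=5.0)
        pack = initialize_pack(cfg, sphere)
        assert np.all(pack.positions >= -5.0) and np.all(pack.positions <= 5.0)
        assert pack.fitness[pack.leaders[0]] == pack.fitness.min()

    def test_seeded_determinism(self):
        cfg = make_config(seed=11)
        p1 = initialize_pack(cfg, sphere)
        p2 = initialize_pack(make_config(seed=11), sphere)
        np.testing.assert_array_equal(p1.positions, p2.positions)

    def test_non_finite_objective_reported(self):
        cfg = make_config()
        with pytest.raises(ValueError, match="non-finite"):
            initialize_pack(cfg, lambda z: float("inf"))


class TestControlParameter:
    @pytest.mark.parametrize("t,T,variant,expected", [
        (0, 100, "standard", 2.0),
        (100, 100, "standard", 0.0),
        (100, 100, "paper", 0.0),
        (50, 100, "paper", 0.25),
        (0, 100, "paper", 0.5),
    ])
    def test_schedule_values(self, t, T, variant, expected):
        cfg = make_config(max_iters=T, variant=variant)
        assert control_parameter(t, cfg) == pytest.approx(expected)

    def test_non_increasing_in_t(self):
        cfg = make_config(max_iters=50)
        vals = [control_parameter(t, cfg) for t in range(51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            control_parameter(11, make_config(max_iters=10))


class TestEncircleCoefficients:
    def test_zero_scale_gives_zero_x(self):
        rng = np.random.default_rng(0)
        for variant in ("standard", "paper"):
            x, _ = encircle_coefficients(0.0, rng, 4, variant)
            np.testing.assert_array_equal(x, 0.0)

    def test_forced_draw_matches_closed_form(self):
        # v1 = v2 = 0.5, m = 1, paper rules: x = 2*1*(0.5+0.5) - 1 = 1, y = 1
        x, y = encircle_coefficients(1.0, None, 1, "paper",
                                     v1=np.array([0.5]), v2=np.array([0.5]))
        assert x[0] == pytest.approx(1.0)
        assert y[0] == pytest.approx(1.0)

    def test_empirical_ranges(self):
        rng = np.random.default_rng(1)
        xs, _ = encircle_coefficients(1.0, rng, 100_000, "standard")
        assert xs.min() >= -1.0 and xs.max() <= 1.0
        xp, yp = encircle_coefficients(1.0, rng, 100_000, "paper")
        assert xp.min() >= -1.0 and xp.max() <= 3.0
        assert yp.min() >= 0.0 and yp.max() <= 2.0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            encircle_coefficients(-0.1, np.random.default_rng(0), 2)


class TestPounceUpdate:
    def test_fixed_point_when_pack_collapsed(self):
        cfg = make_config(n_wolves=3, dim=2)
        pack = initialize_pack(cfg, sphere)
        p = np.array([0.25, -0.5])
        pack.positions = np.tile(p, (3, 1))
        pack.leaders = (0, 1, 2)
        new = pounce_update(pack, m=1.0, config=cfg)
        # E = |y*p - p| depends on y, but x*E with collapsed pack is not 0;
        # only at m=0 is the collapsed pack an exact fixed point:
        new0 = pounce_update(pack, m=0.0, config=cfg)
        np.testing.assert_allclose(new0, np.tile(p, (3, 1)))
        assert new.shape == (3, 2)

    def test_zero_scale_attracts_to_leader_mean(self):
        cfg = make_config(n_wolves=4, dim=1, lower_bounds=-10.0,
                          upper_bounds=10.0)
        pack = initialize_pack(cfg, sphere)
        pack.positions = np.array([[1.0], [2.0], [3.0], [9.0]])
        pack.fitness = np.array([1.0, 2.0, 3.0, 9.0])
        pack.leaders = (0, 1, 2)
        new = pounce_update(pack, m=0.0, config=cfg)
        np.testing.assert_allclose(new, np.full((4, 1), 2.0))

    def test_hand_computed_single_wolf_update(self):
        # 1-D, one moving wolf at 0.2 with leaders at 0.5, 0.3, 0.1; m = 0.4
        # per-leader draws (v1, v2) consumed in order alpha, beta, gamma
        cfg = make_config(n_wolves=3, dim=1, lower_bounds=-10.0,
                          upper_bounds=10.0)
        pack = initialize_pack(cfg, sphere)
        pack.positions = np.array([[0.5], [0.3], [0.1]])
        pack.fitness = np.array([1.0, 2.0, 3.0])
        pack.leaders = (0, 1, 2)
        # v1, v2 per leader for wolf 0, then filler for the other two wolves
        draws = [0.25, 0.75, 0.5, 0.5, 1.0, 0.0] + [0.5] * 12
        pack.rng = FakeRng(draws)
        m = 0.4
        expected = []
        for (gw_l, v1, v2), p in zip(
                [(0.5, 0.25, 0.75), (0.3, 0.5, 0.5), (0.1, 1.0, 0.0)],
                [0.5] * 3):
            x = 2 * m * v1 - m
            y = 2 * v2
            E = abs(y * gw_l - p)
            expected.append(gw_l - x * E)
        want = np.mean(expected)
        new = pounce_update(pack, m=m, config=cfg)
        assert new[0, 0] == pytest.approx(want, abs=1e-12)

    def test_variants_coincide_at_zero_scale(self):
        for variant in ("standard", "paper"):
            cfg = make_config(variant=variant, n_wolves=3, dim=2, seed=5)
            pack = initialize_pack(cfg, sphere)
            new = pounce_update(pack, m=0.0, config=cfg)
            if variant == "standard":
                ref = new
        np.testing.assert_allclose(ref, new)


class TestOptimize:
    def test_sphere_converges(self):
        cfg = GWOConfig(n_wolves=30, dim=5, max_iters=200, lower_bounds=-10.0,
                        upper_bounds=10.0, seed=1)
        res = optimize(sphere, cfg)
        assert res.best_fitness <= 1e-3
        assert res.evaluations == 30 * 201

    def test_constant_objective_flat_history(self):
        cfg = make_config(max_iters=5)
        res = optimize(lambda z: 3.5, cfg)
        assert res.history == [3.5] * 6
        assert res.best_fitness == 3.5

    def test_zero_iterations_returns_best_initial(self):
        cfg = make_config(max_iters=0, seed=2)
        pack = initialize_pack(make_config(max_iters=0, seed=2), sphere)
        res = optimize(sphere, cfg)
        assert res.best_fitness == pack.fitness.min()

    def test_history_monotone_and_bounds_preserved(self):
        checked = []

        def cb(t, pack):
            checked.append(bool(np.all(pack.positions >= -2.0)
                                and np.all(pack.positions <= 2.0)))

        cfg = GWOConfig(n_wolves=8, dim=3, max_iters=100, lower_bounds=-2.0,
                        upper_bounds=2.0, seed=4)
        res = optimize(lambda z: float(np.abs(z).sum()), cfg, callback=cb)
        assert all(checked) and len(checked) == 101
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_seeded_reproducibility_bitwise(self):
        cfg = dict(n_wolves=6, dim=2, max_iters=30, lower_bounds=-3.0,
                   upper_bounds=3.0, seed=9)
        r1 = optimize(sphere, GWOConfig(**cfg))
        r2 = optimize(sphere, GWOConfig(**cfg))
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.history == r2.history

    def test_nan_objective_becomes_inf_with_warning(self):
        calls = {"n": 0}

        def flaky(z):
            calls["n"] += 1
            return float("nan") if calls["n"] == 7 else sphere(z)

        cfg = make_config(max_iters=3)
        with pytest.warns(RuntimeWarning, match="NaN"):
            res = optimize(flaky, cfg)
        assert np.isfinite(res.best_fitness)

    def test_trace_csv_round_trip(self, tmp_path):
        res = optimize(sphere, make_config(max_iters=4))
        path = tmp_path / "trace.csv"
        write_trace_csv(res, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness,mean_fitness,m"
        assert len(lines) == 6  # header + T+1 rows

    def test_object_wrapper(self):
        res = GreyWolfOptimizer(n_wolves=12, dim=2, max_iters=60,
                                lower_bounds=-5, upper_bounds=5,
                                seed=3).optimize(sphere)
        assert res.best_fitness < 1e-2


def test_convergence_three_orders_of_magnitude():
    """Median sphere fitness over 10 seeds drops >= 1000x in 200 iterations."""
    drops = []
    for seed in range(10):
        cfg = GWOConfig(n_wolves=30, dim=5, max_iters=200, lower_bounds=-10.0,
                        upper_bounds=10.0, seed=seed)
        res = optimize(sphere, cfg)
        drops.append(res.history[0] / max(res.history[-1], 1e-300))
    assert np.median(drops) >= 1e3
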