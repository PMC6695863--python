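import numpy as np
import pytest

from npzdvar.adjoint import (ObservationSet, StepPolicy, adjoint_sweep, assimilate,
                             cost, project_to_independent_points, steepest_descent)
from npzdvar.grid import make_synthetic_forcing, surface_to_3d
from npzdvar.ips import IndependentPointSet
from npzdvar.model import NPZDModel

from conftest import rectangle_grid


def _small_problem(grid, days=1.0, n_steps=4, seed=0):
    """Model, base state and synthetic observations on a small grid."""
    f = make_synthetic_forcing(grid, days=days, step_hours=6, seed=seed,
                               max_speed=0.05)
    model = NPZDModel(grid, f)
    rng = np.random.default_rng(seed)
    surf = np.where(grid.mask, 1.0 + 0.5 * rng.random(grid.mask.shape), 0.0)
    state0 = model.initial_state(surface_to_3d(grid, surf), 6.0, 0.1, 0.1)
    traj = model.run(state0.copy(), n_steps)
    obs = ObservationSet(
        traj.surface_p + 0.3 * rng.standard_normal(traj.surface_p.shape),
        np.ones_like(traj.surface_p))
    return model, state0, traj, obs


class TestObservationSet:
    def test_weights_must_be_binary(self):
        with pytest.raises(ValueError):
            ObservationSet(np.ones((2, 3)), np.full((2, 3), 0.5))

    def test_nonfinite_observed_rejected(self):
        vals = np.ones((2, 2))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            ObservationSet(vals, np.ones((2, 2)))
        # NaN is fine where the weight is zero
        w = np.ones((2, 2))
        w[0, 0] = 0.0
        ObservationSet(vals, w)


class TestCost:
    def test_perfect_fit(self):
        p = np.ones((3, 4))
        obs = ObservationSet(p.copy(), np.ones_like(p))
        assert cost(p, obs) == 0.0

    def test_single_point(self):
        p = np.zeros((1, 1))
        obs = ObservationSet(np.full((1, 1), 2.0), np.ones((1, 1)))
        assert cost(p, obs) == pytest.approx(2.0)  # 0.5 * 2^2

    def test_brute_force_sum(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 20))
        po = rng.random((5, 20))
        w = (rng.random((5, 20)) > 0.4).astype(float)
        obs = ObservationSet(po, w)
        manual = 0.5 * sum(
            w[t, i] * (p[t, i] - po[t, i]) ** 2
            for t in range(5) for i in range(20))
        assert cost(p, obs) == pytest.approx(manual, rel=1e-12)

    def test_shape_mismatch(self):
        obs = ObservationSet(np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            cost(np.ones((3, 2)), obs)


class TestAdjointSweep:
    def test_zero_misfit_zero_gradient(self, grid_5x5):
        model, state0, traj, _ = _small_problem(grid_5x5)
        obs = ObservationSet(traj.surface_p.copy(), np.ones_like(traj.surface_p))
        g = adjoint_sweep(traj, obs, model=model)
        assert not g.any()

    def test_time_mismatch_rejected(self, grid_5x5):
        model, state0, traj, obs = _small_problem(grid_5x5)
        bad = ObservationSet(obs.values[:-1], obs.weights[:-1])
        with pytest.raises(ValueError):
            adjoint_sweep(traj, bad, model=model)

    @pytest.mark.parametrize("masked", [False, True])
    def test_gradient_matches_finite_differences(self, grid_5x5, masked):
        """Central-difference oracle on a 5x5x2 grid, 4 steps, <=1e-6 relative."""
        model, state0, traj, obs = _small_problem(grid_5x5, n_steps=4)
        if masked:
            rng = np.random.default_rng(5)
            w = (rng.random(obs.weights.shape) > 0.3).astype(float)
            obs = ObservationSet(obs.values, w)
        g_adj = adjoint_sweep(traj, obs, model=model)

        def j_of_p0(pflat):
            s = state0.copy()
            s[1] = pflat
            return cost(model.run(s, 4).surface_p, obs)

        h = 1e-5
        base = state0[1]
        g_fd = np.zeros_like(g_adj)
        for i in range(grid_5x5.n_active):
            up, dn = base.copy(), base.copy()
            up[i] += h
            dn[i] -= h
            g_fd[i] = (j_of_p0(up) - j_of_p0(dn)) / (2 * h)
        scale = np.abs(g_fd) + 1e-12
        assert (np.abs(g_adj - g_fd) / scale).max() < 1e-6

    def test_transport_dot_product_identity(self, grid_5x5):
        """<Ax, y> == <x, A^T y> to 1e-12 for the pure transport operator."""
        model, *_ = _small_problem(grid_5x5)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, grid_5x5.n_active))
        y = rng.standard_normal((4, grid_5x5.n_active))
        lhs = float(np.sum(model._apply_transport(x) * y))
        rhs = float(np.sum(x * model._apply_transport_T(y)))
        assert abs(lhs - rhs) <= 1e-12 * max(abs(lhs), 1.0)


class TestProjection:
    def test_identity_weights_pass_through(self):
        g = rectangle_grid(6, 6, layers=(5.0,), depth=8.0)
        ips = IndependentPointSet.from_grid(g, 1, "spline")
        rng = np.random.default_rng(0)
        grad = rng.random(g.n_wet)
        out = project_to_independent_points(grad, ips)
        np.testing.assert_allclose(out, grad, atol=1e-9)

    def test_uniform_gradient_gives_column_sums(self):
        g = rectangle_grid(10, 10, layers=(5.0,), depth=8.0)
        ips = IndependentPointSet.from_grid(g, 5, "cressman")
        out = project_to_independent_points(np.ones(g.n_wet), ips)
        np.testing.assert_allclose(out, ips.kappa.sum(axis=0), rtol=1e-12)

    def test_brute_force_transpose(self):
        g = rectangle_grid(8, 7, layers=(5.0,), depth=8.0)
        ips = IndependentPointSet.from_grid(g, 3, "cressman")
        rng = np.random.default_rng(2)
        grad = rng.random(g.n_wet)
        got = project_to_independent_points(grad, ips)
        want = np.zeros(ips.n_points)
        for n in range(ips.n_points):
            for cell in range(g.n_wet):
                want[n] += ips.kappa[cell, n] * grad[cell]
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestSteepestDescent:
    def test_zero_gradient_unchanged(self):
        c = np.array([1.0, 2.0])
        out = steepest_descent(c, np.zeros(2), alpha=0.5)
        np.testing.assert_array_equal(out, c)

    def test_1d_quadratic_unnormalized(self):
        # J = x^2/2, gradient x; x0=1, alpha=0.5 -> x1=0.5
        out = steepest_descent(np.array([1.0]), np.array([1.0]),
                               alpha=0.5, normalize=False)
        assert out[0] == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            steepest_descent(np.ones(2), np.ones(3), alpha=0.1)


def _twin_10x10(seed=0):
    g = rectangle_grid(10, 10, layers=(5.0,), depth=8.0)
    f = make_synthetic_forcing(g, days=2, step_hours=6, seed=seed, max_speed=0.05)
    model = NPZDModel(g, f)
    plane = 1.5 + 0.03 * np.arange(g.nx)[None, :] + 0.02 * np.arange(g.ny)[:, None]
    truth3d = surface_to_3d(g, plane)
    state0 = model.initial_state(truth3d, 6.0, 0.1, 0.1)
    traj = model.run(state0, 8)
    obs = ObservationSet.full_coverage(traj.surface_p)
    ips = IndependentPointSet.from_grid(g, 5, "spline")
    return g, f, obs, ips, plane


class TestAssimilate:
    def test_obs_equal_guess_converges_immediately(self):
        g, f, obs, ips, plane = _twin_10x10()
        control0 = ips.sample(plane)  # plane is exactly representable
        result = assimilate(g, f, obs, ips, control0, days=2, step_hours=6)
        assert result.iterations_run == 0
        np.testing.assert_allclose(result.ncf_history, [1.0])

    def test_recovers_plane_truth(self):
        g, f, obs, ips, plane = _twin_10x10()
        control0 = np.full(ips.n_points, plane.mean())
        result = assimilate(g, f, obs, ips, control0, days=2, step_hours=6,
                            max_iterations=80)
        assert result.final_ncf < 1e-3
        np.testing.assert_allclose(result.final_field[g.mask], plane[g.mask],
                                   atol=0.05)

    def test_ncf_starts_at_one_and_non_increasing(self):
        g, f, obs, ips, plane = _twin_10x10()
        control0 = np.full(ips.n_points, plane.mean())
        result = assimilate(g, f, obs, ips, control0, days=2, step_hours=6,
                            max_iterations=30)
        assert result.ncf_history[0] == 1.0
        assert (np.diff(result.ncf_history) <= 0).all()
        assert len(result.ncf_history) == result.iterations_run + 1

    def test_deterministic(self):
        histories = []
        for _ in range(2):
            g, f, obs, ips, plane = _twin_10x10(seed=3)
            control0 = np.full(ips.n_points, plane.mean())
            r = assimilate(g, f, obs, ips, control0, days=2, step_hours=6,
                           max_iterations=15)
            histories.append(r.ncf_history)
        np.testing.assert_array_equal(histories[0], histories[1])
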