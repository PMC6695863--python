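import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npzdvar.grid import make_bohai_grid, make_synthetic_forcing, make_truth_ie1
from npzdvar.model import (CFLError, EcoParameters, EcoState, NPZDModel,
                           biological_tendencies, grazing_rate, light_limitation,
                           nutrient_limitation, run_forward, spin_up,
                           temperature_factor, transport_step)

from conftest import rectangle_grid


class TestEcoParameters:
    def test_defaults(self):
        p = EcoParameters()
        assert (p.Vm, p.Gm, p.Dp, p.Dz, p.e) == (1.0, 0.5, 0.1, 0.2, 0.05)
        assert (p.AQ10, p.BQ10, p.gamma, p.theta) == (2.08, 3.10, 0.75, 0.03)
        assert (p.Kext, p.Io, p.wp, p.wd, p.Ks, p.f_ivlev) == (1.0, 100.0, 0.73, 1.0, 1.0, 0.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            EcoParameters(Vm=-1.0)
        with pytest.raises(ValueError):
            EcoParameters(gamma=1.5)
        with pytest.raises(ValueError):
            EcoParameters(theta=1.01)


class TestKinetics:
    def test_temperature_factor(self):
        assert temperature_factor(10.0, 2.08) == pytest.approx(1.0)
        assert temperature_factor(20.0, 2.08) == pytest.approx(2.08)
        assert temperature_factor(15.0, 3.10) == pytest.approx(np.sqrt(3.10))

    def test_nutrient_limitation(self):
        assert nutrient_limitation(1.0, 1.0) == pytest.approx(0.5)
        assert nutrient_limitation(0.0, 1.0) == 0.0
        assert nutrient_limitation(3.0, 1.0) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            nutrient_limitation(-1.0, 1.0)

    def test_light_limitation(self):
        assert light_limitation(100.0, 100.0) == pytest.approx(1.0)
        assert light_limitation(0.0, 100.0) == 0.0
        assert light_limitation(200.0, 100.0) == pytest.approx(2.0 * np.exp(-1.0))

    def test_grazing_rate(self):
        assert grazing_rate(0.0, 0.5, 0.2, 10.0, 3.10) == 0.0
        assert grazing_rate(1e9, 0.5, 0.2, 10.0, 3.10) == pytest.approx(0.5)
        assert grazing_rate(5.0, 0.5, 0.2, 10.0, 3.10) == pytest.approx(
            0.5 * (1.0 - np.exp(-1.0)))


def _oracle_tendencies(N, P, Z, D, T, I, p: EcoParameters):
    """Term-by-term scalar reimplementation of the biology."""
    tfA = p.AQ10 ** ((T - 10.0) / 10.0)
    tfB = p.BQ10 ** ((T - 10.0) / 10.0)
    light = (I / p.Io) * np.exp(1.0 - I / p.Io)
    uptake = p.Vm * tfA * light * (N / (p.Ks + N)) * P
    graze = p.Gm * tfB * (1.0 - np.exp(-p.f_ivlev * P)) * Z
    dN = -uptake + p.theta * graze + p.e * D
    dP = uptake - graze - p.Dp * P
    dZ = p.gamma * graze - p.theta * graze - p.Dz * Z
    dD = (1.0 - p.gamma) * graze + p.Dp * P + p.Dz * Z - p.e * D
    return np.array([dN, dP, dZ, dD])


class TestBiologicalTendencies:
    def test_zero_state_fixed_point(self):
        s = EcoState(*(np.zeros(3) for _ in range(4)))
        out = biological_tendencies(s, 15.0, 50.0, EcoParameters())
        assert all(not np.any(t) for t in out)

    def test_nitrogen_closure(self):
        rng = np.random.default_rng(2)
        s = EcoState(*(rng.random(50) * 3 for _ in range(4)))
        dN, dP, dZ, dD = biological_tendencies(s, 18.0, 40.0, EcoParameters())
        np.testing.assert_allclose(dN + dP + dZ + dD, 0.0, atol=1e-14)

    @given(n=st.floats(0, 10), p_=st.floats(0, 5), z=st.floats(0, 5),
           d=st.floats(0, 5), t=st.floats(-2, 35), i=st.floats(0, 300))
    @settings(max_examples=60)
    def test_closure_property(self, n, p_, z, d, t, i):
        s = EcoState(np.array([n]), np.array([p_]), np.array([z]), np.array([d]))
        out = biological_tendencies(s, t, i, EcoParameters())
        assert abs(sum(float(x[0]) for x in out)) < 1e-12 * max(1.0, n + p_ + z + d)

    def test_against_oracle(self):
        p = EcoParameters()
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, pp, z, d = rng.random(4) * 4
            t, i = rng.uniform(5, 30), rng.uniform(0, 200)
            s = EcoState(*(np.array([v]) for v in (n, pp, z, d)))
            got = np.array([float(x[0]) for x in biological_tendencies(s, t, i, p)])
            want = _oracle_tendencies(n, pp, z, d, t, i, p)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_negative_input_rejected(self):
        s = EcoState(np.array([-0.1]), np.zeros(1), np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError):
            biological_tendencies(s, 15.0, 50.0, EcoParameters())


class TestTransport:
    def test_identity_when_quiescent(self, coarse_grid):
        g = coarse_grid
        f = make_synthetic_forcing(g, days=1, seed=0, max_speed=0.0,
                                   horizontal_diffusivity=0.0, vertical_diffusivity=0.0)
        rng = np.random.default_rng(0)
        field = np.where(g.active, rng.random(g.active.shape), 0.0)
        out = transport_step(field, g, f, sinking_speed=0.0)
        np.testing.assert_array_equal(out[g.active], field[g.active])

    def test_constant_preserved_under_divergence_free_flow(self, coarse_grid):
        g = coarse_grid
        f = make_synthetic_forcing(g, days=1, seed=3, max_speed=0.1)
        field = np.where(g.active, 2.5, 0.0)
        out = transport_step(field, g, f, sinking_speed=0.0)
        np.testing.assert_allclose(out[g.active], 2.5, rtol=1e-12)

    def test_mass_conservation_with_sinking(self, coarse_grid):
        g = coarse_grid
        f = make_synthetic_forcing(g, days=1, seed=4, max_speed=0.1)
        rng = np.random.default_rng(1)
        field = np.where(g.active, rng.random(g.active.shape) + 0.5, 0.0)
        vol = g.cell_volumes
        m0 = (g.flatten(field) * vol).sum()
        out = field
        for _ in range(10):
            out = transport_step(out, g, f, sinking_speed=1.0)
        m1 = (g.flatten(out) * vol).sum()
        assert abs(m1 - m0) / m0 < 1e-10

    def test_cfl_violation_raises(self, default_grid):
        f = make_synthetic_forcing(default_grid, days=1, seed=0, max_speed=2.0)
        field = np.zeros(default_grid.active.shape)
        with pytest.raises(CFLError):
            transport_step(field, default_grid, f, dt_seconds=21600.0)


class TestRunForward:
    def test_zero_days_returns_initial(self, coarse_grid, coarse_forcing):
        truth = make_truth_ie1(coarse_grid)
        traj = run_forward(truth, coarse_grid, coarse_forcing, days=0)
        assert traj.n_times == 1
        np.testing.assert_array_equal(traj.states[0, 1], coarse_grid.flatten(truth.values))

    def test_closed_basin_nitrogen_conservation(self, coarse_grid, coarse_forcing):
        truth = make_truth_ie1(coarse_grid)
        traj = run_forward(truth, coarse_grid, coarse_forcing, days=30)
        vol = coarse_grid.cell_volumes
        total = (traj.states.sum(axis=1) * vol).sum(axis=1)
        assert np.abs(total - total[0]).max() / total[0] < 1e-8

    def test_positivity(self, coarse_grid, coarse_forcing):
        truth = make_truth_ie1(coarse_grid)
        traj = run_forward(truth, coarse_grid, coarse_forcing, days=30)
        assert traj.states.min() >= 0.0
        vol = coarse_grid.cell_volumes
        total0 = (traj.states[0].sum(axis=0) * vol).sum()
        assert traj.clipped_mass / total0 < 1e-3

    def test_surface_series_shape(self, coarse_grid, coarse_forcing):
        truth = make_truth_ie1(coarse_grid)
        traj = run_forward(truth, coarse_grid, coarse_forcing, days=2)
        assert traj.surface_p.shape == (9, coarse_grid.n_wet)

    def test_zero_d_oracle_bitwise(self):
        """Single wet cell, no flow: match an independent scalar Euler loop."""
        depth = np.zeros((4, 5))
        depth[2, 2] = 6.0
        g = make_bohai_grid(60.0, [5.0], bathymetry=depth)
        assert g.n_active == 1
        f = make_synthetic_forcing(g, days=3, step_hours=6, seed=11, max_speed=0.0,
                                   horizontal_diffusivity=0.0, vertical_diffusivity=0.0)
        p = EcoParameters()
        traj = run_forward(2.0, g, f, p, days=3, step_hours=6,
                           initial_N=6.0, initial_Z=0.1, initial_D=0.1)

        state = np.array([6.0, 2.0, 0.1, 0.1])
        h = 0.25
        z_mid = 2.5
        for k in range(12):
            T = f.sst[k, 2, 2]
            irr = f.surface_irradiance[k] * np.exp(-p.Kext * z_mid)
            state = state + h * _oracle_tendencies(*state, T, irr, p)
            np.testing.assert_array_equal(traj.states[k + 1, :, 0], state)

    def test_spin_up_returns_positive_fields(self, coarse_grid, coarse_forcing):
        z0, d0 = spin_up(coarse_grid, coarse_forcing, days=2)
        assert z0.shape == (coarse_grid.n_active,)
        assert (z0 >= 0).all() and (d0 >= 0).all()
        assert not np.allclose(d0, d0[0])  # structure has developed


class TestConservativeClipping:
    def test_deficit_taken_from_n(self):
        g = rectangle_grid(2, 2, layers=(5.0,), depth=6.0)
        f = make_synthetic_forcing(g, days=1, seed=0, max_speed=0.0,
                                   horizontal_diffusivity=0.0, vertical_diffusivity=0.0)
        model = NPZDModel(g, f)
        state = np.stack([np.full(4, 5.0), np.full(4, -0.2),
                          np.full(4, 0.3), np.full(4, 0.4)])
        clipped = model._clip(state)
        assert (clipped[1] == 0.0).all()
        np.testing.assert_allclose(clipped[0], 4.8)
        np.testing.assert_allclose(clipped.sum(axis=0), state.sum(axis=0))
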