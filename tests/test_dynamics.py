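"""Euler–Maruyama stepping, boundaries, initialization and ensemble contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mechanocell as mc
from mechanocell.dynamics import (
    CellState,
    IntegrationInstabilityError,
    apply_boundary,
    em_step,
    sample_initial_positions,
)
from mechanocell.potentials import PotentialSpec


class TestEmStep:
    def test_no_force_no_noise_leaves_position(self):
        s = CellState(position=np.array([3.0, 4.0]))
        out = em_step(s, PotentialSpec(alpha=0.0), DT=1.0, dt=1e-3, noise=np.zeros(2))
        assert np.allclose(out.position, s.position)

    def test_deterministic_drift(self):
        # force (-3, 0) on the attractive branch at unit separation, alpha=1
        s = CellState(position=np.array([1.0 + 1e-12, 0.0]))
        out = em_step(s, PotentialSpec(alpha=1.0), DT=0.0, dt=1e-3, noise=np.zeros(2))
        assert np.allclose(out.position - s.position, [-3e-3, 0.0], rtol=1e-6)
        assert np.allclose(out.unwrapped_position, out.position)

    def test_noise_variance_matches_diffusivity(self):
        # accumulated per-component displacement variance over many steps = 2*DT*dt
        rng = np.random.default_rng(1234)
        DT, dt, n = 2.0, 1e-3, 100_000
        s = CellState(position=np.array([50.0, 50.0]))
        deltas = []
        spec = PotentialSpec(alpha=0.0)
        for noise in rng.standard_normal((n, 2)):
            out = em_step(s, spec, DT=DT, dt=dt, noise=noise)
            deltas.append(out.position - s.position)
        var = np.var(np.asarray(deltas), axis=0)
        assert np.allclose(var, 2 * DT * dt, rtol=0.03)

    def test_invalid_steps(self):
        s = CellState(position=np.array([2.0, 0.0]))
        with pytest.raises(ValueError):
            em_step(s, PotentialSpec(alpha=1.0), DT=1.0, dt=0.0, noise=np.zeros(2))
        with pytest.raises(ValueError):
            em_step(s, PotentialSpec(alpha=1.0), DT=-1.0, dt=1e-3, noise=np.zeros(2))


class TestApplyBoundary:
    CFG_R = mc.SimulationConfig(dt=1e-3, total_time=1.0, boundary="reflecting")
    CFG_P = mc.SimulationConfig(dt=1e-3, total_time=1.0, boundary="periodic")

    def test_specular_mirror(self):
        s = CellState(position=np.array([12.3, 5.0]))
        out = apply_boundary(s, self.CFG_R)
        assert np.allclose(out.position, [11.7, 5.0])
        assert np.allclose(out.unwrapped_position, out.position)

    def test_periodic_wrap_preserves_unwrapped(self):
        s = CellState(position=np.array([12.3, 5.0]), unwrapped_position=np.array([12.3, 5.0]))
        out = apply_boundary(s, self.CFG_P)
        assert np.allclose(out.position, [0.3, 5.0])
        assert np.allclose(out.unwrapped_position, [12.3, 5.0])

    def test_in_range_identity(self):
        s = CellState(position=np.array([3.0, 4.0]))
        for cfg in (self.CFG_R, self.CFG_P):
            assert np.allclose(apply_boundary(s, cfg).position, s.position)

    def test_negative_coordinate_mirrors(self):
        s = CellState(position=np.array([-0.4, 6.0]))
        assert np.allclose(apply_boundary(s, self.CFG_R).position, [0.4, 6.0])

    def test_runaway_step_raises(self):
        s = CellState(position=np.array([40.0, 5.0]))
        with pytest.raises(IntegrationInstabilityError):
            apply_boundary(s, self.CFG_R)

    @given(x=st.floats(-11.9, 23.9), y=st.floats(-11.9, 23.9))
    def test_reflection_lands_inside(self, x, y):
        out = apply_boundary(CellState(position=np.array([x, y])), self.CFG_R)
        assert np.all(out.position >= 0.0) and np.all(out.position <= 12.0)


class TestInitialization:
    CFG = mc.SimulationConfig(dt=1e-3, total_time=1.0)

    def test_positions_respect_exclusion_and_box(self):
        rng = np.random.default_rng(0)
        pos = sample_initial_positions(self.CFG, 2000, rng)
        r = np.linalg.norm(pos - 6.0, axis=1)
        assert np.all(r > 1.5)
        assert np.all((pos >= 0) & (pos <= 12))

    def test_no_exclusion_is_uniform_box(self):
        cfg = mc.SimulationConfig(dt=1e-3, total_time=1.0, contact_radius=0.0)
        rng = np.random.default_rng(0)
        pos = sample_initial_positions(cfg, 5000, rng)
        assert np.all((pos >= 0) & (pos <= 12))
        # uniform mean is the box centre; se = L/sqrt(12 n)
        se = 12.0 / np.sqrt(12 * 5000)
        assert np.allclose(pos.mean(axis=0), 6.0, atol=3 * se)

    def test_mean_is_box_centre_by_symmetry(self):
        rng = np.random.default_rng(1)
        pos = sample_initial_positions(self.CFG, 10_000, rng)
        se = 12.0 / np.sqrt(12 * 10_000)
        assert np.allclose(pos.mean(axis=0), 6.0, atol=3.5 * se)

    def test_covering_disc_is_invalid(self):
        # contact disc of radius > L/sqrt(2) covers the whole box
        cfg = mc.SimulationConfig(
            dt=1e-3, total_time=1.0, box_size=6.0, contact_radius=4.5, boundary="none"
        )
        with pytest.raises(ValueError):
            sample_initial_positions(cfg, 5, np.random.default_rng(0))


class TestTrajectories:
    def test_deterministic_attraction_without_noise(self):
        # DT=0, init on the attractive branch: monotone radial approach
        params = mc.ScaledParams(alpha=5.0, DT=1e-300)
        cfg = mc.SimulationConfig(dt=1e-3, total_time=20.0, n_trajectories=1, seed=0)
        init = mc.CellState(position=np.array([10.0, 6.0]))
        traj = mc.run_trajectory(params, None, cfg, init)
        r = mc.distance_to_stationary(traj.positions, cfg)
        assert np.all(np.diff(r) <= 1e-12)
        assert r[-1] < r[0]

    def test_nothing_moves_without_force_or_noise(self):
        params = mc.ScaledParams(alpha=0.0, DT=1e-300)
        cfg = mc.SimulationConfig(dt=1e-3, total_time=1.0, seed=0)
        init = mc.CellState(position=np.array([3.0, 3.0]))
        traj = mc.run_trajectory(params, None, cfg, init)
        assert np.allclose(traj.positions, traj.positions[0])

    def test_same_seed_bitwise_identical(self):
        params = mc.ScaledParams(alpha=2.0, DT=1.0)
        cfg = mc.SimulationConfig(dt=1e-3, total_time=5.0, n_trajectories=4, seed=99)
        a = mc.run_ensemble(params, cfg)
        b = mc.run_ensemble(params, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.unwrapped, b.unwrapped)

    def test_single_trajectory_matches_ensemble_substream(self):
        params = mc.ScaledParams(alpha=2.0, DT=1.0)
        cfg = mc.SimulationConfig(dt=1e-3, total_time=2.0, n_trajectories=1, seed=7)
        init = np.array([[3.0, 4.0]])
        ens = mc.run_ensemble(params, cfg, init_positions=init)
        traj = mc.run_trajectory(params, None, cfg, mc.CellState(position=init[0]))
        assert np.array_equal(ens.positions[0], traj.positions)

    def test_em_step_equivalence_with_engine(self):
        # the vectorized engine reproduces repeated em_step + apply_boundary
        params = mc.ScaledParams(alpha=3.0, DT=1.5)
        cfg = mc.SimulationConfig(
            dt=1e-3, total_time=0.05, n_trajectories=1, seed=5, record_stride=1
        )
        init = np.array([[4.0, 7.0]])
        ens = mc.run_ensemble(params, cfg, init_positions=init)
        # replay with the same substream
        children = np.random.SeedSequence(5).spawn(2)
        rng = np.random.Generator(np.random.PCG64(children[1]))
        spec = PotentialSpec(alpha=3.0, ksteric=1e3)
        state = mc.CellState(position=init[0])
        for k in range(cfg.n_steps):
            noise = rng.standard_normal(2)
            state = em_step(state, spec, DT=1.5, dt=1e-3, noise=noise, center=cfg.center)
            state = apply_boundary(state, cfg)
        assert np.allclose(ens.positions[0, -1], state.position, rtol=1e-12)

    def test_reflecting_conserves_probability(self, reflecting_ensemble):
        assert np.all(reflecting_ensemble.positions >= 0.0)
        assert np.all(reflecting_ensemble.positions <= 12.0)

    def test_periodic_unwrapped_offset_is_lattice_vector(self):
        params = mc.ScaledParams(alpha=1.0, DT=3.0)
        cfg = mc.SimulationConfig(
            dt=1e-3, total_time=30.0, boundary="periodic", n_trajectories=10, seed=11
        )
        ens = mc.run_ensemble(params, cfg)
        offset = (ens.unwrapped - ens.positions) / cfg.box_size
        assert np.allclose(offset, np.round(offset), atol=1e-9)

    def test_displacement_variance_grows_diffusively(self, free_diffusion_ensemble):
        # free diffusion: per-component variance of displacement = 2*DT*t
        ens = free_diffusion_ensemble
        disp = ens.unwrapped[:, -1] - ens.unwrapped[:, 0]
        t = ens.times[-1]
        var = disp.var(axis=0)
        se = 2 * 2.0 * t * np.sqrt(2.0 / len(ens))
        assert np.allclose(var, 2 * 2.0 * t, atol=3 * se)

    def test_boltzmann_equilibrium_in_reflecting_box(self):
        # long-run occupancy of the contact disc matches the equilibrium oracle
        params = mc.ScaledParams(alpha=2.0, DT=2.0)
        cfg = mc.SimulationConfig(
            dt=5e-4, total_time=120.0, boundary="reflecting",
            n_trajectories=80, seed=1234, record_stride=100,
        )
        ens = mc.run_ensemble(params, cfg)
        cap = mc.capture_statistics(ens)
        pss_eq = mc.boltzmann_pss(mc.OracleSpec(alpha=2.0, DT=2.0))
        assert cap.pss == pytest.approx(pss_eq, abs=3 * cap.pss_se)

    def test_trajectory_sampling_grid(self, reflecting_ensemble):
        traj = reflecting_ensemble.trajectory(0)
        assert np.allclose(np.diff(traj.times), 1e-3 * 10)
        assert len(traj) == reflecting_ensemble.positions.shape[1]


class TestConfigValidation:
    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            mc.SimulationConfig(dt=1e-3, total_time=1.0, box_size=2.0, contact_radius=1.5)
        with pytest.raises(ValueError):
            mc.SimulationConfig(dt=0.0, total_time=1.0)
        with pytest.raises(ValueError):
            mc.SimulationConfig(dt=1e-3, total_time=1.0, boundary="open")
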