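"""Brownian-dynamics engine: construction, physics oracles, kinetics, turnover."""

import copy
import math

import numpy as np
import pytest

from contranet.connectors import ConnectorType, SubunitKind
from contranet.dynamics import (
    SimulationUnstable,
    bending_energy,
    step_dynamics,
)
from contranet.kinetics import step_kinetics
from contranet.simulate import apply_turnover, run_simulation
from contranet.validation import (
    critical_buckling_load,
    diffusion_msd_experiment,
    motor_speed_experiment,
    sliding_speed_experiment,
)
from contranet.world import (
    Domain,
    FilamentSpec,
    Scenario,
    SimParams,
    TurnoverSpec,
    build_world,
)

DISC = Domain("disc", radius=5.0)


def _scenario(n_fil=10, connectors=(), seed=0, **param_kw) -> Scenario:
    defaults = dict(dt=1e-3, rng_seed=seed)
    defaults.update(param_kw)
    return Scenario(
        filaments=FilamentSpec(count=n_fil, length=3.0, rigidity=0.075),
        connectors=tuple(connectors),
        domain=DISC,
        params=SimParams(**defaults),
    )


def _motor(count, **kw):
    return ConnectorType((SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR), count=count, **kw)


def _xl(count, **kw):
    return ConnectorType((SubunitKind.SIDE_BINDER, SubunitKind.SIDE_BINDER), count=count, **kw)


class TestBuildWorld:
    def test_seed_determinism_is_bit_exact(self):
        w1 = build_world(_scenario(20, [_motor(50)], seed=42))
        w2 = build_world(_scenario(20, [_motor(50)], seed=42))
        assert w1.fingerprint() == w2.fingerprint()

    def test_different_seeds_differ(self):
        w1 = build_world(_scenario(20, seed=1))
        w2 = build_world(_scenario(20, seed=2))
        assert w1.fingerprint() != w2.fingerprint()

    def test_filament_count_and_exact_length(self):
        w = build_world(_scenario(17))
        assert w.fil_x.shape[0] == 17
        lengths = w.filament_segment_lengths().sum(axis=1)
        assert lengths == pytest.approx(np.full(17, 3.0), abs=1e-12)

    def test_disc_center_distribution_first_moment(self):
        """Uniform disc: E[r] = (2/3) R0."""
        w = build_world(_scenario(10_000, seed=7))
        centers = w.fil_x.mean(axis=1)
        mean_r = float(np.linalg.norm(centers, axis=1).mean())
        assert mean_r == pytest.approx(2.0 / 3.0 * DISC.radius, rel=0.02)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            FilamentSpec(count=-1)

    def test_unstable_dt_rejected_at_build(self):
        with pytest.raises(ValueError, match="stability"):
            build_world(_scenario(5, [_motor(5, stiffness=1e5)]))


class TestDynamics:
    def test_athermal_straight_filament_does_not_move(self):
        w = build_world(_scenario(3, kT=0.0))
        before = w.fil_x.copy()
        for _ in range(10):
            step_dynamics(w)
        assert np.array_equal(w.fil_x, before)

    def test_free_particle_msd_matches_einstein_relation(self):
        out = diffusion_msd_experiment(n_particles=3000, n_steps=1500, seed=3)
        assert out["measured"] == pytest.approx(out["expected"], rel=0.05)

    def test_bent_filament_relaxes_monotonically_athermal(self):
        w = build_world(_scenario(1, kT=0.0, drag=0.1))
        s = np.linspace(0, 3.0, w.n_pts)
        w.fil_x[0, :, 0] = s
        w.fil_x[0, :, 1] = 0.2 * np.sin(math.pi * s / 3.0)
        energies = [bending_energy(w)]
        for _ in range(3000):
            step_dynamics(w)
            energies.append(bending_energy(w))
        assert energies[-1] < 0.1 * energies[0]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_internal_forces_preserve_center_of_mass(self):
        """Two crossed filaments bridged by one stretched connector, kT = 0."""
        sc = _scenario(2, [_xl(1)], kT=0.0)
        w = build_world(sc)
        s = np.linspace(0, 3.0, w.n_pts)
        w.fil_x[0, :, 0] = s - 1.5
        w.fil_x[0, :, 1] = 0.0
        w.fil_x[1, :, 1] = s - 1.5
        w.fil_x[1, :, 0] = 0.3  # offset so the bridge is under tension
        w.c_fil[0] = (0, 1)
        w.c_s[0] = (1.5, 1.5)
        com0 = w.fil_x.mean(axis=(0, 1))
        for _ in range(100):
            step_dynamics(w)
        com1 = w.fil_x.mean(axis=(0, 1))
        assert com1 == pytest.approx(com0, abs=1e-10)

    def test_filament_length_conserved_in_active_network(self):
        sc = _scenario(20, [_motor(120), _xl(120)], seed=5)
        w = build_world(sc)
        run_simulation(w, t_end=2.0, record_frames=False)
        seg = w.filament_segment_lengths()
        assert np.max(np.abs(seg - w.seg)) / w.seg < 0.005

    def test_euler_buckling_load(self):
        out = critical_buckling_load(kappa=0.075, length=3.0)
        assert out["measured"] == pytest.approx(out["euler"], rel=0.15)

    def test_instability_is_reported(self):
        w = build_world(_scenario(2, kT=0.0))
        w.external_force = np.zeros_like(w.fil_x)
        w.external_force[0, 0] = (1e6, 0.0)
        with pytest.raises(SimulationUnstable):
            for _ in range(5):
                step_dynamics(w)


class TestMotors:
    def test_unloaded_motor_advances_exactly_v0_dt(self):
        out = motor_speed_experiment(load_fraction=0.0)
        assert out["advance"] == pytest.approx(out["v0_dt"], abs=1e-15)

    def test_stalled_motor_does_not_move(self):
        out = motor_speed_experiment(load_fraction=1.0)
        assert out["advance"] == 0.0

    def test_half_load_halves_speed(self):
        out = motor_speed_experiment(load_fraction=0.5)
        assert out["advance"] == pytest.approx(0.5 * out["v0_dt"], rel=1e-9)

    def test_antiparallel_sliding_speed_is_two_v0(self):
        out = sliding_speed_experiment()
        assert out["measured"] == pytest.approx(out["expected"], rel=0.05)

    def test_motor_detaches_at_filament_end(self):
        sc = _scenario(2, [_motor(1, k_off=0.0)], kT=0.0)
        w = build_world(sc)
        s = np.linspace(0, 3.0, w.n_pts)
        w.fil_x[0, :, 0] = s
        w.fil_x[0, :, 1] = 0.0
        w.fil_x[1, :, 0] = s
        w.fil_x[1, :, 1] = 0.02
        w.c_fil[0] = (0, 1)
        w.c_s[0] = (2.999, 2.999)
        for _ in range(10):
            step_kinetics(w)
        assert w.c_fil[0, 0] == -1 and w.c_fil[0, 1] == -1


class TestKinetics:
    def test_binding_respects_capture_range(self):
        """A crosslinker far from every filament never binds; one within ε
        binds at the closest filament point."""
        sc = _scenario(1, [_xl(2, k_on=1e4)], kT=0.0)
        w = build_world(sc)
        s = np.linspace(0, 3.0, w.n_pts)
        w.fil_x[0, :, 0] = s
        w.fil_x[0, :, 1] = 0.0
        w.c_pos[0] = (1.23, 0.04)  # within ε = 0.05
        w.c_pos[1] = (1.23, 1.0)  # far away
        for _ in range(5):
            step_kinetics(w)
        assert w.c_fil[0, 0] == 0 or w.c_fil[0, 1] == 0
        slot = 0 if w.c_fil[0, 0] == 0 else 1
        assert w.c_s[0, slot] == pytest.approx(1.23, abs=1e-9)
        assert (w.c_fil[1] == -1).all()

    def test_end_binder_attaches_at_the_end(self):
        eb = ConnectorType(
            (SubunitKind.PLUS_END_BINDER, SubunitKind.PLUS_END_BINDER), count=1, k_on=1e4
        )
        sc = _scenario(1, [eb], kT=0.0)
        w = build_world(sc)
        s = np.linspace(0, 3.0, w.n_pts)
        w.fil_x[0, :, 0] = s
        w.fil_x[0, :, 1] = 0.0
        w.c_pos[0] = (2.97, 0.02)  # near the plus end
        for _ in range(5):
            step_kinetics(w)
        bound = w.c_fil[0] >= 0
        assert bound.any()
        assert w.c_s[0, np.argmax(bound)] == 3.0

    def test_both_subunits_never_bind_one_filament(self):
        sc = _scenario(1, [_xl(30, k_on=1e3)], seed=9)
        w = build_world(sc)
        run_simulation(w, t_end=1.0, record_frames=False)
        both = (w.c_fil[:, 0] >= 0) & (w.c_fil[:, 1] >= 0)
        assert not np.any(w.c_fil[both, 0] == w.c_fil[both, 1])

    def test_seed_determinism_of_full_run(self):
        sc = _scenario(15, [_motor(60), _xl(60)], seed=11)
        t1 = run_simulation(build_world(sc), t_end=1.0, record_frames=False)
        t2 = run_simulation(build_world(sc), t_end=1.0, record_frames=False)
        assert np.array_equal(t1.radii, t2.radii)
        assert t1.events == t2.events


class TestPeriodicBoundaries:
    def _pbc_world(self, seed=3):
        sc = Scenario(
            filaments=FilamentSpec(count=12, length=3.0, rigidity=0.075),
            connectors=(_motor(40), _xl(40)),
            domain=Domain("periodic", side=6.0),
            params=SimParams(dt=1e-3, rng_seed=seed),
        )
        return build_world(sc)

    def test_lattice_translation_leaves_evolution_unchanged(self):
        w1 = self._pbc_world()
        w2 = copy.deepcopy(w1)
        shift = np.array([w2.domain.side, 2 * w2.domain.side])
        w2.fil_x += shift
        w2.c_pos += shift
        for _ in range(50):
            step_dynamics(w1)
            step_kinetics(w1)
            step_dynamics(w2)
            step_kinetics(w2)
        assert np.array_equal(w1.c_fil, w2.c_fil)
        assert np.allclose(w2.fil_x - shift, w1.fil_x, atol=1e-9)


class TestTurnover:
    def test_lifetime_arithmetic(self):
        spec = TurnoverSpec(enabled=True, rate=64.0)
        assert spec.mean_lifetime(1400) == pytest.approx(21.875)

    def test_disabled_turnover_changes_nothing(self):
        sc = _scenario(10)
        w = build_world(sc)
        fp = w.fingerprint()
        apply_turnover(w)
        assert w.fingerprint() == fp

    def test_event_counts_are_poisson_consistent(self):
        """Total events over t with rate R fall in the 99.7% Poisson band."""
        R, t_end, dt = 64.0, 10.0, 1e-3
        sc = Scenario(
            filaments=FilamentSpec(count=50, length=3.0, rigidity=0.075),
            connectors=(),
            domain=DISC,
            params=SimParams(dt=dt, rng_seed=21, kT=0.0),
            turnover=TurnoverSpec(enabled=True, rate=R),
        )
        w = build_world(sc)
        for _ in range(int(t_end / dt)):
            apply_turnover(w)
        mean = R * t_end
        assert abs(w.events["turnover"] - mean) <= 3.0 * math.sqrt(mean)

    def test_replacement_keeps_count_and_detaches_connectors(self):
        sc = Scenario(
            filaments=FilamentSpec(count=5, length=3.0, rigidity=0.075),
            connectors=(_xl(50, k_on=1e3),),
            domain=Domain("disc", radius=2.0),
            params=SimParams(dt=1e-3, rng_seed=2),
            turnover=TurnoverSpec(enabled=True, rate=2000.0),
        )
        w = build_world(sc)
        traj = run_simulation(w, t_end=0.5, record_frames=False)
        assert w.fil_x.shape[0] == 5
        assert traj.events["turnover"] > 0
        # all remaining attachments reference live filament indices
        att = w.c_fil[w.c_fil >= 0]
        assert att.size == 0 or att.max() < 5
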