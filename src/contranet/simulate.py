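"""Simulation driver: turnover events, the main loop, trajectories."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import step_dynamics
from .kinetics import step_kinetics
from .observables import network_radius
from .world import Domain, Scenario, World, build_world

__all__ = ["Trajectory", "apply_turnover", "run_simulation", "simulate_scenario"]


@dataclass
class Trajectory:
    """Sampled time series of a run.

    ``frames`` holds filament point coordinates, shape
    (n_frames, n_filaments, n_points, 2); frames are sampled on the
    half-open interval [0, t_end).  ``radii`` is the network radius per
    frame (see :func:`contranet.observables.network_radius`).
    """

    times: np.ndarray
    frames: np.ndarray
    radii: np.ndarray
    domain: Domain
    scenario: Scenario
    events: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def apply_turnover(world: World, dt: float | None = None) -> World:
    """Poisson filament-replacement events at the total turnover rate.

    Each event removes one uniformly chosen filament (its bound subunits
    detach; bridging connectors degrade to single-bound) and inserts a new
    straight filament at a uniform random position and orientation, keeping
    the filament count invariant.
    """
    spec = world.turnover
    if not spec.enabled or spec.rate <= 0.0 or world.n_fil == 0:
        return world
    dt = world.params.dt if dt is None else dt
    n_events = int(world.rng.poisson(spec.rate * dt))
    for _ in range(n_events):
        f = int(world.rng.integers(world.n_fil))
        if world.c_type.size:
            hit = world.c_fil == f
            if hit.any():
                world.c_fil[hit] = -1
        if world.m_type.size:
            hit = world.m_fil == f
            if hit.any():
                world.m_fil[hit] = -1
        center = world.domain.sample_positions(world.rng, 1)[0]
        phi = float(world.rng.uniform(0.0, 2.0 * math.pi))
        u = np.array([math.cos(phi), math.sin(phi)])
        offsets = np.linspace(-world.fil_length / 2.0, world.fil_length / 2.0, world.n_pts)
        world.fil_x[f] = center[None, :] + offsets[:, None] * u[None, :]
        world.events["turnover"] += 1
    if n_events:
        world.invalidate_neighbors()
    return world


def run_simulation(
    world: World,
    t_end: float | None = None,
    sample_interval: float | None = None,
    record_frames: bool = True,
    adaptive_dt: bool = False,
    max_dt_halvings: int = 4,
    log: bool = False,
) -> Trajectory:
    """Alternate dynamics, kinetics and turnover until ``t_end``.

    Frames are sampled every ``sample_interval`` on [0, t_end).  The run is
    fully determined by the scenario seed.

    With ``adaptive_dt`` the timestep is halved (up to ``max_dt_halvings``
    times below the configured dt) whenever the integrator reports an
    unstable step — transiently stiff spots such as dense contraction foci —
    and doubled back toward the configured dt after a stable stretch.  The
    state is never advanced by an unstable step, so the trajectory remains
    well defined.
    """
    from dataclasses import replace as _replace

    from .dynamics import SimulationUnstable

    p0 = world.params
    t_end = p0.t_end if t_end is None else t_end
    si = p0.sample_interval if sample_interval is None else sample_interval
    kin = p0.kinetics_stride
    dt_min = p0.dt / 2**max_dt_halvings

    times, frames, radii = [], [], []
    next_sample = 0.0
    step = 0
    stable_run = 0
    while world.time < t_end - 1e-12:
        if world.time >= next_sample - 1e-12:
            next_sample += si
            times.append(world.time)
            radii.append(network_radius(world.fil_x, world.domain))
            if record_frames:
                frames.append(world.fil_x.copy())
            if not np.all(np.isfinite(world.fil_x)):
                raise FloatingPointError(f"non-finite coordinates at t={world.time:.4f}s")
            if log:
                print(
                    f"t={world.time:8.3f}s  dt={world.params.dt:.2g}  R={radii[-1]:7.3f}μm  "
                    f"bind={world.events['bind']} unbind={world.events['unbind']} "
                    f"turnover={world.events['turnover']}"
                )
        try:
            step_dynamics(world)
        except SimulationUnstable:
            if not adaptive_dt or world.params.dt <= dt_min * (1 + 1e-9):
                raise
            world.params = _replace(world.params, dt=world.params.dt / 2.0)
            stable_run = 0
            continue
        stable_run += 1
        if adaptive_dt and world.params.dt < p0.dt and stable_run >= 2000:
            world.params = _replace(world.params, dt=min(p0.dt, world.params.dt * 2.0))
            stable_run = 0
        step += 1
        if step % kin == 0:
            step_kinetics(world, dt=world.params.dt * kin)
        apply_turnover(world)

    world.params = p0
    return Trajectory(
        times=np.asarray(times),
        frames=np.asarray(frames) if record_frames else np.zeros((0, world.n_fil, world.n_pts, 2)),
        radii=np.asarray(radii),
        domain=world.domain,
        scenario=world.scenario,
        events=dict(world.events),
    )


def simulate_scenario(scenario: Scenario, **kwargs) -> Trajectory:
    """Build the world for a scenario and run it to its configured t_end."""
    return run_simulation(build_world(scenario), **kwargs)
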