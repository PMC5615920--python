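"""Numerical validation experiments for the Brownian-dynamics engine.

Each experiment builds a micro-scenario with a known closed-form answer and
measures it with the same integrator used in production runs: free-particle
diffusion against the Einstein relation, the critical Euler buckling load of
a compressed filament, and the motor force–velocity law on constructed
filament pairs.  The experiments double as regression oracles in the test
suite and as reported diagnostics of the acceptance run.
"""

from __future__ import annotations

import math

import numpy as np

from .connectors import ConnectorType, SubunitKind
from .dynamics import step_dynamics
from .kinetics import step_kinetics
from .world import Domain, FilamentSpec, Scenario, SimParams, build_world

__all__ = [
    "diffusion_msd_experiment",
    "critical_buckling_load",
    "motor_speed_experiment",
    "sliding_speed_experiment",
]

_BIG_DISC = Domain("disc", radius=50.0)


def _crosslinker(count: int, **kw) -> ConnectorType:
    return ConnectorType(
        subunits=(SubunitKind.SIDE_BINDER, SubunitKind.SIDE_BINDER), count=count, **kw
    )


def _motor(count: int, **kw) -> ConnectorType:
    return ConnectorType(
        subunits=(SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR), count=count, **kw
    )


def diffusion_msd_experiment(
    n_particles: int = 2000,
    n_steps: int = 2000,
    dt: float = 1e-3,
    seed: int = 0,
) -> dict[str, float]:
    """Free point particles: measured MSD vs the Einstein value 4 D t.

    Returns measured and expected mean squared displacements (μm²) after
    ``n_steps`` steps, with D = kT / γ for the point-connector drag γ.
    """
    params = SimParams(dt=dt, rng_seed=seed, kT=0.0042)
    scenario = Scenario(
        filaments=FilamentSpec(count=0),
        connectors=(_crosslinker(n_particles, k_on=0.0),),
        domain=_BIG_DISC,
        params=params,
    )
    world = build_world(scenario)
    start = world.c_pos.copy()
    for _ in range(n_steps):
        step_dynamics(world)
    disp = world.c_pos - start
    msd = float(np.mean((disp * disp).sum(axis=1)))
    D = params.kT / params.drag_connector
    return {"measured": msd, "expected": 4.0 * D * n_steps * dt, "diffusivity": D}


def _bow_amplitude(x: np.ndarray) -> float:
    """Maximum distance of filament points from the end-to-end chord."""
    chord = x[-1] - x[0]
    n = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)
    return float(np.max(np.abs((x - x[0]) @ n)))


def _buckles(kappa, length, load, n_points, drag, dt, t_relax, amp0) -> bool:
    """Does a compressed filament's bow grow under axial end loads?

    The filament is loaded by two opposing follower forces applied at its
    ends along the end-to-end chord (the loading exerted by motors pulling
    the two ends together), whose critical load is the pinned-pinned Euler
    value π² κ / L².  Athermal run; the initial bow is a small sinusoid.
    """
    seg = length / (n_points - 1)
    params = SimParams(dt=dt, kT=0.0, drag=drag, segment_length=seg, rng_seed=0)
    scenario = Scenario(
        filaments=FilamentSpec(count=1, length=length, rigidity=kappa),
        connectors=(),
        domain=_BIG_DISC,
        params=params,
    )
    world = build_world(scenario)
    s = np.linspace(0.0, length, world.n_pts)
    world.fil_x[0, :, 0] = s
    world.fil_x[0, :, 1] = amp0 * np.sin(math.pi * s / length)
    world.external_force = np.zeros_like(world.fil_x)
    a_start = _bow_amplitude(world.fil_x[0])
    n_steps = int(round(t_relax / dt))
    for _ in range(n_steps):
        chord = world.fil_x[0, -1] - world.fil_x[0, 0]
        axis = chord / np.linalg.norm(chord)
        world.external_force[0, 0] = load * axis
        world.external_force[0, -1] = -load * axis
        step_dynamics(world)
    return _bow_amplitude(world.fil_x[0]) > a_start


def critical_buckling_load(
    kappa: float = 0.075,
    length: float = 3.0,
    n_points: int = 11,
    drag: float = 0.5,
    dt: float = 1e-3,
    t_relax: float = 10.0,
    amp0: float = 0.02,
    n_bisect: int = 7,
) -> dict[str, float]:
    """Critical axial load of a compressed filament, by bisection on the load.

    Returns the measured critical load and the Euler prediction π² κ / L².
    """
    euler = math.pi**2 * kappa / length**2
    lo, hi = 0.2 * euler, 5.0 * euler
    if _buckles(kappa, length, lo, n_points, drag, dt, t_relax, amp0):
        raise RuntimeError("lower bracket already buckles")
    if not _buckles(kappa, length, hi, n_points, drag, dt, t_relax, amp0):
        raise RuntimeError("upper bracket does not buckle")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if _buckles(kappa, length, mid, n_points, drag, dt, t_relax, amp0):
            hi = mid
        else:
            lo = mid
    return {"measured": 0.5 * (lo + hi), "euler": euler}


def _two_filament_world(
    offset: float,
    antiparallel: bool = False,
    drag: float = 5.0,
    dt: float = 1e-3,
    **conn_kw,
):
    """Two straight filaments along x, the second shifted by ``offset`` along
    x (and flipped when antiparallel), bridged by one plus/plus motor."""
    params = SimParams(dt=dt, kT=0.0, drag=drag, rng_seed=0)
    scenario = Scenario(
        filaments=FilamentSpec(count=2, length=3.0, rigid=True),
        connectors=(_motor(1, **conn_kw),),
        domain=_BIG_DISC,
        params=params,
    )
    world = build_world(scenario)
    s = np.linspace(0.0, 3.0, world.n_pts)
    world.fil_x[0, :, 0] = s
    world.fil_x[0, :, 1] = 0.0
    x2 = s + offset
    if antiparallel:
        x2 = x2[::-1]
    world.fil_x[1, :, 0] = x2
    world.fil_x[1, :, 1] = 0.02
    return world


def motor_speed_experiment(load_fraction: float = 0.0, dt: float = 1e-3) -> dict[str, float]:
    """Abscissa advance of a bridging motor per kinetics step, under a
    controlled opposing load (``load_fraction`` of the stall force).

    The opposing spring force is set by offsetting the partner attachment
    along the filament axis by load_fraction · f_s / k.  Filament dynamics
    is not stepped, so the measurement isolates the force–velocity law.
    """
    world = _two_filament_world(offset=0.0, dt=dt)
    ct = world.types[0]
    offset = load_fraction * ct.stall_force / ct.stiffness
    world.c_fil[0] = (0, 1)
    world.c_s[0] = (1.5, 1.5 - offset)  # partner sits `offset` behind along +x
    s_before = world.c_s[0, 0]
    step_kinetics(world)
    return {
        "advance": float(world.c_s[0, 0] - s_before),
        "expected": ct.v0 * max(0.0, 1.0 - load_fraction) * dt,
        "v0_dt": ct.v0 * dt,
    }


def sliding_speed_experiment(
    t_end: float = 0.5, dt: float = 2e-5
) -> dict[str, float]:
    """Relative sliding of two antiparallel filaments driven by one
    plus/plus motor in a low-drag medium (drag force « stall force);
    the unloaded expectation is 2 v0 (each motor subunit walks at v0 on its
    own filament).  The tiny dt keeps the spring-drag relaxation stable."""
    world = _two_filament_world(offset=0.0, antiparallel=True, drag=0.05, dt=dt, k_off=0.0)
    world.c_fil[0] = (0, 1)
    world.c_s[0] = (0.5, 0.5)
    x0 = world.fil_x[0, :, 0].mean() - world.fil_x[1, :, 0].mean()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        step_dynamics(world)
        step_kinetics(world)
    x1 = world.fil_x[0, :, 0].mean() - world.fil_x[1, :, 0].mean()
    v0 = world.types[0].v0
    return {"measured": abs(x1 - x0) / t_end, "expected": 2.0 * v0}
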