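"""Theory-versus-simulation comparison of two-connector systems.

For a subsample of the 210 equal-quantity two-connector systems (15
connector types × flexible/rigid filaments), the predicted χ and a
scaled-down simulated contraction rate are computed side by side.  A system
the theory calls non-neutral agrees when the simulated rate has the opposite
sign of χ (the rate convention is positive = contracting, χ < 0 =
contractile); a neutral system agrees when its |rate| stays within a noise
floor measured on connector-free networks of the same geometry.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .connectors import ALL_SUBUNIT_KINDS, OccupancyModel, SystemSpec, enumerate_connector_types
from .dynamics import SimulationUnstable
from .observables import contraction_rate_fit
from .scenarios import combination_pair
from .simulate import simulate_scenario
from .theory import FLEXIBLE, RIGID, MechanicalRegime, chi
from .world import SimParams

__all__ = ["noise_floor", "run_system", "sign_agreement_study"]

#: multiple of the connector-free rate spread defining the neutrality band
NOISE_FLOOR_SIGMAS = 3.0


def _sim_params(seed: int, t_end: float, dt: float = 1e-3) -> SimParams:
    return SimParams(
        dt=dt, t_end=t_end, sample_interval=0.25, rng_seed=seed, kinetics_stride=2
    )


def _simulate_stable(scenario):
    """Run a scenario with adaptive timestep halving on stiff transients.

    Dense systems (many springs per filament) can exceed the single-spring
    stability bound; adapting dt is a pure numerics adjustment that leaves
    the physical scenario unchanged.
    """
    return simulate_scenario(scenario, record_frames=False, adaptive_dt=True)


def noise_floor(
    regime: MechanicalRegime,
    scale: float,
    t_end: float,
    seeds: range = range(5),
) -> float:
    """Neutrality band: NOISE_FLOOR_SIGMAS × the std of fitted rates of
    connector-free networks across seeds (stochastic runs never give 0)."""
    rates = []
    for seed in seeds:
        scenario = combination_pair(
            # connector types are irrelevant at count 0
            *_floor_types(),
            regime=regime,
            scale=scale,
            n_each=0,
            params=_sim_params(seed, t_end),
        )
        traj = _simulate_stable(scenario)
        rates.append(contraction_rate_fit(traj.times, traj.radii).rate)
    return NOISE_FLOOR_SIGMAS * float(np.std(rates))


def _floor_types():
    types = enumerate_connector_types(ALL_SUBUNIT_KINDS)
    return types[0], types[1]


def run_system(
    system: SystemSpec,
    seed: int = 0,
    scale: float = 0.025,
    t_end: float = 10.0,
) -> dict:
    """Predict χ and simulate one equal-quantity two-type system."""
    regime: MechanicalRegime = system.regime  # type: ignore[assignment]
    res = chi(system, regime, OccupancyModel.simplified(system))
    a, b = system.connector_types
    scenario = combination_pair(a, b, regime, scale=scale, params=_sim_params(seed, t_end))
    traj = _simulate_stable(scenario)
    fit = contraction_rate_fit(traj.times, traj.radii)
    return {
        "system": system.name,
        "type_a": a.name,
        "type_b": b.name,
        "regime": regime.kind,
        "chi": res.chi,
        "predicted_phase": res.phase,
        "simulated_rate": fit.rate,
        "fit_flagged": fit.flagged,
    }


def sign_agreement_study(
    n_systems: int = 20,
    seed: int = 0,
    scale: float = 0.025,
    t_end: float = 10.0,
    n_floor_seeds: int = 5,
    systems: list[SystemSpec] | None = None,
):
    """Sign agreement between theory and simulation on a seeded subsample.

    ``scale`` = 0.025 gives ~100 filaments at the survey densities.  Returns
    a dict with the per-system pandas table, the agreement fraction over
    non-neutral systems, the fraction of neutral systems inside the noise
    floor, and the floors used.
    """
    import pandas as pd

    from .connectors import enumerate_two_connector_systems

    if systems is None:
        types = enumerate_connector_types(ALL_SUBUNIT_KINDS)
        systems = enumerate_two_connector_systems(types, [FLEXIBLE, RIGID])
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(systems), size=min(n_systems, len(systems)), replace=False)
    chosen = [systems[i] for i in sorted(pick)]

    floors = {
        regime.kind: noise_floor(regime, scale, t_end, seeds=range(n_floor_seeds))
        for regime in (FLEXIBLE, RIGID)
    }

    rows = []
    for k, system in enumerate(chosen):
        row = run_system(system, seed=seed + 1 + k, scale=scale, t_end=t_end)
        floor = floors[row["regime"]]
        if row["predicted_phase"] == "neutral":
            row["agrees"] = abs(row["simulated_rate"]) <= floor
        else:
            row["agrees"] = row["simulated_rate"] * row["chi"] < 0.0
        row["noise_floor"] = floor
        rows.append(row)
    table = pd.DataFrame(rows)

    non_neutral = table[table.predicted_phase != "neutral"]
    neutral = table[table.predicted_phase == "neutral"]
    return {
        "table": table,
        "agreement": float(non_neutral.agrees.mean()) if len(non_neutral) else math.nan,
        "neutral_within_floor": float(neutral.agrees.mean()) if len(neutral) else math.nan,
        "n_non_neutral": int(len(non_neutral)),
        "n_neutral": int(len(neutral)),
        "noise_floors": floors,
    }
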