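"""Scenario presets and builders.

The presets reproduce the published study conditions at scale 1.0:

``actomyosin``         1,500 flexible filaments (κ = 0.01 pN·μm²) with 12,000
                       bifunctional plus-end motors and 12,000 crosslinkers in
                       a disc of radius 15 μm — a contractile actin-like gel.
``end_binder_mixture`` 1,500 rigid filaments with motor/plus-end-binder and
                       motor/minus-end-binder connectors (48,000 / 1,500 by
                       default) in a disc of radius 15 μm — contractile or
                       expansile depending on the split.
``combination_pair``   one equal-quantity two-connector system at the
                       densities of the systematic pair survey: 4,000
                       filaments and 32,000 + 32,000 connectors in a disc of
                       radius 25 μm.
``cortex_turnover``    1,400 semi-flexible filaments (κ = 0.075 pN·μm²),
                       22,400 myosin-like minifilaments (0.5 μm backbone, a
                       plus-end motor at each end) and 5,600 crosslinkers in
                       a 16 μm periodic box, with whole-filament turnover at
                       total rate 64 s⁻¹ (mean lifetime ≈ 21.9 s).

``scale`` multiplies every object count and the domain area, preserving all
number densities, composition ratios and the filament lifetime, so
desk-scale runs stay in the same physical regime.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .connectors import ConnectorType, SubunitKind, SystemSpec
from .theory import FLEXIBLE, RIGID, MechanicalRegime
from .world import Domain, FilamentSpec, Scenario, SimParams, TurnoverSpec

__all__ = [
    "bifunctional_motor",
    "crosslinker",
    "motor_end_binder",
    "myosin_minifilament",
    "actomyosin",
    "end_binder_mixture",
    "combination_pair",
    "cortex_turnover",
    "PRESETS",
    "preset",
    "system_of",
]


def bifunctional_motor(count: int = 0, **kw) -> ConnectorType:
    """Two plus-end-directed motor subunits (myosin-oligomer-like)."""
    return ConnectorType(
        subunits=(SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR),
        count=count, name="motor", **kw,
    )


def crosslinker(count: int = 0, **kw) -> ConnectorType:
    """Two passive anywhere-binding subunits."""
    return ConnectorType(
        subunits=(SubunitKind.SIDE_BINDER, SubunitKind.SIDE_BINDER),
        count=count, name="crosslinker", **kw,
    )


def motor_end_binder(end: str, count: int = 0, **kw) -> ConnectorType:
    """A plus-end motor paired with a plus- or minus-end-binding subunit."""
    binder = SubunitKind.PLUS_END_BINDER if end == "plus" else SubunitKind.MINUS_END_BINDER
    return ConnectorType(
        subunits=(SubunitKind.PLUS_MOTOR, binder),
        count=count, name=f"motor+{end}_end_binder", **kw,
    )


def myosin_minifilament(count: int = 0, backbone_length: float = 0.5, **kw) -> ConnectorType:
    """Rigid backbone with a plus-end motor subunit permanently at each end."""
    return ConnectorType(
        subunits=(SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR),
        count=count, backbone_length=backbone_length, name="minifilament", **kw,
    )


def _scaled(count: int, scale: float) -> int:
    return max(0, int(round(count * scale)))


def actomyosin(
    scale: float = 1.0,
    n_motors: int = 12_000,
    n_crosslinkers: int = 12_000,
    params: SimParams | None = None,
) -> Scenario:
    """Flexible-filament motor+crosslinker gel (contractile)."""
    return Scenario(
        filaments=FilamentSpec(count=_scaled(1500, scale), length=3.0, rigidity=0.01),
        connectors=(
            bifunctional_motor(_scaled(n_motors, scale)),
            crosslinker(_scaled(n_crosslinkers, scale)),
        ),
        domain=Domain("disc", radius=15.0 * math.sqrt(scale)),
        params=params or SimParams(),
        name="actomyosin",
    )


def end_binder_mixture(
    scale: float = 1.0,
    n_plus: int = 48_000,
    n_minus: int = 1_500,
    params: SimParams | None = None,
) -> Scenario:
    """Rigid filaments with motor/plus-end and motor/minus-end connectors.

    The default split (many motor/plus-end binders) is strongly contractile;
    inverting it makes the network expansile.
    """
    return Scenario(
        filaments=FilamentSpec(count=_scaled(1500, scale), rigid=True),
        connectors=(
            motor_end_binder("plus", _scaled(n_plus, scale)),
            motor_end_binder("minus", _scaled(n_minus, scale)),
        ),
        domain=Domain("disc", radius=15.0 * math.sqrt(scale)),
        params=params or SimParams(),
        name="end_binder_mixture",
    )


def combination_pair(
    type_a: ConnectorType,
    type_b: ConnectorType,
    regime: MechanicalRegime,
    scale: float = 1.0,
    n_filaments: int = 4000,
    n_each: int = 32_000,
    params: SimParams | None = None,
) -> Scenario:
    """Equal-quantity two-connector system at the pair-survey densities."""
    rigid = regime.kind == "rigid"
    return Scenario(
        filaments=FilamentSpec(
            count=_scaled(n_filaments, scale),
            rigidity=math.inf if rigid else regime.rigidity,
            rigid=rigid,
        ),
        connectors=(
            type_a.with_count(_scaled(n_each, scale)),
            type_b.with_count(_scaled(n_each, scale)),
        ),
        domain=Domain("disc", radius=25.0 * math.sqrt(scale)),
        params=params or SimParams(),
        name=f"{type_a.name}/{type_b.name}[{regime.kind}]",
    )


def cortex_turnover(
    scale: float = 1.0,
    turnover: bool = True,
    params: SimParams | None = None,
) -> Scenario:
    """Minifilament + crosslinker cortex in a periodic box, with turnover.

    The total turnover rate scales with the filament count so the mean
    filament lifetime N/R ≈ 21.9 s is scale-invariant.
    """
    n_fil = _scaled(1400, scale)
    return Scenario(
        filaments=FilamentSpec(count=n_fil, length=3.0, rigidity=0.075),
        connectors=(
            myosin_minifilament(_scaled(22_400, scale)),
            crosslinker(_scaled(5_600, scale)),
        ),
        domain=Domain("periodic", side=16.0 * math.sqrt(scale)),
        params=params or SimParams(),
        turnover=TurnoverSpec(enabled=turnover, rate=64.0 * scale if turnover else 0.0),
        name="cortex_turnover",
    )


PRESETS = {
    "actomyosin": actomyosin,
    "end-binder-mixture": end_binder_mixture,
    "cortex-turnover": cortex_turnover,
}


def preset(name: str, scale: float = 1.0, **kwargs) -> Scenario:
    """Look up a named preset; see :data:`PRESETS` for the catalogue."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory(scale=scale, **kwargs)


def system_of(scenario: Scenario, regime: MechanicalRegime | None = None) -> SystemSpec:
    """The declared connector system of a scenario, for theory evaluation."""
    if regime is None:
        regime = RIGID if scenario.filaments.rigid else (
            FLEXIBLE if scenario.filaments.rigidity <= 0.02 else
            MechanicalRegime.semiflexible(
                scenario.filaments.rigidity,
                max(ct.stall_force for ct in scenario.connectors) if scenario.connectors else 5.0,
            )
        )
    return SystemSpec(connector_types=scenario.connectors, regime=regime, name=scenario.name)
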