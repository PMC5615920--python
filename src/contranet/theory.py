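"""Analytical contractility prediction for disordered filament networks.

The census of two-connector configurations on a focal filament
(:mod:`contranet.connectors`) is combined into a single scalar

    χ = S / D,     S = Σ_i p_i Φ_i v_i,     D = Σ_i p_i a_i,

where p_i is the configuration weight, v_i its relative speed (unloaded),
a_i the expected subunit separation, and Φ_i a regime-dependent factor that
discards expansile contributions spoiled by filament buckling.  χ < 0
predicts contraction, χ > 0 expansion, χ = 0 a neutral network.

Regimes
-------
rigid        filaments never buckle: Φ = 1 for every configuration.
flexible     filaments buckle under any compression: expansile
             configurations (v_i > 0) are discarded, Φ = 0.
semiflexible a filament segment buckles only if longer than the Euler
             threshold b = π sqrt(κ/f) and not pinned laterally by a
             crosslinked crossing.  With mesh size L1, a segment of length b
             crosses β0 = b/L1 other filaments; the expansile configuration
             survives with probability 1 - (1-P_C)^(max(β0,1)-1), i.e. it is
             spoiled only when every intermediate crossing is free of
             crosslinkers.  For the motor+crosslinker system this yields the
             net numerator -P_M P_C (1-P_C)^max(β0,1) v, which reduces to the
             always-buckle (flexible) value -P_M P_C (1-P_C) v when b <= L1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectors import (
    Configuration,
    MechClass,
    OccupancyModel,
    SystemSpec,
    configuration_probabilities,
    enumerate_configurations,
    enumerate_two_connector_systems,
)

__all__ = [
    "MechanicalRegime",
    "MeshStats",
    "TheoryResult",
    "buckling_threshold",
    "mesh_size",
    "phi_weight",
    "chi",
    "predict_phase_table",
    "rate_curve",
    "predicted_radial_rate",
    "RIGID",
    "FLEXIBLE",
]


@dataclass(frozen=True)
class MechanicalRegime:
    """Filament mechanics entering the Φ weighting.

    ``rigidity`` is the bending modulus κ in pN·μm² (``inf`` for rigid);
    ``buckling_threshold`` b in μm is derived from κ and the motor stall
    force (``inf`` for rigid, 0 for the idealized flexible limit).
    """

    kind: str  # 'rigid' | 'flexible' | 'semiflexible'
    rigidity: float = math.inf
    buckling_threshold: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "flexible", "semiflexible"):
            raise ValueError(f"unknown regime kind: {self.kind!r}")

    @classmethod
    def rigid(cls) -> "MechanicalRegime":
        return cls("rigid", math.inf, math.inf)

    @classmethod
    def flexible(cls, rigidity: float = 0.01) -> "MechanicalRegime":
        return cls("flexible", rigidity, 0.0)

    @classmethod
    def semiflexible(cls, rigidity: float, stall_force: float) -> "MechanicalRegime":
        return cls("semiflexible", rigidity, buckling_threshold(rigidity, stall_force))


RIGID = MechanicalRegime.rigid()
FLEXIBLE = MechanicalRegime.flexible()


def buckling_threshold(rigidity: float, force: float) -> float:
    """Euler buckling length b = π sqrt(κ/f) of a pinned filament segment.

    A segment of length above b buckles under axial load ``force``;
    equivalently a segment of length L buckles when loaded beyond π²κ/L².
    Returns ``inf`` for infinitely rigid filaments.
    """
    if force <= 0:
        raise ValueError("force must be > 0")
    if math.isinf(rigidity):
        return math.inf
    if rigidity <= 0:
        raise ValueError("rigidity must be > 0 (or inf)")
    return math.pi * math.sqrt(rigidity / force)


@dataclass(frozen=True)
class MeshStats:
    """Geometry of a random 2D network: mesh size and crossing counts."""

    mesh_size: float  # L1, μm
    crossings_per_filament: float
    beta0: float = math.nan  # b / L1, set when a buckling length is supplied

    def with_buckling(self, b: float) -> "MeshStats":
        return MeshStats(self.mesh_size, self.crossings_per_filament, b / self.mesh_size)


def mesh_size(
    n_filaments: int,
    filament_length: float,
    area: float,
    buckling_length: float | None = None,
) -> MeshStats:
    """Mesh statistics of n randomly placed filaments of length L in area A.

    For uniformly random positions and orientations, a filament crosses on
    average 2 (n-1) L² / (π A) others; the mesh size L1 is the mean spacing
    between crossings along a filament, L1 = L / crossings.  If
    ``buckling_length`` b is given, β0 = b / L1 is filled in.
    """
    if n_filaments < 2:
        raise ValueError("mesh undefined for fewer than 2 filaments")
    if filament_length <= 0 or area <= 0:
        raise ValueError("filament_length and area must be > 0")
    crossings = 2.0 * (n_filaments - 1) * filament_length**2 / (math.pi * area)
    L1 = filament_length / crossings if crossings > 0 else math.inf
    beta0 = math.nan if buckling_length is None else buckling_length / L1
    return MeshStats(L1, crossings, beta0)


def phi_weight(
    config: Configuration,
    regime: MechanicalRegime,
    occupancy: OccupancyModel | None = None,
    mesh: MeshStats | None = None,
) -> float:
    """Buckling survival factor Φ_i ∈ [0, 1] for one configuration.

    Contractile, neutral and static configurations always count (Φ = 1).
    Expansile ones count fully for rigid filaments, not at all for flexible
    ones, and for semiflexible filaments survive with probability
    1 - (1 - P_C)^(max(β0, 1) - 1): buckling is averted if any crossing
    between the two subunits is pinned by a crosslinker.
    """
    if config.relative_speed <= 0:
        return 1.0
    if regime.kind == "rigid":
        return 1.0
    if regime.kind == "flexible":
        return 0.0
    # semiflexible
    if mesh is None:
        raise ValueError("semiflexible regime requires mesh statistics")
    beta0 = mesh.beta0
    if math.isnan(beta0):
        beta0 = regime.buckling_threshold / mesh.mesh_size
    P_C = occupancy.static_crossing_probability if occupancy is not None else 0.0
    exponent = max(beta0, 1.0) - 1.0
    return 1.0 - (1.0 - P_C) ** exponent


@dataclass
class TheoryResult:
    """χ with its census breakdown.

    ``numerator`` S = Σ p_i Φ_i v_i (μm/s·weight), ``denominator``
    D = Σ p_i a_i (μm·weight), ``chi`` = S/D (1/s).  ``neutral_by_vacuity``
    flags D = 0 (no weighted configurations), in which case χ is 0 by
    convention but carries no prediction.
    """

    chi: float
    numerator: float
    denominator: float
    per_config: list[tuple[Configuration, float]] = field(default_factory=list)
    neutral_by_vacuity: bool = False

    @property
    def phase(self) -> str:
        if self.neutral_by_vacuity or self.numerator == 0.0:
            return "neutral"
        return "contract" if self.numerator < 0 else "expand"


def chi(
    system: SystemSpec,
    regime: MechanicalRegime | None = None,
    occupancy: OccupancyModel | None = None,
    mesh: MeshStats | None = None,
    filament_length: float = 3.0,
) -> TheoryResult:
    """Evaluate χ for a declared system.

    ``regime`` defaults to the system's own; ``occupancy`` defaults to the
    simplified equal-kinetics model; ``mesh`` supplies L1 and β0 (needed for
    the semiflexible regime, optional otherwise; mesh size defaults to 1 μm).
    """
    if regime is None:
        regime = system.regime  # type: ignore[assignment]
    if regime is None:
        raise ValueError("no mechanical regime given")
    if occupancy is None:
        occupancy = OccupancyModel.simplified(system)
    L1 = mesh.mesh_size if mesh is not None else 1.0
    census = enumerate_configurations(system, mesh_size=L1, filament_length=filament_length)
    census = configuration_probabilities(census, occupancy)
    per = [(c, phi_weight(c, regime, occupancy, mesh)) for c in census]
    S = sum(c.probability * phi * c.relative_speed for c, phi in per)
    D = sum(c.probability * c.separation for c, phi in per)
    if D == 0.0:
        return TheoryResult(0.0, S, 0.0, per, neutral_by_vacuity=True)
    return TheoryResult(S / D, S, D, per)


def predicted_radial_rate(
    result: TheoryResult, dimensionality: int = 2, radius: float = 1.0, constant: float = 1.0
) -> float:
    """Predicted dR/dt = constant · χ · R / d (μm/s; negative = contracting).

    The division by the dimensionality d reflects that the isotropic strain
    rate χ is shared between d directions; ``constant`` is an exposed overall
    calibration factor (default 1).
    """
    if dimensionality not in (1, 2, 3):
        raise ValueError("dimensionality must be 1, 2 or 3")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return constant * result.chi * radius / dimensionality


def predict_phase_table(
    connector_types: Sequence,
    regimes: Sequence[MechanicalRegime],
    occupancy: OccupancyModel | None = None,
    mesh: MeshStats | None = None,
):
    """Predicted phase for every equal-quantity two-type system per regime.

    Returns a pandas DataFrame with one row per (type pair, regime):
    columns type_a, type_b, regime, chi, phase.  15 types over two regimes
    give 210 rows.
    """
    import pandas as pd

    rows = []
    for system in enumerate_two_connector_systems(connector_types, regimes):
        occ = occupancy if occupancy is not None else OccupancyModel.simplified(system)
        res = chi(system, system.regime, occ, mesh)  # type: ignore[arg-type]
        a, b = system.connector_types
        rows.append(
            {
                "type_a": a.name,
                "type_b": b.name,
                "regime": system.regime.kind,  # type: ignore[union-attr]
                "chi": res.chi,
                "phase": res.phase,
            }
        )
    return pd.DataFrame(rows)


def rate_curve(
    system: SystemSpec,
    compositions: Sequence[tuple[int, int]],
    regime: MechanicalRegime | None = None,
    n_crossings_total: float = 1000.0,
    mesh: MeshStats | None = None,
) -> list[tuple[tuple[int, int], float]]:
    """χ along a composition sweep of a two-type system.

    ``compositions`` are (count_a, count_b) pairs (typically with fixed
    total); occupancies are recomputed per composition with the kinetic
    steady-state model over ``n_crossings_total`` crossings.  Endpoints with
    a zero count of either type give χ = 0 for the motor+crosslinker system.
    """
    if len(system.connector_types) != 2:
        raise ValueError("rate_curve expects a two-type system")
    out = []
    a, b = system.connector_types
    for na, nb in compositions:
        sys_i = SystemSpec(
            (a.with_count(na), b.with_count(nb)), regime=regime or system.regime
        )
        occ = OccupancyModel.kinetic(sys_i, n_crossings_total)
        res = chi(sys_i, regime or system.regime, occ, mesh)  # type: ignore[arg-type]
        out.append(((na, nb), res.chi))
    return out
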