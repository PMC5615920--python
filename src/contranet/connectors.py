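"""Connector taxonomy and the two-connector configuration census.

The contractility theory implemented in :mod:`contranet.theory` rests on a
census of the ways two connector subunits can sit on one *focal* filament.
This module defines the five filament-binding subunit kinds, connector types
(unordered pairs of subunits with kinetic parameters), and performs the
exhaustive enumeration, classification and probability weighting of the
resulting configurations.

Conventions
-----------
A filament is oriented minus end -> plus end; abscissae run from 0 (minus
end) to L (plus end).  A configuration places two bound subunits at
abscissae x1 < x2.  Its relative speed is

    v_i = speed(subunit at x2) - speed(subunit at x1)

using the *unloaded* signed motor speeds (+v0 for a plus-end-directed motor,
-v0 for a minus-end-directed motor, 0 for binders).  v_i < 0 means the
subunits approach each other (contractile), v_i > 0 that they separate
(expansile).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ALL_SUBUNIT_KINDS",
    "KIND_ORDER",
    "SubunitKind",
    "MechClass",
    "ConnectorType",
    "Configuration",
    "SystemSpec",
    "OccupancyModel",
    "enumerate_connector_types",
    "enumerate_two_connector_systems",
    "enumerate_configurations",
    "classify_configuration",
    "configuration_probabilities",
    "census_table",
]


class SubunitKind(str, Enum):
    """The five filament-binding subunit kinds.

    Motors walk along the filament toward their directed end; binders stay
    where they bound.  End binders attach only within a short range of their
    designated filament end.
    """

    PLUS_MOTOR = "plus_motor"
    MINUS_MOTOR = "minus_motor"
    SIDE_BINDER = "side_binder"
    PLUS_END_BINDER = "plus_end_binder"
    MINUS_END_BINDER = "minus_end_binder"

    @property
    def is_motor(self) -> bool:
        return self in (SubunitKind.PLUS_MOTOR, SubunitKind.MINUS_MOTOR)

    @property
    def direction(self) -> int:
        """Sign of the unloaded speed along the minus->plus axis (0 for binders)."""
        if self is SubunitKind.PLUS_MOTOR:
            return 1
        if self is SubunitKind.MINUS_MOTOR:
            return -1
        return 0

    @property
    def binding_site(self) -> str:
        """Where the subunit may attach: 'anywhere', 'plus_end' or 'minus_end'."""
        if self is SubunitKind.PLUS_END_BINDER:
            return "plus_end"
        if self is SubunitKind.MINUS_END_BINDER:
            return "minus_end"
        return "anywhere"

    def unloaded_speed(self, v0: float) -> float:
        """Signed unloaded speed for a motor of magnitude ``v0`` (0 for binders)."""
        return self.direction * v0


#: Canonical ordering used everywhere a deterministic order is needed.
KIND_ORDER: tuple[SubunitKind, ...] = (
    SubunitKind.PLUS_MOTOR,
    SubunitKind.MINUS_MOTOR,
    SubunitKind.SIDE_BINDER,
    SubunitKind.PLUS_END_BINDER,
    SubunitKind.MINUS_END_BINDER,
)

ALL_SUBUNIT_KINDS: frozenset[SubunitKind] = frozenset(KIND_ORDER)

_KIND_RANK = {k: i for i, k in enumerate(KIND_ORDER)}


class MechClass(str, Enum):
    """Mechanical class of a configuration."""

    STATIC = "static"
    NEUTRAL = "neutral"
    CONTRACTILE = "contractile"
    EXPANSILE = "expansile"


@dataclass(frozen=True)
class ConnectorType:
    """A connector: an unordered pair of subunits plus kinetic parameters.

    Parameters are in μm, s and pN.  ``backbone_length > 0`` declares a rigid
    minifilament whose two (motor) subunits sit permanently at the backbone
    ends; ordinary connectors have ``backbone_length == 0`` and act as
    zero-rest-length Hookean springs of stiffness ``stiffness`` when both
    subunits are bound.
    """

    subunits: tuple[SubunitKind, SubunitKind]
    v0: float = 1.0  # unloaded motor speed, μm/s
    stall_force: float = 5.0  # pN
    k_on: float = 10.0  # 1/s
    k_off: float = 1.0  # 1/s
    capture_range: float = 0.05  # ε, μm
    end_range: float = 0.05  # δ, μm
    stiffness: float = 100.0  # k, pN/μm
    count: int = 0
    backbone_length: float = 0.0  # μm; >0 only for minifilaments
    name: str = ""

    def __post_init__(self) -> None:
        a, b = self.subunits
        if not isinstance(a, SubunitKind) or not isinstance(b, SubunitKind):
            raise TypeError("subunits must be SubunitKind members")
        # canonicalize the unordered pair
        if _KIND_RANK[a] > _KIND_RANK[b]:
            object.__setattr__(self, "subunits", (b, a))
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.stall_force <= 0:
            raise ValueError("stall_force must be > 0")
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("k_on and k_off must be >= 0")
        if self.capture_range <= 0 or self.end_range <= 0:
            raise ValueError("capture_range and end_range must be > 0")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.backbone_length < 0:
            raise ValueError("backbone_length must be >= 0")
        if self.backbone_length > 0 and not all(s.is_motor for s in self.subunits):
            raise ValueError("a minifilament (backbone_length > 0) must have two motor subunits")
        if not self.name:
            object.__setattr__(self, "name", f"{self.subunits[0].value}+{self.subunits[1].value}")

    @property
    def is_minifilament(self) -> bool:
        return self.backbone_length > 0

    def with_count(self, count: int) -> "ConnectorType":
        return replace(self, count=count)


@dataclass(frozen=True)
class Configuration:
    """One census entry: two bound subunits on the focal filament.

    ``focal_subunits`` is ordered by position (subunit at x1, subunit at x2)
    along the minus->plus axis.  ``owners`` lists the connector-type names
    that can contribute each subunit (merged entries may have several).
    """

    focal_subunits: tuple[SubunitKind, SubunitKind]
    owners: tuple[tuple[str, ...], tuple[str, ...]]
    separation: float  # a_i, μm
    relative_speed: float  # v_i, μm/s
    probability: float = 0.0  # p_i
    mech_class: MechClass = MechClass.STATIC

    @property
    def config_id(self) -> str:
        k1, k2 = self.focal_subunits
        return f"{k1.value}|{k2.value}"


@dataclass(frozen=True)
class SystemSpec:
    """A declared system: connector types (with counts) and, optionally, the
    mechanical regime of the filaments (see :mod:`contranet.theory`)."""

    connector_types: tuple[ConnectorType, ...]
    regime: "object | None" = None  # theory.MechanicalRegime; kept untyped to avoid a cycle
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.connector_types) == 0:
            raise ValueError("a system needs at least one connector type")
        object.__setattr__(self, "connector_types", tuple(self.connector_types))


# ---------------------------------------------------------------------------
# enumeration


def enumerate_connector_types(
    subunit_kinds: Iterable[SubunitKind], **params
) -> list[ConnectorType]:
    """All connector types constructible from the given subunit kinds.

    Returns every unordered pair with repetition, n(n+1)/2 for n kinds, in
    canonical order.  Extra keyword arguments (kinetics, counts) are applied
    to every type.
    """
    kinds = sorted(set(subunit_kinds), key=_KIND_RANK.get)
    if not kinds:
        raise ValueError("no subunit kinds")
    out = []
    for i, a in enumerate(kinds):
        for b in kinds[i:]:
            out.append(ConnectorType(subunits=(a, b), **params))
    return out


def enumerate_two_connector_systems(
    connector_types: Sequence[ConnectorType], regimes: Sequence[object]
) -> list[SystemSpec]:
    """All equal-quantity systems of two *distinct* connector types, one per
    unordered type pair per mechanical regime: C(m,2) * len(regimes) systems."""
    if len(connector_types) < 2:
        raise ValueError("need at least two connector types")
    if len(set(ct.subunits + (ct.backbone_length,) for ct in connector_types)) != len(
        connector_types
    ):
        raise ValueError("duplicate connector types in input")
    if len(regimes) < 1:
        raise ValueError("need at least one regime")
    systems = []
    for regime in regimes:
        for a, b in itertools.combinations(connector_types, 2):
            systems.append(
                SystemSpec(
                    connector_types=(a, b),
                    regime=regime,
                    name=f"{a.name} / {b.name} [{getattr(regime, 'kind', regime)}]",
                )
            )
    return systems


def classify_configuration(config: Configuration) -> MechClass:
    """Mechanical class from the sign of the relative speed v_i."""
    return _classify(config.relative_speed, config.focal_subunits)


def _classify(v: float, kinds: tuple[SubunitKind, SubunitKind]) -> MechClass:
    if v < 0:
        return MechClass.CONTRACTILE
    if v > 0:
        return MechClass.EXPANSILE
    if any(k.is_motor for k in kinds):
        return MechClass.NEUTRAL
    return MechClass.STATIC


def _focal_states(system: SystemSpec) -> dict[tuple[SubunitKind, float], list[str]]:
    """Map (focal subunit kind, signed unloaded speed) -> owner type names.

    Either subunit of a heterodimeric connector may be the one bound to the
    focal filament; both subunits of one connector are never placed on the
    focal filament (the other subunit bridges to the rest of the network).
    Entries that share kind and speed are merged.
    """
    states: dict[tuple[SubunitKind, float], list[str]] = {}
    for ct in system.connector_types:
        for kind in sorted(set(ct.subunits), key=_KIND_RANK.get):
            key = (kind, kind.unloaded_speed(ct.v0))
            states.setdefault(key, [])
            if ct.name not in states[key]:
                states[key].append(ct.name)
    return states


def enumerate_configurations(
    system: SystemSpec,
    mesh_size: float = 1.0,
    filament_length: float = 3.0,
) -> list[Configuration]:
    """Exhaustive census of two-connector configurations on a focal filament.

    Each configuration places two bound subunits (each contributed by a
    connector bridging to the rest of the network) at ordered abscissae
    x1 < x2.  End binders sit at their designated end (minus-end binders at
    x1 = 0, plus-end binders at x2 = L); two same-end binders coincide with
    separation 0.  Side-bound subunits of different kinds give two distinct
    ordered placements.  Configurations identical under (kind, unloaded
    speed) equality are merged.

    ``mesh_size`` (L1) is the expected spacing of two side-bound subunits;
    ``filament_length`` (L) sets end-binder abscissae.  Probabilities are
    left at 0; see :func:`configuration_probabilities`.
    """
    states = _focal_states(system)
    keys = sorted(states, key=lambda ks: (_KIND_RANK[ks[0]], ks[1]))
    L, L1 = filament_length, mesh_size
    configs: list[Configuration] = []
    for i, s1 in enumerate(keys):
        for s2 in keys[i:]:
            for placement in _placements(s1, s2):
                (k1, v1), (k2, v2) = placement
                a = _separation(k1, k2, L, L1)
                v = v2 - v1
                configs.append(
                    Configuration(
                        focal_subunits=(k1, k2),
                        owners=(
                            tuple(states[placement[0]]),
                            tuple(states[placement[1]]),
                        ),
                        separation=a,
                        relative_speed=v,
                        mech_class=_classify(v, (k1, k2)),
                    )
                )
    configs.sort(
        key=lambda c: (
            _KIND_RANK[c.focal_subunits[0]],
            _KIND_RANK[c.focal_subunits[1]],
            c.owners,
        )
    )
    return configs


def _placements(s1, s2):
    """Ordered (x1, x2) placements of two focal states, honoring end sites."""
    (k1, _), (k2, _) = s1, s2

    def slot(kind: SubunitKind) -> int | None:
        # 0 = must sit at x1 (minus end), 1 = must sit at x2 (plus end)
        if kind is SubunitKind.MINUS_END_BINDER:
            return 0
        if kind is SubunitKind.PLUS_END_BINDER:
            return 1
        return None

    c1, c2 = slot(k1), slot(k2)
    if c1 is None and c2 is None:
        if s1 == s2:
            return [(s1, s2)]
        return [(s1, s2), (s2, s1)]
    if c1 is not None and c2 is not None:
        if c1 == c2:  # both at the same end: one degenerate placement
            return [(s1, s2)]
        return [(s1, s2)] if c1 == 0 else [(s2, s1)]
    # exactly one end binder: it fixes the order
    if c1 is not None:
        return [(s1, s2)] if c1 == 0 else [(s2, s1)]
    return [(s2, s1)] if c2 == 0 else [(s1, s2)]


def _separation(k1: SubunitKind, k2: SubunitKind, L: float, L1: float) -> float:
    end1, end2 = k1.binding_site != "anywhere", k2.binding_site != "anywhere"
    if end1 and end2:
        return 0.0 if k1 == k2 else L
    if end1 or end2:
        return L / 2.0
    return L1


# ---------------------------------------------------------------------------
# probabilities


@dataclass
class OccupancyModel:
    """Per-site probabilities used to weight census configurations.

    ``site_probability[kind]`` is the probability that a filament crossing
    presents a bound subunit of that kind as the acting element;
    ``end_probability[kind]`` plays the same role for end sites.  A
    configuration's weight is the product of its two site probabilities
    (sites are independent).  ``static_crossing_probability`` is the
    probability that a crossing is pinned by a passive side binder (the P_C
    of the buckling-protection factor in the semiflexible regime).
    """

    site_probability: Mapping[SubunitKind, float]
    end_probability: Mapping[SubunitKind, float] = field(default_factory=dict)
    static_crossing_probability: float = 0.0

    def __post_init__(self) -> None:
        for table in (self.site_probability, self.end_probability):
            for kind, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {kind} outside [0, 1]: {p}")
        if not 0.0 <= self.static_crossing_probability <= 1.0:
            raise ValueError("static_crossing_probability outside [0, 1]")

    def prob(self, kind: SubunitKind) -> float:
        table = (
            self.end_probability if kind.binding_site != "anywhere" else self.site_probability
        )
        return float(table.get(kind, 0.0))

    # -- constructors -------------------------------------------------------

    @classmethod
    def actomyosin(cls, P_M: float, P_C: float) -> "OccupancyModel":
        """Motor/crosslinker occupancy with crosslinker precedence.

        P_M (P_C) is the probability of at least one motor (crosslinker) at a
        filament crossing.  A crossing acts as a moving motor site only if a
        motor is present and no crosslinker pins it, hence the motor site
        probability P_M (1 - P_C), while a crosslinked crossing is static
        with probability P_C.
        """
        if not (0.0 <= P_M <= 1.0 and 0.0 <= P_C <= 1.0):
            raise ValueError("P_M and P_C must lie in [0, 1]")
        return cls(
            site_probability={
                SubunitKind.PLUS_MOTOR: P_M * (1.0 - P_C),
                SubunitKind.MINUS_MOTOR: P_M * (1.0 - P_C),
                SubunitKind.SIDE_BINDER: P_C,
            },
            end_probability={},
            static_crossing_probability=P_C,
        )

    @classmethod
    def simplified(cls, system: SystemSpec, site_occupancy: float = 0.5) -> "OccupancyModel":
        """Equal-kinetics model: every subunit slot is equally likely.

        Used when all binding parameters and connector counts are equal, so
        only the relative abundances of subunit kinds matter.  Each kind's
        site probability is ``site_occupancy`` times its share of subunit
        slots, weighted by connector counts (equal counts if all are zero).
        """
        weights: dict[SubunitKind, float] = {}
        total = 0.0
        counts = [ct.count for ct in system.connector_types]
        equal = all(c == 0 for c in counts)
        for ct in system.connector_types:
            w = 1.0 if equal else float(ct.count)
            for kind in ct.subunits:
                weights[kind] = weights.get(kind, 0.0) + w
                total += w
        if total == 0:
            return cls(site_probability={}, end_probability={})
        site = {k: site_occupancy * w / total for k, w in weights.items()}
        static = sum(p for k, p in site.items() if k is SubunitKind.SIDE_BINDER)
        return cls(
            site_probability={k: p for k, p in site.items() if k.binding_site == "anywhere"},
            end_probability={k: p for k, p in site.items() if k.binding_site != "anywhere"},
            static_crossing_probability=static,
        )

    @classmethod
    def kinetic(
        cls,
        system: SystemSpec,
        n_crossings_total: float,
        n_end_sites: float | None = None,
    ) -> "OccupancyModel":
        """Steady-state Poisson closure from counts and kinetics.

        The mean number of subunits of a kind bound per crossing is
        μ = Σ_types count · (slots of that kind) · duty / n_crossings_total,
        with duty = k_on / (k_on + k_off); the probability of at least one is
        1 - exp(-μ).  Moving kinds are additionally multiplied by the
        probability that no passive side binder pins the crossing, matching
        the crosslinker-precedence rule of :meth:`actomyosin`.
        """
        if n_crossings_total <= 0:
            raise ValueError("n_crossings_total must be > 0")
        if n_end_sites is None:
            n_end_sites = n_crossings_total
        mu: dict[SubunitKind, float] = {}
        for ct in system.connector_types:
            duty = ct.k_on / (ct.k_on + ct.k_off) if (ct.k_on + ct.k_off) > 0 else 0.0
            for kind in ct.subunits:
                sites = n_end_sites if kind.binding_site != "anywhere" else n_crossings_total
                mu[kind] = mu.get(kind, 0.0) + ct.count * duty / sites
        prob = {k: 1.0 - math.exp(-m) for k, m in mu.items()}
        P_static = prob.get(SubunitKind.SIDE_BINDER, 0.0)
        site = {}
        for k, p in prob.items():
            if k.binding_site != "anywhere":
                continue
            site[k] = p * (1.0 - P_static) if k.is_motor else p
        return cls(
            site_probability=site,
            end_probability={
                k: p for k, p in prob.items() if k.binding_site != "anywhere"
            },
            static_crossing_probability=P_static,
        )


def configuration_probabilities(
    census: Sequence[Configuration], occupancy: OccupancyModel
) -> list[Configuration]:
    """Fill each configuration's weight p_i = q(subunit at x1) · q(subunit at x2).

    Weights are unnormalized, nonnegative, and zero for configurations that
    require a subunit kind absent from the occupancy model.
    """
    out = []
    for cfg in census:
        p = occupancy.prob(cfg.focal_subunits[0]) * occupancy.prob(cfg.focal_subunits[1])
        out.append(replace(cfg, probability=p))
    return out


def census_table(census: Sequence[Configuration]):
    """Census as a pandas DataFrame (config_id, subunits, a_i, v_i, p_i, class)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "config_id": [c.config_id for c in census],
            "subunit1": [c.focal_subunits[0].value for c in census],
            "subunit2": [c.focal_subunits[1].value for c in census],
            "a_i": [c.separation for c in census],
            "v_i": [c.relative_speed for c in census],
            "p_i": [c.probability for c in census],
            "class": [c.mech_class.value for c in census],
        }
    )
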