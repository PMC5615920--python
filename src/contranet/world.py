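"""Simulation state for 2D overdamped filament/connector networks.

A :class:`World` holds semi-flexible (or rigid) filaments discretized as
oriented strings of equidistant points, point-like connectors with two
filament-binding subunits, rigid minifilaments carrying a motor subunit at
each backbone end, the domain (open disc or periodic box) and the random
number generator.  All lengths are μm, times s, forces pN.

Array layout
------------
Filaments are homogeneous within a world: ``fil_x`` has shape
(n_filaments, n_points, 2), minus end first.  Point connectors are stored in
flat arrays (``c_*``); subunit slot j of connector i is attached iff
``c_fil[i, j] >= 0``, with abscissa ``c_s[i, j]`` in [0, L].  Minifilaments
use ``m_*`` arrays with center + orientation angle.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .connectors import ConnectorType, SubunitKind

__all__ = [
    "SimParams",
    "Domain",
    "TurnoverSpec",
    "FilamentSpec",
    "Scenario",
    "World",
    "build_world",
    "KIND_CODES",
    "KIND_DIRECTION",
]

#: integer codes for subunit kinds, in canonical order
KIND_CODES: dict[SubunitKind, int] = {
    SubunitKind.PLUS_MOTOR: 0,
    SubunitKind.MINUS_MOTOR: 1,
    SubunitKind.SIDE_BINDER: 2,
    SubunitKind.PLUS_END_BINDER: 3,
    SubunitKind.MINUS_END_BINDER: 4,
}
KIND_DIRECTION = np.array([1.0, -1.0, 0.0, 0.0, 0.0])  # unloaded speed sign
KIND_IS_MOTOR = np.array([True, True, False, False, False])
#: binding site per kind: 0 anywhere, +1 plus end, -1 minus end
KIND_SITE = np.array([0, 0, 0, 1, -1])


@dataclass(frozen=True)
class SimParams:
    """Numerical parameters of the Brownian-dynamics integration."""

    dt: float = 1e-3  # s
    kT: float = 0.0042  # pN·μm (room temperature)
    drag: float = 5.0  # filament drag per unit length γ, pN·s/μm²
    drag_connector: float = 0.002  # point-connector drag, pN·s/μm
    segment_length: float = 0.5  # μm
    rng_seed: int = 0
    t_end: float = 10.0  # s
    sample_interval: float = 0.25  # s
    projection_iterations: int = 40
    projection_tol: float = 5e-4  # relative segment-length tolerance
    neighbor_stride: int = 10  # steps between neighbor-grid rebuilds
    neighbor_margin: float = 0.1  # μm of slack in the stale neighbor grid
    kinetics_stride: int = 1  # dynamics steps per kinetics update

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.kT < 0 or self.drag <= 0 or self.drag_connector <= 0:
            raise ValueError("kT must be >= 0 and drags > 0")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")
        if self.kinetics_stride < 1:
            raise ValueError("kinetics_stride must be >= 1")


@dataclass(frozen=True)
class Domain:
    """Open disc (initial radius, no boundary force) or periodic square box."""

    kind: str  # 'disc' | 'periodic'
    radius: float = 0.0  # disc initial radius R0, μm
    side: float = 0.0  # periodic box side, μm

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "periodic"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "disc" and self.radius <= 0:
            raise ValueError("disc domain needs radius > 0")
        if self.kind == "periodic" and self.side <= 0:
            raise ValueError("periodic domain needs side > 0")

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic"

    @property
    def area(self) -> float:
        if self.periodic:
            return self.side**2
        return math.pi * self.radius**2

    def sample_positions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.periodic:
            return rng.uniform(0.0, self.side, size=(n, 2))
        r = self.radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0.0, 2.0 * math.pi, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vector(s)."""
        if not self.periodic:
            return d
        return d - self.side * np.round(d / self.side)

    def wrap(self, x: np.ndarray) -> np.ndarray:
        if not self.periodic:
            return x
        return np.mod(x, self.side)


@dataclass(frozen=True)
class TurnoverSpec:
    """Whole-filament replacement at total event rate R (1/s).

    With N filaments the mean individual lifetime is T = N / R.
    """

    enabled: bool = False
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("turnover rate must be >= 0")

    def mean_lifetime(self, n_filaments: int) -> float:
        if not self.enabled or self.rate <= 0:
            return math.inf
        return n_filaments / self.rate


@dataclass(frozen=True)
class FilamentSpec:
    count: int
    length: float = 3.0  # μm
    rigidity: float = 0.075  # κ, pN·μm²
    rigid: bool = False  # infinitely rigid rods

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("filament count must be >= 0")
        if self.length <= 0:
            raise ValueError("filament length must be > 0")
        if self.rigidity <= 0 and not self.rigid:
            raise ValueError("rigidity must be > 0 (or rigid=True)")


@dataclass(frozen=True)
class Scenario:
    """A fully declared simulation scenario."""

    filaments: FilamentSpec
    connectors: tuple[ConnectorType, ...]
    domain: Domain
    params: SimParams = field(default_factory=SimParams)
    turnover: TurnoverSpec = field(default_factory=TurnoverSpec)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "connectors", tuple(self.connectors))


class World:
    """Mutable simulation state; build with :func:`build_world`."""

    def __init__(self, scenario: Scenario):
        self.scenario = scenario
        self.params = scenario.params
        self.domain = scenario.domain
        self.turnover = scenario.turnover
        self.time = 0.0
        self.rng = np.random.default_rng(scenario.params.rng_seed)
        self.events = {"bind": 0, "unbind": 0, "turnover": 0}

        fs = scenario.filaments
        self.n_fil = fs.count
        self.fil_length = fs.length
        self.rigid = fs.rigid
        self.kappa = math.inf if fs.rigid else fs.rigidity
        seg = scenario.params.segment_length
        self.n_pts = max(2, int(round(fs.length / seg)) + 1)
        self.seg = fs.length / (self.n_pts - 1)
        self.fil_x = np.zeros((self.n_fil, self.n_pts, 2))
        self.external_force: np.ndarray | None = None

        # connector type tables
        types = list(scenario.connectors)
        self.types = types
        self.t_v0 = np.array([t.v0 for t in types]) if types else np.zeros(0)
        self.t_fs = np.array([t.stall_force for t in types]) if types else np.zeros(0)
        self.t_kon = np.array([t.k_on for t in types]) if types else np.zeros(0)
        self.t_koff = np.array([t.k_off for t in types]) if types else np.zeros(0)
        self.t_eps = np.array([t.capture_range for t in types]) if types else np.zeros(0)
        self.t_delta = np.array([t.end_range for t in types]) if types else np.zeros(0)
        self.t_k = np.array([t.stiffness for t in types]) if types else np.zeros(0)

        # point connectors
        n_point = sum(t.count for t in types if not t.is_minifilament)
        self.c_type = np.zeros(n_point, dtype=np.int32)
        self.c_kind = np.zeros((n_point, 2), dtype=np.int8)
        self.c_pos = np.zeros((n_point, 2))
        self.c_fil = np.full((n_point, 2), -1, dtype=np.int32)
        self.c_s = np.zeros((n_point, 2))

        # minifilaments
        n_mini = sum(t.count for t in types if t.is_minifilament)
        self.m_type = np.zeros(n_mini, dtype=np.int32)
        self.m_kind = np.zeros((n_mini, 2), dtype=np.int8)
        self.m_backbone = np.zeros(n_mini)
        self.m_center = np.zeros((n_mini, 2))
        self.m_angle = np.zeros(n_mini)
        self.m_fil = np.full((n_mini, 2), -1, dtype=np.int32)
        self.m_s = np.zeros((n_mini, 2))

        self._neighbor_grid = None  # kinetics cache
        self._neighbor_age = 10**9

    # -- derived quantities --------------------------------------------------

    @property
    def gamma_point(self) -> float:
        """Drag coefficient of one filament point, γ · segment_length."""
        return self.params.drag * self.seg

    def filament_segment_lengths(self) -> np.ndarray:
        e = self.fil_x[:, 1:] - self.fil_x[:, :-1]
        return np.linalg.norm(e, axis=-1)

    def attachment_positions(self, fil: np.ndarray, s: np.ndarray):
        """World positions of attachments (vectorized); returns (pos, seg index, weight)."""
        t = s * (1.0 / self.seg)
        i = np.minimum(t.astype(np.int64), self.n_pts - 2)
        w = t - i
        flat = self.fil_x.reshape(-1, 2)
        base = fil * self.n_pts + i
        p0 = flat[base]
        p1 = flat[base + 1]
        return p0 + w[:, None] * (p1 - p0), i, w

    def minifilament_ends(self) -> np.ndarray:
        """Backbone end positions, shape (n_mini, 2, 2)."""
        half = np.empty_like(self.m_center)
        half[:, 0] = np.cos(self.m_angle)
        half[:, 1] = np.sin(self.m_angle)
        half *= 0.5 * self.m_backbone[:, None]
        ends = np.empty((self.m_center.shape[0], 2, 2))
        ends[:, 0] = self.m_center - half
        ends[:, 1] = self.m_center + half
        return ends

    # -- bookkeeping ---------------------------------------------------------

    def invalidate_neighbors(self) -> None:
        self._neighbor_age = 10**9

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            "time": np.array([self.time]),
            "fil_x": self.fil_x,
            "c_type": self.c_type,
            "c_kind": self.c_kind,
            "c_pos": self.c_pos,
            "c_fil": self.c_fil,
            "c_s": self.c_s,
            "m_type": self.m_type,
            "m_center": self.m_center,
            "m_angle": self.m_angle,
            "m_fil": self.m_fil,
            "m_s": self.m_s,
        }

    def fingerprint(self) -> str:
        """SHA-256 over the full serialized state (bit-reproducibility checks)."""
        h = hashlib.sha256()
        for key in sorted(self.state_dict()):
            arr = np.ascontiguousarray(self.state_dict()[key])
            h.update(key.encode())
            h.update(arr.tobytes())
        return h.hexdigest()


def _stability_bound(world: World) -> float:
    """Largest stable dt: γ_point / (4 k_max) over the springs in the system."""
    k_max = float(world.t_k.max()) if world.t_k.size else 0.0
    if k_max <= 0:
        return math.inf
    gammas = [world.gamma_point]
    backbones = [t.backbone_length for t in world.types if t.is_minifilament and t.count > 0]
    if backbones:
        gammas.append(world.params.drag * min(backbones))
    return min(gammas) / (4.0 * k_max)


def build_world(scenario: Scenario) -> World:
    """Initialize a world: straight filaments and free connectors uniformly
    at random over the domain; deterministic under the scenario seed."""
    world = World(scenario)
    rng = world.rng
    bound = _stability_bound(world)
    if scenario.params.dt > bound:
        raise ValueError(
            f"dt={scenario.params.dt} exceeds the stability bound "
            f"gamma_point/(4 k_max) = {bound:.2e}; reduce dt"
        )

    # filaments: straight, uniform random center and orientation
    n, L = world.n_fil, world.fil_length
    centers = scenario.domain.sample_positions(rng, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    u = np.column_stack([np.cos(phi), np.sin(phi)])
    offsets = np.linspace(-L / 2.0, L / 2.0, world.n_pts)
    world.fil_x = centers[:, None, :] + offsets[None, :, None] * u[:, None, :]

    # connectors
    point_rows, mini_rows = [], []
    for ti, ct in enumerate(world.types):
        (mini_rows if ct.is_minifilament else point_rows).extend([ti] * ct.count)
    if point_rows:
        world.c_type = np.array(point_rows, dtype=np.int32)
        world.c_kind = np.array(
            [[KIND_CODES[k] for k in world.types[ti].subunits] for ti in point_rows],
            dtype=np.int8,
        )
        world.c_pos = scenario.domain.sample_positions(rng, len(point_rows))
        world.c_fil = np.full((len(point_rows), 2), -1, dtype=np.int32)
        world.c_s = np.zeros((len(point_rows), 2))
    if mini_rows:
        world.m_type = np.array(mini_rows, dtype=np.int32)
        world.m_kind = np.array(
            [[KIND_CODES[k] for k in world.types[ti].subunits] for ti in mini_rows],
            dtype=np.int8,
        )
        world.m_backbone = np.array([world.types[ti].backbone_length for ti in mini_rows])
        world.m_center = scenario.domain.sample_positions(rng, len(mini_rows))
        world.m_angle = rng.uniform(0.0, 2.0 * math.pi, size=len(mini_rows))
        world.m_fil = np.full((len(mini_rows), 2), -1, dtype=np.int32)
        world.m_s = np.zeros((len(mini_rows), 2))
    return world
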