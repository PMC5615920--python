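"""Overdamped Brownian dynamics: forces and one explicit integration step.

Forces on filament points are the discretized bending elasticity, the
zero-rest-length Hookean springs of bridging connectors and minifilament
arms, an optional external force field (used by validation experiments), and
thermal noise of variance 2 kT dt / γ per degree of freedom.  Filament
inextensibility is enforced by an iterative, centroid-preserving projection
of segment lengths after each step; rigid filaments are advanced as rigid
bodies (translation + rotation) instead.
"""

from __future__ import annotations

import math

import numpy as np

from .world import World

__all__ = ["step_dynamics", "bending_energy", "SimulationUnstable"]


class SimulationUnstable(RuntimeError):
    """Raised when a step moves a point further than half a segment length.

    This indicates the explicit integration left its stability region;
    reduce dt (or stiffnesses).  The offending world state is attached as
    ``world`` for diagnosis.
    """

    def __init__(self, message: str, world: World):
        super().__init__(message)
        self.world = world


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _scatter_forces(F: np.ndarray, fil, seg_idx, f_lo, f_hi) -> None:
    """Accumulate interpolated attachment forces onto filament vertices."""
    n_pts = F.shape[1]
    flat = F.reshape(-1, 2)
    idx = np.concatenate([fil * n_pts + seg_idx, fil * n_pts + seg_idx + 1])
    w = np.concatenate([f_lo, f_hi], axis=0)
    flat[:, 0] += np.bincount(idx, weights=w[:, 0], minlength=flat.shape[0])
    flat[:, 1] += np.bincount(idx, weights=w[:, 1], minlength=flat.shape[0])


def bending_forces(world: World) -> np.ndarray:
    """-∇ of the discrete bending energy (κ / 2 seg³) Σ |p_{i-1} - 2 p_i + p_{i+1}|²."""
    x = world.fil_x
    if world.rigid or world.n_pts < 3 or not math.isfinite(world.kappa):
        return np.zeros_like(x)
    c = world.kappa / world.seg**3
    d = x[:, 2:] - 2.0 * x[:, 1:-1] + x[:, :-2]
    F = np.zeros_like(x)
    F[:, :-2] -= c * d
    F[:, 1:-1] += 2.0 * c * d
    F[:, 2:] -= c * d
    return F


def bending_energy(world: World) -> float:
    x = world.fil_x
    if world.rigid or world.n_pts < 3 or not math.isfinite(world.kappa):
        return 0.0
    d = x[:, 2:] - 2.0 * x[:, 1:-1] + x[:, :-2]
    return 0.5 * world.kappa / world.seg**3 * float(np.sum(d * d))


def connector_spring_forces(world: World, F: np.ndarray):
    """Spring forces of bridging connectors and minifilament arms.

    Accumulates onto filament vertex forces ``F`` and returns the net force
    and torque on each minifilament, shape (n_mini, 2) and (n_mini,).
    """
    dom = world.domain

    # point connectors bridging two filaments
    bridging = np.where((world.c_fil[:, 0] >= 0) & (world.c_fil[:, 1] >= 0))[0]
    if bridging.size:
        fa, fb = world.c_fil[bridging, 0], world.c_fil[bridging, 1]
        xa, ia, wa = world.attachment_positions(fa, world.c_s[bridging, 0])
        xb, ib, wb = world.attachment_positions(fb, world.c_s[bridging, 1])
        k = world.t_k[world.c_type[bridging]][:, None]
        f = -k * dom.min_image(xa - xb)  # force on subunit a; -f on b
        _scatter_forces(F, fa, ia, f * (1.0 - wa)[:, None], f * wa[:, None])
        _scatter_forces(F, fb, ib, -f * (1.0 - wb)[:, None], -f * wb[:, None])

    Fm = np.zeros((world.m_type.size, 2))
    Tm = np.zeros(world.m_type.size)
    if world.m_type.size:
        flat_fil = world.m_fil.reshape(-1)
        att = np.where(flat_fil >= 0)[0]
        if att.size:
            ends = world.minifilament_ends().reshape(-1, 2)
            mini = att // 2
            fil = flat_fil[att]
            x_att, i, w = world.attachment_positions(fil, world.m_s.reshape(-1)[att])
            x_end = ends[att]
            k = world.t_k[world.m_type[mini]][:, None]
            d = dom.min_image(x_att - x_end)
            f_fil = -k * d  # on the filament attachment point
            _scatter_forces(F, fil, i, f_fil * (1.0 - w)[:, None], f_fil * w[:, None])
            f_end = k * d  # reaction on the backbone end
            n_mini = Fm.shape[0]
            Fm[:, 0] += np.bincount(mini, weights=f_end[:, 0], minlength=n_mini)
            Fm[:, 1] += np.bincount(mini, weights=f_end[:, 1], minlength=n_mini)
            lever = x_end - world.m_center[mini]
            Tm += np.bincount(mini, weights=_cross2(lever, f_end), minlength=n_mini)
    return Fm, Tm


def _project_segment_lengths(world: World) -> None:
    """Constraint projection restoring segment rest lengths.

    Solves the linearized length constraints with Lagrange multipliers: for
    a chain the multiplier system is tridiagonal (diagonal 2, off-diagonal
    -ê_i·ê_{i+1}) and is solved with the Thomas algorithm, vectorized across
    filaments.  The correction field telescopes, so the filament centroid is
    preserved exactly.  A couple of passes reach ``projection_tol``.
    """
    x = world.fil_x
    seg = world.seg
    tol = world.params.projection_tol * seg
    for _ in range(world.params.projection_iterations):
        e = x[:, 1:] - x[:, :-1]  # (n_fil, m, 2)
        ln = np.sqrt((e * e).sum(-1))
        c = ln - seg
        if abs(c).max() < tol:
            return
        u = e / ln[:, :, None]
        a = (u[:, :-1] * u[:, 1:]).sum(-1)  # couplings, (n_fil, m-1)
        m = c.shape[1]
        # Thomas forward sweep of (2, -a) tridiagonal systems, batched
        cp = np.empty_like(c)  # modified superdiagonal / rhs storage
        dp = np.empty_like(c)
        cp[:, 0] = (-a[:, 0] / 2.0) if m > 1 else 0.0
        dp[:, 0] = c[:, 0] / 2.0
        for i in range(1, m):
            denom = 2.0 - (-a[:, i - 1]) * cp[:, i - 1]
            if i < m - 1:
                cp[:, i] = -a[:, i] / denom
            dp[:, i] = (c[:, i] + a[:, i - 1] * dp[:, i - 1]) / denom
        lam = np.empty_like(c)
        lam[:, m - 1] = dp[:, m - 1]
        for i in range(m - 2, -1, -1):
            lam[:, i] = dp[:, i] - cp[:, i] * lam[:, i + 1]
        corr = lam[:, :, None] * u
        x[:, :-1] += corr
        x[:, 1:] -= corr


def step_dynamics(world: World) -> World:
    """One explicit Euler–Maruyama step for filaments, minifilaments and
    free connectors.  Raises :class:`SimulationUnstable` on a step larger
    than half a segment length or on non-finite coordinates."""
    p = world.params
    dt = p.dt
    rng = world.rng
    dom = world.domain

    F = bending_forces(world)
    if world.external_force is not None:
        F += world.external_force
    Fm, Tm = connector_spring_forces(world, F)

    # --- filaments (updates validated before any state is mutated, so an
    # instability leaves the world intact for an adaptive-dt retry)
    new_fil_x = None
    if world.n_fil:
        if world.rigid:
            center = world.fil_x.mean(axis=1)
            r = world.fil_x - center[:, None, :]
            F_tot = F.sum(axis=1)
            torque = _cross2(r, F).sum(axis=1)
            g_t = p.drag * world.fil_length
            g_r = p.drag * world.fil_length**3 / 12.0
            dc = dt * F_tot / g_t
            dth = dt * torque / g_r
            if p.kT > 0:
                dc = dc + math.sqrt(2.0 * p.kT * dt / g_t) * rng.standard_normal(dc.shape)
                dth = dth + math.sqrt(2.0 * p.kT * dt / g_r) * rng.standard_normal(dth.shape)
            cos, sin = np.cos(dth), np.sin(dth)
            rx = cos[:, None] * r[..., 0] - sin[:, None] * r[..., 1]
            ry = sin[:, None] * r[..., 0] + cos[:, None] * r[..., 1]
            new_fil_x = (center + dc)[:, None, :] + np.stack([rx, ry], axis=-1)
            disp_max = float(np.max(np.abs(new_fil_x - world.fil_x)))
        else:
            g = world.gamma_point
            disp = (dt / g) * F
            if p.kT > 0:
                disp += math.sqrt(2.0 * p.kT * dt / g) * rng.standard_normal(disp.shape)
            disp_max = float(np.max(np.abs(disp)))
        if not np.isfinite(disp_max) or disp_max > 0.5 * world.seg:
            raise SimulationUnstable(
                f"t={world.time:.4f}s: max point displacement {disp_max:.3g} μm exceeds "
                f"segment_length/2 = {0.5 * world.seg:.3g} μm; reduce dt",
                world,
            )

    # --- minifilaments (rigid rods), validated likewise
    d_center = d_angle = None
    if world.m_type.size:
        g_t = p.drag * world.m_backbone
        g_r = p.drag * world.m_backbone**3 / 3.0
        d_center = dt * Fm / g_t[:, None]
        d_angle = dt * Tm / g_r
        if p.kT > 0:
            d_center = d_center + (
                np.sqrt(2.0 * p.kT * dt / g_t)[:, None]
                * rng.standard_normal(world.m_center.shape)
            )
            d_angle = d_angle + np.sqrt(2.0 * p.kT * dt / g_r) * rng.standard_normal(
                world.m_angle.shape
            )
        c_max = float(np.max(np.abs(d_center))) if d_center.size else 0.0
        a_max = float(np.max(np.abs(d_angle))) if d_angle.size else 0.0
        if not np.isfinite(c_max) or not np.isfinite(a_max) or c_max > 0.5 * world.seg or a_max > 0.5:
            raise SimulationUnstable(
                f"t={world.time:.4f}s: minifilament step too large "
                f"(|dx|={c_max:.3g} μm, |dθ|={a_max:.3g} rad); reduce dt",
                world,
            )

    # --- commit
    if new_fil_x is not None:
        world.fil_x = new_fil_x
    elif world.n_fil:
        world.fil_x += disp
        _project_segment_lengths(world)
    if world.m_type.size:
        world.m_center += d_center
        world.m_angle += d_angle
        if dom.periodic:
            world.m_center = dom.wrap(world.m_center)

    # --- point connectors: free ones diffuse, single-bound ones ride the filament
    if world.c_type.size:
        n_att = (world.c_fil >= 0).sum(axis=1)
        free = np.where(n_att == 0)[0]
        if free.size and p.kT > 0:
            D_step = math.sqrt(2.0 * p.kT * dt / p.drag_connector)
            world.c_pos[free] += D_step * rng.standard_normal((free.size, 2))
            if dom.periodic:
                world.c_pos[free] = dom.wrap(world.c_pos[free])
        single = np.where(n_att == 1)[0]
        if single.size:
            slot = (world.c_fil[single, 0] < 0).astype(np.int64)  # the bound slot
            pos, _, _ = world.attachment_positions(
                world.c_fil[single, slot], world.c_s[single, slot]
            )
            world.c_pos[single] = dom.wrap(pos)

    world.time += dt
    return world
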