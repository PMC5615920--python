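"""Stochastic connector kinetics: motor stepping, unbinding, binding.

Binding: an unattached subunit binds at rate k_on whenever a filament lies
within the capture range ε, attaching at the closest point of the filament;
end-binding subunits attach at their designated end when it is within the
end range δ.  Unbinding is force-independent at rate k_off.  Motor subunits
advance their abscissa at the unloaded speed reduced linearly by the
opposing component of the connector spring force, v(f) = v0 max(0, 1-f/f_s)
(clamped to [0, v0]), and detach immediately upon reaching a filament end.

Neighbor queries use a k-d tree over filament vertices (periodic boxes use
the tree's native wrap-around), rebuilt every ``neighbor_stride`` steps with
a distance margin covering the motion accumulated in between; candidate
attachments are then checked with exact point-segment distances, so the tree
only ever prunes, never silently misses.  Binding attempts are sampled
first (rate k_on) and only the sampled subunits are searched, which is
equivalent to testing eligibility for every subunit but much cheaper.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .world import KIND_DIRECTION, KIND_SITE, World

__all__ = ["step_kinetics"]


def _advance_motors(world: World, ends: np.ndarray | None, dt: float) -> None:
    L = world.fil_length
    dom = world.domain

    # point connectors
    if world.c_type.size:
        kind_dir = KIND_DIRECTION[world.c_kind]
        for j in (0, 1):
            sel = np.where((world.c_fil[:, j] >= 0) & (kind_dir[:, j] != 0.0))[0]
            if not sel.size:
                continue
            fil = world.c_fil[sel, j]
            s = world.c_s[sel, j]
            xa, i, _ = world.attachment_positions(fil, s)
            tang = world.fil_x[fil, i + 1] - world.fil_x[fil, i]
            tang /= np.sqrt((tang * tang).sum(-1))[:, None]
            d = kind_dir[sel, j]
            v0 = world.t_v0[world.c_type[sel]]
            fs = world.t_fs[world.c_type[sel]]
            speed = v0.copy()
            other = 1 - j
            br = world.c_fil[sel, other] >= 0
            if br.any():
                bsel = sel[br]
                xb, _, _ = world.attachment_positions(
                    world.c_fil[bsel, other], world.c_s[bsel, other]
                )
                k = world.t_k[world.c_type[bsel]]
                f = -k[:, None] * dom.min_image(xa[br] - xb)
                e = d[br, None] * tang[br]
                f_opp = np.maximum(0.0, -(f * e).sum(axis=-1))
                speed[br] = v0[br] * np.minimum(
                    1.0, np.maximum(0.0, 1.0 - f_opp / fs[br])
                )
            s_new = s + d * speed * dt
            done = (s_new <= 0.0) | (s_new >= L)
            world.c_s[sel, j] = np.minimum(L, np.maximum(0.0, s_new))
            if done.any():
                _detach_point_slots(world, sel[done], j)

    # minifilament arms
    if world.m_type.size:
        kind_dir = KIND_DIRECTION[world.m_kind]
        for arm in (0, 1):
            sel = np.where((world.m_fil[:, arm] >= 0) & (kind_dir[:, arm] != 0.0))[0]
            if not sel.size:
                continue
            fil = world.m_fil[sel, arm]
            s = world.m_s[sel, arm]
            xa, i, _ = world.attachment_positions(fil, s)
            tang = world.fil_x[fil, i + 1] - world.fil_x[fil, i]
            tang /= np.sqrt((tang * tang).sum(-1))[:, None]
            d = kind_dir[sel, arm]
            v0 = world.t_v0[world.m_type[sel]]
            fs = world.t_fs[world.m_type[sel]]
            k = world.t_k[world.m_type[sel]]
            f = -k[:, None] * dom.min_image(xa - ends[sel, arm])
            e = d[:, None] * tang
            f_opp = np.maximum(0.0, -(f * e).sum(axis=-1))
            speed = v0 * np.minimum(1.0, np.maximum(0.0, 1.0 - f_opp / fs))
            s_new = s + d * speed * dt
            done = (s_new <= 0.0) | (s_new >= L)
            world.m_s[sel, arm] = np.minimum(L, np.maximum(0.0, s_new))
            world.m_fil[sel[done], arm] = -1
            world.events["unbind"] += int(done.sum())


def _detach_point_slots(world: World, conns: np.ndarray, slot: int) -> None:
    """Detach the given slot of the given point connectors, updating the
    free-molecule position when the connector loses its last attachment."""
    if not conns.size:
        return
    other = 1 - slot
    lone = world.c_fil[conns, other] < 0
    if lone.any():
        lose = conns[lone]
        pos, _, _ = world.attachment_positions(world.c_fil[lose, slot], world.c_s[lose, slot])
        world.c_pos[lose] = world.domain.wrap(pos)
    world.c_fil[conns, slot] = -1
    world.events["unbind"] += int(conns.size)


def _unbind(world: World, dt: float) -> None:
    p_off = 1.0 - np.exp(-world.t_koff * dt)
    if world.c_type.size:
        for j in (0, 1):
            att = np.where(world.c_fil[:, j] >= 0)[0]
            if not att.size:
                continue
            u = world.rng.uniform(size=att.size)
            go = att[u < p_off[world.c_type[att]]]
            _detach_point_slots(world, go, j)
    if world.m_type.size:
        for arm in (0, 1):
            att = np.where(world.m_fil[:, arm] >= 0)[0]
            if not att.size:
                continue
            u = world.rng.uniform(size=att.size)
            go = att[u < p_off[world.m_type[att]]]
            world.m_fil[go, arm] = -1
            world.events["unbind"] += int(go.size)


def _refresh_neighbors(world: World) -> None:
    if world._neighbor_age < world.params.neighbor_stride and world._neighbor_grid is not None:
        world._neighbor_age += 1
        return
    verts = world.fil_x.reshape(-1, 2)
    if world.domain.periodic:
        verts = np.mod(verts, world.domain.side)
        # guard against the half-open interval: mod can return exactly `side`
        verts[verts >= world.domain.side] = 0.0
        tree = cKDTree(verts, boxsize=world.domain.side)
    else:
        tree = cKDTree(verts)
    world._neighbor_grid = tree
    world._neighbor_age = 1


def _first_per_group(groups: np.ndarray, order_value: np.ndarray):
    """Index of the row minimizing ``order_value`` within each group id."""
    order = np.lexsort((order_value, groups))
    g = groups[order]
    first = np.ones(g.size, dtype=bool)
    first[1:] = g[1:] != g[:-1]
    return order[first]


def _search_anywhere(world: World, pos: np.ndarray, eps: np.ndarray, excl: np.ndarray):
    """Closest-point attachment search for anywhere-binding subunits.

    Returns (candidate row, filament, abscissa) arrays for the successful
    candidates.  Exact point-segment distances; the tree only prunes.
    """
    tree: cKDTree = world._neighbor_grid
    n_pts = world.n_pts
    r = float(eps.max()) + 0.5 * world.seg + world.params.neighbor_margin
    q = np.mod(pos, world.domain.side) if world.domain.periodic else pos
    lists = tree.query_ball_point(q, r)
    lens = np.array([len(l) for l in lists])
    if lens.sum() == 0:
        return (np.zeros(0, dtype=np.int64),) * 3
    cand = np.repeat(np.arange(pos.shape[0]), lens)
    vert = np.fromiter(
        (v for l in lists for v in l), dtype=np.int64, count=int(lens.sum())
    )
    fil = vert // n_pts
    pt = vert % n_pts
    keep = fil != excl[cand]
    if not keep.any():
        return (np.zeros(0, dtype=np.int64),) * 3
    cand, fil, pt = cand[keep], fil[keep], pt[keep]
    # both segments adjacent to each vertex (duplicates are harmless in a min)
    seg_lo = np.maximum(pt - 1, 0)
    seg_hi = np.minimum(pt, n_pts - 2)
    cand2 = np.concatenate([cand, cand])
    fil2 = np.concatenate([fil, fil])
    si = np.concatenate([seg_lo, seg_hi])
    a = world.fil_x[fil2, si]
    e = world.fil_x[fil2, si + 1] - a
    d0 = world.domain.min_image(pos[cand2] - a)
    t = (d0 * e).sum(-1) / (e * e).sum(-1)
    t = np.minimum(1.0, np.maximum(0.0, t))
    dvec = d0 - t[:, None] * e
    dist = np.sqrt((dvec * dvec).sum(-1))
    best = _first_per_group(cand2, dist)
    ok = dist[best] <= eps[cand2[best]]
    best = best[ok]
    return cand2[best], fil2[best], (si[best] + t[best]) * world.seg


def _search_ends(world: World, pos: np.ndarray, delta: np.ndarray, excl: np.ndarray,
                 site: np.ndarray):
    """Attachment search for end binders: the designated end vertex within δ."""
    tree: cKDTree = world._neighbor_grid
    n_pts = world.n_pts
    r = float(delta.max()) + world.params.neighbor_margin
    q = np.mod(pos, world.domain.side) if world.domain.periodic else pos
    lists = tree.query_ball_point(q, r)
    lens = np.array([len(l) for l in lists])
    if lens.sum() == 0:
        return (np.zeros(0, dtype=np.int64),) * 2 + (np.zeros(0),)
    cand = np.repeat(np.arange(pos.shape[0]), lens)
    vert = np.fromiter(
        (v for l in lists for v in l), dtype=np.int64, count=int(lens.sum())
    )
    fil = vert // n_pts
    pt = vert % n_pts
    target = np.where(site[cand] > 0, n_pts - 1, 0)
    keep = (pt == target) & (fil != excl[cand])
    if not keep.any():
        return (np.zeros(0, dtype=np.int64),) * 2 + (np.zeros(0),)
    cand, fil, pt = cand[keep], fil[keep], pt[keep]
    d = world.domain.min_image(pos[cand] - world.fil_x[fil, pt])
    dist = np.sqrt((d * d).sum(-1))
    best = _first_per_group(cand, dist)
    ok = dist[best] <= delta[cand[best]]
    best = best[ok]
    s = np.where(site[cand[best]] > 0, world.fil_length, 0.0)
    return cand[best], fil[best], s


def _bind(world: World, ends: np.ndarray | None, dt: float) -> None:
    if world.n_fil == 0:
        return
    p_on = 1.0 - np.exp(-world.t_kon * dt)

    # sample binding attempts: (tag, object index, slot, position, kind)
    tags, objs, slots, poss, kinds, typs = [], [], [], [], [], []
    if world.c_type.size:
        for j in (0, 1):
            fr = np.where(world.c_fil[:, j] < 0)[0]
            if not fr.size:
                continue
            u = world.rng.uniform(size=fr.size)
            hit = fr[u < p_on[world.c_type[fr]]]
            if hit.size:
                tags.append(np.zeros(hit.size, dtype=np.int8))
                objs.append(hit)
                slots.append(np.full(hit.size, j, dtype=np.int8))
                poss.append(world.c_pos[hit])
                kinds.append(world.c_kind[hit, j])
                typs.append(world.c_type[hit])
    if world.m_type.size:
        for arm in (0, 1):
            fr = np.where(world.m_fil[:, arm] < 0)[0]
            if not fr.size:
                continue
            u = world.rng.uniform(size=fr.size)
            hit = fr[u < p_on[world.m_type[fr]]]
            if hit.size:
                tags.append(np.ones(hit.size, dtype=np.int8))
                objs.append(hit)
                slots.append(np.full(hit.size, arm, dtype=np.int8))
                poss.append(ends[hit, arm])
                kinds.append(world.m_kind[hit, arm])
                typs.append(world.m_type[hit])
    if not tags:
        world._neighbor_age += 1
        return

    tag = np.concatenate(tags)
    obj = np.concatenate(objs)
    slot = np.concatenate(slots)
    pos = np.concatenate(poss)
    kind = np.concatenate(kinds)
    typ = np.concatenate(typs)
    other = 1 - slot
    excl = np.empty(obj.size, dtype=np.int64)
    pt_mask = tag == 0
    excl[pt_mask] = world.c_fil[obj[pt_mask], other[pt_mask]]
    excl[~pt_mask] = world.m_fil[obj[~pt_mask], other[~pt_mask]]

    _refresh_neighbors(world)
    site = KIND_SITE[kind]

    for is_end in (False, True):
        mask = (site != 0) if is_end else (site == 0)
        if not mask.any():
            continue
        rows = np.where(mask)[0]
        if is_end:
            c, fil, s = _search_ends(
                world, pos[rows], world.t_delta[typ[rows]], excl[rows], site[rows]
            )
        else:
            c, fil, s = _search_anywhere(
                world, pos[rows], world.t_eps[typ[rows]], excl[rows]
            )
        for ci, fi, si in zip(rows[c], fil, s):
            o, sl = int(obj[ci]), int(slot[ci])
            if tag[ci] == 0:
                if world.c_fil[o, 1 - sl] == fi:  # partner bound this filament meanwhile
                    continue
                world.c_fil[o, sl] = fi
                world.c_s[o, sl] = si
            else:
                if world.m_fil[o, 1 - sl] == fi:
                    continue
                world.m_fil[o, sl] = fi
                world.m_s[o, sl] = si
            world.events["bind"] += 1


def step_kinetics(world: World, dt: float | None = None) -> World:
    """Advance motors, then apply unbinding, then binding over one
    kinetics interval ``dt`` (defaults to the dynamics dt)."""
    if dt is None:
        dt = world.params.dt
    ends = world.minifilament_ends() if world.m_type.size else None
    _advance_motors(world, ends, dt)
    _unbind(world, dt)
    _bind(world, ends, dt)
    return world
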