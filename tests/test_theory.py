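"""The contractility scalar χ, regime weighting Φ, and derived predictions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contranet.connectors import (
    ALL_SUBUNIT_KINDS,
    ConnectorType,
    OccupancyModel,
    SubunitKind,
    SystemSpec,
    enumerate_configurations,
    enumerate_connector_types,
)
from contranet.theory import (
    FLEXIBLE,
    RIGID,
    MechanicalRegime,
    MeshStats,
    buckling_threshold,
    chi,
    mesh_size,
    phi_weight,
    predict_phase_table,
    predicted_radial_rate,
    rate_curve,
)


def _system(*pairs, **kw) -> SystemSpec:
    return SystemSpec(tuple(ConnectorType(p, **kw) for p in pairs))


MOTOR = (SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_MOTOR)
XLINK = (SubunitKind.SIDE_BINDER, SubunitKind.SIDE_BINDER)


class TestBucklingThreshold:
    def test_euler_formula(self):
        kappa = 0.075
        assert buckling_threshold(kappa, math.pi**2 * kappa) == pytest.approx(1.0)

    def test_rigid_limit_is_infinite(self):
        assert buckling_threshold(math.inf, 5.0) == math.inf

    def test_nonpositive_force_rejected(self):
        with pytest.raises(ValueError):
            buckling_threshold(0.075, 0.0)


class TestMeshSize:
    def test_crossing_formula_matches_monte_carlo(self, rng):
        """Oracle: brute-force intersection counting of random needles on a
        torus (edge-effect free), vs 2 L² / (π A) per filament pair."""
        L, side = 3.0, 10.0
        n_pairs = 60_000
        hits = 0
        for _ in range(n_pairs):
            c = rng.uniform(0, side, size=(2, 2))
            th = rng.uniform(0, 2 * math.pi, size=2)
            u = np.array([[math.cos(t), math.sin(t)] for t in th])
            d = c[1] - c[0]
            d -= side * np.round(d / side)  # minimum image of the pair offset
            if _segments_intersect(-0.5 * L * u[0], 0.5 * L * u[0],
                                   d - 0.5 * L * u[1], d + 0.5 * L * u[1]):
                hits += 1
        p_mc = hits / n_pairs
        p_formula = 2 * L**2 / (math.pi * side**2)
        assert p_mc == pytest.approx(p_formula, rel=0.05)

    def test_mesh_shrinks_with_filament_count(self):
        l1 = [mesh_size(n, 3.0, 100.0).mesh_size for n in (10, 100, 1000)]
        assert l1[0] > l1[1] > l1[2]

    def test_doubling_area_halves_crossings(self):
        a = mesh_size(100, 3.0, 100.0).crossings_per_filament
        b = mesh_size(100, 3.0, 200.0).crossings_per_filament
        assert a == pytest.approx(2 * b)

    def test_fewer_than_two_filaments_rejected(self):
        with pytest.raises(ValueError, match="mesh undefined"):
            mesh_size(1, 3.0, 100.0)

    def test_beta0_definition(self):
        m = mesh_size(100, 3.0, 100.0, buckling_length=1.2)
        assert m.beta0 == pytest.approx(1.2 / m.mesh_size)


def _segments_intersect(a0, a1, b0, b1) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1, d2 = orient(b0, b1, a0), orient(b0, b1, a1)
    d3, d4 = orient(a0, a1, b0), orient(a0, a1, b1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


class TestPhiWeight:
    def _expansile(self):
        system = _system(MOTOR, XLINK)
        return [c for c in enumerate_configurations(system) if c.relative_speed > 0][0]

    def test_rigid_keeps_everything(self):
        assert phi_weight(self._expansile(), RIGID) == 1.0

    def test_flexible_discards_expansile(self):
        assert phi_weight(self._expansile(), FLEXIBLE) == 0.0

    def test_contractile_always_kept(self):
        system = _system(MOTOR, XLINK)
        contractile = [c for c in enumerate_configurations(system) if c.relative_speed < 0][0]
        mesh = MeshStats(0.5, 6.0, beta0=3.0)
        semi = MechanicalRegime.semiflexible(0.075, 5.0)
        for regime in (RIGID, FLEXIBLE, semi):
            assert phi_weight(contractile, regime, OccupancyModel.actomyosin(0.5, 0.5), mesh) == 1.0

    def test_semiflexible_without_crosslinkers_discards_expansile(self):
        mesh = MeshStats(0.5, 6.0, beta0=3.0)
        semi = MechanicalRegime.semiflexible(0.075, 5.0)
        occ = OccupancyModel.actomyosin(0.5, 0.0)
        assert phi_weight(self._expansile(), semi, occ, mesh) == pytest.approx(0.0)

    def test_semiflexible_reduces_to_flexible_below_one_mesh(self):
        mesh = MeshStats(0.5, 6.0, beta0=0.7)  # buckling length below mesh size
        semi = MechanicalRegime.semiflexible(0.075, 5.0)
        occ = OccupancyModel.actomyosin(0.5, 0.5)
        assert phi_weight(self._expansile(), semi, occ, mesh) == pytest.approx(0.0)


class TestChi:
    def test_rigid_motor_crosslinker_sum_is_null(self):
        res = chi(_system(MOTOR, XLINK), RIGID, OccupancyModel.actomyosin(0.7, 0.3))
        assert res.numerator == pytest.approx(0.0, abs=1e-15)
        assert res.chi == pytest.approx(0.0, abs=1e-15)
        assert res.phase == "neutral"

    @settings(derandomize=True, max_examples=60)
    @given(
        P_M=st.floats(0.0, 1.0),
        P_C=st.floats(0.0, 1.0),
        v=st.floats(0.01, 5.0),
    )
    def test_flexible_numerator_formula(self, P_M, P_C, v):
        res = chi(_system(MOTOR, XLINK, v0=v), FLEXIBLE, OccupancyModel.actomyosin(P_M, P_C))
        assert res.numerator == pytest.approx(-P_M * P_C * (1 - P_C) * v, abs=1e-12)

    @pytest.mark.parametrize("beta0", [0.5, 1.0, 2.0, 4.0])
    def test_semiflexible_numerator_formula(self, beta0):
        P_M, P_C, v = 0.6, 0.4, 1.0
        mesh = MeshStats(0.5, 6.0, beta0=beta0)
        semi = MechanicalRegime.semiflexible(0.075, 5.0)
        res = chi(_system(MOTOR, XLINK, v0=v), semi, OccupancyModel.actomyosin(P_M, P_C), mesh)
        expected = -P_M * P_C * (1 - P_C) ** max(beta0, 1.0) * v
        assert res.numerator == pytest.approx(expected, abs=1e-12)

    def test_chi_zero_without_motors_or_crosslinkers(self):
        for P_M, P_C in ((0.0, 0.5), (0.5, 0.0)):
            res = chi(_system(MOTOR, XLINK), FLEXIBLE, OccupancyModel.actomyosin(P_M, P_C))
            assert res.numerator == 0.0

    def test_end_binder_sign_switch(self):
        expansile = _system((SubunitKind.PLUS_MOTOR, SubunitKind.MINUS_END_BINDER))
        contractile = _system((SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_END_BINDER))
        assert chi(expansile, RIGID).chi > 0
        assert chi(contractile, RIGID).chi < 0

    def test_empty_weight_census_is_neutral_by_vacuity(self):
        res = chi(_system(MOTOR), RIGID, OccupancyModel(site_probability={}))
        assert res.neutral_by_vacuity and res.phase == "neutral"

    def test_semiflexible_approaches_rigid_as_rigidity_diverges(self):
        system = _system(MOTOR, XLINK)
        occ = OccupancyModel.actomyosin(0.5, 0.5)
        mesh = mesh_size(100, 3.0, 100.0)
        stiff = MechanicalRegime.semiflexible(1e9, 5.0)
        res = chi(system, stiff, occ, mesh.with_buckling(stiff.buckling_threshold))
        rigid = chi(system, RIGID, occ, mesh)
        assert res.chi == pytest.approx(rigid.chi, abs=1e-9)

    def test_buckling_monotone_in_beta0(self):
        system = _system(MOTOR, XLINK)
        occ = OccupancyModel.actomyosin(0.5, 0.5)
        semi = MechanicalRegime.semiflexible(0.075, 5.0)
        mags = [
            abs(chi(system, semi, occ, MeshStats(0.5, 6.0, beta0=b)).numerator)
            for b in (1.0, 2.0, 3.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(mags, mags[1:]))
        flexible_mag = abs(chi(system, FLEXIBLE, occ).numerator)
        assert mags[0] == pytest.approx(flexible_mag)


class TestPhaseTable:
    def test_full_table_has_210_entries(self):
        types = enumerate_connector_types(ALL_SUBUNIT_KINDS)
        table = predict_phase_table(types, [FLEXIBLE, RIGID])
        assert len(table) == 210

    def test_all_passive_pairs_are_neutral(self):
        passive = enumerate_connector_types(
            {SubunitKind.SIDE_BINDER, SubunitKind.PLUS_END_BINDER, SubunitKind.MINUS_END_BINDER}
        )
        table = predict_phase_table(passive, [FLEXIBLE, RIGID])
        assert (table.phase == "neutral").all()

    def test_table_invariant_to_type_order(self):
        types = enumerate_connector_types(ALL_SUBUNIT_KINDS)
        a = predict_phase_table(types, [RIGID])
        b = predict_phase_table(list(reversed(types)), [RIGID])
        key = lambda df: {frozenset((r.type_a, r.type_b)): r.phase for r in df.itertuples()}
        assert key(a) == key(b)

    def test_sarcomere_like_pair_contracts_in_both_regimes(self):
        plus_motor_end = ConnectorType((SubunitKind.PLUS_MOTOR, SubunitKind.PLUS_END_BINDER))
        passive = ConnectorType(XLINK)
        table = predict_phase_table([plus_motor_end, passive], [FLEXIBLE, RIGID])
        assert (table.phase == "contract").all()


class TestRateCurve:
    def _sweep(self, total=20_000, steps=21):
        system = _system(MOTOR, XLINK)
        comps = [(total - i * total // (steps - 1), i * total // (steps - 1))
                 for i in range(steps)]
        return rate_curve(system, comps, regime=FLEXIBLE, n_crossings_total=5_000)

    def test_endpoints_vanish(self):
        curve = self._sweep()
        assert curve[0][1] == pytest.approx(0.0, abs=1e-12)  # no crosslinkers
        assert curve[-1][1] == pytest.approx(0.0, abs=1e-12)  # no motors

    def test_interior_maximum(self):
        curve = self._sweep()
        mags = [abs(v) for _, v in curve]
        best = int(np.argmax(mags))
        assert 0 < best < len(curve) - 1

    def test_coarse_and_fine_grid_agree_on_argmax(self):
        """Oracle: a dense grid around the coarse argmax refines it without
        jumping to a different basin (the curve is unimodal)."""
        coarse = self._sweep(steps=11)
        fine = self._sweep(steps=101)
        frac = lambda comp: comp[1] / (comp[0] + comp[1])
        best_c = frac(coarse[int(np.argmax([abs(v) for _, v in coarse]))][0])
        best_f = frac(fine[int(np.argmax([abs(v) for _, v in fine]))][0])
        assert abs(best_c - best_f) <= 0.1


class TestRadialRate:
    def test_zero_chi_zero_rate(self):
        res = chi(_system(XLINK), RIGID)
        assert predicted_radial_rate(res, 2, 10.0) == 0.0

    def test_dimensionality_scaling_and_sign(self):
        res = chi(_system(MOTOR, XLINK), FLEXIBLE)
        r2 = predicted_radial_rate(res, 2, 10.0)
        r1 = predicted_radial_rate(res, 1, 10.0)
        assert r2 < 0  # contracting
        assert r2 == pytest.approx(r1 / 2)

    def test_invalid_inputs_rejected(self):
        res = chi(_system(MOTOR, XLINK), FLEXIBLE)
        with pytest.raises(ValueError):
            predicted_radial_rate(res, 4, 10.0)
        with pytest.raises(ValueError):
            predicted_radial_rate(res, 2, -1.0)
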