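"""Mesh generation and the generalized plane-strain hyperelastic solver."""

import numpy as np
import pytest

from capmech import fem
from capmech.contours import CapSamples, make_cap_samples
from capmech.materials import DEFAULT_MATERIALS, LIPID, VESSEL
from capmech.mesh import build_mesh
from capmech.synthetic import CohortSpec, generate_cohort, generate_cylinder_fixture
from capmech.tube import analytic_tube_inflation

LAM_Z = 1.0 / 0.95  # in-vivo axial stretch for 5% axial shrinkage
P_SYS = 13.3  # kPa, ~100 mmHg


class TestBuildMesh:
    def test_cylinder_quality_and_labels(self, cylinder):
        mesh = build_mesh(cylinder, 0.2)
        assert np.all(mesh.tissue == 0)  # all vessel
        assert mesh.min_angle_deg() > 20.0
        assert np.all(mesh.element_areas() > 0)

    def test_lipid_elements_inside_lipid_polygon(self, lipid_slice):
        from shapely import contains_xy
        from shapely.geometry import Polygon

        mesh = build_mesh(lipid_slice, 0.15)
        lipid_poly = Polygon(lipid_slice.lipids[0]).buffer(0.12)
        cen = mesh.nodes[mesh.elements].mean(axis=1)
        lab = mesh.tissue == 1
        assert lab.sum() > 0
        assert contains_xy(lipid_poly, cen[lab, 0], cen[lab, 1]).all()

    def test_halving_size_quadruples_count(self, cylinder):
        n1 = build_mesh(cylinder, 0.3).n_elements
        n2 = build_mesh(cylinder, 0.15).n_elements
        assert 4 * 0.7 <= n2 / n1 <= 4 * 1.3

    def test_wall_area_covered(self, lipid_slice):
        from capmech.contours import polygon_area

        mesh = build_mesh(lipid_slice, 0.2)
        wall = polygon_area(lipid_slice.outer) - polygon_area(lipid_slice.lumen)
        assert mesh.element_areas().sum() == pytest.approx(wall, rel=0.02)


class TestSolve:
    def test_zero_load_zero_response(self, cylinder):
        mesh = build_mesh(cylinder, 0.3)
        sol = fem.solve(mesh, DEFAULT_MATERIALS, pressure=0.0, axial_stretch=1.0)
        assert sol.converged
        assert np.max(np.abs(sol.displacement)) < 1e-10
        assert np.max(np.abs(sol.cauchy_stress)) < 1e-6

    def test_matches_tube_inflation_oracle(self, cylinder):
        """Deformed inner radius within 1%, lumen-wall hoop stress within 3%."""
        oracle = analytic_tube_inflation(VESSEL, 1.5, 3.0, P_SYS, LAM_Z)
        mesh = build_mesh(cylinder, 0.15, boundary_layer=True)
        sol = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        ri_fe = np.sqrt(sol.lumen_area() / np.pi)
        assert abs(ri_fe - oracle.ri) / oracle.ri < 0.01
        base = make_cap_samples(cylinder)
        samples = CapSamples(
            points=base.points * (oracle.ri / 1.5),  # on the deformed lumen
            quarter=base.quarter,
            in_cap=base.in_cap,
            cap_thickness=base.cap_thickness,
        )
        filled = fem.extract_cap_mechanics(sol, samples)
        sigma_in = oracle.hoop_stress[0]
        assert np.max(np.abs(filled.stress - sigma_in)) / sigma_in < 0.03
        # inner-wall circumferential Green-Lagrange strain
        e_in = ((oracle.ri / 1.5) ** 2 - 1.0) / 2.0
        assert filled.strain.mean() == pytest.approx(e_in, rel=0.03)

    def test_increment_count_path_independence(self, cylinder):
        mesh = build_mesh(cylinder, 0.3)
        s1 = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z, n_increments=5)
        s2 = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z, n_increments=10)
        p1 = np.linalg.eigvalsh(s1.cauchy_stress)[:, -1].max()
        p2 = np.linalg.eigvalsh(s2.cauchy_stress)[:, -1].max()
        assert abs(p1 - p2) / p1 < 1e-3

    def test_global_equilibrium_of_constraints(self, cylinder):
        """Pressure loading is self-equilibrated: rigid-mode reactions vanish."""
        mesh = build_mesh(cylinder, 0.3)
        sol = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        # residual at equilibrium without constraint forces
        asm = fem._Assembler(mesh, DEFAULT_MATERIALS, LAM_Z)
        r = fem._residual(asm, mesh, sol.displacement, P_SYS)
        net_force = np.abs(r.sum(axis=0)).max()
        load = P_SYS * 2 * np.pi * 1.5
        assert net_force / load < 1e-8

    def test_objectivity_under_rigid_rotation(self, cylinder):
        rot = cylinder.rotated(0.6)
        m1 = build_mesh(cylinder, 0.3)
        m2 = build_mesh(rot, 0.3)
        s1 = fem.solve(m1, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        s2 = fem.solve(m2, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        p1 = np.sort(np.linalg.eigvalsh(s1.cauchy_stress)[:, -1])
        p2 = np.sort(np.linalg.eigvalsh(s2.cauchy_stress)[:, -1])
        np.testing.assert_allclose(p1, p2, rtol=1e-5, atol=1e-6)

    def test_negative_pressure_rejected(self, cylinder):
        mesh = build_mesh(cylinder, 0.4)
        with pytest.raises(ValueError):
            fem.solve(mesh, DEFAULT_MATERIALS, -1.0)


class TestAnalyticTube:
    def test_zero_pressure_pure_axial_kinematics(self):
        sol = analytic_tube_inflation(LIPID, 1.5, 3.0, 0.0, axial_stretch=1.21)
        assert sol.ri == pytest.approx(1.5 / np.sqrt(1.21), rel=1e-3)

    def test_monotone_in_pressure(self):
        radii = [
            analytic_tube_inflation(VESSEL, 1.5, 3.0, p, LAM_Z).ri
            for p in (0.0, 5.0, 10.0, 15.0)
        ]
        assert np.all(np.diff(radii) > 0)

    def test_compliance_limit_linear(self):
        """Small-pressure response of a soft tube is linear within 1%."""
        r0 = analytic_tube_inflation(LIPID, 1.5, 3.0, 0.0, 1.0).ri
        d1 = analytic_tube_inflation(LIPID, 1.5, 3.0, 0.005, 1.0).ri - r0
        d2 = analytic_tube_inflation(LIPID, 1.5, 3.0, 0.010, 1.0).ri - r0
        assert d2 / d1 == pytest.approx(2.0, rel=0.01)

    def test_boundary_stress_values(self):
        sol = analytic_tube_inflation(VESSEL, 1.5, 3.0, P_SYS, LAM_Z)
        assert sol.radial_stress[0] == pytest.approx(-P_SYS, rel=1e-6)
        assert abs(sol.radial_stress[-1]) < 1e-6 * P_SYS

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            analytic_tube_inflation(VESSEL, 3.0, 1.5, 1.0)


class TestCapMechanicsExtraction:
    def test_symmetric_inflation_uniform_stress(self, cylinder):
        """On the symmetric annulus MaxCapS/MeanCapS -> 1."""
        mesh = build_mesh(cylinder, 0.2, boundary_layer=True)
        sol = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        ri = np.sqrt(sol.lumen_area() / np.pi)
        base = make_cap_samples(cylinder)
        samples = CapSamples(
            points=base.points * (ri / 1.5),
            quarter=base.quarter,
            in_cap=np.ones(base.n, dtype=bool),  # treat whole wall as cap
            cap_thickness=np.full(base.n, 1.5),
        )
        rec = fem.cap_mechanics_record(fem.extract_cap_mechanics(sol, samples))
        assert rec["MaxCapS"] / rec["MeanCapS"] == pytest.approx(1.0, abs=0.02)

    def test_no_cap_aggregates_absent(self, cylinder):
        mesh = build_mesh(cylinder, 0.3)
        sol = fem.solve(mesh, DEFAULT_MATERIALS, P_SYS, LAM_Z)
        filled = fem.extract_cap_mechanics(sol, make_cap_samples(cylinder))
        rec = fem.cap_mechanics_record(filled)
        assert rec["MaxCapS"] is None and rec["MeanCapSn"] is None

    def test_thinner_cap_concentrates_stress(self):
        """Same lumen and lipid arc, thinner cap -> larger peak cap stress."""
        from capmech.pipeline import slice_mechanics

        def make(cap):
            from capmech.synthetic import _build_slice, _draw_shape

            rng = np.random.default_rng(5)
            shape = {"e2": 0.0, "e3": 0.0, "p2": 0.0, "p3": 0.0}
            return _build_slice(
                rng, f"cap{cap}", "T", "baseline", 1.5, 1.0, cap, 120.0, 0.0,
                shape, {"dia": 70, "sys": 120}, 96,
            )

        recs = {}
        for cap in (0.2, 0.5):
            recs[cap] = slice_mechanics(make(cap))
        assert recs[0.2]["MaxCapS"] > recs[0.5]["MaxCapS"]


def test_mesh_convergence_terminates_near_oracle(cylinder):
    """The 10%-density refinement loop stops and lands near the oracle."""
    oracle = analytic_tube_inflation(VESSEL, 1.5, 3.0, P_SYS, LAM_Z)
    sol, mesh, history = fem.mesh_convergence(
        cylinder, DEFAULT_MATERIALS, P_SYS, LAM_Z, start_size=0.35
    )
    assert len(history) >= 2
    assert abs(history[-1] - history[-2]) <= 0.02 * abs(history[-2])
    assert history[-1] == pytest.approx(oracle.hoop_stress[0], rel=0.03)
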