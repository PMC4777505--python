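"""Blood/saline flow: inlet-speed conversion, Poiseuille oracle, mass
conservation and design contrasts."""

import numpy as np
import pytest

from rfablate.flow import (FlowParams, extract_region_submesh,
                           saline_inlet_velocity, solve_ns,
                           solve_steady_flow)
from rfablate.geometry import (GeometryConfig, MeshSpec, build_domain,
                               generate_mesh, irrigation_band_area)
from rfablate.io_config import FixtureSpec, generate_fixture


class TestSalineInletVelocity:
    @pytest.mark.parametrize("Q,area,expected,tol", [
        (13.0, 1.32, 0.164, 0.003),    # six-hole ring
        (13.0, 10.37, 0.021, 0.003),   # multi-hole surface
        (0.0, 1.32, 0.0, 0.0),         # non-irrigated
    ])
    def test_printed_speeds(self, Q, area, expected, tol):
        assert saline_inlet_velocity(Q, area) == pytest.approx(expected,
                                                               abs=tol)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            saline_inlet_velocity(13.0, 0.0)
        with pytest.raises(ValueError):
            saline_inlet_velocity(-1.0, 1.32)


class TestPoiseuilleOracle:
    def test_profile_matches_closed_form(self):
        """Imposed pressure drop in a plane channel reproduces the
        parabolic profile within 1%."""
        fx = generate_fixture(FixtureSpec(oracle="poiseuille_channel",
                                          resolution=32))
        p = fx["params"]
        dirich = [(fx["walls"], 0, 0.0), (fx["walls"], 1, 0.0),
                  (fx["inlet_nodes"], 1, 0.0)]
        u, press, hist = solve_ns(
            fx["mesh"], FlowParams(mu=p["mu"]), dirich,
            traction=[(fx["inlet_facets"], p["dP"], fx["inlet_normals"])])
        pts = fx["mesh"].points
        cols = np.unique(pts[:, 0])
        mid = np.isclose(pts[:, 0], cols[len(cols) // 2])
        exact = fx["exact_profile"](pts[mid, 1])
        err = np.max(np.abs(u[mid, 0] - exact)) / exact.max()
        assert err < 0.01

    def test_no_forcing_gives_rest(self):
        fx = generate_fixture(FixtureSpec(oracle="poiseuille_channel"))
        dirich = [(fx["walls"], 0, 0.0), (fx["walls"], 1, 0.0)]
        u, press, _ = solve_ns(fx["mesh"], FlowParams(), dirich,
                               pin_pressure=True)
        assert np.allclose(u, 0.0, atol=1e-12)
        assert np.allclose(press - press[0], 0.0, atol=1e-8)


class TestSteadyFlow:
    def test_mass_conservation(self, default_domain, default_mesh):
        u_s = saline_inlet_velocity(13.0, 1.32)
        fs = solve_steady_flow(default_mesh, FlowParams(), u_s,
                               domain=default_domain)
        assert fs.mass_balance_error <= 0.005

    def test_no_slip_on_solid_interfaces(self, default_domain, default_mesh):
        u_s = saline_inlet_velocity(13.0, 1.32)
        fs = solve_steady_flow(default_mesh, FlowParams(), u_s,
                               domain=default_domain)
        nodes = default_mesh.node_sets["tissue_blood_interface"]
        assert np.abs(fs.u[nodes]).max() < 1e-12

    def test_six_hole_much_faster_than_multi_hole(self):
        """At the same flow rate the six-hole jet is an order of magnitude
        faster near the band (smaller irrigation area)."""
        speeds = {}
        for design in ("six_hole", "multi_hole"):
            cfg = GeometryConfig(design=design)
            dom = build_domain(cfg)
            mesh = generate_mesh(dom)
            u_s = saline_inlet_velocity(
                13.0, irrigation_band_area(design, "perpendicular"))
            fs = solve_steady_flow(mesh, FlowParams(), u_s, domain=dom)
            speeds[design] = np.linalg.norm(fs.u, axis=1).max()
        assert speeds["six_hole"] > 3.0 * speeds["multi_hole"]

    def test_axisym_drops_lateral_stream_with_stamp(self, default_domain,
                                                    default_mesh):
        fs = solve_steady_flow(default_mesh, FlowParams(u_blood_in=0.1),
                               saline_inlet_velocity(13.0, 1.32),
                               domain=default_domain)
        assert "u_blood_in_dropped" in fs.metadata

    def test_reynolds_reported(self, default_domain, default_mesh):
        fs = solve_steady_flow(default_mesh, FlowParams(),
                               saline_inlet_velocity(13.0, 1.32),
                               domain=default_domain)
        # Re = rho u d / mu with the 8Fr diameter and the jet speed
        assert fs.reynolds == pytest.approx(
            1000.0 * 0.164 * (8.0 / 3.0 * 1e-3) / 2.1e-3, rel=0.01)

    def test_saline_flux_matches_flow_rate(self, default_domain,
                                           default_mesh):
        """Realized saline influx equals the nominal Q-derived flux."""
        u_s = saline_inlet_velocity(13.0, 1.32)
        fs = solve_steady_flow(default_mesh, FlowParams(), u_s,
                               domain=default_domain)
        assert fs.metadata["inflow_m3s"] == pytest.approx(
            fs.metadata["saline_flux_nominal"], rel=1e-9)

    def test_determinism(self, default_domain, default_mesh):
        u_s = saline_inlet_velocity(13.0, 1.32)
        f1 = solve_steady_flow(default_mesh, FlowParams(), u_s,
                               domain=default_domain)
        f2 = solve_steady_flow(default_mesh, FlowParams(), u_s,
                               domain=default_domain)
        np.testing.assert_array_equal(f1.u, f2.u)


class TestFlowParams:
    def test_body_force_fixed_to_zero(self):
        with pytest.raises(ValueError):
            FlowParams(body_force=1.0)
        with pytest.raises(ValueError):
            FlowParams(mu=0.0)
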