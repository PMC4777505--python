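"""Bioheat stepping: conduction oracle, lumped heating rates, the latent
plateau, sensor readout and stability properties."""

import numpy as np
import pytest

from rfablate.fem import Mesh
from rfablate.geometry import _grid_to_tris
from rfablate.io_config import FixtureSpec, generate_fixture
from rfablate.materials import PhaseChangeParams
from rfablate.thermal import (TemperatureField, ThermalBCs,
                              advance_temperature, initial_temperature,
                              sensor_temperature)


def _insulated_block(n=6, L=0.01):
    """Small all-tissue planar mesh with no Dirichlet sets (adiabatic)."""
    xx = np.linspace(0.0, L, n)
    X, Y = np.meshgrid(xx, xx, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    cells = _grid_to_tris(n, n)
    return Mesh(points=pts, cells=cells,
                cell_regions=np.zeros(len(cells), dtype=np.int64),
                region_names=["tissue"], mode="planar")


ADIABATIC = ThermalBCs(irrigation_active=False)


class TestConductionOracles:
    def test_equilibrium_is_preserved(self):
        mesh = _insulated_block()
        temp = TemperatureField(np.full(mesh.n_points, 37.0))
        out, rep = advance_temperature(mesh, temp, 0.05, bcs=ADIABATIC)
        np.testing.assert_allclose(out.T, 37.0, atol=1e-10)
        assert rep.balance_error < 1e-4

    def test_slab_series_solution(self):
        """Transient conduction in a slab with clamped ends matches the
        separation-of-variables series within 1%."""
        fx = generate_fixture(FixtureSpec(oracle="slab_conduction",
                                          resolution=60))
        mesh = fx["mesh"]
        mesh.node_sets["outer_walls"] = fx["end_nodes"]
        bc = ThermalBCs(outer_wall_T=fx["params"]["Ta"],
                        irrigation_active=False)
        temp = TemperatureField(np.full(mesh.n_points, fx["params"]["T0"]))
        dt, t_end = 0.05, 30.0
        for _ in range(int(t_end / dt)):
            temp, _ = advance_temperature(mesh, temp, dt, bcs=bc)
        x = mesh.points[:, 0]
        exact = fx["exact"](x, t_end)
        scale = fx["params"]["T0"] - fx["params"]["Ta"]
        L = fx["params"]["L"]
        interior = (x > 0.25 * L) & (x < 0.75 * L)
        assert np.max(np.abs(temp.T - exact)[interior]) / scale < 0.01

    def test_maximum_principle_source_free(self):
        """Pure conduction creates no new extrema."""
        mesh = _insulated_block(n=9)
        rng = np.random.default_rng(7)
        T0 = 37.0 + 10.0 * rng.random(mesh.n_points)
        temp = TemperatureField(T0.copy())
        for _ in range(20):
            temp, _ = advance_temperature(mesh, temp, 0.1, bcs=ADIABATIC)
            assert temp.T.max() <= T0.max() + 1e-9
            assert temp.T.min() >= T0.min() - 1e-9


class TestLumpedHeating:
    def test_heating_rate_below_latent_band(self):
        """Uniform source in an insulated block: dT/dt = q/(rho_l c_l)."""
        mesh = _insulated_block()
        pc = PhaseChangeParams()
        q = 5e6
        temp = TemperatureField(np.full(mesh.n_points, 50.0))
        dt = 0.5
        out, rep = advance_temperature(mesh, temp, dt, q_cells=q,
                                       bcs=ADIABATIC, pc=pc)
        rate = (out.T.mean() - 50.0) / dt
        assert rate == pytest.approx(q / (pc.rho_l * pc.c_l), rel=0.01)
        assert rep.balance_error < 0.02

    def test_latent_band_slowdown(self):
        """Crossing 99 degC the heating rate drops by H_fg C/(rho_l c_l)
        ~ 491."""
        mesh = _insulated_block()
        pc = PhaseChangeParams()
        q = 5e6
        below = TemperatureField(np.full(mesh.n_points, 95.0))
        out_b, _ = advance_temperature(mesh, below, 0.1, q_cells=q,
                                       bcs=ADIABATIC, pc=pc)
        rate_liquid = (out_b.T.mean() - 95.0) / 0.1

        inside = TemperatureField(np.full(mesh.n_points, 99.3))
        out_i, _ = advance_temperature(mesh, inside, 0.1, q_cells=q,
                                       bcs=ADIABATIC, pc=pc)
        rate_latent = (out_i.T.mean() - 99.3) / 0.1
        assert rate_liquid / rate_latent == pytest.approx(
            pc.slowdown_factor, rel=0.05)

    def test_energy_balance_identity_per_step(self, default_mesh):
        """On the real domain with walls held at 37 degC the per-step
        enthalpy bookkeeping closes within 2%."""
        temp = initial_temperature(default_mesh)
        q = np.where(default_mesh.region_mask("tissue"), 2e6, 0.0)
        for _ in range(3):
            temp, rep = advance_temperature(default_mesh, temp, 0.05,
                                            q_cells=q)
            assert rep.balance_error < 0.02


class TestTimestepRobustness:
    def test_halving_dt_changes_little(self, default_mesh):
        """Temporal resolution: halving dt from 0.05 to 0.025 s moves the
        short-horizon peak temperature by <0.5%."""
        q = np.where(default_mesh.region_mask("tissue"), 2e7, 0.0)
        finals = []
        for dt in (0.05, 0.025):
            temp = initial_temperature(default_mesh)
            for _ in range(int(2.0 / dt)):
                temp, _ = advance_temperature(default_mesh, temp, dt,
                                              q_cells=q)
            finals.append(temp.T.max())
        assert abs(finals[1] - finals[0]) / finals[0] < 0.005


class TestSensor:
    def test_uniform_field(self, default_mesh):
        t = TemperatureField(np.full(default_mesh.n_points, 37.0))
        assert sensor_temperature(default_mesh, t) == pytest.approx(37.0)

    def test_initial_tip_is_cold(self, default_mesh):
        t = initial_temperature(default_mesh)
        assert sensor_temperature(default_mesh, t) == pytest.approx(22.0)

    def test_linear_field_reads_centroid(self, default_mesh):
        """Volume averaging is exact for fields linear in z."""
        z = default_mesh.points[:, -1]
        t = TemperatureField(37.0 + 1000.0 * z)
        m = default_mesh.region_mask("thermistor")
        w = default_mesh.cell_weights[m]
        zc = (default_mesh.cell_centroids[m][:, -1] * w).sum() / w.sum()
        assert sensor_temperature(default_mesh, t) == pytest.approx(
            37.0 + 1000.0 * zc, rel=1e-6)


class TestIrrigationCooling:
    def test_band_cooling_lowers_blood_peak(self, run_35W_Q5, run_35W_Q20):
        """More irrigation keeps the blood pool cooler at fixed power."""
        assert (run_35W_Q20.T_max_blood.max()
                <= run_35W_Q5.T_max_blood.max() + 1e-9)

    def test_rejects_nonpositive_dt(self, default_mesh):
        temp = initial_temperature(default_mesh)
        with pytest.raises(ValueError):
            advance_temperature(default_mesh, temp, 0.0)
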