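"""Domain construction, irrigation-band areas, meshing and convergence."""

import numpy as np
import pytest

from rfablate.fem import facet_areas
from rfablate.geometry import (ConvergenceResult, GeometryConfig, MeshSpec,
                               build_domain, convergence_harness,
                               generate_mesh, irrigation_band_area)


class TestBandAreas:
    @pytest.mark.parametrize("design,orientation,area", [
        ("six_hole", "perpendicular", 1.32),
        ("six_hole", "parallel", 0.77),
        ("multi_hole", "perpendicular", 10.37),
        ("multi_hole", "parallel", 8.58),
    ])
    def test_canonical_lookup(self, design, orientation, area):
        assert irrigation_band_area(design, orientation) == area

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError):
            irrigation_band_area("no_hole", "perpendicular")


class TestGeometryConfig:
    def test_defaults(self):
        c = GeometryConfig()
        assert c.X == 80.0 and c.Y == 40.0 and c.Z_eff == 40.0
        assert c.H == 20.0
        assert c.electrode_diameter == pytest.approx(8.0 / 3.0)

    def test_axisymmetric_requires_perpendicular(self):
        with pytest.raises(ValueError):
            GeometryConfig(orientation="parallel", mode="axisymmetric")

    def test_six_hole_insertion_limit(self):
        """Beyond 1 mm the hole ring would submerge below the tissue."""
        with pytest.raises(ValueError):
            GeometryConfig(design="six_hole", insertion_depth=1.5)
        GeometryConfig(design="multi_hole", insertion_depth=1.5)  # allowed

    def test_insertion_must_be_less_than_length(self):
        with pytest.raises(ValueError):
            GeometryConfig(design="multi_hole", insertion_depth=3.5)


class TestMeshing:
    def test_determinism_bitwise(self, default_domain):
        m1 = generate_mesh(default_domain, MeshSpec())
        m2 = generate_mesh(default_domain, MeshSpec())
        np.testing.assert_array_equal(m1.points, m2.points)
        np.testing.assert_array_equal(m1.cells, m2.cells)

    def test_all_regions_present(self, default_mesh):
        present = set(np.unique(default_mesh.cell_regions))
        assert present == set(range(len(default_mesh.region_names)))

    def test_min_edge_size_at_interface(self, default_domain):
        spec = MeshSpec()
        mesh = generate_mesh(default_domain, spec)
        eti = mesh.facet_sets["electrode_tissue_interface"]
        p = mesh.points[eti]
        lengths = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        assert lengths.min() <= spec.min_size_at_interface * 1e-3 + 1e-12

    def test_region_volumes_match_cad(self, default_domain, default_mesh):
        vols = default_domain.analytic_volumes()
        for region in ("electrode", "thermistor"):
            meshed = default_mesh.region_volume(region)
            assert meshed == pytest.approx(vols[region], rel=0.01)

    def test_revolved_electrode_volume(self, default_domain, default_mesh):
        """Revolving the half-section reproduces the analytic
        cylinder-plus-hemisphere volume within 1%."""
        dom = default_domain
        re, L = dom.re, dom.L
        v_exact = (np.pi * re**2 * (L - re) + 2.0 / 3.0 * np.pi * re**3)
        v_mesh = (default_mesh.region_volume("electrode")
                  + default_mesh.region_volume("thermistor"))
        assert v_mesh == pytest.approx(v_exact, rel=0.01)

    @pytest.mark.parametrize("design,orientation", [
        ("six_hole", "perpendicular"),
        ("multi_hole", "perpendicular"),
        ("six_hole", "parallel"),
        ("multi_hole", "parallel"),
    ])
    def test_band_area_fidelity(self, design, orientation):
        """Meshed band area matches the canonical value within 5%
        (half-model convention)."""
        mode = "axisymmetric" if orientation == "perpendicular" else "full3d"
        cfg = GeometryConfig(design=design, orientation=orientation,
                             mode=mode)
        spec = (MeshSpec() if mode == "axisymmetric"
                else MeshSpec(min_size_at_interface=0.4, far_size=6.0))
        mesh = generate_mesh(build_domain(cfg), spec)
        band = mesh.facet_sets["irrigation_band"]
        area = facet_areas(mesh, band).sum() * 1e6
        if mode == "axisymmetric":
            area /= 2.0  # full revolution -> half-model convention
        assert area == pytest.approx(
            irrigation_band_area(design, orientation), rel=0.05)

    def test_insertion_depth_monotonicity(self):
        """Deeper insertion exposes more electrode-tissue contact area."""
        areas = []
        for de in (0.5, 1.0, 1.5):
            cfg = GeometryConfig(design="multi_hole", insertion_depth=de)
            mesh = generate_mesh(build_domain(cfg))
            eti = mesh.facet_sets["electrode_tissue_interface"]
            areas.append(facet_areas(mesh, eti).sum())
        assert areas[0] < areas[1] < areas[2]

    def test_refinement_increases_cell_count(self, default_domain):
        coarse = generate_mesh(default_domain, MeshSpec())
        fine = generate_mesh(default_domain,
                             MeshSpec(min_size_at_interface=0.1,
                                      far_size=2.0))
        assert fine.n_cells > coarse.n_cells

    def test_band_above_tissue(self, default_mesh):
        band = default_mesh.facet_sets["irrigation_band"]
        assert band.size
        assert default_mesh.points[band][..., -1].min() > 0


class TestConvergenceHarness:
    def test_single_candidate_not_converged(self):
        res = convergence_harness(lambda s: 100.0, [1])
        assert isinstance(res, ConvergenceResult)
        assert not res.converged and res.chosen is None

    def test_vacuous_tolerance_accepts_first(self):
        res = convergence_harness(lambda s: 100.0 / s, [1, 2, 3], rtol=1.0)
        assert res.converged and res.chosen == 1

    def test_analytic_surrogate_sequence(self):
        """On a value settling like T(s) = T_inf + c/s^2 the deltas shrink
        monotonically and the harness picks the first settled size."""
        sizes = (1, 2, 4, 8, 16, 32)
        values = {s: 90.0 + 40.0 / s**2 for s in sizes}
        res = convergence_harness(lambda s: values[s], list(sizes))
        assert all(d2 < d1 for d1, d2 in zip(res.deltas, res.deltas[1:]))
        assert res.converged
        assert res.chosen in (8, 16)
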