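"""50 degC-isotherm lesion extraction and metrics on synthetic fields."""

import numpy as np
import pytest

from rfablate.fem import Mesh
from rfablate.geometry import _grid_to_tris
from rfablate.io_config import FixtureSpec, generate_fixture
from rfablate.lesion import (characterize_lesion, extract_lesion_region,
                             lesion_dimensions, lesion_volume)


def _tissue_block_axisym(n=60, R=20e-3, H=20e-3):
    xx = np.linspace(0.0, R, n + 1)
    zz = np.linspace(-H, 0.0, n + 1)
    X, Z = np.meshgrid(xx, zz, indexing="ij")
    pts = np.stack([X.ravel(), Z.ravel()], axis=1)
    cells = _grid_to_tris(n + 1, n + 1)
    return Mesh(points=pts, cells=cells,
                cell_regions=np.zeros(len(cells), dtype=np.int64),
                region_names=["tissue"], mode="axisym")


def _tissue_block_3d(n=22, L=20e-3):
    xx = np.linspace(-L, L, 2 * n + 1)
    yy = np.linspace(0.0, L, n + 1)
    zz = np.linspace(-L, 0.0, n + 1)
    from rfablate.geometry import _grid_to_tets
    X, Y, Z = np.meshgrid(xx, yy, zz, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    cells = _grid_to_tets(len(xx), len(yy), len(zz))
    return Mesh(points=pts, cells=cells,
                cell_regions=np.zeros(len(cells), dtype=np.int64),
                region_names=["tissue"], mode="3d")


class TestExtraction:
    def test_uniform_body_temperature_gives_empty_region(self):
        mesh = _tissue_block_axisym(20)
        region = extract_lesion_region(mesh, np.full(mesh.n_points, 37.0))
        assert region.empty
        m = lesion_dimensions(region)
        assert (m.D, m.MW, m.DW, m.SW) == (0.0, 0.0, 0.0, 0.0)
        assert lesion_volume(region) == 0.0

    def test_uniformly_hot_tissue_is_entirely_lesioned(self):
        mesh = _tissue_block_axisym(16, R=5e-3, H=5e-3)
        region = extract_lesion_region(mesh, np.full(mesh.n_points, 60.0))
        assert region.node_mask.all()
        lv = lesion_volume(region)
        exact = np.pi * (5e-3) ** 2 * 5e-3 * 1e9   # full cylinder, mm^3
        assert lv == pytest.approx(exact, rel=0.01)

    def test_gaussian_isotherm_radius(self):
        """Synthetic hot spot: the extracted boundary sits on the analytic
        50 degC radius to sub-cell accuracy."""
        fx = generate_fixture(FixtureSpec(oracle="gaussian_lesion",
                                          resolution=60))
        mesh, T = fx["mesh"], fx["T"]
        region = extract_lesion_region(mesh, T)
        h = 20e-3 / 60
        rho = np.linalg.norm(region.points, axis=1)
        assert np.abs(rho.max() - fx["exact"]["r50"]) < h
        m = characterize_lesion(mesh, T)
        assert m.D == pytest.approx(fx["exact"]["D_mm"], abs=h * 1e3)
        assert m.MW == pytest.approx(fx["exact"]["MW_mm"], abs=2 * h * 1e3)
        assert m.LV == pytest.approx(fx["exact"]["LV_mm3"], rel=0.05)

    def test_satellite_nodes_are_discarded(self):
        """A disconnected hot node far from the main lesion does not
        inflate the metrics."""
        mesh = _tissue_block_axisym(40)
        rho = np.linalg.norm(mesh.points, axis=1)
        T = 37.0 + 40.0 * np.exp(-(rho / 4e-3) ** 2)
        far = np.argmin(np.abs(mesh.points[:, 0] - 15e-3)
                        + np.abs(mesh.points[:, 1] + 15e-3))
        T[far] = 55.0   # above threshold but cooler than the main lesion
        m = characterize_lesion(mesh, T)
        assert m.D < 10.0   # satellite at 15 mm depth is excluded


class TestDimensions:
    def test_half_ellipsoid(self):
        """Region (r/b)^2 + (z/a)^2 <= 1 with a = 4 mm, b = 5 mm:
        D = 4, MW = SW = 10, DW = 0, LV = (2/3) pi a b^2."""
        mesh = _tissue_block_axisym(80, R=12e-3, H=12e-3)
        r, z = mesh.points[:, 0], mesh.points[:, 1]
        a, b = 4e-3, 5e-3
        T = 50.0 + 10.0 * (1.0 - (r / b) ** 2 - (z / a) ** 2)
        m = characterize_lesion(mesh, T)
        assert m.D == pytest.approx(4.0, abs=0.1)
        assert m.MW == pytest.approx(10.0, abs=0.2)
        assert m.DW == pytest.approx(0.0, abs=0.2)
        assert m.SW == pytest.approx(10.0, abs=0.2)
        exact_lv = 2.0 / 3.0 * np.pi * (4.0) * (5.0) ** 2
        assert m.LV == pytest.approx(exact_lv, rel=0.02)

    def test_buried_sphere(self):
        """Sphere of radius 2 mm centred 3 mm deep: D = 5, MW = 4,
        DW = 3, SW = 0 (no surface contact)."""
        mesh = _tissue_block_axisym(80, R=10e-3, H=10e-3)
        r, z = mesh.points[:, 0], mesh.points[:, 1]
        c, rad = -3e-3, 2e-3
        T = 50.0 + 10.0 * (1.0 - (r**2 + (z - c) ** 2) / rad**2)
        m = characterize_lesion(mesh, T)
        assert m.D == pytest.approx(5.0, abs=0.1)
        assert m.MW == pytest.approx(4.0, abs=0.15)
        assert m.DW == pytest.approx(3.0, abs=0.2)
        assert m.SW == 0.0

    def test_translation_invariance_in_plane(self):
        """Shifting the hot spot along x leaves all metrics unchanged
        (half-symmetric 3D measurement)."""
        mesh = _tissue_block_3d()
        metrics = []
        for x0 in (0.0, 4e-3):
            d = np.sqrt((mesh.points[:, 0] - x0) ** 2
                        + mesh.points[:, 1] ** 2 + mesh.points[:, 2] ** 2)
            T = 37.0 + 40.0 * np.exp(-(d / 4e-3) ** 2)
            m = characterize_lesion(mesh, T)
            metrics.append(m)
        m0, m1 = metrics
        assert m1.D == pytest.approx(m0.D, abs=0.05)  # to grid resolution
        assert m1.MW == pytest.approx(m0.MW, rel=0.05)
        assert m1.SW == pytest.approx(m0.SW, rel=0.05)
        assert m1.LV == pytest.approx(m0.LV, rel=0.05)

    def test_monotonicity_under_hotter_field(self):
        mesh = _tissue_block_axisym(50)
        rho = np.linalg.norm(mesh.points, axis=1)
        T1 = 37.0 + 30.0 * np.exp(-(rho / 4e-3) ** 2)
        T2 = T1 + 5.0
        m1 = characterize_lesion(mesh, T1)
        m2 = characterize_lesion(mesh, T2)
        for attr in ("D", "MW", "SW", "LV"):
            assert getattr(m2, attr) >= getattr(m1, attr) - 1e-9


class TestVolume:
    def test_ellipsoid_formula_agrees_on_ellipsoidal_lesion(self):
        """Documentation-grade cross-check: direct integration and the
        half-ellipsoid formula agree within 25% on a near-ellipsoidal
        region."""
        mesh = _tissue_block_axisym(60, R=10e-3, H=10e-3)
        r, z = mesh.points[:, 0], mesh.points[:, 1]
        T = 50.0 + 10.0 * (1.0 - (r / 4e-3) ** 2 - (z / 3e-3) ** 2)
        region = extract_lesion_region(mesh, T)
        lv_int = lesion_volume(region, "integration")
        lv_ell = lesion_volume(region, "ellipsoid")
        assert lv_ell == pytest.approx(lv_int, rel=0.25)

    def test_volume_refinement_convergence(self):
        """LV error versus the analytic ball volume shrinks at least
        first-order under refinement."""
        fx_exact = None
        errs = []
        for n in (20, 40, 80):
            fx = generate_fixture(FixtureSpec(oracle="gaussian_lesion",
                                              resolution=n))
            lv = characterize_lesion(fx["mesh"], fx["T"]).LV
            errs.append(abs(lv - fx["exact"]["LV_mm3"]))
        assert errs[2] < errs[0] / 2.0

    def test_unknown_method_rejected(self):
        mesh = _tissue_block_axisym(10)
        region = extract_lesion_region(mesh,
                                       np.full(mesh.n_points, 60.0))
        with pytest.raises(ValueError):
            lesion_volume(region, "guess")
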