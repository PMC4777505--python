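"""Parametric model geometry and meshing.

The domain is a fragment of cardiac chamber (blood) over a myocardial slab,
with an open-irrigated catheter electrode (8Fr, 3.5 mm, hemispherical tip)
inserted a depth ``D_E`` into the tissue.  Two build modes exist:

* ``axisymmetric`` - the (r, z) half-section of the perpendicular
  configuration; cheap, used for fast studies and tests.  The lateral blood
  stream cannot be represented in this mode.
* ``full3d``       - the half-symmetric 3D box (symmetry plane y = 0),
  supporting both perpendicular and parallel electrode orientation.

Meshes are graded structured simplex meshes: tensor-product grid lines are
refined near the electrode-tissue interface and grow geometrically away
from it; nodes adjacent to the curved electrode surfaces are snapped onto
them so interface geometry is second-order accurate.  Key coordinates
(tissue surface, electrode extents, irrigation-band edges) are grid lines,
so the planar interfaces and the band are meshed exactly.

Units: configuration values are in clinician-facing millimetres; the
``DomainModel`` and all meshes are in metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fem import Mesh

__all__ = [
    "GeometryConfig", "MeshSpec", "DomainModel", "irrigation_band_area",
    "build_domain", "generate_mesh", "convergence_harness",
    "ConvergenceResult",
]

MM = 1e-3
#: 1 French = 1/3 mm diameter.
FR_MM = 1.0 / 3.0

_BAND_AREAS_MM2 = {
    ("six_hole", "perpendicular"): 1.32,
    ("six_hole", "parallel"): 0.77,
    ("multi_hole", "perpendicular"): 10.37,
    ("multi_hole", "parallel"): 8.58,
}


def irrigation_band_area(design: str, orientation: str) -> float:
    """Canonical irrigation inlet area in mm^2 (half-model convention).

    These are the areas through which the saline is taken to enter the
    blood pool: the 6-hole ring strip or the whole exposed electrode-blood
    surface for the multi-hole design.  They are the authoritative values
    used to convert a flow rate into an inlet speed, independent of mesh
    resolution.
    """
    try:
        return _BAND_AREAS_MM2[(design, orientation)]
    except KeyError:
        raise ValueError(
            f"unknown design/orientation combination ({design!r}, {orientation!r})"
        ) from None


class GeometryConfig(BaseModel):
    """Chamber, tissue and electrode geometry (millimetres).

    ``insertion_depth`` doubles as the contact-pressure surrogate
    (0.5-1.5 mm).  Six-hole designs reject insertions beyond 1 mm: the hole
    ring would submerge below the tissue surface.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    X: float = 80.0
    Y: float = 40.0
    Z: float | None = None          # defaults to Y
    H: float = 20.0
    electrode_diameter: float = 8.0 * FR_MM
    electrode_length: float = 3.5
    insertion_depth: float = Field(default=1.0, gt=0)
    orientation: Literal["perpendicular", "parallel"] = "perpendicular"
    design: Literal["six_hole", "multi_hole"] = "six_hole"
    mode: Literal["axisymmetric", "full3d"] = "axisymmetric"
    thermistor_radius: float = 0.3
    thermistor_length: float = 1.0
    thermistor_tip_gap: float = 0.3
    hole_ring_offset: float = 0.2   # band lower edge above hemisphere equator

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if min(self.X, self.Y, self.H, self.electrode_diameter,
               self.electrode_length) <= 0:
            raise ValueError("all geometric dimensions must be positive")
        if self.insertion_depth >= self.electrode_length:
            raise ValueError("insertion_depth must be smaller than electrode_length")
        if self.mode == "axisymmetric" and self.orientation != "perpendicular":
            raise ValueError(
                "axisymmetric mode supports only the perpendicular orientation")
        if self.design == "six_hole" and self.insertion_depth > 1.0:
            raise ValueError(
                "six-hole design: insertion beyond 1 mm submerges the hole ring")
        return self

    @property
    def Z_eff(self) -> float:
        return self.Y if self.Z is None else self.Z


class MeshSpec(BaseModel):
    """Discretization parameters.

    ``min_size_at_interface`` (mm) is the grid size in the finest zone, the
    electrode-tissue interface; element size grows geometrically with
    distance at rate ``growth_rate`` up to ``far_size``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    min_size_at_interface: float = Field(default=0.2, gt=0)
    growth_rate: float = Field(default=1.25, gt=1.0)
    far_size: float = Field(default=4.0, gt=0)
    order: int = 1

    @model_validator(mode="after")
    def _check(self) -> "MeshSpec":
        if self.order != 1:
            raise ValueError("only linear (order 1) elements are supported")
        if self.far_size < self.min_size_at_interface:
            raise ValueError("far_size must be >= min_size_at_interface")
        return self


REGIONS = ["electrode", "thermistor", "catheter", "blood", "tissue"]

SURFACE_TAGS = [
    "symmetry_plane", "dispersive_ground", "outer_walls", "blood_inlet_face",
    "blood_outlet_face", "irrigation_band", "tissue_blood_interface",
    "electrode_blood_interface", "electrode_tissue_interface",
]


@dataclass
class DomainModel:
    """Resolved geometry (metres) with region predicates and CAD volumes."""

    config: GeometryConfig
    # derived SI quantities
    re: float = field(init=False)       # electrode radius
    L: float = field(init=False)        # electrode length (incl. tip cap)
    DE: float = field(init=False)       # insertion depth
    H: float = field(init=False)
    band_z: tuple[float, float] | None = field(init=False, default=None)
    band_x: tuple[float, float] | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        c = self.config
        self.re = 0.5 * c.electrode_diameter * MM
        self.L = c.electrode_length * MM
        self.DE = c.insertion_depth * MM
        self.H = c.H * MM
        if c.orientation == "perpendicular":
            self.zc = -self.DE + self.re        # hemisphere centre height
            self.z_top = -self.DE + self.L      # electrode/catheter junction
            if c.design == "six_hole":
                # annular strip whose revolved area equals the canonical
                # (full-ring) value; canonical lookup is the half-model area
                full = 2.0 * irrigation_band_area(c.design, c.orientation) * MM**2
                dh = full / (2.0 * np.pi * self.re)
                zb0 = self.zc + c.hole_ring_offset * MM
                self.band_z = (zb0, zb0 + dh)
                if zb0 <= 0:
                    raise ValueError("irrigation band must lie above the tissue")
        else:
            # electrode axis along x, lying on/in the tissue
            self.zA = self.re - self.DE
            self.x_tip = -0.5 * self.L          # centre of the tip sphere - re
            self.xc = self.x_tip + self.re      # tip sphere centre (x)
            self.x_top = self.x_tip + self.L    # electrode/catheter junction
            if c.design == "six_hole":
                # ring strip at fixed x; width chosen so the exposed
                # (above-tissue) area matches the canonical value
                full = 2.0 * irrigation_band_area(c.design, c.orientation) * MM**2
                frac = self._exposed_ring_fraction()
                dh = full / (2.0 * np.pi * self.re * frac)
                x0 = self.xc + c.hole_ring_offset * MM
                self.band_x = (x0, x0 + dh)

    # -- parallel-mode helper -------------------------------------------
    def _exposed_ring_fraction(self) -> float:
        """Fraction of the lateral ring circumference above z = 0.

        Ring points sit at z = zA + re*cos(theta); the exposed arc is
        cos(theta) > -zA/re, i.e. theta in (-theta*, theta*) with
        theta* = arccos(-zA/re).
        """
        x = min(1.0, max(-1.0, -self.zA / self.re))
        return math.acos(x) / math.pi

    # -- region predicates (points in metres) ---------------------------
    def classify(self, pts: np.ndarray) -> np.ndarray:
        """Region code (index into REGIONS) for each point."""
        pts = np.atleast_2d(pts)
        c = self.config
        if pts.shape[1] == 2:
            r = pts[:, 0]
            z = pts[:, 1]
            in_elec = self._in_electrode_rz(r, z)
            in_th = self._in_thermistor_rz(r, z)
            in_cath = (r <= self.re) & (z > self.z_top)
        else:
            x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
            if c.orientation == "perpendicular":
                r = np.hypot(x, y)
                in_elec = self._in_electrode_rz(r, z)
                in_th = self._in_thermistor_rz(r, z)
                in_cath = (r <= self.re) & (z > self.z_top)
            else:
                rho = np.hypot(y, z - self.zA)
                in_cyl = (rho <= self.re) & (x >= self.xc) & (x <= self.x_top)
                in_tip = (np.sqrt((x - self.xc) ** 2 + y**2
                                  + (z - self.zA) ** 2) <= self.re) & (x < self.xc)
                in_elec = in_cyl | in_tip
                in_th = self._in_thermistor_parallel(x, y, z)
                in_cath = (rho <= self.re) & (x > self.x_top)
        out = np.where(z <= 0, REGIONS.index("tissue"), REGIONS.index("blood"))
        out = np.where(in_cath, REGIONS.index("catheter"), out)
        out = np.where(in_elec, REGIONS.index("electrode"), out)
        out = np.where(in_th, REGIONS.index("thermistor"), out)
        return out

    def _in_electrode_rz(self, r, z):
        cyl = (r <= self.re) & (z >= self.zc) & (z <= self.z_top)
        tip = (np.sqrt(r**2 + (z - self.zc) ** 2) <= self.re) & (z < self.zc)
        return cyl | tip

    def _in_thermistor_rz(self, r, z):
        c = self.config
        z0 = -self.DE + c.thermistor_tip_gap * MM
        z1 = z0 + c.thermistor_length * MM
        return (r <= c.thermistor_radius * MM) & (z >= z0) & (z <= z1)

    def _in_thermistor_parallel(self, x, y, z):
        c = self.config
        x0 = self.x_tip + c.thermistor_tip_gap * MM
        x1 = x0 + c.thermistor_length * MM
        rho = np.hypot(y, z - self.zA)
        return (rho <= c.thermistor_radius * MM) & (x >= x0) & (x <= x1)

    # -- analytic (CAD) volumes -----------------------------------------
    def analytic_volumes(self) -> dict[str, float]:
        """Closed-form region volumes (m^3), full-revolution / half-model
        convention matching the mesh integration mode."""
        c = self.config
        re, L = self.re, self.L
        v_elec_full = math.pi * re**2 * (L - re) + (2.0 / 3.0) * math.pi * re**3
        v_th = math.pi * (c.thermistor_radius * MM) ** 2 * c.thermistor_length * MM
        vols = {"electrode": v_elec_full - v_th, "thermistor": v_th}
        if self.config.mode == "full3d":
            vols = {k: v / 2.0 for k, v in vols.items()}
        return vols

    # -- band predicate on facet centroids ------------------------------
    def on_band(self, centroids: np.ndarray) -> np.ndarray:
        c = self.config
        pts = np.atleast_2d(centroids)
        z = pts[:, -1]
        if c.design == "multi_hole":
            return z > 0
        if c.orientation == "perpendicular":
            zb0, zb1 = self.band_z
            tol = 1e-9
            return (z >= zb0 - tol) & (z <= zb1 + tol)
        xb0, xb1 = self.band_x
        x = pts[:, 0]
        return (x >= xb0 - 1e-9) & (x <= xb1 + 1e-9) & (z > 0)


def build_domain(config: GeometryConfig) -> DomainModel:
    """Resolve a :class:`GeometryConfig` into a tagged parametric domain."""
    return DomainModel(config)


# ---------------------------------------------------------------------------
# graded 1D point distributions
# ---------------------------------------------------------------------------

def _size_at(d: float, h_min: float, h_far: float, growth: float) -> float:
    """Target spacing at distance d from the fine zone."""
    return min(h_far, h_min + (growth - 1.0) * d)


def _fill_interval(x0: float, x1: float, hfun: Callable[[float], float]) -> np.ndarray:
    """Points on [x0, x1] stepping with the local size, rescaled to fit."""
    length = x1 - x0
    if length <= 1e-15:
        return np.array([x0, x1])
    # step from the end with the smaller target size outward
    h0, h1 = hfun(x0), hfun(x1)
    forward = h0 <= h1
    a, b = (x0, x1) if forward else (x1, x0)
    sgn = 1.0 if forward else -1.0
    pts = [a]
    guard = 0
    while (b - pts[-1]) * sgn > 1e-15:
        step = max(hfun(pts[-1]), 1e-9)
        pts.append(pts[-1] + sgn * step)
        guard += 1
        if guard > 200000:
            raise RuntimeError("mesh grading failed to terminate")
    arr = np.asarray(pts)
    arr = a + (arr - a) * (b - a) / (arr[-1] - a)
    arr = arr if forward else arr[::-1]
    return arr


def _graded_axis(keys: Sequence[float], fine: tuple[float, float],
                 h_min: float, h_far: float, growth: float) -> np.ndarray:
    """Monotone axis coordinates through all ``keys``, fine inside ``fine``."""
    keys = np.unique(np.asarray(keys, dtype=float))
    f0, f1 = fine

    def dist(x: float) -> float:
        if x < f0:
            return f0 - x
        if x > f1:
            return x - f1
        return 0.0

    def hfun(x: float) -> float:
        return _size_at(dist(x), h_min, h_far, growth)

    out = [np.array([keys[0]])]
    for a, b in zip(keys[:-1], keys[1:]):
        out.append(_fill_interval(a, b, hfun)[1:])
    coords = np.concatenate(out)
    # drop near-duplicate coordinates introduced by tightly spaced keys
    keep = np.concatenate([[True], np.diff(coords) > 1e-7 * max(1.0, h_min)])
    return coords[keep]


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def _snap_rz(points: np.ndarray, dom: DomainModel, tol: float) -> np.ndarray:
    """Project nodes near the hemisphere arc onto it (axisym section)."""
    p = points.copy()
    centre = np.array([0.0, dom.zc])
    d = np.linalg.norm(p - centre, axis=1)
    near = (np.abs(d - dom.re) < tol) & (p[:, 1] < dom.zc) & (d > 1e-12)
    p[near] = centre + (p[near] - centre) * (dom.re / d[near])[:, None]
    return p


def _snap_3d(points: np.ndarray, dom: DomainModel, tol: float) -> np.ndarray:
    """Project nodes near the curved electrode surfaces onto them (3D)."""
    p = points.copy()
    c = dom.config
    if c.orientation == "perpendicular":
        # tip sphere (z < zc)
        centre = np.array([0.0, 0.0, dom.zc])
        d = np.linalg.norm(p - centre, axis=1)
        near = (np.abs(d - dom.re) < tol) & (p[:, 2] < dom.zc) & (d > 1e-12)
        p[near] = centre + (p[near] - centre) * (dom.re / d[near])[:, None]
        # lateral cylinder (zc <= z): snap radially in (x, y)
        r = np.hypot(p[:, 0], p[:, 1])
        near = (np.abs(r - dom.re) < tol) & (p[:, 2] >= dom.zc) & (r > 1e-12)
        scale = dom.re / r[near]
        p[near, 0] *= scale
        p[near, 1] *= scale
    else:
        centre = np.array([dom.xc, 0.0, dom.zA])
        d = np.linalg.norm(p - centre, axis=1)
        near = (np.abs(d - dom.re) < tol) & (p[:, 0] < dom.xc) & (d > 1e-12)
        p[near] = centre + (p[near] - centre) * (dom.re / d[near])[:, None]
        rho = np.hypot(p[:, 1], p[:, 2] - dom.zA)
        near = (np.abs(rho - dom.re) < tol) & (p[:, 0] >= dom.xc) & (rho > 1e-12)
        scale = dom.re / rho[near]
        p[near, 1] *= scale
        p[near, 2] = dom.zA + (p[near, 2] - dom.zA) * scale
    return p


def _revert_bad_snaps(pts: np.ndarray, pts0: np.ndarray,
                      cells: np.ndarray) -> np.ndarray:
    """Undo surface snapping for nodes whose cells degenerated.

    Snapping projects nodes onto curved surfaces; on coarse grids this can
    collapse or invert a cell.  Reverting the offending nodes to their
    structured-grid positions restores a valid (if locally stair-cased)
    mesh.  Deterministic fixed-point loop, at most 5 sweeps.
    """
    for _ in range(5):
        vols = np.linalg.det(pts[cells[:, 1:]] - pts[cells[:, :1]])
        ref = np.abs(np.linalg.det(pts0[cells[:, 1:]] - pts0[cells[:, :1]]))
        bad = np.abs(vols) < 1e-3 * ref
        if not bad.any():
            return pts
        nodes = np.unique(cells[bad])
        moved = nodes[np.any(pts[nodes] != pts0[nodes], axis=1)]
        if len(moved) == 0:
            return pts
        pts = pts.copy()
        pts[moved] = pts0[moved]
    return pts


def _grid_to_tris(nr: int, nz: int) -> np.ndarray:
    """Split an (nr x nz) structured quad grid into triangles
    (alternating diagonals for isotropy)."""
    idx = np.arange(nr * nz).reshape(nr, nz)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    ii, jj = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1), indexing="ij")
    alt = ((ii + jj) % 2 == 0).ravel()
    t1 = np.where(alt[:, None], np.stack([v00, v10, v11], 1),
                  np.stack([v00, v10, v01], 1))
    t2 = np.where(alt[:, None], np.stack([v00, v11, v01], 1),
                  np.stack([v10, v11, v01], 1))
    return np.vstack([t1, t2])


_HEX_TETS = [(0, 1, 3, 7), (0, 2, 3, 7), (0, 1, 5, 7),
             (0, 4, 5, 7), (0, 2, 6, 7), (0, 4, 6, 7)]


def _grid_to_tets(nx: int, ny: int, nz: int) -> np.ndarray:
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    c = np.empty((nx - 1, ny - 1, nz - 1, 8), dtype=np.int64)
    corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
               (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    for k, (dx, dy, dz) in enumerate(corners):
        c[..., k] = idx[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz]
    c = c.reshape(-1, 8)
    tets = np.concatenate([c[:, t] for t in _HEX_TETS], axis=0)
    return tets


def _boundary_facets(cells: np.ndarray):
    """Unique facets of a simplex mesh with owner-cell bookkeeping.

    Returns ``(uniq, counts, inv, owners)`` where ``uniq`` is the unique
    sorted-facet array, ``counts`` how many cells share each, ``inv`` maps
    each stacked (cell, local-face) entry to its unique facet, and
    ``owners`` the cell index of each stacked entry.
    """
    d1 = cells.shape[1]
    faces = []
    owners = []
    for i in range(d1):
        f = np.delete(cells, i, axis=1)
        faces.append(np.sort(f, axis=1))
        owners.append(np.arange(cells.shape[0]))
    faces = np.vstack(faces)
    owners = np.concatenate(owners)
    uniq, inv, counts = np.unique(faces, axis=0, return_inverse=True,
                                  return_counts=True)
    return uniq, counts, inv, owners


class MeshGenerationError(RuntimeError):
    """Raised when mesh construction produces an invalid discretization."""


def generate_mesh(domain: DomainModel, spec: MeshSpec | None = None) -> Mesh:
    """Generate a tagged simplex mesh of the domain.

    Deterministic: identical domain/spec always yields bitwise-identical
    node coordinates.
    """
    spec = spec or MeshSpec()
    c = domain.config
    h_min = spec.min_size_at_interface * MM
    h_far = spec.far_size * MM
    g = spec.growth_rate

    if c.mode == "axisymmetric":
        mesh = _mesh_axisym(domain, h_min, h_far, g)
    else:
        mesh = _mesh_3d(domain, h_min, h_far, g)
    _validate_mesh(mesh)
    return mesh


def _validate_mesh(mesh: Mesh) -> None:
    try:
        vols = mesh.cell_volumes
    except ValueError as exc:
        raise MeshGenerationError(str(exc)) from exc
    if np.any(vols <= 0):
        raise MeshGenerationError("degenerate cells after snapping")
    present = set(np.unique(mesh.cell_regions).tolist())
    missing = [r for i, r in enumerate(mesh.region_names) if i not in present]
    if missing:
        raise MeshGenerationError(f"regions without any element: {missing}")


def _mesh_axisym(dom: DomainModel, h_min: float, h_far: float,
                 g: float) -> Mesh:
    c = dom.config
    R = c.Y * MM
    Ztop = c.Z_eff * MM
    H = dom.H
    rt = c.thermistor_radius * MM
    z_th0 = -dom.DE + c.thermistor_tip_gap * MM
    z_th1 = z_th0 + c.thermistor_length * MM

    r_keys = [0.0, rt, dom.re, R]
    z_keys = [-H, -dom.DE, z_th0, z_th1, dom.zc, 0.0, dom.z_top, Ztop]
    if dom.band_z is not None:
        z_keys += list(dom.band_z)
    rr = _graded_axis(r_keys, (0.0, dom.re + 2 * h_min), h_min, h_far, g)
    zz = _graded_axis(z_keys, (-dom.DE - 2 * h_min, dom.z_top + 2 * h_min),
                      h_min, h_far, g)
    Rg, Zg = np.meshgrid(rr, zz, indexing="ij")
    pts0 = np.stack([Rg.ravel(), Zg.ravel()], axis=1)
    pts = _snap_rz(pts0, dom, min(0.45 * h_min, 0.3 * dom.re))
    cells = _grid_to_tris(len(rr), len(zz))
    pts = _revert_bad_snaps(pts, pts0, cells)
    return _finalize(dom, pts, cells, mode="axisym")


def _mesh_3d(dom: DomainModel, h_min: float, h_far: float, g: float) -> Mesh:
    c = dom.config
    X2 = 0.5 * c.X * MM
    Y = c.Y * MM
    Ztop = c.Z_eff * MM
    H = dom.H

    rt = c.thermistor_radius * MM
    if c.orientation == "perpendicular":
        z_th0 = -dom.DE + c.thermistor_tip_gap * MM
        z_th1 = z_th0 + c.thermistor_length * MM
        x_keys = [-X2, -dom.re, -rt, 0.0, rt, dom.re, X2]
        y_keys = [0.0, rt, dom.re, Y]
        z_keys = [-H, -dom.DE, z_th0, z_th1, dom.zc, 0.0, dom.z_top, Ztop]
        if dom.band_z is not None:
            z_keys += list(dom.band_z)
        fine_x = (-dom.re - 2 * h_min, dom.re + 2 * h_min)
        fine_y = (0.0, dom.re + 2 * h_min)
        fine_z = (-dom.DE - 2 * h_min, dom.z_top + 2 * h_min)
    else:
        x_th0 = dom.x_tip + c.thermistor_tip_gap * MM
        x_th1 = x_th0 + c.thermistor_length * MM
        x_keys = [-X2, dom.x_tip, dom.xc, x_th0, x_th1, dom.x_top, X2]
        if dom.band_x is not None:
            x_keys += list(dom.band_x)
        y_keys = [0.0, rt, dom.re, Y]
        z_keys = [-H, -dom.DE, dom.zA - rt, dom.zA, dom.zA + rt, 0.0,
                  dom.zA + dom.re, Ztop]
        fine_x = (dom.x_tip - 2 * h_min, dom.x_top + 2 * h_min)
        fine_y = (0.0, dom.re + 2 * h_min)
        fine_z = (-dom.DE - 2 * h_min, dom.zA + dom.re + 2 * h_min)

    xx = _graded_axis(x_keys, fine_x, h_min, h_far, g)
    yy = _graded_axis(y_keys, fine_y, h_min, h_far, g)
    zz = _graded_axis(z_keys, fine_z, h_min, h_far, g)
    Xg, Yg, Zg = np.meshgrid(xx, yy, zz, indexing="ij")
    pts0 = np.stack([Xg.ravel(), Yg.ravel(), Zg.ravel()], axis=1)
    # cap the snap distance: on very coarse grids an aggressive projection
    # onto the curved electrode surfaces would collapse or invert cells
    pts = _snap_3d(pts0, dom, min(0.45 * h_min, 0.25 * dom.re))
    cells = _grid_to_tets(len(xx), len(yy), len(zz))
    pts = _revert_bad_snaps(pts, pts0, cells)
    return _finalize(dom, pts, cells, mode="3d")


def _finalize(dom: DomainModel, pts: np.ndarray, cells: np.ndarray,
              mode: str) -> Mesh:
    c = dom.config
    centroids = pts[cells].mean(axis=1)
    regions = dom.classify(centroids)
    mesh = Mesh(points=pts, cells=cells, cell_regions=regions,
                region_names=list(REGIONS), mode=mode)

    # facet bookkeeping
    uniq, counts, inv, owners = _boundary_facets(cells)
    order = np.argsort(inv, kind="stable")
    owners_sorted = owners[order]
    starts = np.concatenate([[0], np.cumsum(counts)])

    boundary = uniq[counts == 1]
    fc_b = pts[boundary].mean(axis=1)

    eps = 1e-9
    H = dom.H
    sets: dict[str, list] = {k: [] for k in SURFACE_TAGS}

    if mode == "axisym":
        R = c.Y * MM
        Ztop = c.Z_eff * MM
        ground = np.abs(fc_b[:, 1] + H) < eps
        outer = (np.abs(fc_b[:, 0] - R) < eps) | (np.abs(fc_b[:, 1] - Ztop) < eps)
        sets["dispersive_ground"] = boundary[ground]
        sets["outer_walls"] = boundary[outer]
        sets["symmetry_plane"] = boundary[np.abs(fc_b[:, 0]) < eps]
    else:
        X2 = 0.5 * c.X * MM
        Y = c.Y * MM
        Ztop = c.Z_eff * MM
        ground = np.abs(fc_b[:, 2] + H) < eps
        left = np.abs(fc_b[:, 0] + X2) < eps
        right = np.abs(fc_b[:, 0] - X2) < eps
        blood_side = fc_b[:, 2] > 0
        sets["dispersive_ground"] = boundary[ground]
        sets["blood_inlet_face"] = boundary[left & blood_side]
        sets["blood_outlet_face"] = boundary[right & blood_side]
        sets["symmetry_plane"] = boundary[np.abs(fc_b[:, 1]) < eps]
        outer = ((np.abs(fc_b[:, 1] - Y) < eps)
                 | (np.abs(fc_b[:, 2] - Ztop) < eps)
                 | (left & ~blood_side) | (right & ~blood_side))
        sets["outer_walls"] = boundary[outer]

    # interfaces between regions
    int_ids = np.flatnonzero(counts == 2)
    own_a = owners_sorted[starts[int_ids]]
    own_b = owners_sorted[starts[int_ids] + 1]
    pr = np.sort(np.stack([regions[own_a], regions[own_b]], axis=1), axis=1)
    facets_int = uniq[int_ids]

    def _iface(a: str, b: str) -> np.ndarray:
        ia, ib = sorted((REGIONS.index(a), REGIONS.index(b)))
        m = (pr[:, 0] == ia) & (pr[:, 1] == ib)
        return facets_int[m]

    sets["electrode_blood_interface"] = _iface("electrode", "blood")
    sets["electrode_tissue_interface"] = _iface("electrode", "tissue")
    sets["tissue_blood_interface"] = _iface("tissue", "blood")
    sets["catheter_blood_interface"] = _iface("catheter", "blood")

    eb = sets["electrode_blood_interface"]
    if len(eb):
        fc = pts[eb].mean(axis=1)
        sets["irrigation_band"] = eb[dom.on_band(fc)]
    else:
        sets["irrigation_band"] = np.empty((0, pts.shape[1]), dtype=np.int64)

    mesh.facet_sets = {k: np.asarray(v, dtype=np.int64).reshape(-1, pts.shape[1])
                       for k, v in sets.items()}
    for name, fac in mesh.facet_sets.items():
        mesh.node_sets[name] = np.unique(fac) if fac.size else np.empty(0, np.int64)
    # convenience: all nodes on the metallic electrode surface
    mesh.node_sets["electrode_surface"] = np.unique(np.concatenate([
        mesh.node_sets["electrode_blood_interface"],
        mesh.node_sets["electrode_tissue_interface"]]))
    return mesh


# ---------------------------------------------------------------------------
# convergence harness
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    converged: bool
    chosen: object | None
    sweep: list[tuple[object, float]]
    deltas: list[float]


def convergence_harness(evaluate: Callable[[object], float],
                        candidates: Sequence,
                        rtol: float = 0.005) -> ConvergenceResult:
    """Sweep a discretization parameter until the control quantity settles.

    ``evaluate`` maps a candidate parameter (chamber size, grid size, time
    step) to the control value -- canonically the maximum tissue temperature
    after 60 s of heating.  The first candidate whose successor changes the
    control by less than ``rtol`` (relative) is accepted.  With fewer than
    two candidates, or if no pair meets the tolerance, a non-converged
    result is returned rather than an exception.
    """
    sweep = [(cand, float(evaluate(cand))) for cand in candidates]
    deltas = []
    chosen = None
    for (c0, v0), (c1, v1) in zip(sweep[:-1], sweep[1:]):
        rel = abs(v1 - v0) / max(abs(v0), 1e-300)
        deltas.append(rel)
        if chosen is None and rel < rtol:
            chosen = c0
    return ConvergenceResult(converged=chosen is not None, chosen=chosen,
                             sweep=sweep, deltas=deltas)
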