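"""Linear (P1) simplex finite-element core.

A deliberately small FEM kernel shared by the electrical, thermal and flow
solvers: simplex meshes (triangles or tetrahedra) with region and boundary
tags, vectorized gradient/volume precomputation, and assembly of the
standard operators (diffusion, lumped mass, advection with streamline
diffusion).  Three integration modes are supported:

* ``planar``  - 2D Cartesian, unit thickness,
* ``axisym``  - 2D in (r, z) with the 2*pi*r revolution Jacobian,
* ``3d``      - 3D Cartesian.

Axisymmetric weights use the element-centroid radius, which is first-order
consistent and keeps the axis (r = 0) regular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["Mesh", "assemble_stiffness", "assemble_lumped_mass",
           "assemble_advection", "apply_dirichlet", "facet_areas",
           "facet_normals"]


@dataclass
class Mesh:
    """Simplex mesh with region tags and named facet/node sets.

    Attributes
    ----------
    points:
        (n_points, dim) coordinates, metres.
    cells:
        (n_cells, dim+1) vertex indices.
    cell_regions:
        (n_cells,) integer codes into ``region_names``.
    region_names:
        Ordered region labels; ``cell_regions[i]`` indexes this list.
    mode:
        ``planar`` | ``axisym`` | ``3d``.
    facet_sets:
        name -> (n_facets, dim) vertex-index array (boundary or interface
        facets).
    node_sets:
        name -> sorted unique node indices (derived from facet sets or
        set directly).
    """

    points: np.ndarray
    cells: np.ndarray
    cell_regions: np.ndarray
    region_names: list[str]
    mode: str = "planar"
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("planar", "axisym", "3d"):
            raise ValueError(f"unknown mesh mode {self.mode!r}")
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self._geom = None

    # ---- geometry ------------------------------------------------------
    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def _geometry(self):
        """Precompute (volumes, basis gradients, weights, centroids, h)."""
        if self._geom is not None:
            return self._geom
        d = self.dim
        pts = self.points[self.cells]                       # (nc, d+1, d)
        edges = pts[:, 1:, :] - pts[:, :1, :]               # (nc, d, d)
        det = np.linalg.det(edges)
        vol = np.abs(det) / math.factorial(d)
        if np.any(vol <= 0):
            raise ValueError("degenerate (zero-volume) cell in mesh")
        inv = np.linalg.inv(edges)                          # (nc, d, d)
        grads = np.empty((self.n_cells, d + 1, d))
        grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        centroids = pts.mean(axis=1)
        if self.mode == "axisym":
            weights = vol * 2.0 * np.pi * centroids[:, 0]
        else:
            weights = vol.copy()
        # characteristic cell size: longest edge
        n_vert = d + 1
        hmax = np.zeros(self.n_cells)
        for i in range(n_vert):
            for j in range(i + 1, n_vert):
                e = np.linalg.norm(pts[:, i, :] - pts[:, j, :], axis=1)
                np.maximum(hmax, e, out=hmax)
        self._geom = (vol, grads, weights, centroids, hmax)
        return self._geom

    @property
    def cell_volumes(self) -> np.ndarray:
        """Geometric simplex volumes (areas in 2D), without mode weight."""
        return self._geometry()[0]

    @property
    def cell_weights(self) -> np.ndarray:
        """Integration weights including the axisymmetric Jacobian."""
        return self._geometry()[2]

    @property
    def cell_grads(self) -> np.ndarray:
        return self._geometry()[1]

    @property
    def cell_centroids(self) -> np.ndarray:
        return self._geometry()[3]

    @property
    def cell_sizes(self) -> np.ndarray:
        return self._geometry()[4]

    def region_mask(self, *names: str) -> np.ndarray:
        """Cell mask of the named regions (absent names match nothing)."""
        codes = [self.region_names.index(n) for n in names
                 if n in self.region_names]
        return np.isin(self.cell_regions, codes)

    def region_volume(self, *names: str) -> float:
        """Integrated volume of the named regions (mode-weighted)."""
        return float(self.cell_weights[self.region_mask(*names)].sum())

    def nodes_of(self, *set_names: str) -> np.ndarray:
        """Union of the named node sets."""
        idx = [self.node_sets[n] for n in set_names if len(self.node_sets.get(n, ()))]
        if not idx:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(idx))

    def interpolate_to_cells(self, nodal: np.ndarray) -> np.ndarray:
        """Vertex average of a nodal field per cell (midpoint value)."""
        return np.asarray(nodal)[self.cells].mean(axis=1)


# ---- assembly ----------------------------------------------------------

def _accumulate(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Scatter (nc, d+1, d+1) local matrices into a global CSR matrix."""
    n_vert = mesh.cells.shape[1]
    rows = np.repeat(mesh.cells, n_vert, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, n_vert)).ravel()
    A = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_points, mesh.n_points))
    return A.tocsr()


def assemble_stiffness(mesh: Mesh, coeff) -> sp.csr_matrix:
    """Diffusion operator  K[i,j] = sum_c w_c a_c  grad(phi_i).grad(phi_j).

    ``coeff`` is a per-cell array (or scalar) of the diffusivity.
    """
    a = np.broadcast_to(np.asarray(coeff, dtype=float), (mesh.n_cells,))
    G = mesh.cell_grads
    local = np.einsum("c,cid,cjd->cij", a * mesh.cell_weights, G, G)
    return _accumulate(mesh, local)


def assemble_lumped_mass(mesh: Mesh, coeff) -> np.ndarray:
    """Row-sum-lumped mass 'matrix' as a nodal vector, sum_c w_c c_c / (d+1)."""
    c = np.broadcast_to(np.asarray(coeff, dtype=float), (mesh.n_cells,))
    share = c * mesh.cell_weights / mesh.cells.shape[1]
    out = np.zeros(mesh.n_points)
    np.add.at(out, mesh.cells.ravel(), np.repeat(share, mesh.cells.shape[1]))
    return out


def assemble_advection(mesh: Mesh, u_cells: np.ndarray, coeff,
                       diffusivity=None) -> sp.csr_matrix:
    """Advection operator  A[i,j] = sum_c w_c c_c phi_i (u . grad phi_j)
    with optional streamline (SUPG-type) stabilization.

    ``u_cells`` is (n_cells, dim); cells with zero velocity contribute
    nothing.  When ``diffusivity`` (per-cell kappa = k/(rho c)) is given,
    the stabilization parameter uses the standard Peclet switch
    tau = h/(2|u|) * min(Pe/3, 1); otherwise the pure-advection limit
    tau = h/(2|u|) is used.
    """
    c = np.broadcast_to(np.asarray(coeff, dtype=float), (mesh.n_cells,))
    G = mesh.cell_grads
    udotG = np.einsum("cd,cjd->cj", u_cells, G)            # (nc, d+1)
    n_vert = mesh.cells.shape[1]
    w = c * mesh.cell_weights
    local = (w / n_vert)[:, None, None] * udotG[:, None, :].repeat(n_vert, axis=1)

    speed = np.linalg.norm(u_cells, axis=1)
    active = speed > 0
    if np.any(active):
        h = mesh.cell_sizes
        tau = np.zeros(mesh.n_cells)
        if diffusivity is not None:
            kappa = np.broadcast_to(np.asarray(diffusivity, float),
                                    (mesh.n_cells,))
            pe = np.divide(speed * h, 2.0 * kappa,
                           out=np.full(mesh.n_cells, np.inf),
                           where=kappa > 0)
            xi = np.minimum(pe / 3.0, 1.0)
        else:
            xi = 1.0
        tau[active] = h[active] / (2.0 * speed[active]) * (
            xi[active] if np.ndim(xi) else xi)
        local += np.einsum("c,ci,cj->cij", tau * w, udotG, udotG)
    return _accumulate(mesh, local)


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray,
                    nodes: np.ndarray, values) -> tuple[sp.csr_matrix, np.ndarray]:
    """Impose ``x[nodes] = values`` by symmetric elimination.

    Returns modified copies of (A, b).  Column contributions are moved to
    the right-hand side so symmetry of symmetric operators is preserved.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    vals = np.broadcast_to(np.asarray(values, dtype=float), nodes.shape)
    n = A.shape[0]
    x0 = np.zeros(n)
    x0[nodes] = vals
    b = b - A @ x0
    mask = np.zeros(n, dtype=bool)
    mask[nodes] = True
    keep = sp.diags((~mask).astype(float))
    A = keep @ A @ keep + sp.diags(mask.astype(float))
    b[nodes] = vals
    return A.tocsr(), b


# ---- facet utilities ---------------------------------------------------

def facet_areas(mesh: Mesh, facets: np.ndarray) -> np.ndarray:
    """Mode-weighted facet measures (length, revolved area or area)."""
    p = mesh.points[facets]
    if mesh.dim == 2:
        L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        if mesh.mode == "axisym":
            rbar = p[:, :, 0].mean(axis=1)
            return L * 2.0 * np.pi * rbar
        return L
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def facet_normals(mesh: Mesh, facets: np.ndarray,
                  interior_point: np.ndarray | None = None) -> np.ndarray:
    """Unit normals of facets.

    Orientation: if ``interior_point`` is given, normals point away from it;
    otherwise the raw orientation of the vertex ordering is returned.
    """
    p = mesh.points[facets]
    if mesh.dim == 2:
        t = p[:, 1] - p[:, 0]
        n = np.stack([t[:, 1], -t[:, 0]], axis=1)
    else:
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    if interior_point is not None:
        mid = p.mean(axis=1)
        flip = np.einsum("fd,fd->f", n, mid - np.asarray(interior_point)) < 0
        n[flip] *= -1.0
    return n
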