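"""Configuration I/O, run logging, oracle fixtures and mesh/field writers.

Units policy: SI everywhere inside the package; clinician-facing units
(mm, mL/min, degC, W) appear only in configuration files and reported
metrics, converted exactly once at load/write time.  Logs are plain CSV so
test assertions can diff them; fields export to ASCII VTU readable by
ParaView/VTK and meshes additionally to Gmsh MSH 2.2.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fem import Mesh
from .geometry import _grid_to_tris

if TYPE_CHECKING:  # pragma: no cover
    from .driver import SimulationConfig

__all__ = ["load_config", "save_config", "RunLog", "FixtureSpec",
           "generate_fixture", "write_vtu", "write_msh"]


# ---------------------------------------------------------------------------
# configuration round-trip
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> "SimulationConfig":
    """Load and validate a YAML/JSON simulation configuration.

    Unknown keys are rejected; defaults fill everything not specified.
    Raises a validation error naming the offending field otherwise.
    """
    from .driver import SimulationConfig
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return SimulationConfig.model_validate(data)


def save_config(config: "SimulationConfig", path: str | Path) -> None:
    """Write a configuration as YAML; save(load(x)) is idempotent."""
    payload = config.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# incremental run log
# ---------------------------------------------------------------------------

class RunLog:
    """Incrementally flushed CSV log of per-step scalars.

    Columns: t, V, P, Z, T_sensor, T_max_tissue, T_max_blood.  Events
    (step rejections, saturations) go to a sibling ``*.events.csv``.
    Aborted runs keep everything written so far.
    """

    FIELDS = ["t", "V", "P", "Z", "T_sensor", "T_max_tissue", "T_max_blood"]

    def __init__(self, path: str | Path | None):
        self.rows: list[dict] = []
        self.events: list[dict] = []
        self._path = Path(path) if path else None
        self._fh = None
        if self._path:
            self._path.parent.mkdir(parents=True, exist_ok=True)
            self._fh = open(self._path, "w", newline="")
            self._writer = csv.DictWriter(self._fh, fieldnames=self.FIELDS)
            self._writer.writeheader()

    def record(self, **kw) -> None:
        if self.rows and kw["t"] <= self.rows[-1]["t"]:
            raise ValueError("log times must be strictly increasing")
        self.rows.append(kw)
        if self._fh:
            self._writer.writerow({k: kw.get(k) for k in self.FIELDS})
            self._fh.flush()

    def event(self, t: float, kind: str, detail: str = "") -> None:
        self.events.append({"t": t, "kind": kind, "detail": detail})

    def close(self) -> None:
        if self._fh:
            self._fh.close()
            self._fh = None
            if self.events and self._path:
                ep = self._path.with_suffix(".events.csv")
                with open(ep, "w", newline="") as fh:
                    w = csv.DictWriter(fh, fieldnames=["t", "kind", "detail"])
                    w.writeheader()
                    w.writerows(self.events)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {k: np.array([r.get(k, np.nan) for r in self.rows])
                for k in self.FIELDS}


# ---------------------------------------------------------------------------
# oracle fixtures
# ---------------------------------------------------------------------------

ORACLES = ["poiseuille_channel", "slab_conduction", "grounded_sphere",
           "gaussian_lesion", "analytic_plant"]


class FixtureSpec(BaseModel):
    """Request for one analytic test fixture (mesh + reference solution)."""

    model_config = ConfigDict(extra="forbid")

    oracle: str
    params: dict = Field(default_factory=dict)
    resolution: int = 24
    seed: int = 0


def generate_fixture(spec: FixtureSpec) -> dict:
    """Build the requested oracle fixture.

    Every fixture bundles the inputs consumable by the corresponding solver
    module together with an independent closed-form reference evaluated on
    the same mesh.
    """
    if spec.oracle not in ORACLES:
        raise ValueError(f"unknown oracle {spec.oracle!r}; choose from {ORACLES}")
    return getattr(_Fixtures, spec.oracle)(spec)


def _rect_mesh(Lx: float, Ly: float, nx: int, ny: int, mode: str = "planar",
               region: str = "tissue", y0: float = 0.0) -> Mesh:
    xx = np.linspace(0.0, Lx, nx)
    yy = np.linspace(y0, y0 + Ly, ny)
    X, Y = np.meshgrid(xx, yy, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    cells = _grid_to_tris(nx, ny)
    return Mesh(points=pts, cells=cells,
                cell_regions=np.zeros(len(cells), dtype=np.int64),
                region_names=[region], mode=mode)


class _Fixtures:
    @staticmethod
    def poiseuille_channel(spec: FixtureSpec) -> dict:
        """Plane channel with an imposed pressure drop.

        Exact profile u_x(y) = dP/(2 mu L) * y (H - y).
        """
        p = {"Lx": 0.01, "H": 0.001, "mu": 2.1e-3, "dP": 2.0,
             **spec.params}
        n = spec.resolution
        nx, ny = max(8, n), max(9, n | 1)
        mesh = _rect_mesh(p["Lx"], p["H"], nx, ny)
        pts = mesh.points
        walls = np.flatnonzero((np.abs(pts[:, 1]) < 1e-12)
                               | (np.abs(pts[:, 1] - p["H"]) < 1e-12))
        inlet_nodes = np.flatnonzero(np.abs(pts[:, 0]) < 1e-12)
        idx = np.arange(nx * ny).reshape(nx, ny)
        inlet_facets = np.stack([idx[0, :-1], idx[0, 1:]], axis=1)
        inlet_normals = np.tile([-1.0, 0.0], (len(inlet_facets), 1))

        def exact(y: np.ndarray) -> np.ndarray:
            return p["dP"] / (2 * p["mu"] * p["Lx"]) * y * (p["H"] - y)

        return {"mesh": mesh, "params": p, "walls": walls,
                "inlet_nodes": inlet_nodes, "inlet_facets": inlet_facets,
                "inlet_normals": inlet_normals, "exact_profile": exact}

    @staticmethod
    def slab_conduction(spec: FixtureSpec) -> dict:
        """1D transient conduction: slab at T0, ends clamped at Ta.

        Separation-of-variables series with truncation bound; exact
        T(x,t) = Ta + sum_odd 4(T0-Ta)/(n pi) sin(n pi x/L) exp(-kappa (n pi/L)^2 t).
        """
        p = {"L": 0.02, "T0": 37.0, "Ta": 0.0, "k": 0.531,
             "rho_c": 1060.0 * 3111.0, "terms": 51, **spec.params}
        n = max(10, spec.resolution)
        mesh = _rect_mesh(p["L"], p["L"] / n * 2, n + 1, 3)
        kappa = p["k"] / p["rho_c"]

        def exact(x: np.ndarray, t: float) -> np.ndarray:
            out = np.full_like(np.asarray(x, float), p["Ta"])
            for m in range(1, p["terms"] + 1, 2):
                out = out + (4 * (p["T0"] - p["Ta"]) / (m * np.pi)
                             * np.sin(m * np.pi * np.asarray(x) / p["L"])
                             * math.exp(-kappa * (m * np.pi / p["L"]) ** 2 * t))
            return out

        ends = np.flatnonzero((np.abs(mesh.points[:, 0]) < 1e-12)
                              | (np.abs(mesh.points[:, 0] - p["L"]) < 1e-12))
        return {"mesh": mesh, "params": p, "end_nodes": ends,
                "diffusivity": kappa, "exact": exact}

    @staticmethod
    def grounded_sphere(spec: FixtureSpec) -> dict:
        """Spreading resistance of a grounded sphere in a uniform medium.

        Shell a <= rho <= b meshed in axisymmetric coordinates; exact
        Z = (1/a - 1/b) / (4 pi sigma); for b >> a this approaches the
        unbounded value 1/(4 pi sigma a).
        """
        p = {"a": 1e-3, "b": 50e-3, "sigma": 0.2, **spec.params}
        n = max(12, spec.resolution)
        # geometric grading in rho, uniform in polar angle
        rho = p["a"] * (p["b"] / p["a"]) ** np.linspace(0, 1, 3 * n)
        theta = np.linspace(0.0, np.pi, n + 1)
        Rg, Tg = np.meshgrid(rho, theta, indexing="ij")
        pts = np.stack([(Rg * np.sin(Tg)).ravel(), (Rg * np.cos(Tg)).ravel()],
                       axis=1)
        cells = _grid_to_tris(len(rho), len(theta))
        # drop degenerate slivers on the axis
        mesh = Mesh(points=pts, cells=cells,
                    cell_regions=np.zeros(len(cells), dtype=np.int64),
                    region_names=["tissue"], mode="axisym")
        keep = mesh.cell_volumes > 1e-12 * p["a"] ** 2
        mesh = Mesh(points=pts, cells=cells[keep],
                    cell_regions=np.zeros(int(keep.sum()), dtype=np.int64),
                    region_names=["tissue"], mode="axisym")
        rr = np.linalg.norm(pts, axis=1)
        inner = np.flatnonzero(np.abs(rr - p["a"]) < 1e-9)
        outer = np.flatnonzero(np.abs(rr - p["b"]) < 1e-6)
        Z_exact = (1.0 / p["a"] - 1.0 / p["b"]) / (4.0 * np.pi * p["sigma"])
        Z_unbounded = 1.0 / (4.0 * np.pi * p["sigma"] * p["a"])
        return {"mesh": mesh, "params": p, "inner_nodes": inner,
                "outer_nodes": outer, "Z_exact": Z_exact,
                "Z_unbounded": Z_unbounded}

    @staticmethod
    def gaussian_lesion(spec: FixtureSpec) -> dict:
        """Synthetic hot spot T = 37 + dT exp(-rho^2/w^2) in a tissue block.

        The 50 degC isotherm is the sphere rho_50 = w sqrt(ln(dT/13));
        exact metrics follow from the hemisphere it cuts in the tissue.
        """
        p = {"w": 4e-3, "dT": 40.0, "R": 20e-3, "H": 20e-3, **spec.params}
        n = max(16, spec.resolution)
        xx = np.linspace(0.0, p["R"], n + 1)
        zz = np.linspace(-p["H"], 0.0, n + 1)
        X, Z = np.meshgrid(xx, zz, indexing="ij")
        pts = np.stack([X.ravel(), Z.ravel()], axis=1)
        cells = _grid_to_tris(n + 1, n + 1)
        mesh = Mesh(points=pts, cells=cells,
                    cell_regions=np.zeros(len(cells), dtype=np.int64),
                    region_names=["tissue"], mode="axisym")
        rho = np.linalg.norm(pts, axis=1)
        T = 37.0 + p["dT"] * np.exp(-(rho / p["w"]) ** 2)
        r50 = p["w"] * math.sqrt(math.log(p["dT"] / 13.0))
        exact = {"r50": r50, "D_mm": r50 * 1e3, "MW_mm": 2 * r50 * 1e3,
                 "SW_mm": 2 * r50 * 1e3, "DW_mm": 0.0,
                 "LV_mm3": (2.0 / 3.0) * np.pi * r50**3 * 1e9}
        return {"mesh": mesh, "params": p, "T": T, "exact": exact}

    @staticmethod
    def analytic_plant(spec: FixtureSpec) -> dict:
        """Resistive plant P = V^2/Z for closed-loop controller tests."""
        p = {"Z": 140.0, "P_target": 35.0, "dt": 0.05, **spec.params}

        def plant(V: float) -> float:
            return V * V / p["Z"]

        return {"params": p, "plant": plant}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_VTK_CELL = {3: 5, 4: 10}       # triangle, tetrahedron


def write_vtu(mesh: Mesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """ASCII XML VTU export of the mesh with optional fields.

    2D meshes are embedded at z = 0.  Vector point data of shape
    (n_points, dim) is padded to three components.
    """
    pts = mesh.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    ctype = _VTK_CELL[mesh.cells.shape[1]]
    offs = np.arange(1, mesh.n_cells + 1) * mesh.cells.shape[1]

    def arr2txt(a, fmt="%.10g"):
        return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row))
                         for row in np.atleast_2d(a))

    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{mesh.n_points}" NumberOfCells="{mesh.n_cells}">',
             '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             arr2txt(pts), "</DataArray></Points>", "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">',
             arr2txt(mesh.cells, "%d"),
             '</DataArray><DataArray type="Int64" Name="offsets" format="ascii">',
             " ".join(str(o) for o in offs),
             '</DataArray><DataArray type="UInt8" Name="types" format="ascii">',
             " ".join(str(ctype) for _ in range(mesh.n_cells)),
             "</DataArray></Cells>"]

    def data_block(tag: str, data: dict[str, np.ndarray]) -> list[str]:
        out = [f"<{tag}>"]
        for name, values in data.items():
            values = np.asarray(values, dtype=float)
            if values.ndim == 2:
                if values.shape[1] == 2:
                    values = np.column_stack([values,
                                              np.zeros(len(values))])
                nc = values.shape[1]
            else:
                nc = 1
            out.append(f'<DataArray type="Float64" Name="{name}" '
                       f'NumberOfComponents="{nc}" format="ascii">')
            out.append(arr2txt(values))
            out.append("</DataArray>")
        out.append(f"</{tag}>")
        return out

    lines += data_block("PointData", point_data or {})
    lines += data_block("CellData", cell_data or {})
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def write_msh(mesh: Mesh, path: str | Path) -> None:
    """Gmsh 2.2 ASCII export with region tags as physical groups."""
    elem_type = 2 if mesh.cells.shape[1] == 3 else 4
    pts = mesh.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(mesh.region_names))]
    dim = 2 if mesh.cells.shape[1] == 3 else 3
    for i, name in enumerate(mesh.region_names):
        lines.append(f'{dim} {i + 1} "{name}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_points)]
    for i, p in enumerate(pts, start=1):
        lines.append(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_cells)]
    for i, (cell, reg) in enumerate(zip(mesh.cells, mesh.cell_regions),
                                    start=1):
        conn = " ".join(str(v + 1) for v in cell)
        lines.append(f"{i} {elem_type} 2 {reg + 1} {reg + 1} {conn}")
    lines += ["$EndElements"]
    Path(path).write_text("\n".join(lines))


def write_result_json(path: str | Path, payload: dict) -> None:
    """JSON result summary (lesion metrics + provenance)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=float))
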