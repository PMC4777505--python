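"""Steady incompressible blood flow with the saline-irrigation inlet.

The blood pool obeys the incompressible Navier-Stokes equations with
constant viscosity and no body forces, so nothing couples the flow back to
the thermal problem: the velocity field is solved once per configuration
(steady state) and frozen for the whole ablation.

Discretization: equal-order P1-P1 elements with Brezzi-Pitkaranta pressure
stabilization and streamline diffusion for the convective term, solved by
Picard (fixed-point) iteration starting from the Stokes solution.  The
saline irrigation enters as a Dirichlet inflow of speed Q / A_band on the
irrigation band, directed along the outward electrode normal; the lateral
blood stream enters at 0.1 m/s through the left face (3D mode only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrical import SolverError
from .fem import (Mesh, _accumulate, apply_dirichlet, assemble_advection,
                  assemble_stiffness, facet_areas, facet_normals)
from .geometry import DomainModel, _boundary_facets

__all__ = ["FlowParams", "FlowState", "saline_inlet_velocity",
           "extract_region_submesh", "solve_ns", "solve_steady_flow"]


@dataclass(frozen=True)
class FlowParams:
    """Blood rheology and inflow settings (SI units)."""

    mu: float = 2.1e-3            # dynamic viscosity, kg/(m s)
    rho_blood: float = 1000.0     # kg/m^3
    u_blood_in: float = 0.1       # lateral inflow speed, m/s (+x)
    body_force: float = 0.0       # fixed at zero

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if self.body_force != 0.0:
            raise ValueError("body forces are not modelled (F = 0)")


@dataclass
class FlowState:
    """Velocity/pressure on the full mesh (zero inside solids)."""

    u: np.ndarray                 # (n_points, dim), m/s
    P: np.ndarray                 # (n_points,), Pa
    u_saline: float
    mass_balance_error: float = 0.0
    reynolds: float = 0.0
    residual_history: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def saline_inlet_velocity(Q_ml_min: float, band_area_mm2: float) -> float:
    """Inlet saline speed (m/s) = flow rate / irrigation area.

    13 mL/min through the 1.32 mm^2 six-hole ring gives 0.164 m/s; through
    the 10.37 mm^2 multi-hole surface, 0.021 m/s.
    """
    if band_area_mm2 <= 0:
        raise ValueError("band area must be positive")
    if Q_ml_min < 0:
        raise ValueError("flow rate must be non-negative")
    return (Q_ml_min * 1e-6 / 60.0) / (band_area_mm2 * 1e-6)


def extract_region_submesh(mesh: Mesh, region: str = "blood",
                           ) -> tuple[Mesh, np.ndarray]:
    """Submesh of one region; facet sets are remapped where fully contained.

    Returns (submesh, node_map) with ``node_map`` giving, for each submesh
    node, its index in the parent mesh.
    """
    cmask = mesh.region_mask(region)
    cells = mesh.cells[cmask]
    used = np.unique(cells)
    new_idx = -np.ones(mesh.n_points, dtype=np.int64)
    new_idx[used] = np.arange(len(used))
    sub = Mesh(points=mesh.points[used], cells=new_idx[cells],
               cell_regions=np.zeros(cmask.sum(), dtype=np.int64),
               region_names=[region], mode=mesh.mode)
    inside = np.zeros(mesh.n_points, dtype=bool)
    inside[used] = True
    for name, fac in mesh.facet_sets.items():
        if fac.size == 0:
            sub.facet_sets[name] = fac.copy()
            continue
        keep = inside[fac].all(axis=1)
        sub.facet_sets[name] = new_idx[fac[keep]]
    for name, fac in sub.facet_sets.items():
        sub.node_sets[name] = np.unique(fac) if fac.size else np.empty(0, np.int64)
    return sub, used


def _pressure_gradient_blocks(mesh: Mesh) -> list[sp.csr_matrix]:
    """G_i with G_i[m, n] = -int phi_n d_i phi_m (+ axisym v_r/r term).

    In axisymmetric mode the weighted moments int phi_n r dA and
    int phi_n phi_m dA are integrated exactly (r is linear per cell), which
    keeps the discrete divergence - and hence global mass conservation -
    consistent near the axis.
    """
    nv = mesh.cells.shape[1]
    G = mesh.cell_grads
    blocks = []
    if mesh.mode == "axisym":
        A = mesh.cell_volumes
        r_nodes = mesh.points[mesh.cells][:, :, 0]          # (nc, 3)
        rsum = r_nodes.sum(axis=1)
        # int phi_n r dA = A (rsum + r_n) / 12
        mom = 2.0 * np.pi * A[:, None] * (rsum[:, None] + r_nodes) / 12.0
        # int phi_m phi_n dA = A/12 (1 + delta_mn)
        eye = np.eye(nv)
        mass = 2.0 * np.pi * A[:, None, None] * (1.0 + eye) / 12.0
        for i in range(mesh.dim):
            local = -np.einsum("cm,cn->cmn", G[:, :, i], mom)
            if i == 0:
                local = local - mass
            blocks.append(_accumulate(mesh, local))
        return blocks
    w = mesh.cell_weights
    for i in range(mesh.dim):
        local = -(w[:, None] * G[:, :, i] / nv)[:, :, None].repeat(nv, axis=2)
        blocks.append(_accumulate(mesh, local))
    return blocks


def _axisym_hoop_mass(mesh: Mesh, mu: float) -> sp.csr_matrix:
    """mu * int u_r v_r / r^2 for the r-momentum equation (axisym only)."""
    nv = mesh.cells.shape[1]
    rbar = mesh.cell_centroids[:, 0]
    local = (mu * mesh.cell_weights / rbar**2 / nv**2)[:, None, None]
    local = np.broadcast_to(local, (mesh.n_cells, nv, nv)).copy()
    return _accumulate(mesh, local)


def solve_ns(mesh: Mesh, params: FlowParams,
             dirichlet: list[tuple[np.ndarray, int, np.ndarray | float]],
             traction: list[tuple[np.ndarray, float, np.ndarray]] | None = None,
             pin_pressure: bool = False,
             alpha_stab: float = 0.2,
             max_iter: int = 200,
             tol: float = 1e-8,
             relax: float = 0.9) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Solve steady incompressible Navier-Stokes on a (fluid-only) mesh.

    Parameters
    ----------
    dirichlet:
        List of ``(nodes, component, value)`` velocity constraints; later
        entries override earlier ones on shared nodes.
    traction:
        Optional ``(facets, pressure, outward_normals)`` entries adding the
        boundary term -p0 n.v (an imposed-pressure inlet/outlet).
    pin_pressure:
        Fix the pressure at one node (needed for fully enclosed flows).

    Returns (u_nodal, p_nodal, residual_history).
    """
    traction = traction or []
    d, n = mesh.dim, mesh.n_points
    mu, rho = params.mu, params.rho_blood
    nv = mesh.cells.shape[1]

    K1 = assemble_stiffness(mesh, 1.0)
    Gblocks = _pressure_gradient_blocks(mesh)
    hoop = _axisym_hoop_mass(mesh, mu) if mesh.mode == "axisym" else None
    h = mesh.cell_sizes
    w = mesh.cell_weights
    Ggrad = mesh.cell_grads

    # global Dirichlet dof lists (later entries win)
    dofs = []
    vals = []
    for nodes, comp, value in dirichlet:
        nodes = np.asarray(nodes, dtype=np.int64)
        dofs.append(comp * n + nodes)
        vals.append(np.broadcast_to(np.asarray(value, float), nodes.shape))
    if pin_pressure:
        dofs.append(np.array([d * n]))
        vals.append(np.array([0.0]))
    dofs = np.concatenate(dofs)
    vals = np.concatenate(vals)
    _, last = np.unique(dofs[::-1], return_index=True)
    idx = len(dofs) - 1 - last
    dofs, vals = dofs[idx], vals[idx]

    rhs0 = np.zeros((d + 1) * n)
    for facets, p0, normals in traction:
        a = facet_areas(mesh, facets)
        for i in range(d):
            contrib = -p0 * normals[:, i] * a / facets.shape[1]
            np.add.at(rhs0, i * n + facets.ravel(),
                      np.repeat(contrib, facets.shape[1]))

    u = np.zeros((n, d))
    p = np.zeros(n)
    history: list[float] = []
    for it in range(max_iter):
        u_cells = u[mesh.cells].mean(axis=1)
        speed = np.linalg.norm(u_cells, axis=1)
        C = assemble_advection(mesh, u_cells, rho, diffusivity=mu / rho)
        A = mu * K1 + C
        if hoop is not None:
            A_r = A + hoop
        delta = alpha_stab * h**2 / (4.0 * mu + 2.0 * rho * speed * h)
        S = assemble_stiffness(mesh, delta)

        blocks = [[None] * (d + 1) for _ in range(d + 1)]
        for i in range(d):
            blocks[i][i] = A_r if (hoop is not None and i == 0) else A
            blocks[i][d] = Gblocks[i]
            blocks[d][i] = Gblocks[i].T
        blocks[d][d] = -S
        Abig = sp.bmat(blocks, format="csr")
        bbig = rhs0.copy()
        Abc, bbc = apply_dirichlet(Abig, bbig, dofs, vals)
        try:
            sol = spla.spsolve(Abc.tocsc(), bbc)
        except Exception as exc:  # pragma: no cover
            raise SolverError(f"flow solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("flow solve returned non-finite values")
        u_new = sol[: d * n].reshape(d, n).T
        p_new = sol[d * n:]
        du = np.linalg.norm(u_new - u) / max(np.linalg.norm(u_new), 1e-300)
        history.append(du)
        # full steps once the fixed point is nearly reached: under-relaxation
        # only guards the early, convection-dominated iterations
        omega = 1.0 if du < 1e-4 else relax
        u = u + omega * (u_new - u)
        p = p + omega * (p_new - p)
        if du < tol:
            u, p = u_new, p_new
            break
    else:
        raise SolverError(
            f"Picard iteration did not converge: residuals {history[-3:]}")
    return u, p, history


def _oriented_boundary(sub: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """All boundary facets of a mesh with outward unit normals."""
    uniq, counts, inv, owners = _boundary_facets(sub.cells)
    order = np.argsort(inv, kind="stable")
    osort = owners[order]
    starts = np.concatenate([[0], np.cumsum(counts)])
    bidx = np.flatnonzero(counts == 1)
    facets = uniq[bidx]
    own = osort[starts[bidx]]
    nrm = facet_normals(sub, facets)
    fc = sub.points[facets].mean(axis=1)
    cc = sub.points[sub.cells[own]].mean(axis=1)
    flip = np.einsum("fd,fd->f", nrm, fc - cc) < 0
    nrm[flip] *= -1.0
    return facets, nrm


def _band_normals(mesh: Mesh, facets: np.ndarray,
                  domain: DomainModel | None) -> np.ndarray:
    """Outward (electrode -> blood) unit normals of band facets."""
    fc = mesh.points[facets].mean(axis=1)
    nrm = facet_normals(mesh, facets)
    if domain is None or domain.config.orientation == "perpendicular":
        # electrode axis is the z axis; reference point on the axis
        ref = fc.copy()
        ref[:, :-1] *= 0.0
        if mesh.dim == 2:
            ref[:, 0] = 0.0
    else:
        ref = fc.copy()
        ref[:, 1] = 0.0
        ref[:, 2] = domain.zA
    flip = np.einsum("fd,fd->f", nrm, fc - ref) < 0
    nrm[flip] *= -1.0
    return nrm


def boundary_flux(mesh: Mesh, facets: np.ndarray, u: np.ndarray,
                  normals: np.ndarray) -> float:
    """Integral of u . n over a facet set (m^3/s, mode-weighted).

    Exact for P1 velocity on straight facets, including the 2*pi*r
    revolution weight in axisymmetric mode (integrand then quadratic).
    """
    p = mesh.points[facets]
    un = np.einsum("fvd,fd->fv", u[facets], normals)     # u.n at facet nodes
    if mesh.dim == 2:
        L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        if mesh.mode == "axisym":
            r0, r1 = p[:, 0, 0], p[:, 1, 0]
            val = 2.0 * np.pi * L * (un[:, 0] * (2 * r0 + r1)
                                     + un[:, 1] * (r0 + 2 * r1)) / 6.0
            return float(val.sum())
        return float((L * un.mean(axis=1)).sum())
    a = facet_areas(mesh, facets)
    return float(np.sum(a * un.mean(axis=1)))


def solve_steady_flow(mesh: Mesh, params: FlowParams, u_saline: float,
                      domain: DomainModel | None = None,
                      alpha_stab: float = 0.2,
                      **kwargs) -> FlowState:
    """Steady blood-pool flow for the ablation domain.

    Boundary conditions: uniform ``u_blood_in`` (+x) on the left blood face
    and zero traction on the right face (3D); ``u_saline`` inflow along the
    outward electrode normal on the irrigation band; no-slip on the upper
    walls and at the tissue-blood / electrode-blood / catheter-blood
    interfaces; symmetry (zero normal velocity) on y = 0 and on the axis.

    In axisymmetric mode the lateral blood stream cannot be represented:
    ``u_blood_in`` is forced to zero, outflow leaves through the lateral
    (r = R) boundary as a zero-traction outlet, and the limitation is
    stamped into ``metadata``.
    """
    sub, node_map = extract_region_submesh(mesh, "blood")
    d = sub.dim
    meta: dict = {}

    noslip_names = ["tissue_blood_interface", "electrode_blood_interface",
                    "catheter_blood_interface"]
    dirichlet: list[tuple[np.ndarray, int, np.ndarray | float]] = []

    if sub.mode == "axisym":
        u_in = 0.0
        if params.u_blood_in != 0.0:
            meta["u_blood_in_dropped"] = (
                "axisymmetric mode cannot represent the lateral blood "
                "stream; inlet speed forced to 0")
        R = sub.points[:, 0].max()
        Ztop = sub.points[:, 1].max()
        wall = sub.facet_sets.get("outer_walls", np.empty((0, d)))
        wall_c = sub.points[wall].mean(axis=1) if wall.size else wall
        top = wall[np.abs(wall_c[:, 1] - Ztop) < 1e-9] if wall.size else wall
        side = wall[np.abs(wall_c[:, 0] - R) < 1e-9] if wall.size else wall
        # top wall: no-slip; lateral boundary: zero-traction outlet
        for nm in noslip_names:
            nodes = sub.node_sets.get(nm, np.empty(0, np.int64))
            for c in range(d):
                dirichlet.append((nodes, c, 0.0))
        tn = np.unique(top) if top.size else np.empty(0, np.int64)
        for c in range(d):
            dirichlet.append((tn, c, 0.0))
        axis_nodes = np.flatnonzero(np.abs(sub.points[:, 0]) < 1e-12)
        dirichlet.append((axis_nodes, 0, 0.0))
        outlet_facets = side
        outlet_normals = facet_normals(sub, side, interior_point=np.array(
            [0.0, 0.5 * (sub.points[:, 1].min() + Ztop)])) if side.size else side
    else:
        u_in = params.u_blood_in
        for nm in noslip_names + ["outer_walls"]:
            nodes = sub.node_sets.get(nm, np.empty(0, np.int64))
            for c in range(d):
                dirichlet.append((nodes, c, 0.0))
        inlet = sub.node_sets.get("blood_inlet_face", np.empty(0, np.int64))
        dirichlet.append((inlet, 0, u_in))
        dirichlet.append((inlet, 1, 0.0))
        dirichlet.append((inlet, 2, 0.0))
        sym = sub.node_sets.get("symmetry_plane", np.empty(0, np.int64))
        dirichlet.append((sym, 1, 0.0))
        outlet_facets = sub.facet_sets.get("blood_outlet_face",
                                           np.empty((0, d), np.int64))
        centre = sub.points.mean(axis=0)
        outlet_normals = (facet_normals(sub, outlet_facets, interior_point=centre)
                          if outlet_facets.size else outlet_facets)

    # boundary partition for flux accounting
    all_facets, all_normals = _oriented_boundary(sub)
    if outlet_facets.size:
        outlet_keys = set(map(tuple, np.sort(outlet_facets, axis=1)))
        is_outlet = np.array([tuple(f) in outlet_keys for f in all_facets])
    else:
        is_outlet = np.zeros(len(all_facets), dtype=bool)

    band = sub.facet_sets.get("irrigation_band", np.empty((0, d), np.int64))
    meta["saline_flux_nominal"] = 0.0
    meta["band_flux_scale"] = 1.0
    if u_saline != 0.0 and band.size:
        nrm = _band_normals(sub, band, domain)
        # nodal normals: average of adjacent facet normals
        nodal_n = np.zeros((sub.n_points, d))
        np.add.at(nodal_n, band.ravel(), np.repeat(nrm, band.shape[1], axis=0))
        bn = np.unique(band)
        nodal_n[bn] /= np.linalg.norm(nodal_n[bn], axis=1, keepdims=True)
        # flux-consistent scaling: the realized discrete influx of the
        # Dirichlet pattern (including facets straddling the band edge)
        # is normalized to the nominal flow rate u_s * A_band
        u_pat = np.zeros((sub.n_points, d))
        u_pat[bn] = u_saline * nodal_n[bn]
        realized = -boundary_flux(sub, all_facets[~is_outlet], u_pat,
                                  all_normals[~is_outlet])
        a_band = facet_areas(sub, band).sum()
        nominal = u_saline * a_band
        scale = nominal / realized if realized > 0 else 1.0
        meta["saline_flux_nominal"] = nominal
        meta["band_flux_scale"] = scale
        for c in range(d):
            dirichlet.append((bn, c, scale * u_saline * nodal_n[bn, c]))

    u_sub, p_sub, history = solve_ns(sub, params, dirichlet,
                                     alpha_stab=alpha_stab, **kwargs)

    # global mass balance: total inflow (blood inlet + saline band,
    # measured on the discrete solution) vs outlet flux
    q_out = boundary_flux(sub, all_facets[is_outlet], u_sub,
                          all_normals[is_outlet]) if is_outlet.any() else 0.0
    q_in = -boundary_flux(sub, all_facets[~is_outlet], u_sub,
                          all_normals[~is_outlet])
    denom = max(abs(q_in), abs(q_out), 1e-300)
    mass_err = abs(q_out - q_in) / denom if (q_in or q_out) else 0.0
    meta["inflow_m3s"] = q_in
    meta["outflow_m3s"] = q_out

    u_full = np.zeros((mesh.n_points, d))
    p_full = np.zeros(mesh.n_points)
    u_full[node_map] = u_sub
    p_full[node_map] = p_sub

    d_e = 2.0 * (domain.re if domain is not None else 1.3335e-3)
    umax = max(abs(u_in), abs(u_saline))
    re_num = params.rho_blood * umax * d_e / params.mu
    meta["picard_iterations"] = len(history)
    return FlowState(u=u_full, P=p_full, u_saline=float(u_saline),
                     mass_balance_error=float(mass_err), reynolds=float(re_num),
                     residual_history=history, metadata=meta)
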