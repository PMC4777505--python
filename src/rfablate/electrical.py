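"""Quasi-static electrical problem.

At RF frequencies (~500 kHz) cardiac tissue is almost purely resistive, so
the potential solves the DC conduction problem div(sigma grad(phi)) = 0
with the applied voltage on the metallic electrode surface, 0 V on the
bottom (dispersive-electrode) boundary and zero normal current elsewhere.
The Joule heat density q = sigma |grad phi|^2 drives the thermal problem;
delivered power is its volume integral (doubled in the half-symmetric 3D
mode) and impedance is Z = V^2 / P, which on coarse meshes is variationally
more accurate than surface-current integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .fem import Mesh, apply_dirichlet, assemble_stiffness

__all__ = ["ElectricalState", "SolverError", "solve_potential",
           "cell_sigma", "baseline_impedance"]


class SolverError(RuntimeError):
    """A linear or nonlinear solve failed."""


@dataclass
class ElectricalState:
    """Potential solution and derived quantities.

    ``phi`` is nodal (V); ``E_mag`` and ``q`` are per-cell (V/m, W/m^3).
    ``P_delivered`` is the total delivered power (W), already doubled for
    half-symmetric 3D meshes; ``Z`` the impedance (ohm).
    """

    phi: np.ndarray
    E_mag: np.ndarray
    q: np.ndarray
    V_applied: float
    P_delivered: float
    Z: float

    def scaled(self, V_new: float) -> "ElectricalState":
        """Exploit linearity: rescale the solution to a new applied voltage."""
        if self.V_applied == 0:
            raise ValueError("cannot rescale the trivial V=0 solution")
        s = V_new / self.V_applied
        return ElectricalState(phi=self.phi * s, E_mag=self.E_mag * abs(s),
                               q=self.q * s * s, V_applied=V_new,
                               P_delivered=self.P_delivered * s * s,
                               Z=self.Z)


def cell_sigma(mesh: Mesh, T_cells: np.ndarray | None = None,
               baseline: mat.TissueBaseline | None = None) -> np.ndarray:
    """Per-cell electrical conductivity.

    Constant Table-value conductivities everywhere except myocardium, which
    follows the temperature law evaluated at the element midpoint value of
    T (None means uniform 37 degC).
    """
    baseline = baseline or mat.TissueBaseline()
    sig = np.empty(mesh.n_cells)
    for code, name in enumerate(mesh.region_names):
        m = mesh.cell_regions == code
        if not np.any(m):
            continue
        if name == "tissue":
            T = np.full(m.sum(), 37.0) if T_cells is None else T_cells[m]
            sig[m] = mat.sigma_tissue(T, baseline.sigma_o)
        else:
            sig[m] = mat.REGION_PROPS[name].sigma
    return sig


def solve_potential(mesh: Mesh, sigma_cells, V_applied: float,
                    electrode_nodes: np.ndarray | None = None,
                    ground_nodes: np.ndarray | None = None) -> ElectricalState:
    """Solve the quasi-static conduction problem.

    Dirichlet ``V_applied`` on the electrode metal surface, 0 V on the
    dispersive ground, natural (zero-current) conditions elsewhere and on
    the symmetry plane.  ``sigma_cells`` must be positive per cell.
    """
    sigma_cells = np.broadcast_to(np.asarray(sigma_cells, float),
                                  (mesh.n_cells,))
    if np.any(sigma_cells <= 0):
        raise ValueError("sigma must be positive on every element")
    if V_applied < 0:
        raise ValueError("V_applied must be non-negative")

    if electrode_nodes is None:
        electrode_nodes = mesh.node_sets["electrode_surface"]
    if ground_nodes is None:
        ground_nodes = mesh.node_sets["dispersive_ground"]
    if len(electrode_nodes) == 0 or len(ground_nodes) == 0:
        raise SolverError("electrode or ground surface has no nodes")

    K = assemble_stiffness(mesh, sigma_cells)
    b = np.zeros(mesh.n_points)
    bc_nodes = np.concatenate([electrode_nodes, ground_nodes])
    bc_vals = np.concatenate([np.full(len(electrode_nodes), float(V_applied)),
                              np.zeros(len(ground_nodes))])
    A, rhs = apply_dirichlet(K, b, bc_nodes, bc_vals)
    try:
        phi = spla.spsolve(A.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - singular systems
        raise SolverError(f"potential solve failed: {exc}") from exc
    if not np.all(np.isfinite(phi)):
        raise SolverError("potential solve returned non-finite values")

    grad = np.einsum("cid,ci->cd", mesh.cell_grads, phi[mesh.cells])
    E_mag = np.linalg.norm(grad, axis=1)
    q = sigma_cells * E_mag**2
    P = float(np.dot(q, mesh.cell_weights))
    if mesh.mode == "3d":
        P *= 2.0
    Z = V_applied**2 / P if P > 0 else np.inf
    return ElectricalState(phi=phi, E_mag=E_mag, q=q,
                           V_applied=float(V_applied), P_delivered=P, Z=Z)


def baseline_impedance(mesh: Mesh,
                       baseline: mat.TissueBaseline | None = None,
                       V_probe: float = 25.0) -> float:
    """Initial impedance of the full geometry at a uniform 37 degC state.

    With the reference properties and sigma_o = 0.12 S/m this is ~140 ohm,
    matching the in vitro setup the tissue conductivity was calibrated to.
    """
    state = solve_potential(mesh, cell_sigma(mesh, None, baseline), V_probe)
    return state.Z
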