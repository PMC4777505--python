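"""Transient bioheat solve with enthalpy-method phase change.

The governing balance is the bioheat equation with the perfusion and
metabolic terms set to zero (both are negligible during RF ablation away
from coronary vessels):

    d(rho h)/dt = div(k grad T) + q - rho c u . grad T

The enthalpy derivative d(rho h)/dT is the apparent volumetric heat
capacity: liquid-phase rho_l c_l below 99 degC, the latent plateau
H_fg * C over the 99-100 degC vaporization band, and gas-phase rho_g c_g
above.  Time stepping is implicit (backward Euler) with lumped mass, so the
default 0.05 s step is unconditionally stable; material nonlinearity is
handled by Picard iteration whenever any tissue element sits near the
latent band.  Advection acts in the blood region only and is stabilized by
streamline diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .electrical import SolverError
from .fem import (Mesh, apply_dirichlet, assemble_advection,
                  assemble_lumped_mass, assemble_stiffness)

__all__ = ["TemperatureField", "ThermalBCs", "StepReport", "cell_thermal_props",
           "initial_temperature", "advance_temperature", "sensor_temperature"]

#: diagnostic hard cap; exceeding it flags a run as suspect
DEFAULT_T_CAP = 300.0


@dataclass
class TemperatureField:
    """Nodal temperature (degC) at elapsed time ``t`` (s)."""

    T: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class ThermalBCs:
    """Thermal boundary/initial conditions.

    Outer model surfaces are held at body temperature; the irrigation band
    carries 22 degC saline while irrigation is active; the electrode tip
    (electrode + thermistor volume) starts at 22 degC, a consequence of the
    pre-ablation irrigation.  ``clamp_tip`` optionally holds the tip at
    22 degC throughout (an alternative reading of irrigated-tip behaviour).
    """

    outer_wall_T: float = 37.0
    saline_inlet_T: float = 22.0
    initial_T: float = 37.0
    tip_initial_T: float = 22.0
    irrigation_active: bool = True
    clamp_tip: bool = False


@dataclass
class StepReport:
    """Per-step energy bookkeeping (J) and solver diagnostics."""

    joule_in: float
    boundary_loss: float
    advective_out: float
    stored_change: float
    balance_error: float
    picard_iters: int
    dt_used: float
    T_capped: bool = False
    converged: bool = True


def cell_thermal_props(mesh: Mesh, T_cells: np.ndarray,
                       baseline: mat.TissueBaseline | None = None,
                       pc: mat.PhaseChangeParams | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (k, apparent volumetric heat capacity).

    Myocardium follows the temperature laws (element-midpoint evaluation);
    all other regions use their constant Table values.
    """
    baseline = baseline or mat.TissueBaseline()
    pc = pc or mat.PhaseChangeParams()
    k = np.empty(mesh.n_cells)
    cap = np.empty(mesh.n_cells)
    for code, name in enumerate(mesh.region_names):
        m = mesh.cell_regions == code
        if not np.any(m):
            continue
        if name == "tissue":
            k[m] = mat.k_tissue(T_cells[m], baseline.k_o)
            cap[m] = mat.apparent_volumetric_heat_capacity(T_cells[m], pc)
        else:
            p = mat.REGION_PROPS[name]
            k[m] = p.k
            cap[m] = p.rho * p.c
    return k, cap


def initial_temperature(mesh: Mesh, bcs: ThermalBCs | None = None) -> TemperatureField:
    """37 degC everywhere except the electrode-tip volume at 22 degC."""
    bcs = bcs or ThermalBCs()
    T = np.full(mesh.n_points, bcs.initial_T)
    tip_cells = mesh.region_mask("electrode", "thermistor")
    tip_nodes = np.unique(mesh.cells[tip_cells])
    T[tip_nodes] = bcs.tip_initial_T
    return TemperatureField(T=T, t=0.0)


def _dirichlet_sets(mesh: Mesh, bcs: ThermalBCs):
    names = ["outer_walls", "dispersive_ground", "blood_inlet_face",
             "blood_outlet_face"]
    wall_nodes = mesh.nodes_of(*[n for n in names if n in mesh.node_sets])
    nodes = [wall_nodes]
    vals = [np.full(len(wall_nodes), bcs.outer_wall_T)]
    if bcs.irrigation_active and len(mesh.node_sets.get("irrigation_band", ())):
        band = mesh.node_sets["irrigation_band"]
        nodes.append(band)
        vals.append(np.full(len(band), bcs.saline_inlet_T))
    if bcs.clamp_tip:
        tip_cells = mesh.region_mask("electrode", "thermistor")
        tip = np.unique(mesh.cells[tip_cells])
        nodes.append(tip)
        vals.append(np.full(len(tip), bcs.saline_inlet_T))
    alln = np.concatenate(nodes)
    allv = np.concatenate(vals)
    # later entries win on duplicates
    _, last = np.unique(alln[::-1], return_index=True)
    idx = len(alln) - 1 - last
    return alln[idx], allv[idx]


def advance_temperature(mesh: Mesh, state: TemperatureField, dt: float,
                        q_cells: np.ndarray | float = 0.0,
                        u_cells: np.ndarray | None = None,
                        bcs: ThermalBCs | None = None,
                        baseline: mat.TissueBaseline | None = None,
                        pc: mat.PhaseChangeParams | None = None,
                        max_picard: int = 12,
                        picard_tol: float = 1e-3,
                        T_cap: float = DEFAULT_T_CAP,
                        _retries: int = 3,
                        ) -> tuple[TemperatureField, StepReport]:
    """One implicit step of the apparent-heat-capacity bioheat equation.

    ``q_cells`` is the Joule source per cell (W/m^3); ``u_cells`` the blood
    velocity per cell (zero/None in solids).  Returns the new field and an
    energy-balance report; the stored-enthalpy change equals Joule input
    minus boundary/advective losses up to the linear-solver tolerance by
    construction, and the report records the mismatch actually measured.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bcs = bcs or ThermalBCs()
    pc = pc or mat.PhaseChangeParams()
    n = mesh.n_points
    q_cells = np.broadcast_to(np.asarray(q_cells, float), (mesh.n_cells,))

    blood = mesh.region_mask("blood")
    if u_cells is None:
        u_cells = np.zeros((mesh.n_cells, mesh.dim))
    else:
        u_cells = np.where(blood[:, None], u_cells, 0.0)

    bc_nodes, bc_vals = _dirichlet_sets(mesh, bcs)

    # nodal source vector
    share = q_cells * mesh.cell_weights / mesh.cells.shape[1]
    f = np.zeros(n)
    np.add.at(f, mesh.cells.ravel(), np.repeat(share, mesh.cells.shape[1]))

    T_old = state.T
    T_it = T_old.copy()
    T_new = T_old.copy()
    iters = 0
    delta = 0.0
    converged = True
    # Picard with damped iterates; capacities are chords of the enthalpy
    # curve (H(T_k) - H(T_n)) / (T_k - T_n), which conserve latent heat
    # exactly for cells crossing the 99-100 degC band.  A single pass
    # suffices away from the band (properties at the previous-step field).
    T_old_cells = mesh.interpolate_to_cells(T_old)
    tissue_cells = mesh.region_mask("tissue")
    while True:
        iters += 1
        T_cells = mesh.interpolate_to_cells(T_it)
        k_c, cap_c = cell_thermal_props(mesh, T_cells, baseline, pc)
        dT = T_cells - T_old_cells
        big = tissue_cells & (np.abs(dT) > 1e-6)
        if np.any(big):
            dH = (mat.volumetric_enthalpy(T_cells[big], pc)
                  - mat.volumetric_enthalpy(T_old_cells[big], pc))
            cap_c[big] = dH / dT[big]
        K = assemble_stiffness(mesh, k_c)
        M = assemble_lumped_mass(mesh, cap_c)
        rhoc_blood = mat.REGION_PROPS["blood"].rho * mat.REGION_PROPS["blood"].c
        if np.any(np.linalg.norm(u_cells, axis=1) > 0):
            kappa = np.divide(k_c, cap_c)
            A = assemble_advection(mesh, u_cells, rhoc_blood, diffusivity=kappa)
        else:
            A = sp.csr_matrix((n, n))
        lhs = sp.diags(M / dt) + K + A
        rhs = (M / dt) * T_old + f
        lhs_bc, rhs_bc = apply_dirichlet(lhs, rhs.copy(), bc_nodes, bc_vals)
        T_next = spla.spsolve(lhs_bc.tocsc(), rhs_bc)
        if not np.all(np.isfinite(T_next)):
            raise SolverError("temperature solve returned non-finite values")
        delta = float(np.max(np.abs(T_next - T_it)))
        T_new = T_next
        near_band = np.any(
            tissue_cells & (T_cells > pc.T_lower - 4.0)) or np.any(big)
        if not near_band or delta < picard_tol or iters >= max_picard:
            if near_band and delta > 0.5 and iters >= max_picard:
                # nonlinear iteration did not settle: halve the step; if
                # retries are exhausted, accept the last solve and flag it
                # (residual ringing localizes to desiccated-front cells)
                if _retries <= 0:
                    converged = False
                    break
                half = dt / 2.0
                mid, r1 = advance_temperature(
                    mesh, state, half, q_cells, u_cells, bcs, baseline, pc,
                    max_picard, picard_tol, T_cap, _retries - 1)
                end, r2 = advance_temperature(
                    mesh, mid, half, q_cells, u_cells, bcs, baseline, pc,
                    max_picard, picard_tol, T_cap, _retries - 1)
                report = StepReport(
                    joule_in=r1.joule_in + r2.joule_in,
                    boundary_loss=r1.boundary_loss + r2.boundary_loss,
                    advective_out=r1.advective_out + r2.advective_out,
                    stored_change=r1.stored_change + r2.stored_change,
                    balance_error=max(r1.balance_error, r2.balance_error),
                    picard_iters=r1.picard_iters + r2.picard_iters,
                    dt_used=half, T_capped=r1.T_capped or r2.T_capped,
                    converged=r1.converged and r2.converged)
                return end, report
            break
        T_it = T_it + 0.5 * (T_next - T_it)

    # energy bookkeeping from the unconstrained residual: Dirichlet rows
    # carry the boundary fluxes
    resid = lhs @ T_new - rhs
    mask = np.zeros(n, dtype=bool)
    mask[bc_nodes] = True
    # sign: positive = heat leaving through the constrained boundaries
    boundary_loss = -float(resid[mask].sum()) * dt
    advective_out = float((A @ T_new).sum()) * dt
    stored = float((M * (T_new - T_old)).sum())
    joule = float(np.dot(q_cells, mesh.cell_weights)) * dt
    # floor: the energy that would heat the whole domain by 1 nK, so the
    # relative error stays meaningful for equilibrium (zero-energy) steps
    denom = max(abs(joule), abs(stored), abs(boundary_loss),
                1e-9 * float(M.sum()))
    balance_error = abs(stored
                        - (joule - boundary_loss - advective_out)) / denom

    capped = bool(np.any(T_new > T_cap))
    report = StepReport(joule_in=joule, boundary_loss=boundary_loss,
                        advective_out=advective_out, stored_change=stored,
                        balance_error=balance_error,
                        picard_iters=iters, dt_used=dt, T_capped=capped,
                        converged=converged)
    return TemperatureField(T=T_new, t=state.t + dt), report


def sensor_temperature(mesh: Mesh, state: TemperatureField) -> float:
    """Volume-averaged temperature over the thermistor region (degC)."""
    m = mesh.region_mask("thermistor")
    if not np.any(m):
        raise ValueError("mesh has no thermistor region")
    w = mesh.cell_weights[m]
    T_cells = mesh.interpolate_to_cells(state.T)[m]
    return float(np.dot(T_cells, w) / w.sum())
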