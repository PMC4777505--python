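"""Ablation-run orchestration: coupled time loop, presets, result summary.

A run executes the staggered (segregated) coupling:

1. build the parametric domain and graded mesh;
2. solve the steady blood/saline flow once -- the velocity field is frozen
   for the whole ablation (constant viscosity, no body forces, nothing
   couples flow to temperature);
3. march the thermal problem at dt (default 0.05 s): update sigma(T), k(T)
   from the element-midpoint temperatures, re-solve the quasi-static
   potential, let the PI controller pick the voltage holding delivered
   power at the set-point, advance the bioheat equation one implicit step;
4. extract the 50 degC-isotherm lesion metrics from the final field.

Half-model quantities (power, lesion volume) are doubled before reporting
in 3D mode; axisymmetric integrals carry the 2*pi*r Jacobian throughout.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .control import (ControllerParams, ControllerState, pi_update,
                      pi_voltage_for_impedance)
from .electrical import cell_sigma, solve_potential
from .flow import FlowParams, FlowState, saline_inlet_velocity, solve_steady_flow
from .geometry import (GeometryConfig, MeshSpec, build_domain, generate_mesh,
                       irrigation_band_area)
from .io_config import RunLog, write_result_json, write_vtu
from .lesion import LesionMetrics, characterize_lesion
from .materials import PhaseChangeParams, TissueBaseline
from .thermal import (ThermalBCs, advance_temperature, initial_temperature,
                      sensor_temperature)

__all__ = ["ProtocolConfig", "ControllerConfig", "MaterialConfig",
           "OutputConfig", "SimulationConfig", "SimulationResult",
           "run_ablation", "scenario_presets"]


class ProtocolConfig(BaseModel):
    """Ablation protocol in clinician units."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    P_target: float = Field(default=35.0, ge=0)   # W
    duration: float = Field(default=30.0, gt=0)   # s
    Q: float = Field(default=13.0, ge=0)          # mL/min
    dt: float = Field(default=0.05, gt=0)         # s


class ControllerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    Kp: float = Field(default=4.78, ge=0)
    Ki: float = Field(default=3.39, ge=0)
    V_max: float = Field(default=150.0, gt=0)

    def to_params(self, P_target: float) -> ControllerParams:
        return ControllerParams(Kp=self.Kp, Ki=self.Ki, P_target=P_target,
                                V_max=self.V_max)


class MaterialConfig(BaseModel):
    """Material overrides: tissue 37 degC baselines and tip handling."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    sigma_o: float = Field(default=0.12, gt=0)
    k_o: float = Field(default=0.531, gt=0)
    clamp_tip_22C: bool = False
    #: whether desiccated tissue recovers conductivity on cooling
    reversible_desiccation: bool = True


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    log_path: str | None = None
    vtu_dir: str | None = None
    snapshot_every_steps: int = Field(default=0, ge=0)


class SimulationConfig(BaseModel):
    """Single source of truth for a run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    mesh: MeshSpec = Field(default_factory=MeshSpec)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    materials: MaterialConfig = Field(default_factory=MaterialConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    config: SimulationConfig
    times: np.ndarray
    V: np.ndarray
    P: np.ndarray
    Z: np.ndarray
    T_sensor: np.ndarray
    T_max_tissue: np.ndarray
    T_max_blood: np.ndarray
    lesion: LesionMetrics
    final_T: np.ndarray
    mesh_stats: dict
    flow: FlowState | None
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "lesion": self.lesion.as_dict(),
            "T_max_tissue_C": float(self.T_max_tissue[-1]),
            "T_max_blood_C": float(self.T_max_blood.max()),
            "T_sensor_final_C": float(self.T_sensor[-1]),
            "impedance_final_ohm": float(self.Z[-1]),
            "power_mean_W": float(self.P.mean()),
            "provenance": self.provenance,
        }
        if self.flow is not None:
            out["flow"] = {
                "mass_balance_error": self.flow.mass_balance_error,
                "reynolds": self.flow.reynolds,
                "u_saline_m_s": self.flow.u_saline,
            }
        return out


class StageError(RuntimeError):
    """Run failure tagged with the pipeline stage that produced it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def run_ablation(config: SimulationConfig) -> SimulationResult:
    """Execute a full constant-power ablation.

    Deterministic: an identical configuration reproduces the scalar logs
    bitwise.  Any stage failure aborts with a stage-tagged error; partial
    logs are flushed.
    """
    geom = config.geometry
    prot = config.protocol
    baseline = TissueBaseline(sigma_o=config.materials.sigma_o,
                              k_o=config.materials.k_o)
    pc = PhaseChangeParams()

    try:
        domain = build_domain(geom)
        mesh = generate_mesh(domain, config.mesh)
    except Exception as exc:
        raise StageError("mesh", exc) from exc

    log = RunLog(config.output.log_path)
    vtu_dir = Path(config.output.vtu_dir) if config.output.vtu_dir else None
    if vtu_dir:
        vtu_dir.mkdir(parents=True, exist_ok=True)

    # ---- steady flow (frozen for the whole run) -----------------------
    flow_state: FlowState | None = None
    u_cells = np.zeros((mesh.n_cells, mesh.dim))
    if prot.Q > 0 or geom.mode == "full3d":
        try:
            area = irrigation_band_area(geom.design, geom.orientation)
            u_s = saline_inlet_velocity(prot.Q, area)
            flow_state = solve_steady_flow(mesh, FlowParams(), u_s,
                                           domain=domain)
            u_cells = flow_state.u[mesh.cells].mean(axis=1)
            blood = mesh.region_mask("blood")
            u_cells[~blood] = 0.0
        except Exception as exc:
            log.close()
            raise StageError("flow", exc) from exc
    u_fingerprint = hashlib.sha256(u_cells.tobytes()).hexdigest()

    # ---- initial state ------------------------------------------------
    bcs = ThermalBCs(irrigation_active=prot.Q > 0,
                     clamp_tip=config.materials.clamp_tip_22C)
    temp = initial_temperature(mesh, bcs)
    blood_nodes = np.unique(mesh.cells[mesh.region_mask("blood")])
    tissue_nodes = np.unique(mesh.cells[mesh.region_mask("tissue")])

    params = config.controller.to_params(prot.P_target)
    try:
        sig0 = cell_sigma(mesh, mesh.interpolate_to_cells(temp.T), baseline)
        es0 = solve_potential(mesh, sig0, 1.0)
        Z0 = es0.Z
    except Exception as exc:
        log.close()
        raise StageError("electrical", exc) from exc
    # seed the integrator near the operating point sqrt(P_target * Z0)
    state = ControllerState()
    if params.Ki > 0 and prot.P_target > 0:
        state.integral_error = math.sqrt(prot.P_target * Z0) / params.Ki

    n_steps = int(round(prot.duration / prot.dt))
    series = {k: np.empty(n_steps) for k in
              ("t", "V", "P", "Z", "T_sensor", "T_max_tissue", "T_max_blood")}
    max_balance_error = 0.0

    try:
        for i in range(n_steps):
            t = (i + 1) * prot.dt
            T_cells = mesh.interpolate_to_cells(temp.T)
            sig = cell_sigma(mesh, T_cells, baseline)
            es = solve_potential(mesh, sig, 1.0)     # unit-voltage solve
            Z = es.Z
            if prot.P_target > 0:
                V = pi_voltage_for_impedance(state, params, Z, prot.dt)
                P = V * V / Z
                state = pi_update(state, params, P, prot.dt)
                state.V_applied = V
            else:
                V, P = 0.0, 0.0
            q_cells = es.q * V * V    # rescale the unit solve
            temp, report = advance_temperature(
                mesh, temp, prot.dt, q_cells, u_cells, bcs, baseline, pc)
            if report.dt_used != prot.dt:
                log.event(t, "step_halved", f"dt={report.dt_used}")
            if report.T_capped:
                log.event(t, "T_cap_exceeded", "")
            if not report.converged:
                log.event(t, "picard_not_converged", "")
            max_balance_error = max(max_balance_error, report.balance_error)

            series["t"][i] = t
            series["V"][i] = V
            series["P"][i] = P
            series["Z"][i] = Z
            series["T_sensor"][i] = sensor_temperature(mesh, temp)
            series["T_max_tissue"][i] = temp.T[tissue_nodes].max()
            series["T_max_blood"][i] = (temp.T[blood_nodes].max()
                                        if len(blood_nodes) else np.nan)
            log.record(t=t, V=V, P=P, Z=Z,
                       T_sensor=series["T_sensor"][i],
                       T_max_tissue=series["T_max_tissue"][i],
                       T_max_blood=series["T_max_blood"][i])
            if (vtu_dir and config.output.snapshot_every_steps
                    and (i + 1) % config.output.snapshot_every_steps == 0):
                write_vtu(mesh, vtu_dir / f"fields_{i + 1:05d}.vtu",
                          point_data={"T": temp.T},
                          cell_data={"q": q_cells, "sigma": sig})
    except StageError:
        log.close()
        raise
    except Exception as exc:
        log.close()
        raise StageError("thermal", exc) from exc
    finally:
        log.close()

    lesion = characterize_lesion(mesh, temp.T)

    assert hashlib.sha256(u_cells.tobytes()).hexdigest() == u_fingerprint, \
        "flow field must be reused unchanged across the time loop"

    mesh_stats = {"n_points": mesh.n_points, "n_cells": mesh.n_cells,
                  "mode": mesh.mode}
    prov = {"config_hash": config.config_hash(), "code_version": __version__,
            "mesh": mesh_stats,
            "max_energy_balance_error": max_balance_error,
            "flow_metadata": (flow_state.metadata if flow_state else {})}
    return SimulationResult(
        config=config, times=series["t"], V=series["V"], P=series["P"],
        Z=series["Z"], T_sensor=series["T_sensor"],
        T_max_tissue=series["T_max_tissue"],
        T_max_blood=series["T_max_blood"], lesion=lesion, final_T=temp.T,
        mesh_stats=mesh_stats, flow=flow_state, provenance=prov)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _recommended_flow(design: str, P: float) -> float:
    """Manufacturer-recommended irrigation rate (mL/min) by power level."""
    if design == "six_hole":
        return 17.0 if P <= 30.0 else 30.0
    return 8.0 if P <= 30.0 else 15.0


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named configurations for the validation and study grids.

    Covers: the validation matrix (2 powers x 2 durations x 2 designs at
    13 mL/min, perpendicular); the irrigation-flow-rate sweeps (0-20
    mL/min at 35 W for both designs and orientations); the power sweeps
    (20-50 W at manufacturer-recommended flow rates); and the
    insertion-depth (contact-pressure) sweep for the multi-hole electrode.
    """
    cat: dict[str, SimulationConfig] = {}

    def geo(design: str, orientation: str, DE: float = 1.0) -> GeometryConfig:
        mode = "axisymmetric" if orientation == "perpendicular" else "full3d"
        return GeometryConfig(design=design, orientation=orientation,
                              insertion_depth=DE, mode=mode)

    short = {"six_hole": "sixhole", "multi_hole": "multihole"}

    # validation matrix at 13 mL/min
    for P in (20.0, 35.0):
        for dur in (30.0, 60.0):
            for design in ("six_hole", "multi_hole"):
                name = f"table2_{P:.0f}W_{dur:.0f}s_{short[design]}"
                cat[name] = SimulationConfig(
                    geometry=geo(design, "perpendicular"),
                    protocol=ProtocolConfig(P_target=P, duration=dur, Q=13.0))
            # unsuffixed alias: the six-hole electrode
            cat[f"table2_{P:.0f}W_{dur:.0f}s"] = \
                cat[f"table2_{P:.0f}W_{dur:.0f}s_sixhole"]

    # irrigation flow-rate sweep, 35 W / 30 s
    for design in ("six_hole", "multi_hole"):
        for orientation, tag in (("perpendicular", "perp"), ("parallel", "par")):
            for Q in (0.0, 5.0, 10.0, 15.0, 20.0):
                name = f"fig4_{short[design]}_{tag}_Q{Q:.0f}"
                cat[name] = SimulationConfig(
                    geometry=geo(design, orientation),
                    protocol=ProtocolConfig(P_target=35.0, duration=30.0, Q=Q))

    # power sweep at recommended flow rates
    for design in ("six_hole", "multi_hole"):
        for P in (20.0, 30.0, 40.0, 50.0):
            name = f"fig7_{short[design]}_{P:.0f}W"
            cat[name] = SimulationConfig(
                geometry=geo(design, "perpendicular"),
                protocol=ProtocolConfig(P_target=P, duration=30.0,
                                        Q=_recommended_flow(design, P)))

    # contact-pressure (insertion-depth) sweep, multi-hole only
    for orientation, tag in (("perpendicular", "perp"), ("parallel", "par")):
        for DE in (0.5, 0.75, 1.0, 1.5):
            name = f"fig9_multihole_{tag}_DE{DE:g}"
            cat[name] = SimulationConfig(
                geometry=geo("multi_hole", orientation, DE),
                protocol=ProtocolConfig(P_target=35.0, duration=30.0, Q=15.0))

    return cat


def coarsen(config: SimulationConfig, factor: float = 3.0) -> SimulationConfig:
    """Derived config with a coarser mesh for desk-scale runs."""
    ms = config.mesh
    new = MeshSpec(min_size_at_interface=ms.min_size_at_interface * factor,
                   growth_rate=ms.growth_rate,
                   far_size=max(ms.far_size, ms.min_size_at_interface * factor * 4),
                   order=ms.order)
    return config.model_copy(update={"mesh": new})
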