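"""Constant-power PI control of the applied RF voltage.

The ablation generator holds delivered power at a set-point by modulating
the applied voltage with a proportional-integral law (Kp = 4.78,
Ki = 3.39; units absorbed into the gains):

    e = P_target - P_delivered
    V = clamp(Kp * e + Ki * int e dt,  0, V_max)

Power is measured synchronously: the voltage applied over a step is
consistent with the power delivered during that same step.  Because the
electrical problem is linear, the plant seen by the controller within one
step is the resistive law P = V^2 / Z with the current impedance Z, so the
synchronous update reduces to a closed-form quadratic for V.  An
anti-windup rule freezes the integrator while the output is saturated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ControllerParams", "ControllerState", "pi_update",
           "pi_voltage_for_impedance", "run_controller_selftest"]


@dataclass(frozen=True)
class ControllerParams:
    Kp: float = 4.78
    Ki: float = 3.39
    P_target: float = 35.0
    V_max: float = 150.0
    V_min: float = 0.0

    def __post_init__(self) -> None:
        if self.Kp < 0 or self.Ki < 0:
            raise ValueError("gains must be non-negative")
        if self.V_min > self.V_max:
            raise ValueError("V_min must not exceed V_max")


@dataclass
class ControllerState:
    """PI memory: integral of the power error and the last applied voltage."""

    integral_error: float = 0.0     # W s
    V_applied: float = 0.0          # V
    history: list = field(default_factory=list)  # (t, P, V, e) tuples
    t: float = 0.0


def _clamp(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def pi_update(state: ControllerState, params: ControllerParams,
              P_measured: float, dt: float) -> ControllerState:
    """One PI step given the power delivered over the current interval.

    e = P_target - P_measured; the integral accumulates e*dt with
    anti-windup (frozen while the clamped output stays saturated in the
    direction the error pushes); V = clamp(Kp e + Ki int_e).
    Deterministic and pure: replaying a history reproduces outputs bitwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if P_measured < 0:
        raise ValueError("P_measured must be non-negative")
    e = params.P_target - P_measured
    integral = state.integral_error + e * dt
    V_raw = params.Kp * e + params.Ki * integral
    V = _clamp(V_raw, params.V_min, params.V_max)
    if V != V_raw:
        # anti-windup: do not integrate into the saturation
        saturated_high = V_raw > params.V_max and e > 0
        saturated_low = V_raw < params.V_min and e < 0
        if saturated_high or saturated_low:
            integral = state.integral_error
            V = _clamp(params.Kp * e + params.Ki * integral,
                       params.V_min, params.V_max)
    t = state.t + dt
    hist = state.history + [(t, P_measured, V, e)]
    return ControllerState(integral_error=integral, V_applied=V,
                           history=hist, t=t)


def pi_voltage_for_impedance(state: ControllerState, params: ControllerParams,
                             Z: float, dt: float) -> float:
    """Voltage of the synchronous PI step against a resistive load Z.

    Solves V = Kp e + Ki (I + e dt) with e = P_target - V^2/Z, i.e. the
    update of :func:`pi_update` evaluated at its same-step fixed point:

        (a/Z) V^2 + V - (a P_target + Ki I) = 0,  a = Kp + Ki dt

    returning the positive root clamped to [V_min, V_max].
    """
    if Z <= 0 or not math.isfinite(Z):
        return params.V_min
    a = params.Kp + params.Ki * dt
    b = a * params.P_target + params.Ki * state.integral_error
    if a == 0:
        return _clamp(state.V_applied, params.V_min, params.V_max)
    disc = 1.0 + 4.0 * (a / Z) * b
    if disc < 0:
        return params.V_min
    V = (math.sqrt(disc) - 1.0) / (2.0 * a / Z)
    return _clamp(V, params.V_min, params.V_max)


def step_against_plant(state: ControllerState, params: ControllerParams,
                       Z: float, dt: float) -> tuple[ControllerState, float]:
    """Advance the closed loop one step against the plant P = V^2/Z."""
    V = pi_voltage_for_impedance(state, params, Z, dt)
    P = V * V / Z
    new = pi_update(state, params, P, dt)
    new.V_applied = V
    return new, P


def run_controller_selftest(params: ControllerParams | None = None,
                            Z: float = 140.0, duration: float = 30.0,
                            dt: float = 0.05, settle: float = 5.0,
                            Z_step: tuple[float, float] | None = None) -> dict:
    """Closed-loop run against the analytic resistive plant.

    Starts from a cold state (V = 0, empty integrator) and reports settling
    time (first entry into the +/-3% band that is never left), overshoot,
    and the maximum relative power deviation after the ``settle`` window.
    ``Z_step = (t_step, Z_new)`` optionally applies a mid-run impedance
    change.  Compliance means staying within 3% of target after settling.
    """
    params = params or ControllerParams()
    state = ControllerState()
    n = int(round(duration / dt))
    t_arr, p_arr, v_arr = [], [], []
    Z_cur = Z
    for i in range(n):
        t = (i + 1) * dt
        if Z_step is not None and t >= Z_step[0]:
            Z_cur = Z_step[1]
        state, P = step_against_plant(state, params, Z_cur, dt)
        t_arr.append(t)
        p_arr.append(P)
        v_arr.append(state.V_applied)

    Pt = params.P_target
    rel = [abs(p - Pt) / Pt if Pt > 0 else abs(p) for p in p_arr]
    tail = [r for t, r in zip(t_arr, rel) if t > settle]
    max_dev_after = max(tail) if tail else float("nan")
    # settling: last time the trajectory is outside the 3% band
    outside = [t for t, r in zip(t_arr, rel) if r > 0.03]
    settling_time = outside[-1] if outside else 0.0
    overshoot = max((p - Pt) / Pt for p in p_arr) if Pt > 0 else 0.0
    steady_error = abs(p_arr[-1] - Pt) / Pt if Pt > 0 else abs(p_arr[-1])
    return {
        "t": t_arr, "P": p_arr, "V": v_arr,
        "settling_time_s": settling_time,
        "overshoot_frac": overshoot,
        "max_rel_deviation_after_settle": max_dev_after,
        "steady_state_rel_error": steady_error,
        "compliant_3pct": bool(max_dev_after <= 0.03),
    }
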