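"""Material properties for the five model regions.

Electrical/thermal constants for the platinum-iridium electrode, the glass
fiber thermistor bead, the polyurethane catheter shaft, circulating blood and
myocardium, plus the temperature laws of cardiac tissue: an exponential rise
of electrical conductivity (+1.5 %/degC) up to 100 degC followed by a linear
four-decade desiccation drop over 100-105 degC, a linear rise of thermal
conductivity plateauing at 100 degC, and the enthalpy-method apparent heat
capacity that represents the latent heat of water vaporization as a large
capacity over the 99-100 degC band.

All temperatures are in degC; other quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MaterialProps",
    "TissueBaseline",
    "PhaseChangeParams",
    "REGION_PROPS",
    "sigma_tissue",
    "k_tissue",
    "apparent_volumetric_heat_capacity",
    "props_to_table",
    "props_from_table",
]


@dataclass(frozen=True)
class MaterialProps:
    """Constant properties of one model region.

    Attributes
    ----------
    region_name:
        One of ``electrode``, ``thermistor``, ``catheter``, ``blood``,
        ``tissue`` (liquid phase) or ``tissue_gas`` (post-vaporization).
    sigma:
        Electrical conductivity, S/m.
    k:
        Thermal conductivity, W/(m K).
    rho:
        Density, kg/m^3.
    c:
        Specific heat, J/(kg K).
    """

    region_name: str
    sigma: float
    k: float
    rho: float
    c: float

    def __post_init__(self) -> None:
        for name in ("sigma", "k", "rho", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"MaterialProps.{name} must be strictly positive, got {v!r}"
                )

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c, J/(m^3 K)."""
        return self.rho * self.c


#: Reference property set.  Tissue sigma/k entries hold the 37 degC baseline
#: values; the temperature laws below modify them at run time.
REGION_PROPS: dict[str, MaterialProps] = {
    "electrode": MaterialProps("electrode", 4.6e6, 71.0, 21500.0, 132.0),
    "thermistor": MaterialProps("thermistor", 1e-5, 0.038, 32.0, 835.0),
    "catheter": MaterialProps("catheter", 1e-5, 0.026, 70.0, 1045.0),
    "blood": MaterialProps("blood", 0.667, 0.54, 1000.0, 4180.0),
    "tissue": MaterialProps("tissue", 0.12, 0.531, 1060.0, 3111.0),
    "tissue_gas": MaterialProps("tissue_gas", 0.12, 0.531, 370.44, 2155.92),
}


@dataclass(frozen=True)
class TissueBaseline:
    """Baseline (37 degC) conductivities of cardiac tissue.

    ``sigma_o`` is the single calibration knob of the model: it is chosen so
    the initial impedance of the whole system matches the in vitro value of
    about 140 ohm.
    """

    sigma_o: float = 0.12
    k_o: float = 0.531

    def __post_init__(self) -> None:
        if self.sigma_o <= 0 or self.k_o <= 0:
            raise ValueError("TissueBaseline values must be positive")


@dataclass(frozen=True)
class PhaseChangeParams:
    """Enthalpy-method parameters for tissue vaporization.

    The latent heat ``H_fg`` is stored volumetrically: 2257 kJ/kg (water at
    100 degC) x 958 kg/m^3 = 2.162e9 J/m^3.  The water-content fraction ``C``
    multiplies it inside the apparent-capacity branch, so the latent plateau
    contributes H_fg * C over the ``T_lower``..``T_upper`` band.
    """

    T_lower: float = 99.0
    T_upper: float = 100.0
    H_fg: float = 2.162e9
    C: float = 0.75
    rho_l: float = 1060.0
    c_l: float = 3111.0
    rho_g: float = 370.44
    c_g: float = 2155.92

    def __post_init__(self) -> None:
        if not self.T_lower < self.T_upper:
            raise ValueError("require T_lower < T_upper")
        if not 0.0 < self.C <= 1.0:
            raise ValueError("water content C must lie in (0, 1]")
        if self.H_fg * self.C <= self.rho_l * self.c_l:
            raise ValueError("latent plateau must dominate sensible capacity")

    @property
    def slowdown_factor(self) -> float:
        """Ratio of latent-band to liquid-phase apparent capacity.

        This is the factor by which the heating rate of an insulated tissue
        block drops when it enters the vaporization band (~491 for defaults).
        """
        return (self.H_fg * self.C) / (self.rho_l * self.c_l)


def sigma_tissue(T, sigma_o: float = 0.12):
    """Electrical conductivity of cardiac tissue, S/m.

    Piecewise in temperature: ``sigma_o * exp(0.015 (T - 37))`` up to
    100 degC (a +1.5 %/degC growth reaching sigma_o*2.5728 at 100), then a
    linear four-decade drop ``sigma_o*(2.5728 - 0.5145 (T - 100))`` over
    100-105 degC modelling desiccation, constant ``sigma_o*2.5728e-4``
    above.  The middle branch is clamped below at the desiccated value so it
    stays positive under floating-point evaluation near 105 degC.

    Accepts scalars or arrays; vectorized and pure.
    """
    if sigma_o <= 0 or not np.isfinite(sigma_o):
        raise ValueError(f"sigma_o must be positive, got {sigma_o!r}")
    T = np.asarray(T, dtype=float)
    floor = sigma_o * 2.5728e-4
    mid = np.maximum(sigma_o * 2.5728 - sigma_o * 0.5145 * (T - 100.0), floor)
    out = np.where(
        T <= 100.0,
        sigma_o * np.exp(0.015 * (np.minimum(T, 100.0) - 37.0)),
        np.where(T <= 105.0, mid, floor),
    )
    return out if out.ndim else float(out)


def k_tissue(T, k_o: float = 0.531):
    """Thermal conductivity of cardiac tissue, W/(m K).

    ``k_o + 0.0012 (T - 37)`` up to 100 degC, constant ``k_o + 0.0756``
    above; continuous and non-decreasing.
    """
    if k_o <= 0 or not np.isfinite(k_o):
        raise ValueError(f"k_o must be positive, got {k_o!r}")
    T = np.asarray(T, dtype=float)
    out = k_o + 0.0012 * (np.minimum(T, 100.0) - 37.0)
    return out if out.ndim else float(out)


def apparent_volumetric_heat_capacity(T, pc: PhaseChangeParams | None = None):
    """Apparent volumetric heat capacity d(rho h)/dT of tissue, J/(m^3 K).

    Three branches: liquid-phase ``rho_l c_l`` for T <= 99 degC, latent
    plateau ``H_fg C`` for 99 < T <= 100 degC, gas-phase ``rho_g c_g``
    above.  Total on finite T (temperatures below 0 degC reuse the liquid
    branch).
    """
    pc = pc or PhaseChangeParams()
    T = np.asarray(T, dtype=float)
    out = np.where(
        T <= pc.T_lower,
        pc.rho_l * pc.c_l,
        np.where(T <= pc.T_upper, pc.H_fg * pc.C, pc.rho_g * pc.c_g),
    )
    return out if out.ndim else float(out)


def volumetric_enthalpy(T, pc: PhaseChangeParams | None = None):
    """Volumetric enthalpy rho*h of tissue, J/m^3 (zero datum at 0 degC).

    The antiderivative of :func:`apparent_volumetric_heat_capacity`:
    sensible liquid heat up to 99 degC, the latent ramp H_fg*C across the
    99-100 degC band, sensible gas heat above.  Used by the thermal solver
    to form chord (secant) capacities that conserve latent heat exactly
    when a node crosses the band within one time step.
    """
    pc = pc or PhaseChangeParams()
    T = np.asarray(T, dtype=float)
    cl = pc.rho_l * pc.c_l
    cb = pc.H_fg * pc.C
    cg = pc.rho_g * pc.c_g
    H99 = cl * pc.T_lower
    H100 = H99 + cb * (pc.T_upper - pc.T_lower)
    out = np.where(
        T <= pc.T_lower,
        cl * T,
        np.where(T <= pc.T_upper,
                 H99 + cb * (T - pc.T_lower),
                 H100 + cg * (T - pc.T_upper)),
    )
    return out if out.ndim else float(out)


def props_to_table(props: dict[str, MaterialProps] | None = None) -> dict:
    """Serialize a property set to a plain dict (sigma, k, rho, c order)."""
    props = props or REGION_PROPS
    return {
        name: {k: v for k, v in asdict(p).items() if k != "region_name"}
        for name, p in props.items()
    }


def props_from_table(table: dict) -> dict[str, MaterialProps]:
    """Inverse of :func:`props_to_table`; validates positivity."""
    return {
        name: MaterialProps(region_name=name, **row) for name, row in table.items()
    }
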