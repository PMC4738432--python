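"""Rothermel surface fire-spread model, single fuel class.

The classic steady-state spread model for a homogeneous surface fuel bed:

    R = I_R * xi * (1 + phi_w + phi_s) / (rho_b * eps * Q_ig)

where I_R is the reaction intensity, xi the propagating flux ratio, phi_w
and phi_s the wind and slope factors, rho_b the fuel-bed bulk density, eps
the effective heating number and Q_ig the heat of preignition.  The grass
clump is treated as a single dead fuel class parameterized entirely from
the five measured plant traits: SA/V ratio, effective heat of combustion,
moisture content, height (fuel depth) and fuel load.

Internally the equations are evaluated in the source model's imperial units
(ft, lb, Btu, min) — the form in which the coefficients were published and
in which the reference R implementation operates — with SI conversions at
the boundary.  The reaction-velocity exponent uses the revised form
A = 133 * sigma^-0.7913 and net fuel load w_n = w0 / (1 + S_T).  Spread
rate is returned in m/min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from grassflam.config import RothermelEnv

logger = logging.getLogger(__name__)

# unit conversions (SI -> imperial), exact from the definitions of the
# foot (0.3048 m), pound (0.45359237 kg) and Btu (1055.05585262 J)
FT_PER_M = 1.0 / 0.3048
BTU_LB_PER_KJ_KG = 0.45359237 / 1.05505585262
LB_FT2_PER_KG_M2 = 0.3048**2 / 0.45359237
LB_FT3_PER_KG_M3 = 0.3048**3 / 0.45359237
FT_MIN_PER_M_S = 60.0 / 0.3048


@dataclass
class FuelModel:
    """Single-class fuel bed in SI units."""

    sav_m2_m3: float                 # surface-area-to-volume ratio (1/m)
    heat_content_kj_kg: float        # leaf EHoC
    fuel_load_kg_m2: float           # oven-dry load
    fuel_depth_m: float              # plant height
    moisture_fraction: float         # g water / g dry
    moisture_of_extinction: float = 0.25
    total_mineral_content: float = 0.0555
    effective_mineral_content: float = 0.010
    particle_density_kg_m3: float = 512.6

    def validate(self) -> None:
        for name in ("sav_m2_m3", "heat_content_kj_kg", "fuel_load_kg_m2",
                     "fuel_depth_m", "particle_density_kg_m3", "moisture_of_extinction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.moisture_fraction < 0:
            raise ValueError("moisture_fraction must be >= 0")
        for name in ("total_mineral_content", "effective_mineral_content"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class RothermelResult:
    """Spread rate plus every intermediate of the equation chain.

    Dimensionless quantities are unit-free; dimensional intermediates are
    reported in SI (reaction intensity kW/m^2, bulk density kg/m^3, heat of
    preignition kJ/kg, spread rate m/min).
    """

    spread_rate_m_min: float
    reaction_intensity_kw_m2: float
    optimum_reaction_velocity_min: float
    moisture_damping: float
    mineral_damping: float
    propagating_flux_ratio: float
    packing_ratio: float
    optimum_packing_ratio: float
    bulk_density_kg_m3: float
    effective_heating_number: float
    heat_of_preignition_kj_kg: float
    wind_factor: float
    slope_factor: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def moisture_damping_coefficient(moisture: float, mx: float) -> float:
    """Cubic moisture damping eta_M in the relative moisture r = M_f / M_x.

    eta_M = 1 - 2.59 r + 5.11 r^2 - 3.52 r^3, clamped to 0 for r >= 1 (the
    polynomial itself vanishes at r = 1): fuel wetter than the moisture of
    extinction cannot sustain spread.
    """
    r = moisture / mx
    if r >= 1.0:
        return 0.0
    eta = 1.0 - 2.59 * r + 5.11 * r**2 - 3.52 * r**3
    return max(0.0, min(1.0, eta))


def spread_rate(fm: FuelModel, wind_m_s: float = 0.0, slope_fraction: float = 0.0) -> RothermelResult:
    """Forward rate of spread (m/min) with all intermediate quantities.

    ``slope_fraction`` is tan of the slope angle (rise/run); wind is the
    midflame wind speed in m/s.
    """
    fm.validate()
    if wind_m_s < 0 or slope_fraction < 0:
        raise ValueError("wind and slope must be >= 0")

    # SI -> imperial
    sigma = fm.sav_m2_m3 / FT_PER_M            # 1/m -> 1/ft
    w0 = fm.fuel_load_kg_m2 * LB_FT2_PER_KG_M2
    delta = fm.fuel_depth_m * FT_PER_M
    h = fm.heat_content_kj_kg * BTU_LB_PER_KJ_KG
    rho_p = fm.particle_density_kg_m3 * LB_FT3_PER_KG_M3
    mf = fm.moisture_fraction
    mx = fm.moisture_of_extinction
    st = fm.total_mineral_content
    se = fm.effective_mineral_content
    u = wind_m_s * FT_MIN_PER_M_S

    rho_b = w0 / delta
    beta = rho_b / rho_p
    beta_op = 3.348 * sigma ** (-0.8189)
    rel_packing = beta / beta_op

    gamma_max = sigma**1.5 / (495.0 + 0.0594 * sigma**1.5)
    a_exp = 133.0 * sigma ** (-0.7913)
    gamma = gamma_max * rel_packing**a_exp * math.exp(a_exp * (1.0 - rel_packing))

    w_n = w0 / (1.0 + st)
    eta_m = moisture_damping_coefficient(mf, mx)
    eta_s = min(1.0, 0.174 * se ** (-0.19))

    i_r = gamma * w_n * h * eta_m * eta_s                      # Btu/ft^2/min
    xi = math.exp((0.792 + 0.681 * sigma**0.5) * (beta + 0.1)) / (192.0 + 0.2595 * sigma)

    eps = math.exp(-138.0 / sigma)
    q_ig = 250.0 + 1116.0 * mf                                 # Btu/lb

    c = 7.47 * math.exp(-0.133 * sigma**0.55)
    b = 0.02526 * sigma**0.54
    e = 0.715 * math.exp(-3.59e-4 * sigma)
    phi_w = 0.0 if u == 0 else c * u**b * rel_packing ** (-e)
    phi_s = 5.275 * beta ** (-0.3) * slope_fraction**2

    r_ft_min = i_r * xi * (1.0 + phi_w + phi_s) / (rho_b * eps * q_ig)
    if eta_m == 0.0:
        r_ft_min = 0.0
        logger.info("spread_rate: moisture %.3f >= extinction %.3f, no spread", mf, mx)

    return RothermelResult(
        spread_rate_m_min=r_ft_min * 0.3048,
        reaction_intensity_kw_m2=i_r * 0.189275,               # Btu/ft^2/min -> kW/m^2
        optimum_reaction_velocity_min=gamma,
        moisture_damping=eta_m,
        mineral_damping=eta_s,
        propagating_flux_ratio=xi,
        packing_ratio=beta,
        optimum_packing_ratio=beta_op,
        bulk_density_kg_m3=rho_b / LB_FT3_PER_KG_M3,
        effective_heating_number=eps,
        heat_of_preignition_kj_kg=q_ig * 2.326,
        wind_factor=phi_w,
        slope_factor=phi_s,
    )


def build_fuel_model(ind_traits: "pd.Series | dict", env: Optional[RothermelEnv] = None) -> FuelModel:
    """Assemble a fuel model from one individual's trait record.

    Converts the field units into SI: SA/V per mm -> m^2/m^3 (x1000), fuel
    load g/cm^2 -> kg/m^2 (x10), height cm -> m, EHoC kJ/g -> kJ/kg (x1000).
    Environmental/non-measured parameters come from ``env``.
    """
    env = env or RothermelEnv()
    needed = ["leaf_sav_mm", "leaf_ehoc_kj_g", "fuel_load_g_cm2", "height_cm", "moisture_content"]
    for name in needed:
        val = ind_traits.get(name) if isinstance(ind_traits, dict) else ind_traits.get(name, None)
        if val is None or (isinstance(val, float) and not np.isfinite(val)):
            raise ValueError(f"missing trait {name!r} for fuel model")
    get = ind_traits.get if isinstance(ind_traits, dict) else lambda k: ind_traits[k]
    return FuelModel(
        sav_m2_m3=float(get("leaf_sav_mm")) * 1000.0,
        heat_content_kj_kg=float(get("leaf_ehoc_kj_g")) * 1000.0,
        fuel_load_kg_m2=float(get("fuel_load_g_cm2")) * 10.0,
        fuel_depth_m=float(get("height_cm")) / 100.0,
        moisture_fraction=float(get("moisture_content")),
        moisture_of_extinction=env.moisture_of_extinction,
        total_mineral_content=env.total_mineral_content,
        effective_mineral_content=env.effective_mineral_content,
        particle_density_kg_m3=env.particle_density_kg_m3,
    )


SENSITIVITY_TRAITS = {
    "sav": "sav_m2_m3",
    "heat_content": "heat_content_kj_kg",
    "fuel_load": "fuel_load_kg_m2",
    "fuel_depth": "fuel_depth_m",
    "moisture": "moisture_fraction",
}


def sensitivity(fm: FuelModel, trait: str, grid: Iterable[float],
                wind_m_s: float = 0.0, slope_fraction: float = 0.0) -> pd.DataFrame:
    """Spread rate and intermediates along a grid of one fuel parameter."""
    if trait not in SENSITIVITY_TRAITS:
        raise ValueError(f"trait must be one of {sorted(SENSITIVITY_TRAITS)}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    attr = SENSITIVITY_TRAITS[trait]
    rows = []
    for val in grid:
        fm_i = FuelModel(**{**fm.__dict__, attr: float(val)})
        res = spread_rate(fm_i, wind_m_s=wind_m_s, slope_fraction=slope_fraction)
        rows.append({"trait": trait, "value": float(val), **res.as_dict()})
    return pd.DataFrame(rows)
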