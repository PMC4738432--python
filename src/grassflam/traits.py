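"""The five explanatory plant traits.

* biomass quantity — total above-ground dry mass of the clump (g)
* biomass density  — slope of log10 cumulative dry biomass against vertical
  height, a proxy for how densely biomass is packed along the tiller
* moisture content — (fresh - dry) / dry mass, g water per g dry biomass
* leaf SA/V ratio  — surface area / volume of the leaf lamina, per mm
* leaf EHoC        — effective heat of combustion of pyrolysate vapours, kJ/g

plus plant height, cover area and fuel load (= biomass quantity / cover
area), which parameterize the fire-spread model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLOWED_INTERVALS_CM = (2.5, 5.0, 10.0, 15.0)

#: traits aggregated per species, in the order reported downstream
TRAIT_NAMES = [
    "biomass_quantity_g",
    "density_slope",
    "moisture_content",
    "leaf_sav_mm",
    "leaf_ehoc_kj_g",
    "height_cm",
    "cover_area_cm2",
    "fuel_load_g_cm2",
]


@dataclass
class VerticalProfile:
    """Per-interval dry (and optionally fresh) masses along plant height.

    ``interval_top_cm`` are the upper boundaries of equal-length intervals
    counted from ground level; interval k holds the biomass cut between
    heights (k-1)*L and k*L.
    """

    individual_id: str
    interval_top_cm: np.ndarray
    interval_dry_mass_g: np.ndarray
    interval_fresh_mass_g: Optional[np.ndarray] = None
    species_id: str = ""

    def __post_init__(self) -> None:
        self.interval_top_cm = np.asarray(self.interval_top_cm, dtype=float)
        self.interval_dry_mass_g = np.asarray(self.interval_dry_mass_g, dtype=float)
        if self.interval_fresh_mass_g is not None:
            self.interval_fresh_mass_g = np.asarray(self.interval_fresh_mass_g, dtype=float)

    def validate(self, allowed_intervals=ALLOWED_INTERVALS_CM) -> None:
        h = self.interval_top_cm
        if np.any(np.diff(h) <= 0):
            raise ValueError(f"profile {self.individual_id}: heights not strictly increasing")
        if np.any(self.interval_dry_mass_g < 0):
            raise ValueError(f"profile {self.individual_id}: negative interval mass")
        widths = np.diff(np.concatenate([[0.0], h]))
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError(f"profile {self.individual_id}: unequal interval lengths")
        if allowed_intervals is not None and not any(
            np.isclose(widths[0], a) for a in allowed_intervals
        ):
            raise ValueError(
                f"profile {self.individual_id}: interval length {widths[0]:.3g} cm "
                f"not in {allowed_intervals}"
            )
        if h.size < 5:
            warnings.warn(
                f"profile {self.individual_id}: only {h.size} intervals (< 5)",
                stacklevel=2,
            )

    @property
    def total_dry_mass_g(self) -> float:
        return float(self.interval_dry_mass_g.sum())


@dataclass
class DensitySlopeFit:
    """OLS fit of logged cumulative biomass against height."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_dropped: int
    mode: str


def moisture_content(fresh_mass_g: float, dry_mass_g: float, tol: float = 0.01) -> float:
    """Gravimetric moisture content (fresh - dry) / dry, in g water / g dry.

    ``fresh < dry`` within ``tol`` (relative) is treated as measurement noise
    and clamped to 0; beyond it the pair is rejected.
    """
    if dry_mass_g <= 0:
        raise ValueError("dry_mass_g must be positive")
    if fresh_mass_g < dry_mass_g * (1 - tol):
        raise ValueError(
            f"fresh mass {fresh_mass_g} below dry mass {dry_mass_g} beyond {tol:.0%} tolerance"
        )
    return max(0.0, (fresh_mass_g - dry_mass_g) / dry_mass_g)


def leaf_sav(mean_leaf_area_mm2: float, mean_thickness_mm: float) -> float:
    """Leaf surface-area-to-volume ratio (per mm) under a flat-slab model.

    The lamina is treated as a thin two-sided slab: SA = 2*area,
    V = area*thickness, so SA/V = 2/thickness and the area cancels (edge
    area is neglected).  Thickness should be the mean of several leaves.
    """
    if mean_leaf_area_mm2 <= 0 or mean_thickness_mm <= 0:
        raise ValueError("leaf area and thickness must be positive")
    return 2.0 / mean_thickness_mm


def density_slope(profile: VerticalProfile, mode: str = "log-linear") -> DensitySlopeFit:
    """Slope of log10 cumulative dry biomass against vertical height.

    Cumulative mass is accumulated from ground level upward and evaluated at
    interval-top heights.  ``log-linear`` regresses log10(mass) on height in
    cm (the default); ``log-log`` regresses log10(mass) on log10(height),
    giving a dimensionless power-law exponent.  High slopes mean biomass
    concentrated low on the plant (densely packed fuel).
    """
    if mode not in ("log-linear", "log-log"):
        raise ValueError(f"unknown mode {mode!r}")
    h = profile.interval_top_cm
    cum = np.cumsum(profile.interval_dry_mass_g)
    keep = cum > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"profile {profile.individual_id}: dropped {n_dropped} zero-mass point(s)",
            stacklevel=2,
        )
    h, cum = h[keep], cum[keep]
    if h.size < 3:
        raise ValueError(f"profile {profile.individual_id}: fewer than 3 usable points")
    x = h if mode == "log-linear" else np.log10(h)
    y = np.log10(cum)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    return DensitySlopeFit(float(slope), float(intercept), r2, int(h.size), n_dropped, mode)


def ehoc_mean(heat_release_kj: np.ndarray, sample_mass_g: np.ndarray) -> float:
    """Mean effective heat of combustion over replicates, kJ per g.

    Each replicate's total heat release is divided by its sample mass; the
    replicate values are then averaged (duplicates per individual in the
    study design).
    """
    heat = np.atleast_1d(np.asarray(heat_release_kj, dtype=float))
    mass = np.atleast_1d(np.asarray(sample_mass_g, dtype=float))
    if np.any(mass <= 0):
        raise ValueError("sample masses must be positive")
    return float(np.mean(heat / mass))


def ehoc_by_individual(ehoc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual EHoC from the replicate table (mean of duplicates)."""
    rows = []
    for (sp, ind), grp in ehoc_table.groupby(["species_id", "individual_id"], sort=False):
        rows.append(
            {
                "species_id": sp,
                "individual_id": ind,
                "leaf_ehoc_kj_g": ehoc_mean(
                    grp["heat_release_kj"].to_numpy(), grp["sample_mass_g"].to_numpy()
                ),
            }
        )
    return pd.DataFrame(rows)


def individual_traits(
    trait_table: pd.DataFrame,
    profiles: list[VerticalProfile],
    ehoc_table: Optional[pd.DataFrame] = None,
    density_mode: str = "log-linear",
) -> pd.DataFrame:
    """Assemble the full per-individual trait set.

    Moisture content and biomass quantity come from the fresh/dry clump-total
    masses; the density slope from each individual's vertical profile; SA/V
    from leaf area and thickness; EHoC from the replicate table (species mean
    imputed for individuals not sampled for calorimetry, mirroring the
    3-individuals-per-species calorimetry subsample).
    """
    fresh = trait_table[trait_table["state"] == "fresh"].set_index(["species_id", "individual_id"])
    prof_map = {(p.species_id, p.individual_id): p for p in profiles}
    ehoc_ind = ehoc_by_individual(ehoc_table) if ehoc_table is not None else None

    rows = []
    for (sp, ind), row in fresh.iterrows():
        rec = {"species_id": sp, "individual_id": ind}
        rec["moisture_content"] = moisture_content(row["fresh_mass_g"], row["dry_mass_g"])
        rec["leaf_sav_mm"] = leaf_sav(row["leaf_area_mm2"], row["leaf_thickness_mm"])
        rec["height_cm"] = row["height_cm"]
        rec["cover_area_cm2"] = row["cover_area_cm2"]
        prof = prof_map.get((sp, ind))
        if prof is not None:
            rec["biomass_quantity_g"] = prof.total_dry_mass_g
            rec["density_slope"] = density_slope(prof, mode=density_mode).slope
        else:
            rec["biomass_quantity_g"] = row["dry_mass_g"]
            rec["density_slope"] = np.nan
        rec["fuel_load_g_cm2"] = rec["biomass_quantity_g"] / rec["cover_area_cm2"]
        rows.append(rec)
    out = pd.DataFrame(rows)

    if ehoc_ind is not None:
        out = out.merge(ehoc_ind, on=["species_id", "individual_id"], how="left")
        sp_mean = out.groupby("species_id")["leaf_ehoc_kj_g"].transform("mean")
        out["leaf_ehoc_kj_g"] = out["leaf_ehoc_kj_g"].fillna(sp_mean)
    else:
        out["leaf_ehoc_kj_g"] = np.nan
    return out[["species_id", "individual_id"] + TRAIT_NAMES]


def aggregate_species(ind_traits: pd.DataFrame, trait_cols: Optional[list[str]] = None) -> pd.DataFrame:
    """Species means and coefficients of variation (CV, %) per trait."""
    trait_cols = trait_cols or [c for c in TRAIT_NAMES if c in ind_traits.columns]
    g = ind_traits.groupby("species_id", sort=True)[trait_cols]
    means = g.mean()
    sds = g.std(ddof=1)
    cvs = 100.0 * sds / means
    means.columns = [f"{c}_mean" for c in trait_cols]
    cvs.columns = [f"{c}_cv_pct" for c in trait_cols]
    out = pd.concat([means, cvs], axis=1).reset_index()
    logger.info("aggregate_species: %d species from %d individuals", len(out), len(ind_traits))
    return out
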