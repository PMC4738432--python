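"""Flammability components from burn records.

Leaf scale (epiradiator tests): time to ignition (ignitability), flaming
time (sustainability) and average combustion rate = sample mass / flaming
time (combustibility), with fresh-minus-dry differences quantifying the
moisture effect.

Plant scale (clump burns on a balance): the mass-loss curve is fitted with a
Boltzmann sigmoid

    m(t) = A2 + (A1 - A2) / (1 + exp((t - t0) / dx))

whose width parameter dx is the plant-scale flaming time; the maximum
combustion rate is the |slope| of an OLS line through the observations
within +/- 3 s of the inflection t0.  Because maximum rate scales with
sample mass, species are standardized by regressing log10(rate) on
log10(mass burned): the intercept is the species' intrinsic combustibility,
and extrapolating a common across-species slope to the species mean total
biomass yields whole-plant combustion rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from grassflam.io import LeafBurnEvents, MassLossSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- leaf scale

@dataclass
class LeafFlammability:
    individual_id: str
    state: str
    tti_s: float
    ft_s: float
    combustion_rate_g_s: float
    excluded: bool = False
    reason: str = ""
    species_id: str = ""


def leaf_metrics(events: LeafBurnEvents) -> LeafFlammability:
    """TTI, flaming time and average combustion rate from one leaf test."""
    events.validate()
    tti = events.t_first_flame_s - events.t_application_s
    ft = events.t_flame_out_s - events.t_first_flame_s
    if ft <= 0:
        return LeafFlammability(
            events.individual_id, events.state, tti, 0.0, np.nan,
            excluded=True, reason="no sustained flaming", species_id=events.species_id,
        )
    return LeafFlammability(
        events.individual_id, events.state, tti, ft, events.sample_mass_g / ft,
        species_id=events.species_id,
    )


def leaf_metrics_table(events_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`leaf_metrics` over a leaf-events table."""
    recs = []
    for row in events_df.itertuples(index=False):
        ev = LeafBurnEvents(
            individual_id=row.individual_id, state=row.state,
            sample_mass_g=row.sample_mass_g, t_application_s=row.t_application_s,
            t_first_flame_s=row.t_first_flame_s, t_flame_out_s=row.t_flame_out_s,
            species_id=row.species_id,
        )
        recs.append(leaf_metrics(ev).__dict__)
    out = pd.DataFrame(recs)
    n_excl = int(out["excluded"].sum())
    logger.info("leaf_metrics: %d records, %d excluded", len(out), n_excl)
    return out


METRICS = ["tti_s", "ft_s", "combustion_rate_g_s"]


def moisture_effect(leaf_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fresh-minus-dry differences per individual, averaged per species.

    Returns ``(per_individual, per_species)``.  Differences are fresh - dry
    for each leaf metric; relative columns (``*_rel``) give fresh/dry - 1,
    so a fresh sample taking 42% longer to ignite appears as
    ``tti_s_rel = 0.42``.  Unpaired individuals are excluded (logged).
    """
    keep = leaf_df[~leaf_df["excluded"]]
    fresh = keep[keep["state"] == "fresh"].set_index(["species_id", "individual_id"])
    dry = keep[keep["state"] == "dry"].set_index(["species_id", "individual_id"])
    paired = fresh.index.intersection(dry.index)
    n_unpaired = len(fresh.index.symmetric_difference(dry.index))
    if n_unpaired:
        logger.info("moisture_effect: excluded %d unpaired records", n_unpaired)
    rows = []
    for key in paired:
        rec = {"species_id": key[0], "individual_id": key[1]}
        for m in METRICS:
            f, d = fresh.loc[key, m], dry.loc[key, m]
            rec[f"{m}_diff"] = f - d
            rec[f"{m}_rel"] = f / d - 1.0 if d != 0 else np.nan
        rows.append(rec)
    cols = (["species_id", "individual_id"]
            + [f"{m}{suffix}" for m in METRICS for suffix in ("_diff", "_rel")])
    per_ind = pd.DataFrame(rows, columns=cols)
    per_sp = per_ind.groupby("species_id", sort=True).mean(numeric_only=True).reset_index()
    return per_ind, per_sp


# --------------------------------------------------------------- plant scale

@dataclass
class BoltzmannFit:
    A1: float            # upper asymptote (g)
    A2: float            # lower asymptote (g)
    t0: float            # inflection time (s)
    dx: float            # width parameter (s)
    rss: float
    r_squared: float
    converged: bool


def boltzmann(t: np.ndarray, A1: float, A2: float, t0: float, dx: float) -> np.ndarray:
    """Falling Boltzmann sigmoid: A1 at t << t0, A2 at t >> t0."""
    return A2 + (A1 - A2) / (1.0 + np.exp((t - t0) / dx))


def _initial_guesses(time: np.ndarray, mass: np.ndarray, n_starts: int) -> list[tuple]:
    n = time.size
    head = float(np.median(mass[: max(3, n // 10)]))
    tail = float(np.median(mass[-max(3, n // 10):]))
    drop = head - tail
    # inflection guess: steepest decline of a lightly smoothed curve
    k = max(1, n // 50)
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    smooth = np.convolve(mass, kernel, mode="same")
    i0 = int(np.argmin(np.gradient(smooth, time)))
    t0_guess = float(time[i0])
    # 10-90% transit time of the drop maps to 2*ln(9)*dx for a Boltzmann
    lo, hi = tail + 0.1 * drop, tail + 0.9 * drop
    below_hi = np.nonzero(smooth < hi)[0]
    below_lo = np.nonzero(smooth < lo)[0]
    if below_hi.size and below_lo.size and below_lo[0] > below_hi[0]:
        transit = float(time[below_lo[0]] - time[below_hi[0]])
    else:
        transit = float((time[-1] - time[0]) / 4)
    dx_guess = max(transit / (2 * np.log(9.0)), 2 * float(np.median(np.diff(time))))
    guesses = [(head, tail, t0_guess, dx_guess)]
    span = float(time[-1] - time[0])
    for frac in np.linspace(-0.15, 0.15, max(0, n_starts - 1)):
        guesses.append((head, tail, t0_guess + frac * span, dx_guess))
    return guesses


def fit_boltzmann(series: MassLossSeries, n_starts: int = 5,
                  r2_threshold: Optional[float] = None) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit to one mass-loss series.

    Multi-start initialization: the inflection starts at the steepest
    observed drop (perturbed across starts), the width from the 10-90%
    transit time, asymptotes from head/tail medians.  ``converged`` is False
    when the optimizer fails or, if ``r2_threshold`` is given, when R^2
    falls below it (noise-around-the-curve exclusion).
    """
    series.validate()
    t, m = series.time, series.mass
    if m.max() - m.min() <= 0:
        raise ValueError(f"series {series.individual_id}/{series.state}: zero mass range")

    def resid(p):
        return boltzmann(t, *p) - m

    best, best_rss = None, np.inf
    span = float(t[-1] - t[0])
    for p0 in _initial_guesses(t, m, n_starts):
        try:
            sol = optimize.least_squares(
                resid, p0,
                bounds=([0.0, 0.0, t[0] - span, 1e-6], [np.inf, np.inf, t[-1] + span, np.inf]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:       # singular start: try the next one
            continue
        rss = float(2 * sol.cost)
        if sol.success and rss < best_rss:
            best, best_rss = sol, rss
    if best is None:
        return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, np.inf, -np.inf, False)
    A1, A2, t0, dx = best.x
    tss = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - best_rss / tss if tss > 0 else np.nan
    converged = bool(A1 > A2)
    if r2_threshold is not None and r2 < r2_threshold:
        converged = False
    return BoltzmannFit(float(A1), float(A2), float(t0), float(dx), best_rss, r2, converged)


def max_combustion_rate(series: MassLossSeries, fit: BoltzmannFit,
                        window_s: float = 3.0, min_points: int = 5) -> float:
    """|slope| of mass vs time within +/- ``window_s`` of the inflection.

    An OLS line is fitted to the observed points in [t0 - w, t0 + w]; its
    absolute slope (g/s) is the maximum combustion rate.  Errors if the
    window falls outside the recorded series or holds too few points.
    """
    lo, hi = fit.t0 - window_s, fit.t0 + window_s
    if lo < series.time[0] - 1e-9 or hi > series.time[-1] + 1e-9:
        raise ValueError("inflection outside series")
    sel = (series.time >= lo) & (series.time <= hi)
    if int(sel.sum()) < min_points:
        raise ValueError(f"only {int(sel.sum())} points in rate window (need >= {min_points})")
    slope = np.polyfit(series.time[sel], series.mass[sel], 1)[0]
    return float(abs(slope))


@dataclass
class PlantFlammability:
    individual_id: str
    state: str
    flaming_time_s: float        # Boltzmann width parameter dx
    max_combustion_rate_g_s: float
    mass_burned_g: float         # A1 - A2
    initial_mass_g: float        # A1
    excluded: bool = False
    reason: str = ""
    species_id: str = ""


def plant_metrics(series: MassLossSeries, n_starts: int = 5, r2_threshold: float = 0.95,
                  window_s: float = 3.0) -> PlantFlammability:
    """Plant-scale sustainability and combustibility from one clump burn."""
    fit = fit_boltzmann(series, n_starts=n_starts, r2_threshold=r2_threshold)
    if not fit.converged:
        return PlantFlammability(
            series.individual_id, series.state, np.nan, np.nan, np.nan, np.nan,
            excluded=True, reason="noise around the curve", species_id=series.species_id,
        )
    try:
        rate = max_combustion_rate(series, fit, window_s=window_s)
    except ValueError as err:
        return PlantFlammability(
            series.individual_id, series.state, fit.dx, np.nan, fit.A1 - fit.A2, fit.A1,
            excluded=True, reason=str(err), species_id=series.species_id,
        )
    if rate <= 0:
        return PlantFlammability(
            series.individual_id, series.state, fit.dx, rate, fit.A1 - fit.A2, fit.A1,
            excluded=True, reason="zero combustion rate", species_id=series.species_id,
        )
    return PlantFlammability(
        series.individual_id, series.state, fit.dx, rate, fit.A1 - fit.A2, fit.A1,
        species_id=series.species_id,
    )


def plant_metrics_table(series_list: list[MassLossSeries], **kw) -> pd.DataFrame:
    recs = [plant_metrics(s, **kw).__dict__ for s in series_list]
    out = pd.DataFrame(recs)
    logger.info(
        "plant_metrics: %d burns, %d excluded", len(out), int(out["excluded"].sum())
    )
    return out


# --------------------------------------- mass-standardized combustibility

@dataclass
class IntrinsicCombustibility:
    species_id: str
    slope: float                 # common log-log slope actually used
    y_intercept: float           # log10 rate at log10 mass = 0
    source: str                  # "combined" or "fresh-only"
    p_slope_equality: float
    p_intercept_equality: float
    n_pairs: int


def _ols(x: np.ndarray, X_extra: Optional[np.ndarray], y: np.ndarray):
    """OLS of y on [1, x, X_extra]; returns (beta, rss, dof)."""
    cols = [np.ones_like(x), x]
    if X_extra is not None:
        cols.extend(list(np.atleast_2d(X_extra)))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss, y.size - X.shape[1]


def intrinsic_combustibility(plant_df: pd.DataFrame, species_id: str,
                             mass_change: str = "burned", alpha: float = 0.05) -> IntrinsicCombustibility:
    """Mass-standardized combustion capacity of one species.

    Regresses log10(max combustion rate) on log10(mass change) for the
    fresh, dry and combined data sets (balanced: unpaired burns dropped).
    A nested-model F-test compares fresh and dry slopes (interaction term);
    when they do not differ the data sets are pooled.  A second F-test
    compares intercepts under a common slope: if they differ, the intercept
    is taken from the fresh-only model, otherwise from the combined model.
    """
    df = plant_df[(plant_df["species_id"] == species_id) & (~plant_df["excluded"])]
    fresh = df[df["state"] == "fresh"].set_index("individual_id")
    dry = df[df["state"] == "dry"].set_index("individual_id")
    paired = fresh.index.intersection(dry.index)
    if len(paired) < 3:
        raise ValueError(f"{species_id}: fewer than 3 balanced fresh/dry pairs")
    fresh, dry = fresh.loc[paired], dry.loc[paired]

    mass_col = "mass_burned_g" if mass_change == "burned" else "initial_mass_g"
    x = np.log10(np.concatenate([fresh[mass_col], dry[mass_col]]))
    y = np.log10(
        np.concatenate([fresh["max_combustion_rate_g_s"], dry["max_combustion_rate_g_s"]])
    )
    state = np.concatenate([np.ones(len(paired)), np.zeros(len(paired))])  # 1 = fresh
    if np.ptp(x) < 1e-12:
        raise ValueError(f"{species_id}: intercept unidentifiable (degenerate mass range)")

    # nested F-tests: full (state-specific slopes+intercepts) vs common slope
    # vs single line
    _, rss_full, dof_full = _ols(x, np.array([state, state * x]), y)
    b_common, rss_cslope, dof_cslope = _ols(x, np.array([state]), y)
    b_single, rss_single, dof_single = _ols(x, None, y)

    tss = float(np.sum((y - y.mean()) ** 2))

    def ftest(rss0, dof0, rss1, dof1):
        # an (essentially) perfect nested fit carries no evidence against it
        if rss1 <= 1e-12 * tss or dof1 <= 0:
            return 1.0
        f = ((rss0 - rss1) / (dof0 - dof1)) / (rss1 / dof1)
        return float(stats.f.sf(max(f, 0.0), dof0 - dof1, dof1))

    p_slope = ftest(rss_cslope, dof_cslope, rss_full, dof_full)
    p_int = ftest(rss_single, dof_single, rss_cslope, dof_cslope)

    if p_int < alpha:
        # intercepts differ between states: characterize with the fresh data
        beta_f, _, _ = _ols(x[state == 1], None, y[state == 1])
        return IntrinsicCombustibility(
            species_id, float(beta_f[1]), float(beta_f[0]), "fresh-only",
            p_slope, p_int, len(paired),
        )
    return IntrinsicCombustibility(
        species_id, float(b_single[1]), float(b_single[0]), "combined",
        p_slope, p_int, len(paired),
    )


def whole_plant_rate(y_intercept: float, b_common: float,
                     species_mean_total_biomass_g: float) -> float:
    """Whole-plant combustion rate (g/s) extrapolated to total biomass.

    log10(rate) = y_intercept + b_common * log10(total biomass): the common
    across-species log-log relationship shifted by each species' intrinsic
    combustibility.
    """
    if species_mean_total_biomass_g <= 0:
        raise ValueError("total biomass must be positive")
    if not np.isfinite(b_common):
        raise ValueError("across-species slope must be finite")
    return float(10.0 ** (y_intercept + b_common * np.log10(species_mean_total_biomass_g)))
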