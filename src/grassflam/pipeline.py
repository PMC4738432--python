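"""End-to-end orchestration: traits -> burn curves -> spread -> phylogenetics.

``run`` consumes a study bundle (real or synthetic), executes every analysis
stage, and writes the species-level summary tables, the trait-contribution
PGLS coefficient tables, the phylogenetic-signal table, the bivariate
mixed-model posterior and a sign-concordance matrix comparing fitted
coefficient signs against the a-priori trait/flammability prediction matrix.
All results are computed in memory first and written only when every stage
has succeeded, so a failed run leaves no partial output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from grassflam._version import __version__
from grassflam import burncurve, phylocomp, rothermel, synthdata, traits
from grassflam.config import RunConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


# a-priori predictions: sign of each plant trait's influence on each
# flammability COMPONENT; measures flagged ``invert`` (time to ignition)
# decrease when their component increases
PREDICTED_SIGNS = {
    "tti_s": {
        "component": "ignitability", "invert": True,
        "signs": {"biomass_quantity_g": "n/a", "density_slope": "n/a",
                  "moisture_content": "-", "leaf_sav_mm": "+", "leaf_ehoc_kj_g": "0"},
    },
    "spread_rate_m_min": {
        "component": "ignitability", "invert": False,
        "signs": {"biomass_quantity_g": "+", "density_slope": "+",
                  "moisture_content": "-", "leaf_sav_mm": "+", "leaf_ehoc_kj_g": "+"},
    },
    "flaming_time_s": {
        "component": "sustainability", "invert": False,
        "signs": {"biomass_quantity_g": "+", "density_slope": "-",
                  "moisture_content": "+", "leaf_sav_mm": "-", "leaf_ehoc_kj_g": "-"},
    },
    "max_combustion_rate_g_s": {
        "component": "combustibility", "invert": False,
        "signs": {"biomass_quantity_g": "+", "density_slope": "+",
                  "moisture_content": "-", "leaf_sav_mm": "+", "leaf_ehoc_kj_g": "+"},
    },
}

_FLIP = {"+": "-", "-": "+", "0": "0"}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrapped
    return deco


@_stage("traits")
def _run_traits(bundle, cfg):
    ind = traits.individual_traits(
        bundle.trait_table, bundle.profiles, bundle.ehoc_table,
        density_mode=cfg.density_mode,
    )
    sp = traits.aggregate_species(ind)
    return ind, sp


@_stage("burncurve")
def _run_burncurve(bundle, cfg):
    leaf = burncurve.leaf_metrics_table(bundle.leaf_events)
    moist_ind, moist_sp = burncurve.moisture_effect(leaf)
    plant = burncurve.plant_metrics_table(
        bundle.mass_loss,
        n_starts=cfg.boltzmann.n_starts,
        r2_threshold=cfg.boltzmann.r2_threshold,
        window_s=cfg.boltzmann.rate_window_s,
    )
    intr = []
    for sp_id in sorted(plant["species_id"].unique()):
        try:
            ic = burncurve.intrinsic_combustibility(plant, sp_id, mass_change=cfg.mass_change_def)
            intr.append(ic.__dict__)
        except ValueError as err:
            logger.warning("intrinsic_combustibility skipped for %s: %s", sp_id, err)
    return leaf, moist_ind, moist_sp, plant, pd.DataFrame(intr)


@_stage("rothermel")
def _run_rothermel(ind_traits, cfg):
    rows = []
    for row in ind_traits.itertuples(index=False):
        fm = rothermel.build_fuel_model(row._asdict(), cfg.rothermel)
        res = rothermel.spread_rate(fm, wind_m_s=cfg.rothermel.wind_m_s,
                                    slope_fraction=cfg.rothermel.slope_fraction)
        rows.append({"species_id": row.species_id, "individual_id": row.individual_id,
                     **res.as_dict()})
    return pd.DataFrame(rows)


@_stage("phylo")
def _run_phylo(bundle, species_table, cfg):
    order, v = phylocomp.phylo_covariance(bundle.tree, 1.0)
    st = species_table.set_index("species_id").loc[order]

    # phylogenetic signal per trait / flammability measure
    sig_rows = []
    for col in st.columns:
        y = st[col].to_numpy(dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < 5 or np.ptp(y[mask]) == 0:
            continue
        s = phylocomp.estimate_lambda(y[mask], v[np.ix_(mask, mask)])
        sig_rows.append({"trait": col, "lambda_ml": s.lambda_ml,
                         "loglik_ml": s.loglik_ml, "p_vs_0": s.p_vs_0, "p_vs_1": s.p_vs_1})
    signal = pd.DataFrame(sig_rows)

    # trait-contribution PGLS, leaf and plant scale
    def fit_table(resp_cols, pred_cols, pred_logs):
        frames = []
        for resp in resp_cols:
            cols, names = [np.ones(len(st))], ["intercept"]
            for p, lg in zip(pred_cols, pred_logs):
                vals = st[p].to_numpy(dtype=float)
                cols.append(np.log10(vals) if lg else vals)
                names.append(f"log10_{p}" if lg else p)
            x = np.column_stack(cols)
            y = st[resp].to_numpy(dtype=float)
            mask = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
            fit = phylocomp.pgls_fit(y[mask], x[mask], v[np.ix_(mask, mask)],
                                     lam="ml", names=names)
            for i, name in enumerate(names):
                frames.append({
                    "response": resp, "predictor": name, "trait": (pred_cols[i - 1] if i else None),
                    "estimate": fit.coef[i], "ci_lower": fit.ci_lower[i],
                    "ci_upper": fit.ci_upper[i], "lambda": fit.lam, "r_squared": fit.r_squared,
                })
        return pd.DataFrame(frames)

    leaf_preds = ["moisture_content", "leaf_sav_mm", "leaf_ehoc_kj_g"]
    plant_preds = ["biomass_quantity_g", "density_slope", "moisture_content",
                   "leaf_sav_mm", "leaf_ehoc_kj_g"]
    pgls_leaf = fit_table(
        ["tti_s", "ft_s", "combustion_rate_g_s"], leaf_preds, [False, False, True],
    )
    pgls_plant = fit_table(
        ["flaming_time_s", "max_combustion_rate_g_s", "spread_rate_m_min"],
        plant_preds, [True, True, True, False, True],
    )
    return signal, pgls_leaf, pgls_plant


@_stage("bivariate")
def _run_bivariate(bundle, plant, cfg):
    keep = plant[(~plant["excluded"]) & (plant["mass_burned_g"] > 0)
                 & (plant["max_combustion_rate_g_s"] > 0)]
    order, a = phylocomp.phylo_covariance(bundle.tree, 1.0)
    present = [s for s in order if s in set(keep["species_id"])]
    sel = [order.index(s) for s in present]
    a_sub = a[np.ix_(sel, sel)]
    sub = keep[keep["species_id"].isin(present)]
    return phylocomp.bivariate_mixed_model(
        np.log10(sub["mass_burned_g"].to_numpy()),
        np.log10(sub["max_combustion_rate_g_s"].to_numpy()),
        sub["species_id"].to_numpy(), present, a_sub,
        iterations=cfg.mcmc.iterations, burnin=cfg.mcmc.burnin, thin=cfg.mcmc.thin,
        prior_nu=cfg.mcmc.prior_nu, prior_v=cfg.mcmc.prior_v, seed=cfg.seed,
    )


def sign_concordance(pgls_leaf: pd.DataFrame, pgls_plant: pd.DataFrame) -> pd.DataFrame:
    """Compare fitted PGLS coefficient signs with the prediction matrix.

    A coefficient counts as '+' or '-' when its 95% CI excludes zero, '0'
    otherwise; measures that shrink as their flammability component grows
    (time to ignition) have their fitted sign flipped into component
    direction before comparison.
    """
    fits = pd.concat([pgls_leaf, pgls_plant], ignore_index=True)
    resp_map = {"tti_s": "tti_s", "ft_s": "flaming_time_s",
                "combustion_rate_g_s": "max_combustion_rate_g_s",
                "flaming_time_s": "flaming_time_s",
                "max_combustion_rate_g_s": "max_combustion_rate_g_s",
                "spread_rate_m_min": "spread_rate_m_min"}
    rows = []
    for row in fits.itertuples(index=False):
        if row.trait is None or row.response not in resp_map:
            continue
        pred_spec = PREDICTED_SIGNS[resp_map[row.response]]
        predicted = pred_spec["signs"].get(row.trait, "n/a")
        if row.ci_lower > 0:
            fitted = "+"
        elif row.ci_upper < 0:
            fitted = "-"
        else:
            fitted = "0"
        component_sign = _FLIP[fitted] if pred_spec["invert"] else fitted
        rows.append({
            "response": row.response, "component": pred_spec["component"],
            "trait": row.trait, "predicted": predicted, "fitted": fitted,
            "fitted_component_direction": component_sign,
            "consistent": ("n/a" if predicted == "n/a" else bool(component_sign == predicted)),
        })
    return pd.DataFrame(rows)


def species_summary(species_traits: pd.DataFrame, leaf: pd.DataFrame,
                    moist_sp: pd.DataFrame, plant: pd.DataFrame,
                    intrinsic: pd.DataFrame, whole_plant: pd.DataFrame,
                    spread: pd.DataFrame) -> pd.DataFrame:
    """One row per species with all flammability components and traits."""
    leaf_keep = leaf[~leaf["excluded"]]
    leaf_sp = (leaf_keep[leaf_keep["state"] == "fresh"]
               .groupby("species_id")[["tti_s", "ft_s", "combustion_rate_g_s"]]
               .mean().reset_index())
    plant_keep = plant[~plant["excluded"]]
    plant_sp = (plant_keep[plant_keep["state"] == "fresh"]
                .groupby("species_id")[["flaming_time_s", "max_combustion_rate_g_s"]]
                .mean().reset_index())
    excl = (plant.groupby("species_id")["excluded"].sum().rename("n_burns_excluded")
            .reset_index())
    spread_sp = spread.groupby("species_id")[["spread_rate_m_min"]].mean().reset_index()
    out = species_traits.merge(leaf_sp, on="species_id", how="left")
    out = out.merge(plant_sp, on="species_id", how="left")
    out = out.merge(intrinsic[["species_id", "y_intercept", "slope", "source"]],
                    on="species_id", how="left")
    out = out.merge(whole_plant, on="species_id", how="left")
    out = out.merge(spread_sp, on="species_id", how="left")
    out = out.merge(excl, on="species_id", how="left")
    out = out.merge(moist_sp[["species_id", "tti_s_rel", "ft_s_rel"]],
                    on="species_id", how="left")
    return out


def run(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the result tables and writes them.

    If ``cfg.bundle_dir`` holds a written bundle it is loaded; otherwise a
    synthetic study is generated there with ``cfg.seed``.
    """
    bundle_dir = Path(cfg.bundle_dir)
    if (bundle_dir / "trait_table.csv").exists():
        bundle = synthdata.load_bundle(bundle_dir)
        logger.info("loaded bundle from %s", bundle_dir)
    else:
        bundle = synthdata.gen_study(synthdata.GeneratorSpec(seed=cfg.seed))
        bundle.write(bundle_dir)
        logger.info("generated synthetic bundle in %s", bundle_dir)

    ind_traits, sp_traits = _run_traits(bundle, cfg)
    leaf, moist_ind, moist_sp, plant, intrinsic = _run_burncurve(bundle, cfg)

    spread_input = ind_traits  # traits are measured on the fresh clump
    if cfg.spread_state == "dry":
        spread_input = ind_traits.assign(moisture_content=0.0)
    spread = _run_rothermel(spread_input, cfg)

    post = _run_bivariate(bundle, plant, cfg)

    wp_rows = []
    sp_mean_mass = ind_traits.groupby("species_id")["biomass_quantity_g"].mean()
    for row in intrinsic.itertuples(index=False):
        wp_rows.append({
            "species_id": row.species_id,
            "whole_plant_rate_g_s": burncurve.whole_plant_rate(
                row.y_intercept, post.b_across_mean, float(sp_mean_mass[row.species_id])
            ),
        })
    whole_plant = pd.DataFrame(wp_rows)

    # species table for comparative statistics: traits + flammability means
    summary = species_summary(
        traits.aggregate_species(ind_traits)
        .rename(columns={f"{c}_mean": c for c in traits.TRAIT_NAMES}),
        leaf, moist_sp, plant, intrinsic, whole_plant, spread,
    )
    phylo_cols = ["species_id"] + traits.TRAIT_NAMES[:5] + [
        "tti_s", "ft_s", "combustion_rate_g_s",
        "flaming_time_s", "max_combustion_rate_g_s", "spread_rate_m_min",
    ]
    signal, pgls_leaf, pgls_plant = _run_phylo(bundle, summary[phylo_cols], cfg)
    concord = sign_concordance(pgls_leaf, pgls_plant)

    post_summary = pd.DataFrame([{
        "b_within_mean": post.b_within_mean, "b_within_hpd_lo": post.b_within_hpd[0],
        "b_within_hpd_hi": post.b_within_hpd[1],
        "b_across_mean": post.b_across_mean, "b_across_hpd_lo": post.b_across_hpd[0],
        "b_across_hpd_hi": post.b_across_hpd[1],
        "delta_b_mean": post.delta_b_mean, "delta_b_hpd_lo": post.delta_b_hpd[0],
        "delta_b_hpd_hi": post.delta_b_hpd[1],
        "ess_within": post.ess_within, "ess_across": post.ess_across,
        "rhat_within": post.rhat_within, "rhat_across": post.rhat_across,
    }])

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "individual_traits": ind_traits,
        "species_traits": sp_traits,
        "leaf_flammability": leaf,
        "moisture_effect_individual": moist_ind,
        "moisture_effect_species": moist_sp,
        "plant_flammability": plant,
        "intrinsic_combustibility": intrinsic,
        "whole_plant_rates": whole_plant,
        "spread_rates": spread,
        "species_flammability": summary,
        "lambda_signal": signal,
        "pgls_leaf": pgls_leaf,
        "pgls_plant": pgls_plant,
        "bivariate_posterior": post_summary,
        "sign_concordance": concord,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
    draws = pd.DataFrame({
        "b_within": post.b_within_draws, "b_across": post.b_across_draws,
    })
    draws.to_csv(out_dir / "bivariate_draws.csv", index=False, float_format="%.10g")

    manifest = {
        "grassflam_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_species": int(sp_traits.shape[0]),
        "n_individual_records": int(ind_traits.shape[0]),
        "n_leaf_records": int(leaf.shape[0]),
        "n_leaf_excluded": int(leaf["excluded"].sum()),
        "n_burns": int(plant.shape[0]),
        "n_burns_excluded": int(plant["excluded"].sum()),
        "outputs": {name: _file_hash(out_dir / f"{name}.csv") for name in tables},
    }
    cfg.save(out_dir / "config_used.yml")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %d tables in %s", len(tables), out_dir)
    return {"tables": tables, "posterior": post, "manifest": manifest, "bundle": bundle}


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
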