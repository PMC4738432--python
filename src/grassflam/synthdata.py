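"""Synthetic study generator with known ground truth.

Emulates the full sampling design of the field study: 25 grass species x 7
individuals, each split into a fresh and an oven-dried clump; species trait
values evolved on an ultrametric phylogeny under a Brownian/lambda model;
log-linear vertical biomass profiles; epiradiator leaf-burn event times with
a configurable fresh-over-dry ignition-delay effect (default fresh TTI =
1.42 x dry TTI); and plant-scale mass-loss series shaped as Boltzmann
sigmoids with Gaussian balance noise at 0.2-s sampling.

Every generated quantity is recorded in a ``truth`` dictionary so the
analysis stages can be checked against the parameters that produced the
data.  One pseudo-random stream per stage, all spawned from the master
seed, so stages are independently reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from grassflam import io as gfio
from grassflam.io import LeafBurnEvents, MassLossSeries
from grassflam.phylocomp import phylo_covariance
from grassflam.traits import ALLOWED_INTERVALS_CM, VerticalProfile


@dataclass
class TraitSpec:
    """Species-level range and phylogenetic signal for one trait."""

    low: float
    high: float
    lam: float = 0.0   # Pagel's lambda used in generation


@dataclass
class GeneratorSpec:
    """Study-design parameters; defaults mirror the emulated field design."""

    n_species: int = 25
    n_individuals: int = 7
    seed: int = 0
    # species-level trait ranges and lambdas; SA/V carries strong signal
    traits: dict = field(default_factory=lambda: {
        "biomass_quantity_g": TraitSpec(5.0, 120.0, 0.0),
        "density_slope": TraitSpec(0.01, 0.06, 0.0),       # log10 g per cm
        "moisture_content": TraitSpec(0.05, 0.35, 0.0),    # g/g, dry-season fresh
        "leaf_sav_mm": TraitSpec(5.0, 25.0, 1.0),          # 2/thickness, per mm
        "leaf_ehoc_kj_g": TraitSpec(10.0, 16.0, 0.0),
        "height_cm": TraitSpec(20.0, 100.0, 0.0),
        "width_cm": TraitSpec(15.0, 60.0, 0.0),
    })
    within_species_cv: float = 0.15     # lognormal sd of individual/species ratio
    tti_fresh_over_dry: float = 1.42    # moisture effect on ignition delay
    ft_fresh_over_dry: float = 1.07     # moisture effect on flaming time
    leaf_sample_mass_g: float = 0.2
    leaf_noise_cv: float = 0.10         # lognormal noise on event durations
    mass_loss_noise_sd_g: float = 0.01  # balance noise on the burn curve
    sampling_interval_s: float = 0.2
    burn_fraction_range: tuple = (0.3, 0.9)   # clump fraction burned per test
    char_fraction: float = 0.08               # residue A2 / A1
    profile_noise_cv: float = 0.0              # noise on individual density slopes
    ehoc_individuals: int = 3                  # calorimetry subsample per species
    ehoc_replicates: int = 2
    ehoc_sample_mass_g: float = 0.005
    ehoc_noise_cv: float = 0.02


@dataclass
class StudyBundle:
    """Complete synthetic input set plus the truth record."""

    tree: dendropy.Tree
    species_traits: pd.DataFrame
    trait_table: pd.DataFrame
    profiles: list
    ehoc_table: pd.DataFrame
    leaf_events: pd.DataFrame
    mass_loss: list
    truth: dict

    def profiles_df(self) -> pd.DataFrame:
        frames = []
        for p in self.profiles:
            frames.append(pd.DataFrame({
                "species_id": p.species_id,
                "individual_id": p.individual_id,
                "interval_top_cm": p.interval_top_cm,
                "dry_mass_g": p.interval_dry_mass_g,
                "fresh_mass_g": p.interval_fresh_mass_g,
            }))
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gfio.write_newick(self.tree, out / "tree.nwk")
        self.species_traits.to_csv(out / "species_traits_true.csv", index=False)
        gfio.write_trait_table(self.trait_table, out / "trait_table.csv")
        self.profiles_df().to_csv(out / "profiles.csv", index=False)
        self.ehoc_table.to_csv(out / "ehoc.csv", index=False)
        self.leaf_events.to_csv(out / "leaf_events.csv", index=False)
        gfio.write_mass_loss(self.mass_loss, out / "mass_loss.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def load_bundle(bundle_dir: str | Path) -> StudyBundle:
    """Read a bundle directory written by :meth:`StudyBundle.write`."""
    d = Path(bundle_dir)
    tree = gfio.read_newick(d / "tree.nwk")
    prof_df = gfio.read_profiles(d / "profiles.csv")
    profiles = []
    for (sp, ind), grp in prof_df.groupby(["species_id", "individual_id"], sort=False):
        profiles.append(VerticalProfile(
            individual_id=str(ind),
            interval_top_cm=grp["interval_top_cm"].to_numpy(),
            interval_dry_mass_g=grp["dry_mass_g"].to_numpy(),
            interval_fresh_mass_g=grp["fresh_mass_g"].to_numpy() if "fresh_mass_g" in grp else None,
            species_id=str(sp),
        ))
    truth_path = d / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return StudyBundle(
        tree=tree,
        species_traits=pd.read_csv(d / "species_traits_true.csv"),
        trait_table=gfio.read_trait_table(d / "trait_table.csv"),
        profiles=profiles,
        ehoc_table=gfio.read_ehoc_table(d / "ehoc.csv"),
        leaf_events=gfio.read_leaf_events(d / "leaf_events.csv"),
        mass_loss=gfio.read_mass_loss(d / "mass_loss.csv"),
        truth=truth,
    )


# ------------------------------------------------------------------- tree

def gen_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Ultrametric Yule tree with unit root-to-tip depth.

    Tips are labelled ``sp01 .. spNN`` in namespace order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng,
    )
    # the process stops at the n-th speciation, so the youngest cherry has
    # zero-length tips; run the clock one more waiting time to the present
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    width = len(str(n_tips))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: str(l.taxon.label)), 1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return tree


# -------------------------------------------------------- species traits

def gen_species_traits(tree: dendropy.Tree, spec: GeneratorSpec,
                       rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Species trait values evolved on the tree under a Brownian/lambda model.

    Each trait is drawn from N(0, V(lambda)) and mapped affinely onto its
    configured [low, high] range (an affine map preserves the phylogenetic
    signal); the generating lambda is recorded in the truth record.
    """
    rng = rng or np.random.default_rng(spec.seed)
    labels, v1 = phylo_covariance(tree, 1.0)
    n = len(labels)
    out = {"species_id": labels}
    for name, tspec in spec.traits.items():
        v = phylo_covariance(tree, tspec.lam)[1] if tspec.lam != 1.0 else v1
        chol = np.linalg.cholesky(v + 1e-12 * np.eye(n))
        z = chol @ rng.standard_normal(n)
        rank_range = z.max() - z.min()
        if rank_range == 0:
            mapped = np.full(n, 0.5 * (tspec.low + tspec.high))
        else:
            mapped = tspec.low + (z - z.min()) / rank_range * (tspec.high - tspec.low)
        out[name] = mapped
    df = pd.DataFrame(out)
    # leaf burn-time targets follow from moisture and SA/V (higher moisture
    # -> slower ignition; higher SA/V -> shorter flaming)
    df["tti_fresh_s"] = 0.8 + 4.0 * df["moisture_content"]
    df["tti_dry_s"] = df["tti_fresh_s"] / spec.tti_fresh_over_dry
    df["ft_dry_s"] = 8.5 - 0.16 * df["leaf_sav_mm"]
    df["ft_fresh_s"] = df["ft_dry_s"] * spec.ft_fresh_over_dry
    return df


# ------------------------------------------------------- individual data

def _profile_geometry(height_cm: float) -> tuple[float, int]:
    """Largest allowed interval length giving at least 5 intervals."""
    for interval in sorted(ALLOWED_INTERVALS_CM, reverse=True):
        if height_cm / interval >= 5:
            return interval, int(np.floor(height_cm / interval))
    return ALLOWED_INTERVALS_CM[0], max(5, int(np.ceil(height_cm / ALLOWED_INTERVALS_CM[0])))


def _boltzmann_params(a1: float, sav: float, moisture_state: float,
                      spec: GeneratorSpec) -> tuple[float, float, float, float]:
    """Map traits onto Boltzmann parameters: width grows with moisture and
    shrinks with SA/V; asymptotes from sample mass and char fraction."""
    a2 = spec.char_fraction * a1
    dx = (2.5 + 2.0 * np.log10(1.0 + a1)) * (1.0 + 0.8 * moisture_state) * 15.0 / (10.0 + sav)
    dx = float(np.clip(dx, 2.0, 12.0))
    t0 = 15.0 + 3.0 * dx
    return a1, a2, t0, dx


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(mean=-0.5 * np.log1p(cv**2), sigma=np.sqrt(np.log1p(cv**2)), size=size)


def gen_individual_data(species_traits: pd.DataFrame, spec: GeneratorSpec,
                        seed: Optional[int] = None) -> dict:
    """Per-individual measurements for every species x individual x state.

    Returns a dict with ``trait_table``, ``profiles``, ``ehoc_table``,
    ``leaf_events``, ``mass_loss`` and ``truth``.
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    streams = master.spawn(5)
    rng_ind = np.random.default_rng(streams[0])
    rng_prof = np.random.default_rng(streams[1])
    rng_leaf = np.random.default_rng(streams[2])
    rng_burn = np.random.default_rng(streams[3])
    rng_ehoc = np.random.default_rng(streams[4])

    trait_rows, profiles, ehoc_rows, leaf_rows = [], [], [], []
    mass_loss: list[MassLossSeries] = []
    truth_boltzmann, truth_leaf, truth_profiles = {}, {}, {}

    for sp_row in species_traits.itertuples(index=False):
        sp = sp_row.species_id
        for k in range(1, spec.n_individuals + 1):
            ind = f"i{k}"
            key = f"{sp}/{ind}"
            cv = spec.within_species_cv
            dry_mass = sp_row.biomass_quantity_g * float(_lognoise(rng_ind, cv))
            moisture = sp_row.moisture_content * float(_lognoise(rng_ind, cv))
            sav = sp_row.leaf_sav_mm * float(_lognoise(rng_ind, cv))
            thickness = 2.0 / sav
            leaf_area = 400.0 * float(_lognoise(rng_ind, cv))
            height = sp_row.height_cm * float(_lognoise(rng_ind, cv))
            width = sp_row.width_cm * float(_lognoise(rng_ind, cv))
            interval, n_int = _profile_geometry(height)
            height = interval * n_int          # profile cuts define the height
            cover = np.pi * (width / 2.0) ** 2
            fresh_mass = dry_mass * (1.0 + moisture)

            for state, mass in (("fresh", fresh_mass), ("dry", dry_mass)):
                trait_rows.append({
                    "species_id": sp, "individual_id": ind, "state": state,
                    "fresh_mass_g": fresh_mass, "dry_mass_g": dry_mass,
                    "leaf_area_mm2": leaf_area, "leaf_thickness_mm": thickness,
                    "height_cm": height, "cover_area_cm2": cover,
                })

            # vertical profile: log10 cumulative mass linear in height
            slope = sp_row.density_slope * float(_lognoise(rng_prof, spec.profile_noise_cv))
            tops = interval * np.arange(1, n_int + 1)
            intercept = np.log10(dry_mass) - slope * height
            cum = 10.0 ** (intercept + slope * tops)
            interval_dry = np.diff(np.concatenate([[0.0], cum]))
            profiles.append(VerticalProfile(
                individual_id=ind, interval_top_cm=tops,
                interval_dry_mass_g=interval_dry,
                interval_fresh_mass_g=interval_dry * (1.0 + moisture),
                species_id=sp,
            ))
            truth_profiles[key] = {"density_slope": float(slope), "total_dry_mass_g": float(dry_mass)}

            # leaf burn events, fresh and dry
            tti_dry = sp_row.tti_dry_s * float(_lognoise(rng_leaf, spec.leaf_noise_cv))
            tti_fresh = tti_dry * spec.tti_fresh_over_dry * float(_lognoise(rng_leaf, spec.leaf_noise_cv))
            ft_dry = sp_row.ft_dry_s * float(_lognoise(rng_leaf, spec.leaf_noise_cv))
            ft_fresh = ft_dry * spec.ft_fresh_over_dry * float(_lognoise(rng_leaf, spec.leaf_noise_cv))
            for state, tti, ft in (("fresh", tti_fresh, ft_fresh), ("dry", tti_dry, ft_dry)):
                leaf_rows.append({
                    "species_id": sp, "individual_id": ind, "state": state,
                    "sample_mass_g": spec.leaf_sample_mass_g,
                    "t_application_s": 0.0, "t_first_flame_s": tti,
                    "t_flame_out_s": tti + ft,
                })
                truth_leaf[f"{key}/{state}"] = {"tti_s": float(tti), "ft_s": float(ft)}

            # plant-scale mass-loss burns
            frac = rng_burn.uniform(*spec.burn_fraction_range)
            for state in ("fresh", "dry"):
                m_state = moisture if state == "fresh" else 0.0
                a1 = frac * dry_mass * (1.0 + m_state)
                a1, a2, t0, dx = _boltzmann_params(a1, sav, m_state, spec)
                t_end = t0 + 8.0 * dx
                t = np.arange(0.0, t_end + spec.sampling_interval_s / 2, spec.sampling_interval_s)
                m = a2 + (a1 - a2) / (1.0 + np.exp((t - t0) / dx))
                if spec.mass_loss_noise_sd_g > 0:
                    m = m + rng_burn.normal(0.0, spec.mass_loss_noise_sd_g, size=t.size)
                    m = np.maximum(m, 0.0)
                    m[-1] = min(m[-1], m[0])       # keep the final<=initial invariant
                mass_loss.append(MassLossSeries(
                    individual_id=ind, state=state, time=t, mass=m, species_id=sp,
                    nominal_interval=spec.sampling_interval_s,
                ))
                truth_boltzmann[f"{key}/{state}"] = {
                    "A1": float(a1), "A2": float(a2), "t0": float(t0), "dx": float(dx),
                }

        # calorimetry subsample: first few individuals, duplicate replicates
        for k in range(1, min(spec.ehoc_individuals, spec.n_individuals) + 1):
            for rep in range(1, spec.ehoc_replicates + 1):
                mass = spec.ehoc_sample_mass_g
                heat = sp_row.leaf_ehoc_kj_g * mass * float(_lognoise(rng_ehoc, spec.ehoc_noise_cv))
                ehoc_rows.append({
                    "species_id": sp, "individual_id": f"i{k}", "replicate": rep,
                    "heat_release_kj": heat, "sample_mass_g": mass,
                })

    return {
        "trait_table": pd.DataFrame(trait_rows),
        "profiles": profiles,
        "ehoc_table": pd.DataFrame(ehoc_rows),
        "leaf_events": pd.DataFrame(leaf_rows),
        "mass_loss": mass_loss,
        "truth": {
            "boltzmann": truth_boltzmann,
            "leaf": truth_leaf,
            "profiles": truth_profiles,
            "tti_fresh_over_dry": spec.tti_fresh_over_dry,
            "ft_fresh_over_dry": spec.ft_fresh_over_dry,
        },
    }


def gen_study(spec: Optional[GeneratorSpec] = None) -> StudyBundle:
    """Generate a complete synthetic study bundle."""
    spec = spec or GeneratorSpec()
    tree = gen_tree(spec.n_species, spec.seed)
    rng_sp = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(6)[5])
    sp_traits = gen_species_traits(tree, spec, rng_sp)
    data = gen_individual_data(sp_traits, spec)
    truth = dict(data["truth"])
    truth["trait_lambdas"] = {name: t.lam for name, t in spec.traits.items()}
    truth["species_traits"] = sp_traits.to_dict(orient="list")
    return StudyBundle(
        tree=tree, species_traits=sp_traits,
        trait_table=data["trait_table"], profiles=data["profiles"],
        ehoc_table=data["ehoc_table"], leaf_events=data["leaf_events"],
        mass_loss=data["mass_loss"], truth=truth,
    )


# ----------------------------------------- direct mixed-model simulation

def slope_covariance(var_x: float, slope: float, resid_var_y: float) -> np.ndarray:
    """2x2 covariance with regression slope of y on x equal to ``slope``."""
    cxy = slope * var_x
    return np.array([[var_x, cxy], [cxy, slope**2 * var_x + resid_var_y]])


def gen_bivariate_records(
    tree: dendropy.Tree,
    n_per_species: int,
    sigma_sp: np.ndarray,
    sigma_res: np.ndarray,
    mu: tuple = (0.0, 0.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Draw (x, y) records from the bivariate phylogenetic mixed model.

    Species effects follow N(0, Sigma_sp (x) A) with A the Brownian tree
    covariance; residuals are iid N(0, Sigma_res).  Returns
    ``(x, y, species, species_order)``.
    """
    rng = np.random.default_rng(seed)
    order, a = phylo_covariance(tree, 1.0)
    n_sp = len(order)
    chol_a = np.linalg.cholesky(a + 1e-12 * np.eye(n_sp))
    chol_sp = np.linalg.cholesky(sigma_sp)
    u = chol_a @ rng.standard_normal((n_sp, 2)) @ chol_sp.T
    chol_res = np.linalg.cholesky(sigma_res)
    species = np.repeat(order, n_per_species)
    e = rng.standard_normal((n_sp * n_per_species, 2)) @ chol_res.T
    z = np.asarray(mu) + np.repeat(u, n_per_species, axis=0) + e
    return z[:, 0], z[:, 1], species, order
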