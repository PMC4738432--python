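"""Readers, writers and validation for the study's file formats.

Tables are delimited text (CSV by default, TSV for ``.tsv`` paths) with one
header row, UTF-8, ``.`` decimal separator.  Trees are single-tree Newick
with branch lengths.  Every reader validates row-level invariants and raises
:class:`SchemaError` / :class:`ValidationError` with the offending column or
row so that malformed inputs fail loudly rather than propagate.

Schemas
-------
trait table      : species_id, individual_id, state, fresh_mass_g, dry_mass_g,
                   leaf_area_mm2, leaf_thickness_mm, height_cm, cover_area_cm2
vertical profiles: species_id, individual_id, interval_top_cm, dry_mass_g
                   [, fresh_mass_g]
leaf burn events : species_id, individual_id, state, sample_mass_g,
                   t_application_s, t_first_flame_s, t_flame_out_s
mass-loss series : species_id, individual_id, state, time_s, mass_g
EHoC replicates  : species_id, individual_id, replicate, heat_release_kj,
                   sample_mass_g
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("fresh", "dry")

TRAIT_COLUMNS = [
    "species_id",
    "individual_id",
    "state",
    "fresh_mass_g",
    "dry_mass_g",
    "leaf_area_mm2",
    "leaf_thickness_mm",
    "height_cm",
    "cover_area_cm2",
]
PROFILE_COLUMNS = ["species_id", "individual_id", "interval_top_cm", "dry_mass_g"]
LEAF_EVENT_COLUMNS = [
    "species_id",
    "individual_id",
    "state",
    "sample_mass_g",
    "t_application_s",
    "t_first_flame_s",
    "t_flame_out_s",
]
MASS_LOSS_COLUMNS = ["species_id", "individual_id", "state", "time_s", "mass_g"]
EHOC_COLUMNS = ["species_id", "individual_id", "replicate", "heat_release_kj", "sample_mass_g"]


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message names the row."""


@dataclass
class MassLossSeries:
    """Timestamped sample masses from one plant-scale burn.

    Times are seconds since logging started (nominal 0.2-s interval), masses
    are grams on the balance (fresh burns include water mass).
    """

    individual_id: str
    state: str
    time: np.ndarray
    mass: np.ndarray
    species_id: str = ""
    nominal_interval: float = 0.2

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)

    def validate(self, interval_tol: float = 0.5, min_points: int = 30) -> None:
        if self.state not in STATES:
            raise ValidationError(f"state {self.state!r} not in {STATES}")
        if self.time.size != self.mass.size:
            raise ValidationError("time and mass lengths differ")
        if self.time.size < min_points:
            raise ValidationError(
                f"series {self.individual_id}/{self.state}: only "
                f"{self.time.size} points (need >= {min_points})"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValidationError(f"time not strictly increasing at index {i + 1}")
        if np.any(np.abs(dt - self.nominal_interval) > interval_tol * self.nominal_interval):
            i = int(np.argmax(np.abs(dt - self.nominal_interval) > interval_tol * self.nominal_interval))
            raise ValidationError(
                f"sampling interval {dt[i]:.3g}s at index {i + 1} deviates from "
                f"nominal {self.nominal_interval}s"
            )
        if np.any(self.mass < 0):
            i = int(np.argmax(self.mass < 0))
            raise ValidationError(f"negative mass at index {i}")
        if self.mass[-1] > self.mass[0] + 1e-9:
            raise ValidationError("final mass exceeds initial mass")


@dataclass
class LeafBurnEvents:
    """Event times from one epiradiator leaf burn (seconds since test start)."""

    individual_id: str
    state: str
    sample_mass_g: float
    t_application_s: float
    t_first_flame_s: float
    t_flame_out_s: float
    species_id: str = ""

    def validate(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"state {self.state!r} not in {STATES}")
        if not self.sample_mass_g > 0:
            raise ValidationError("sample_mass_g must be positive")
        if not (self.t_application_s <= self.t_first_flame_s <= self.t_flame_out_s):
            raise ValidationError(
                f"event times out of order for {self.individual_id}/{self.state}"
            )


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def _read_delimited(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    return df


def _check_nonnegative(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    for col in cols:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(f"{name}: negative {col} at row {int(bad[0])}")


def _check_state(df: pd.DataFrame, name: str) -> None:
    bad = df.index[~df["state"].isin(STATES)]
    if len(bad):
        raise ValidationError(
            f"{name}: state {df.loc[bad[0], 'state']!r} at row {int(bad[0])} "
            f"not in {STATES}"
        )


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-individual structural/chemical trait table.

    Unknown columns are preserved and row order retained.  One row per
    individual x state; ``fresh_mass_g`` / ``dry_mass_g`` are clump totals.
    """
    df = _read_delimited(path, TRAIT_COLUMNS)
    _check_state(df, "trait table")
    _check_nonnegative(
        df,
        ["fresh_mass_g", "dry_mass_g", "leaf_area_mm2", "leaf_thickness_mm", "height_cm", "cover_area_cm2"],
        "trait table",
    )
    bad = df.index[df["dry_mass_g"] > df["fresh_mass_g"] * 1.01]
    if len(bad):
        raise ValidationError(
            f"trait table: dry_mass_g exceeds fresh_mass_g at row {int(bad[0])}"
        )
    dup = df.duplicated(subset=["species_id", "individual_id", "state"])
    if dup.any():
        raise ValidationError(
            f"trait table: duplicate individual_id within species x state at "
            f"row {int(df.index[dup][0])}"
        )
    df["species_id"] = df["species_id"].str.strip()
    df["individual_id"] = df["individual_id"].str.strip()
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read vertical biomass profiles (one row per interval, long format)."""
    df = _read_delimited(path, PROFILE_COLUMNS)
    _check_nonnegative(df, ["interval_top_cm", "dry_mass_g"], "profiles")
    return df


def read_leaf_events(path: str | Path) -> pd.DataFrame:
    """Read leaf-scale burn event times; validates event ordering per row."""
    df = _read_delimited(path, LEAF_EVENT_COLUMNS)
    _check_state(df, "leaf events")
    _check_nonnegative(df, ["sample_mass_g"], "leaf events")
    bad = df.index[
        (df["t_application_s"] > df["t_first_flame_s"])
        | (df["t_first_flame_s"] > df["t_flame_out_s"])
    ]
    if len(bad):
        raise ValidationError(f"leaf events: event times out of order at row {int(bad[0])}")
    return df


def read_mass_loss(path: str | Path) -> list[MassLossSeries]:
    """Read mass-loss logs into one :class:`MassLossSeries` per burn."""
    df = _read_delimited(path, MASS_LOSS_COLUMNS)
    out = []
    for (sp, ind, state), grp in df.groupby(["species_id", "individual_id", "state"], sort=False):
        s = MassLossSeries(
            individual_id=str(ind),
            state=str(state),
            time=grp["time_s"].to_numpy(),
            mass=grp["mass_g"].to_numpy(),
            species_id=str(sp),
        )
        s.validate()
        out.append(s)
    return out


def write_mass_loss(series: Iterable[MassLossSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "species_id": s.species_id,
                "individual_id": s.individual_id,
                "state": s.state,
                "time_s": s.time,
                "mass_g": s.mass,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_ehoc_table(path: str | Path) -> pd.DataFrame:
    """Read microcalorimetry replicates (heat release and sample mass)."""
    df = _read_delimited(path, EHOC_COLUMNS)
    _check_nonnegative(df, ["heat_release_kj"], "ehoc table")
    bad = df.index[df["sample_mass_g"] <= 0]
    if len(bad):
        raise ValidationError(f"ehoc table: nonpositive sample_mass_g at row {int(bad[0])}")
    return df


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Raises :class:`ValidationError` for unlabeled tips or negative branch
    lengths; tip labels are whitespace-trimmed species identifiers.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True, rooting="default-rooted"
    )
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not str(leaf.taxon.label).strip():
            raise ValidationError("newick: unlabeled tip")
        leaf.taxon.label = str(leaf.taxon.label).strip()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError("newick: negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [str(leaf.taxon.label).strip() for leaf in tree.leaf_node_iter()]


def validate_inputs(tree: dendropy.Tree, trait_table: pd.DataFrame) -> None:
    """Cross-check that tree tips and trait-table species match exactly."""
    tips = set(tip_labels(tree))
    species = set(trait_table["species_id"].str.strip())
    if tips != species:
        only_tree = sorted(tips - species)
        only_table = sorted(species - tips)
        raise ValidationError(
            f"tree/table species mismatch: in tree only {only_tree}, "
            f"in table only {only_table}"
        )


@dataclass
class ExclusionLog:
    """Per-stage bookkeeping of retained vs excluded records."""

    stage: str
    n_input: int = 0
    n_excluded: int = 0
    reasons: list = field(default_factory=list)

    def exclude(self, ident: str, reason: str) -> None:
        self.n_excluded += 1
        self.reasons.append((ident, reason))
        logger.info("%s: excluded %s (%s)", self.stage, ident, reason)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded
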