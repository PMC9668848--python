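"""Mesofauna biomass estimation and trophic-group aggregation.

Soil mesofauna (Collembola, mites and other small arthropods plus
enchytraeids) are counted by taxon under a dissecting microscope; biomass is
estimated from the per-field mean body length through taxon-family power
laws W = a * L^b (dry mass in micrograms, length in mm).  The allometric
coefficients live in an editable CSV; the shipped defaults are documented
placeholders of the right order of magnitude for temperate grassland fauna,
not values from any single published regression, and the synthetic-data
generator uses the same table so that simulated round trips are exact.

Taxa aggregate into seven trophic groups (detritivorous Collembola,
detritivorous mites, annelids, other detritivores, herbivores, predaceous
mites, predaceous fauna) for isotope analysis and community matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TROPHIC_GROUPS",
    "AllometryTable",
    "TrophicGroupTable",
    "biomass_from_length",
    "add_biomass",
    "aggregate_trophic_groups",
    "build_community_matrix",
]

TROPHIC_GROUPS = (
    "detritivorous_collembola",
    "detritivorous_mites",
    "annelids",
    "other_detritivores",
    "herbivores",
    "predaceous_mites",
    "predaceous_fauna",
)

#: PLFA biomass columns appended to the fauna community matrix
PLFA_MATRIX_GROUPS = ("total_bacteria", "fungi", "amf", "actinobacteria")


def _load_resource(name: str) -> pd.DataFrame:
    path = resources.files("pulsetrace.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class AllometryTable:
    """allometry_key -> (a, b) power-law coefficients; mass in µg, length in mm."""

    coefficients: Mapping[str, tuple[float, float]]

    @classmethod
    def default(cls) -> "AllometryTable":
        df = _load_resource("allometry.csv")
        return cls({r.allometry_key: (float(r.a_ug), float(r.b)) for r in df.itertuples()})

    @classmethod
    def from_csv(cls, path) -> "AllometryTable":
        df = pd.read_csv(path)
        return cls({r.allometry_key: (float(r.a_ug), float(r.b)) for r in df.itertuples()})


@dataclass(frozen=True)
class TrophicGroupTable:
    """taxon -> (trophic group, allometry key) mapping."""

    trophic: Mapping[str, str]
    allometry: Mapping[str, str]

    @classmethod
    def default(cls) -> "TrophicGroupTable":
        df = _load_resource("trophic_map.csv")
        return cls(
            trophic=dict(zip(df["taxon"], df["trophic_group"])),
            allometry=dict(zip(df["taxon"], df["allometry_key"])),
        )

    def __post_init__(self) -> None:
        unknown = set(self.trophic.values()) - set(TROPHIC_GROUPS)
        if unknown:
            raise ValueError(f"unknown trophic groups in mapping: {sorted(unknown)}")


def biomass_from_length(
    taxon: str,
    length_mm: float,
    count_per_m2: float,
    groups: TrophicGroupTable | None = None,
    allometry: AllometryTable | None = None,
) -> float | None:
    """Total dry biomass (µg per m2) of *count* individuals of mean length L.

    Per-individual mass is a * L^b with coefficients selected by the taxon's
    allometry key.  Returns None (with a warning) when no coefficients are
    available — a missing record, never a silent zero.
    """
    if count_per_m2 < 0:
        raise ValueError("count must be non-negative")
    if count_per_m2 == 0:
        return 0.0
    if length_mm <= 0:
        raise ValueError("length must be positive when count > 0")
    groups = groups or TrophicGroupTable.default()
    allometry = allometry or AllometryTable.default()
    key = groups.allometry.get(taxon)
    coeff = allometry.coefficients.get(key) if key else None
    if coeff is None:
        warnings.warn(f"no allometric coefficients for taxon {taxon!r}; record skipped")
        return None
    a, b = coeff
    return a * length_mm**b * count_per_m2


def add_biomass(
    records: pd.DataFrame,
    groups: TrophicGroupTable | None = None,
    allometry: AllometryTable | None = None,
) -> pd.DataFrame:
    """Append ``biomass_ug_m2`` and ``trophic_group`` columns to fauna records."""
    groups = groups or TrophicGroupTable.default()
    allometry = allometry or AllometryTable.default()
    out = records.copy()
    out["biomass_ug_m2"] = [
        biomass_from_length(r["taxon"], r["mean_length_mm"], r["count_per_m2"], groups, allometry)
        for _, r in records.iterrows()
    ]
    out["trophic_group"] = [groups.trophic.get(t) for t in records["taxon"]]
    return out


def aggregate_trophic_groups(records: pd.DataFrame, keys=("plot_id", "day")) -> pd.DataFrame:
    """Sum counts and biomass into the seven trophic groups per plot and day.

    Aggregation conserves totals exactly: the group sums equal the taxon sums
    for every plot/day cell.
    """
    if "trophic_group" not in records.columns:
        records = add_biomass(records)
    agg = (
        records.dropna(subset=["trophic_group"])
        .groupby([*keys, "trophic_group"], as_index=False)[["count_per_m2", "biomass_ug_m2"]]
        .sum(min_count=1)
    )
    return agg


def build_community_matrix(
    fauna: pd.DataFrame,
    plfa_biomass: pd.DataFrame,
    keys=("plot_id", "day"),
) -> pd.DataFrame:
    """Plots x variables matrix of fauna abundances plus PLFA group biomass.

    One row per plot/day; columns are individual fauna taxa (individuals per
    m2, absence = 0) followed by the four PLFA group biomasses (bacterial and
    fungal biomass carbon, AMF and actinobacterial biomarker amount).
    Missing PLFA values stay missing.  Duplicate plot/day/taxon keys are
    rejected.
    """
    keys = list(keys)
    dup = fauna.duplicated(subset=keys + ["taxon"])
    if dup.any():
        raise ValueError(f"duplicate fauna keys at rows {list(fauna.index[dup])}")
    wide = fauna.pivot(index=keys, columns="taxon", values="count_per_m2").fillna(0.0)

    missing = [g for g in PLFA_MATRIX_GROUPS if g not in plfa_biomass.columns]
    if missing:
        raise ValueError(f"plfa_biomass lacks columns {missing}")
    dup2 = plfa_biomass.duplicated(subset=keys)
    if dup2.any():
        raise ValueError("duplicate plot/day keys in plfa_biomass")
    plfa_wide = plfa_biomass.set_index(keys)[list(PLFA_MATRIX_GROUPS)]
    out = wide.join(plfa_wide, how="left")
    out.columns.name = None
    return out
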