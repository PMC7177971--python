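"""Survey-table preparation: derived proportions with propagated margins
of error, log population density, population-weighted centroids, county
controls, and the zero-population/zero-employment exclusion filter.

Input tables follow the paired-column convention ``<var>_est`` /
``<var>_moe`` used for 5-year survey releases.  All race-ethnicity,
children-under-5, poverty, noncitizen, and women covariates enter the
regressions as proportions of total population; agricultural employment
as a proportion of total employment; density as log10 residents per km2.
Margins of error for derived proportions follow the survey handbook
formulas, with the ratio-formula fallback when the subtraction radicand
is negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import shape

__all__ = [
    "POP_SUBGROUPS",
    "DEFAULT_IVS",
    "IVTable",
    "weighted_centroid",
    "weighted_centroids",
    "derive_proportion",
    "derive_density",
    "county_controls",
    "filter_units",
    "prepare_ivs",
    "read_geographies",
]

logger = logging.getLogger(__name__)

#: Subgroup count variables expressed as proportions of total population.
POP_SUBGROUPS = (
    "hispanic",
    "black",
    "indigenous",
    "asian",
    "children",
    "poverty",
    "noncitizens",
    "women",
)

#: Default independent-variable list: demographic proportions, the two
#: density/employment controls, and their county-level counterparts.
DEFAULT_IVS = POP_SUBGROUPS + (
    "ag_employment",
    "log_density",
    "county_ag_employment",
    "county_log_density",
)


@dataclass
class IVTable:
    """Analysis-ready independent variables.

    Attributes
    ----------
    data : DataFrame
        One row per unit (index = unit_id), one column per IV (estimates).
    moe : DataFrame
        Same shape; margin of error per IV (0 for IVs that are never
        resampled, e.g. log density and county controls).
    proportion_cols : tuple of str
        Columns constrained to [0, 1] (clamped after resampling noise).
    """

    data: pd.DataFrame
    moe: pd.DataFrame
    proportion_cols: tuple

    @property
    def iv_names(self) -> tuple:
        return tuple(self.data.columns)

    def copy(self) -> "IVTable":
        return IVTable(self.data.copy(), self.moe.copy(), self.proportion_cols)


def weighted_centroid(points: np.ndarray, pops: np.ndarray) -> tuple[float, float]:
    """Population-weighted centroid of a unit's block points.

    Coordinates are Sum(pop * coord) / Sum(pop).  A unit whose blocks all
    have zero population should have been excluded upstream.
    """
    points = np.asarray(points, dtype=float)
    pops = np.asarray(pops, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a nonempty (m, 2) array")
    total = pops.sum()
    if total <= 0:
        raise ValueError(
            "all block populations are zero; unit should have been excluded"
        )
    cx, cy = (pops[:, None] * points).sum(axis=0) / total
    return float(cx), float(cy)


def weighted_centroids(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-unit weighted centroids from a block table.

    ``blocks`` has columns ``unit_id, x_km, y_km, pop``.  Returns a
    DataFrame ``unit_id, cx_km, cy_km``.
    """
    rows = []
    for uid, grp in blocks.groupby("unit_id", sort=True):
        cx, cy = weighted_centroid(grp[["x_km", "y_km"]].to_numpy(), grp["pop"].to_numpy())
        rows.append({"unit_id": uid, "cx_km": cx, "cy_km": cy})
    return pd.DataFrame(rows)


def derive_proportion(num, num_moe, den, den_moe):
    """Derived proportion p = num/den with propagated margin of error.

    MOE_p = (1/den) * sqrt(MOE_num^2 - p^2 * MOE_den^2); when the
    radicand is negative the ratio formula
    (1/den) * sqrt(MOE_num^2 + p^2 * MOE_den^2) is used instead, which
    guarantees a real nonnegative MOE.  Vectorized over array inputs.
    """
    num = np.asarray(num, dtype=float)
    num_moe = np.asarray(num_moe, dtype=float)
    den = np.asarray(den, dtype=float)
    den_moe = np.asarray(den_moe, dtype=float)
    if np.any(den <= 0):
        raise ValueError("denominator must be positive; filter units first")
    p = num / den
    rad = num_moe**2 - p**2 * den_moe**2
    fallback = num_moe**2 + p**2 * den_moe**2
    moe = np.where(rad >= 0, np.sqrt(np.abs(rad)), np.sqrt(fallback)) / den
    if p.ndim == 0:
        return float(p), float(moe)
    return p, moe


def derive_density(total_pop, area_km2):
    """log10 residents per km2; both arguments must be positive."""
    pop = np.asarray(total_pop, dtype=float)
    area = np.asarray(area_km2, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("zero population: unit should have been excluded")
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = np.log10(pop / area)
    return float(out) if out.ndim == 0 else out


def filter_units(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude units with zero estimated total population or employment.

    Returns (retained, exclusion_log); the log has one row per excluded
    unit with the reason.  Idempotent.
    """
    reasons = []
    pop0 = table["total_pop_est"] <= 0
    emp0 = table["total_employment_est"] <= 0
    for _, row in table.loc[pop0 | emp0].iterrows():
        why = []
        if row["total_pop_est"] <= 0:
            why.append("total population 0")
        if row["total_employment_est"] <= 0:
            why.append("total employment 0")
        reasons.append({"unit_id": row["unit_id"], "reason": "; ".join(why)})
    excluded = pd.DataFrame(reasons, columns=["unit_id", "reason"])
    if len(excluded):
        logger.info("excluded %d units: %s", len(excluded), excluded["reason"].tolist())
    return table.loc[~(pop0 | emp0)].copy(), excluded


def county_controls(table: pd.DataFrame) -> pd.DataFrame:
    """County-level log density and agricultural-employment proportion.

    County values are count aggregates over the retained member units —
    log10(sum pop / sum area) and sum(ag) / sum(employment) — broadcast
    back to each unit.  Returns ``unit_id, county_log_density,
    county_ag_employment``.
    """
    if "ag_employment_est" not in table.columns:
        table = table.assign(ag_employment_est=0.0)
    grp = table.groupby("county_id")
    agg = grp.agg(
        pop=("total_pop_est", "sum"),
        area=("area_km2", "sum"),
        ag=("ag_employment_est", "sum"),
        emp=("total_employment_est", "sum"),
    )
    empty = agg[(agg["pop"] <= 0) | (agg["emp"] <= 0)]
    if len(empty):
        logger.warning("dropping empty counties: %s", list(empty.index))
        agg = agg.drop(empty.index)
    agg["county_log_density"] = np.log10(agg["pop"] / agg["area"])
    agg["county_ag_employment"] = agg["ag"] / agg["emp"]
    out = table[["unit_id", "county_id"]].merge(
        agg[["county_log_density", "county_ag_employment"]],
        left_on="county_id",
        right_index=True,
        how="inner",
    )
    return out[["unit_id", "county_log_density", "county_ag_employment"]]


def prepare_ivs(table: pd.DataFrame, iv_names=DEFAULT_IVS) -> IVTable:
    """Build the analysis IV matrix (estimates + MOEs) from a raw table.

    ``table`` is a filtered demographic table with paired ``<var>_est`` /
    ``<var>_moe`` columns plus ``unit_id, county_id, area_km2``.  Subgroup
    counts exceeding their denominator (possible in reported survey data)
    are clamped so proportions stay within [0, 1], with a logged count.
    County controls and log density carry MOE 0: the source tables define
    no margin of error for them, so the bootstrap leaves them fixed.
    """
    est = {}
    moe = {}
    prop_cols = []
    n_clamped = 0
    for name in iv_names:
        if name in POP_SUBGROUPS or name == "ag_employment":
            den = "total_pop" if name in POP_SUBGROUPS else "total_employment"
            num = table[f"{name}_est"].to_numpy(dtype=float)
            over = num > table[f"{den}_est"].to_numpy(dtype=float)
            if over.any():
                n_clamped += int(over.sum())
                num = np.minimum(num, table[f"{den}_est"].to_numpy(dtype=float))
            p, m = derive_proportion(
                num,
                table[f"{name}_moe"].to_numpy(dtype=float),
                table[f"{den}_est"].to_numpy(dtype=float),
                table[f"{den}_moe"].to_numpy(dtype=float),
            )
            est[name], moe[name] = p, m
            prop_cols.append(name)
        elif name == "log_density":
            est[name] = derive_density(
                table["total_pop_est"].to_numpy(dtype=float),
                table["area_km2"].to_numpy(dtype=float),
            )
            moe[name] = np.zeros(len(table))
        elif name in ("county_log_density", "county_ag_employment"):
            cc = county_controls(table).set_index("unit_id")
            vals = cc.loc[table["unit_id"], name].to_numpy()
            est[name] = vals
            moe[name] = np.zeros(len(table))
        else:
            raise KeyError(f"unknown independent variable {name!r}")
    if n_clamped:
        logger.warning(
            "clamped %d subgroup counts exceeding their denominator", n_clamped
        )
    idx = pd.Index(table["unit_id"], name="unit_id")
    return IVTable(
        data=pd.DataFrame(est, index=idx),
        moe=pd.DataFrame(moe, index=idx),
        proportion_cols=tuple(prop_cols),
    )


def read_geographies(path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection of unit polygons.

    Features must carry ``unit_id``, ``geography_class`` and ``county_id``
    properties.  Returns a DataFrame with those columns plus a shapely
    ``geometry`` column and the polygon ``area_km2``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        rows.append(
            {
                "unit_id": props["unit_id"],
                "geography_class": props["geography_class"],
                "county_id": props["county_id"],
                "geometry": geom,
                "area_km2": geom.area,
            }
        )
    return pd.DataFrame(rows)
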