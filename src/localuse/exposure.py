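"""Distance-weighted local pesticide use under exponential decay.

Point-source use records are aggregated to 1.6 km section centroids, and
each geographic unit's *local use* is the decay-weighted sum of section
totals around its population-weighted centroid:

    q_i = sum_u q_u * 0.37^(d_iu / CTD)

where CTD, the characteristic travel distance, is the distance at which
63% of a volatilized chemical's mass has been degraded or deposited.  The
weight is overridden to 1 when a section centroid falls inside the unit's
polygon (residents are not all at the centroid).  The dependent variable
of the downstream regressions is log10(q_i).

These are estimates of *potential* exposure only: no wind, hydrology, or
mechanistic fate-and-transport is modeled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.strtree import STRtree
from shapely.geometry import Point

__all__ = [
    "aggregate_sections",
    "decay_coefficient",
    "local_use",
    "log_transform",
    "compute_exposure",
    "DEFAULT_CTDS",
]

logger = logging.getLogger(__name__)

#: CTD values (km) of the study design; the literature estimate for
#: chlorpyrifos is 62 km, bracketed here for robustness.
DEFAULT_CTDS = (1.0, 10.0, 30.0, 60.0, 90.0)

# weights below this are indistinguishable from 0 in double precision
_UNDERFLOW = 1e-300


def aggregate_sections(
    records: pd.DataFrame, mode: str = "period_total", n_years: int | None = None
) -> pd.DataFrame:
    """Aggregate use records to one total per section.

    Parameters
    ----------
    records : DataFrame
        Columns ``section_id, x_km, y_km, year, pounds``.
    mode : {"period_total", "annual_mean"}
        ``period_total`` sums pounds over all records; ``annual_mean``
        divides the period total by the number of study years.
    n_years : int, optional
        Number of study years for ``annual_mean``; defaults to the number
        of distinct years present.

    Returns
    -------
    DataFrame with columns ``section_id, x_km, y_km, q`` (pounds), one row
    per section, all q > 0.
    """
    if mode not in ("period_total", "annual_mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    bad = records["pounds"] <= 0
    if bad.any():
        logger.warning("dropping %d use records with nonpositive pounds", bad.sum())
        records = records.loc[~bad]
    if records.empty:
        raise ValueError("no use records remain after filtering")
    if n_years is None:
        n_years = records["year"].nunique()
    out = (
        records.groupby("section_id", sort=True)
        .agg(x_km=("x_km", "first"), y_km=("y_km", "first"), q=("pounds", "sum"))
        .reset_index()
    )
    if mode == "annual_mean":
        out["q"] = out["q"] / n_years
    return out


def decay_coefficient(d_km, ctd_km) -> np.ndarray | float:
    """Exponential decay weight 0.37^(d/CTD) in (0, 1].

    Equals 1 at d = 0 and 0.37 at d = CTD (the defining property of the
    characteristic travel distance: 63% of mass lost at one CTD).  The
    per-km decay-rate constant is ``decay_coefficient(1, ctd)``.
    """
    d = np.asarray(d_km, dtype=float)
    ctd = np.asarray(ctd_km, dtype=float)
    if np.any(ctd <= 0):
        raise ValueError("CTD must be positive")
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = np.float_power(0.37, d / ctd)
    out = np.where(out < _UNDERFLOW, 0.0, out)
    return float(out) if np.isscalar(d_km) and np.isscalar(ctd_km) else out


def local_use(
    centroid_xy: np.ndarray,
    geometry,
    sections: pd.DataFrame,
    ctd_km: float,
) -> float:
    """Distance-weighted local use q_i for one unit.

    Parameters
    ----------
    centroid_xy : (2,) array
        The unit's population-weighted centroid (km).
    geometry : shapely geometry or None
        The unit polygon; sections whose centroid lies inside (boundary
        inclusive) get weight 1 regardless of distance.
    sections : DataFrame
        ``x_km, y_km, q`` section totals.
    ctd_km : float
        Characteristic travel distance (km).
    """
    if sections.empty:
        raise ValueError("sections must be nonempty")
    cx = np.asarray(centroid_xy, dtype=float)
    if cx.shape != (2,) or not np.all(np.isfinite(cx)):
        raise ValueError("unit has no valid weighted centroid")
    pts = sections[["x_km", "y_km"]].to_numpy()
    d = np.hypot(pts[:, 0] - cx[0], pts[:, 1] - cx[1])
    w = decay_coefficient(d, ctd_km)
    if geometry is not None:
        inside = np.array([geometry.covers(Point(x, y)) for x, y in pts])
        w = np.where(inside, 1.0, w)
    return float(np.sum(sections["q"].to_numpy() * w))


def log_transform(q_i):
    """log10 of local use; NaN (flagged for exclusion) where q_i == 0."""
    q = np.asarray(q_i, dtype=float)
    if np.any(q < 0):
        raise ValueError("local use cannot be negative")
    with np.errstate(divide="ignore"):
        out = np.where(q > 0, np.log10(np.where(q > 0, q, 1.0)), np.nan)
    return float(out) if np.isscalar(q_i) else out


def compute_exposure(
    units: pd.DataFrame,
    sections: pd.DataFrame,
    ctds=DEFAULT_CTDS,
) -> pd.DataFrame:
    """Exposure vectors for every unit x CTD combination.

    Parameters
    ----------
    units : DataFrame
        One row per unit with columns ``unit_id, geography_class, cx_km,
        cy_km`` (weighted centroid) and optionally ``geometry`` (shapely
        polygon for the inside-override).
    sections : DataFrame
        Section totals from :func:`aggregate_sections`.
    ctds : sequence of float
        CTD values (km).

    Returns
    -------
    Long DataFrame ``unit_id, geography_class, ctd_km, q_i, log_q_i``;
    log_q_i is NaN where q_i underflows to 0 (those units are excluded
    from the regression for that CTD, and the count is logged).

    Notes
    -----
    Cost is O(units x sections) distance evaluations per CTD; no cutoff
    radius is applied, every section contributes however small its weight.
    """
    pts = sections[["x_km", "y_km"]].to_numpy()
    q_u = sections["q"].to_numpy()
    cxy = units[["cx_km", "cy_km"]].to_numpy(dtype=float)
    D = cdist(cxy, pts)

    # inside-override: section centroids covered by a unit polygon
    inside = np.zeros((len(units), len(sections)), dtype=bool)
    if "geometry" in units.columns:
        geoms = list(units["geometry"])
        tree = STRtree(geoms)
        for j, (x, y) in enumerate(pts):
            p = Point(x, y)
            for gi in tree.query(p, predicate="covers"):
                inside[gi, j] = True

    rows = []
    for ctd in ctds:
        Wgt = decay_coefficient(D, float(ctd))
        Wgt = np.where(inside, 1.0, Wgt)
        qi = Wgt @ q_u
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": units["unit_id"].to_numpy(),
                    "geography_class": units["geography_class"].to_numpy(),
                    "ctd_km": float(ctd),
                    "q_i": qi,
                    "log_q_i": log_transform(qi),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    n_zero = int(out["log_q_i"].isna().sum())
    if n_zero:
        logger.warning("%d unit x CTD cells have zero local use (excluded)", n_zero)
    return out
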