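"""Synthetic study landscapes with a known spatial-Durbin data-generating
process.

No public deposit accompanies the analysis this package implements, so
every pipeline input — point use records, unit polygons, block population
points, and demographic tables with margins of error — is emulated here
on an abstract planar grid (km; the decay model's distances are
Euclidean, so no geodetic projection is needed).  The latent truth behind
each generated table is retained, which is what makes parameter-recovery
and interval-coverage tests possible.

The demographic error model inverts the bootstrap's resampling
assumption: reported = truth + Normal(0, moe_scale), so that resampling
reported values with sd = MOE is correctly specified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .weights import SpatialWeights

__all__ = [
    "LandscapeConfig",
    "DGPConfig",
    "Landscape",
    "gen_landscape",
    "gen_use_records",
    "gen_demographics",
    "gen_outcome",
    "simulate_study",
    "write_inputs",
]

logger = logging.getLogger(__name__)

#: Section lattice spacing: 1 mile-square sections, 1.6 km on a side.
SECTION_SPACING_KM = 1.6

#: Annualized section totals in the source use data span roughly
#: 1e-2 to 1e4 pounds of active ingredient.
DEFAULT_POUNDS_BOUNDS = (1e-2, 1e4)

STUDY_YEARS = (2011, 2012, 2013, 2014, 2015)


@dataclass
class LandscapeConfig:
    """Geometry of a synthetic study area."""

    n_units: int = 100
    grid_extent_km: float = 40.0
    k_blocks_per_unit: int = 5
    section_spacing_km: float = SECTION_SPACING_KM
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 4:
            raise ValueError("n_units must be >= 4")
        if self.grid_extent_km <= 0:
            raise ValueError("grid_extent_km must be positive")
        if self.k_blocks_per_unit < 1:
            raise ValueError("k_blocks_per_unit must be >= 1")


@dataclass
class DGPConfig:
    """Spatial-Durbin data-generating process parameters.

    y = (I - rho W)^{-1} (intercept + X beta + W X theta + eps),
    eps ~ N(0, sigma^2 I).  ``moe_scale`` is the sd of the measurement
    error added to each latent IV to produce its reported value, and is
    published as that IV's margin of error.
    """

    rho: float = 0.4
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    theta: np.ndarray = field(default_factory=lambda: np.array([0.5]))
    sigma: float = 0.2
    moe_scale: np.ndarray = field(default_factory=lambda: np.array([0.05]))
    intercept: float = 0.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.moe_scale = np.broadcast_to(
            np.atleast_1d(np.asarray(self.moe_scale, dtype=float)), self.beta.shape
        ).copy()
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if len(self.beta) != len(self.theta):
            raise ValueError("beta and theta must have equal length")
        if self.sigma < 0 or np.any(self.moe_scale < 0):
            raise ValueError("sigma and moe_scale must be nonnegative")

    @property
    def n_ivs(self) -> int:
        return len(self.beta)

    def total_impacts(self) -> np.ndarray:
        """True total impacts (beta + theta)/(1 - rho), per IV."""
        return (self.beta + self.theta) / (1.0 - self.rho)


@dataclass
class Landscape:
    """Generated geometry bundle."""

    units: pd.DataFrame  # unit_id, geography_class, county_id, geometry, area_km2
    blocks: pd.DataFrame  # unit_id, x_km, y_km, pop
    sections: pd.DataFrame  # section_id, x_km, y_km


def _grid_shape(n_units: int) -> tuple[int, int]:
    """Nearest rows x cols factorization; adjusts n upward if needed."""
    nr = max(2, int(round(np.sqrt(n_units))))
    nc = int(np.ceil(n_units / nr))
    if nr * nc != n_units:
        logger.info(
            "n_units=%d is not a grid; using %dx%d = %d units", n_units, nr, nc, nr * nc
        )
    return nr, nc


def gen_landscape(cfg: LandscapeConfig, geography_class: str = "tract") -> Landscape:
    """Tile the extent with rectangular units, scatter block points, and
    lay the 1.6 km section-centroid lattice.

    Units tile the square extent without overlap; every unit receives
    ``k_blocks_per_unit`` block points with positive populations; county
    labels split the grid into left/right halves.
    """
    rng = np.random.default_rng(cfg.seed)
    nr, nc = _grid_shape(cfg.n_units)
    L = cfg.grid_extent_km
    dx, dy = L / nc, L / nr

    units, blocks = [], []
    for r in range(nr):
        for c in range(nc):
            uid = f"{geography_class[0]}{r * nc + c:04d}"
            x0, y0 = c * dx, r * dy
            geom = box(x0, y0, x0 + dx, y0 + dy)
            units.append(
                {
                    "unit_id": uid,
                    "geography_class": geography_class,
                    "county_id": "west" if c < nc / 2 else "east",
                    "geometry": geom,
                    "area_km2": geom.area,
                }
            )
            bx = rng.uniform(x0, x0 + dx, cfg.k_blocks_per_unit)
            by = rng.uniform(y0, y0 + dy, cfg.k_blocks_per_unit)
            pops = rng.integers(20, 2000, cfg.k_blocks_per_unit)
            for x, y, p in zip(bx, by, pops):
                blocks.append({"unit_id": uid, "x_km": x, "y_km": y, "pop": int(p)})

    s = cfg.section_spacing_km
    ax = np.arange(s / 2, L, s)
    gx, gy = np.meshgrid(ax, ax)
    sections = pd.DataFrame(
        {
            "section_id": [f"s{i:05d}" for i in range(gx.size)],
            "x_km": gx.ravel(),
            "y_km": gy.ravel(),
        }
    )
    return Landscape(pd.DataFrame(units), pd.DataFrame(blocks), sections)


def gen_use_records(
    sections: pd.DataFrame,
    intensity_surface,
    seed: int,
    bounds=DEFAULT_POUNDS_BOUNDS,
    years=STUDY_YEARS,
) -> pd.DataFrame:
    """Point use records: one record per section x year.

    Pounds are drawn log-uniform within ``bounds`` and scaled by the
    (nonnegative) intensity surface evaluated at the section centroid;
    zero-intensity sections produce no records.
    """
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    if not 0 < lo <= hi:
        raise ValueError("bounds must satisfy 0 < lo <= hi")
    inten = np.asarray(
        [intensity_surface(x, y) for x, y in sections[["x_km", "y_km"]].to_numpy()],
        dtype=float,
    )
    if np.any(inten < 0):
        raise ValueError("intensity surface must be nonnegative")
    rows = []
    for year in years:
        draws = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), len(sections))
        pounds = inten * draws
        keep = pounds > 0
        sub = sections.loc[keep]
        rows.append(
            pd.DataFrame(
                {
                    "section_id": sub["section_id"].to_numpy(),
                    "x_km": sub["x_km"].to_numpy(),
                    "y_km": sub["y_km"].to_numpy(),
                    "year": year,
                    "pounds": pounds[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# Latent proportion means loosely follow tract-level descriptive
# statistics for a Central-Valley-like study area.
_IV_PRIORS = {
    "hispanic": (0.42, 0.24),
    "black": (0.05, 0.06),
    "indigenous": (0.02, 0.02),
    "asian": (0.08, 0.08),
    "children": (0.07, 0.03),
    "poverty": (0.22, 0.13),
    "noncitizens": (0.12, 0.08),
    "women": (0.50, 0.03),
    "ag_employment": (0.10, 0.13),
}


def _beta_params(mean, sd):
    v = min(sd**2, mean * (1 - mean) * 0.95)
    nu = mean * (1 - mean) / v - 1
    return max(mean * nu, 0.05), max((1 - mean) * nu, 0.05)


@dataclass
class Demographics:
    """Latent truth and reported (noisy) IV values per unit."""

    truth: pd.DataFrame  # index unit_id, columns = IV names
    reported: pd.DataFrame  # same shape
    moe: pd.DataFrame  # same shape
    clamp_fraction: float


def gen_demographics(
    units: pd.DataFrame,
    dgp: DGPConfig,
    seed: int,
    iv_names=None,
) -> Demographics:
    """Latent IV proportions plus reported estimates with margins of error.

    Latent proportions are Beta-distributed with field-plausible means and
    spreads; reported values add Normal(0, moe_scale) error and are clamped
    to [0, 1] (the clamped fraction is recorded and logged).
    """
    rng = np.random.default_rng(seed)
    p = dgp.n_ivs
    if iv_names is None:
        iv_names = list(_IV_PRIORS)[:p]
    n = len(units)
    truth = {}
    for j, name in enumerate(iv_names):
        mean, sd = _IV_PRIORS.get(name, (0.3, 0.15))
        a, b = _beta_params(mean, sd)
        truth[name] = rng.beta(a, b, n)
    truth = pd.DataFrame(truth, index=pd.Index(units["unit_id"], name="unit_id"))

    noise = rng.normal(0.0, 1.0, (n, p)) * dgp.moe_scale
    reported_raw = truth.to_numpy() + noise
    reported = np.clip(reported_raw, 0.0, 1.0)
    clamp_frac = float(np.mean(reported != reported_raw))
    if clamp_frac > 0:
        logger.info("clamped %.1f%% of reported proportions to [0,1]", 100 * clamp_frac)
    moe = np.broadcast_to(dgp.moe_scale, (n, p)).copy()
    return Demographics(
        truth=truth,
        reported=pd.DataFrame(reported, index=truth.index, columns=truth.columns),
        moe=pd.DataFrame(moe, index=truth.index, columns=truth.columns),
        clamp_fraction=clamp_frac,
    )


def gen_outcome(X, W: SpatialWeights, dgp: DGPConfig, seed: int) -> np.ndarray:
    """Outcome from the spatial-Durbin DGP.

    y = (I - rho W)^{-1} (intercept + X beta + W X theta + eps) with
    eps ~ N(0, sigma^2 I), solved densely.
    """
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != W.n:
        X = X.T
    n = W.n
    Wd = W.matrix.toarray()
    eps = rng.normal(0.0, dgp.sigma, n) if dgp.sigma > 0 else np.zeros(n)
    mean_part = dgp.intercept + X @ dgp.beta + Wd @ X @ dgp.theta + eps
    A = np.eye(n) - dgp.rho * Wd
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"I - rho W is numerically singular (cond={cond:.3g}) at rho={dgp.rho}"
        )
    return np.linalg.solve(A, mean_part)


def simulate_study(
    landscape_cfg: LandscapeConfig,
    dgp: DGPConfig,
    seed: int | None = None,
    geography_classes=("tract", "place"),
):
    """Generate a full multi-class study: shared use surface, one unit
    partition per geography class (places are a coarser partition to mimic
    their sparser coverage).

    Returns a dict with keys ``landscapes`` (per class), ``records``,
    ``demographics`` (per class) and ``seed_sequence`` bookkeeping.
    """
    if seed is None:
        seed = landscape_cfg.seed
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    landscapes = {}
    demographics = {}
    for ci, gclass in enumerate(geography_classes):
        n_units = landscape_cfg.n_units if gclass == "tract" else max(
            4, landscape_cfg.n_units // 2
        )
        cfg = LandscapeConfig(
            n_units=n_units,
            grid_extent_km=landscape_cfg.grid_extent_km,
            k_blocks_per_unit=landscape_cfg.k_blocks_per_unit,
            section_spacing_km=landscape_cfg.section_spacing_km,
            seed=subseeds[0] + ci,
        )
        landscapes[gclass] = gen_landscape(cfg, geography_class=gclass)
        demographics[gclass] = gen_demographics(
            landscapes[gclass].units, dgp, seed=subseeds[1] + ci
        )

    sections = landscapes[geography_classes[0]].sections
    # use intensity rises west->east so exposure correlates with geography
    L = landscape_cfg.grid_extent_km

    def intensity(x, y):
        return 0.1 + 0.9 * (x / L)

    records = gen_use_records(sections, intensity, seed=subseeds[2])
    return {
        "landscapes": landscapes,
        "demographics": demographics,
        "records": records,
        "seed": seed,
    }


def write_inputs(outdir, study, dgp: DGPConfig, employment_rate: float = 0.45) -> dict:
    """Write the four pipeline input files and a manifest.

    Produces, under ``outdir``: ``use_records.csv``,
    ``geographies.geojson`` (all classes in one FeatureCollection),
    ``blocks.csv``, ``demographics.csv`` (paired ``<var>_est`` /
    ``<var>_moe`` count columns derived from the reported proportions),
    and ``manifest.json``.  Returns the file-path dict.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study["records"].to_csv(outdir / "use_records.csv", index=False)

    features = []
    blocks_all = []
    demo_rows = []
    for gclass, ls in study["landscapes"].items():
        blocks_all.append(ls.blocks)
        pop_per_unit = ls.blocks.groupby("unit_id")["pop"].sum()
        dem = study["demographics"][gclass]
        for _, u in ls.units.iterrows():
            uid = u["unit_id"]
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(u["geometry"]),
                    "properties": {
                        "unit_id": uid,
                        "geography_class": gclass,
                        "county_id": u["county_id"],
                    },
                }
            )
            pop = int(pop_per_unit[uid])
            emp = max(1, int(round(employment_rate * pop)))
            row = {
                "unit_id": uid,
                "geography_class": gclass,
                "county_id": u["county_id"],
                "area_km2": u["area_km2"],
                "total_pop_est": pop,
                "total_pop_moe": 0.0,
                "total_employment_est": emp,
                "total_employment_moe": 0.0,
            }
            for name in dem.reported.columns:
                prop = dem.reported.loc[uid, name]
                moe = dem.moe.loc[uid, name]
                den = emp if name == "ag_employment" else pop
                row[f"{name}_est"] = prop * den
                row[f"{name}_moe"] = moe * den
            demo_rows.append(row)

    with open(outdir / "geographies.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    pd.concat(blocks_all, ignore_index=True).to_csv(outdir / "blocks.csv", index=False)
    pd.DataFrame(demo_rows).to_csv(outdir / "demographics.csv", index=False)

    manifest = {
        "seed": study["seed"],
        "dgp": {
            "rho": dgp.rho,
            "beta": dgp.beta.tolist(),
            "theta": dgp.theta.tolist(),
            "sigma": dgp.sigma,
            "moe_scale": dgp.moe_scale.tolist(),
            "intercept": dgp.intercept,
        },
        "iv_names": list(next(iter(study["demographics"].values())).truth.columns),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "use_records": str(outdir / "use_records.csv"),
        "geographies": str(outdir / "geographies.geojson"),
        "blocks": str(outdir / "blocks.csv"),
        "demographics": str(outdir / "demographics.csv"),
        "manifest": str(outdir / "manifest.json"),
    }
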