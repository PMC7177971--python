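"""Full study-design orchestration.

The analysis tracks two researcher degrees of freedom — geographic unit
class (tracts vs places, never pooled) and characteristic travel
distance (1, 10, 30, 60, 90 km) — by running every combination in
parallel: 5 x 2 = 10 model cells.  Each cell is an independent
ingest -> prepare -> exposure -> weights -> SDM -> measurement-error
bootstrap chain with its own derived seed, so subsetting cells never
changes another cell's results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import census, exposure, synth
from .bootstrap import BootstrapConfig, BootstrapSummary, run_bootstrap
from .census import DEFAULT_IVS, IVTable
from .weights import knn_weights

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_tables", "plot_intervals"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either the four input paths or a synthetic landscape spec must be
    given.  Defaults reproduce the 10-cell study design.
    """

    use_records: str | None = None
    geographies: str | None = None
    blocks: str | None = None
    demographics: str | None = None
    synthetic: dict | None = None  # kwargs for LandscapeConfig/DGPConfig
    geography_classes: tuple = ("tract", "place")
    ctds: tuple = exposure.DEFAULT_CTDS
    iv_names: tuple = DEFAULT_IVS
    k_neighbors: int = 3
    aggregation_mode: str = "period_total"
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    outdir: str = "localuse_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bootstrap"] = dict(self.bootstrap.__dict__)
        for key in ("geography_classes", "ctds", "iv_names"):
            d[key] = list(d[key])
        return d


@dataclass
class PipelineResult:
    summaries: dict  # (geography_class, ctd_km) -> BootstrapSummary
    combined: pd.DataFrame
    manifest: dict
    outdir: pathlib.Path
    failures: list


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, outdir: pathlib.Path):
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        ls_cfg = synth.LandscapeConfig(
            n_units=syn.get("n_units", 100),
            grid_extent_km=syn.get("grid_extent_km", 40.0),
            k_blocks_per_unit=syn.get("k_blocks_per_unit", 5),
            seed=cfg.seed,
        )
        dgp = synth.DGPConfig(
            rho=syn.get("rho", 0.4),
            beta=np.asarray(syn.get("beta", [1.0, 0.5])),
            theta=np.asarray(syn.get("theta", [0.5, 0.0])),
            sigma=syn.get("sigma", 0.2),
            moe_scale=np.asarray(syn.get("moe_scale", [0.05, 0.05])),
        )
        study = synth.simulate_study(ls_cfg, dgp, seed=cfg.seed,
                                     geography_classes=cfg.geography_classes)
        paths = synth.write_inputs(outdir / "inputs", study, dgp)
    else:
        paths = {
            "use_records": cfg.use_records,
            "geographies": cfg.geographies,
            "blocks": cfg.blocks,
            "demographics": cfg.demographics,
        }
    for key, p in paths.items():
        if key != "manifest" and (p is None or not pathlib.Path(p).exists()):
            raise FileNotFoundError(f"missing input {key}: {p}")
    records = pd.read_csv(paths["use_records"])
    geoms = census.read_geographies(paths["geographies"])
    blocks = pd.read_csv(paths["blocks"])
    demo = pd.read_csv(paths["demographics"])
    return records, geoms, blocks, demo, paths


def _available_ivs(demo: pd.DataFrame, iv_names) -> tuple:
    """Restrict the IV list to variables present in the table."""
    keep = []
    for name in iv_names:
        if name in ("log_density", "county_log_density"):
            keep.append(name)
        elif name == "county_ag_employment":
            if "ag_employment_est" in demo.columns:
                keep.append(name)
            else:
                logger.info("no ag_employment counts; dropping county control")
        elif f"{name}_est" in demo.columns:
            keep.append(name)
        else:
            logger.info("IV %s not in demographics table; skipping", name)
    return tuple(keep)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full geography-class x CTD design.

    Writes one summary CSV per cell, a combined long-format table, a
    Fig-style interval-plot dataset, and a manifest with the config hash
    and seed.  Raises RuntimeError at the end if any cell aborted.
    """
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, geoms, blocks, demo, paths = _load_inputs(cfg, outdir)
    sections = exposure.aggregate_sections(records, mode=cfg.aggregation_mode)

    cell_seeds = {}
    ss = np.random.SeedSequence(cfg.seed)
    spawned = ss.spawn(len(cfg.geography_classes) * len(cfg.ctds))
    i = 0
    for gclass in cfg.geography_classes:
        for ctd in cfg.ctds:
            cell_seeds[(gclass, float(ctd))] = int(
                spawned[i].generate_state(1)[0] % (2**31)
            )
            i += 1

    summaries: dict = {}
    failures: list = []
    for gclass in cfg.geography_classes:
        dcls = demo[demo["geography_class"] == gclass].copy()
        if dcls.empty:
            logger.warning("no units of class %s; skipping", gclass)
            continue
        retained, excluded = census.filter_units(dcls)
        logger.info(
            "%s: %d units retained, %d excluded", gclass, len(retained), len(excluded)
        )
        iv_names = _available_ivs(retained, cfg.iv_names)
        ivs_all = census.prepare_ivs(retained, iv_names=iv_names)
        cents = census.weighted_centroids(
            blocks[blocks["unit_id"].isin(retained["unit_id"])]
        )
        units = retained[["unit_id", "geography_class"]].merge(
            cents, on="unit_id"
        )
        units = units.merge(
            geoms[["unit_id", "geometry"]], on="unit_id", how="left"
        )
        expo = exposure.compute_exposure(units, sections, ctds=cfg.ctds)

        for ctd in cfg.ctds:
            key = (gclass, float(ctd))
            cell = expo[expo["ctd_km"] == float(ctd)].set_index("unit_id")
            cell = cell.loc[units["unit_id"]]
            ok = cell["log_q_i"].notna()
            if (~ok).any():
                logger.info(
                    "cell %s: dropping %d zero-exposure units", key, int((~ok).sum())
                )
            kept_ids = cell.index[ok]
            u = units.set_index("unit_id").loc[kept_ids]
            try:
                W = knn_weights(
                    u[["cx_km", "cy_km"]].to_numpy(),
                    k=cfg.k_neighbors,
                    ids=np.asarray(kept_ids),
                )
                ivs = IVTable(
                    data=ivs_all.data.loc[kept_ids],
                    moe=ivs_all.moe.loc[kept_ids],
                    proportion_cols=ivs_all.proportion_cols,
                )
                bcfg = BootstrapConfig(
                    n_resamples=cfg.bootstrap.n_resamples,
                    mc_draws_per_resample=cfg.bootstrap.mc_draws_per_resample,
                    moe_to_sd=cfg.bootstrap.moe_to_sd,
                    seed=cell_seeds[key],
                    clamp_proportions=cfg.bootstrap.clamp_proportions,
                    max_failure_frac=cfg.bootstrap.max_failure_frac,
                    trace_order=cfg.bootstrap.trace_order,
                )
                summary = run_bootstrap(
                    cell.loc[kept_ids, "log_q_i"].to_numpy(), ivs, W, bcfg
                )
            except Exception as exc:  # cell-level failures are collected
                logger.error("cell %s aborted: %s", key, exc)
                failures.append({"cell": key, "error": str(exc)})
                continue
            summaries[key] = summary
            _write_cell(outdir, gclass, ctd, summary)

    combined = report_tables(summaries)
    combined.to_csv(outdir / "combined_impacts.csv", index=False)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": {k: str(v) for k, v in paths.items()},
        "n_cells": len(summaries),
        "failures": failures,
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if failures:
        raise RuntimeError(f"{len(failures)} cells aborted: {failures}")
    return PipelineResult(
        summaries=summaries,
        combined=combined,
        manifest=manifest,
        outdir=outdir,
        failures=failures,
    )


def _versions() -> dict:
    import numpy, pandas, scipy, shapely

    from . import __version__

    return {
        "localuse": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "shapely": shapely.__version__,
    }


def _write_cell(outdir, gclass, ctd, summary: BootstrapSummary) -> None:
    tab = summary.table.reset_index()
    tab.insert(1, "geography_class", gclass)
    tab.insert(2, "ctd_km", float(ctd))
    tab["rho_median"] = float(np.median(summary.rho))
    tab["resid_moran_median"] = float(np.median(summary.resid_moran))
    tab["n_failures"] = summary.n_failures
    tab.to_csv(outdir / f"summary_{gclass}_ctd{ctd:g}.csv", index=False)


def report_tables(summaries: dict) -> pd.DataFrame:
    """Combined long-format results across cells.

    One row per (IV, geography_class, CTD) with raw and transformed
    total-impact median and 5/95 percentiles — the plotting dataset for
    interval charts grouped by IV, colored by class, faceted by CTD.
    """
    rows = []
    for (gclass, ctd), s in summaries.items():
        t = s.table
        for iv in t.index:
            rows.append(
                {
                    "iv": iv,
                    "geography_class": gclass,
                    "ctd_km": ctd,
                    "total_median": t.loc[iv, "total_median"],
                    "total_p5": t.loc[iv, "total_p5"],
                    "total_p95": t.loc[iv, "total_p95"],
                    "trans_median": t.loc[iv, "trans_total_median"],
                    "trans_p5": t.loc[iv, "trans_total_p5"],
                    "trans_p95": t.loc[iv, "trans_total_p95"],
                    "rho_median": float(np.median(s.rho)),
                    "resid_moran_median": float(np.median(s.resid_moran)),
                    "n_failures": s.n_failures,
                }
            )
    return pd.DataFrame(rows)


def plot_intervals(combined: pd.DataFrame, path) -> None:
    """Transformed 5-95 interval chart, faceted by CTD, colored by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ctds = sorted(combined["ctd_km"].unique())
    fig, axes = plt.subplots(
        1, len(ctds), figsize=(3.2 * len(ctds), 4.5), sharey=True, squeeze=False
    )
    colors = {"tract": "tab:blue", "place": "tab:red"}
    for ax, ctd in zip(axes[0], ctds):
        sub = combined[combined["ctd_km"] == ctd]
        ivs = sorted(sub["iv"].unique())
        for ci, (gclass, grp) in enumerate(sub.groupby("geography_class")):
            ypos = [ivs.index(v) + 0.15 * ci for v in grp["iv"]]
            ax.hlines(
                ypos, grp["trans_p5"], grp["trans_p95"],
                color=colors.get(gclass, "gray"), label=gclass,
            )
            ax.plot(grp["trans_median"], ypos, "o",
                    color=colors.get(gclass, "gray"), ms=4)
        ax.axvline(1.0, color="k", lw=0.5, ls=":")
        ax.set_xscale("log")
        ax.set_yticks(range(len(ivs)))
        ax.set_yticklabels(ivs)
        ax.set_title(f"CTD = {ctd:g} km")
        ax.set_xlabel("multiplicative change per 10-pt IV increase")
    axes[0][0].legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
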