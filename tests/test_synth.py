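"""Synthetic landscapes, use records, demographics, and the
spatial-Durbin data-generating process."""

import numpy as np
import pandas as pd
import pytest
from shapely.ops import unary_union

from localuse import (
    DGPConfig,
    LandscapeConfig,
    gen_demographics,
    gen_landscape,
    gen_outcome,
    gen_use_records,
    knn_weights,
    morans_i,
    simulate_study,
    weighted_centroids,
    write_inputs,
)


class TestGenLandscape:
    def test_units_tile_extent_without_overlap(self):
        ls = gen_landscape(LandscapeConfig(n_units=4, grid_extent_km=10.0, seed=0))
        assert len(ls.units) == 4
        union = unary_union(list(ls.units["geometry"]))
        assert union.area == pytest.approx(100.0)
        assert sum(g.area for g in ls.units["geometry"]) == pytest.approx(100.0)

    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(n_units=9, grid_extent_km=12.0, seed=3)
        a, b = gen_landscape(cfg), gen_landscape(cfg)
        pd.testing.assert_frame_equal(a.blocks, b.blocks)
        pd.testing.assert_frame_equal(a.sections, b.sections)

    def test_section_lattice_spacing(self):
        # 1.6 km lattice over a 16 km extent -> 10 x 10 centroids
        ls = gen_landscape(LandscapeConfig(n_units=4, grid_extent_km=16.0, seed=0))
        assert len(ls.sections) == 100
        xs = np.sort(ls.sections["x_km"].unique())
        assert np.allclose(np.diff(xs), 1.6)

    def test_every_unit_has_blocks(self):
        ls = gen_landscape(LandscapeConfig(n_units=25, grid_extent_km=20.0, seed=1))
        counts = ls.blocks.groupby("unit_id").size()
        assert (counts >= 1).all() and len(counts) == 25
        assert (ls.blocks["pop"] > 0).all()

    def test_non_rectangular_count_adjusted(self):
        ls = gen_landscape(LandscapeConfig(n_units=7, grid_extent_km=10.0, seed=0))
        assert len(ls.units) >= 7  # rounded up to the nearest grid

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_units=3)
        with pytest.raises(ValueError):
            LandscapeConfig(grid_extent_km=-1)


class TestGenUseRecords:
    def test_zero_intensity_gives_no_records(self, small_landscape):
        recs = gen_use_records(
            small_landscape.sections, lambda x, y: 0.0, seed=0, years=(2011,)
        )
        assert recs.empty

    def test_unit_intensity_unit_bounds(self, small_landscape):
        recs = gen_use_records(
            small_landscape.sections, lambda x, y: 1.0, seed=0,
            bounds=(1.0, 1.0), years=(2011,),
        )
        assert (recs["pounds"] == 1.0).all()

    def test_draws_within_bounds(self):
        sections = pd.DataFrame(
            {
                "section_id": [f"s{i}" for i in range(10_000)],
                "x_km": np.zeros(10_000),
                "y_km": np.zeros(10_000),
            }
        )
        recs = gen_use_records(
            sections, lambda x, y: 1.0, seed=1, bounds=(1e-2, 1e4), years=(2011,)
        )
        assert len(recs) == 10_000
        assert recs["pounds"].between(1e-2, 1e4).all()

    def test_negative_intensity_rejected(self, small_landscape):
        with pytest.raises(ValueError):
            gen_use_records(small_landscape.sections, lambda x, y: -1.0, seed=0)


class TestGenDemographics:
    def test_zero_noise_reports_truth(self, small_landscape):
        dgp = DGPConfig(beta=[1.0], theta=[0.0], moe_scale=[0.0])
        dem = gen_demographics(small_landscape.units, dgp, seed=5)
        pd.testing.assert_frame_equal(dem.truth, dem.reported)
        assert dem.clamp_fraction == 0.0

    def test_noise_sd_recovered(self):
        # 'women' proportions sit near 0.5, so clamping never bites
        units = pd.DataFrame({"unit_id": [f"u{i}" for i in range(10_000)]})
        dgp = DGPConfig(beta=[1.0], theta=[0.0], moe_scale=[0.05])
        dem = gen_demographics(units, dgp, seed=6, iv_names=["women"])
        err = (dem.reported - dem.truth).to_numpy().ravel()
        assert np.std(err) == pytest.approx(0.05, rel=0.02)

    def test_reported_proportions_clamped(self):
        units = pd.DataFrame({"unit_id": [f"u{i}" for i in range(2_000)]})
        dgp = DGPConfig(beta=[1.0], theta=[0.0], moe_scale=[0.5])
        dem = gen_demographics(units, dgp, seed=7, iv_names=["indigenous"])
        vals = dem.reported.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert dem.clamp_fraction > 0


class TestGenOutcome:
    def test_collapses_to_linear_model(self, small_weights):
        dgp = DGPConfig(rho=0.0, beta=[2.0], theta=[0.0], sigma=0.0, moe_scale=[0.0])
        X = np.linspace(0, 1, small_weights.n)[:, None]
        y = gen_outcome(X, small_weights, dgp, seed=0)
        assert np.allclose(y, 2.0 * X[:, 0])

    def test_matches_dense_solve(self):
        # n=5 hand check against a brute-force linear solve
        coords = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [2, 1]], dtype=float)
        W = knn_weights(coords, k=2)
        dgp = DGPConfig(rho=0.6, beta=[1.5], theta=[-0.5], sigma=0.0, moe_scale=[0.0])
        X = np.arange(5.0)[:, None]
        y = gen_outcome(X, W, dgp, seed=0)
        Wd = W.matrix.toarray()
        expected = np.linalg.solve(
            np.eye(5) - 0.6 * Wd, 1.5 * X[:, 0] - 0.5 * (Wd @ X)[:, 0]
        )
        assert np.allclose(y, expected, atol=1e-12)

    def test_positive_rho_induces_positive_moran(self, medium_weights):
        dgp = DGPConfig(rho=0.5, beta=[0.0], theta=[0.0], sigma=1.0, moe_scale=[0.0])
        X = np.zeros((medium_weights.n, 1))
        vals = [
            morans_i(gen_outcome(X, medium_weights, dgp, seed=s), medium_weights)
            for s in range(100)
        ]
        assert np.mean(vals) > 0.1

    def test_reproducible_given_seed(self, medium_weights, simple_dgp):
        X = np.random.default_rng(1).normal(size=(medium_weights.n, 2))
        y1 = gen_outcome(X, medium_weights, simple_dgp, seed=9)
        y2 = gen_outcome(X, medium_weights, simple_dgp, seed=9)
        assert np.array_equal(y1, y2)


def test_write_inputs_roundtrip(tmp_path, simple_dgp):
    """The generator's files are exactly what the ingestion side reads."""
    from localuse import read_geographies

    study = simulate_study(
        LandscapeConfig(n_units=9, grid_extent_km=12.0, seed=2), simple_dgp
    )
    paths = write_inputs(tmp_path, study, simple_dgp)
    geo = read_geographies(paths["geographies"])
    demo = pd.read_csv(paths["demographics"])
    blocks = pd.read_csv(paths["blocks"])
    assert set(geo["geography_class"]) == {"tract", "place"}
    assert set(geo["unit_id"]) == set(demo["unit_id"])
    assert set(blocks["unit_id"]) >= set(geo["unit_id"])
    for col in ("hispanic_est", "hispanic_moe", "total_pop_est", "area_km2"):
        assert col in demo.columns
    # centroid of every unit lies inside its polygon bounding box
    cents = weighted_centroids(blocks).set_index("unit_id")
    for _, row in geo.iterrows():
        cx, cy = cents.loc[row["unit_id"], ["cx_km", "cy_km"]]
        minx, miny, maxx, maxy = row["geometry"].bounds
        assert minx <= cx <= maxx and miny <= cy <= maxy
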