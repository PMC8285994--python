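"""Simulator: layout geometry, population sampling, rendering, fixture I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from cncenum.chipsim import (
    FIXED_ROUND,
    LIVE_ROUND,
    ChipLayout,
    PopulationModel,
    build_layout,
    read_fixture,
    render_images,
    sample_population,
    write_fixture,
    TRUTH_COLUMNS,
)
from cncenum.errors import ConfigurationError, PlacementError


class TestLayout:
    def test_default_is_100_blocks_of_64_wells(self):
        layout = build_layout({})
        assert layout.n_blocks == 100
        assert layout.wells_per_block == 64
        assert layout.total_wells == 6400
        assert layout.well_diameter_um == 30.0
        assert layout.well_depth_um == 20.0

    def test_counts_factorize_into_grids(self):
        layout = build_layout({"n_blocks": 100, "wells_per_block": 64})
        assert layout.block_grid == (10, 10)
        assert layout.well_grid == (8, 8)

    def test_single_well_layout(self):
        layout = build_layout({"block_grid": (1, 1), "well_grid": (1, 1)})
        assert layout.total_wells == 1
        centers = layout.well_centers()
        assert len(centers) == 1
        h, w = layout.image_shape
        assert centers.loc[0, "x_px"] == pytest.approx(w / 2, abs=1)
        assert centers.loc[0, "y_px"] == pytest.approx(h / 2, abs=1)

    @pytest.mark.parametrize("bad", [
        {"well_pitch_um": 20.0},                    # pitch < diameter
        {"block_grid": (3, 3), "n_blocks": 10},     # inconsistent grid
        {"pixel_size_um": -1.0},
        {"not_a_field": 1},
    ])
    def test_invalid_configs_raise(self, bad):
        with pytest.raises(ConfigurationError):
            build_layout(bad)

    def test_well_centers_unique_and_inside(self, mid_layout):
        centers = mid_layout.well_centers()
        assert len(centers) == mid_layout.total_wells
        assert centers.duplicated(["block_id", "well_id"]).sum() == 0
        h, w = mid_layout.image_shape
        r = mid_layout.well_radius_px
        assert (centers["x_px"] > r).all() and (centers["x_px"] < w - r).all()
        assert (centers["y_px"] > r).all() and (centers["y_px"] < h - r).all()


class TestPopulationModel:
    @pytest.mark.parametrize("bad", [
        {"cnc_prevalence": 1.5},
        {"live_fraction": -0.1},
        {"read_noise_sd": -1.0},
        # CNC NeuN mass not above the leukocyte mean + 3 SD
        {"cnc_neun_dist": {"kind": "lognormal", "median": 120.0, "sigma": 0.3}},
    ])
    def test_invalid_models_raise(self, bad):
        with pytest.raises(ConfigurationError):
            PopulationModel(**bad)


class TestSamplePopulation:
    def test_seed_determinism(self, mid_layout, default_model):
        a = sample_population(mid_layout, default_model, seed=5)
        b = sample_population(mid_layout, default_model, seed=5)
        c = sample_population(mid_layout, default_model, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_zero_occupancy_gives_empty_truth(self, mid_layout):
        model = PopulationModel(mean_cells_per_well=0.0)
        truth = sample_population(mid_layout, model, seed=1)
        assert len(truth) == 0
        assert list(truth.columns) == TRUTH_COLUMNS

    def test_zero_prevalence_gives_no_cncs(self, mid_layout):
        model = PopulationModel(cnc_prevalence=0.0)
        truth = sample_population(mid_layout, model, seed=1)
        assert (truth["true_class"] == "cnc").sum() == 0

    def test_exact_spike_in_count(self, mid_layout):
        model = PopulationModel(cnc_prevalence=0.0)
        truth = sample_population(mid_layout, model, seed=3, exact_n_cnc=25)
        assert (truth["true_class"] == "cnc").sum() == 25

    def test_cells_map_to_wells_and_stay_inside(self, big_truth):
        truth, layout = big_truth["truth"], big_truth["layout"]
        centers = layout.well_centers().set_index(["block_id", "well_id"])
        joined = truth.join(centers, on=["block_id", "well_id"], rsuffix="_well")
        d = np.hypot(joined["x_px"] - joined["x_px_well"],
                     joined["y_px"] - joined["y_px_well"])
        assert (d <= layout.well_radius_px + 1e-9).all()

    def test_cnc_prevalence_binomial(self, big_truth):
        """The realized CNC fraction stays within 3 binomial SDs of the
        configured 19% prevalence among non-debris cells."""
        truth, model = big_truth["truth"], big_truth["model"]
        cells = truth[truth["true_class"] != "debris"]
        p = model.cnc_prevalence
        frac = (cells["true_class"] == "cnc").mean()
        band = 3 * np.sqrt(p * (1 - p) / len(cells))
        assert abs(frac - p) <= band

    def test_live_fraction_binomial(self, big_truth):
        truth, model = big_truth["truth"], big_truth["model"]
        cnc_live = truth.loc[truth["true_class"] == "cnc", "is_live"]
        p = model.live_fraction
        band = 3 * np.sqrt(p * (1 - p) / len(cnc_live))
        assert abs(float(cnc_live.mean()) - p) <= band

    def test_is_live_defined_only_for_cells(self, big_truth):
        truth = big_truth["truth"]
        assert truth.loc[truth["true_class"] == "debris", "is_live"].isna().all()
        assert truth.loc[truth["true_class"] != "debris", "is_live"].notna().all()

    def test_occupancy_is_poisson(self, big_truth):
        """Chi-square goodness of fit of per-well counts (zeros included)
        against Poisson with the configured mean, at 10,000 wells."""
        truth, layout, model = big_truth["truth"], big_truth["layout"], big_truth["model"]
        per_well = truth.groupby(["block_id", "well_id"]).size()
        centers = layout.well_centers().set_index(["block_id", "well_id"])
        occ = per_well.reindex(centers.index, fill_value=0).to_numpy()
        kmax = 7
        observed = np.bincount(np.minimum(occ, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), model.mean_cells_per_well)
        expected = np.append(pmf, 1.0 - pmf.sum()) * layout.total_wells
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 1e-3

    @given(seed=st.integers(0, 10_000))
    def test_monolayer_separation_in_sparse_wells(self, seed):
        """Cells sharing a well keep at least one cell diameter between
        centers whenever the well is not overcrowded."""
        layout = build_layout({"block_grid": (1, 1), "well_grid": (2, 2)})
        model = PopulationModel(mean_cells_per_well=2.0, debris_rate=0.0)
        truth = sample_population(layout, model, seed=seed)
        min_sep = model.cell_diameter_um / layout.pixel_size_um
        for _, grp in truth.groupby(["block_id", "well_id"]):
            if len(grp) < 2 or len(grp) > 3:
                continue
            xy = grp[["x_px", "y_px"]].to_numpy()
            for i in range(len(xy)):
                for j in range(i + 1, len(xy)):
                    assert np.hypot(*(xy[i] - xy[j])) >= min_sep - 1e-6


class TestRenderImages:
    def test_empty_truth_is_background_plus_noise(self, small_layout, default_model):
        truth = sample_population(
            small_layout, PopulationModel(mean_cells_per_well=0.0), seed=1
        )
        img = render_images(truth, small_layout, default_model, FIXED_ROUND, seed=2)
        dapi = img.channels["DAPI"].astype(float)
        se = default_model.read_noise_sd / np.sqrt(dapi.size)
        assert abs(dapi.mean() - default_model.background_level) <= 3 * se + 0.5
        # zero-noise scene is exactly flat background
        quiet = PopulationModel(read_noise_sd=0.0)
        img0 = render_images(truth, small_layout, quiet, FIXED_ROUND, seed=2)
        assert (img0.channels["DAPI"] == quiet.background_level).all()

    def test_round_channel_sets(self, mid_scene):
        assert set(mid_scene[LIVE_ROUND].channels) == {"CD45_APC", "NBDG"}
        assert set(mid_scene[FIXED_ROUND].channels) == {"DAPI", "NeuN_FITC", "CD45_APC"}
        shapes = {img.shape for img in
                  (mid_scene[LIVE_ROUND], mid_scene[FIXED_ROUND])}
        assert shapes == {mid_scene["layout"].image_shape}

    def test_single_spot_photometry_matches_analytic_profile(self, small_layout):
        """At zero noise the excess flux of one rendered spot equals
        amplitude x the analytic smoothed-disk integral, and flux is
        proportional to amplitude."""
        model = PopulationModel(read_noise_sd=0.0, debris_rate=0.0)
        centers = small_layout.well_centers()
        flux = {}
        for amp in (500.0, 1000.0):
            truth = pd.DataFrame([{
                "cell_id": "cell0", "block_id": 0, "well_id": 0,
                "x_px": centers.loc[0, "x_px"], "y_px": centers.loc[0, "y_px"],
                "true_class": "cnc", "is_live": True,
                "dapi_true": amp, "neun_true": 0.0, "cd45_true": 0.0, "nbdg_true": 0.0,
            }])
            img = render_images(truth, small_layout, model, FIXED_ROUND, seed=0)
            dapi = img.channels["DAPI"].astype(float)
            flux[amp] = dapi.sum() - model.background_level * dapi.size

        # independent oracle: brute-force grid integral of the erf-edged disk
        r0 = model.spot_radius_um / small_layout.pixel_size_um
        sig = model.psf_sigma_um / small_layout.pixel_size_um
        gy, gx = np.mgrid[-20:21, -20:21]
        d = np.hypot(gx, gy)
        area_eff = (0.5 * special.erfc((d - r0) / (np.sqrt(2) * sig))).sum()
        for amp, f in flux.items():
            assert f == pytest.approx(amp * area_eff, rel=0.02)
        assert flux[1000.0] == pytest.approx(2 * flux[500.0], rel=0.02)

    def test_dapi_peak_count_equals_cell_count(self, small_layout, clean_model):
        """A noise-free fixed-round scene has exactly one DAPI local maximum
        per nucleated truth cell."""
        from scipy import ndimage as ndi
        from skimage.feature import peak_local_max

        truth = sample_population(small_layout, clean_model, seed=11)
        img = render_images(truth, small_layout, clean_model, FIXED_ROUND, seed=0)
        smooth = ndi.gaussian_filter(img.channels["DAPI"].astype(float), 1.0)
        peaks = peak_local_max(
            smooth, min_distance=5,
            threshold_abs=clean_model.background_level + 50,
        )
        assert len(peaks) == len(truth)

    def test_out_of_bounds_cell_raises(self, small_layout, default_model):
        truth = pd.DataFrame([{
            "cell_id": "cellX", "block_id": 0, "well_id": 0,
            "x_px": 1.0, "y_px": 1.0, "true_class": "leukocyte", "is_live": True,
            "dapi_true": 100.0, "neun_true": 0.0, "cd45_true": 0.0, "nbdg_true": 0.0,
        }])
        with pytest.raises(PlacementError, match="cellX"):
            render_images(truth, small_layout, default_model, FIXED_ROUND, seed=0)

    def test_render_seed_determinism(self, small_layout, default_model):
        truth = sample_population(small_layout, default_model, seed=4)
        a = render_images(truth, small_layout, default_model, LIVE_ROUND, seed=9)
        b = render_images(truth, small_layout, default_model, LIVE_ROUND, seed=9)
        for ch in a.channels:
            assert (a.channels[ch] == b.channels[ch]).all()


class TestFixtureIO:
    def test_roundtrip_is_lossless(self, tmp_path, small_layout, default_model):
        ss = np.random.SeedSequence(31)
        s_pop, s_live, s_fixed = ss.spawn(3)
        truth = sample_population(small_layout, default_model, s_pop)
        images = [
            render_images(truth, small_layout, default_model, LIVE_ROUND, s_live),
            render_images(truth, small_layout, default_model, FIXED_ROUND, s_fixed),
        ]
        write_fixture(truth, images, tmp_path / "fx", default_model)
        truth2, images2, layout2, model2 = read_fixture(tmp_path / "fx")

        assert layout2 == small_layout
        assert model2 == default_model
        assert list(truth2.columns) == TRUTH_COLUMNS
        pd.testing.assert_frame_equal(truth2, truth, check_dtype=False)
        for img in images:
            for ch, grid in img.channels.items():
                assert (images2[img.round_id].channels[ch] == grid).all()
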