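"""Bad-pixel masking, plot validity, and plot-level aggregation."""

import numpy as np
import pytest

from ricelai.exceptions import BoundsError, EmptyROIError
from ricelai.extraction import (
    BadPixelMask,
    assess_plot_validity,
    compute_measured_lai,
    extract_observations,
    mask_bad_pixels,
    observation_table,
    plot_canopy_height,
    plot_mean_reflectance,
)
from ricelai.indices import WAVELENGTHS_NM
from ricelai.synthetic import (
    PlotROI,
    RenderOptions,
    SamplingRecord,
    generate_cultivars,
    render_campaign,
    simulate_destructive_sampling,
)

N_BANDS = len(WAVELENGTHS_NM)


class TestMaskBadPixels:
    def test_saturated_in_all_bands_is_bad(self):
        dn = np.full((N_BANDS, 1, 1), 255, dtype=np.uint8)
        assert mask_bad_pixels(dn).mask[0, 0]

    def test_one_clean_band_rescues_the_pixel(self):
        dn = np.full((N_BANDS, 1, 1), 255, dtype=np.uint8)
        dn[5] = 200
        assert not mask_bad_pixels(dn).mask[0, 0]

    def test_threshold_is_strict(self):
        dn = np.full((N_BANDS, 1, 1), 250, dtype=np.uint8)
        assert not mask_bad_pixels(dn).mask[0, 0]  # 250 is not > 250

    def test_constructed_count_on_3x3(self):
        dn = np.full((N_BANDS, 3, 3), 100, dtype=np.uint8)
        for r, c in [(0, 0), (0, 2), (1, 1), (2, 2)]:
            dn[:, r, c] = 255
        mask = mask_bad_pixels(dn)
        assert int(mask.mask.sum()) == 4
        assert mask.count_in(PlotROI("p", 0, 0, 3, 3)) == 4

    def test_float_raster_rejected(self):
        with pytest.raises(ValueError):
            mask_bad_pixels(np.zeros((N_BANDS, 2, 2)))


class TestPlotValidity:
    def make_mask(self, n_bad, shape=(20, 40)):
        m = np.zeros(shape, dtype=bool)
        m.flat[:n_bad] = True
        return BadPixelMask(mask=m)

    def test_more_than_hundred_invalidates(self):
        roi = PlotROI("p", 0, 0, 20, 40)
        assert not assess_plot_validity(roi, self.make_mask(101))

    def test_exactly_hundred_still_valid(self):
        roi = PlotROI("p", 0, 0, 20, 40)
        assert assess_plot_validity(roi, self.make_mask(100))

    def test_clean_plot_valid(self):
        roi = PlotROI("p", 0, 0, 20, 40)
        assert assess_plot_validity(roi, self.make_mask(0))

    def test_roi_outside_grid_rejected(self):
        roi = PlotROI("p", 0, 0, 30, 30)
        with pytest.raises(BoundsError):
            assess_plot_validity(roi, self.make_mask(0, shape=(10, 10)))


class TestPlotMeanReflectance:
    def test_constant_field(self):
        refl = np.full((N_BANDS, 4, 4), 0.3)
        got = plot_mean_reflectance(refl, PlotROI("p", 0, 0, 4, 4))
        assert np.allclose(got, 0.3)

    def test_two_pixel_mean(self):
        refl = np.zeros((N_BANDS, 1, 2))
        refl[:, 0, 0], refl[:, 0, 1] = 0.2, 0.4
        got = plot_mean_reflectance(refl, PlotROI("p", 0, 0, 1, 2))
        assert np.allclose(got, 0.3)

    def test_masked_pixel_excluded(self):
        refl = np.zeros((N_BANDS, 1, 2))
        refl[:, 0, 0], refl[:, 0, 1] = 0.2, 0.4
        mask = BadPixelMask(mask=np.array([[False, True]]))
        got = plot_mean_reflectance(refl, PlotROI("p", 0, 0, 1, 2), mask)
        assert np.allclose(got, 0.2)

    def test_fully_masked_roi_rejected(self):
        refl = np.zeros((N_BANDS, 1, 2))
        mask = BadPixelMask(mask=np.ones((1, 2), dtype=bool))
        with pytest.raises(EmptyROIError):
            plot_mean_reflectance(refl, PlotROI("p", 0, 0, 1, 2), mask)


class TestCanopyHeight:
    def test_dsm_differencing(self):
        dsm = np.full((3, 3), 30.95)
        soil = np.full((3, 3), 30.0)
        h = plot_canopy_height(dsm, soil, PlotROI("p", 0, 0, 3, 3))
        assert h == pytest.approx(0.95)

    def test_equal_surfaces_give_zero(self):
        dsm = np.full((2, 2), 30.0)
        assert plot_canopy_height(dsm, dsm, PlotROI("p", 0, 0, 2, 2)) == 0.0

    def test_two_pixel_mean(self):
        dsm = np.array([[30.8, 31.0]])
        soil = np.full((1, 2), 30.0)
        h = plot_canopy_height(dsm, soil, PlotROI("p", 0, 0, 1, 2))
        assert h == pytest.approx(0.9)

    def test_negative_differences_clamped(self):
        dsm = np.array([[29.5, 31.0]])
        soil = np.full((1, 2), 30.0)
        h = plot_canopy_height(dsm, soil, PlotROI("p", 0, 0, 1, 2))
        assert h == pytest.approx(0.5)  # (0 + 1.0) / 2

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            plot_canopy_height(np.zeros((2, 2)), np.zeros((3, 3)),
                               PlotROI("p", 0, 0, 2, 2))


class TestMeasuredLAI:
    @pytest.mark.parametrize("total,expected", [(0.6, 4.5), (0.0, 0.0),
                                                (0.4, 3.0)])
    def test_formula_arithmetic(self, total, expected):
        rec = SamplingRecord("p", 50, (total / 3,) * 3)
        assert compute_measured_lai(rec) == pytest.approx(expected)

    def test_non_positive_density_rejected(self):
        rec = SamplingRecord("p", 50, (0.1, 0.1, 0.1), plant_density=0.0)
        with pytest.raises(ValueError):
            compute_measured_lai(rec)

    def test_negative_leaf_area_rejected(self):
        rec = SamplingRecord("p", 50, (0.1, -0.1, 0.1))
        with pytest.raises(ValueError):
            compute_measured_lai(rec)


class TestEndToEndScene:
    def test_noiseless_scene_recovers_truth(self):
        # plot means match the simulated spectrum within DN quantization and
        # plot heights match the simulated height exactly on a flat DSM
        cvs = generate_cultivars(8, seed=3)
        opts = RenderOptions(water_bad_plots=0).noiseless()
        scene = render_campaign(cvs, dat=50, options=opts, seed=4)
        from ricelai.synthetic import default_true_calibration
        cal = default_true_calibration()
        sampling = [
            simulate_destructive_sampling(row.true_lai, 0.0, 0,
                                          plot_id=row.plot_id, dat=50)
            for row in scene.truth.itertuples()
        ]
        obs = extract_observations(scene, cal, cvs, sampling)
        from ricelai.synthetic import simulate_spectrum
        for o, row in zip(obs, scene.truth.itertuples()):
            assert o.valid
            expected = simulate_spectrum(row.true_lai, 50 - row.heading_dat,
                                         0, noise_cv=0, f_jitter_sd=0,
                                         nir_jitter_sd=0)
            assert np.max(np.abs(o.reflectance - expected)) \
                <= cal.gain.max() / 2 + 1e-6
            assert o.height == pytest.approx(row.true_height, abs=1e-6)
            assert o.lai == pytest.approx(row.true_lai, abs=1e-9)

    def test_invalid_plots_carry_no_data_downstream(self):
        cvs = generate_cultivars(48, seed=3)
        scene = render_campaign(
            cvs, dat=17, options=RenderOptions(water_bad_plots=24), seed=5)
        from ricelai.synthetic import default_true_calibration
        sampling = [
            simulate_destructive_sampling(row.true_lai, 0.05, i,
                                          plot_id=row.plot_id, dat=17)
            for i, row in enumerate(scene.truth.itertuples())
        ]
        obs = extract_observations(scene, default_true_calibration(), cvs,
                                   sampling)
        table = observation_table(obs)
        assert (~table["valid"]).sum() == 24
        invalid = table[~table["valid"]]
        assert invalid["height"].isna().all()
        assert invalid[[f"r{w}" for w in WAVELENGTHS_NM]].isna().all().all()
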