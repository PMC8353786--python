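"""Contracts of the synthetic campaign generator."""

import numpy as np
import pytest

from ricelai.calibration import CANVAS_REFLECTANCES
from ricelai.exceptions import LayoutError
from ricelai.extraction import (
    assess_plot_validity,
    compute_measured_lai,
    mask_bad_pixels,
)
from ricelai.indices import INDEX_NAMES, compute_all_indices
from ricelai.synthetic import (
    HEADING_DAT_RANGE,
    HEIGHT_FINAL_RANGE,
    LAI_MAX_RANGE,
    CultivarParams,
    GridLayout,
    RenderOptions,
    SOIL_ENDMEMBER,
    generate_cultivars,
    render_campaign,
    simulate_destructive_sampling,
    simulate_spectrum,
    simulate_trajectories,
)

NOISE_OFF = dict(noise_cv=0.0, f_jitter_sd=0.0, nir_jitter_sd=0.0)


class TestGenerateCultivars:
    def test_bounds_of_48_cultivars(self):
        cvs = generate_cultivars(48, seed=7)
        assert len(cvs) == 48
        for c in cvs:
            assert HEADING_DAT_RANGE[0] <= c.heading_dat <= HEADING_DAT_RANGE[1]
            assert LAI_MAX_RANGE[0] <= c.lai_max <= LAI_MAX_RANGE[1]
            assert HEIGHT_FINAL_RANGE[0] <= c.height_final <= HEIGHT_FINAL_RANGE[1]

    def test_seeded_determinism(self):
        assert generate_cultivars(1, seed=0) == generate_cultivars(1, seed=0)

    def test_large_sample_stays_inside_lai_bounds(self):
        # exhaustive scan of 1000 draws against the trial's observed range
        lai_max = [c.lai_max for c in generate_cultivars(1000, seed=1)]
        assert min(lai_max) >= LAI_MAX_RANGE[0]
        assert max(lai_max) <= LAI_MAX_RANGE[1]

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_cultivars(0, seed=0)


class TestTrajectories:
    def test_lai_peaks_ten_days_before_heading(self):
        cv = CultivarParams("x", 65, 6.0, 1.0, 0.13, 0.07)
        dats = np.arange(17, 87)
        lai, _ = simulate_trajectories(cv, dats)
        assert dats[np.argmax(lai)] == 55

    def test_season_start_is_bare(self):
        cv = CultivarParams("x", 65, 6.0, 1.0, 0.13, 0.07)
        lai, h = simulate_trajectories(cv, [0])
        assert lai[0] == pytest.approx(0.0, abs=1e-9)
        assert h[0] == pytest.approx(0.0, abs=0.01)

    def test_height_keeps_rising_after_heading(self):
        cv = CultivarParams("x", 65, 6.0, 1.0, 0.13, 0.07)
        _, h = simulate_trajectories(cv, [65, 70])
        assert h[1] > h[0]

    @pytest.mark.parametrize("cv", generate_cultivars(25, seed=5),
                             ids=lambda c: c.cultivar_id)
    def test_peak_ordering_and_caps(self, cv):
        dats = np.arange(0, 95)
        lai, h = simulate_trajectories(cv, dats)
        lai_peak = dats[np.argmax(lai)]
        # LAI peak ~10 days before heading (within the daily grid), height
        # peak after heading; unimodal decline on both sides
        assert abs(lai_peak - (cv.heading_dat - 10)) <= 1
        assert lai_peak < cv.heading_dat < dats[np.argmax(h)]
        after = lai[lai_peak:]
        assert np.all(np.diff(after) <= 1e-12)
        t_hpeak = cv.heading_dat + 5
        assert np.all(np.diff(h[: t_hpeak + 1]) >= -1e-12)
        assert h[-1] >= 0.95 * h.max() - 1e-12
        assert lai.max() <= cv.lai_max + 1e-9
        assert h.max() <= cv.height_final + 1e-9

    def test_unsorted_dates_rejected(self):
        cv = CultivarParams("x", 65, 6.0, 1.0, 0.13, 0.07)
        with pytest.raises(ValueError):
            simulate_trajectories(cv, [30, 20])
        with pytest.raises(ValueError):
            simulate_trajectories(cv, [-1, 5])


class TestSpectrum:
    def test_post_heading_visible_brightening(self):
        pre = simulate_spectrum(2.9, -20, seed=0, **NOISE_OFF)
        post = simulate_spectrum(2.9, +20, seed=0, **NOISE_OFF)
        visible = slice(0, 7)  # 490-700 nm
        assert np.all(post[visible] >= 1.5 * pre[visible])
        assert post[2] >= 2.0 * pre[2]  # green
        assert post[4] >= 2.0 * pre[4]  # red

    def test_dense_canopy_nir_drops_after_heading(self):
        pre = simulate_spectrum(5.0, -20, seed=0, **NOISE_OFF)
        post = simulate_spectrum(5.0, +20, seed=0, **NOISE_OFF)
        assert np.all(post[8:12] < pre[8:12])  # 800-950 nm

    def test_zero_lai_is_soil_endmember(self):
        for d in (-30, 0, 30):
            rho = simulate_spectrum(0.0, d, seed=3, noise_cv=0.0)
            assert np.allclose(rho, SOIL_ENDMEMBER)

    def test_reflectance_in_unit_interval_and_seeded(self):
        a = simulate_spectrum(3.0, 10, seed=42)
        b = simulate_spectrum(3.0, 10, seed=42)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))

    @pytest.mark.parametrize("lai", [1.0, 2.9, 5.0])
    def test_all_indices_depressed_after_heading(self, lai):
        # the hysteresis the pipeline must detect is built in by construction
        pre = compute_all_indices(simulate_spectrum(lai, -20, 0, **NOISE_OFF))
        at_heading = compute_all_indices(
            simulate_spectrum(lai, 0, 0, **NOISE_OFF))
        late = compute_all_indices(simulate_spectrum(lai, 20, 0, **NOISE_OFF))
        for name in INDEX_NAMES:
            assert at_heading[name] < pre[name]
            assert late[name] < pre[name]

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectrum(-0.1, 0, seed=0)


class TestRenderCampaign:
    def test_canvas_panels_at_standard_reflectances(self):
        cvs = generate_cultivars(8, seed=2)
        scene = render_campaign(cvs, dat=50, seed=1)
        assert sorted(r for _, r in scene.canvas_panels) \
            == sorted(CANVAS_REFLECTANCES)
        assert scene.dn.dtype == np.uint8

    def test_clean_scene_keeps_all_plots(self):
        cvs = generate_cultivars(8, seed=2)
        scene = render_campaign(
            cvs, dat=50, options=RenderOptions(water_bad_plots=0), seed=1)
        mask = mask_bad_pixels(scene.dn)
        assert all(assess_plot_validity(r, mask) for r in scene.plot_rois)

    def test_water_contamination_invalidates_exact_count(self):
        cvs = generate_cultivars(48, seed=2)
        scene = render_campaign(
            cvs, dat=17, options=RenderOptions(water_bad_plots=24), seed=1)
        mask = mask_bad_pixels(scene.dn)
        valid = [assess_plot_validity(r, mask) for r in scene.plot_rois]
        assert sum(valid) == 24

    def test_bit_identical_rerun(self):
        cvs = generate_cultivars(8, seed=2)
        a = render_campaign(cvs, dat=50, seed=9)
        b = render_campaign(cvs, dat=50, seed=9)
        assert np.array_equal(a.dn, b.dn)
        assert np.array_equal(a.dsm, b.dsm)
        assert a.truth.equals(b.truth)

    def test_layout_overflow_rejected(self):
        cvs = generate_cultivars(10, seed=2)
        with pytest.raises(LayoutError):
            render_campaign(cvs, dat=50, layout=GridLayout(n_plots=8))


class TestDestructiveSampling:
    def test_noiseless_inversion_of_lai_formula(self):
        # LAI = LA/n * rho with n=3, rho=22.5 inverts to 0.6 m2 total
        rec = simulate_destructive_sampling(4.5, noise_sd=0.0, seed=0)
        assert sum(rec.leaf_areas) == pytest.approx(0.6)
        assert len(rec.leaf_areas) == 3
        assert compute_measured_lai(rec) == pytest.approx(4.5)

    def test_zero_lai_gives_zero_leaf_area(self):
        rec = simulate_destructive_sampling(0.0, noise_sd=0.1, seed=1)
        assert all(la == 0 for la in rec.leaf_areas)

    def test_monte_carlo_unbiasedness(self):
        # 10^4 replicates: implied LAI unbiased for the true value within 1%
        vals = [
            compute_measured_lai(
                simulate_destructive_sampling(3.0, noise_sd=0.05, seed=s))
            for s in range(10_000)
        ]
        assert np.mean(vals) == pytest.approx(3.0, rel=0.01)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_destructive_sampling(-1.0, 0.05, seed=0)
        with pytest.raises(ValueError):
            simulate_destructive_sampling(1.0, -0.05, seed=0)
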