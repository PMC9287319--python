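import numpy as np
import pytest

from irrimap import (
    SynthConfig,
    degrade_product,
    draw_samples,
    generate_gi_stack,
    generate_landscape,
    generate_scene,
    generate_statistics,
)


class TestGenerateLandscape:
    def test_fractions_and_region_count(self):
        cfg = SynthConfig(shape=(100, 100), n_regions=5, cropland_fraction=0.5,
                          irrigated_fraction=0.4, seed=7)
        regions, cropland, truth = generate_landscape(cfg)
        assert len(np.unique(regions.values)) == 5
        crop_frac = cropland.values.mean()
        irr_frac = truth.values.sum() / cropland.values.sum()
        assert abs(crop_frac - 0.5) <= 0.05
        assert abs(irr_frac - 0.4) <= 0.05

    def test_truth_subset_of_cropland(self, small_scene):
        assert not (small_scene.truth.values.astype(bool)
                    & ~small_scene.cropland.values.astype(bool)).any()

    def test_zero_irrigated_fraction_empty_truth(self):
        cfg = SynthConfig(shape=(30, 30), n_regions=2, irrigated_fraction=0.0, seed=1)
        _, _, truth = generate_landscape(cfg)
        assert truth.values.sum() == 0

    def test_full_fractions_fill_grid(self):
        cfg = SynthConfig(shape=(20, 20), n_regions=2, cropland_fraction=1.0,
                          irrigated_fraction=1.0, seed=1)
        _, cropland, truth = generate_landscape(cfg)
        assert cropland.values.all() and truth.values.all()

    def test_bit_reproducible_for_fixed_seed(self):
        cfg = SynthConfig(shape=(40, 40), n_regions=3, seed=9)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_regions_persist_across_years_truth_redrawn(self):
        cfg = SynthConfig(shape=(40, 40), n_regions=3, seed=9)
        r1, c1, t1 = generate_landscape(cfg, year=2000)
        r2, c2, t2 = generate_landscape(cfg, year=2001)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(c1.values, c2.values)
        assert (t1.values != t2.values).any()


class TestGenerateGIStack:
    def test_zero_noise_peak_exact(self):
        cfg = SynthConfig(shape=(20, 20), n_regions=2, gi_noise_sd=0.0, seed=3)
        _, cropland, truth = generate_landscape(cfg)
        stack = generate_gi_stack(truth, cropland, cfg)
        irr = truth.values.astype(bool)
        peaks = stack.values.max(axis=0)
        assert np.allclose(peaks[irr], cfg.gi_peak_irrigated)
        rainfed = cropland.values.astype(bool) & ~irr
        assert np.allclose(peaks[rainfed], cfg.gi_peak_rainfed)

    def test_class_mean_separation_matches_config(self):
        cfg = SynthConfig(shape=(120, 120), n_regions=4, gi_noise_sd=0.1, seed=4)
        _, cropland, truth = generate_landscape(cfg)
        stack = generate_gi_stack(truth, cropland, cfg)
        at_peak = stack.values[cfg.peak_composite]
        irr = truth.values.astype(bool)
        rainfed = cropland.values.astype(bool) & ~irr
        sep = at_peak[irr].mean() - at_peak[rainfed].mean()
        expected = cfg.gi_peak_irrigated - cfg.gi_peak_rainfed
        tol = 3 * cfg.gi_noise_sd / np.sqrt(min(irr.sum(), rainfed.sum()))
        assert abs(sep - expected) <= 3 * tol

    def test_non_cropland_profile_flat(self):
        cfg = SynthConfig(shape=(20, 20), n_regions=2, cropland_fraction=0.3, seed=3)
        _, cropland, truth = generate_landscape(cfg)
        stack = generate_gi_stack(truth, cropland, cfg)
        bare = ~cropland.values.astype(bool)
        series = stack.values[:, bare]
        assert np.allclose(series, cfg.gi_base)

    def test_gi_never_negative(self):
        cfg = SynthConfig(shape=(30, 30), n_regions=2, gi_noise_sd=3.0, seed=3)
        _, cropland, truth = generate_landscape(cfg)
        assert (generate_gi_stack(truth, cropland, cfg).values >= 0).all()


class TestGenerateStatistics:
    def test_unbiased_statistics_conserve_truth(self, small_scene):
        labels = small_scene.regions.values
        for rec in small_scene.stats:
            count = ((labels == rec.region_id) & (small_scene.truth.values != 0)).sum()
            assert rec.area_ha == pytest.approx(count * small_scene.config.pixel_area_ha)

    def test_bias_scales_reported_area(self):
        cfg = SynthConfig(shape=(30, 30), n_regions=2, seed=2)
        regions, cropland, truth = generate_landscape(cfg)
        exact = generate_statistics(truth, regions, 25.0, 1.0)
        biased = generate_statistics(truth, regions, 25.0, 0.8)
        for rec in exact:
            assert biased.get(rec.region_id, 0, "county").area_ha == pytest.approx(
                0.8 * rec.area_ha)


class TestDegradeProduct:
    def test_zero_rates_identity(self, small_scene):
        out = degrade_product(small_scene.truth, 0.0, 0.0, small_scene.cropland, seed=1)
        np.testing.assert_array_equal(out.values, small_scene.truth.values)

    def test_unit_rates_complement_within_cropland(self, small_scene):
        out = degrade_product(small_scene.truth, 1.0, 1.0, small_scene.cropland, seed=1)
        crop = small_scene.cropland.values.astype(bool)
        truth = small_scene.truth.values.astype(bool)
        np.testing.assert_array_equal(out.values.astype(bool)[crop], ~truth[crop])
        assert not out.values[~crop].any()

    def test_rates_within_binomial_tolerance(self):
        cfg = SynthConfig(shape=(150, 150), n_regions=3, seed=5)
        _, cropland, truth = generate_landscape(cfg)
        out = degrade_product(truth, 0.2, 0.1, cropland, seed=11)
        truth_b = truth.values.astype(bool)
        crop = cropland.values.astype(bool)
        n1 = truth_b.sum()
        omitted = (truth_b & (out.values == 0)).sum() / n1
        n0 = (crop & ~truth_b).sum()
        committed = (crop & ~truth_b & (out.values == 1)).sum() / n0
        assert abs(omitted - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n1)
        assert abs(committed - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / n0)

    def test_invalid_rate_rejected(self, small_scene):
        with pytest.raises(ValueError):
            degrade_product(small_scene.truth, 1.5, 0.0, small_scene.cropland, seed=1)


class TestDrawSamples:
    def test_exhaustive_sample_recovers_all_labels(self, small_scene):
        n_crop = int(small_scene.cropland.values.sum())
        s = draw_samples(small_scene.truth, small_scene.cropland, n_crop, seed=3)
        assert len(s) == n_crop
        assert s["truth"].sum() == small_scene.truth.values.sum()

    def test_stratified_balances_classes(self, small_scene):
        s = draw_samples(small_scene.truth, small_scene.cropland, 100, seed=3,
                         stratified=True)
        assert s["truth"].sum() == 50

    def test_fixed_seed_reproducible(self, small_scene):
        a = draw_samples(small_scene.truth, small_scene.cropland, 50, seed=4)
        b = draw_samples(small_scene.truth, small_scene.cropland, 50, seed=4)
        assert a.equals(b)

    def test_oversized_request_rejected(self, small_scene):
        n_crop = int(small_scene.cropland.values.sum())
        with pytest.raises(ValueError):
            draw_samples(small_scene.truth, small_scene.cropland, n_crop + 1, seed=1)


def test_scene_layers_co_registered(small_scene):
    base = small_scene.regions
    for layer in (small_scene.cropland, small_scene.truth):
        assert base.same_lattice(layer)
    for _name, grid, _rank in small_scene.products:
        assert base.same_lattice(grid)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(cropland_fraction=1.5)
    with pytest.raises(ValueError):
        SynthConfig(gi_peak_irrigated=3.0, gi_peak_rainfed=4.0)
    with pytest.raises(ValueError):
        SynthConfig(product_errors=((0.1, 1.2),))
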