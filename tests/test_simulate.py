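import numpy as np
import pytest

from ovofresh import (AbsorptionBand, SimConfig, ValidationError,
                      generate_dataset, simulate_indices,
                      simulate_spectrum)
from ovofresh.freshness import haugh_unit, weight_loss, yolk_index
from ovofresh.simulate import INDEX_TABLE, indices_frame


class TestSimulateIndices:
    def test_day1_room_temperature_mean_recovered(self):
        """Many draws reproduce the fresh-egg Haugh distribution
        (mean 84.94, sd 4.05) within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        draws = [simulate_indices(1, "A", rng).haugh_unit
                 for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(84.94, abs=0.25)
        assert np.std(draws) == pytest.approx(4.05, abs=0.25)

    def test_weight_loss_ratio_day13_day1(self):
        """Room-temperature weight loss grows nearly thirtyfold between
        day 1 and day 13 in expectation."""
        wr = INDEX_TABLE["A"]
        ratio = wr[13]["wr"][0] / wr[1]["wr"][0]
        assert 25 < ratio <= 30

    def test_zero_noise_returns_exact_day_means(self):
        rng = np.random.default_rng(0)
        idx = simulate_indices(9, "B", rng, index_noise_scale=0.0)
        cell = INDEX_TABLE["B"][9]
        assert idx.haugh_unit == cell["hu"][0]
        assert idx.yolk_index == cell["yi"][0]
        assert idx.weight_loss == cell["wr"][0]

    def test_day_outside_design_strictness(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            simulate_indices(6, "A", rng)
        idx = simulate_indices(6, "A", rng, strict=False)
        assert np.isfinite(idx.haugh_unit)

    def test_weight_loss_never_negative(self):
        rng = np.random.default_rng(1)
        draws = [simulate_indices(1, "A", rng, index_noise_scale=5.0)
                 for _ in range(500)]
        assert min(d.weight_loss for d in draws) >= 0.0


class TestSimulateSpectrum:
    def _quiet_config(self, grid, bands):
        return SimConfig(regime="A", grid=grid, bands=bands, interferents=(),
                         scatter_sd_mult=0.0, scatter_sd_add=0.0,
                         structure_sd=0.0, noise_sd=0.0)

    def test_zero_couplings_and_noise_give_shared_baseline(self,
                                                           thin_study_grid):
        bands = (AbsorptionBand(700.0, 20.0),)
        cfg = self._quiet_config(thin_study_grid, bands)
        rng = np.random.default_rng(0)
        specs = []
        for day in (1, 13):
            idx = simulate_indices(day, "A", rng)
            spec, mult, add = simulate_spectrum(idx, cfg, rng)
            specs.append(spec)
            assert mult == 1.0 and add == 0.0
        np.testing.assert_array_equal(specs[0], specs[1])

    def test_doubling_coupling_doubles_amplitude_difference(
            self, thin_study_grid):
        rng = np.random.default_rng(0)
        idx1 = simulate_indices(1, "A", rng)
        idx2 = simulate_indices(13, "A", rng)
        diffs = []
        for c_wr in (0.01, 0.02):
            bands = (AbsorptionBand(700.0, 20.0, coupling_wr=c_wr),)
            cfg = self._quiet_config(thin_study_grid, bands)
            s1, _, _ = simulate_spectrum(idx1, cfg, rng)
            s2, _, _ = simulate_spectrum(idx2, cfg, rng)
            diffs.append(s2 - s1)
        np.testing.assert_allclose(diffs[1], 2.0 * diffs[0], atol=1e-12)

    def test_scatter_free_differences_are_band_driven(self, thin_study_grid):
        """With scatter, structure and noise off, two eggs differ only
        under the planted bands."""
        cfg = self._quiet_config(thin_study_grid, SimConfig().bands)
        rng = np.random.default_rng(2)
        i1 = simulate_indices(1, "A", rng)
        i2 = simulate_indices(13, "A", rng)
        s1, _, _ = simulate_spectrum(i1, cfg, rng, degradation=0.0)
        s2, _, _ = simulate_spectrum(i2, cfg, rng, degradation=1.0)
        diff = np.abs(s2 - s1)
        w = thin_study_grid.values
        off_band = np.ones(len(w), dtype=bool)
        for b in cfg.bands:
            off_band &= np.abs(w - b.center_nm) > 4 * b.width_nm
        assert diff[off_band].max() < 1e-3 * diff.max()

    def test_band_center_outside_grid_rejected(self, thin_study_grid):
        with pytest.raises(ValidationError):
            SimConfig(grid=thin_study_grid,
                      bands=(AbsorptionBand(1500.0, 10.0),))


class TestGenerateDataset:
    def test_default_design_has_105_samples(self, thin_study_grid):
        s, destructive, truth = generate_dataset(
            SimConfig(seed=5, grid=thin_study_grid))
        assert s.n_samples == 105
        assert len(destructive) == 105
        assert len(truth.indices) == 105
        per_day = s.metadata.groupby("storage_day").size()
        assert (per_day == 15).all()

    def test_same_seed_is_bit_identical(self, thin_study_grid):
        a = generate_dataset(SimConfig(seed=7, grid=thin_study_grid))
        b = generate_dataset(SimConfig(seed=7, grid=thin_study_grid))
        np.testing.assert_array_equal(a[0].absorbance, b[0].absorbance)
        assert a[1].equals(b[1])
        np.testing.assert_array_equal(a[2].scatter_mult, b[2].scatter_mult)

    def test_different_seeds_differ(self, thin_study_grid):
        a = generate_dataset(SimConfig(seed=7, grid=thin_study_grid))
        b = generate_dataset(SimConfig(seed=8, grid=thin_study_grid))
        assert np.abs(a[0].absorbance - b[0].absorbance).max() > 1e-6

    def test_destructive_table_back_solves_to_truth(self, thin_study_grid):
        """Applying the freshness formulas to the emitted destructive
        measurements must reproduce the drawn indices exactly."""
        s, destructive, truth = generate_dataset(
            SimConfig(seed=11, grid=thin_study_grid))
        for row, idx in zip(destructive.itertuples(), truth.indices):
            assert weight_loss(row.mass_original_g, row.mass_current_g) \
                == pytest.approx(idx.weight_loss, abs=1e-9)
            assert yolk_index(row.yolk_height_mm, row.yolk_diameter_mm) \
                == pytest.approx(idx.yolk_index, abs=1e-9)
            assert haugh_unit(row.albumen_height_mm, row.mass_current_g) \
                == pytest.approx(idx.haugh_unit, abs=1e-9)

    def test_informative_mask_covers_band_neighbourhoods(self,
                                                         thin_study_grid):
        cfg = SimConfig(seed=1, grid=thin_study_grid)
        _, _, truth = generate_dataset(cfg)
        w = thin_study_grid.values
        assert truth.informative_mask.any()
        for b in cfg.bands:
            under = np.abs(w - b.center_nm) <= b.width_nm
            assert truth.informative_mask[under].all()

    def test_indices_frame_alignment(self, thin_study_grid):
        s, _, truth = generate_dataset(SimConfig(seed=2, grid=thin_study_grid))
        frame = indices_frame(truth, s.metadata)
        assert frame["sample_id"].tolist() == s.sample_ids
        assert set(frame["grade"]) <= {"AA", "A"}


class TestPreprocessingNecessity:
    def test_scatter_correction_improves_interval_search(self,
                                                         thin_study_grid):
        """With scatter artifacts on, SNV or derivative pretreatment
        lowers the best interval-search RMSECV relative to raw spectra
        in at least 80% of seeded trials."""
        from ovofresh import (PreprocessConfig, apply_preprocess,
                              make_split, sipls_search)
        wins = []
        for seed in range(10):
            cfg = SimConfig(regime="A", seed=seed, grid=thin_study_grid)
            s, _, truth = generate_dataset(cfg)
            split = make_split(s)
            cal = np.asarray(split.calibration_indices)
            y = indices_frame(truth, s.metadata)["haugh_unit"].to_numpy()
            best = {}
            for method in ("snv", "deriv1", "none"):
                treated = apply_preprocess(
                    s, PreprocessConfig(method=method), cal)
                best[method] = sipls_search(
                    treated.absorbance[cal], y[cal], thin_study_grid,
                    10, {2, 3}, 10).best_rmsecv
            wins.append(min(best["snv"], best["deriv1"]) < best["none"])
        assert np.mean(wins) >= 0.8
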