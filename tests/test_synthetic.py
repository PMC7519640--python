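import numpy as np
import pytest
from scipy import ndimage

import serrscell as sc
from serrscell.spectra import DEFAULT_GRID, SpectralGrid
from serrscell.synthetic import (
    DEFAULT_CLASS_MODELS,
    ExperimentSpec,
    NoiseModel,
    Peak,
    ReporterSignature,
    SyntheticCell,
    build_reference_spectrum,
    generate_cell_spectrum,
    render_chamber_image,
    sample_cell_population,
)


def lorentzian_sum(x, peaks):
    """Independent oracle: direct evaluation of the Lorentzian line shape."""
    y = np.zeros_like(x)
    for center, fwhm, height in peaks:
        y = y + height * (fwhm / 2) ** 2 / ((x - center) ** 2 + (fwhm / 2) ** 2)
    return y


class TestReferenceSpectrum:
    def test_normalized_maximum_at_dominant_peak(self):
        sig = ReporterSignature(
            "X", (Peak(1100.0, 10.0, 1.0), Peak(500.0, 10.0, 1e-3), Peak(1700.0, 10.0, 1e-3))
        )
        spec = build_reference_spectrum(sig, DEFAULT_GRID)
        assert spec.intensities.max() == 1.0
        k = int(np.argmax(spec.intensities))
        assert abs(DEFAULT_GRID.wavenumbers[k] - 1100.0) <= DEFAULT_GRID.step

    def test_deterministic(self):
        sig = sc.DEFAULT_SIGNATURES["NS1"]
        a = build_reference_spectrum(sig, DEFAULT_GRID)
        b = build_reference_spectrum(sig, DEFAULT_GRID)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_matches_lorentzian_oracle_with_2_to_1_peak_ratio(self):
        peaks = [(600.0, 10.0, 1.0), (1000.0, 10.0, 0.5), (1600.0, 10.0, 0.25)]
        sig = ReporterSignature("X", tuple(Peak(*p) for p in peaks))
        spec = build_reference_spectrum(sig, DEFAULT_GRID)
        oracle = lorentzian_sum(DEFAULT_GRID.wavenumbers, peaks)
        np.testing.assert_allclose(spec.intensities, oracle / oracle.max(), rtol=1e-12)
        # non-overlapping peaks with heights 1 and 0.5 sit in a 2:1 ratio
        w = DEFAULT_GRID.wavenumbers
        i600 = np.argmin(np.abs(w - 600.0))
        i1000 = np.argmin(np.abs(w - 1000.0))
        assert spec.intensities[i600] / spec.intensities[i1000] == pytest.approx(2.0, rel=0.02)

    def test_peak_outside_grid_is_named(self):
        sig = ReporterSignature(
            "X", (Peak(2000.0, 10.0, 1.0), Peak(500.0, 10.0, 1.0), Peak(700.0, 10.0, 1.0))
        )
        with pytest.raises(ValueError, match="2000"):
            build_reference_spectrum(sig, DEFAULT_GRID)


class TestCellSpectrum:
    def test_pure_reporter_correlates_perfectly(self, library):
        cell = SyntheticCell("LNCaP", 80.0, (0.0, 1.0, 0.0))
        spec = generate_cell_spectrum(cell, library.spectra, NoiseModel.zero(), seed=0)
        assert sc.pearson(spec, library["NS2"]) == pytest.approx(1.0)

    def test_zero_weights_give_the_baseline(self, library):
        cell = SyntheticCell("PBMC", 20.0, (0.0, 0.0, 0.0))
        noise = NoiseModel(baseline_coeffs=(0.3, 0.1), additive_sd=0.0,
                           fluorescence_amplitude=0.0)
        spec = generate_cell_spectrum(cell, library.spectra, noise, seed=0)
        np.testing.assert_allclose(spec.intensities, noise.baseline(library.grid))

    def test_mixture_linearity_without_noise(self, library):
        rng = np.random.default_rng(42)
        zero = NoiseModel.zero()
        for _ in range(5):
            w1, w2 = rng.uniform(0, 2, size=(2, 3))
            a = generate_cell_spectrum(SyntheticCell("U251", 50, w1), library.spectra, zero)
            b = generate_cell_spectrum(SyntheticCell("U251", 50, w2), library.spectra, zero)
            ab = generate_cell_spectrum(SyntheticCell("U251", 50, w1 + w2), library.spectra, zero)
            np.testing.assert_allclose(ab.intensities, a.intensities + b.intensities, rtol=1e-10)

    def test_same_seed_same_spectrum(self, library):
        cell = SyntheticCell("U251", 50.0, (1.0, 0.0, 0.5))
        a = generate_cell_spectrum(cell, library.spectra, NoiseModel(), seed=11)
        b = generate_cell_spectrum(cell, library.spectra, NoiseModel(), seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_mismatched_reference_grids_rejected(self, library):
        other = sc.default_reference_library(SpectralGrid(400, 1800, 512))
        refs = dict(library.spectra)
        refs["NS3"] = other["NS3"]
        cell = SyntheticCell("U251", 50.0, (1.0, 0.0, 0.5))
        with pytest.raises(ValueError, match="grid"):
            generate_cell_spectrum(cell, refs, NoiseModel.zero())


class TestPopulation:
    def test_binomial_thinning_of_tumor_cells(self):
        spec = ExperimentSpec(pbmc_per_ml=0.0)
        counts = []
        for seed in range(200):
            cells = sample_cell_population(spec, seed=seed)
            counts.append(sum(1 for c in cells if c.true_class == "LNCaP"))
        expected = 24 * 0.84  # 20.16 retained on average
        se = np.sqrt(24 * 0.84 * 0.16 / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_full_depletion_and_perfect_efficiency(self):
        spec = ExperimentSpec(depletion=1.0, efficiency=1.0, pbmc_per_ml=1e5)
        cells = sample_cell_population(spec, seed=1)
        assert sum(1 for c in cells if c.true_class == "PBMC") == 0
        assert sum(1 for c in cells if c.true_class == "LNCaP") == 24
        assert sum(1 for c in cells if c.true_class == "U251") == 29

    def test_seed_determinism(self):
        spec = ExperimentSpec()
        a = sample_cell_population(spec, seed=5)
        b = sample_cell_population(spec, seed=5)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.true_class == cb.true_class
            assert ca.area_um2 == cb.area_um2
            np.testing.assert_array_equal(ca.weights, cb.weights)

    def test_area_distributions_follow_the_phenotypes(self):
        spec = ExperimentSpec(
            lncap_per_ml=1000, u251_per_ml=1000, pbmc_per_ml=1500,
            depletion=0.0, efficiency=1.0,
        )
        cells = sample_cell_population(spec, seed=2)
        pbmc = np.array([c.area_um2 for c in cells if c.true_class == "PBMC"])
        tumor = np.array([c.area_um2 for c in cells if c.true_class != "PBMC"])
        assert len(pbmc) >= 1000
        assert (pbmc < 30).mean() > 0.5
        assert tumor.min() > 0 and tumor.max() < 300
        assert ((tumor > 30) & (tumor < 180)).mean() >= 0.90


class TestChamberRendering:
    def test_pixel_count_matches_area(self):
        spec = ExperimentSpec(chamber_mm=0.1, pixel_size_um=1.0)
        cell = SyntheticCell("LNCaP", 100.0, (0, 1, 0), centroid_um=(50.0, 50.0))
        image, _ = render_chamber_image([cell], spec, seed=0)
        assert 99 <= int((image > 0).sum()) <= 101

    def test_zero_cells_black_image(self):
        spec = ExperimentSpec(chamber_mm=0.05, pixel_size_um=1.0)
        image, placed = render_chamber_image([], spec, seed=0)
        assert image.sum() == 0 and placed == []

    def test_two_cells_two_components(self):
        spec = ExperimentSpec(chamber_mm=0.2, pixel_size_um=1.0)
        cells = [
            SyntheticCell("LNCaP", 80.0, (0, 1, 0), centroid_um=(50.0, 50.0)),
            SyntheticCell("U251", 60.0, (1, 0, 0), centroid_um=(150.0, 150.0)),
        ]
        image, _ = render_chamber_image(cells, spec, seed=0)
        _, n = ndimage.label(image > 0, structure=np.ones((3, 3)))
        assert n == 2

    def test_crowded_chamber_raises(self):
        spec = ExperimentSpec(chamber_mm=0.04, pixel_size_um=1.0)
        cells = [
            SyntheticCell("LNCaP", 150.0, (0, 1, 0), centroid_um=(20.0, 20.0))
            for _ in range(30)
        ]
        with pytest.raises(RuntimeError, match="crowded"):
            render_chamber_image(cells, spec, seed=0, max_tries=30)
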