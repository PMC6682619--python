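"""Image-quantification operators against closed-form and brute-force oracles."""

import numpy as np
import pytest
import scipy.fft
from skimage.morphology import diamond, disk

from thromboquant.imaging import (
    BinaryMask,
    ConfigError,
    GrayImage,
    InvalidInputError,
    MorphologyConfig,
    aggregate_coverage,
    bandpass_correct,
    morph_clean_brightfield,
    quantify_brightfield,
    segment,
    surface_area_coverage,
)


# ---------------------------------------------------------------------------
# brute-force grayscale morphology oracle
# ---------------------------------------------------------------------------

def _sliding(arr, footprint, op):
    """Sliding min/max over an explicit footprint, edge-padded."""
    r = footprint.shape[0] // 2
    padded = np.pad(arr, r, mode="edge")
    stacks = []
    for dy in range(footprint.shape[0]):
        for dx in range(footprint.shape[1]):
            if footprint[dy, dx]:
                stacks.append(padded[dy:dy + arr.shape[0], dx:dx + arr.shape[1]])
    return op(np.stack(stacks), axis=0)


def brute_dilate(arr, fp):
    return _sliding(arr, fp, np.max)


def brute_erode(arr, fp):
    return _sliding(arr, fp, np.min)


def brute_close(arr, fp):
    return brute_erode(brute_dilate(arr, fp), fp)


class TestBandpass:
    def test_flat_field_is_fixed_point(self):
        img = GrayImage(np.full((256, 256), 120.0))
        out = bandpass_correct(img, MorphologyConfig())
        assert np.allclose(out.pixels, 120.0)

    def test_long_wavelength_structure_suppressed(self):
        # horizontal sinusoid of period 200 px on a flat field: a structure
        # much larger than the 60 px cutoff must be almost fully removed
        x = np.arange(400)
        wave = 10 * np.sin(2 * np.pi * x / 200)
        img = GrayImage(100 + np.tile(wave, (256, 1)))
        out = bandpass_correct(img, MorphologyConfig())
        residual = out.pixels - out.pixels.mean()
        assert np.abs(residual).max() < 0.10 * 10

    def test_ideal_dft_oracle_agrees_on_sinusoid(self):
        # independent oracle: explicitly zero the large-scale band of the
        # spectrum (ideal filter) and compare the surviving amplitude
        x = np.arange(400)
        arr = 100 + np.tile(10 * np.sin(2 * np.pi * x / 200), (256, 1))
        spec = scipy.fft.fft2(arr)
        fy = scipy.fft.fftfreq(arr.shape[0])[:, None]
        fx = scipy.fft.fftfreq(arr.shape[1])[None, :]
        wavelength_large = np.sqrt(fy ** 2 + fx ** 2) < 1.0 / 60
        spec[wavelength_large] = 0.0
        oracle = scipy.fft.ifft2(spec).real
        assert np.abs(oracle - oracle.mean()).max() < 0.5  # oracle kills the wave
        out = bandpass_correct(GrayImage(arr), MorphologyConfig())
        # the Gaussian-weighted filter must agree with the ideal filter to
        # within 10% of the original amplitude
        assert np.abs((out.pixels - out.pixels.mean())
                      - (oracle - oracle.mean())).max() < 1.0

    def test_small_spot_contrast_retained(self):
        arr = np.full((256, 256), 100.0)
        arr[100:103, 100:103] += 50
        out = bandpass_correct(GrayImage(arr), MorphologyConfig())
        contrast = out.pixels[101, 101] - np.median(out.pixels)
        assert contrast >= 0.70 * 50

    def test_mean_preserved_and_shape_unchanged(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(40, 200, size=(128, 96))
        out = bandpass_correct(GrayImage(arr), MorphologyConfig())
        assert out.pixels.shape == (128, 96)
        assert out.pixels.mean() == pytest.approx(arr.mean(), abs=0.5)

    def test_image_smaller_than_filter_scale_rejected(self):
        img = GrayImage(np.full((64, 64), 50.0))
        with pytest.raises(InvalidInputError):
            bandpass_correct(img, MorphologyConfig(bandpass_large_px=64))

    def test_vertical_stripes_removed_when_suppressed(self):
        cols = np.arange(256)
        arr = 100 + np.tile(20 * np.sin(2 * np.pi * cols / 8), (256, 1))
        out = bandpass_correct(GrayImage(arr), MorphologyConfig())
        assert np.ptp(out.pixels) < 1.0


class TestMorphology:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 77.0)
        out = morph_clean_brightfield(img, MorphologyConfig())
        assert np.allclose(out, 77.0)

    def test_matches_brute_force_oracle(self):
        cfg = MorphologyConfig()
        rng = np.random.default_rng(42)
        for _ in range(3):
            arr = rng.uniform(0, 255, size=(64, 64))
            oracle = brute_close(arr, diamond(cfg.large_diamond_radius_px))
            oracle = brute_close(oracle, disk(cfg.medium_circle_radius_px))
            oracle = brute_dilate(oracle, disk(cfg.small_circle_radius_px))
            out = morph_clean_brightfield(arr, cfg)
            assert np.allclose(out, oracle)

    def test_closing_is_idempotent(self):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0, 255, size=(64, 64))
        for fp in (diamond(4), disk(2)):
            once = brute_close(arr, fp)
            assert np.allclose(brute_close(once, fp), once)

    def test_final_dilation_is_extensive(self):
        cfg = MorphologyConfig()
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 255, size=(64, 64))
        closed = brute_close(arr, diamond(cfg.large_diamond_radius_px))
        closed = brute_close(closed, disk(cfg.medium_circle_radius_px))
        out = morph_clean_brightfield(arr, cfg)
        assert np.all(out >= closed - 1e-9)

    def test_dark_stripe_removed_from_flat_field(self):
        arr = np.full((32, 32), 100.0)
        arr[:, 16] = 60.0
        out = morph_clean_brightfield(arr, MorphologyConfig(4, 2, 1))
        assert np.abs(out - 100.0).max() < 5

    def test_invalid_radius_ordering_rejected(self):
        with pytest.raises(ConfigError):
            MorphologyConfig(large_diamond_radius_px=2, medium_circle_radius_px=3,
                             small_circle_radius_px=1)


class TestSegmentAndCoverage:
    def test_half_bright_half_dark_exact_fraction(self):
        arr = np.full((64, 64), 10.0)
        arr[:32] = 200.0
        mask = segment(GrayImage(arr, channel_label="annexinA5"), threshold=100,
                       polarity="bright_objects")
        assert surface_area_coverage(mask) == 50.0
        assert mask.source_threshold == 100

    def test_auto_threshold_on_background_only_image(self):
        # an object-free frame through the clean-up chain must not have the
        # automatic threshold split its noise floor into spurious platelets
        from thromboquant.simulate import generate_brightfield

        truth = generate_brightfield(n_platelets=0, aggregate_count=0, seed=11)
        cfg = MorphologyConfig()
        processed = morph_clean_brightfield(bandpass_correct(truth.image, cfg), cfg)
        mask = segment(processed, threshold="auto")
        assert surface_area_coverage(mask) < 1.0

    def test_threshold_out_of_range_rejected(self):
        img = GrayImage(np.full((64, 64), 50.0))
        with pytest.raises(InvalidInputError):
            segment(img, threshold=300)

    def test_coverage_extremes_and_exact_count(self):
        assert surface_area_coverage(
            BinaryMask(np.zeros((10, 10), bool), 0)) == 0.0
        assert surface_area_coverage(
            BinaryMask(np.ones((10, 10), bool), 0)) == 100.0
        m = np.zeros((10, 10), bool)
        m.ravel()[:37] = True
        assert surface_area_coverage(BinaryMask(m, 0)) == 37.0

    def test_nonrectangular_input_rejected(self):
        with pytest.raises(InvalidInputError):
            GrayImage(np.zeros((64, 64, 3)))
        with pytest.raises(InvalidInputError):
            GrayImage(np.zeros((40, 200)))  # below 64 px minimum


class TestAggregateCoverage:
    def _image_with_aggregate(self):
        arr = np.full((128, 128), 20.0)
        arr[10:16, 10:16] = 150.0      # small platelet, 36 px < 80
        arr[40:80, 40:80] = 150.0      # big component, 1600 px
        arr[50:70, 50:70] = 220.0      # bright multilayer core
        mask = arr > 100
        return arr, BinaryMask(mask, source_threshold=100.0)

    def test_component_and_contrast_rule(self):
        arr, mask = self._image_with_aggregate()
        sac = aggregate_coverage(arr, mask, min_area_px=80)
        assert sac == pytest.approx(100.0 * 1600 / arr.size)
        assert sac <= surface_area_coverage(mask)

    def test_sparse_single_platelets_yield_zero(self):
        arr = np.full((128, 128), 20.0)
        for r in (10, 40, 70):
            arr[r:r + 5, r:r + 5] = 150.0
        mask = BinaryMask(arr > 100, source_threshold=100.0)
        assert aggregate_coverage(arr, mask, min_area_px=80) == 0.0

    def test_empty_mask_yields_zero(self):
        arr = np.full((64, 64), 20.0)
        mask = BinaryMask(np.zeros((64, 64), bool), source_threshold=100.0)
        assert aggregate_coverage(arr, mask) == 0.0

    def test_lax_stringent_threshold_rejected(self):
        arr, mask = self._image_with_aggregate()
        with pytest.raises(ConfigError):
            aggregate_coverage(arr, mask, stringent_threshold=50.0)


class TestBrightfieldPipeline:
    def test_deterministic(self):
        from thromboquant import generate_brightfield

        truth = generate_brightfield(seed=5)
        a = quantify_brightfield(truth.image)
        b = quantify_brightfield(truth.image)
        assert a["sac_percent"] == b["sac_percent"]
        assert np.array_equal(a["mask"].pixels, b["mask"].pixels)

    def test_fluorescence_pipeline_recovers_stained_fraction(self):
        from thromboquant import generate_brightfield, generate_fluorescence
        from thromboquant.imaging import quantify_fluorescence

        base = generate_brightfield(seed=6)
        for fraction in (0.0, 0.3, 1.0):
            fl = generate_fluorescence(base.platelet_mask, fraction, seed=2)
            est = quantify_fluorescence(fl.image)["sac_percent"]
            assert est == pytest.approx(fl.true_sac_percent, abs=0.5)

    def test_recovers_truth_with_gradient_where_naive_threshold_fails(self):
        from thromboquant import generate_brightfield

        truth = generate_brightfield(seed=21, illumination_amplitude=0.20,
                                     stripe_amplitude=0.10)
        res = quantify_brightfield(truth.image)
        assert res["sac_percent"] == pytest.approx(truth.true_sac_percent, abs=2.0)
        assert res["aggregate_percent"] <= res["sac_percent"]
        naive = surface_area_coverage(segment(truth.image, threshold="auto"))
        assert abs(naive - truth.true_sac_percent) > \
            abs(res["sac_percent"] - truth.true_sac_percent)
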