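"""Spectral chain: low-signal masking, white referencing, normalization,
binning, and image/patient aggregation."""

import numpy as np
import pytest

import snapmsi as sm
from snapmsi.raw import ImageCube, MASK_LOW_SIGNAL, MASK_VALID
from snapmsi.spectral import (
    STAGE_ORDER,
    Spectrum,
    WhiteReference,
    compute_white_reference,
)
from snapmsi.synthetic import BAND_THROUGHPUT


def _cube(values, mask=None, labels=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape[:2], dtype=np.uint8)
    return ImageCube(values, mask, labels=labels or {})


class TestLowSignal:
    @pytest.mark.parametrize("peak,masked", [(49, True), (50, False), (49.999, True)])
    def test_threshold_is_strict(self, peak, masked):
        values = np.zeros((2, 2, 9))
        values[:, :, 3] = peak
        cube = sm.mask_low_signal(_cube(values))
        assert np.all((cube.mask == MASK_LOW_SIGNAL) == masked)

    def test_bright_cube_untouched(self):
        cube = sm.mask_low_signal(_cube(np.full((3, 3, 9), 255.0)))
        assert np.all(cube.mask == MASK_VALID)


class TestWhiteReference:
    def test_identity_when_cube_equals_reference(self):
        ref = WhiteReference(np.linspace(50, 200, 9))
        cube = _cube(np.broadcast_to(ref.w, (2, 2, 9)).copy())
        out = sm.apply_white_reference(cube, ref)
        assert np.allclose(out.values, 1.0)

    def test_linearity_in_reference(self):
        ref = WhiteReference(np.linspace(50, 200, 9))
        ref2 = WhiteReference(2 * ref.w)
        cube = _cube(np.random.default_rng(0).uniform(10, 100, (2, 2, 9)))
        a = sm.apply_white_reference(cube, ref)
        b = sm.apply_white_reference(cube, ref2)
        assert np.allclose(b.values, a.values / 2)

    def test_nonpositive_reference_band_rejected(self):
        w = np.linspace(50, 200, 9)
        w[4] = 0.0
        with pytest.raises(ValueError):
            WhiteReference(w)


class TestMaxNormalize:
    def test_arithmetic_example(self):
        s = Spectrum(np.array([1, 2, 4, 4, 2, 1, 1, 1, 1], dtype=float))
        out = sm.max_normalize(s)
        assert np.allclose(out.y, [0.25, 0.5, 1, 1, 0.5, 0.25, 0.25, 0.25, 0.25])
        assert out.normalized

    def test_idempotent(self):
        s = Spectrum(np.array([0.25, 0.5, 1, 1, 0.5, 0.25, 0.25, 0.25, 0.25]))
        out = sm.max_normalize(sm.max_normalize(s))
        assert np.allclose(out.y, s.y)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sm.max_normalize(Spectrum(np.zeros(9)))

    def test_normalized_max_is_exactly_one(self, rng):
        for _ in range(20):
            s = Spectrum(rng.uniform(0.01, 5.0, 9))
            assert sm.max_normalize(s).y.max() == 1.0


class TestBinSpatial:
    def test_full_frame_shape(self):
        """A 1280x1024 sensor frame bins into a 40x32 (W x H) cube."""
        cube = _cube(np.ones((1024, 1280, 9)))
        out = sm.bin_spatial(cube, block=32)
        assert out.values.shape == (32, 40, 9)

    def test_single_block_mean_of_constant(self):
        cube = _cube(np.full((32, 32, 9), 3.7))
        out = sm.bin_spatial(cube, block=32)
        assert out.values.shape == (1, 1, 9)
        assert np.allclose(out.values, 3.7)

    def test_masked_half_excluded_from_mean(self, rng):
        """Blocks average only their valid pixels (explicit masked-mean
        oracle)."""
        values = rng.uniform(0, 10, (32, 32, 9))
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[:16, :] = MASK_LOW_SIGNAL
        out = sm.bin_spatial(_cube(values, mask), block=32)
        oracle = values[16:, :, :].reshape(-1, 9).mean(axis=0)
        assert np.allclose(out.values[0, 0], oracle)

    def test_fully_masked_block_is_masked(self):
        mask = np.full((32, 64), MASK_LOW_SIGNAL, dtype=np.uint8)
        mask[:, 32:] = MASK_VALID
        out = sm.bin_spatial(_cube(np.ones((32, 64, 9)), mask), block=32)
        assert out.mask[0, 0] != MASK_VALID
        assert out.mask[0, 1] == MASK_VALID

    def test_block_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            sm.bin_spatial(_cube(np.ones((16, 16, 9))), block=32)

    def test_global_mean_conserved_when_blocks_full(self, rng):
        values = rng.uniform(0, 1, (64, 96, 9))
        out = sm.bin_spatial(_cube(values), block=32)
        assert np.allclose(out.values.mean(), values.mean(), atol=1e-9)


class TestMeanImageSpectrum:
    def test_uniform_cube_returns_normalized_spectrum(self):
        base = np.linspace(0.2, 0.9, 9)
        cube = _cube(np.broadcast_to(base, (8, 8, 9)).copy())
        spec = sm.mean_image_spectrum(cube, roi_radius_frac=0.6)
        assert np.allclose(spec.y, base / base.max())
        assert spec.level == "image"

    def test_scalar_multiples_average_to_same_shape(self):
        s = np.linspace(0.1, 0.9, 9)
        values = np.zeros((1, 2, 9))
        values[0, 0] = 3 * s
        values[0, 1] = 1 * s
        cube = _cube(values)
        spec = sm.mean_image_spectrum(cube, roi_radius_frac=2.0)
        assert np.allclose(spec.y, s / s.max())

    def test_mean_then_normalize_not_normalize_then_mean(self):
        """Brightness weighting: the brighter pixel dominates because the
        average is taken before max-normalization."""
        a = np.array([10.0, 1, 1, 1, 1, 1, 1, 1, 1])
        b = np.array([1.0, 1, 1, 1, 1, 1, 1, 1, 0.1])
        values = np.stack([[a, b]])
        spec = sm.mean_image_spectrum(_cube(values), roi_radius_frac=2.0)
        mean_first = (a + b) / 2
        mean_first /= mean_first.max()
        norm_first = (a / a.max() + b / b.max()) / 2
        norm_first /= norm_first.max()
        assert np.allclose(spec.y, mean_first)
        assert not np.allclose(spec.y, norm_first)

    def test_fully_masked_roi_rejected(self):
        mask = np.full((8, 8), MASK_LOW_SIGNAL, dtype=np.uint8)
        with pytest.raises(ValueError):
            sm.mean_image_spectrum(_cube(np.ones((8, 8, 9)), mask))


class TestPatientSpectrum:
    def _img(self, y, patient=1, cls="ndbe"):
        return sm.max_normalize(
            Spectrum(np.asarray(y, dtype=float), level="image",
                     labels={"patient": patient, "class": cls})
        )

    def test_single_image_is_identity(self):
        s = self._img(np.linspace(0.5, 1.0, 9))
        out = sm.patient_spectrum([s])
        assert np.allclose(out.y, s.y)
        assert out.level == "patient"

    def test_two_identical_images(self):
        s = self._img(np.linspace(0.5, 1.0, 9))
        out = sm.patient_spectrum([s, self._img(np.linspace(0.5, 1.0, 9))])
        assert np.allclose(out.y, s.y)

    def test_mixed_labels_rejected(self):
        a = self._img(np.ones(9), cls="ndbe")
        b = self._img(np.ones(9), cls="neoplasia")
        with pytest.raises(ValueError):
            sm.patient_spectrum([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sm.patient_spectrum([])


class TestStageLedger:
    def test_pipeline_order_is_audited(self, processed_tissue):
        """Cubes record the canonical stage order: saturation, dark
        subtraction, demosaic, decomb, low-signal, white reference,
        binning, max-normalization."""
        for cube in processed_tissue.cubes:
            order = [STAGE_ORDER.index(s) for s in cube.stages]
            assert order == sorted(order)
            assert tuple(cube.stages) == STAGE_ORDER

    def test_zero_noise_recovery_at_binned_pixels(self, clean_dataset):
        """With all sigmas zero and flat illumination, the full chain
        recovers each class's mean reflectance at every valid binned pixel
        to within 8-bit quantization (1/255 per band, pre-normalization)."""
        model, ds = clean_dataset
        dark = ds.references[0]["dark"]
        mean_white = np.maximum(
            np.mean([w.pixels.astype(float) - dark.pixels.astype(float)
                     for w in ds.references[0]["white"]], axis=0), 0.0,
        )
        fibers = sm.detect_fiber_cores(mean_white)
        for frame, truth in zip(ds.frames, ds.truths):
            cube = sm.restore_frame(frame, dark, ds.mosaic, fibers)
            cube = sm.mask_low_signal(cube)
            binned = sm.bin_spatial(cube, block=32)
            # expected intensity in counts; 1/255 of full scale = 1 count
            expected = (
                model.class_means[int(truth.class_grid[0, 0])] * BAND_THROUGHPUT * 220.0
            )
            valid = binned.mask == MASK_VALID
            err = np.abs(binned.values[valid] - expected[None, :]) / 255.0
            assert err.max() <= 1.0 / 255

    def test_white_reference_from_clean_whites_matches_throughput(self, clean_dataset):
        """The computed white reference is proportional to the spectral
        throughput profile."""
        _, ds = clean_dataset
        dark = ds.references[0]["dark"]
        mean_white = np.maximum(
            np.mean([w.pixels.astype(float) - dark.pixels.astype(float)
                     for w in ds.references[0]["white"]], axis=0), 0.0,
        )
        fibers = sm.detect_fiber_cores(mean_white)
        cubes = [sm.restore_frame(w, dark, ds.mosaic, fibers) for w in ds.references[0]["white"]]
        ref = compute_white_reference(cubes)
        ratio = ref.w / BAND_THROUGHPUT
        assert np.ptp(ratio) / ratio.mean() < 0.02
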