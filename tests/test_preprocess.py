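import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftirfuse import phantom, preprocess
from ftirfuse.cubeio import HyperCube, PixelMask
from ftirfuse.preprocess import (
    PreprocessConfig,
    denoise,
    emsc_mie_correct,
    mie_extinction_basis,
    preprocess_pipeline,
    quality_filter,
    rubberband_baseline,
    truncate_paraffin_and_fingerprint,
    vector_normalise,
)


def brute_force_rubberband(axis, values):
    """O(n^2) oracle: the baseline is the pointwise maximum of every line
    through two data points that underestimates the whole spectrum."""
    n = len(axis)
    baseline = np.full(n, -np.inf)
    for j, k in itertools.combinations(range(n), 2):
        slope = (values[k] - values[j]) / (axis[k] - axis[j])
        line = values[j] + slope * (axis - axis[j])
        if np.all(line <= values + 1e-12):
            baseline = np.maximum(baseline, line)
    return values - baseline


class TestRubberband:
    def test_collinear_points_zeroed(self):
        out = rubberband_baseline([1.0, 2.0, 3.0], [1000.0, 1100.0, 1200.0])
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_flat_baseline_plus_peak(self):
        axis = np.arange(1000.0, 1005.0)
        out = rubberband_baseline([0.5, 0.5, 1.5, 0.5, 0.5], axis)
        assert np.allclose(out, [0, 0, 1.0, 0, 0], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        axis = np.sort(rng.uniform(900, 1800, 50))
        for _ in range(20):
            values = rng.random(50)
            assert np.allclose(
                rubberband_baseline(values, axis),
                brute_force_rubberband(axis, values),
                atol=1e-9,
            )

    def test_endpoints_map_to_zero(self):
        rng = np.random.default_rng(2)
        axis = np.arange(50.0)
        out = rubberband_baseline(rng.random(50), axis)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[-1] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=3, max_size=40))
    def test_idempotent(self, values):
        axis = np.arange(len(values), dtype=float)
        once = rubberband_baseline(values, axis)
        twice = rubberband_baseline(once, axis)
        assert np.allclose(twice, once, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rubberband_baseline([1.0], [1000.0])


class TestDenoise:
    def test_rank3_cube_exact_at_k3(self, small_cube_clean):
        out = denoise(small_cube_clean, 3)
        assert np.abs(out.data - small_cube_clean.data).max() < 1e-8

    def test_k_equal_bands_is_identity(self):
        rng = np.random.default_rng(0)
        cube = HyperCube(rng.random((4, 4, 6)), np.arange(6.0) + 1000, 1.0)
        out = denoise(cube, 6)
        assert np.allclose(out.data, cube.data, atol=1e-10)

    def test_noise_reduced_on_noisy_rank3(self, small_scene, refs_full,
                                          small_cube_clean):
        noisy = phantom.render_ftir(
            small_scene, refs_full, pixel_size_lr=1.0, psf_sigma=0.5,
            noise_sd=0.01, baseline_amp=0.0, scatter_amp=0.0, seed=6,
        )
        den = denoise(noisy, 3)
        mse_noisy = np.mean((noisy.data - small_cube_clean.data) ** 2)
        mse_den = np.mean((den.data - small_cube_clean.data) ** 2)
        assert mse_den < mse_noisy

    def test_k_out_of_range(self, small_cube_clean):
        with pytest.raises(ValueError):
            denoise(small_cube_clean, 0)
        with pytest.raises(ValueError):
            denoise(small_cube_clean, small_cube_clean.nbands + 1)


class TestEMSC:
    def _uniform_cube(self, spectrum, n=5):
        data = np.tile(spectrum, (n, n, 1))
        axis = np.linspace(990.0, 1800.0, spectrum.size)
        return HyperCube(data, axis, 1.0)

    def test_reference_spectrum_unchanged(self):
        rng = np.random.default_rng(1)
        spectrum = rng.random(80) + 0.5
        cube = self._uniform_cube(spectrum)
        out, flagged = emsc_mie_correct(cube, 1)
        assert not flagged.any()
        assert np.allclose(out.data, cube.data, atol=1e-9)

    def test_known_mie_combination_recovered(self):
        rng = np.random.default_rng(2)
        spectrum = rng.random(80) + 0.5
        cube = self._uniform_cube(spectrum, n=4)
        basis = mie_extinction_basis(cube.axis)
        coeffs = np.array([0.3, -0.2, 0.1, 0.05, -0.1, 0.2])
        distorted = spectrum + basis @ coeffs + 0.15
        cube.data[0, 0] = distorted
        mask = PixelMask(np.ones((4, 4), bool))
        mask.mask[0, 0] = False  # reference mean from clean pixels only
        out, flagged = emsc_mie_correct(cube, 1, mask=mask)
        assert not flagged[0, 0]
        assert np.allclose(out.data[0, 0], spectrum, atol=1e-6)

    def test_distortion_free_cube_barely_changed(self, small_cube_clean, refs_full):
        out, _ = emsc_mie_correct(
            small_cube_clean, 1, constituents=refs_full.values
        )
        # up to the per-pixel multiplicative rescale the spectra are intact:
        # compare directions
        a = small_cube_clean.spectra()
        b = out.spectra()
        cos = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        assert np.arccos(np.clip(cos, -1, 1)).max() < 1e-6

    def test_tiny_multiplicative_constant_flagged(self):
        rng = np.random.default_rng(3)
        spectrum = rng.random(60) + 0.5
        cube = self._uniform_cube(spectrum, n=3)
        cube.data[2, 2] = -spectrum  # c fitted negative, below the floor
        out, flagged = emsc_mie_correct(cube, 1)
        assert flagged[2, 2]
        assert np.allclose(out.data[2, 2], -spectrum)  # left untouched


class TestQualityFilter:
    def _cube_with_amide(self, maxima):
        """One pixel per requested amide-window maximum."""
        axis = np.arange(990.0, 1801.0, 4.0)
        data = np.zeros((1, len(maxima), axis.size))
        band = np.exp(-0.5 * ((axis - 1650.0) / 25.0) ** 2)
        for j, m in enumerate(maxima):
            data[0, j] = m * band
        return HyperCube(data, axis, 5.5)

    def test_thresholds_and_boundaries(self):
        cube = self._cube_with_amide([0.05, 0.1, 1.0, 2.0, 2.5])
        mask = quality_filter(cube)
        # below 0.1 and above 2.0 removed; boundaries and interior retained
        assert mask.mask.tolist() == [[False, True, True, True, False]]

    def test_window_outside_axis_rejected(self):
        axis = np.arange(990.0, 1201.0, 4.0)
        cube = HyperCube(np.ones((2, 2, axis.size)), axis, 5.5)
        with pytest.raises(ValueError, match="amide"):
            quality_filter(cube)

    def test_monotone_under_brightening(self):
        rng = np.random.default_rng(4)
        axis = np.arange(990.0, 1801.0, 4.0)
        amide = (axis >= 1600) & (axis <= 1700)
        data = rng.random((6, 6, axis.size)) * 0.4
        cube = HyperCube(data, axis, 5.5)
        bright = HyperCube(data * 10, axis, 5.5)
        a1 = cube.data[:, :, amide].max(axis=2)
        cat = lambda a: np.digitize(a, [0.1, 2.0 + 1e-12])  # dim / ok / bright
        assert np.all(cat(a1 * 10) >= cat(a1))


class TestTruncation:
    def test_enumerated_band_set(self):
        axis = 990.0 + 4.0 * np.arange(703)
        cube = HyperCube(
            np.arange(703)[None, None, :] * np.ones((2, 2, 1)), axis, 5.5
        )
        out = truncate_paraffin_and_fingerprint(cube)
        expected = [
            v for v in axis
            if 900.0 <= v <= 1800.0
            and not (1350.0 < v < 1500.0)
            and not (2835.0 < v < 3000.0)
        ]
        assert out.axis.tolist() == expected
        assert not np.any((out.axis > 1350) & (out.axis < 1500))
        # pure band selection: retained values untouched
        keep = np.isin(axis, expected)
        assert np.array_equal(out.data, cube.data[:, :, keep])

    def test_boundary_band_1350_retained(self):
        axis = 990.0 + 4.0 * np.arange(703)
        cube = HyperCube(np.ones((1, 1, 703)), axis, 5.5)
        out = truncate_paraffin_and_fingerprint(cube)
        assert 1350.0 in out.axis

    def test_cube_within_fingerprint_unchanged(self):
        axis = np.arange(1000.0, 1301.0, 4.0)
        cube = HyperCube(np.random.default_rng(0).random((2, 2, axis.size)),
                         axis, 5.5)
        out = truncate_paraffin_and_fingerprint(cube)
        assert np.array_equal(out.data, cube.data)

    def test_empty_result_rejected(self):
        axis = np.arange(2900.0, 2921.0, 4.0)
        cube = HyperCube(np.ones((1, 1, axis.size)), axis, 5.5)
        with pytest.raises(ValueError):
            truncate_paraffin_and_fingerprint(cube)


class TestVectorNormalise:
    def test_three_four_five(self):
        cube = HyperCube(np.array([[[3.0, 4.0]]]), [1000.0, 1004.0], 1.0)
        out, mask = vector_normalise(cube)
        assert np.allclose(out.data[0, 0], [0.6, 0.8])
        assert mask.mask.all()

    def test_zero_spectrum_flagged_not_divided(self):
        data = np.ones((2, 2, 3))
        data[1, 1] = 0.0
        cube = HyperCube(data, [1.0, 2.0, 3.0], 1.0)
        out, mask = vector_normalise(cube)
        assert not mask.mask[1, 1]
        assert np.all(out.data[1, 1] == 0.0)

    def test_unit_norm_postcondition(self, small_cube_noisy):
        out, mask = vector_normalise(small_cube_noisy)
        norms = np.linalg.norm(out.spectra()[mask.mask.ravel()], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)


class TestPipeline:
    def test_stage_order_and_count(self, small_cube_noisy, refs_full):
        _, _, report = preprocess_pipeline(
            small_cube_noisy, constituents=refs_full.values
        )
        assert report["n_stages"] == 6
        assert [s["stage"] for s in report["stages"]] == [
            "rubberband", "denoise", "emsc", "quality_filter",
            "truncate", "vector_normalise",
        ]

    def test_clean_phantom_all_usable_and_unit_norm(self, small_cube_clean,
                                                    refs_full):
        out, mask, _ = preprocess_pipeline(
            small_cube_clean, constituents=refs_full.values
        )
        assert mask.mask.all()
        norms = np.linalg.norm(out.spectra(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_quality_before_normalise_matters(self):
        """Normalising first would hide over-bright spectra from the gate."""
        axis = np.arange(990.0, 1801.0, 4.0)
        band = np.exp(-0.5 * ((axis - 1650.0) / 25.0) ** 2)
        data = np.stack([[0.8 * band, 3.0 * band]])  # ok and too bright
        cube = HyperCube(data, axis, 5.5)
        gate_first = quality_filter(cube)
        normed, _ = vector_normalise(cube)
        gate_after_norm = quality_filter(normed)
        assert gate_first.mask.tolist() == [[True, False]]
        assert gate_after_norm.mask.tolist() == [[True, True]]

    def test_clean_phantom_pairwise_class_sam_preserved(
        self, small_scene, small_cube_clean, refs_full
    ):
        """Preprocessing must not distort clean data: pairwise SAM between
        class-mean spectra changes by < 1e-3 rad."""
        out, _, _ = preprocess_pipeline(
            small_cube_clean, constituents=refs_full.values
        )
        base, _ = vector_normalise(
            truncate_paraffin_and_fingerprint(small_cube_clean)
        )
        # majority class per low-res pixel
        f = 4
        lab = small_scene.label_map
        lab_lr = np.array([
            [np.bincount(lab[i*f:(i+1)*f, j*f:(j+1)*f].ravel()).argmax()
             for j in range(out.ncols)] for i in range(out.nrows)
        ])
        def pair_angles(cube):
            angles = {}
            for a, b in itertools.combinations([1, 2, 3, 4], 2):
                ma = cube.data[lab_lr == a].mean(axis=0)
                mb = cube.data[lab_lr == b].mean(axis=0)
                cos = ma @ mb / (np.linalg.norm(ma) * np.linalg.norm(mb))
                angles[(a, b)] = np.arccos(np.clip(cos, -1, 1))
            return angles
        before, after = pair_angles(base), pair_angles(out)
        for key in before:
            assert abs(after[key] - before[key]) < 1e-3


class TestConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(quality_lo=2.0, quality_hi=0.1)
        with pytest.raises(ValueError):
            PreprocessConfig(fingerprint=(1800.0, 900.0))
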