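import numpy as np
import pytest

from urimet import (
    Spectrum,
    SpectrumSet,
    normalize_to_reference,
    bin_spectrum,
    build_matrix,
    pareto_scale,
    apply_scaling,
)
from urimet.preprocess import WATER_WINDOW, _bin_edges_for_axis


def flat_spectrum(n=2048, lo=0.0, hi=9.5, value=1.0):
    ppm = np.linspace(lo, hi, n)
    return Spectrum(ppm, np.full(n, value))


def tsp_spectrum(n=4096):
    """A lone reference-like Gaussian at 0.05 ppm with integral > 0."""
    ppm = np.linspace(0.0, 9.5, n)
    return Spectrum(ppm, np.exp(-0.5 * ((ppm - 0.03) / 0.005) ** 2))


class TestNormalizeToReference:
    def test_divides_by_reference_integral(self):
        spec = tsp_spectrum()
        out = normalize_to_reference(spec)
        mask = (out.ppm >= -0.05) & (out.ppm <= 0.05)
        integral = np.trapezoid(out.intensity[mask], out.ppm[mask])
        assert np.isclose(integral, 1.0)
        # pure scaling: shape preserved
        ratio = spec.intensity[mask] / out.intensity[mask]
        assert np.allclose(ratio, ratio[0])

    def test_idempotent(self):
        once = normalize_to_reference(tsp_spectrum())
        twice = normalize_to_reference(once)
        assert np.allclose(once.intensity, twice.intensity)

    def test_zero_spectrum_errors_with_sample_name(self):
        spec = flat_spectrum(value=0.0)
        with pytest.raises(ValueError, match="urine_007"):
            normalize_to_reference(spec, sample_id="urine_007")

    def test_window_outside_axis_errors(self):
        with pytest.raises(ValueError, match="window"):
            normalize_to_reference(tsp_spectrum(), ref_window=(-2.0, -1.0))


def brute_force_edges(ppm_max, ppm_min, width, exclude):
    """Independent enumeration: walk down from ppm_max, drop overlaps."""
    edges = []
    right = ppm_max
    while right > ppm_min + 1e-12:
        left = max(ppm_min, right - width)
        if not (left < exclude[1] and right > exclude[0]):
            edges.append((left, right))
        right -= width
    return edges


class TestBinSpectrum:
    def test_constant_spectrum_uniform_full_bins(self):
        spec = flat_spectrum(n=9501, lo=0.0, hi=9.5)  # exactly 1000 points/ppm
        values, edges = bin_spectrum(spec, width=0.5, exclude=None)
        # all full interior bins hold the same number of points
        interior = values[1:-1]
        assert np.ptp(interior) == 0

    def test_no_bin_touches_water_window(self):
        spec = flat_spectrum()
        _, edges = bin_spectrum(spec)
        for left, right in edges:
            assert right <= WATER_WINDOW[0] or left >= WATER_WINDOW[1]

    def test_edges_match_brute_force_enumeration(self):
        spec = flat_spectrum()
        _, edges = bin_spectrum(spec)  # default width/exclusion
        oracle = brute_force_edges(9.5, 0.0, 0.0092, WATER_WINDOW)
        assert len(edges) == len(oracle)
        assert np.allclose(np.array(edges), np.array(oracle))

    def test_conservation_without_exclusion(self):
        rng = np.random.default_rng(0)
        spec = Spectrum(np.linspace(0, 9.5, 3000), rng.random(3000))
        values, _ = bin_spectrum(spec, exclude=None)
        assert np.isclose(values.sum(), spec.intensity.sum())

    def test_conservation_minus_dropped_points(self):
        rng = np.random.default_rng(1)
        spec = Spectrum(np.linspace(0, 9.5, 3000), rng.random(3000))
        all_values, all_edges = bin_spectrum(spec, exclude=None)
        kept_values, kept_edges = bin_spectrum(spec)
        dropped = sum(
            v for v, e in zip(all_values, all_edges) if e not in set(kept_edges)
        )
        assert np.isclose(kept_values.sum() + dropped, spec.intensity.sum())

    def test_width_exceeding_span_errors(self):
        with pytest.raises(ValueError, match="width"):
            bin_spectrum(flat_spectrum(), width=20.0)


class TestBuildMatrix:
    def test_identical_spectra_identical_rows(self):
        spec = flat_spectrum()
        sset = SpectrumSet(
            spec.ppm, np.tile(spec.intensity, (3, 1)), ["a", "b", "c"]
        )
        m = build_matrix(sset)
        assert np.array_equal(m.values[0], m.values[1])
        assert np.array_equal(m.values[0], m.values[2])

    def test_column_order_descending_ppm(self, small_scaled):
        _, _, matrix = small_scaled
        centers = matrix.bin_centers
        assert np.all(np.diff(centers) < 0)

    def test_stacking_equals_per_spectrum_binning(self, small_cohort):
        sset, _ = small_cohort
        m = build_matrix(sset)
        for i in (0, 7, 39):
            values, edges = bin_spectrum(sset.spectrum(i))
            assert np.allclose(m.values[i], values)
            assert edges == m.bin_edges

    def test_row_permutation_equivariance(self, small_cohort):
        sset, labels = small_cohort
        perm = np.random.default_rng(3).permutation(len(sset))
        shuffled = SpectrumSet(
            sset.ppm,
            sset.intensities[perm],
            [sset.sample_ids[i] for i in perm],
            labels[perm],
        )
        m1 = build_matrix(sset)
        m2 = build_matrix(shuffled)
        assert np.allclose(m1.values[perm], m2.values)


class TestParetoScaling:
    def test_forced_by_formula_column_123(self):
        X = np.array([[1.0], [2.0], [3.0]])
        scaled, params = pareto_scale(X)
        assert np.allclose(scaled.ravel(), [-1.0, 0.0, 1.0])
        assert params.col_sds[0] == 1.0

    def test_zero_variance_column_becomes_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        scaled, _ = pareto_scale(X)
        assert np.all(scaled[:, 0] == 0.0)

    def test_column_004_matches_hand_computation(self):
        col = np.array([0.0, 0.0, 4.0])
        scaled, _ = pareto_scale(col[:, None])
        # brute-force recomputation of (x - mean)/sqrt(sd)
        mean = sum(col) / 3
        sd = (sum((x - mean) ** 2 for x in col) / 2) ** 0.5
        expected = [(x - mean) / sd**0.5 for x in col]
        assert np.allclose(scaled.ravel(), expected)

    def test_scaled_matrix_means_and_pareto_variance(self, small_scaled):
        X, _, matrix = small_scaled
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-10)
        sd_before = matrix.values.std(axis=0, ddof=1)
        sd_after = X.std(axis=0, ddof=1)
        nz = sd_before > 0
        assert np.allclose(sd_after[nz], np.sqrt(sd_before[nz]))

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="2 samples"):
            pareto_scale(np.ones((1, 5)))


class TestApplyScaling:
    def test_training_params_reproduce_training_scaling(self, small_scaled):
        X, _, matrix = small_scaled
        _, params = pareto_scale(matrix)
        assert np.allclose(apply_scaling(matrix, params), X)

    def test_single_new_sample_and_mean_maps_to_zero(self):
        X = np.array([[1.0, 10.0], [3.0, 30.0], [5.0, 20.0]])
        _, params = pareto_scale(X)
        new = apply_scaling(params.col_means.copy(), params)
        assert new.shape == (1, 2)
        assert np.allclose(new, 0.0)

    def test_dimension_mismatch_errors(self):
        _, params = pareto_scale(np.random.default_rng(0).random((4, 6)))
        with pytest.raises(ValueError, match="column count"):
            apply_scaling(np.ones((2, 5)), params)
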