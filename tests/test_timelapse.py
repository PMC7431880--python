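"""Time-lapse feature transforms and vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasetrack.frame_features import MultivariateSeries, SERIES_FEATURE_NAMES
from phasetrack.timelapse import (
    PCAFeatures,
    TransformConfig,
    approximate_entropy,
    assemble_feature_based,
    assemble_value_based,
    dwt_features,
    fft_features,
    fit_apply_normalization,
    motion_features,
    paa,
    sax_features,
    stat_features,
    trend_features,
)

SQRT2 = np.sqrt(2.0)


class TestStatFeatures:
    def test_hand_computed(self):
        mean, median, std, lo, hi, _, _ = stat_features([1, 2, 3, 4])
        assert (mean, median, lo, hi) == (2.5, 2.5, 1.0, 4.0)
        assert std == pytest.approx(np.sqrt(1.25))

    def test_constant_series(self):
        mean, median, std, lo, hi, skew, kurt = stat_features(np.full(10, 3.0))
        assert std == 0.0 and lo == hi == mean == 3.0
        assert skew == 0.0 and kurt == 0.0

    def test_permutation_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        assert np.allclose(stat_features(x), stat_features(x[::-1]))


class TestFftFeatures:
    def test_pure_tone_dominates_at_its_bin(self):
        t = np.arange(30)
        mags = fft_features(np.cos(2 * np.pi * t * 3 / 30), n_coeff=5)
        assert np.argmax(mags) == 2  # 1-based frequency index 3
        others = np.delete(mags, 2)
        assert mags[2] > 10 * others.max()

    def test_constant_series_all_zero(self):
        assert np.allclose(fft_features(np.full(30, 2.0), 5), 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        assert np.allclose(fft_features(x, 5), fft_features(x + 17.0, 5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fft_features(np.arange(9), 5)


class TestDwtFeatures:
    def test_haar_level1_of_constant(self):
        coeffs = dwt_features([1.0, 1.0, 1.0, 1.0], "haar", 1)
        assert np.allclose(coeffs, [SQRT2, SQRT2, 0.0, 0.0])

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=32)
        coeffs = dwt_features(x, "haar", 2)
        assert np.sum(coeffs ** 2) == pytest.approx(np.sum(x ** 2))

    def test_step_inside_a_pair_yields_single_detail(self):
        coeffs = dwt_features([0.0, 1.0, 1.0, 1.0], "haar", 1)
        details = coeffs[2:]
        assert np.sum(np.abs(details) > 1e-12) == 1

    def test_length_30_padded_to_32_coefficients(self):
        assert dwt_features(np.arange(30.0), "haar", 2).size == 32

    def test_too_short_for_level(self):
        with pytest.raises(ValueError):
            dwt_features([1.0, 2.0], "haar", 2)


class TestTrend:
    def test_exact_line(self):
        slope, intercept = trend_features(2.0 * np.arange(10) + 1.0, dt_min=1.0)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)

    def test_slope_is_per_minute(self):
        slope, _ = trend_features(2.0 * np.arange(10) + 1.0, dt_min=5.0)
        assert slope == pytest.approx(0.4)

    def test_constant_series_zero_slope(self):
        slope, _ = trend_features(np.full(10, 7.0), 5.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_slope_unbiased(self):
        rng = np.random.default_rng(0)
        slopes = [trend_features(rng.normal(size=30), 1.0)[0] for _ in range(1000)]
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 2 * se + 1e-4


def apen_bruteforce(x, m=2, r_factor=0.2):
    """Independent O(n^2 m) double-loop oracle (Pincus convention)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = sum(1 for b in templates if np.max(np.abs(a - b)) <= r)
            total += np.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert approximate_entropy(np.full(30, 2.0)) == 0.0

    def test_periodic_below_noise(self):
        rng = np.random.default_rng(0)
        periodic = approximate_entropy(np.tile([0.0, 1.0], 15))
        noise = np.median(
            [approximate_entropy(rng.uniform(size=30)) for _ in range(100)]
        )
        assert periodic < noise

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(size=25)
            assert approximate_entropy(x) == pytest.approx(
                apen_bruteforce(x), abs=1e-12
            )


def paa_repeat_oracle(x, w):
    """Exact PAA via the upsample-by-w trick: independent of the
    interval-overlap implementation."""
    x = np.asarray(x, dtype=float)
    return np.repeat(x, w).reshape(w, x.size).mean(axis=1)


def sax_oracle(x, w=5, a=4):
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.full(w, a // 2, dtype=float)
    z = (x - x.mean()) / x.std()
    segments = np.repeat(z, w).reshape(w, x.size).mean(axis=1)
    return np.searchsorted(norm.ppf(np.arange(1, a) / a), segments, side="right").astype(float)


class TestSax:
    def test_constant_series_middle_symbol(self):
        assert np.all(sax_features(np.ones(30), 5, 4) == 2.0)

    def test_monotone_ramp_spans_alphabet(self):
        symbols = sax_features(np.arange(30.0), 5, 4)
        assert symbols[0] == 0 and symbols[-1] == 3
        assert np.all(np.diff(symbols) >= 0)

    def test_breakpoints_are_normal_quartiles(self):
        from phasetrack.timelapse import _sax_breakpoints

        assert np.allclose(
            _sax_breakpoints(4), [-0.6744897501960817, 0.0, 0.6744897501960817]
        )

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(10, 40)
            x = rng.normal(size=n)
            assert np.array_equal(sax_features(x, 5, 4), sax_oracle(x, 5, 4))

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            sax_features(np.arange(10.0), 5, 1)

    def test_paa_matches_repeat_oracle(self):
        rng = np.random.default_rng(3)
        for n in (10, 29, 30, 35):
            x = rng.normal(size=n)
            assert np.allclose(paa(x, 5), paa_repeat_oracle(x, 5))


class TestMotion:
    def test_straight_path(self):
        acc, euc, vel, direc = motion_features(
            [(0.0, 0.0), (1.5, 2.0), (3.0, 4.0)], dt_min=5.0
        )
        assert acc == pytest.approx(5.0) and euc == pytest.approx(5.0)
        assert vel == pytest.approx(0.5) and direc == pytest.approx(1.0)

    def test_closed_square_zero_directionality(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        acc, euc, _, direc = motion_features(square, 5.0)
        assert acc == pytest.approx(4.0) and euc == 0.0 and direc == 0.0

    def test_right_angle_path(self):
        acc, euc, _, direc = motion_features([(0, 0), (1, 0), (1, 1)], 5.0)
        assert acc == pytest.approx(2.0)
        assert euc == pytest.approx(np.sqrt(2.0))
        assert direc == pytest.approx(0.7071067811865476)

    def test_stationary_cell_directionality_one(self):
        _, _, _, direc = motion_features([(2.0, 2.0)] * 5, 5.0)
        assert direc == 1.0

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
            ),
            min_size=2,
            max_size=10,
        ),
        st.floats(-20, 20, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_translation_invariance(self, path, shift):
        base = motion_features(path, 5.0)
        moved = motion_features([(r + shift, c - shift) for r, c in path], 5.0)
        assert np.allclose(base, moved, atol=1e-8)


class TestPca:
    def test_train_mean_projects_to_zero(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(20, 12))
        pca = PCAFeatures(3).fit(train)
        assert np.allclose(pca.transform(train.mean(axis=0)), 0.0, atol=1e-10)

    def test_single_axis_variance_captured(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(50, 1))
        train = np.hstack([t, 1e-6 * rng.normal(size=(50, 1))])
        pca = PCAFeatures(1).fit(train)
        assert pca._pca.explained_variance_ratio_[0] > 0.99

    def test_training_scores_uncorrelated(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(30, 8))
        scores = PCAFeatures(3).fit(train).transform(train)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8


def toy_series(n=30, d=len(SERIES_FEATURE_NAMES), seed=0):
    rng = np.random.default_rng(seed)
    return MultivariateSeries(
        cell_id=0,
        values=rng.normal(size=(n, d)),
        feature_names=SERIES_FEATURE_NAMES,
        frame_interval_min=5.0,
        centroids_px=rng.normal(size=(n, 2)),
    )


class TestAssembly:
    def test_feature_based_length(self):
        cfg = TransformConfig()
        series = toy_series()
        vec = assemble_feature_based(series, cfg, pca_scores=np.zeros(3))
        d = len(SERIES_FEATURE_NAMES)
        partial_len = 7 + cfg.n_fft_coeff + 32 + 2 + 1 + cfg.sax_word_len
        assert vec.values.size == d * partial_len + 3 + 4
        assert len(vec.names) == vec.values.size

    def test_name_lists_identical_across_cells(self):
        a = assemble_feature_based(toy_series(seed=1))
        b = assemble_feature_based(toy_series(seed=2))
        assert a.names == b.names

    def test_value_based_roundtrip(self):
        series = toy_series()
        vec = assemble_value_based(series)
        d = len(SERIES_FEATURE_NAMES)
        assert vec.values.size == 30 * d
        assert np.array_equal(vec.values.reshape(d, 30).T, series.values)

    def test_constant_cell_constant_value_vector(self):
        series = toy_series()
        series.values[:] = 2.0
        assert np.all(assemble_value_based(series).values == 2.0)


class TestNormalization:
    def test_train_column_spans_unit_interval(self):
        train = np.array([[2.0], [4.0]])
        scaled, _, stats = fit_apply_normalization(train)
        assert scaled.ravel().tolist() == [0.0, 1.0]

    def test_test_values_clipped(self):
        train = np.array([[2.0], [4.0]])
        _, test, _ = fit_apply_normalization(train, np.array([[5.0], [1.0]]))
        assert test.ravel().tolist() == [1.0, 0.0]

    def test_zero_range_maps_to_zero(self):
        train = np.full((3, 2), 7.0)
        scaled, _, _ = fit_apply_normalization(train)
        assert np.all(scaled == 0.0)

    def test_idempotent_on_train(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(10, 4))
        once, _, _ = fit_apply_normalization(train)
        twice, _, _ = fit_apply_normalization(once)
        assert np.allclose(once, twice)
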