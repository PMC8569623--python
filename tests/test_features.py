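"""Windowing, the four per-channel features, feature images, patches,
and mutual-information ranking."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semg.exceptions import DimensionError, EmptyInputError
from semg.features import (BandConfig, EmgImage, FeatureNormalizer,
                           build_feature_image, decompose_patches,
                           frequency_ratio, mean_absolute_value, mean_power,
                           median_frequency, mutual_information,
                           power_spectrum, rank_features_mutual_information,
                           reassemble_patches, window_signal)

FS = 1000.0


class TestWindowing:
    def test_window_count_and_starts(self, rng):
        x = rng.normal(size=(2, 1000))
        wins = window_signal(x, 200, 100)
        assert len(wins) == 9
        assert [w.t0 for w in wins] == list(range(0, 900, 100))

    def test_full_length_window_is_identity(self, rng):
        x = rng.normal(size=(3, 256))
        wins = window_signal(x, 256, 64)
        assert len(wins) == 1
        assert np.array_equal(wins[0].pixels, x)

    def test_non_overlapping_windows_reconstruct_signal(self, rng):
        x = rng.normal(size=(2, 1050))
        wins = window_signal(x, 100, 100)
        rebuilt = np.concatenate([w.pixels for w in wins], axis=1)
        assert np.array_equal(rebuilt, x[:, :1000])

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(EmptyInputError):
            window_signal(np.zeros((1, 50)), 100, 10)


class TestMav:
    def test_constant(self):
        assert mean_absolute_value(np.full(10, -3.0)) == 3.0

    def test_hand_example(self):
        assert mean_absolute_value(np.array([1.0, -1.0, 2.0, -2.0])) == 1.5

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=1000)
        acc = 0.0
        for v in x:
            acc += abs(v)
        assert mean_absolute_value(x) == pytest.approx(acc / 1000, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            mean_absolute_value(np.array([]))


class TestPowerSpectrum:
    def test_sine_power_concentrates_at_its_bin(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 100.0 * t)     # exactly bin 100
        f, P = power_spectrum(x, FS)
        assert P[np.argmin(np.abs(f - 100.0))] >= 0.99 * P.sum()

    def test_zero_signal(self):
        _, P = power_spectrum(np.zeros(128), FS)
        assert np.all(P == 0)

    def test_parseval_consistency(self, rng):
        x = rng.normal(size=999)
        _, P = power_spectrum(x, FS)
        assert P.sum() == pytest.approx(np.mean(x ** 2), rel=1e-6)

    def test_one_sided_length(self):
        f, P = power_spectrum(np.ones(200), FS)
        assert len(P) == 101


class TestFrequencyRatio:
    band = BandConfig(llc=10, lhc=90, hlc=110, hhc=190)

    def test_equal_power_gives_one(self):
        freqs = np.arange(0, 201.0)
        P = np.ones_like(freqs)
        assert frequency_ratio(P, freqs, self.band) == pytest.approx(1.0)

    def test_zero_high_band_gives_inf_sentinel(self):
        freqs = np.arange(0, 201.0)
        P = np.zeros_like(freqs)
        P[20] = 1.0
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fr = frequency_ratio(P, freqs, self.band)
        assert fr == np.inf
        assert any("high-band" in str(w.message) for w in caught)

    def test_two_tone_matches_amplitude_ratio(self):
        t = np.arange(2000) / FS
        a, b = 3.0, 1.5
        x = a * np.sin(2 * np.pi * 50 * t) + b * np.sin(2 * np.pi * 150 * t)
        f, P = power_spectrum(x, FS)
        fr = frequency_ratio(P, f, self.band)
        assert fr == pytest.approx(a ** 2 / b ** 2, rel=0.05)


class TestMedianFrequency:
    def test_flat_spectrum(self):
        freqs = np.arange(10.0)
        P = np.ones(10)
        # first bin whose cumulative sum reaches half of the total
        assert median_frequency(P, freqs) == freqs[4]

    def test_point_mass(self):
        freqs = np.arange(8.0)
        P = np.zeros(8)
        P[5] = 2.2
        assert median_frequency(P, freqs) == 5.0

    def test_matches_cumulative_scan_oracle(self, rng):
        freqs = np.arange(64.0)
        P = rng.random(64)
        half = 0.5 * P.sum()
        acc = 0.0
        for j in range(64):
            acc += P[j]
            if acc >= half:
                expected = freqs[j]
                break
        assert median_frequency(P, freqs) == expected

    def test_zero_spectrum_rejected(self):
        with pytest.raises(EmptyInputError):
            median_frequency(np.zeros(8), np.arange(8.0))


class TestMeanPower:
    def test_flat(self):
        assert mean_power(np.full(7, 3.0)) == 3.0

    def test_point_mass(self):
        P = np.zeros(10)
        P[3] = 5.0
        assert mean_power(P) == 0.5

    def test_matches_loop_oracle(self, rng):
        P = rng.random(333)
        acc = 0.0
        for v in P:
            acc += v
        assert mean_power(P) == pytest.approx(acc / 333, abs=1e-12)


class TestFeatureImage:
    def test_mav_row_of_constant_channels(self):
        win = EmgImage(np.vstack([np.full(100, 2.0), np.full(100, -3.0)]),
                       0, 100, 100)
        img = build_feature_image(win, FS)
        assert img.values[0] == pytest.approx([2.0, 3.0])

    def test_determinism(self, rng):
        win = EmgImage(rng.normal(size=(4, 200)), 0, 200, 100)
        a = build_feature_image(win, FS).values
        b = build_feature_image(win, FS).values
        assert np.array_equal(a, b)

    def test_matches_standalone_ops_per_channel(self, rng):
        px = rng.normal(size=(3, 200))
        img = build_feature_image(EmgImage(px, 0, 200, 100), FS).values
        for c in range(3):
            f, P = power_spectrum(px[c], FS)
            assert img[0, c] == mean_absolute_value(px[c])
            assert img[1, c] == frequency_ratio(P, f)
            assert img[2, c] == median_frequency(P, f)
            assert img[3, c] == mean_power(P)

    def test_no_cross_channel_leakage(self, rng):
        px = rng.normal(size=(2, 128))
        both = build_feature_image(EmgImage(px, 0, 128, 64), FS).values
        solo = build_feature_image(EmgImage(px[:1], 0, 128, 64), FS).values
        assert np.array_equal(both[:, 0], solo[:, 0])

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_equivariance(self, a):
        rng = np.random.default_rng(99)
        x = rng.normal(size=400)
        f, P = power_spectrum(x, FS)
        fa, Pa = power_spectrum(a * x, FS)
        assert mean_absolute_value(a * x) == pytest.approx(
            a * mean_absolute_value(x), rel=1e-9)
        assert median_frequency(Pa, fa) == median_frequency(P, f)
        assert frequency_ratio(Pa, fa) == pytest.approx(
            frequency_ratio(P, f), rel=1e-9)
        assert mean_power(Pa) == pytest.approx(a * a * mean_power(P), rel=1e-9)


class TestFeatureNormalizer:
    def test_inf_maps_to_largest_finite_normalized_value(self):
        from semg.features import FeatureImage
        imgs = [FeatureImage(np.arange(8.0).reshape(4, 2)),
                FeatureImage(np.arange(8.0, 16.0).reshape(4, 2))]
        norm = FeatureNormalizer().fit(imgs)
        bad = np.ones((4, 2))
        bad[1, 0] = np.inf
        z = norm.transform(FeatureImage(bad)).values
        assert np.isfinite(z).all()
        assert z[1, 0] == norm.max_norm_[1]

    def test_train_statistics_reused_on_test(self):
        from semg.features import FeatureImage
        train = [FeatureImage(np.full((4, 2), 10.0) + i) for i in range(3)]
        norm = FeatureNormalizer().fit(train)
        z = norm.transform(FeatureImage(np.zeros((4, 2)))).values
        # normalized with train mean 11, train std ~0.8165
        assert z[0, 0] == pytest.approx((0 - 11.0) / np.std([10, 11, 12]))


class TestPatches:
    def test_single_patch_identity(self, rng):
        img = rng.normal(size=(4, 12))
        ps = decompose_patches(img, 1)
        assert ps.n == 1 and np.array_equal(ps.patches[0], img)

    def test_partition_roundtrip(self, rng):
        img = rng.normal(size=(3, 200))
        ps = decompose_patches(img, 4)
        assert all(p.shape == (3, 50) for p in ps.patches)
        assert np.array_equal(reassemble_patches(ps), img)

    def test_indivisible_raises_with_hint(self):
        with pytest.raises(DimensionError, match="pad"):
            decompose_patches(np.zeros((2, 200)), 3)


class TestMutualInformationRanking:
    def test_label_encoding_eliminated_last(self, rng):
        n = 600
        labels = rng.integers(0, 3, size=n)
        X = np.column_stack([rng.normal(size=n),
                             labels.astype(float),      # 1-to-1 with labels
                             rng.normal(size=n)])
        order, _ = rank_features_mutual_information(X, labels, n_select=1)
        assert order[-1] == 1

    def test_independent_feature_has_low_mi(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=2000)
        noise = rng.uniform(size=2000)
        assert mutual_information(noise, labels) <= 0.05

    def test_noise_column_eliminated_before_informative_twins(self):
        rng = np.random.default_rng(8)
        n = 1500
        labels = rng.integers(0, 2, size=n)
        informative = labels + 0.1 * rng.normal(size=n)
        X = np.column_stack([informative, informative.copy(),
                             rng.uniform(size=n)])
        order, selected = rank_features_mutual_information(X, labels, n_select=2)
        assert order[0] == 2
        assert sorted(selected) == [0, 1]

    def test_constant_column_mi_zero_and_dropped_first(self, rng):
        labels = rng.integers(0, 2, size=500)
        X = np.column_stack([np.full(500, 3.3),
                             labels + 0.05 * rng.normal(size=500)])
        assert mutual_information(X[:, 0], labels) == pytest.approx(0.0, abs=1e-12)
        order, _ = rank_features_mutual_information(X, labels, n_select=1)
        assert order[0] == 0

    def test_requires_two_classes(self, rng):
        with pytest.raises(DimensionError):
            rank_features_mutual_information(rng.normal(size=(50, 3)),
                                             np.zeros(50, dtype=int))
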