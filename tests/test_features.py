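"""The 51-feature system, with brute-force oracles for the nonlinear features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepcascade import synth_epoch, wtd_denoise
from sleepcascade.features import (
    AUX_TIME_FEATURES,
    FEATURE_NAMES,
    Spectrum,
    auxiliary_time_features,
    binarize_median,
    coarse_grain,
    energy_features,
    extract_feature_vector,
    frequency_features,
    fuzzy_entropy,
    lz76_phrase_count,
    lzc,
    multiscale_entropy,
    power_spectrum,
    renyi_entropy,
    sample_entropy,
    spectral_entropy,
    std_features,
)
from sleepcascade.preprocessing import WAVE_ORDER, extract_characteristic_waves

FS = 100.0


def _waves_from(values_by_name):
    """Minimal six-wave dict for the time/energy features."""
    return {name: np.asarray(values_by_name[name], float) for name in WAVE_ORDER}


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------


def _lz76_oracle(bits) -> int:
    """Exhaustive-history parse via substring search (definition-level)."""
    s = "".join(str(int(b)) for b in bits)
    phrases, i, n = 0, 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        phrases += 1
        i += k
    return phrases


def _sampen_oracle(x, m, r):
    n = len(x)
    nt = n - m

    def count(length):
        hits = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) < r:
                    hits += 1
        return hits

    a, b = count(m + 1), count(m)
    return -math.log(a / b)


def _fuzzen_oracle(x, m, r, gradient=2.0):
    x = np.asarray(x, float)
    nt = len(x) - m

    def phi(length):
        acc = 0.0
        pairs = 0
        for i in range(nt - 1):
            ti = x[i : i + length] - x[i : i + length].mean()
            for j in range(i + 1, nt):
                tj = x[j : j + length] - x[j : j + length].mean()
                d = np.max(np.abs(ti - tj))
                acc += math.exp(-((d / r) ** gradient))
                pairs += 1
        return acc / pairs

    return math.log(phi(m)) - math.log(phi(m + 1))


# ---------------------------------------------------------------------------
# Time / energy / frequency domains
# ---------------------------------------------------------------------------


class TestStdAndEnergy:
    def test_printed_std_has_no_1_over_n(self):
        waves = _waves_from({name: [1.0, -1.0] for name in WAVE_ORDER})
        out = std_features(waves)
        for name in WAVE_ORDER:
            assert out[f"std_{name}"] == pytest.approx(math.sqrt(2.0))

    def test_constant_wave_zero_std(self):
        waves = _waves_from({name: [3.0, 3.0, 3.0] for name in WAVE_ORDER})
        assert all(v == 0.0 for v in std_features(waves).values())

    def test_std_homogeneous_in_scale(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        waves = _waves_from({name: base for name in WAVE_ORDER})
        scaled = _waves_from({name: -2.5 * base for name in WAVE_ORDER})
        a = std_features(waves)["std_alpha"]
        b = std_features(scaled)["std_alpha"]
        assert b == pytest.approx(2.5 * a)

    def test_energy_and_ratios(self):
        values = {name: [0.0, 0.0, 0.0] for name in WAVE_ORDER}
        values["alpha"] = [1.0, 0.0, 0.0]
        values["theta"] = [1.0, 0.0, 0.0]
        values["delta"] = [2.0, 0.0, 0.0]
        out = energy_features(_waves_from(values))
        assert out["energy_alpha"] == 1.0
        assert out["energy_ratio_alpha_theta"] == pytest.approx(1.0)
        assert out["energy_ratio_delta_theta"] == pytest.approx(4.0)

    def test_zero_theta_energy_raises(self):
        waves = _waves_from({name: [0.0, 0.0] for name in WAVE_ORDER})
        with pytest.raises(ValueError):
            energy_features(waves)


class TestSpectrumFeatures:
    def test_periodogram_peak_at_tone(self):
        t = np.arange(3000) / FS
        spec = power_spectrum(np.sin(2 * np.pi * 10 * t), FS)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(10.0, abs=0.05)

    def test_parseval(self):
        x = np.random.default_rng(1).normal(size=2048)
        spec = power_spectrum(x, FS)
        df = spec.frequencies[1] - spec.frequencies[0]
        assert np.sum(spec.power) * df == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_mnf_of_tone(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        waves = extract_characteristic_waves(x, FS)
        out = frequency_features(waves, x, FS)
        assert out["mnf"] == pytest.approx(10.0, abs=0.5)

    def test_mnf_flat_spectrum_is_centroid(self):
        # white-ish impulse: flat periodogram -> centroid at Nyquist/2
        x = np.zeros(1000)
        x[0] = 1.0
        spec = power_spectrum(x, FS)
        mnf = np.sum(spec.power * spec.frequencies) / np.sum(spec.power)
        assert mnf == pytest.approx(25.0, rel=0.01)

    def test_renyi_uniform_and_point_mass(self):
        uniform = Spectrum(np.arange(4.0), np.ones(4))
        point = Spectrum(np.arange(4.0), np.array([0.0, 5.0, 0.0, 0.0]))
        assert renyi_entropy(uniform) == pytest.approx(math.log(4))
        assert renyi_entropy(point) == pytest.approx(0.0)

    def test_renyi_scale_invariant(self):
        p = np.array([0.5, 1.0, 2.0, 0.25])
        a = renyi_entropy(Spectrum(np.arange(4.0), p))
        b = renyi_entropy(Spectrum(np.arange(4.0), 7.3 * p))
        assert a == pytest.approx(b, rel=1e-12)

    def test_spectral_entropy_bounds_and_order(self):
        uniform = Spectrum(np.arange(8.0), np.ones(8))
        point = Spectrum(np.arange(8.0), np.eye(8)[0])
        assert spectral_entropy(point) == pytest.approx(0.0)
        assert spectral_entropy(uniform) == pytest.approx(math.log(8))
        mixed = Spectrum(np.arange(4.0), np.array([4.0, 2.0, 1.0, 1.0]))
        assert spectral_entropy(mixed) >= renyi_entropy(mixed)


# ---------------------------------------------------------------------------
# Nonlinear dynamics
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_median_split(self):
        np.testing.assert_array_equal(
            binarize_median([1.0, 2.0, 3.0, 4.0]), [0, 0, 1, 1]
        )

    def test_constant_is_all_ones(self):
        np.testing.assert_array_equal(binarize_median([5.0] * 4), [1, 1, 1, 1])

    @given(
        st.lists(st.integers(-100, 100), min_size=4, max_size=40),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values, dtype=float)
        np.testing.assert_array_equal(binarize_median(x), binarize_median(a * x + b))


class TestLZC:
    def test_all_zero_sequence(self):
        bits = np.zeros(10, dtype=np.uint8)
        assert lz76_phrase_count(bits) == 2
        assert lzc(bits) == pytest.approx(2 * math.log2(10) / 10)

    @pytest.mark.parametrize(
        "bits",
        [
            "0110100110010110",  # Thue-Morse prefix
            "0001101001000101",
            "01" * 20,
            "0000000000",
            "1111010001",
        ],
    )
    def test_matches_substring_oracle(self, bits):
        arr = np.array([int(b) for b in bits], dtype=np.uint8)
        assert lz76_phrase_count(arr) == _lz76_oracle(bits)

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            bits = rng.integers(0, 2, rng.integers(10, 200)).astype(np.uint8)
            assert lz76_phrase_count(bits) == _lz76_oracle(bits)

    def test_random_more_complex_than_alternating(self):
        rng = np.random.default_rng(3)
        random_bits = rng.integers(0, 2, 1000).astype(np.uint8)
        periodic = np.tile([0, 1], 500).astype(np.uint8)
        assert lzc(random_bits) > lzc(periodic)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            lzc(np.array([0, 1, 2]))


class TestCoarseGrain:
    def test_identity_at_tau_1(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means_and_remainder(self):
        np.testing.assert_array_equal(coarse_grain([1.0, 1, 2, 2], 2), [1.0, 2.0])
        np.testing.assert_array_equal(
            coarse_grain([1.0, 2, 3, 4, 5], 2), [1.5, 3.5]
        )

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 0)


class TestEntropies:
    def test_sampen_periodic_is_zero(self):
        x = np.tile([1.0, 2.0], 50)
        assert sample_entropy(x, m=2) == pytest.approx(0.0, abs=1e-12)

    def test_sampen_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        for n in (50, 120, 200):
            x = rng.normal(size=n)
            r = 0.2 * np.std(x)
            assert sample_entropy(x, 2, r) == pytest.approx(
                _sampen_oracle(x, 2, r), abs=1e-9
            )

    def test_noise_exceeds_sine(self):
        rng = np.random.default_rng(5)
        t = np.arange(500) / FS
        sine = np.sin(2 * np.pi * 5 * t)
        noise = rng.normal(size=500)
        noise *= sine.std() / noise.std()
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(100))

    def test_msen_tau1_equals_sampen(self):
        x = np.random.default_rng(6).normal(size=300)
        assert multiscale_entropy(x, tau=1) == pytest.approx(sample_entropy(x))

    def test_msen_matches_oracle_at_scale(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        r = 0.2 * np.std(x)
        grained = coarse_grain(x, 11)
        assert multiscale_entropy(x, tau=11) == pytest.approx(
            _sampen_oracle(grained, 2, r), abs=1e-9
        )
        assert multiscale_entropy(x, tau=11) != pytest.approx(
            sample_entropy(x), abs=1e-6
        )

    def test_msen_literal_sum_is_block_multiple(self):
        x = np.random.default_rng(8).normal(size=220)
        single = multiscale_entropy(x, tau=11)
        summed = multiscale_entropy(x, tau=11, literal_sum=True)
        assert summed == pytest.approx(single * (220 // 11))

    def test_fuzzen_period2_is_zero_and_period4_matches_oracle(self):
        x2 = np.tile([1.0, 2.0], 50)
        assert fuzzy_entropy(x2) == pytest.approx(0.0, abs=1e-12)
        x4 = np.tile([0.5, -0.5, 1.0, -1.0], 30)
        r = 0.2 * np.std(x4)
        assert fuzzy_entropy(x4, 2, r) == pytest.approx(
            _fuzzen_oracle(x4, 2, r), abs=1e-9
        )

    def test_fuzzen_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        for n in (60, 150):
            x = rng.normal(size=n)
            r = 0.2 * np.std(x)
            assert fuzzy_entropy(x, 2, r) == pytest.approx(
                _fuzzen_oracle(x, 2, r), abs=1e-9
            )

    def test_fuzzen_mean_shift_invariant(self):
        x = np.random.default_rng(10).normal(size=120)
        r = 0.2 * np.std(x)
        assert fuzzy_entropy(x, 2, r) == pytest.approx(
            fuzzy_entropy(x + 40.0, 2, r), rel=1e-9
        )

    def test_fuzzen_increases_with_impulsive_noise(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, 400)
        spiky = base.copy()
        spiky[::40] += rng.choice([-6, 6], size=spiky[::40].size)
        r = 0.2 * np.std(base)
        assert fuzzy_entropy(spiky, 2, r) > fuzzy_entropy(base, 2, r)


# ---------------------------------------------------------------------------
# Auxiliary registry and assembly
# ---------------------------------------------------------------------------


class TestAuxiliaryFeatures:
    def test_constant_epoch_degenerates(self):
        out = auxiliary_time_features(np.full(3000, 2.0), FS)
        assert out["variance"] == 0.0
        assert out["zero_crossings"] == 0.0
        assert out["peak_to_peak"] == 0.0

    def test_hjorth_mobility_of_tone_is_angular_frequency(self):
        t = np.arange(3000) / FS
        for f in (5.0, 10.0):
            out = auxiliary_time_features(np.sin(2 * np.pi * f * t), FS)
            assert out["hjorth_mobility"] == pytest.approx(2 * np.pi * f, rel=0.05)

    def test_symmetric_sample_has_small_skew(self):
        x = np.random.default_rng(12).normal(size=3000)
        out = auxiliary_time_features(x, FS)
        assert abs(out["skewness"]) < 0.1

    def test_registry_size(self):
        assert len(AUX_TIME_FEATURES) == 17


class TestFeatureVector:
    def test_canonical_names_are_51(self):
        assert len(FEATURE_NAMES) == 51
        assert len(set(FEATURE_NAMES)) == 51

    def test_vector_complete_and_deterministic(self):
        x = wtd_denoise(synth_epoch("N2", seed=21).samples)
        one = extract_feature_vector(x, FS)
        two = extract_feature_vector(x.copy(), FS)
        assert list(one) == list(FEATURE_NAMES)
        assert one == two
        assert all(np.isfinite(v) for v in one.values())

    def test_alpha_dominant_epoch_has_largest_alpha_std(self):
        t = np.arange(3000) / FS
        x = 40 * np.sin(2 * np.pi * 10 * t) + np.random.default_rng(13).normal(
            0, 2, 3000
        )
        vec = extract_feature_vector(x, FS)
        stds = {w: vec[f"std_{w}"] for w in WAVE_ORDER}
        assert max(stds, key=stds.get) == "alpha"
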