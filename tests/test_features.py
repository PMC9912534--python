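"""Feature families against independent oracles (closed forms, brute force,
periodogram integration)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eegdem.containers import EpochSet
from eegdem.features import (band_power, band_powers, build_feature_matrix,
                             epoch_features, feature_columns, hjorth,
                             relative_power, sample_entropy,
                             stft_band_features)
from eegdem.montage import DEFAULT_BANDS, MONTAGE_16

FS = 200.0
BANDS = [(1, 4), (4, 8), (8, 13), (13, 30), (30, 45)]


def sinusoid(freq, duration=5.0, amplitude=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestBandPower:
    def test_zero_signal(self):
        assert band_power(np.zeros(1000), (8, 13), FS) == 0.0

    def test_sinusoid_parseval(self):
        """Unit 10 Hz sinusoid: alpha power = A^2/2 = 0.5 uV^2 within 5%."""
        p = band_power(sinusoid(10.0), (8, 13), FS)
        assert abs(p - 0.5) < 0.025

    @pytest.mark.parametrize("freq,band", [(2.5, (1, 4)), (6.0, (4, 8)),
                                           (20.0, (13, 30)), (38.0, (30, 45))])
    def test_sinusoid_lands_in_its_band(self, freq, band):
        x = sinusoid(freq)
        p_in = band_power(x, band, FS)
        assert abs(p_in - 0.5) < 0.05
        total = sum(band_power(x, b, FS) for b in BANDS)
        assert p_in / total > 0.9

    def test_white_noise_flat_spectrum_oracle(self):
        """Five-band power sum of white noise ~ sigma^2 * 44/(fs/2)."""
        rng = np.random.default_rng(0)
        sums = []
        for _ in range(100):
            x = rng.standard_normal(1000) * 2.0
            sums.append(sum(band_power(x, b, FS) for b in BANDS))
        expect = 4.0 * 44.0 / 100.0
        assert abs(np.mean(sums) - expect) < 0.05 * expect

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.ones(1000), (50, 120), FS)


class TestRelativePower:
    def test_uniform_powers(self):
        rel = relative_power({b: 1.0 for b in "abcde"})
        assert all(abs(v - 0.2) < 1e-12 for v in rel.values())

    def test_pure_sinusoid_dominates_alpha(self):
        powers = band_powers(sinusoid(10.0), FS)
        rel = relative_power(powers)
        assert rel["alpha"] >= 0.95

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_power({b: 0.0 for b in "abcde"})

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=5,
                    max_size=5))
    @settings(derandomize=True, max_examples=50)
    def test_normalization_sums_to_one(self, powers):
        rel = relative_power(dict(zip("abcde", powers)))
        assert abs(sum(rel.values()) - 1.0) < 1e-9


def hjorth_oracle(x):
    """Direct variance-formula computation, independent of the implementation."""
    d1 = x[1:] - x[:-1]
    d2 = d1[1:] - d1[:-1]
    act = np.mean((x - x.mean()) ** 2)
    mob = np.sqrt(np.mean((d1 - d1.mean()) ** 2) / act)
    comp = np.sqrt(np.mean((d2 - d2.mean()) ** 2)
                   / np.mean((d1 - d1.mean()) ** 2)) / mob
    return act, mob, comp


class TestHjorth:
    def test_white_noise_activity(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        assert abs(hjorth(x).activity - 1.0) < 0.02

    @pytest.mark.parametrize("freq", [5.0, 10.0, 25.0])
    def test_sinusoid_mobility_closed_form(self, freq):
        """First differences of sin(2 pi f n / fs) give mobility
        2 sin(pi f / fs)."""
        x = sinusoid(freq, duration=10.0)
        expect = 2 * np.sin(np.pi * freq / FS)
        assert abs(hjorth(x).mobility - expect) < 0.01 * expect

    def test_sinusoid_complexity_near_one(self):
        assert abs(hjorth(sinusoid(10.0, duration=10.0)).complexity - 1.0) < 0.02

    def test_constant_signal_flagged(self):
        h = hjorth(np.ones(100))
        assert h.degenerate and h.activity == 0.0
        assert np.isnan(h.mobility) and np.isnan(h.complexity)

    def test_matches_direct_formula_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.standard_normal(500) * rng.uniform(0.5, 20)
            h = hjorth(x)
            act, mob, comp = hjorth_oracle(x)
            assert abs(h.activity - act) < 1e-9 * max(act, 1)
            assert abs(h.mobility - mob) < 1e-12
            assert abs(h.complexity - comp) < 1e-12


def sampen_bruteforce(x, m, r):
    """Naive O(N^2) pairwise template counting."""
    n = len(x)
    def count(length):
        templates = [x[i:i + length] for i in range(n - m)]
        hits = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    hits += 1
        return hits
    a, b = count(m + 1), count(m)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


class TestSampleEntropy:
    def test_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.standard_normal(50)
            r = 0.2 * x.std()
            got = sample_entropy(x, m=2, r=r)
            want = sampen_bruteforce(x, 2, r)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert abs(got - want) < 1e-12

    def test_periodic_signal_near_zero(self):
        x = np.tile([0.0, 1.0], 500)      # period 2 <= m
        assert sample_entropy(x, m=2, r=0.1) < 1e-9

    def test_monotone_in_tolerance(self):
        x = np.random.default_rng(4).standard_normal(300)
        values = [sample_entropy(x, r=r) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_no_matches_yields_nan(self):
        x = np.arange(10.0) ** 3          # strictly accelerating: no matches
        assert np.isnan(sample_entropy(x, m=2, r=1e-6))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), m=2, r=0.1)


class TestStftFeatures:
    def test_zero_signal(self):
        assert stft_band_features(np.zeros((16, 1000)), FS, (8, 13)) == (0.0, 0.0)

    def test_stationary_sinusoid_low_temporal_sd(self):
        x = np.tile(sinusoid(10.0), (16, 1))
        mu, sd = stft_band_features(x, FS, (8, 13))
        assert sd < 0.05 * mu

    def test_burst_modulation_high_temporal_sd(self):
        x = sinusoid(10.0)
        envelope = (np.arange(len(x)) // 200) % 2   # 1-s on/off square
        x = np.tile(x * envelope, (16, 1))
        mu, sd = stft_band_features(x, FS, (8, 13))
        assert sd > 0.5 * mu


@pytest.fixture(scope="module")
def epoch_sets():
    rng = np.random.default_rng(5)
    sets = []
    for sid in ("s1", "s2"):
        data = rng.standard_normal((4, 16, 1000)) * 10
        sets.append(EpochSet(data, FS, sid, MONTAGE_16,
                             offsets=np.arange(4) * 1000))
    return sets


class TestFeatureMatrix:
    def test_column_inventory(self, epoch_sets):
        cols = feature_columns(MONTAGE_16)
        fams = pd.Series([c.split("/")[0] for c in cols]).value_counts()
        assert fams["abs_power"] == 80 and fams["rel_power"] == 80
        assert (fams["hjorth_activity"] == fams["hjorth_mobility"]
                == fams["hjorth_complexity"] == 16)
        assert fams["sampen"] == 16
        assert fams["stft_mean"] == fams["stft_sd"] == 5
        assert len(cols) == 243
        assert len(set(cols)) == len(cols)

    def test_epoch_level_rows_and_provenance(self, epoch_sets):
        fm = build_feature_matrix(epoch_sets, level="epoch")
        assert len(fm) == 8
        assert set(fm["subject_id"]) == {"s1", "s2"}
        assert fm.shape[1] == 245
        rel_cols = [c for c in fm.columns if c.startswith("rel_power")
                    and c.endswith("/O2")]
        np.testing.assert_allclose(fm[rel_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_subject_level_mean_of_identical_epochs(self):
        rng = np.random.default_rng(6)
        one = rng.standard_normal((1, 16, 1000)) * 10
        data = np.repeat(one, 3, axis=0)
        es = EpochSet(data, FS, "dup", MONTAGE_16, offsets=np.arange(3))
        fm_e = build_feature_matrix([es], level="epoch")
        fm_s = build_feature_matrix([es], level="subject")
        vals_e = fm_e.drop(columns=["subject_id", "epoch"]).iloc[0]
        vals_s = fm_s.drop(columns=["subject_id"]).iloc[0]
        np.testing.assert_allclose(vals_s.to_numpy(), vals_e.to_numpy(),
                                   rtol=1e-9)

    def test_all_values_finite_on_clean_data(self, epoch_sets):
        fm = build_feature_matrix(epoch_sets, level="epoch")
        assert np.isfinite(fm.drop(columns=["subject_id"]).to_numpy()).all()
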