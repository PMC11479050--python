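"""Feature formulas against closed forms and naive loop oracles."""

import math

import numpy as np
import pytest

from tonus import features as ft
from tonus.segment import SignalWindow
from tonus.synth import ToneClass

FS = 2000.0


# --- naive loop oracles, independent of the vectorized implementations -----

def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_mmav(x, m):
    parts = np.array_split(np.asarray(x, float), min(m, len(x)))
    return sum(naive_mav(p) for p in parts) / len(parts)


def naive_std(x):
    mean = sum(x) / len(x)
    return math.sqrt(sum((v - mean) ** 2 for v in x) / len(x))


def naive_wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def naive_zc(x):
    def sgn(v):
        return 1 if v >= 0 else -1

    return sum(sgn(x[i]) != sgn(x[i + 1]) for i in range(len(x) - 1))


def naive_ssc(x):
    count = sum(
        1 for i in range(len(x) - 2) if (x[i + 1] - x[i]) * (x[i + 2] - x[i + 1]) < 0
    )
    return count / len(x)


def naive_rms(x):
    return math.sqrt(sum(v**2 for v in x) / len(x))


def naive_ld(x):
    return math.log(sum(v**2 for v in x) / len(x) + 1.0)


class TestClosedForms:
    """The printed-formula spot checks evaluate exactly."""

    def test_mav(self):
        assert ft.mav([1.0, -2.0, 3.0]) == pytest.approx(2.0, abs=0)

    def test_rms(self):
        assert ft.rms([3.0, -4.0]) == pytest.approx(math.sqrt(12.5))

    def test_ld_null_signal(self):
        assert ft.log_detector([0.0, 0.0, 0.0]) == 0.0

    def test_std_population_divisor(self):
        assert ft.std([1.0, 2.0, 3.0]) == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_wl(self):
        assert ft.waveform_length([0.0, 2.0, -1.0]) == pytest.approx(5.0)

    def test_zc(self):
        assert ft.zero_crossings([1.0, -1.0, 2.0, 3.0]) == 2

    def test_ssc_with_1_over_n_prefactor(self):
        assert ft.slope_sign_changes([0.0, 1.0, 0.0, 1.0]) == pytest.approx(0.5)

    def test_mmav_reduces_to_mav_with_one_subwindow(self, rng):
        x = rng.normal(size=37)
        assert ft.mmav(x, m=1) == pytest.approx(ft.mav(x), rel=1e-15)


class TestLoopOracleEquivalence:
    def test_all_time_domain_features_match_naive_loops(self):
        rng = np.random.default_rng(2024)
        pairs = [
            (ft.mav, naive_mav),
            (ft.std, naive_std),
            (ft.waveform_length, naive_wl),
            (ft.zero_crossings, naive_zc),
            (ft.slope_sign_changes, naive_ssc),
            (ft.rms, naive_rms),
            (ft.log_detector, naive_ld),
        ]
        for _ in range(200):
            n = int(rng.integers(3, 65))
            x = rng.normal(scale=rng.uniform(0.1, 5.0), size=n)
            xs = list(map(float, x))
            for fast, slow in pairs:
                assert fast(x) == pytest.approx(slow(xs), rel=1e-12, abs=1e-12)
            m = int(rng.integers(1, 6))
            assert ft.mmav(x, m) == pytest.approx(naive_mmav(xs, m), rel=1e-12)


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    signals = arrays(
        np.float64,
        st.integers(3, 64),
        elements=st.floats(-100, 100, allow_nan=False),
    )

    @given(signals)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_amplitude_feature_bounds(self, x):
        assert ft.mav(x) >= 0 and ft.rms(x) >= 0 and ft.std(x) >= 0
        assert ft.mav(x) <= ft.rms(x) + 1e-9  # Cauchy-Schwarz
        assert 0 <= ft.zero_crossings(x) <= x.size - 1
        assert 0.0 <= ft.slope_sign_changes(x) <= 1.0
        assert ft.log_detector(x) >= 0.0


class TestScaleRelations:
    def test_homogeneity_under_gain(self, rng):
        x = rng.normal(size=256)
        g = 2.5
        for f in (ft.mav, ft.std, ft.waveform_length, ft.rms):
            assert f(g * x) == pytest.approx(g * f(x), rel=1e-12)
        assert ft.mmav(g * x) == pytest.approx(g * ft.mmav(x), rel=1e-12)
        assert ft.zero_crossings(g * x) == ft.zero_crossings(x)
        spec1 = ft.periodogram(x, FS)
        spec2 = ft.periodogram(g * x, FS)
        p1, mnf1, mdf1 = ft.spectral_features(spec1)
        p2, mnf2, mdf2 = ft.spectral_features(spec2)
        assert p2 == pytest.approx(g**2 * p1, rel=1e-9)
        assert mnf2 == pytest.approx(mnf1, rel=1e-12)
        assert mdf2 == pytest.approx(mdf1, rel=1e-12)


class TestSpectral:
    def _tone(self, freq, amp=1.0, n=4000):
        return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)

    def test_parseval_tone_power(self):
        a = 3.0
        spec = ft.periodogram(self._tone(100.0, amp=a), FS)
        assert spec.power.sum() == pytest.approx(a**2 / 2, rel=0.01)

    def test_additivity_of_orthogonal_tones(self):
        t1, t2 = self._tone(80.0), self._tone(120.0, amp=2.0)
        p1 = ft.periodogram(t1, FS).power.sum()
        p2 = ft.periodogram(t2, FS).power.sum()
        p12 = ft.periodogram(t1 + t2, FS).power.sum()
        assert p12 == pytest.approx(p1 + p2, rel=0.01)

    def test_zero_window_zero_spectrum(self):
        spec = ft.periodogram(np.zeros(1024), FS)
        assert np.all(spec.power == 0.0)

    def test_mnf_mdf_of_pure_tone(self):
        spec = ft.periodogram(self._tone(100.0), FS)
        bin_hz = FS / 4000
        _, mnf, mdf = ft.spectral_features(spec)
        assert abs(mnf - 100.0) <= bin_hz
        assert abs(mdf - 100.0) <= bin_hz

    def test_mnf_of_two_equal_tones_is_midpoint(self):
        spec = ft.periodogram(self._tone(80.0) + self._tone(120.0), FS)
        _, mnf, _ = ft.spectral_features(spec)
        assert mnf == pytest.approx(100.0, abs=1.0)

    def test_mdf_brackets_half_power(self, rng):
        x = rng.normal(size=2048)
        spec = ft.periodogram(x, FS)
        total, _, mdf = ft.spectral_features(spec)
        f, p = spec.frequencies, spec.power
        mask = (f >= 20.0) & (f <= 500.0)
        f_in, p_in = f[mask], p[mask]
        # linear interpolation lands between bins: power strictly below the
        # median frequency stays <= half, and adding the straddling bin
        # reaches at least half
        k = int(np.searchsorted(f_in, mdf))
        assert p_in[:k].sum() <= 0.5 * total + 1e-9
        assert p_in[: k + 1].sum() >= 0.5 * total - 1e-9

    def test_zero_in_band_power_raises(self):
        spec = ft.periodogram(np.zeros(1024), FS)
        with pytest.raises(ValueError):
            ft.spectral_features(spec)


def _window(x, muscle="biceps", rep=1, subject="S1"):
    return SignalWindow(
        samples=np.asarray(x, float),
        muscle=muscle,
        repetition_index=rep,
        subject_id=subject,
        tone_class=ToneClass.NORMAL,
    )


class TestFeatureTable:
    def test_tiny_cohort_geometry(self, tiny_table):
        # 8 subjects x 3 repetitions, 22 features + label
        assert tiny_table.shape == (24, 23)
        assert list(tiny_table.columns) == list(ft.TABLE_COLUMNS)
        assert set(tiny_table["label"]) == {c.value for c in ToneClass}

    def test_single_repetition_table(self, rng):
        wins = [
            _window(rng.normal(size=256), "biceps"),
            _window(rng.normal(size=256), "triceps"),
        ]
        table = ft.build_feature_table(wins, FS)
        assert table.shape == (1, 23)

    def test_missing_muscle_raises_naming_repetition(self, rng):
        wins = [_window(rng.normal(size=256), "biceps", rep=2)]
        with pytest.raises(ValueError, match="repetition 2"):
            ft.build_feature_table(wins, FS)

    def test_deterministic(self, rng):
        x = rng.normal(size=512)
        wins = [_window(x, "biceps"), _window(x * 0.5, "triceps")]
        t1 = ft.build_feature_table(wins, FS)
        t2 = ft.build_feature_table(wins, FS)
        assert t1.equals(t2)

    def test_csv_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "features.csv"
        ft.write_feature_table(tiny_table, path)
        back = ft.read_feature_table(path)
        assert list(back.columns) == list(ft.TABLE_COLUMNS)
        np.testing.assert_allclose(
            back[list(ft.TABLE_COLUMNS[:-1])].to_numpy(),
            tiny_table[list(ft.TABLE_COLUMNS[:-1])].to_numpy(),
        )
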