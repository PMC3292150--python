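import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfatigue.core import FeatureSeries, Trial, ValidationError
from emgfatigue.features import (
    SpectralMomentSpec,
    extract_all,
    fi_nsm,
    imdf,
    rolling_std,
    spectro_1d,
    spectro_std,
    total_band_power,
    unify_1d_spectro,
    wavelet_feature,
    welch_psd,
)

FS = 2000.0


def sine(freq, seconds=1.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def flat_multisine(seconds=1.0, f_lo=8, f_hi=500, seed=1, fs=FS):
    """Deterministic flat-line-spectrum signal over [f_lo, f_hi] Hz."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(seconds * fs)) / fs
    return sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
               for f in range(f_lo, f_hi + 1))


def noise_trial(seconds=8, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    return Trial(emg=rng.normal(size=(2, n)), gonio_angle=np.full(n, 90.0),
                 fs_emg=fs, fs_gonio=fs)


class TestWelchPsd:
    def test_zero_window(self):
        psd = welch_psd(np.zeros(2000), FS)
        assert np.all(psd.power == 0.0)

    def test_parseval_white_noise(self):
        x = np.random.default_rng(0).standard_normal(2000)
        psd = welch_psd(x, FS)
        integral = np.trapezoid(psd.power, psd.freqs)
        assert integral == pytest.approx(x.var(), rel=0.10)

    def test_peak_at_sine_frequency(self):
        psd = welch_psd(sine(50), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(50.0, abs=FS / 256)

    def test_too_short(self):
        with pytest.raises(ValidationError, match="seg_len"):
            welch_psd(np.zeros(100), FS)


class TestImdf:
    def test_pure_sine_exact(self):
        assert imdf(sine(50), FS) == 50.0

    def test_equal_lines_takes_lower(self):
        assert imdf(sine(40) + sine(160), FS) == 40.0

    def test_band_limited_noise(self):
        # independent construction: flat line spectrum over [100, 300] Hz
        x = flat_multisine(f_lo=100, f_hi=300, seed=5)
        assert imdf(x, FS) == pytest.approx(200.0, abs=10.0)

    def test_zero_window_error(self):
        with pytest.raises(ValidationError, match="all-zero"):
            imdf(np.zeros(2000), FS)

    def test_time_scaling_equivariance(self):
        x = flat_multisine(f_lo=50, f_hi=150, seed=2)
        assert imdf(x, 2 * FS) == pytest.approx(2 * imdf(x, FS))


class TestTotalBandPower:
    def test_zero_window(self):
        assert total_band_power(np.zeros(2000), FS) == 0.0

    def test_sine_power(self):
        assert total_band_power(sine(50, amp=2.0), FS) == pytest.approx(2.0, rel=0.10)

    def test_quadratic_homogeneity(self):
        x = np.random.default_rng(1).standard_normal(2000)
        assert total_band_power(3 * x, FS) == pytest.approx(
            9 * total_band_power(x, FS), rel=1e-9)


class TestUnify:
    def test_identical_series_cancel(self):
        t = [0.0, 1.0, 2.0]
        p = FeatureSeries("bandpower", t, [1.0, 2.0, 3.0])
        m = FeatureSeries("imdf", t, [1.0, 2.0, 3.0])
        assert np.allclose(unify_1d_spectro(p, m).values, 0.0)

    def test_opposite_ramps(self):
        # sample-SD z-scores: [-1,0,1] - [1,0,-1]
        t = [0.0, 1.0, 2.0]
        p = FeatureSeries("bandpower", t, [1.0, 2.0, 3.0])
        m = FeatureSeries("imdf", t, [3.0, 2.0, 1.0])
        assert np.allclose(unify_1d_spectro(p, m).values, [-2.0, 0.0, 2.0])

    def test_zero_variance_error(self):
        t = [0.0, 1.0, 2.0]
        p = FeatureSeries("bandpower", t, [1.0, 1.0, 1.0])
        m = FeatureSeries("imdf", t, [3.0, 2.0, 1.0])
        with pytest.raises(ValidationError, match="zero-variance"):
            unify_1d_spectro(p, m)

    def test_misaligned_times_error(self):
        p = FeatureSeries("bandpower", [0.0, 1.0], [1.0, 2.0])
        m = FeatureSeries("imdf", [0.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="timestamps"):
            unify_1d_spectro(p, m)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_unified_rises_with_fatigue(self, seed, battery20):
        metrics = battery20[seed]
        assert metrics["unified_f"] > metrics["unified_nf"]


class TestRollingStd:
    def test_constant_series(self):
        s = FeatureSeries("x", [0.0, 1.0, 2.0, 3.0], [5.0] * 4)
        assert np.allclose(rolling_std(s).values, 0.0)

    def test_known_values(self):
        s = FeatureSeries("x", [0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        out = rolling_std(s, span=3)
        assert np.allclose(out.values, [1.0, 1.0])
        assert np.allclose(out.times, [2.0, 3.0])  # causal: span-end stamps
        assert out.name == "x_std3"

    def test_span_one_zeros(self):
        s = FeatureSeries("x", [0.0, 1.0], [3.0, 7.0])
        assert np.allclose(rolling_std(s, span=1).values, 0.0)

    def test_too_short(self):
        s = FeatureSeries("x", [0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="span"):
            rolling_std(s, span=3)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=-100, max_value=100),
           st.floats(min_value=0.01, max_value=50))
    def test_shift_invariance_and_scaling(self, shift, scale):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        t = np.arange(12.0)
        base = rolling_std(FeatureSeries("x", t, values), 3).values
        shifted = rolling_std(FeatureSeries("x", t, values + shift), 3).values
        scaled = rolling_std(FeatureSeries("x", t, values * scale), 3).values
        assert np.allclose(shifted, base, atol=1e-8)
        assert np.allclose(scaled, scale * base, rtol=1e-8, atol=1e-12)


class TestSpectroStd:
    def test_three_second_trial_single_value(self):
        out = spectro_std(noise_trial(seconds=3))
        assert len(out) == 1
        assert out.name == "spectro_std"

    def test_spikes_at_transition(self, battery20):
        metrics = battery20[1]
        assert metrics["ss_tf"] > metrics["ss_nf"]
        assert metrics["ss_tf"] > metrics["ss_late_f"]


class TestFiNsm:
    def test_single_line_closed_form(self):
        # delta spectrum at f0: index = f0**(-1 - X)
        assert fi_nsm(sine(100), FS) == pytest.approx(100.0 ** -3, rel=1e-6)

    def test_flat_spectrum_closed_form(self):
        closed = np.log(500 / 8) / ((500 ** 3 - 8 ** 3) / 3)
        assert fi_nsm(flat_multisine(), FS) == pytest.approx(closed, rel=0.05)

    def test_amplitude_invariance(self):
        x = flat_multisine(seed=3)
        assert fi_nsm(5.0 * x, FS) == pytest.approx(fi_nsm(x, FS), rel=1e-9)

    def test_rises_as_spectrum_shifts_down(self):
        low = flat_multisine(f_lo=60, f_hi=160, seed=4)
        high = flat_multisine(f_lo=120, f_hi=220, seed=4)
        assert fi_nsm(low, FS) > fi_nsm(high, FS)

    def test_grid_must_cover_band(self):
        with pytest.raises(ValidationError, match="cover"):
            fi_nsm(sine(50, fs=800), fs=800)

    def test_moment_spec_validation(self):
        with pytest.raises(ValidationError):
            SpectralMomentSpec(X=6)
        with pytest.raises(ValidationError):
            SpectralMomentSpec(f1=500, f2=8)


class TestWaveletFeature:
    def test_zero_signal(self):
        n = int(4 * FS)
        trial = Trial(emg=np.zeros((2, n)), gonio_angle=np.full(n, 90.0))
        assert np.allclose(wavelet_feature(trial).values, 0.0)

    def test_low_frequency_dominates_interior(self):
        t = np.arange(int(40 * FS)) / FS
        slow = Trial(emg=np.vstack([np.sin(2 * np.pi * 1 * t)] * 2),
                     gonio_angle=np.full(t.size, 90.0))
        fast = Trial(emg=np.vstack([np.sin(2 * np.pi * 400 * t)] * 2),
                     gonio_angle=np.full(t.size, 90.0))
        # compare away from the (deep-level) boundary-effect region
        interior = slice(14, 26)
        v_slow = wavelet_feature(slow).values[interior]
        v_fast = wavelet_feature(fast).values[interior]
        assert np.all(v_slow > v_fast)

    def test_non_negative(self):
        assert np.all(wavelet_feature(noise_trial(seed=2)).values >= 0.0)

    def test_unsupported_wavelet(self):
        with pytest.raises(ValidationError, match="db2"):
            wavelet_feature(noise_trial(), wavelet="morlet")


@pytest.fixture(scope="module")
def features():
    return extract_all(noise_trial(seconds=10, seed=3))


class TestExtractAll:
    def test_expected_keys(self, features):
        assert set(features) == {
            "spectro_std", "imdf_std3", "bandpower_std3", "fi2_std3",
            "wavelet_db3_std3",
        }

    def test_alignment_contract(self, features):
        lengths = {name: len(s) for name, s in features.items()}
        assert set(lengths.values()) == {10 - 2}
        ref = features["spectro_std"].times
        for series in features.values():
            assert np.array_equal(series.times, ref)

    def test_higher_moments_optional(self):
        feats = extract_all(noise_trial(seconds=5, seed=4), fi_moments=(2, 3))
        assert "fi3_std3" in feats

    def test_deterministic(self):
        trial = noise_trial(seconds=5, seed=5)
        f1 = extract_all(trial)
        f2 = extract_all(trial)
        for name in f1:
            assert np.array_equal(f1[name].values, f2[name].values)


class TestFatigueDirectionInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_imdf_declines_with_fatigue(self, seed, battery20):
        metrics = battery20[seed]
        assert metrics["imdf_f"] < metrics["imdf_nf"]
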