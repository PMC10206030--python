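"""Padding, zero-phase filtering and EMD detrending contracts."""

import numpy as np
import pytest

from nirscomp import (
    CHANNELS,
    PreprocessConfig,
    SimulationConfig,
    generate_trial,
    lowpass,
    pad_missing,
    preprocess_recording,
    remove_baseline,
)
from nirscomp.emd import emd
from nirscomp.exceptions import (
    ConfigurationError,
    FilterLengthError,
    UnpaddablePrefixError,
)

FS = 16.0


class TestPadMissing:
    def test_stated_rule_mean_of_four(self):
        out = pad_missing(np.array([1.0, 2.0, 3.0, 4.0, np.nan]), lookback=4)
        np.testing.assert_array_equal(out, [1.0, 2.0, 3.0, 4.0, 2.5])

    def test_no_missing_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(pad_missing(x), x)

    def test_sequential_fill_uses_padded_values(self):
        out = pad_missing(np.array([1.0, 1.0, 1.0, 1.0, np.nan, np.nan]), lookback=4)
        np.testing.assert_array_equal(out, np.ones(6))
        # hand-unrolled recursion on a non-constant prefix
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan, np.nan])
        out = pad_missing(x, lookback=4)
        assert out[4] == 2.5
        assert out[5] == pytest.approx((2.0 + 3.0 + 4.0 + 2.5) / 4)

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        x[20] = np.nan
        x[60] = np.nan
        once = pad_missing(x)
        np.testing.assert_array_equal(pad_missing(once), once)

    def test_unpaddable_prefix_raises(self):
        with pytest.raises(UnpaddablePrefixError):
            pad_missing(np.array([1.0, np.nan, 3.0, 4.0, 5.0]), lookback=4)


class TestLowpass:
    def test_dc_gain_unity(self):
        c = np.full(200, 3.7)
        np.testing.assert_allclose(lowpass(c, FS), c, atol=1e-9)

    def test_stopband_2hz_attenuated(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        assert np.std(lowpass(x, FS)) < 0.01 * np.std(x)

    def test_passband_005hz_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        assert np.std(lowpass(x, FS)) == pytest.approx(np.std(x), rel=0.05)

    def test_linear_in_pad_mode(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        lhs = lowpass(2.0 * x - 3.0 * y, FS, edge="pad")
        rhs = 2.0 * lowpass(x, FS, edge="pad") - 3.0 * lowpass(y, FS, edge="pad")
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_ar_and_pad_agree_in_the_interior(self, rng):
        x = rng.normal(size=800).cumsum() * 0.01 + rng.normal(size=800)
        a = lowpass(x, FS, edge="ar")
        b = lowpass(x, FS, edge="pad")
        np.testing.assert_allclose(a[200:-200], b[200:-200], atol=1e-4)

    def test_errors(self):
        with pytest.raises(FilterLengthError):
            lowpass(np.zeros(10), FS)
        with pytest.raises(ConfigurationError):
            lowpass(np.zeros(100), FS, cutoff=8.0)
        with pytest.raises(ConfigurationError):
            lowpass(np.array([1.0, np.nan] + [0.0] * 98), FS)


class TestRemoveBaseline:
    def test_linear_ramp_removed(self):
        t = np.arange(160) / FS
        a = 3.0
        with pytest.warns(UserWarning):
            out = remove_baseline(a * t, FS)
        slope = np.polynomial.polynomial.polyfit(t, out, 1)[1]
        assert abs(slope) < 0.01 * a

    def test_zero_series_stays_zero(self):
        with pytest.warns(UserWarning):
            out = remove_baseline(np.zeros(160), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_plateau_with_drift_recovers_clean_shape(self):
        """Detrended signal correlates >= 0.9 with the drift-free truth."""
        cfg = SimulationConfig()
        cors = []
        for seed in range(10):
            rec, truth = generate_trial(cfg, "SE", seed=seed)
            for ch in ("LDT", "LES"):
                clean = truth.cms[ch] + truth.dms[ch]
                x = pad_missing(rec.hbo2[ch])
                x = lowpass(x, FS)
                x = remove_baseline(x, FS)
                cors.append(np.corrcoef(x, clean)[0, 1])
        assert np.median(cors) >= 0.9


class TestEMD:
    def test_monotone_input_yields_no_imfs(self):
        imfs, residual = emd(np.linspace(0.0, 5.0, 100))
        assert imfs == []
        np.testing.assert_allclose(residual, np.linspace(0.0, 5.0, 100))

    def test_oscillation_plus_trend_separates(self):
        t = np.arange(400) / FS
        trend = 0.5 * t
        osc = np.sin(2 * np.pi * 1.0 * t)
        imfs, residual = emd(osc + trend)
        assert len(imfs) >= 1
        # residual tracks the trend away from the edges
        core = slice(50, -50)
        assert np.corrcoef(residual[core], trend[core])[0, 1] > 0.99


class TestPreprocessRecording:
    def test_clean_input_shape_preserved(self, clean_trial):
        rec, truth = clean_trial
        with pytest.warns(UserWarning):
            out = preprocess_recording(rec)
        assert out.n_samples == rec.n_samples
        assert out.channels == rec.channels
        clean = truth.cms["LDT"] + truth.dms["LDT"]
        assert np.corrcoef(out.hbo2["LDT"], clean)[0, 1] > 0.99

    def test_cardiac_band_power_removed(self):
        cfg = SimulationConfig(noise_sd=0.0, drift_amplitude=0.0, missing_rate=0.0,
                               cardiac_amplitude=0.2)
        rec, truth = generate_trial(cfg, "NC", seed=4)
        out = preprocess_recording(rec)
        ch = "ROEA"  # zero activation: raw series is pure cardiac sinusoid
        p_before = float(np.sum(rec.hbo2[ch] ** 2))
        p_after = float(np.sum(out.hbo2[ch] ** 2))
        assert p_after < 0.01 * p_before

    def test_missing_values_all_padded(self):
        cfg = SimulationConfig(missing_rate=0.05)
        rec, _ = generate_trial(cfg, "LF", seed=6)
        assert any(rec.missing_mask[ch].any() for ch in CHANNELS)
        out = preprocess_recording(rec)
        for ch in CHANNELS:
            assert np.all(np.isfinite(out.hb[ch]))
            assert np.all(np.isfinite(out.hbo2[ch]))


def test_config_validation():
    with pytest.raises(ConfigurationError):
        PreprocessConfig(cutoff=-1.0)
    with pytest.raises(ConfigurationError):
        PreprocessConfig(emd_baseline_rule="imfs_only")
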