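"""CBSI / DBSI transforms: worked examples, oracles, algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirscomp import cbsi, dbsi, dbsi_inverse, improve_recording
from nirscomp.exceptions import DegenerateChannelError, ShapeError


def cbsi_oracle(hb, hbo2):
    """Direct transcription of the correlation-based decomposition."""
    alpha = np.sqrt(np.mean((hbo2 - hbo2.mean()) ** 2)) / np.sqrt(
        np.mean((hb - hb.mean()) ** 2)
    )
    return alpha, (hbo2 + alpha * hb) / 2.0, (hbo2 - alpha * hb) / 2.0


def dbsi_oracle(hb, hbo2):
    return (hbo2 + hb) / 2.0, (hbo2 - hb) / 2.0


class TestCBSI:
    def test_perfect_anticorrelation_gives_zero_tns(self):
        hbo2 = np.array([1.0, -1.0, 1.0, -1.0])
        hb = np.array([-1.0, 1.0, -1.0, 1.0])
        sig = cbsi(hb, hbo2)
        assert sig.alpha == pytest.approx(1.0)
        np.testing.assert_allclose(sig.series_a, 0.0, atol=1e-15)  # TNS
        np.testing.assert_allclose(sig.series_b, hbo2, atol=1e-15)  # TFS

    def test_alpha_is_std_ratio(self):
        sig = cbsi(np.array([1.0, -1.0]), np.array([2.0, -2.0]))
        assert sig.alpha == pytest.approx(2.0)

    def test_matches_oracle_elementwise(self, rng):
        hb = rng.normal(size=100)
        hbo2 = rng.normal(size=100)
        sig = cbsi(hb, hbo2)
        alpha, tns, tfs = cbsi_oracle(hb, hbo2)
        assert sig.alpha == pytest.approx(alpha, rel=1e-12)
        np.testing.assert_allclose(sig.series_a, tns, atol=1e-10)
        np.testing.assert_allclose(sig.series_b, tfs, atol=1e-10)

    def test_constant_hb_rejected(self):
        with pytest.raises(DegenerateChannelError):
            cbsi(np.ones(10), np.arange(10.0))

    def test_null_space_gives_constant_tns(self, rng):
        # hb = -hbo2/alpha + const  ->  TNS has zero variance
        hbo2 = rng.normal(size=50)
        hb = -hbo2 / 1.0 + 3.0
        sig = cbsi(hb, hbo2)
        assert np.std(sig.series_a) < 1e-12

    def test_alpha_invariant_to_common_scaling(self, rng):
        hb = rng.normal(size=64)
        hbo2 = rng.normal(size=64)
        assert cbsi(5.0 * hb, 5.0 * hbo2).alpha == pytest.approx(
            cbsi(hb, hbo2).alpha, rel=1e-12
        )


class TestDBSI:
    def test_single_sample_arithmetic(self):
        sig = dbsi(np.array([0.0]), np.array([2.0]))
        assert sig.series_a[0] == 1.0 and sig.series_b[0] == 1.0

    def test_common_series_gives_zero_dms(self, rng):
        c = rng.normal(size=30)
        sig = dbsi(c, c)
        np.testing.assert_allclose(sig.series_b, 0.0, atol=1e-15)
        np.testing.assert_allclose(sig.series_a, c)

    def test_reconstruction_identity(self, rng):
        hb = rng.normal(size=80)
        hbo2 = rng.normal(size=80)
        sig = dbsi(hb, hbo2)
        np.testing.assert_allclose(sig.series_a + sig.series_b, hbo2, atol=1e-12)
        np.testing.assert_allclose(sig.series_a - sig.series_b, hb, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            dbsi(np.zeros(3), np.zeros(4))

    def test_common_mode_rejection(self, rng):
        hb = rng.normal(size=60)
        hbo2 = rng.normal(size=60)
        s = rng.normal(size=60)
        base = dbsi(hb, hbo2)
        shifted = dbsi(hb + s, hbo2 + s)
        np.testing.assert_allclose(shifted.series_b, base.series_b, atol=1e-12)
        anti = dbsi(hb - s, hbo2 + s)
        np.testing.assert_allclose(anti.series_a, base.series_a, atol=1e-12)

    def test_homogeneous_scaling(self, rng):
        hb = rng.normal(size=40)
        hbo2 = rng.normal(size=40)
        base = dbsi(hb, hbo2)
        scaled = dbsi(2.5 * hb, 2.5 * hbo2)
        np.testing.assert_allclose(scaled.series_a, 2.5 * base.series_a, atol=1e-12)
        np.testing.assert_allclose(scaled.series_b, 2.5 * base.series_b, atol=1e-12)


class TestInverse:
    def test_trivial_cases(self):
        hb, hbo2 = dbsi_inverse(np.array([1.0]), np.array([1.0]))
        assert hb[0] == 0.0 and hbo2[0] == 2.0
        d = np.array([0.3, -0.7])
        hb, hbo2 = dbsi_inverse(d, np.zeros(2))
        np.testing.assert_array_equal(hb, d)
        np.testing.assert_array_equal(hbo2, d)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(np.float64, 17, elements=st.floats(-1e6, 1e6)),
        arrays(np.float64, 17, elements=st.floats(-1e6, 1e6)),
    )
    def test_round_trip_exact(self, cms, dms):
        sig = dbsi(*dbsi_inverse(cms, dms))
        np.testing.assert_allclose(sig.series_a, cms, rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(sig.series_b, dms, rtol=1e-12, atol=1e-9)


def test_improve_recording_methods(noisy_trial):
    rec, _ = noisy_trial
    rec = rec.copy_with()
    for ch in rec.channels:  # transforms need finite input
        rec.hb[ch] = np.nan_to_num(rec.hb[ch])
        rec.hbo2[ch] = np.nan_to_num(rec.hbo2[ch])
    raw = improve_recording(rec, "raw")
    np.testing.assert_array_equal(raw.series("LDT", "Hb"), rec.hb["LDT"])
    imp = improve_recording(rec, "dbsi")
    assert imp.series_names == ("CMS", "DMS")
    c = improve_recording(rec, "cbsi")
    assert all(c.signals[ch].alpha > 0 for ch in rec.channels)
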