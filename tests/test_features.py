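"""Windowed features: geometry, hand-derived values, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wristmood import features as F

from oracles import (
    naive_acc_features,
    naive_eda_features,
    naive_hr_features,
    naive_percentile,
    naive_temp_features,
    naive_welch,
)


class TestWindows:
    def test_168s_span_gives_three_windows(self):
        w = F.windows(0.0, 168.0)
        assert w == [(0.0, 60.0), (54.0, 114.0), (108.0, 168.0)]

    def test_zero_overlap_tiles_disjointly(self):
        w = F.windows(0.0, 300.0, F.WindowSpec(60.0, 0.0))
        assert w == [(0, 60), (60, 120), (120, 180), (180, 240), (240, 300)]

    def test_consecutive_windows_share_six_seconds(self):
        w = F.windows(0.0, 600.0)
        for (s1, e1), (s2, _) in zip(w, w[1:]):
            assert e1 - s2 == pytest.approx(6.0)

    def test_short_span_yields_no_windows(self):
        assert F.windows(0.0, 59.0) == []


class TestTimeStats:
    def test_alternating_segment_hand_values(self):
        vals = F.time_stats(np.array([1.0, -1.0, 1.0, -1.0]))
        assert vals["MAX"] == 1.0
        assert vals["MIN"] == -1.0
        assert vals["AMP"] == 1.0
        assert vals["MAVFD"] == 2.0
        assert vals["RMS"] == 1.0

    def test_constant_segment(self):
        c = -3.0
        vals = F.time_stats(np.full(10, c))
        assert vals["VAR"] == 0.0
        assert vals["MAVFD"] == 0.0
        assert vals["MAVFDN"] == 0.0  # guarded normalization
        assert vals["RMS"] == abs(c)
        assert vals["Norm"] == pytest.approx(abs(c) * np.sqrt(10))

    def test_p90_matches_brute_force_percentile(self):
        x = np.arange(1.0, 11.0)
        vals = F.time_stats(x)
        assert vals["P90"] == pytest.approx(naive_percentile(np.abs(x), 90))

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=64))
    def test_shift_invariance(self, values):
        x = np.array(values)
        a = F.time_stats(x)
        b = F.time_stats(x + 17.0)
        for key in ("VAR", "STD", "MAVFD", "MAVSD"):
            assert a[key] == pytest.approx(b[key], rel=1e-6, abs=1e-6)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=16, max_size=128))
    def test_features_finite_for_arbitrary_segments(self, values):
        x = np.array(values)
        vals = {**F.time_stats(x), **F.spectral_stats(x, 4.0)}
        assert all(np.isfinite(v) for v in vals.values())


class TestSpectralStats:
    def test_pure_sinusoid_edges_at_tone_frequency(self):
        fs, f0, n = 32.0, 4.0, 1920
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        vals = F.spectral_stats(x, fs)
        bin_hz = fs / min(n, 256)
        for key in ("FP25", "FP50", "FP75"):
            assert abs(vals[key] - f0) <= bin_hz

    def test_white_noise_median_edge_near_half_nyquist(self, rng):
        fs, n = 32.0, 32 * 240
        x = rng.normal(0, 1, n)
        vals = F.spectral_stats(x, fs)
        assert abs(vals["FP50"] - fs / 4) < 1.5

    def test_zero_segment_all_zero(self):
        vals = F.spectral_stats(np.zeros(64), 4.0)
        assert all(v == 0.0 for v in vals.values())

    def test_welch_matches_naive_reimplementation(self, rng):
        x = rng.normal(0, 1, 700)
        f, p = F.welch_psd(x, 4.0)
        nf, np_ = naive_welch(x, 4.0)
        np.testing.assert_allclose(f, nf, atol=1e-12)
        np.testing.assert_allclose(p, np_, rtol=1e-10)


class TestModalityCounts:
    def test_acc_block_has_72_features(self, rng):
        segs = rng.normal(0, 1, (4, 1920))
        vals = F.acc_features(*segs, fs=32.0)
        assert len(vals) == 72

    def test_temp_block_has_13_features(self, rng):
        vals = F.temp_features(33 + rng.normal(0, 0.1, 240))
        assert len(vals) == 13

    def test_hr_block_has_27_features(self, rng):
        vals = F.hr_features(rng.normal(0, 1, 60))
        assert len(vals) == 27

    def test_eda_block_has_82_features(self, rng):
        e = 2 + np.abs(rng.normal(0, 0.3, 240))
        vals = F.eda_features(eda=e, scl=e * 0.8, scr=e * 0.2)
        assert len(vals) == 82

    def test_column_list_has_194_unique_names(self):
        cols = F.feature_columns()
        assert len(cols) == 194
        assert len(set(cols)) == 194


class TestHandDerivedValues:
    def test_temp_linear_ramp_recovers_line(self):
        t = np.arange(240) / 4.0
        vals = F.temp_features(0.02 * t + 31.0)
        assert vals["temp_SRL"] == pytest.approx(0.02)
        assert vals["temp_IRL"] == pytest.approx(31.0)

    def test_temp_constant_has_zero_slope(self):
        vals = F.temp_features(np.full(240, 33.5))
        assert vals["temp_SRL"] == pytest.approx(0.0, abs=1e-12)
        assert vals["temp_IRL"] == pytest.approx(33.5)

    def test_constant_hr_has_no_band_power(self):
        vals = F.hr_features(np.full(60, 1.5))
        assert vals["hr_aLF"] == pytest.approx(0.0, abs=1e-12)
        assert vals["hr_MFD"] == 0.0
        assert vals["hr_LFHF"] == 0.0

    def test_hr_sinusoid_peaks_in_lf_band(self):
        fs, f0 = 1.0, 0.1
        x = np.sin(2 * np.pi * f0 * np.arange(120) / fs)
        vals = F.hr_features(x, fs)
        bin_hz = fs / 120
        assert abs(vals["hr_peakLF"] - f0) <= bin_hz
        assert vals["hr_aLF"] / vals["hr_aTotal"] > 0.95

    def test_constant_eda_component_algebra(self):
        c, n = 2.5, 240
        seg = np.full(n, c)
        vals = F.eda_features(eda=seg, scl=seg, scr=seg)
        assert vals["eda_DRSC_eda"] == 0.0
        assert vals["eda_ALSC_eda"] == pytest.approx(n - 1)
        assert vals["eda_INSC_eda"] == pytest.approx(n * c)
        assert vals["eda_ILSC_eda"] == pytest.approx(n * c / (n - 1))

    def test_symmetric_segment_has_zero_skewness(self):
        seg = np.concatenate([np.arange(120.0), -np.arange(120.0)])
        vals = F.eda_features(eda=seg, scl=seg, scr=seg)
        assert vals["eda_SKSC_eda"] == pytest.approx(0.0, abs=1e-9)


def assert_windows_match_oracle(pre_days, n_windows=50, seed=99, rel=1e-8):
    """Compare every emitted feature against the naive oracle on random windows."""
    rng = np.random.default_rng(seed)
    checked = 0
    for _ in range(n_windows):
        pre = pre_days[rng.integers(len(pre_days))]
        start, end = pre.span
        all_w = F.windows(start, end)
        ws, we = all_w[rng.integers(len(all_w))]

        def seg(samples, s0, rate, n):
            i0 = int(round((ws - s0) * rate))
            return samples[i0 : i0 + n]

        fx = seg(pre.acc[0].samples, pre.acc[0].start_epoch, 32.0, 1920)
        fy = seg(pre.acc[1].samples, pre.acc[1].start_epoch, 32.0, 1920)
        fz = seg(pre.acc[2].samples, pre.acc[2].start_epoch, 32.0, 1920)
        fn = seg(pre.acc[3].samples, pre.acc[3].start_epoch, 32.0, 1920)
        tseg = seg(pre.temp.samples, pre.temp.start_epoch, 4.0, 240)
        t0 = int(round((ws - pre.temp.start_epoch) * 4.0))
        tmask = pre.temp_valid[t0 : t0 + 240]
        hseg = seg(pre.hr.samples, pre.hr.start_epoch, 1.0, 60)
        e0 = int(round((ws - pre.eda.start_epoch) * 4.0))
        eda, scl, scr = (
            pre.eda.eda[e0 : e0 + 240],
            pre.eda.scl[e0 : e0 + 240],
            pre.eda.scr[e0 : e0 + 240],
        )

        got = {}
        got.update(F.acc_features(fx, fy, fz, fn, fs=32.0))
        times = np.arange(tseg.size)[tmask] / 4.0
        got.update(F.temp_features(tseg[tmask], fs=4.0, times_s=times))
        got.update(F.hr_features(hseg, fs=1.0))
        got.update(F.eda_features(eda=eda, scl=scl, scr=scr, fs=4.0))

        want = {}
        want.update(naive_acc_features(fx, fy, fz, fn))
        want.update(naive_temp_features(tseg[tmask], times_s=times))
        want.update(naive_hr_features(hseg))
        want.update(naive_eda_features(eda, scl, scr))

        assert set(got) == set(want)
        for name in got:
            assert got[name] == pytest.approx(want[name], rel=rel, abs=1e-10), name
        checked += 1
    assert checked == n_windows


class TestOracleEquivalence:
    def test_random_windows_match_brute_force(self, separable3_preprocessed):
        """Spot-check a handful of windows; the full 50-window sweep runs
        with the acceptance checks."""
        assert_windows_match_oracle(separable3_preprocessed, n_windows=5, seed=1)
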