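"""ME/RE metric extraction: HRV formulas, R-peak detection, EDA
decomposition, activity metrics, and epoch/rolling aggregation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadsync as ds
from dyadsync.metrics import (BeatSeries, detect_r_peaks,
                              eda_decompose_and_peaks, hrv_time_domain,
                              ibi_artifact_mask, mad_ima, rolling_re)
from dyadsync.session import Channel


def brute_sdnn_rmssd(ibi):
    """Independent literal evaluation of the HRV formulas."""
    n = len(ibi)
    mean = sum(ibi) / n
    sdnn = (sum((v - mean) ** 2 for v in ibi) / (n - 1)) ** 0.5
    diffs = [ibi[i + 1] - ibi[i] for i in range(n - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    return sdnn, rmssd


class TestHrvTimeDomain:
    def test_hand_computed_window(self):
        sdnn, rmssd, q = hrv_time_domain([800, 850, 790, 820])
        assert sdnn == pytest.approx((2100 / 3) ** 0.5, abs=1e-9)
        assert rmssd == pytest.approx(((50**2 + 60**2 + 30**2) / 3) ** 0.5,
                                      abs=1e-9)
        assert q == pytest.approx(sdnn / rmssd, abs=1e-9)

    def test_two_ibis_closed_form(self):
        sdnn, rmssd, q = hrv_time_domain([800, 900])
        assert sdnn == pytest.approx(100 / 2 ** 0.5, abs=1e-9)
        assert rmssd == pytest.approx(100.0, abs=1e-9)

    def test_constant_window_zero_variability(self):
        sdnn, rmssd, q = hrv_time_domain([800.0] * 5)
        assert sdnn == 0.0 and rmssd == 0.0
        assert np.isnan(q)  # division guard

    def test_insufficient_beats_missing(self):
        sdnn, rmssd, q = hrv_time_domain([800.0])
        assert np.isnan(sdnn) and np.isnan(rmssd) and np.isnan(q)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ibi = rng.uniform(400, 1200, size=rng.integers(2, 40))
        sdnn, rmssd, _ = hrv_time_domain(ibi)
        b_sdnn, b_rmssd = brute_sdnn_rmssd(list(ibi))
        assert sdnn == pytest.approx(b_sdnn, abs=1e-9)
        assert rmssd == pytest.approx(b_rmssd, abs=1e-9)


class TestDetectRPeaks:
    def _channel(self, hr, seed, duration=300, fs=250.0, noise=0.05):
        ibi = ds.simulate_ibi_series(hr, 50, 40, duration, seed=seed)
        t, ecg, r = ds.render_ecg(ibi, fs, seed=seed + 1, noise_sd=noise)
        return Channel("X", "ECG", "chest", fs, t, ecg), r

    def test_human_five_minutes_count_and_timing(self):
        ch, r_true = self._channel(75, seed=21)
        beats = detect_r_peaks(ch, "human")
        assert abs(beats.n_beats - len(r_true)) <= 1
        idx = np.searchsorted(beats.t, r_true)
        near = np.minimum(
            np.abs(beats.t[np.clip(idx, 0, beats.n_beats - 1)] - r_true),
            np.abs(beats.t[np.clip(idx - 1, 0, beats.n_beats - 1)] - r_true))
        assert (near < 0.020).mean() >= 0.99

    def test_canine_rate_recovered(self):
        ch, r_true = self._channel(95, seed=22)
        beats = detect_r_peaks(ch, "canine")
        hr = 60000.0 / beats.ibi[beats.valid].mean()
        true_hr = 60.0 / np.diff(r_true).mean()
        assert abs(hr - true_hr) < 1.0

    def test_flatline_gives_no_beats(self):
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        ch = Channel("X", "ECG", "chest", fs, t, np.zeros(len(t)))
        beats = detect_r_peaks(ch, "human")
        assert beats.n_beats <= 2  # nothing resembling a rhythm

    def test_artifact_mask_rejects_out_of_bounds(self):
        ibi = np.array([800.0, 810, 200, 805, 795, 2500, 790])
        mask = ibi_artifact_mask(ibi, "human")
        assert not mask[2] and not mask[5]
        assert mask[[0, 1, 3, 4, 6]].all()


class TestMadIma:
    def test_zero_dynamic_signal(self):
        mad, ima = mad_ima(np.zeros((100, 3)), fs=32.0)
        assert np.allclose(mad, 0.0) and ima == 0.0

    def test_square_wave_closed_form(self):
        # oracle: direct summation of |a - mean| and L1 modulus
        v = np.zeros((100, 3))
        v[::2, 0] = 1.0
        v[1::2, 0] = -1.0
        mad, ima = mad_ima(v, fs=32.0)
        assert mad[0] == pytest.approx(1.0, abs=1e-12)
        assert mad[1] == mad[2] == 0.0
        assert ima == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_homogeneity_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(rng.integers(4, 60), 3))
        mad, ima = mad_ima(v, fs=32.0)
        mad2, ima2 = mad_ima(2.0 * v, fs=32.0)
        assert np.allclose(mad2, 2 * mad, atol=1e-9)
        assert ima2 == pytest.approx(2 * ima, abs=1e-9)
        b_mad = [np.mean([abs(a - np.mean(v[:, j])) for a in v[:, j]])
                 for j in range(3)]
        b_ima = np.mean([sum(abs(x) for x in row) for row in v])
        assert np.allclose(mad, b_mad, atol=1e-9)
        assert ima == pytest.approx(b_ima, abs=1e-9)


class TestEdaDecompose:
    def test_injected_scrs_counted(self):
        t, x = ds.simulate_eda(120, 4, [30, 34, 38], [0.5] * 3,
                               tonic_level=1.5, noise_sd=0.002, seed=6)
        ch = Channel("H1", "EDA", "left_wrist", 4.0, t, x)
        tonic, phasic, peaks = eda_decompose_and_peaks(ch)
        in_epoch = ((peaks >= 30) & (peaks < 45)).sum()
        assert in_epoch == 3

    def test_flat_signal_no_peaks(self):
        t = np.arange(400) / 4.0
        ch = Channel("H1", "EDA", "left_wrist", 4.0, t, np.full(400, 2.0))
        tonic, phasic, peaks = eda_decompose_and_peaks(ch)
        assert len(peaks) == 0
        assert np.allclose(phasic[np.isfinite(phasic)], 0.0, atol=1e-9)

    def test_pure_ramp_no_peaks(self):
        t = np.arange(2400) / 4.0
        ch = Channel("H1", "EDA", "left_wrist", 4.0, t, 1.0 + 0.001 * t)
        _, phasic, peaks = eda_decompose_and_peaks(ch)
        assert len(peaks) == 0


class TestEpochMe:
    def test_table_invariants(self, analyzed):
        me = analyzed.me
        piv = me.pivot_table(index=["subject", "placement", "epoch"],
                             columns="metric", values="value")
        # HR = 60000/IBI wherever both exist
        both = piv.dropna(subset=["HR", "IBI"])
        assert np.allclose(both["HR"], 60000.0 / both["IBI"], atol=1e-9)
        # EDA_max >= EDA_mean, variability metrics >= 0
        eda = piv.dropna(subset=["EDA_mean", "EDA_max"])
        assert (eda["EDA_max"] >= eda["EDA_mean"] - 1e-12).all()
        for m in ("SDNN", "RMSSD", "IMA"):
            assert (piv[m].dropna() >= 0).all()

    def test_canine_missing_in_neutral(self, analyzed):
        me = analyzed.me
        c_neu = me[(me.subject == "C1") & (me.subsession == "NEU1")]
        assert c_neu["value"].isna().all()

    def test_st_linear_ramp_mean_is_midpoint(self):
        from dyadsync.session import (SessionBundle, Subject,
                                      SubsessionTimeline, build_epoch_grid)
        from dyadsync.metrics import epoch_me
        fs = 4.0
        t = np.arange(40) / fs  # one 10 s epoch
        st_vals = 30.0 + 0.1 * t  # 30 -> 31 over the epoch
        tl = SubsessionTimeline.from_plan([("BASE", 10)])
        b = SessionBundle("s", [Subject("H1", "human")], tl,
                          [Channel("H1", "ST", "left_wrist", fs, t, st_vals)])
        me = epoch_me(b, build_epoch_grid(tl))
        v = me[me.metric == "ST"]["value"].iloc[0]
        assert v == pytest.approx(30.0 + 0.1 * (39 / 4.0) / 2, abs=1e-9)

    def test_fully_masked_epoch_missing(self):
        from dyadsync.session import (SessionBundle, Subject,
                                      SubsessionTimeline, build_epoch_grid)
        from dyadsync.metrics import epoch_me
        fs = 4.0
        t = np.arange(80) / fs
        x = np.full(80, 30.0)
        x[40:] = np.nan
        tl = SubsessionTimeline.from_plan([("BASE", 20)])
        b = SessionBundle("s", [Subject("H1", "human")], tl,
                          [Channel("H1", "ST", "left_wrist", fs, t, x)])
        me = epoch_me(b, build_epoch_grid(tl))
        vals = me[me.metric == "ST"].sort_values("epoch")["value"].to_numpy()
        assert np.isfinite(vals[0]) and np.isnan(vals[1])


class TestRollingRe:
    def _beats(self, ibi_ms, n):
        t = np.cumsum([0.0] + [ibi_ms / 1000.0] * n)
        ibi = np.diff(t) * 1000.0
        return BeatSeries("X", t, ibi, np.ones(len(ibi), dtype=bool))

    def test_constant_ibi_gives_constant_hr(self):
        beats = self._beats(800.0, 200)
        re = rolling_re(beats, "HR", 0.0, beats.t[-1])
        inner = re.values[~re.edge]
        assert np.allclose(inner, 75.0, atol=1e-9)

    def test_edge_ticks_flagged(self):
        beats = self._beats(800.0, 200)
        re = rolling_re(beats, "HR", 0.0, beats.t[-1])
        assert re.edge[re.t < 30.0].all()
        assert re.edge[re.t > beats.t[-1] - 30.0].all()
        assert not re.edge[(re.t >= 30.0) & (re.t <= beats.t[-1] - 30.0)].any()

    def test_re_matches_me_for_stationary_record(self, short_session,
                                                 analyzed):
        _, bundle, _ = short_session
        from dyadsync.metrics import detect_r_peaks
        from dyadsync.preprocess import preprocess_bundle
        pre = preprocess_bundle(bundle)
        beats = detect_r_peaks(pre.channel("H1", "ECG"), "human")
        re = rolling_re(beats, "HR", 0.0, bundle.timeline.t_end)
        me = analyzed.me
        hr_me = me[(me.subject == "H1") & (me.metric == "HR")]
        # compare one mid-session epoch average of RE to the ME value
        row = hr_me[(hr_me.subsession == "INT1")].iloc[10]
        grid = analyzed.grid.frame
        g = grid[grid.epoch == row["epoch"]].iloc[0]
        ticks = (re.t >= g.t0) & (re.t < g.t1) & ~re.edge
        assert abs(np.nanmean(re.values[ticks]) - row["value"]) \
            < 0.05 * row["value"]

    def test_sdnn_rmssd_re_nonnegative(self, short_session):
        _, bundle, _ = short_session
        from dyadsync.metrics import detect_r_peaks
        from dyadsync.preprocess import preprocess_bundle
        pre = preprocess_bundle(bundle)
        beats = detect_r_peaks(pre.channel("C1", "ECG"), "canine")
        for metric in ("SDNN", "RMSSD"):
            re = rolling_re(beats, metric, 0.0, bundle.timeline.t_end)
            v = re.values[np.isfinite(re.values)]
            assert (v >= 0).all() and len(v) > 100
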