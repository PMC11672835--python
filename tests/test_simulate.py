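"""Generator contracts: targeted HRV moments, waveform/truth consistency,
activity bouts, coupled behavior chains and session assembly."""
import numpy as np
import pytest

import dyadsync as ds
from dyadsync.session import ValidationError
from dyadsync.simulate import (DEFAULT_TRANSITION, _presence_blocks,
                               stationary_distribution)


class TestIbiSeries:
    def test_zero_variance_gives_constant_ibi(self):
        ibi = ds.simulate_ibi_series(75, 0.0, 0.0, 60, seed=0)
        assert np.allclose(ibi, 800.0)
        assert np.sqrt(np.mean(np.diff(ibi) ** 2)) == 0.0

    def test_sdnn_target_recovered_over_seeds(self):
        sds = [np.std(ds.simulate_ibi_series(75, 50, 40, 300, seed=s), ddof=1)
               for s in range(20)]
        assert abs(np.mean(sds) - 50.0) / 50.0 < 0.15

    def test_rmssd_sdnn_ratio_matches_ar1_identity(self):
        # oracle: RMSSD^2 = 2 Var (1 - phi) with phi chosen for ratio 0.8
        ratios = []
        for s in range(20):
            ibi = ds.simulate_ibi_series(75, 50, 40, 300, seed=s)
            ratios.append(np.sqrt(np.mean(np.diff(ibi) ** 2))
                          / np.std(ibi, ddof=1))
        assert abs(np.mean(ratios) - 0.8) < 0.08

    def test_infeasible_pair_raises_naming_bound(self):
        with pytest.raises(ValidationError, match="2\\*sdnn"):
            ds.simulate_ibi_series(75, 20, 50, 60, seed=0)

    def test_covers_requested_duration(self):
        ibi = ds.simulate_ibi_series(60, 30, 25, 120, seed=3)
        assert ibi.sum() >= 120_000.0


class TestRenderEcg:
    def test_constant_ibi_gives_constant_spacing(self):
        t, ecg, r = ds.render_ecg([800.0] * 10, 250, noise_sd=0.0)
        idx = np.round(r * 250).astype(int)
        assert len(r) == 10
        assert np.all(np.diff(idx) == 200)

    def test_noiseless_argmax_recovers_truth_exactly(self):
        ibi = ds.simulate_ibi_series(75, 50, 40, 30, seed=4)
        t, ecg, r = ds.render_ecg(ibi, 250, noise_sd=0.0)
        fs = 250
        for rt in r:
            i = int(round(rt * fs))
            a, b = max(0, i - 50), min(len(ecg), i + 50)
            assert a + np.argmax(ecg[a:b]) == i

    def test_peak_count_matches_beats(self):
        # oracle: count local maxima above half the R amplitude
        from scipy.signal import find_peaks
        ibi = ds.simulate_ibi_series(90, 40, 30, 60, seed=5)
        t, ecg, r = ds.render_ecg(ibi, 250, noise_sd=0.0)
        peaks, _ = find_peaks(ecg, height=0.5)
        assert len(peaks) == len(r) == len(ibi)

    def test_low_fs_rejected(self):
        with pytest.raises(ValidationError, match="100"):
            ds.render_ecg([800.0] * 5, 80)


class TestEda:
    def test_flat_without_events(self):
        t, x = ds.simulate_eda(60, 4, [], [], tonic_level=2.0, noise_sd=0.0)
        assert np.allclose(x, 2.0)

    def test_three_scrs_three_peaks(self):
        # oracle: peak count on the noiseless phasic component
        from scipy.signal import find_peaks
        t, x = ds.simulate_eda(60, 4, [10, 25, 40], [0.5] * 3,
                               tonic_level=1.0, noise_sd=0.0)
        peaks, _ = find_peaks(x - 1.0, height=0.25)
        assert len(peaks) == 3
        # each injected SCR produces a local rise >= 0.9x amplitude
        for ts in (10, 25, 40):
            seg = x[(t >= ts) & (t < ts + 5)]
            assert seg.max() - x[(t >= ts - 1) & (t < ts)].min() >= 0.45

    def test_drift_ramp_closed_form(self):
        t, x = ds.simulate_eda(600, 4, [], [], tonic_level=1.0, drift=0.1,
                               noise_sd=0.0)
        rise = x[t >= 540].mean() - x[t < 60].mean()
        assert 0.85 <= rise <= 1.0  # 0.1 uS/min over 9 min between window centers

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            ds.simulate_eda(10, 4, [5], [-0.1], tonic_level=1.0)


class TestAccelerometer:
    def test_rest_only_ima_below_noise_floor(self):
        t, v = ds.simulate_accelerometer(60, 32, [], seed=0)
        dyn = v.copy()
        dyn[:, 2] -= 9.81
        ima = np.abs(dyn).sum(axis=1).mean()
        assert ima < 0.2

    def test_bout_epochs_elevated(self):
        # oracle: direct integral of |dynamic| on the noiseless layout
        t, v = ds.simulate_accelerometer(100, 32, [(40, 60, 2.0)], seed=1)
        dyn = v.copy()
        dyn[:, 2] -= 9.81
        l1 = np.abs(dyn).sum(axis=1)
        bout = l1[(t >= 45) & (t < 55)].mean()
        rest = l1[t < 35].mean()
        assert bout > 5 * rest

    def test_two_disjoint_bouts_only_those_elevated(self):
        t, v = ds.simulate_accelerometer(120, 32, [(20, 30, 2.0), (80, 90, 2.0)],
                                         seed=2)
        dyn = v.copy()
        dyn[:, 2] -= 9.81
        l1 = np.abs(dyn).sum(axis=1)
        for a, b, hot in ((22, 28, True), (82, 88, True), (40, 70, False),
                          (100, 118, False)):
            seg = l1[(t >= a) & (t < b)].mean()
            assert (seg > 0.5) == hot

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValidationError, match="verlapping"):
            ds.simulate_accelerometer(60, 32, [(10, 30, 1.0), (25, 40, 1.0)])


class TestBehaviorCodes:
    def test_full_copy_is_identical(self):
        h, c = ds.simulate_behavior_codes(500, DEFAULT_TRANSITION, 1.0, seed=0)
        assert np.array_equal(h, c)

    def test_independent_chains_match_product_of_stationaries(self):
        # oracle: chance agreement = sum of squared stationary probabilities
        tm = np.full((3, 3), 1.0 / 3)
        h, c = ds.simulate_behavior_codes(30_000, tm, 0.0, seed=1)
        assert abs((h == c).mean() - 1.0 / 3) < 0.02

    def test_copy_prob_bounds_agreement(self):
        pi = stationary_distribution(DEFAULT_TRANSITION)
        chance = float((pi ** 2).sum())
        h, c = ds.simulate_behavior_codes(20_000, DEFAULT_TRANSITION, 0.8,
                                          seed=2)
        expected = 0.8 + 0.2 * chance
        agree = (h == c).mean()
        assert agree >= 0.8 - 0.02
        assert abs(agree - expected) < 0.03

    def test_bad_transition_rows_rejected(self):
        tm = np.full((3, 3), 0.4)
        with pytest.raises(ValidationError, match="sum to 1"):
            ds.simulate_behavior_codes(10, tm, 0.5)


class TestSession:
    def test_same_seed_reproduces_bytewise(self, short_session):
        cfg, bundle, truth = short_session
        bundle2, truth2 = ds.simulate_session(
            ds.SimConfig(seed=cfg.seed, subsession_plan=cfg.subsession_plan))
        for c1, c2 in zip(bundle.channels, bundle2.channels):
            assert np.array_equal(c1.values, c2.values, equal_nan=True)
        assert bundle.surveys.equals(bundle2.surveys)
        for k in truth.r_peak_times:
            assert np.array_equal(truth.r_peak_times[k],
                                  truth2.r_peak_times[k])

    def test_canine_faster_than_human_every_subsession(self, short_session):
        _, bundle, truth = short_session
        for sub in bundle.timeline:
            for sid, lo, hi in (("H1", 60, 90), ("C1", 80, 115)):
                bt = truth.r_peak_times[sid]
                bt = bt[(bt >= sub.t_start) & (bt < sub.t_end)]
                if sid == "C1" and sub.label.startswith("NEU"):
                    assert len(bt) == 0
                    continue
                hr = 60.0 / np.diff(bt).mean()
                assert lo < hr < hi

    def test_canine_channels_absent_during_neutral(self, short_session):
        _, bundle, _ = short_session
        neu = bundle.timeline["NEU1"]
        ecg = bundle.channel("C1", "ECG")
        sel = (ecg.t >= neu.t_start + 1) & (ecg.t < neu.t_end - 1)
        assert np.isnan(ecg.values[sel]).all()
        sel_int = (ecg.t >= 70) & (ecg.t < 290)
        assert np.isfinite(ecg.values[sel_int]).all()

    def test_surveys_interstitial_only(self, short_session):
        _, bundle, _ = short_session
        tps = set(bundle.surveys["timepoint"])
        assert tps == {"post_BASE", "post_INT1", "post_NEU1", "post_INT2",
                       "post_POST", "session"}
        assert not any(tp.startswith("pre") for tp in tps)

    def test_truth_invariants(self, short_session):
        cfg, bundle, truth = short_session
        for bt in truth.r_peak_times.values():
            assert (np.diff(bt) > 0).all()
        n_sec = int(bundle.timeline.duration)
        for seq in truth.state_sequence.values():
            assert len(seq) >= n_sec
            assert np.isin(seq, (-1, 0, 1)).all()

    def test_zero_coupling_independent_latents(self):
        cfg = ds.SimConfig(seed=5, coupling_rho=0.0)
        _, truth = ds.simulate_session(cfg)
        assert abs(truth.realized_coupling) < 0.5  # wide finite-sample band

    def test_presence_blocks_merge_contiguous(self, short_session):
        _, bundle, _ = short_session
        blocks = _presence_blocks(bundle.timeline, "canine")
        assert blocks == [(0.0, 300.0), (360.0, 660.0)]
        assert _presence_blocks(bundle.timeline, "human") == [(0.0, 660.0)]
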