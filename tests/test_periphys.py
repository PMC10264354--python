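"""Cardiac, respiratory, and electrodermal quantification."""

import numpy as np
import pytest

from gutwave.channels import Channel
from gutwave.periphys import (IBISeries, clean_ibis, deconvolve_scr,
                              detect_r_peaks, estimate_br, make_pseudo_events,
                              phasic_hr, phasic_scr, plf_phf, sdnn, tonic_hr)
from gutwave.synth import scr_impulse_response, simulate_ecg, simulate_scr


def _series(ibis_ms, t0=0.0):
    ibis = np.asarray(ibis_ms, float)
    r = t0 + np.concatenate([[0.0], np.cumsum(ibis / 1000.0)])
    return IBISeries(r, ibis, np.zeros(len(ibis), bool))


class TestRPeaks:
    def test_one_peak_per_second_at_60_bpm(self):
        ch, r_true = simulate_ecg(60.0, 0.0, 15.0, 1000.0, duration=120.0,
                                  noise_mv=0.02, seed=0)
        r = detect_r_peaks(ch)
        assert len(r) == len(r_true)
        err = np.abs(r - r_true)
        assert err.max() < 0.004

    def test_zero_signal_empty(self):
        assert len(detect_r_peaks(Channel("ecg", np.zeros(5000), 1000.0, "mV"))) == 0

    def test_recall_on_default_noise_session(self, session):
        rec, gt = session["rec"], session["gt"]
        r = detect_r_peaks(rec["ecg"])
        d = np.abs(r[:, None] - gt.r_peak_times[None, :]).min(axis=0)
        recall = (d < 0.02).mean()
        assert recall >= 0.99


class TestHrv:
    def test_sdnn_handcomputed_values(self):
        assert sdnn(_series([750.0, 850.0])) == pytest.approx(70.71, abs=0.01)
        assert sdnn(_series([800.0] * 3)) == 0.0

    def test_sdnn_invariances(self, rng):
        ibis = rng.uniform(700.0, 900.0, 50)
        base = sdnn(_series(ibis))
        assert sdnn(_series(rng.permutation(ibis))) == pytest.approx(base)
        # scaling about the mean scales SDNN linearly
        scaled = ibis.mean() + 2.0 * (ibis - ibis.mean())
        assert sdnn(_series(scaled)) == pytest.approx(2.0 * base)

    def test_outlier_ibi_masked(self):
        ibis = [800.0] * 20 + [1500.0] + [800.0] * 20
        s = clean_ibis(np.concatenate([[0.0], np.cumsum(np.array(ibis) / 1000.0)]))
        assert s.outlier_mask.sum() == 1
        assert s.outlier_mask[20]
        assert sdnn(s) == pytest.approx(0.0, abs=1e-9)

    def test_pure_hf_oscillation(self):
        t = np.arange(0.0, 300.0, 0.8)
        ibis = 800.0 + 50.0 * np.sin(2 * np.pi * 0.25 * t)
        r = np.concatenate([[0.0], np.cumsum(ibis / 1000.0)])
        plf, phf = plf_phf(IBISeries(r, ibis, np.zeros(len(ibis), bool)))
        assert phf > 0.9 and plf < 0.1
        assert plf + phf == pytest.approx(1.0)


class TestTonicPhasic:
    def test_constant_ibis_give_exact_hr(self):
        s = _series([1000.0] * 200)
        assert tonic_hr(s, (0.0, 180.0)) == pytest.approx(60.0)

    def test_step_profile_window_weighted(self):
        # 120 s at 60 bpm then 120 s at 80 bpm: window means 60, 60, 80, 80
        ibis = [1000.0] * 120 + [750.0] * 160
        s = _series(ibis)
        v = tonic_hr(s, (0.0, 240.0))
        assert v == pytest.approx(70.0, abs=0.5)

    def test_constant_hr_zero_deltas(self):
        s = _series([800.0] * 400)
        d = phasic_hr(s, [10.0, 50.0, 100.0])
        assert np.allclose(d.delta_bpm, 0.0, atol=1e-9)

    def test_edge_event_skipped(self):
        s = _series([800.0] * 50)
        d = phasic_hr(s, [0.5, 20.0])
        assert len(d) == 1

    def test_pseudo_event_layout(self):
        evs = make_pseudo_events((0.0, 320.0), n=60, spacing_s=3.0, skip_s=120.0)
        onsets = [e["onset_s"] for e in evs]
        assert len(evs) == 60
        assert onsets[0] == 120.0
        assert np.allclose(np.diff(onsets), 3.0)
        with pytest.raises(ValueError):
            make_pseudo_events((0.0, 200.0), n=60)

    def test_pseudo_event_deltas_mean_zero_under_stationarity(self):
        ch, r = simulate_ecg(70.0, 40.0, 15.0, 250.0, duration=400.0,
                             ibi_jitter_ms=3.0, seed=8)
        s = clean_ibis(r)
        d = phasic_hr(s, [e["onset_s"] for e in
                          make_pseudo_events((0.0, 400.0), n=60)])
        ci = 3 * d.delta_bpm.std() / np.sqrt(len(d))
        assert abs(d.delta_bpm.mean()) <= ci

    def test_planted_phasic_step_recovered(self):
        # a +3 bpm step during each 3-s event; beat quantization can only
        # attenuate a windowed estimate, by at most one mean IBI per window,
        # so the recovered delta must land in [delta*(1 - IBI/3), delta]
        onsets = np.arange(20.0, 560.0, 18.0)
        def prof(t):
            return 70.0 + (3.0 if any(o <= t < o + 3.0 for o in onsets) else 0.0)
        _, r = simulate_ecg(prof, 0.0, 15.0, 250.0, duration=580.0)
        d = phasic_hr(clean_ibis(r), onsets)
        mean_ibi = 60.0 / 70.0
        got = d.delta_bpm.mean()
        assert 3.0 * (1.0 - mean_ibi / 3.0) <= got <= 3.0 + 0.05


class TestBreathingRate:
    @pytest.mark.parametrize("br", [10.0, 12.0, 15.0, 18.0, 20.0])
    def test_recovery_within_one_breath(self, br):
        _, r = simulate_ecg(65.0, 40.0, br, 250.0, duration=300.0,
                            ibi_jitter_ms=3.0, seed=int(br))
        est = estimate_br(clean_ibis(r), (0.0, 300.0))
        assert est == pytest.approx(br, abs=1.0)

    def test_no_rsa_gives_absent_value(self):
        _, r = simulate_ecg(65.0, 0.0, 15.0, 250.0, duration=300.0,
                            ibi_jitter_ms=3.0, seed=2)
        assert np.isnan(estimate_br(clean_ibis(r), (0.0, 300.0)))

    def test_ordering_preserved_between_blocks(self):
        _, r1 = simulate_ecg(65.0, 40.0, 12.0, 250.0, duration=300.0, seed=3,
                             ibi_jitter_ms=2.0)
        _, r2 = simulate_ecg(65.0, 40.0, 18.0, 250.0, duration=300.0, seed=4,
                             ibi_jitter_ms=2.0)
        b1 = estimate_br(clean_ibis(r1), (0.0, 300.0))
        b2 = estimate_br(clean_ibis(r2), (0.0, 300.0))
        assert b1 < b2


class TestScr:
    def test_drift_only_signal_all_zero(self):
        t = np.arange(0, 300.0, 0.02)
        drift = 2.0 + 0.001 * t + 0.05 * np.sin(2 * np.pi * 0.003 * t)
        ch = Channel("scr", drift, 50.0, "uS")
        vals = phasic_scr(ch, [50.0, 150.0, 250.0])
        assert np.all(vals.max_scr_us == 0.0)

    def test_event_maxima_track_driver_amplitudes(self):
        ch = simulate_scr([50.0, 150.0], [0.08, 0.16], rate=50.0,
                          duration=300.0, noise_us=0.0)
        vals = phasic_scr(ch, [50.0, 150.0])
        assert vals.max_scr_us[1] / vals.max_scr_us[0] == pytest.approx(2.0, rel=0.05)

    def test_subthreshold_recorded_as_zero(self):
        ch = simulate_scr([100.0], [0.004], rate=50.0, duration=200.0, noise_us=0.0)
        vals = phasic_scr(ch, [100.0])
        assert vals.max_scr_us[0] == 0.0

    def test_nonfinite_rejected(self):
        x = np.zeros(1000)
        x[5] = np.nan
        with pytest.raises(ValueError):
            phasic_scr(Channel("scr", x, 20.0, "uS"), [10.0])

    def test_deconvolve_reconvolve_roundtrip(self):
        # a drift-free phasic signal: deconvolving and re-convolving with the
        # impulse response must reproduce it up to the calibration scale and
        # regularization smoothing
        ch = simulate_scr([40.0, 90.0, 160.0], [0.1, 0.25, 0.15], rate=50.0,
                          duration=240.0, noise_us=0.0, drift=(0.0, 0.0))
        t, driver, smoothed = deconvolve_scr(ch, work_rate=20.0)
        h = scr_impulse_response(20.0)
        recon = np.convolve(driver, h)[:len(driver)]
        target = smoothed - np.median(smoothed)
        mid = slice(len(t) // 8, -len(t) // 8)
        a = np.dot(recon[mid], target[mid]) / np.dot(recon[mid], recon[mid])
        resid = np.sqrt(np.mean((a * recon[mid] - target[mid]) ** 2))
        peak = np.abs(target[mid]).max()
        assert resid / peak < 0.1   # regularization tolerance
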