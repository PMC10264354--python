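"""Generator contracts: determinism, scheduling, responder and channel fidelity."""

import numpy as np
import pytest
from scipy import stats as sps

from gutwave.periphys import clean_ibis, deconvolve_scr, estimate_br, tonic_hr
from gutwave.synth import (EffectParams, ResponderParams, SchedulingError,
                           SessionConfig, simulate_ecg, simulate_scr,
                           simulate_session)
from tests.conftest import scaled_config


class TestScheduling:
    def test_identical_seed_bit_identical_output(self):
        cfg = scaled_config(seed=42)
        rec1, ev1, pr1, _ = simulate_session(cfg)
        rec2, ev2, pr2, _ = simulate_session(scaled_config(seed=42))
        assert ev1 == ev2
        assert np.array_equal(pr1[0], pr2[0])
        for name in rec1.channels:
            assert np.array_equal(rec1[name].data, rec2[name].data)

    def test_different_seed_differs(self):
        _, ev1, _, _ = simulate_session(scaled_config(seed=1, channels=()))
        _, ev2, _, _ = simulate_session(scaled_config(seed=2, channels=()))
        assert ev1 != ev2

    def test_schedule_conservation_and_disjoint(self, session):
        events = session["events"]
        cfg = session["cfg"]
        for cond in ("normal", "enhanced"):
            evs = sorted((e for e in events if e["block"] == cond),
                         key=lambda e: e["onset_s"])
            assert len(evs) == cfg.n_stims[cond]
            for a, b in zip(evs[:-1], evs[1:]):
                assert b["onset_s"] >= a["offset_s"] + cfg.min_gap - 1e-9
        blocks = {b.label: b for b in session["rec"].blocks}
        for e in events:
            blk = blocks[e["block"]]
            assert blk.start <= e["onset_s"] and e["offset_s"] <= blk.stop

    def test_enhanced_counterbalancing(self):
        cfg = scaled_config(seed=5, channels=(), enhanced_first=True)
        _, events, _, _ = simulate_session(cfg)
        assert events[0]["block"] == "enhanced"

    def test_block_too_short_raises(self):
        cfg = scaled_config(channels=(), block_plan=[("normal", 30.0)],
                            n_stims={"normal": 20})
        with pytest.raises(SchedulingError):
            simulate_session(cfg)


class TestResponder:
    def test_hit_rate_calibration_binomial_ci(self):
        # over >=1000 events the empirical hit rate must sit inside the
        # 99% binomial interval of the configured rate
        rp = ResponderParams(hit_rate={"normal": 0.75, "enhanced": 0.75})
        cfg = scaled_config(seed=3, channels=(), responder=rp,
                            block_plan=[("normal", 4600.0), ("enhanced", 4600.0)],
                            n_stims={"normal": 550, "enhanced": 550})
        _, _, _, gt = simulate_session(cfg)
        n = len(gt.responded)
        assert n >= 1000
        lo, hi = sps.binom.interval(0.99, n, 0.75)
        assert lo <= gt.responded.sum() <= hi

    def test_enhanced_latency_matches_study_mean(self):
        # defaults: enhanced latency 0.74 s; scored mean within 2 SE over 57 events
        cfg = SessionConfig(block_plan=[("normal", 780.0), ("enhanced", 780.0)],
                            seed=29, channels=())
        _, events, presses, gt = simulate_session(cfg)
        from gutwave.behavior import score_block
        evs = [e for e in events if e["block"] == "enhanced"]
        assert len(evs) == 57
        span = (min(e["onset_s"] for e in evs) - 2, max(e["offset_s"] for e in evs) + 2)
        sb = score_block(evs, presses, span)
        se = 0.28 / np.sqrt(len(evs))
        assert sb.latency_mean == pytest.approx(0.74, abs=2 * se)

    def test_presses_paired_and_nonoverlapping(self, session):
        press, release = session["presses"]
        assert len(press) == len(release)
        assert np.all(release > press)
        assert np.all(press[1:] > release[:-1])


class TestEcg:
    def test_constant_rate_no_rsa_gives_exact_ibis(self):
        _, r = simulate_ecg(60.0, 0.0, 15.0, 250.0, duration=120.0)
        ibis = np.diff(r) * 1000.0
        assert np.allclose(ibis, 1000.0, atol=4.0)  # within one 250 Hz sample

    def test_br_recovery_from_rsa(self):
        _, r = simulate_ecg(60.0, 50.0, 15.0, 250.0, duration=300.0, seed=1)
        br = estimate_br(clean_ibis(r), (0.0, 300.0))
        assert br == pytest.approx(15.0, abs=1.0)

    def test_tonic_step_is_recovered(self):
        prof = lambda t: 70.0 if t < 150.0 else 75.0
        _, r = simulate_ecg(prof, 0.0, 15.0, 250.0, duration=300.0)
        s = clean_ibis(r)
        assert tonic_hr(s, (0.0, 150.0)) == pytest.approx(70.0, abs=0.5)
        assert tonic_hr(s, (150.0, 300.0)) == pytest.approx(75.0, abs=0.5)

    def test_nonpositive_ibi_raises(self):
        with pytest.raises(ValueError):
            simulate_ecg(60.0, 900.0, 15.0, 250.0, duration=60.0)

    def test_br_out_of_range_raises(self):
        with pytest.raises(ValueError):
            simulate_ecg(60.0, 40.0, 3.0, 250.0, duration=60.0)


class TestScr:
    def test_no_drivers_zero_noise_subthreshold_everywhere(self):
        ch = simulate_scr([], [], rate=50.0, duration=240.0, noise_us=0.0)
        _, driver, _ = deconvolve_scr(ch, work_rate=10.0)
        assert driver.max() < 0.01

    def test_driver_amplitude_linearity(self):
        ch = simulate_scr([60.0, 150.0], [0.1, 0.2], rate=50.0, duration=240.0,
                          noise_us=0.0)
        t, driver, _ = deconvolve_scr(ch, work_rate=10.0)
        m1 = driver[(t >= 60) & (t < 63)].max()
        m2 = driver[(t >= 150) & (t < 153)].max()
        assert m2 / m1 == pytest.approx(2.0, rel=0.05)

    def test_negative_amp_and_bad_tau_raise(self):
        with pytest.raises(ValueError):
            simulate_scr([1.0], [-0.1], rate=50.0, duration=10.0)
        with pytest.raises(ValueError):
            simulate_scr([1.0], [0.1], irf_params=(-1.0, 2.0), rate=50.0, duration=10.0)


class TestChannels:
    def test_egg_peak_at_configured_frequency(self, session):
        from gutwave.egg import egg_spectrum
        spec = egg_spectrum(session["rec"]["egg"], session["rec"].block("baseline").span)
        bin_cpm = spec.freq_cpm[1] - spec.freq_cpm[0]
        assert abs(spec.peak_freq - session["gt"].effects.egg_freq) <= bin_cpm

    def test_stetho_burst_scales_with_condition(self, session):
        rec, events = session["rec"], session["events"]
        st = rec["stetho"]
        def burst_rms(cond):
            vals = []
            for e in events:
                if e["block"] != cond:
                    continue
                seg = st.crop(e["onset_s"] + 0.5, e["offset_s"] - 0.5).data
                vals.append(np.sqrt(np.mean(seg ** 2)))
            return np.mean(vals)
        assert burst_rms("enhanced") / burst_rms("normal") == pytest.approx(2.0, rel=0.05)

    def test_lpp_planted_only_on_responded_events(self, session):
        gt = session["gt"]
        assert np.all(gt.lpp_trial_amp[~gt.responded] == 0.0)
        assert np.all(gt.lpp_trial_amp[gt.responded] >= 0.0)
        assert gt.lpp_trial_amp[gt.responded].mean() > 0.0

    def test_amplitude_validation(self):
        with pytest.raises(ValueError):
            EffectParams(lpp_amplitude={"normal": -1.0, "enhanced": 1.0})
        with pytest.raises(ValueError):
            EffectParams(egg_freq=20.0)
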