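"""EEG preprocessing, epoching, rejection rules and LPP recovery."""

import numpy as np
import pytest

from gutwave.channels import Channel
from gutwave.erp import (average_erp, epoch, lpp_metrics, preprocess,
                         reject_artifacts, rereference_mastoids)
from gutwave.montage import EEG_CHANNELS
from gutwave.synth import (EffectParams, ResponderParams, lpp_template,
                           simulate_session)
from tests.conftest import scaled_config


def _sine(freq, rate=1000.0, dur=120.0, amp=1.0):
    # block-length records: the 0.1 Hz high-pass needs tens of seconds to
    # settle, as in the real 13-min blocks
    t = np.arange(int(dur * rate)) / rate
    return Channel("eeg", amp * np.sin(2 * np.pi * freq * t), rate, "uV")


class TestPreprocess:
    def test_line_noise_attenuated_40_db(self):
        out = preprocess(_sine(60.0))
        mid = out.data[len(out.data) // 4: -len(out.data) // 4]
        rms_in = 1.0 / np.sqrt(2)
        assert 20 * np.log10(rms_in / np.sqrt(np.mean(mid ** 2))) >= 40.0

    def test_passband_preserved_within_1pc(self):
        out = preprocess(_sine(10.0))
        mid = out.data[len(out.data) // 4: -len(out.data) // 4]
        assert np.sqrt(np.mean(mid ** 2)) * np.sqrt(2) == pytest.approx(1.0, rel=0.01)

    def test_dc_removed(self):
        ch = Channel("eeg", np.full(120000, 7.5), 1000.0, "uV")
        out = preprocess(ch)
        mid = out.data[len(out.data) // 4: -len(out.data) // 4]
        assert abs(mid.mean()) < 0.01

    def test_output_rate_and_low_input_rate(self):
        assert preprocess(_sine(10.0, rate=1000.0)).rate == 250.0
        with pytest.raises(ValueError):
            preprocess(_sine(10.0, rate=120.0))


class TestRereference:
    def _labelled(self, data):
        return Channel("eeg", data, 250.0, "uV", labels=list(EEG_CHANNELS))

    def test_common_signal_cancels(self, rng):
        common = rng.normal(size=1000)
        ch = self._labelled(np.tile(common, (31, 1)))
        out = rereference_mastoids(ch)
        assert np.allclose(out.data, 0.0)

    def test_zero_mastoids_is_identity(self, rng):
        data = rng.normal(size=(31, 500))
        for m in ("TP9", "TP10"):
            data[EEG_CHANNELS.index(m)] = 0.0
        out = rereference_mastoids(self._labelled(data))
        assert np.allclose(out.data, data)

    def test_idempotent(self, rng):
        ch = self._labelled(rng.normal(size=(31, 500)))
        once = rereference_mastoids(ch)
        twice = rereference_mastoids(once)
        assert np.allclose(once.data, twice.data)

    def test_missing_mastoid_raises(self, rng):
        labels = [c for c in EEG_CHANNELS if c != "TP9"]
        ch = Channel("eeg", rng.normal(size=(30, 100)), 250.0, "uV", labels=labels)
        with pytest.raises(ValueError):
            rereference_mastoids(ch)


class TestEpoching:
    def _channel(self, data):
        return Channel("eeg", data, 250.0, "uV",
                       labels=list(EEG_CHANNELS)[: data.shape[0]])

    def test_window_is_800_samples_with_zero_baseline(self, rng):
        data = rng.normal(size=(4, 250 * 60))
        eps = epoch(self._channel(data), [{"onset_s": 10.0}, {"onset_s": 30.0}])
        assert eps.data.shape == (2, 4, 800)
        assert eps.times[0] == pytest.approx(-0.2)
        base = eps.data[:, :, :50].mean(axis=2)
        assert np.allclose(base, 0.0, atol=1e-12)

    def test_constant_channel_gives_zero_epochs(self):
        data = np.full((2, 250 * 20), 42.0)
        eps = epoch(self._channel(data), [{"onset_s": 5.0}])
        assert np.allclose(eps.data, 0.0)

    def test_edge_event_skipped_and_counted(self, rng):
        data = rng.normal(size=(2, 250 * 10))
        eps = epoch(self._channel(data), [{"onset_s": 0.1}, {"onset_s": 5.0}])
        assert len(eps.data) == 1
        assert eps.n_skipped_edge == 1

    def test_class_filter_selects_true_positives(self, rng):
        data = rng.normal(size=(2, 250 * 40))
        evs = [{"onset_s": 5.0, "cls": "true_positive"},
               {"onset_s": 15.0, "cls": "miss"},
               {"onset_s": 25.0, "cls": "true_positive"}]
        eps = epoch(self._channel(data), evs, class_filter="true_positive")
        assert len(eps.data) == 2


class TestRejection:
    def _eps(self, data):
        ch = Channel("eeg", data, 250.0, "uV", labels=list(EEG_CHANNELS)[:1])
        return epoch(ch, [{"onset_s": 1.0}])

    def test_step_rule(self, rng):
        data = rng.normal(0, 5, (1, 250 * 6))
        data[0, 400] += 60.0          # one 60 µV jump
        out = reject_artifacts(self._eps(data))
        assert out.reject_mask[0] and "step50" in out.reject_reason[0]

    def test_large_slow_range_rule(self):
        # 300 µV swing spread over 200 ms: no single step exceeds 50 µV
        t = np.arange(250 * 6) / 250.0
        data = 150.0 * np.sin(2 * np.pi * 2.5 * t)[None, :]
        data += np.random.default_rng(0).normal(0, 1, data.shape)
        out = reject_artifacts(self._eps(data))
        assert out.reject_mask[0] and "range200" in out.reject_reason[0]

    def test_moderate_sinusoid_accepted(self):
        t = np.arange(250 * 6) / 250.0
        data = 20.0 * np.sin(2 * np.pi * 10.0 * t)[None, :]   # 40 µV peak-to-peak
        out = reject_artifacts(self._eps(data))
        assert not out.reject_mask[0]

    def test_flatline_rule(self, rng):
        data = rng.normal(0, 5, (1, 250 * 6))
        data[0, 500:575] = data[0, 500]   # 300 ms frozen amplifier
        out = reject_artifacts(self._eps(data))
        assert out.reject_mask[0] and "flatline" in out.reject_reason[0]

    def test_count_conservation(self, rng):
        data = rng.normal(0, 5, (3, 250 * 90))
        data[0, 2000] += 80.0
        ch = Channel("eeg", data, 250.0, "uV", labels=list(EEG_CHANNELS)[:3])
        eps = reject_artifacts(epoch(ch, [{"onset_s": o} for o in (4.0, 8.0, 30.0, 60.0)]))
        c = eps.counts()
        assert c["accepted"] + c["rejected"] == c["extracted"] == 4


class TestAveraging:
    def test_linearity_and_single_epoch_sem(self, rng):
        data = rng.normal(size=(1, 2, 800))
        from gutwave.erp import EpochSet
        import pandas as pd
        eps = EpochSet(data, np.arange(800) / 250.0 - 0.2, 250.0,
                       ["Cz", "Pz"], pd.DataFrame({"onset_s": [0.0],
                                                   "condition": ["normal"],
                                                   "cls": ["true_positive"]}))
        e = average_erp(eps)
        assert np.allclose(e.mean, data[0])
        assert np.all(e.sem == 0.0)   # single-epoch convention

    def test_zero_noise_template_integral_oracle(self):
        # epoch the raw generated EEG (no filtering): the LPP amplitude must
        # equal planted amplitude x window-average of the unit template
        fx = EffectParams(lpp_trial_jitter=0.0, eeg_noise_uv=0.0, eeg_alpha_uv=0.0)
        rp = ResponderParams(hit_rate={"normal": 1.0, "enhanced": 1.0},
                             fp_rate={"normal": 0.0, "enhanced": 0.0})
        cfg = scaled_config(seed=2, channels=("eeg",), effects=fx, responder=rp,
                            block_plan=[("normal", 160.0), ("enhanced", 160.0)],
                            n_stims={"normal": 6, "enhanced": 6})
        rec, events, _, gt = simulate_session(cfg)
        eps = epoch(rereference_mastoids(rec["eeg"]),
                    [{"onset_s": e["onset_s"], "condition": e["condition"],
                      "cls": "true_positive"} for e in events],
                    class_filter="true_positive")
        tmpl_mean = lpp_template(np.arange(0.4, 0.72, 0.004)).mean()
        for cond in ("normal", "enhanced"):
            m = lpp_metrics(average_erp(eps, cond))
            planted = fx.lpp_amplitude[cond] * tmpl_mean
            assert m.amplitude == pytest.approx(planted, rel=1e-6)
            assert 0.4 <= m.latency < 0.72

    def test_planted_amplitude_recovered_within_10pc_at_default_noise(self):
        # 60 trials per condition, generator-default noise
        rp = ResponderParams(hit_rate={"normal": 1.0, "enhanced": 1.0},
                             fp_rate={"normal": 0.0, "enhanced": 0.0})
        cfg = scaled_config(seed=21, channels=("eeg",), responder=rp,
                            block_plan=[("normal", 480.0), ("enhanced", 480.0)],
                            n_stims={"normal": 60, "enhanced": 60})
        rec, events, _, gt = simulate_session(cfg)
        eps = epoch(rereference_mastoids(rec["eeg"]),
                    [{"onset_s": e["onset_s"], "condition": e["condition"],
                      "cls": "true_positive"} for e in events],
                    class_filter="true_positive")
        eps = reject_artifacts(eps)
        tmpl_mean = lpp_template(np.arange(0.4, 0.72, 0.004)).mean()
        for cond in ("normal", "enhanced"):
            m = lpp_metrics(average_erp(eps, cond))
            recovered = m.amplitude / tmpl_mean
            planted = np.mean(gt.lpp_trial_amp[
                [i for i, e in enumerate(events) if e["condition"] == cond]])
            assert recovered == pytest.approx(planted, rel=0.10)

    def test_miss_epochs_carry_no_deflection(self):
        # a half-responsive participant: only responded vibrations carry the
        # planted deflection, so miss-class epochs average to background
        rp = ResponderParams(hit_rate={"normal": 0.5, "enhanced": 0.5},
                             fp_rate={"normal": 0.0, "enhanced": 0.0})
        cfg = scaled_config(seed=13, channels=("eeg",), responder=rp,
                            block_plan=[("normal", 300.0), ("enhanced", 300.0)],
                            n_stims={"normal": 30, "enhanced": 30})
        rec, events, _, gt = simulate_session(cfg)
        evs = [{"onset_s": e["onset_s"], "condition": e["condition"],
                "cls": "true_positive" if r else "miss"}
               for e, r in zip(events, gt.responded)]
        clean = rereference_mastoids(rec["eeg"])
        tp = epoch(clean, evs, class_filter="true_positive")
        miss = epoch(clean, evs, class_filter="miss")
        assert len(tp.data) >= 5 and len(miss.data) >= 5
        amp_tp = lpp_metrics(average_erp(tp)).amplitude
        amp_miss = lpp_metrics(average_erp(miss)).amplitude
        assert amp_tp > amp_miss + 0.5
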