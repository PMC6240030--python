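"""Spike detection, bouts, classes, onset, band power and severity."""

import numpy as np
import pytest

import csdscope as cs
from csdscope.epileptiform import SpikeDetectParams, annotate_channel
from csdscope.exceptions import QualityError, UndefinedSeverityError
from csdscope.simulate import spike_waveform
from conftest import match_events

FS = 300.0


def spike_train(times, dur_s, amp=2.2, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur_s * FS)) / FS
    x = rng.normal(scale=noise, size=t.size)
    for s in times:
        lo = max(int((s - 0.2) * FS), 0)
        hi = min(int((s + 0.2) * FS), t.size)
        x[lo:hi] += spike_waveform(t[lo:hi] - s, amp)
    return x


class TestDetectSpikes:
    def test_recall_and_precision_on_simulated_train(self, default_g301r_sim,
                                                     g301r_filtered):
        _, rec, truth = default_g301r_sim
        _, hp = g301r_filtered
        det = cs.detect_spikes(hp["M1_left"], rec.fs)
        _, recall, precision = match_events(det, truth.spike_times["M1_left"],
                                            tol=0.05)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_refractory_merges_nearby_crossings(self):
        # two crossings 10 ms apart must collapse to a single spike
        x = np.zeros(3000)
        x[900] = 5.0
        x[903] = 4.0
        x += np.random.default_rng(0).normal(scale=0.1, size=x.size)
        det = cs.detect_spikes(x, FS, SpikeDetectParams(refractory_s=0.05))
        assert det.size == 1

    def test_flat_trace_rejected(self):
        with pytest.raises(QualityError):
            cs.detect_spikes(np.zeros(10_000), FS)

    def test_noise_false_positive_rate_low(self, noise_only_sim,
                                           g301r_filtered):
        from csdscope.filters import apply_filter
        from csdscope.recording import EPI_FILTER

        _, rec, _ = noise_only_sim
        hp = apply_filter(rec.channel("M1_left"), rec.fs, EPI_FILTER)
        det = cs.detect_spikes(hp, rec.fs)
        assert det.size / rec.duration_s < 0.02


class TestBouts:
    def test_definition_example(self):
        spikes = np.array([10.0, 10.5, 11.0, 100.0, 100.4, 100.9])
        p = SpikeDetectParams(bout_max_gap_s=2.0, bout_min_spikes=3)
        assert cs.group_bouts(spikes, p) == [(10.0, 11.0), (100.0, 100.9)]

    def test_minimum_spike_count(self):
        p = SpikeDetectParams(bout_min_spikes=3)
        assert cs.group_bouts(np.array([5.0, 50.0]), p) == []

    def test_empty(self):
        assert cs.group_bouts(np.array([]), SpikeDetectParams()) == []


class TestClassify:
    def test_no_organized_activity_is_none(self):
        assert cs.classify_activity(np.array([]), 3600.0) == "none"
        # two isolated crossings never form a discharge train
        assert cs.classify_activity(np.array([100.0, 900.0]), 3600.0) == "none"

    def test_continuous_terminal_window(self):
        dur = 3600.0
        spikes = np.arange(2400.0, dur, 0.5)
        assert cs.classify_activity(spikes, dur) == "continuous"

    def test_bouts_when_terminal_window_has_gaps(self):
        dur = 3600.0
        spikes = np.concatenate([np.arange(s, s + 8.0, 0.5)
                                 for s in np.arange(600.0, dur - 60.0, 120.0)])
        assert cs.classify_activity(spikes, dur) == "bouts"

    @pytest.mark.parametrize("escalation", ["bouts", "continuous"])
    def test_simulated_class_recovered(self, escalation):
        p = cs.SimParams(csd_rate_per_hr=0.0, epi_onset_s=200.0,
                         epi_escalation=escalation, duration_s=1500.0, seed=11)
        rec, _ = cs.simulate_recording(p)
        from csdscope.filters import apply_filter
        from csdscope.recording import EPI_FILTER

        hp = apply_filter(rec.channel("M1_left"), rec.fs, EPI_FILTER)
        det = cs.detect_spikes(hp, rec.fs)
        assert cs.classify_activity(det, rec.duration_s) == escalation


class TestOnset:
    def test_definition(self):
        assert cs.epileptiform_onset(np.array([840.0, 900.0])) == 840.0
        assert cs.epileptiform_onset(np.array([])) is None

    def test_monotone_adding_spikes_never_delays_onset(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 3600, 50))
        base = cs.epileptiform_onset(times)
        for extra in rng.uniform(0, 3600, 20):
            assert cs.epileptiform_onset(np.sort(np.r_[times, extra])) <= base

    def test_recovered_onset_close_to_process_onset(self):
        p = cs.SimParams(csd_rate_per_hr=0.0, epi_onset_s=600.0,
                         epi_escalation="bouts", duration_s=1500.0, seed=2)
        rec, _ = cs.simulate_recording(p)
        from csdscope.filters import apply_filter
        from csdscope.recording import EPI_FILTER

        hp = apply_filter(rec.channel("M1_left"), rec.fs, EPI_FILTER)
        ann = annotate_channel(hp, rec.fs, "M1_left")
        assert 600.0 <= ann.onset_s <= 630.0


class TestBandPower:
    def test_spectral_concentration_of_sine(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        inband = cs.band_power(x, FS, 0, 120, band=(0.5, 4.0))
        outband = cs.band_power(x, FS, 0, 120, band=(10.0, 20.0))
        assert inband >= 100 * outband

    def test_white_noise_flat_across_bands(self):
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=int(300 * FS))
            a = cs.band_power(x, FS, 0, 300, band=(10.0, 20.0))
            b = cs.band_power(x, FS, 0, 300, band=(30.0, 40.0))
            ratios.append(a / b)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_zero_trace(self):
        assert cs.band_power(np.zeros(int(60 * FS)), FS, 0, 60) == 0.0

    def test_window_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            cs.band_power(np.zeros(int(60 * FS)), FS, 0, 10)


class TestSeverity:
    def test_doubled_amplitude_quadruples_power_ratio(self):
        x = np.random.default_rng(0).normal(size=int(600 * FS))
        trace = np.r_[x, np.zeros(int(300 * FS)), 2.0 * x]
        assert cs.severity(trace, FS) == pytest.approx(4.0, rel=1e-9)

    def test_offset_invariant(self):
        x = np.random.default_rng(1).normal(size=int(1500 * FS))
        assert cs.severity(x + 3.0, FS) == pytest.approx(cs.severity(x, FS),
                                                         rel=1e-6)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            cs.severity(np.zeros(int(600 * FS)), FS)

    def test_zero_reference_window_rejected(self):
        trace = np.r_[np.zeros(int(700 * FS)),
                      np.random.default_rng(0).normal(size=int(800 * FS))]
        with pytest.raises(UndefinedSeverityError):
            cs.severity(trace, FS)


class TestGeneralized:
    def ann(self, channel, onset):
        from csdscope.epileptiform import EpiAnnotation

        return EpiAnnotation(channel=channel, spike_times_s=np.array([]),
                             bouts=[], onset_s=onset,
                             activity_class="bouts" if onset else "none")

    def test_bilateral_onsets_close(self):
        anns = {"M1_left": self.ann("M1_left", 900.0),
                "M1_right": self.ann("M1_right", 930.0)}
        assert cs.is_generalized(anns)

    def test_ipsilateral_only(self):
        anns = {"M1_left": self.ann("M1_left", 900.0),
                "M1_right": self.ann("M1_right", None)}
        assert not cs.is_generalized(anns)

    def test_no_activity_anywhere(self):
        anns = {"M1_left": self.ann("M1_left", None),
                "M1_right": self.ann("M1_right", None)}
        assert not cs.is_generalized(anns)

    def test_simulated_activity_is_generalized(self, default_g301r_sim,
                                               g301r_filtered):
        _, rec, _ = default_g301r_sim
        _, hp = g301r_filtered
        anns = {r: annotate_channel(hp[r], rec.fs, r, compute_severity=False)
                for r in rec.channels}
        assert cs.is_generalized(anns)
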