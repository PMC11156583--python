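"""Event detection: filters, thresholding, classification, grouping."""

import numpy as np
import pytest

from epimap.ephys import (DetectionParams, ElectrodeClass, Event, EventKind,
                          bandpass_filter, classify_event, detect_iilds,
                          detect_mua, group_network_iilds, normalized_power,
                          summarize_electrode)
from epimap.errors import InputError, ParameterError
from epimap.spatial import MEALayout
from epimap.synth import gen_mea_recording, iild_waveform, spike_waveform

from conftest import match_events

FS = 10_000.0


def _noise(seed, dur_s=10.0, sd=5.0):
    return np.random.default_rng(seed).normal(0, sd, int(dur_s * FS))


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        t = np.arange(0, 5, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_filter(x, FS, 1, 40)
        mid = slice(int(FS), int(4 * FS))  # avoid edges
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_suppressed(self):
        t = np.arange(0, 5, 1 / FS)
        x = np.sin(2 * np.pi * 300 * t)
        y = bandpass_filter(x, FS, 1, 40)
        assert np.sqrt(np.mean(y**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_zeros_map_to_zeros(self):
        assert np.allclose(bandpass_filter(np.zeros(20_000), FS, 1, 40), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(1000), FS, 40, 1)

    def test_output_length_preserved(self):
        x = _noise(0, 2.0)
        assert bandpass_filter(x, FS, 250, FS / 2).size == x.size


class TestNormalizationContract:
    def test_z_signal_standardized(self):
        x = _noise(1, 5.0)
        _, z, sigma = normalized_power(x, FS, 1, 40, DetectionParams())
        assert abs(z.mean()) < 1e-6
        assert abs(z.std() - 1.0) < 1e-6
        assert sigma > 0

    def test_constant_trace_guarded(self):
        evs = detect_iilds(np.full(int(2 * FS), 3.7), FS)
        assert evs == []


class TestDetectIILDs:
    def test_injected_discharges_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5.0, int(30 * FS))
        wave = iild_waveform(FS, 300.0, 150.0, 250.0, 15.0)
        true_t = []
        for t0 in [5.0, 14.0, 23.0]:
            a = int(t0 * FS)
            x[a:a + wave.size] += wave
            true_t.append((a + int(np.argmax(np.abs(wave)))) / FS)
        evs = detect_iilds(x, FS)
        assert len(evs) == 3
        for e, t in zip(evs, true_t):
            assert abs(e.t_peak_s - t) <= 0.02
            assert e.kind == EventKind.IILD
            assert e.t_onset_s <= e.t_peak_s < e.t_offset_s

    def test_all_zero_trace(self):
        assert detect_iilds(np.zeros(int(2 * FS)), FS) == []

    def test_noise_only_false_positive_rate(self):
        # 20 seeds of 60 s noise at the default threshold: at most one
        # spurious discharge per seed survives the duration gate
        for seed in range(20):
            evs = detect_iilds(_noise(seed, 60.0), FS)
            assert len(evs) <= 1

    def test_short_trace_rejected(self):
        with pytest.raises(InputError):
            detect_iilds(np.zeros(100), FS)


class TestDetectMUA:
    def test_injected_spikes_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 5.0, int(30 * FS))
        spike = spike_waveform(FS, 1.0, 60.0)
        pk = int(np.argmax(np.abs(spike)))
        true_t = np.linspace(1.0, 29.0, 50)
        for t0 in true_t:
            a = int(t0 * FS)
            x[a:a + spike.size] += spike
        evs = detect_mua(x, FS)
        tp, n_true, n_det = match_events(
            [e.t_peak_s for e in evs], (true_t * FS + pk) / FS, 0.001)
        assert n_det == 50 and tp == 50

    def test_refractory_collapses_close_crossings(self):
        x = np.random.default_rng(4).normal(0, 5.0, int(2 * FS))
        spike = spike_waveform(FS, 1.0, 80.0)
        a = int(1.0 * FS)
        x[a:a + spike.size] += spike
        b = a + int(0.0005 * FS)  # second crossing 0.5 ms later
        x[b:b + spike.size] += spike
        evs = detect_mua(x, FS)
        assert len(evs) == 1

    def test_all_zero_trace(self):
        assert detect_mua(np.zeros(int(2 * FS)), FS) == []


class TestClassifyEvent:
    def test_discharge_and_spike_discriminated(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 5.0, int(10 * FS))
        wave = iild_waveform(FS, 300.0, 150.0, 250.0, 15.0)
        x[int(2 * FS):int(2 * FS) + wave.size] += wave
        spike = spike_waveform(FS, 1.0, 60.0)
        x[int(6 * FS):int(6 * FS) + spike.size] += spike

        iild_ev = detect_iilds(x, FS)[0]
        assert classify_event(x, FS, iild_ev).kind == EventKind.IILD
        spike_ev = [e for e in detect_mua(x, FS)
                    if abs(e.t_peak_s - 6.0) < 0.01][0]
        assert classify_event(x, FS, spike_ev).kind == EventKind.MUA_SPIKE

    def test_pure_slow_burst_is_iild(self):
        x = np.zeros(int(4 * FS))
        t = np.arange(0, 0.5, 1 / FS)
        x[int(FS):int(FS) + t.size] = 50 * np.sin(2 * np.pi * 10 * t)
        ev = Event(0, 1.0, 1.02, 1.5, EventKind.IILD, 10.0)
        res = classify_event(x, FS, ev)
        assert res.slow_fraction == pytest.approx(1.0, abs=0.02)
        assert res.kind == EventKind.IILD
        assert res.spectrogram_power.ndim == 2

    def test_window_outside_trace_rejected(self):
        ev = Event(0, 0.5, 0.6, 5.0, EventKind.IILD, 10.0)
        with pytest.raises(InputError):
            classify_event(np.zeros(int(1 * FS)), FS, ev)


class TestSummarizeElectrode:
    def _spikes(self, n):
        return [Event(0, i, i, i + 0.001, EventKind.MUA_SPIKE, 9.0)
                for i in range(n)]

    def _iilds(self, n):
        return [Event(0, 10 * i, 10 * i + 0.1, 10 * i + 0.3, EventKind.IILD, 9.0)
                for i in range(n)]

    def test_mua_only(self):
        a = summarize_electrode([], self._spikes(30), 60.0)
        assert a.mua_rate_hz == pytest.approx(0.5)
        assert a.cls == ElectrodeClass.MUA_ONLY

    def test_iild_dominates(self):
        a = summarize_electrode(self._iilds(3), self._spikes(30), 60.0)
        assert a.cls == ElectrodeClass.IILD_MUA and a.iild_count == 3

    def test_silent(self):
        a = summarize_electrode([], [], 60.0)
        assert a.cls == ElectrodeClass.SILENT and a.mua_rate_hz == 0.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ParameterError):
            summarize_electrode([], [], -1.0)


class TestNetworkGrouping:
    def _ev(self, ch, t):
        return Event(ch, t - 0.05, t, t + 0.1, EventKind.IILD, 5.0)

    def test_adjacent_synchronous_events_group(self, small_layout):
        evs = {5: [self._ev(5, 1.00)], 6: [self._ev(6, 1.02)]}
        nets = group_network_iilds(evs, small_layout)
        assert len(nets) == 1
        assert nets[0].channels == (5, 6) and nets[0].n_members == 2

    def test_same_channel_distant_events_stay_separate(self, small_layout):
        evs = {5: [self._ev(5, 1.0), self._ev(5, 1.5)]}
        nets = group_network_iilds(evs, small_layout)
        assert len(nets) == 2

    def test_non_adjacent_channels_stay_separate(self, small_layout):
        evs = {0: [self._ev(0, 1.0)], 15: [self._ev(15, 1.0)]}
        assert len(group_network_iilds(evs, small_layout)) == 2

    def test_empty_input(self, small_layout):
        assert group_network_iilds({}, small_layout) == []

    def test_unknown_channel_rejected(self, small_layout):
        with pytest.raises(InputError):
            group_network_iilds({99: [self._ev(0, 1.0)]}, small_layout)

    def test_generator_network_events_recovered(self, small_mea_cfg, small_layout):
        rec, truth = gen_mea_recording(small_mea_cfg)
        evs = {ch: detect_iilds(rec.traces[ch], rec.fs_hz, channel=ch)
               for ch in range(16)}
        nets = group_network_iilds(evs, small_layout)
        # one network event per true network discharge, spanning the core
        assert len(nets) == len(truth.network_iilds)
        for net, (t_true, members) in zip(nets, truth.network_iilds):
            assert abs(net.t_s - t_true) < 0.2
            assert set(net.channels) == set(members)
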