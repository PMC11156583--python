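"""Generators: seeded determinism, rate calibration, ground-truth structure."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import binom

from epimap.errors import ConfigurationError
from epimap.spatial import MEALayout
from epimap.synth import (CellSimConfig, EEGSimConfig, MEASimConfig,
                          default_colabel_probs, gen_cell_map, gen_eeg_study,
                          gen_eeg_trace, gen_mea_recording, high_k_variant,
                          iild_waveform, spike_waveform, PANEL_MARKERS)

from conftest import CORE, SURROUND


class TestMEAGenerator:
    def test_shapes_and_trace_per_electrode(self, small_mea_cfg):
        rec, truth = gen_mea_recording(small_mea_cfg)
        assert rec.traces.shape == (16, int(60 * 10_000))
        assert rec.traces.dtype == np.float32
        assert truth.duration_s == 60.0

    def test_iild_locality(self, small_mea_cfg):
        _, truth = gen_mea_recording(small_mea_cfg)
        iild_channels = set(truth.events.query("kind == 'IILD'")["channel"])
        assert iild_channels == set(CORE)
        for t, members in truth.network_iilds:
            assert set(members) == set(CORE)

    def test_seeded_determinism(self, small_mea_cfg):
        rec1, truth1 = gen_mea_recording(small_mea_cfg)
        rec2, truth2 = gen_mea_recording(small_mea_cfg)
        assert np.array_equal(rec1.traces, rec2.traces)
        pd.testing.assert_frame_equal(truth1.events, truth2.events)

    def test_zero_rates_give_pure_noise(self, small_layout):
        cfg = MEASimConfig(seed=1, duration_s=5.0, layout=small_layout,
                           core_electrodes=CORE, surround_electrodes=SURROUND,
                           mua_rate_core_hz=0.0, mua_rate_surround_hz=0.0,
                           iild_rate_per_min=0.0)
        rec, truth = gen_mea_recording(cfg)
        assert truth.events.empty
        # pure Gaussian noise: sample SD near the configured noise level
        assert rec.traces.std() == pytest.approx(cfg.noise_sd_uv, rel=0.02)

    def test_overlapping_sets_rejected(self, small_layout):
        with pytest.raises(ConfigurationError):
            MEASimConfig(layout=small_layout, core_electrodes=frozenset({1}),
                         surround_electrodes=frozenset({1, 2}))

    def test_fs_too_low_for_ripple_rejected(self, small_layout):
        with pytest.raises(ConfigurationError):
            MEASimConfig(layout=small_layout, core_electrodes=CORE,
                         surround_electrodes=SURROUND, fs_hz=900.0)

    def test_high_k_scales_spike_counts_not_iilds(self, small_layout):
        cfg = MEASimConfig(seed=5, duration_s=120.0, layout=small_layout,
                           core_electrodes=CORE, surround_electrodes=SURROUND)
        _, truth = gen_mea_recording(cfg)
        _, truth_k = gen_mea_recording(high_k_variant(cfg))
        # identical IILD placement
        iild = truth.events.query("kind == 'IILD'").reset_index(drop=True)
        iild_k = truth_k.events.query("kind == 'IILD'").reset_index(drop=True)
        pd.testing.assert_frame_equal(iild, iild_k)
        # core spike counts ~5x control, within Poisson error of both draws
        for ch in CORE:
            n0 = len(truth.channel_events(ch, "MUA_SPIKE"))
            nk = len(truth_k.channel_events(ch, "MUA_SPIKE"))
            lam0 = cfg.mua_rate_core_hz * cfg.duration_s
            assert abs(nk - 5 * n0) < 3 * np.sqrt(25 * lam0 + 5 * lam0)

    def test_rate_calibration(self):
        # all-core 2x2 grid: empirical rate within 3 sqrt(rate/T) of the
        # configured rate for >= 95% of channel-draws across 20 seeds
        layout = MEALayout(rows=2, cols=2)
        ok = n_tot = 0
        for seed in range(20):
            cfg = MEASimConfig(seed=seed, duration_s=600.0, layout=layout,
                               core_electrodes=frozenset(range(4)),
                               surround_electrodes=frozenset(),
                               iild_rate_per_min=0.0)
            _, truth = gen_mea_recording(cfg)
            for ch in range(4):
                n = len(truth.channel_events(ch, "MUA_SPIKE"))
                rate = n / cfg.duration_s
                tol = 3 * np.sqrt(cfg.mua_rate_core_hz / cfg.duration_s)
                ok += abs(rate - cfg.mua_rate_core_hz) <= tol
                n_tot += 1
        assert ok / n_tot >= 0.95

    def test_full_default_recording_dimensions(self):
        # the full acquisition-scale default: 120 electrodes, 10 min, 10 kHz
        cfg = MEASimConfig(seed=42)
        rec, truth = gen_mea_recording(cfg)
        assert rec.traces.shape == (120, 6_000_000)
        iild_channels = set(truth.events.query("kind == 'IILD'")["channel"])
        assert iild_channels == set(cfg.core_electrodes)
        assert len(truth.events.query("kind == 'MUA_SPIKE'")) > 0
        del rec, truth

    def test_waveform_energy_separation(self):
        fs = 10_000.0
        spike = spike_waveform(fs, 1.0, 60.0)
        iild = iild_waveform(fs, 300.0, 150.0, 250.0, 15.0)
        for w, lo in [(spike, 250.0), (iild, None)]:
            freqs = np.fft.rfftfreq(w.size, 1 / fs)
            spec = np.abs(np.fft.rfft(w)) ** 2
            if lo:  # spike energy concentrated above the MUA high-pass
                assert spec[freqs > lo].sum() / spec.sum() > 0.6
            else:  # discharge energy dominated by the slow (<40 Hz) band
                assert spec[freqs < 40.0].sum() / spec.sum() > 0.9


class TestCellMapGenerator:
    def test_dn_count_poisson_and_colabels(self):
        cfg = CellSimConfig(seed=0, field_w_mm=2.0, field_h_mm=1.0,
                            bc_density_mm2=0.0, normal_density_mm2=0.0,
                            image_channels=())
        cells, img = gen_cell_map(cfg)
        # countable phenotype over the 2/3 mm^2 core zone
        zone_area = cfg.field_w_mm * cfg.field_h_mm / 3
        dn = cells.query("celltype == 'dn_like'")
        core_dn = dn[(dn.x_um < cfg.field_w_mm * 1e3 / 3)
                     & (dn.pS6 > 0) & (dn.NeuN > 0) & (dn.diam_um > 25)]
        mean = 53.6 * zone_area
        assert abs(len(core_dn) - mean) <= 3 * np.sqrt(mean) + 3

    def test_all_probabilities_one(self):
        probs = {m: 1.0 for m in default_colabel_probs()}
        cfg = CellSimConfig(seed=1, field_w_mm=1.0, field_h_mm=1.0,
                            colabel_probs=probs, bc_density_mm2=0.0,
                            image_channels=())
        cells, _ = gen_cell_map(cfg)
        sab = cells.query("SABGAL > 0")
        assert len(sab) > 0
        assert (sab[list(PANEL_MARKERS)].to_numpy() == 1).all()

    def test_zero_densities_empty_map(self):
        cfg = CellSimConfig(seed=2, field_w_mm=1.0, field_h_mm=1.0,
                            dn_density_core_mm2=0.0,
                            dn_density_surround_mm2=0.0, bc_density_mm2=0.0,
                            normal_density_mm2=0.0)
        cells, img = gen_cell_map(cfg)
        assert cells.empty
        # background-only image: noise, no unit-intensity disks
        assert img.channels.max() < 0.5

    def test_zero_field_rejected(self):
        with pytest.raises(ConfigurationError):
            CellSimConfig(field_w_mm=0.0)

    def test_colabel_calibration(self):
        # observed fractions among the dysmorphic-like SAβGal+ population
        # stay inside the 99% binomial band of each configured probability
        probs = default_colabel_probs()
        checks = ok = 0
        for seed in range(10):
            cfg = CellSimConfig(seed=seed, field_w_mm=3.0, field_h_mm=2.0,
                                dn_density_core_mm2=180.0,
                                dn_density_surround_mm2=180.0,
                                bc_density_mm2=0.0, normal_density_mm2=0.0,
                                image_channels=())
            cells, _ = gen_cell_map(cfg)
            sab = cells.query("celltype == 'dn_like' and SABGAL > 0")
            n = len(sab)
            assert n > 500
            for m, p in probs.items():
                lo, hi = binom.interval(0.99, n, p)
                checks += 1
                ok += lo <= sab[m].sum() <= hi
        assert ok / checks >= 0.95

    def test_balloon_cells_confined_to_band(self):
        cfg = CellSimConfig(seed=3, field_w_mm=1.0, field_h_mm=2.0,
                            dn_density_core_mm2=0.0,
                            dn_density_surround_mm2=0.0,
                            normal_density_mm2=0.0, bc_density_mm2=60.0,
                            bc_band_mm=(1.6, 2.0), image_channels=())
        cells, _ = gen_cell_map(cfg)
        bc = cells.query("celltype == 'bc_like'")
        assert len(bc) > 0
        assert (bc.y_um >= 1600).all() and (bc.y_um <= 2000).all()
        assert (bc.pS6 == 1).all() and (bc.NeuN == 0).all()


class TestEEGGenerator:
    def test_poisson_mean_recovery_no_effect(self):
        cfg = EEGSimConfig(seed=4, n_animals=8, rate_dispersion=0.0,
                           baseline_rate_per_day=3.0,
                           treatment_multiplier=1.0,
                           phase_schedule=(("pre", 14), ("post", 14)))
        study = gen_eeg_study(cfg)
        post = study.counts.query("phase == 'post'")["n_seizures"]
        se = np.sqrt(3.0 / len(post))
        assert abs(post.mean() - 3.0) <= 3 * se

    def test_zero_multiplier_gives_seizure_freedom(self):
        cfg = EEGSimConfig(seed=5, treatment_multiplier=0.0)
        study = gen_eeg_study(cfg)
        assert (study.counts.query("phase in ('end', 'post')")["n_seizures"]
                == 0).all()
        assert (study.counts.query("phase == 'pre'")["n_seizures"].sum()) > 0

    def test_seeded_determinism(self):
        cfg = EEGSimConfig(seed=6)
        s1, s2 = gen_eeg_study(cfg), gen_eeg_study(cfg)
        pd.testing.assert_frame_equal(s1.counts, s2.counts)
        for k in s1.event_times:
            assert np.array_equal(s1.event_times[k], s2.event_times[k])

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            EEGSimConfig(phase_schedule=())

    def test_trace_bursts_at_requested_times(self):
        x, intervals = gen_eeg_trace(120.0, 256.0, [30.0, 80.0], seed=0)
        assert len(intervals) == 2
        seg = x[int(30 * 256):int(50 * 256)]
        base = x[:int(20 * 256)]
        assert seg.std() > 2 * base.std()
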