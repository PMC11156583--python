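"""Study-scale benchmark runs: recovery of generative truth end to end.

This module fixes the synthetic study conditions used by the analysis
scripts and the acceptance suite — a 4 x 4 electrode grid with a 2 x 2
discharge core and 3-minute recordings, histology fields matched to the
grid's Voronoi regions, and the longitudinal seizure-study design — and
implements the recovery measurements on them: detector sensitivity and
precision against ground truth, MUA-rate contrast, the high-K
monotonicity property, density and co-label recovery, and treatment-
effect estimation.  Problem sizes are chosen so each benchmark runs in
minutes on one CPU while keeping the statistics well inside their
sampling tolerances.
"""

from __future__ import annotations


import numpy as np
from scipy.stats import binom, poisson
from shapely.geometry import box
from shapely.ops import unary_union

from .eeg import compare_phases, detect_seizures
from .ephys import DetectionParams, ElectrodeClass, detect_recording
from .histo import SegmentationParams, cell_density, segment_cells
from .spatial import (AffineTransform2D, MEALayout, density_by_class,
                      voronoi_regions)
from .synth import (CellSimConfig, EEGSimConfig, MEASimConfig,
                    default_colabel_probs, gen_cell_map, gen_eeg_study,
                    gen_eeg_trace, gen_mea_recording, high_k_variant)

STUDY_CORE = frozenset({5, 6, 9, 10})
STUDY_SURROUND = frozenset({1, 2, 4, 7, 8, 11, 13, 14}) - STUDY_CORE
STUDY_BOUNDS_UM = (-500.0, -500.0, 3500.0, 3500.0)


def study_layout() -> MEALayout:
    return MEALayout(rows=4, cols=4, pitch_h_um=1000.0, pitch_v_um=1000.0)


def study_mea_config(seed: int, duration_s: float = 180.0) -> MEASimConfig:
    return MEASimConfig(seed=seed, duration_s=duration_s,
                        layout=study_layout(), core_electrodes=STUDY_CORE,
                        surround_electrodes=STUDY_SURROUND)


def _match(detected_times, true_times, tol_s):
    det = np.asarray(detected_times, dtype=float)
    used: set[int] = set()
    tp = 0
    for t in np.asarray(true_times, dtype=float):
        if det.size == 0:
            break
        d = np.abs(det - t)
        for j in np.argsort(d):
            if d[j] > tol_s:
                break
            if j not in used:
                used.add(int(j))
                tp += 1
                break
    return tp


def mea_detection_recovery(seeds=range(20), duration_s: float = 180.0,
                           iild_tol_s: float = 0.05,
                           mua_tol_s: float = 0.002) -> dict:
    """Detection sensitivity/precision and rate recovery over seeded runs.

    Returns pooled IILD and MUA sensitivity/precision against generator
    truth, the detected core and surround MUA rates with their 3-SE
    recovery tolerances, and the configured rates.
    """
    params = DetectionParams()
    tp = {"IILD": 0, "MUA_SPIKE": 0}
    n_true = {"IILD": 0, "MUA_SPIKE": 0}
    n_det = {"IILD": 0, "MUA_SPIKE": 0}
    core_count = surr_count = 0
    core_time = surr_time = 0.0
    cfg0 = study_mea_config(0, duration_s)
    for seed in seeds:
        cfg = study_mea_config(seed, duration_s)
        rec, truth = gen_mea_recording(cfg)
        iilds, muas, _ = detect_recording(rec, params)
        for ch in range(cfg.layout.n_channels):
            for kind, evs, tol in (("IILD", iilds[ch], iild_tol_s),
                                   ("MUA_SPIKE", muas[ch], mua_tol_s)):
                tt = truth.channel_events(ch, kind)
                det_t = [e.t_peak_s for e in evs]
                tp[kind] += _match(det_t, tt, tol)
                n_true[kind] += tt.size
                n_det[kind] += len(det_t)
            if ch in STUDY_CORE:
                core_count += len(muas[ch])
                core_time += cfg.duration_s
            elif ch in STUDY_SURROUND:
                surr_count += len(muas[ch])
                surr_time += cfg.duration_s
    out = {
        "iild_sensitivity": tp["IILD"] / n_true["IILD"],
        "iild_precision": tp["IILD"] / n_det["IILD"],
        "mua_sensitivity": tp["MUA_SPIKE"] / n_true["MUA_SPIKE"],
        "mua_precision": tp["MUA_SPIKE"] / n_det["MUA_SPIKE"],
        "core_rate_hz": core_count / core_time,
        "surround_rate_hz": surr_count / surr_time,
        "core_rate_true_hz": cfg0.mua_rate_core_hz,
        "surround_rate_true_hz": cfg0.mua_rate_surround_hz,
        "core_rate_tol_3se": 3 * np.sqrt(cfg0.mua_rate_core_hz / core_time),
        "surround_rate_tol_3se":
            3 * np.sqrt(cfg0.mua_rate_surround_hz / surr_time),
        "n_true_iild": n_true["IILD"],
        "n_true_mua": n_true["MUA_SPIKE"],
    }
    return out


def high_k_property(seeds=range(3), duration_s: float = 180.0) -> dict:
    """Pro-convulsive condition: MUA rises everywhere, IILD zone is stable.

    For each seed, compares control and high-K detection.  Reports
    whether the detected MUA count increased on every active channel
    (control class not SILENT) and whether the set of IILD-bearing
    channels is identical.
    """
    all_increase = True
    sets_stable = True
    ratios = []
    for seed in seeds:
        cfg = study_mea_config(seed, duration_s)
        rec_c, _ = gen_mea_recording(cfg)
        rec_k, _ = gen_mea_recording(high_k_variant(cfg))
        _, mua_c, act_c = detect_recording(rec_c)
        _, mua_k, act_k = detect_recording(rec_k)
        active = {a.channel for a in act_c if a.cls != ElectrodeClass.SILENT}
        for ch in active:
            if len(mua_k[ch]) <= len(mua_c[ch]):
                all_increase = False
            if len(mua_c[ch]):
                ratios.append(len(mua_k[ch]) / len(mua_c[ch]))
        set_c = {a.channel for a in act_c if a.cls == ElectrodeClass.IILD_MUA}
        set_k = {a.channel for a in act_k if a.cls == ElectrodeClass.IILD_MUA}
        if set_c != set_k or set_c != set(STUDY_CORE):
            sets_stable = False
    return {
        "mua_increases_on_every_active_channel": all_increase,
        "iild_channel_set_unchanged": sets_stable,
        "median_mua_ratio": float(np.median(ratios)),
        "configured_multiplier": study_mea_config(0).high_k_mua_multiplier,
    }


def study_zones() -> dict:
    """Histology zones matched to the electrode classes' Voronoi regions."""
    regs = voronoi_regions(study_layout(), AffineTransform2D.identity(),
                           STUDY_BOUNDS_UM)
    return {
        "core": unary_union([regs[c] for c in STUDY_CORE]),
        "surround": unary_union([regs[c] for c in STUDY_SURROUND]),
    }


def density_recovery(n_seeds: int = 10, seed_offset: int = 0) -> dict:
    """End-to-end dysmorphic-neuron density per activity class.

    Generates cell maps whose core/surround zones are the Voronoi
    regions of the study grid, runs the density pipeline, and pools the
    counts over seeds.  Reports the estimated densities and whether the
    pooled counts sit inside the 95% Poisson intervals implied by the
    generative 53.6 and 11.7 cells/mm^2.
    """
    layout = study_layout()
    zones = study_zones()
    cls = {ch: ("IILD_MUA" if ch in STUDY_CORE else
                "MUA_ONLY" if ch in STUDY_SURROUND else "SILENT")
           for ch in range(layout.n_channels)}
    transform = AffineTransform2D.identity()
    counts = {"IILD_MUA": 0, "MUA_ONLY": 0}
    areas = {}
    for k in range(n_seeds):
        cfg = CellSimConfig(seed=seed_offset + k, field_w_mm=4.0,
                            field_h_mm=4.0, bc_density_mm2=0.0,
                            image_channels=())
        cells, _ = gen_cell_map(cfg, zones=zones)
        res = density_by_class(cells, cls, layout, transform,
                               field_bounds_um=STUDY_BOUNDS_UM)
        for key in counts:
            counts[key] += res.n_cells[key]
        areas = res.region_area_mm2
    out = {}
    for key, true_d in (("IILD_MUA", 53.6), ("MUA_ONLY", 11.7)):
        mu = true_d * areas[key] * n_seeds
        lo, hi = poisson.interval(0.95, mu)
        out[key] = {
            "density_per_mm2": counts[key] / (areas[key] * n_seeds),
            "true_density_per_mm2": true_d,
            "count": counts[key],
            "interval_95": (float(lo), float(hi)),
            "in_interval": bool(lo <= counts[key] <= hi),
        }
    return out


def colabel_calibration(n_runs: int = 50, seed_offset: int = 0) -> dict:
    """Marker-panel recovery across seeded simulations.

    Each run simulates a field of SAβGal+ cytomegalic cells, measures
    every co-label fraction, and checks it against the 99% binomial
    band of the configured probability.  Reports the share of
    (run, marker) checks inside their band.
    """
    probs = default_colabel_probs()
    ok = checks = 0
    per_marker = {m: [] for m in probs}
    for k in range(n_runs):
        cfg = CellSimConfig(seed=seed_offset + k, field_w_mm=2.0,
                            field_h_mm=1.5, dn_density_core_mm2=110.0,
                            dn_density_surround_mm2=110.0, bc_density_mm2=0.0,
                            normal_density_mm2=0.0, image_channels=())
        cells, _ = gen_cell_map(cfg)
        sab = cells[(cells["celltype"] == "dn_like") & (cells["SABGAL"] > 0)]
        n = len(sab)
        for m, p in probs.items():
            lo, hi = binom.interval(0.99, n, p)
            k_pos = int(sab[m].sum())
            ok += lo <= k_pos <= hi
            checks += 1
            per_marker[m].append(k_pos / n)
    return {
        "share_in_band": ok / checks,
        "n_runs": n_runs,
        "mean_fraction": {m: float(np.mean(v)) for m, v in per_marker.items()},
        "true_probability": probs,
    }


def treatment_effect_recovery(n_seeds: int = 10, seed_offset: int = 0) -> dict:
    """Image-based recovery of senolytic-style density reductions.

    Paired vehicle/treated fields are generated with 70% (pS6+) and 80%
    (SAβGal+) generative density reductions; each image is segmented and
    the estimated percentage reduction compared with truth.
    """
    seg = SegmentationParams(threshold_mode="fixed", threshold_value=0.5,
                             watershed=True, um_per_px=2.0)
    zones = {"core": box(0, 0, 2000, 2000)}
    area_mm2 = 4.0
    base = dict(field_w_mm=2.0, field_h_mm=2.0, um_per_px=2.0,
                bc_density_mm2=0.0, normal_density_mm2=0.0,
                dn_density_surround_mm2=0.0, image_channels=("pS6", "SABGAL"))
    results = {"pS6": [], "SABGAL": []}
    for k in range(n_seeds):
        veh = CellSimConfig(seed=seed_offset + 2 * k,
                            dn_density_core_mm2=100.0, **base)
        trt = CellSimConfig(seed=seed_offset + 2 * k + 1,
                            dn_density_core_mm2=30.0, **base)
        # SAβGal reduction of 80%: rendered from its own treated field
        trt_sab = CellSimConfig(seed=seed_offset + 2 * k + 1001,
                                dn_density_core_mm2=20.0, **base)
        imgs = {
            "veh": gen_cell_map(veh, zones=zones)[1],
            "trt_ps6": gen_cell_map(trt, zones=zones)[1],
            "trt_sab": gen_cell_map(trt_sab, zones=zones)[1],
        }

        def dens(img, channel):
            return cell_density(segment_cells(img.channel(channel), seg),
                                area_mm2)

        d_v_p = dens(imgs["veh"], "pS6")
        d_t_p = dens(imgs["trt_ps6"], "pS6")
        d_v_s = dens(imgs["veh"], "SABGAL")
        d_t_s = dens(imgs["trt_sab"], "SABGAL")
        results["pS6"].append(100.0 * (1 - d_t_p / d_v_p))
        results["SABGAL"].append(100.0 * (1 - d_t_s / d_v_s))
    return {
        "ps6_reduction_pct": float(np.mean(results["pS6"])),
        "sabgal_reduction_pct": float(np.mean(results["SABGAL"])),
        "ps6_true_pct": 70.0,
        "sabgal_true_pct": 80.0,
        "ps6_max_abs_err_pct":
            float(np.max(np.abs(np.asarray(results["pS6"]) - 70.0))),
        "sabgal_max_abs_err_pct":
            float(np.max(np.abs(np.asarray(results["SABGAL"]) - 80.0))),
    }


def seizure_freedom_after_treatment(seed: int = 0) -> dict:
    """Longitudinal study with complete response: all animals seizure-free.

    Simulates the within-animal design (pre / dosing / end / post) with
    a treatment multiplier of zero from the end of dosing, computes
    per-animal phase frequencies, and compares phases with the exact
    Mann-Whitney test.
    """
    cfg = EEGSimConfig(seed=seed, treatment_multiplier=0.0)
    study = gen_eeg_study(cfg)
    freq = (study.phase_daily_frequency()
            .pivot(index="animal", columns="phase", values="daily_frequency"))
    res = compare_phases(freq["pre"], freq["end"], freq["post"])
    return {
        "n_animals": cfg.n_animals,
        "all_seizure_free_post": all(res.seizure_free["post"]),
        "n_seizure_free_pre": int(np.sum(res.seizure_free["pre"])),
        "p_pre_vs_post": res.tests[("pre", "post")].p_two_sided,
        "pre_mean_per_day": res.stats["pre"].mean,
        "post_mean_per_day": res.stats["post"].mean,
    }


def eeg_detector_calibration(n_seeds: int = 10, fs_hz: float = 256.0,
                             duration_s: float = 400.0) -> dict:
    """Seizure-detector sensitivity and precision on rendered traces."""
    tp = n_true = n_det = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        onsets = np.sort(rng.uniform(30.0, duration_s - 40.0, size=4))
        onsets = onsets[np.diff(np.concatenate(([0.0], onsets))) > 25][:4]
        x, truth = gen_eeg_trace(duration_s, fs_hz, onsets, seed=seed)
        events = detect_seizures(x, fs_hz)
        n_true += len(truth)
        n_det += len(events)
        for a, b in truth:
            tp += any(min(b, e.t_offset_s) > max(a, e.t_onset_s)
                      for e in events)
    return {"sensitivity": tp / n_true, "precision": tp / n_det,
            "n_true": n_true}
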