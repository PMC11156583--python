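"""Generate the seeded synthetic study datasets used by every later step.

Produces one MEA slice recording on the study grid (4 x 4 electrodes,
2 x 2 discharge core, 3 min at 10 kHz), one histology cell map whose
zones are the electrode classes' Voronoi regions, and one longitudinal
EEG seizure study.  Ground-truth tables go to results/; the bulky raw
containers (HDF5 traces, TIFF image) go to scratch/.
"""

import argparse
from pathlib import Path

from epimap import io, study
from epimap.synth import (CellSimConfig, EEGSimConfig, gen_cell_map,
                          gen_eeg_study, gen_mea_recording)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    results = io.ensure_dir(ROOT / "results")
    scratch = io.ensure_dir(ROOT / "scratch")

    cfg = study.study_mea_config(seed)
    rec, truth = gen_mea_recording(cfg)
    io.write_recording(scratch / "recording.h5", rec)
    io.write_table(results / "mea_ground_truth.csv", truth.events)
    n_iild = (truth.events["kind"] == "IILD").sum()
    n_spk = (truth.events["kind"] == "MUA_SPIKE").sum()
    print(f"MEA recording: {rec.traces.shape[0]} channels x "
          f"{cfg.duration_s:.0f} s at {cfg.fs_hz:.0f} Hz "
          f"({rec.traces.nbytes / 1e6:.0f} MB)")
    print(f"  ground truth: {len(truth.network_iilds)} network discharges "
          f"({n_iild} channel-level IILDs, core only), {n_spk} spikes")

    ccfg = CellSimConfig(seed=seed, field_w_mm=4.0, field_h_mm=4.0,
                         bc_density_mm2=0.0)
    cells, img = gen_cell_map(ccfg, zones=study.study_zones())
    io.write_table(results / "cell_map.csv", cells)
    io.write_image(scratch / "histology.tif", img)
    dn = cells.query("celltype == 'dn_like' and pS6 > 0 and NeuN > 0")
    print(f"Cell map: {len(cells)} cells over {ccfg.field_w_mm:.0f} x "
          f"{ccfg.field_h_mm:.0f} mm, {len(dn)} countable dysmorphic neurons")

    ecfg = EEGSimConfig(seed=seed, treatment_multiplier=0.0)
    eeg_study = gen_eeg_study(ecfg)
    io.write_table(results / "eeg_study.csv", eeg_study.counts)
    total = eeg_study.counts["n_seizures"].sum()
    print(f"EEG study: {ecfg.n_animals} animals x "
          f"{eeg_study.counts['day'].nunique()} days, {total} seizures "
          f"(treatment multiplier {ecfg.treatment_multiplier})")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
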