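import numpy as np
import pytest
from shapely.ops import unary_union

from epimap.spatial import AffineTransform2D, MEALayout, voronoi_regions
from epimap.synth import MEASimConfig

# A 4 x 4 study grid used throughout the suite: a 2 x 2 discharge core,
# its remaining 8-neighbors as spiking surround, corners silent.
CORE = frozenset({5, 6, 9, 10})
SURROUND = frozenset({1, 2, 4, 7, 8, 11, 13, 14}) - CORE


@pytest.fixture(scope="session")
def small_layout() -> MEALayout:
    return MEALayout(rows=4, cols=4, pitch_h_um=1000.0, pitch_v_um=1000.0)


@pytest.fixture(scope="session")
def small_mea_cfg(small_layout) -> MEASimConfig:
    return MEASimConfig(
        seed=7, duration_s=60.0, layout=small_layout,
        core_electrodes=CORE, surround_electrodes=SURROUND,
    )


@pytest.fixture(scope="session")
def class_map() -> dict[int, str]:
    return {ch: ("IILD_MUA" if ch in CORE else
                 "MUA_ONLY" if ch in SURROUND else "SILENT")
            for ch in range(16)}


@pytest.fixture(scope="session")
def zone_geometries(small_layout):
    """Voronoi-cell unions of the core and surround electrodes."""
    bounds = (-500.0, -500.0, 3500.0, 3500.0)
    regs = voronoi_regions(small_layout, AffineTransform2D.identity(), bounds)
    return {
        "bounds": bounds,
        "core": unary_union([regs[c] for c in CORE]),
        "surround": unary_union([regs[c] for c in SURROUND]),
    }


def match_events(detected_times, true_times, tol_s):
    """Greedy one-to-one matching; returns (tp, n_true, n_detected)."""
    det = np.asarray(detected_times, dtype=float)
    used: set[int] = set()
    tp = 0
    for t in np.asarray(true_times, dtype=float):
        if det.size == 0:
            break
        d = np.abs(det - t)
        order = np.argsort(d)
        for j in order:
            if d[j] > tol_s:
                break
            if j not in used:
                used.add(int(j))
                tp += 1
                break
    return tp, len(true_times), det.size
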