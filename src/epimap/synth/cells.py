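"""Synthetic histology cell maps and multi-channel images.

Emulates the cellular topography of a dysplastic cortical field:
cytomegalic senescent (SAβGal+) dysmorphic-neuron-like cells at high
density in the electrophysiological core and low density in the
surround, balloon-cell-like cells confined to a gray-white boundary
strip, and a background of normal-sized cells everywhere.

Marker model.  Every cytomegalic cell is SAβGal+ and draws each marker
of the senescence/identity panel independently with the configured
co-label probability.  Because a dysmorphic neuron is *counted* as
pS6+ / NeuN+ / soma > 25 um, the generator places the core and
surround populations at density ``configured / (p_pS6 * p_NeuN)`` so
the expected density of the countable phenotype equals the configured
value.  Balloon-cell-like cells are pS6+ / NeuN- by definition and
draw the remaining panel markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from ..errors import ConfigurationError
from ..io import HistoImage

PANEL_MARKERS = ("P53", "P16", "SMI311", "VIM", "pS6", "NeuN", "P21",
                 "HMGB1_LOSS", "LAMINB1_LOSS")


def default_colabel_probs() -> dict[str, float]:
    """Fractions of SAβGal+ cytomegalic cells positive for each marker."""
    return {
        "P53": 0.92, "P16": 0.85, "SMI311": 0.88, "VIM": 0.95,
        "pS6": 0.89, "NeuN": 0.98, "P21": 0.81,
        "HMGB1_LOSS": 0.92, "LAMINB1_LOSS": 0.84,
    }


@dataclass(frozen=True)
class CellSimConfig:
    seed: int = 0
    field_w_mm: float = 4.0
    field_h_mm: float = 3.0
    um_per_px: float = 4.0
    dn_density_core_mm2: float = 53.6
    dn_density_surround_mm2: float = 11.7
    bc_density_mm2: float = 25.0
    bc_band_mm: tuple[float, float] | None = None  # (y_lo, y_hi); None: bottom 15%
    normal_density_mm2: float = 150.0
    cytomegalic_diam_um: tuple[float, float] = (32.0, 4.0)  # mean, sd; floor 25.5
    normal_diam_um: tuple[float, float] = (12.0, 2.0)
    colabel_probs: dict[str, float] = field(default_factory=default_colabel_probs)
    image_channels: tuple[str, ...] = ("SABGAL", "pS6", "NeuN")
    image_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.field_w_mm <= 0 or self.field_h_mm <= 0:
            raise ConfigurationError("field size must be positive")
        if self.um_per_px <= 0:
            raise ConfigurationError("um_per_px must be positive")
        for name, p in self.colabel_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {name} outside [0, 1]")
        for d in (self.dn_density_core_mm2, self.dn_density_surround_mm2,
                  self.bc_density_mm2, self.normal_density_mm2):
            if d < 0:
                raise ConfigurationError("densities must be non-negative")


def default_zones(cfg: CellSimConfig) -> dict:
    """Vertical thirds of the field: core | surround | silent (left to right)."""
    w = cfg.field_w_mm * 1e3
    h = cfg.field_h_mm * 1e3
    return {
        "core": box(0, 0, w / 3, h),
        "surround": box(w / 3, 0, 2 * w / 3, h),
        "silent": box(2 * w / 3, 0, w, h),
    }


def _sample_in(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a shapely geometry by rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    from shapely import contains_xy

    xmin, ymin, xmax, ymax = geom.bounds
    pts = np.empty((0, 2))
    while pts.shape[0] < n:
        m = max(64, 2 * (n - pts.shape[0]))
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(m, 2))
        cand = cand[contains_xy(geom, cand[:, 0], cand[:, 1])]
        pts = np.vstack([pts, cand])
    return pts[:n]


def gen_cell_map(cfg: CellSimConfig, zones: dict | None = None
                 ) -> tuple[pd.DataFrame, HistoImage]:
    """Simulate a cell table and its rasterized multi-channel image.

    ``zones`` maps "core" / "surround" (and optionally more labels) to
    shapely geometries in micrometres; cytomegalic cells are placed by a
    homogeneous Poisson process per zone.  Returns the ground-truth
    table (x_um, y_um, diam_um, celltype, one 0/1 column per marker)
    and the rasterized image (somata as unit-intensity disks per
    positive marker channel, plus Gaussian noise).
    """
    rng = np.random.default_rng(cfg.seed)
    zones = zones if zones is not None else default_zones(cfg)
    p = cfg.colabel_probs
    placement_factor = p.get("pS6", 1.0) * p.get("NeuN", 1.0)
    if placement_factor == 0:
        placement_factor = 1.0  # degenerate config: place at face value

    blocks = []

    def place(geom, density_mm2, celltype):
        area_mm2 = geom.area / 1e6
        n = rng.poisson(density_mm2 * area_mm2)
        xy = _sample_in(geom, n, rng)
        if celltype == "normal":
            diam = rng.normal(*cfg.normal_diam_um, size=n).clip(5.0, 24.0)
        else:
            diam = np.maximum(rng.normal(*cfg.cytomegalic_diam_um, size=n), 25.5)
        df = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1],
                           "diam_um": diam, "celltype": celltype})
        if celltype == "normal":
            df["SABGAL"] = 0
            for m in PANEL_MARKERS:
                df[m] = 0
            df["NeuN"] = (rng.random(n) < 0.8).astype(int)
        else:
            df["SABGAL"] = 1
            for m in PANEL_MARKERS:
                df[m] = (rng.random(n) < p.get(m, 0.0)).astype(int)
            if celltype == "bc_like":  # balloon cells: pS6+ / NeuN- by definition
                df["pS6"] = 1
                df["NeuN"] = 0
        blocks.append(df)

    for label, geom in zones.items():
        if label == "core":
            place(geom, cfg.dn_density_core_mm2 / placement_factor, "dn_like")
        elif label == "surround":
            place(geom, cfg.dn_density_surround_mm2 / placement_factor, "dn_like")

    field = box(0, 0, cfg.field_w_mm * 1e3, cfg.field_h_mm * 1e3)
    if cfg.bc_density_mm2 > 0:
        if cfg.bc_band_mm is None:
            y_lo = cfg.field_h_mm * 0.85
            y_hi = cfg.field_h_mm
        else:
            y_lo, y_hi = cfg.bc_band_mm
        band = box(0, y_lo * 1e3, cfg.field_w_mm * 1e3, y_hi * 1e3)
        place(band, cfg.bc_density_mm2, "bc_like")
    place(field, cfg.normal_density_mm2, "normal")

    cols = ["x_um", "y_um", "diam_um", "celltype", "SABGAL", *PANEL_MARKERS]
    cells = (pd.concat(blocks, ignore_index=True)[cols] if blocks
             else pd.DataFrame(columns=cols))
    return cells, rasterize_cells(cells, cfg, rng)


def rasterize_cells(cells: pd.DataFrame, cfg: CellSimConfig,
                    rng: np.random.Generator) -> HistoImage:
    """Draw each positive cell as a unit-intensity disk in its marker channels."""
    from skimage.draw import disk

    h = int(round(cfg.field_h_mm * 1e3 / cfg.um_per_px))
    w = int(round(cfg.field_w_mm * 1e3 / cfg.um_per_px))
    names = list(cfg.image_channels)
    img = np.zeros((len(names), h, w), dtype=np.float32)
    for _, c in cells.iterrows():
        rr_cc = None
        for k, name in enumerate(names):
            if c.get(name, 0) > 0:
                if rr_cc is None:
                    rr_cc = disk((c["y_um"] / cfg.um_per_px,
                                  c["x_um"] / cfg.um_per_px),
                                 max(1.0, c["diam_um"] / 2 / cfg.um_per_px),
                                 shape=(h, w))
                img[k][rr_cc] = 1.0
    if cfg.image_noise_sd > 0:
        img += rng.normal(0.0, cfg.image_noise_sd,
                          size=img.shape).astype(np.float32)
    return HistoImage(img, names, cfg.um_per_px)
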