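"""MEA geometry, landmark registration and cell-density maps.

The recording grid is a planar array of electrodes (default 10 x 12,
1,500 um horizontal by 1,000 um vertical pitch).  After a slice is
recorded it is immunostained, the stained image is registered onto the
recording-time image through manually picked anatomical landmarks, and
each electrode's activity class (discharge-bearing, spiking-only,
silent) is compared with the density of dysmorphic neurons around it.

Coordinates are micrometres; the y axis increases downward (image
convention).  The region claimed by an electrode is its Voronoi cell,
clipped to the histology field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram

from .errors import ConfigurationError, InputError

# Morphological gate for calling a dysmorphic neuron: cytomegalic soma.
DN_MIN_DIAM_UM = 25.0


@dataclass(frozen=True)
class MEALayout:
    """Planar electrode grid; channel indices are row-major from top-left."""

    rows: int = 10
    cols: int = 12
    pitch_h_um: float = 1500.0
    pitch_v_um: float = 1000.0
    electrode_diam_um: float = 30.0
    defective: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("layout needs at least one row and column")
        if self.pitch_h_um <= 0 or self.pitch_v_um <= 0:
            raise ConfigurationError("electrode pitches must be positive")
        object.__setattr__(self, "defective", frozenset(self.defective))
        if any(ch < 0 or ch >= self.n_channels for ch in self.defective):
            raise ConfigurationError("defective channels outside layout")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def row_col(self, channel: int) -> tuple[int, int]:
        if not 0 <= channel < self.n_channels:
            raise InputError(f"channel {channel} outside layout")
        return divmod(channel, self.cols)

    def are_adjacent(self, ch_a: int, ch_b: int) -> bool:
        """8-neighborhood adjacency on the grid (a channel is not its own neighbor)."""
        ra, ca = self.row_col(ch_a)
        rb, cb = self.row_col(ch_b)
        return ch_a != ch_b and abs(ra - rb) <= 1 and abs(ca - cb) <= 1


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map layout um -> image um: x_img = A @ x_layout + t."""

    linear: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    rms_residual_um: float = 0.0

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        off = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(lin)) <= 1e-12:
            raise ConfigurationError("affine linear part is singular")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "offset", off)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.offset)


@dataclass(frozen=True)
class DensityByClass:
    """Per-activity-class cell counts and densities (cells per mm^2)."""

    region_area_mm2: dict[str, float]
    n_cells: dict[str, int]
    density_per_mm2: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        classes = sorted(self.region_area_mm2)
        return pd.DataFrame({
            "cls": classes,
            "region_area_mm2": [self.region_area_mm2[c] for c in classes],
            "n_cells": [self.n_cells[c] for c in classes],
            "density_per_mm2": [self.density_per_mm2[c] for c in classes],
        })


def electrode_positions(layout: MEALayout) -> dict[int, tuple[float, float]]:
    """Channel -> (x_um, y_um), row-major grid with origin at the top-left electrode."""
    pos = {}
    for ch in range(layout.n_channels):
        r, c = layout.row_col(ch)
        pos[ch] = (c * layout.pitch_h_um, r * layout.pitch_v_um)
    return pos


def fit_affine(pairs) -> AffineTransform2D:
    """Least-squares affine from (layout_pt, image_pt) landmark pairs.

    Requires at least three non-collinear layout points.  The fit is
    exact (zero residual) whenever the pairs are affine-consistent.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InputError("affine registration needs >= 3 landmark pairs")
    src = np.asarray([p[0] for p in pairs], dtype=float)
    dst = np.asarray([p[1] for p in pairs], dtype=float)
    design = np.column_stack([src, np.ones(len(pairs))])
    if np.linalg.matrix_rank(design) < 3:
        raise InputError("landmarks are collinear; affine underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    linear = coef[:2].T
    offset = coef[2]
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(linear, offset, rms_residual_um=rms)


def voronoi_regions(
    layout: MEALayout,
    transform: AffineTransform2D,
    field_bounds_um: tuple[float, float, float, float],
):
    """Voronoi cell (shapely polygon) of each non-defective electrode in image space.

    ``field_bounds_um`` is (xmin, ymin, xmax, ymax) of the histology
    field; every cell is clipped to it.  Returns channel -> polygon.
    """
    pos = electrode_positions(layout)
    channels = [ch for ch in sorted(pos) if ch not in layout.defective]
    pts_img = transform.apply([pos[ch] for ch in channels])
    clip = box(*field_bounds_um)
    if len(channels) == 1:
        return {channels[0]: clip}
    cells = voronoi_diagram(MultiPoint(pts_img.tolist()), envelope=clip)
    # voronoi_diagram does not preserve input order; match by containment
    regions = {}
    tree = cKDTree(pts_img)
    for poly in cells.geoms:
        d, i = tree.query(poly.representative_point().coords[0])
        # representative point of a Voronoi cell is nearest to its seed
        regions[channels[i]] = poly.intersection(clip)
    return regions


def is_dysmorphic(cells: pd.DataFrame) -> np.ndarray:
    """Dysmorphic-neuron mask: pS6+ and NeuN+ with soma diameter > 25 um.

    Balloon cells (pS6+ / NeuN-) do not qualify.
    """
    required = {"pS6", "NeuN", "diam_um"}
    missing = required - set(cells.columns)
    if missing:
        raise InputError(f"cell table lacks columns: {sorted(missing)}")
    return (
        (cells["pS6"].to_numpy() > 0)
        & (cells["NeuN"].to_numpy() > 0)
        & (cells["diam_um"].to_numpy() > DN_MIN_DIAM_UM)
    )


def density_by_class(
    cells: pd.DataFrame,
    activity,
    layout: MEALayout,
    transform: AffineTransform2D,
    field_bounds_um: tuple[float, float, float, float] | None = None,
    cell_filter=is_dysmorphic,
) -> DensityByClass:
    """Dysmorphic-neuron density per electrode-activity class.

    ``cells`` is a table with image-space ``x_um``/``y_um`` coordinates,
    ``diam_um`` and 0/1 marker columns.  ``activity`` maps channel ->
    class label (or is a list of objects with ``channel``/``cls``
    attributes, as produced by event detection).  Each non-defective
    electrode claims its Voronoi cell clipped to the field; class
    regions are unions of same-class cells.  Qualifying cells (by
    ``cell_filter``, default the dysmorphic-neuron gate) are assigned
    to their nearest electrode, which is exactly the Voronoi partition,
    so no cell is counted twice.
    """
    cls_by_channel = _as_class_map(activity)
    non_def = [ch for ch in range(layout.n_channels) if ch not in layout.defective]
    missing = set(non_def) - set(cls_by_channel)
    if not cls_by_channel:
        raise InputError("activity classification is empty")
    if missing:
        raise InputError(f"activity missing for channels: {sorted(missing)[:5]}...")

    if field_bounds_um is None:
        xs = cells["x_um"].to_numpy(dtype=float)
        ys = cells["y_um"].to_numpy(dtype=float)
        field_bounds_um = (xs.min(), ys.min(), xs.max(), ys.max())

    regions = voronoi_regions(layout, transform, field_bounds_um)
    channels = sorted(regions)
    area_mm2 = {c: 0.0 for c in set(cls_by_channel.values())}
    for ch in channels:
        area_mm2[cls_by_channel[ch]] += regions[ch].area / 1e6  # um^2 -> mm^2

    keep = np.asarray(cell_filter(cells), dtype=bool)
    xy = cells.loc[keep, ["x_um", "y_um"]].to_numpy(dtype=float)
    counts = {c: 0 for c in area_mm2}
    if xy.size:
        xmin, ymin, xmax, ymax = field_bounds_um
        inside = (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
            & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )
        xy = xy[inside]
    if xy.size:
        pos = electrode_positions(layout)
        pts_img = transform.apply([pos[ch] for ch in channels])
        _, nearest = cKDTree(pts_img).query(xy)
        for i in nearest:
            counts[cls_by_channel[channels[i]]] += 1

    density = {
        c: (counts[c] / area_mm2[c]) if area_mm2[c] > 0 else float("nan")
        for c in area_mm2
    }
    return DensityByClass(area_mm2, counts, density)


def _as_class_map(activity) -> dict[int, str]:
    if isinstance(activity, dict):
        return {int(k): str(v) for k, v in activity.items()}
    out = {}
    for item in activity:
        out[int(item.channel)] = str(item.cls)
    return out
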