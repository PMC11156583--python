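"""Histology image quantification: segmentation, co-labeling, mutant load.

Cell counting follows the slide-quantification recipe used for
colorimetric senescence assays: threshold the staining channel (a fixed
transferable cut, or Otsu), optionally split touching somata by
watershed, keep connected components larger than 25 px^2, and report
counts per mm^2.  Co-label fractions (e.g. the share of SAβGal+ cells
that are p53+) come with exact Clopper-Pearson intervals.  Variant
allele frequency from microdissected cells converts to a mutant-cell
fraction under the heterozygosity assumption (fraction = 2 x VAF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import beta
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class SegmentationParams:
    threshold_mode: str = "fixed"  # "fixed" | "otsu"
    threshold_value: float = 0.5
    min_area_px2: float = 25.0
    watershed: bool = False
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ParameterError("threshold_mode must be 'fixed' or 'otsu'")
        if self.min_area_px2 < 0:
            raise ParameterError("min_area_px2 must be >= 0")
        if self.um_per_px <= 0:
            raise ParameterError("um_per_px must be positive")


@dataclass
class CellObject:
    """A segmented object with physical centroid and marker calls."""

    x_um: float
    y_um: float
    area_px2: float
    equiv_diam_um: float
    marker_pos: dict[str, int] = field(default_factory=dict)
    marker_mean: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ColabelResult:
    ref_marker: str
    test_marker: str
    n_ref: int
    n_double: int
    fraction: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_double > self.n_ref:
            raise InputError("double-positive count exceeds reference count")


@dataclass(frozen=True)
class MutantLoad:
    vaf: float
    cell_fraction: float
    heterozygous_consistent: bool


def segment_cells(image: np.ndarray, params: SegmentationParams,
                  marker_channels: dict[str, np.ndarray] | None = None
                  ) -> list[CellObject]:
    """Segment somata in a single staining channel.

    Threshold -> binarize -> optional distance-transform watershed ->
    8-connected components -> discard objects with area <= min_area_px2.
    When ``marker_channels`` is given, each object is called positive
    for a marker when its mean intensity in that channel exceeds the
    channel's Otsu cut.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InputError("expected a non-empty single-channel 2-D image")
    if params.threshold_mode == "fixed":
        cut = params.threshold_value
    else:
        cut = threshold_otsu(img)
    binary = img > cut
    if not binary.any():
        return []

    if params.watershed:
        dist = ndi.distance_transform_edt(binary)
        min_dist = max(2, int(round(np.sqrt(max(params.min_area_px2, 1) / np.pi))))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=binary,
                               exclude_border=False)
        markers = np.zeros_like(img, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = label(binary, connectivity=2)
        else:
            labels = watershed(-dist, markers, mask=binary, connectivity=2)
    else:
        labels = label(binary, connectivity=2)

    marker_cuts = {}
    if marker_channels:
        for name, ch in marker_channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != img.shape:
                raise InputError(f"marker channel {name!r} shape mismatch")
            marker_cuts[name] = threshold_otsu(ch)

    out = []
    for rp in regionprops(labels):
        if rp.area <= params.min_area_px2:
            continue
        cy, cx = rp.centroid
        area_um2 = rp.area * params.um_per_px**2
        obj = CellObject(
            x_um=cx * params.um_per_px,
            y_um=cy * params.um_per_px,
            area_px2=float(rp.area),
            equiv_diam_um=2.0 * np.sqrt(area_um2 / np.pi),
        )
        if marker_channels:
            rr, cc = rp.coords[:, 0], rp.coords[:, 1]
            for name, ch in marker_channels.items():
                mean = float(np.asarray(ch, dtype=float)[rr, cc].mean())
                obj.marker_mean[name] = mean
                obj.marker_pos[name] = int(mean > marker_cuts[name])
        out.append(obj)
    return out


def _marker_flags(cells, marker: str) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        if marker not in cells.columns:
            raise InputError(f"no marker column {marker!r}")
        return cells[marker].to_numpy() > 0
    flags = []
    for c in cells:
        if marker not in c.marker_pos:
            raise InputError(f"cell lacks marker call {marker!r}")
        flags.append(c.marker_pos[marker] > 0)
    return np.asarray(flags, dtype=bool)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n <= 0:
        raise InputError("n must be positive")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def colabel_fraction(cells, ref_marker: str, test_marker: str) -> ColabelResult:
    """Fraction of ref-positive cells also positive for the test marker.

    ``cells`` is a list of :class:`CellObject` or a table with 0/1
    marker columns.  Raises when no cell is ref-positive (the fraction
    is undefined).
    """
    ref = _marker_flags(cells, ref_marker)
    test = _marker_flags(cells, test_marker)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise InputError(f"no cells positive for {ref_marker!r}; "
                         "co-label fraction undefined")
    n_double = int((ref & test).sum())
    return ColabelResult(ref_marker, test_marker, n_ref, n_double,
                         n_double / n_ref, clopper_pearson(n_double, n_ref))


def mutant_cell_fraction(vaf: float) -> MutantLoad:
    """Mutant-cell fraction implied by a VAF under heterozygosity.

    Each mutant cell carries one variant allele out of two, so the
    fraction of mutant cells is min(1, 2 x VAF).  A VAF above 0.5 is
    inconsistent with a purely heterozygous variant and is flagged.
    """
    if not 0.0 <= vaf <= 1.0:
        raise InputError("VAF must lie in [0, 1]")
    consistent = vaf <= 0.5
    if not consistent:
        warnings.warn(f"VAF {vaf} exceeds 0.5: inconsistent with a "
                      "heterozygous variant", stacklevel=2)
    return MutantLoad(vaf, min(1.0, 2.0 * vaf), consistent)


def cell_density(cells, roi_area_mm2: float) -> float:
    """Cells per mm^2 in a region of interest."""
    if roi_area_mm2 <= 0:
        raise ParameterError("ROI area must be positive")
    n = len(cells) if not isinstance(cells, pd.DataFrame) else len(cells.index)
    return n / roi_area_mm2
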