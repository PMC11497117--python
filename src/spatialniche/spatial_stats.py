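"""Region-level descriptive spatial statistics.

Density grids, per-region composition percentages, immune-desert calling
(CD8+ density < 100 cells/mm^2), cross-type nearest-neighbor gap distances,
Pearson correlation, and the caliper tumor-volume formula used in
preclinical work (short^2 x long / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

UM2_PER_MM2 = 1e6

REGION_LABELS = (
    "lymphoid_aggregate",
    "large_tumor_nest",
    "tumor_core",
    "satellite",
    "edge_NOS2pos",
    "edge_NOS2neg",
    "stroma",
    "immune_desert",
)

#: assignment priority when annotations overlap (first wins)
REGION_PRIORITY = (
    "lymphoid_aggregate",
    "satellite",
    "edge_NOS2pos",
    "edge_NOS2neg",
    "large_tumor_nest",
    "tumor_core",
    "immune_desert",
    "stroma",
)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labeled simple polygon (vertices in μm)."""

    label: str
    polygon: Polygon

    def __post_init__(self):
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"invalid polygon for region {self.label!r}")

    @property
    def area_mm2(self) -> float:
        return self.polygon.area / UM2_PER_MM2


def density_grid(
    cells: pd.DataFrame,
    selector: np.ndarray | None = None,
    bin_size_um: float = 100.0,
    bounds=None,
):
    """Grid of cell densities (cells/mm^2) for a selected subset.

    ``selector`` is a boolean mask over rows (default: all cells).  Returns
    ``(grid, x_edges, y_edges)``; total count is conserved:
    ``grid.sum() * bin_area_mm2 == n selected``.
    """
    if bin_size_um <= 0:
        raise ValueError("bin_size_um must be > 0")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    if selector is None:
        selector = np.ones(len(cells), bool)
    sel = xy[np.asarray(selector, bool)]
    if bounds is None:
        if len(xy) == 0:
            raise ValueError("no cells and no bounds given")
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
    else:
        xmin, ymin, xmax, ymax = bounds
    x_edges = np.arange(xmin, xmax + bin_size_um, bin_size_um)
    y_edges = np.arange(ymin, ymax + bin_size_um, bin_size_um)
    if len(sel) == 0:
        warnings.warn("density_grid: empty selection, all-zero grid")
        counts = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    else:
        counts, _, _ = np.histogram2d(
            sel[:, 0], sel[:, 1], bins=(x_edges, y_edges)
        )
    area_mm2 = bin_size_um**2 / UM2_PER_MM2
    return counts / area_mm2, x_edges, y_edges


def assign_regions(
    cells: pd.DataFrame, annotations: list
) -> np.ndarray:
    """Region label per cell (boundary-inclusive point-in-polygon).

    Overlaps resolve by :data:`REGION_PRIORITY` (a warning is emitted when
    any cell matches more than one annotation).  Cells in no region get
    the empty string.
    """
    order = sorted(
        annotations, key=lambda a: REGION_PRIORITY.index(a.label)
    )
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    out = np.full(len(cells), "", dtype=object)
    hits = np.zeros(len(cells), int)
    for ann in order:
        prepared = prep(ann.polygon)
        inside = np.array(
            [prepared.intersects(Point(x, y)) for x, y in xy]
        )
        hits += inside
        fresh = inside & (out == "")
        out[fresh] = ann.label
    if (hits > 1).any():
        warnings.warn(
            f"{int((hits > 1).sum())} cells fall in overlapping annotations; "
            "assigned by priority order"
        )
    return out


def region_percentages(
    cells: pd.DataFrame,
    annotations: list,
    selector: np.ndarray,
) -> pd.Series:
    """Per-region percentage of cells satisfying ``selector``.

    The denominator is region-local (all cells assigned to the region).
    Regions containing zero cells are reported as NaN (missing), not 0.
    """
    labels = assign_regions(cells, annotations)
    selector = np.asarray(selector, bool)
    out = {}
    for ann in annotations:
        in_region = labels == ann.label
        n = in_region.sum()
        out[ann.label] = (
            100.0 * (selector & in_region).sum() / n if n else np.nan
        )
    return pd.Series(out, name="percent")


def immune_desert_call(
    cells: pd.DataFrame,
    region: RegionAnnotation,
    cd8_positive: np.ndarray,
    threshold: float = 100.0,
) -> bool:
    """True iff the region's CD8+ density is strictly below ``threshold``
    (default 100 cells/mm^2, the immune-desert definition)."""
    if region.area_mm2 <= 0:
        raise ValueError("zero-area region")
    labels = assign_regions(cells, [region])
    n_cd8 = int((np.asarray(cd8_positive, bool) & (labels == region.label)).sum())
    return n_cd8 / region.area_mm2 < threshold


def crosstype_nn_gap(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict:
    """Nearest-neighbor distance from each A cell to the B point set.

    Returns ``{"mean", "median", "distances"}`` in μm.  Not symmetric in
    its arguments.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both cell sets must be nonempty")
    a = set_a[["x_um", "y_um"]].to_numpy(float)
    b = set_b[["x_um", "y_um"]].to_numpy(float)
    d, _ = cKDTree(b).query(a)
    return {
        "mean": float(np.mean(d)),
        "median": float(np.median(d)),
        "distances": d,
    }


def pearson_r2(x, y):
    """Pearson r, R^2 and two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def tumor_volume(short_diameter_mm: float, long_diameter_mm: float) -> float:
    """Caliper tumor volume in mm^3: short^2 * long / 2."""
    if not 0 < short_diameter_mm <= long_diameter_mm:
        raise ValueError(
            "require 0 < short <= long (measurements may be swapped)"
        )
    return short_diameter_mm**2 * long_diameter_mm / 2.0
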