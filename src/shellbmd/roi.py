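"""Polygonal ROI extraction, summary statistics, side comparison and
exclusion bookkeeping.

ROIs are planar polygons in physical mm on a named plane (sagittal,
dorsal or transverse) at a fixed slice index.  Rasterization selects
the pixels whose *centers* are covered by the polygon (even-odd rule;
centers exactly on an edge are included), so pixel counts are
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .rank_tests import wilcoxon_rank_sum
from .volumes import BMDMap, PLANE_AXIS, pixel_centers_mm

__all__ = [
    "ROI",
    "ROIStats",
    "SiteMeasurement",
    "HistogramSummary",
    "SideComparison",
    "ExclusionReport",
    "rasterize_roi",
    "extract_roi_values",
    "summarize_roi",
    "compare_sides",
    "apply_exclusions",
    "histogram",
    "DegeneratePolygonError",
]

SITES = ("gular", "ilium", "scapula")
PAIRED_SITES = ("ilium", "scapula")
SIDES = ("left", "right", "none")

#: per-animal measurement plan: gular x1 (unpaired), scapula and ilium x2
SITE_PLAN = (
    ("gular", "none"),
    ("scapula", "left"),
    ("scapula", "right"),
    ("ilium", "left"),
    ("ilium", "right"),
)


class DegeneratePolygonError(ValueError):
    """Polygon has fewer than 3 vertices, zero area, or self-intersects."""


@dataclass
class ROI:
    """One polygonal region at one anatomical site/side of one animal."""

    animal_id: int | str
    site: str               # gular | scapula | ilium
    side: str               # left | right | none
    plane: str              # sagittal | dorsal | transverse
    slice_index: int
    polygon_mm: list[tuple[float, float]]   # in-plane vertices, mm

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.plane not in PLANE_AXIS:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.site == "gular" and self.side != "none":
            raise ValueError("gular ROIs are unpaired (side must be 'none')")
        if self.site in PAIRED_SITES and self.side == "none":
            raise ValueError(f"{self.site} ROIs are paired (side left/right)")
        self.polygon_mm = [(float(u), float(v)) for u, v in self.polygon_mm]

    def shapely_polygon(self) -> shapely.Polygon:
        if len(self.polygon_mm) < 3:
            raise DegeneratePolygonError("polygon needs at least 3 vertices")
        poly = shapely.Polygon(self.polygon_mm)
        if poly.area == 0:
            raise DegeneratePolygonError("polygon has zero area")
        if not poly.is_valid:
            raise DegeneratePolygonError("polygon is self-intersecting")
        return poly


@dataclass(frozen=True)
class ROIStats:
    """Summary of one ROI's pixel population (mgHA/cm^3).

    Percentiles use linear interpolation between order statistics; SD is
    the sample (n-1) convention (0 for a single pixel).
    """

    mean: float
    median: float
    sd: float
    minimum: float
    maximum: float
    p1: float
    p99: float
    pixel_count: int
    voxel_volume_mm3: float
    total_volume_mm3: float


@dataclass
class SiteMeasurement:
    """One site/side measurement of one animal, with exclusion status."""

    animal_id: int | str
    site: str
    side: str
    pixel_values: np.ndarray
    stats: ROIStats | None = None
    status: str = "retained"    # retained | missing_motion | excluded_side_difference
    exclusion_p: float | None = None
    roi: ROI | None = None

    def __post_init__(self):
        self.pixel_values = np.asarray(self.pixel_values, dtype=float)
        if self.status == "retained" and self.pixel_values.size == 0:
            raise ValueError("retained measurements must carry pixel values")


@dataclass(frozen=True)
class HistogramSummary:
    bin_edges: np.ndarray           # mgHA/cm^3, strictly increasing
    normalized_counts: np.ndarray   # sums to 1


@dataclass(frozen=True)
class SideComparison:
    """Outcome of one left/right comparison."""

    outcome: str            # pooled | excluded | single
    p: float | None
    values: np.ndarray      # pooled (or single-side) retained pixel values


@dataclass
class ExclusionReport:
    planned: int
    obtained: int
    retained: int
    missing: list[tuple]
    excluded: list[tuple]
    warnings: list[str] = field(default_factory=list)


def rasterize_roi(roi: ROI, bmd_map: BMDMap) -> np.ndarray:
    """Indices (N x 3 int array) of voxels whose pixel centers the ROI covers.

    Pixel centers on the ROI's slice are tested against the polygon with
    boundary included.  Raises on degenerate polygons and out-of-bounds
    slice indices.
    """
    poly = roi.shapely_polygon()
    axis = PLANE_AXIS[roi.plane]
    if not (0 <= roi.slice_index < bmd_map.shape[axis]):
        raise IndexError(
            f"slice {roi.slice_index} outside map extent {bmd_map.shape[axis]} on axis {axis}"
        )
    in_plane, cu, cv = pixel_centers_mm(
        bmd_map.shape, bmd_map.spacing_mm, bmd_map.origin_mm, roi.plane
    )
    # restrict to the polygon bounding box for speed
    minu, minv, maxu, maxv = poly.bounds
    iu = np.nonzero((cu >= minu - 1e-9) & (cu <= maxu + 1e-9))[0]
    iv = np.nonzero((cv >= minv - 1e-9) & (cv <= maxv + 1e-9))[0]
    if iu.size == 0 or iv.size == 0:
        return np.empty((0, 3), dtype=int)
    UU, VV = np.meshgrid(cu[iu], cv[iv], indexing="ij")
    pts = shapely.points(UU.ravel(), VV.ravel())
    inside = shapely.covers(poly, pts).reshape(UU.shape)  # covers includes boundary
    su, sv = np.nonzero(inside)
    idx = np.empty((su.size, 3), dtype=int)
    idx[:, in_plane[0]] = iu[su]
    idx[:, in_plane[1]] = iv[sv]
    idx[:, axis] = roi.slice_index
    return idx


def extract_roi_values(roi: ROI, bmd_map: BMDMap) -> np.ndarray:
    """Pixel values of the map inside the ROI (rasterization order)."""
    idx = rasterize_roi(roi, bmd_map)
    return bmd_map.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]


def summarize_roi(values, voxel_volume_mm3: float = 1.0) -> ROIStats:
    """Mean/median/SD/min/max/percentile summary of an ROI pixel population."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty pixel population")
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    p1, med, p99 = np.percentile(v, [1, 50, 99])
    return ROIStats(
        mean=float(v.mean()),
        median=float(med),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        minimum=float(v.min()),
        maximum=float(v.max()),
        p1=float(p1),
        p99=float(p99),
        pixel_count=int(v.size),
        voxel_volume_mm3=float(voxel_volume_mm3),
        total_volume_mm3=float(v.size * voxel_volume_mm3),
    )


def compare_sides(left, right, alpha_side: float = 1e-4) -> SideComparison:
    """Left/right consistency gate for paired sites.

    Two-sided Wilcoxon rank-sum on the pixel values.  A difference at
    ``p <= alpha_side`` flags a measurement inconsistency and excludes
    both sides; otherwise the sides are pooled into one population.  A
    missing side passes the present one through untested (``single``).
    """
    left = None if left is None else np.asarray(left, dtype=float)
    right = None if right is None else np.asarray(right, dtype=float)
    if left is None and right is None:
        raise ValueError("at least one side must be present")
    if left is None or right is None:
        present = left if right is None else right
        return SideComparison(outcome="single", p=None, values=present)
    _, p = wilcoxon_rank_sum(left, right)
    if p <= alpha_side:
        return SideComparison(outcome="excluded", p=p, values=np.empty(0))
    return SideComparison(outcome="pooled", p=p, values=np.concatenate([left, right]))


def apply_exclusions(
    measurements: list[SiteMeasurement],
    missing_sites: list[tuple],
    side_results: dict | None = None,
) -> tuple[ExclusionReport, list[SiteMeasurement]]:
    """Site accounting: planned -> obtained -> retained.

    ``measurements`` are the obtained (non-missing) site measurements;
    ``missing_sites`` lists ``(animal_id, site, side)`` slots lost to
    motion artifacts; ``side_results`` maps ``(animal_id, site)`` to a
    :class:`SideComparison` (or a bare p-value interpreted as an
    exclusion).  Excluded measurements are flagged in place; the
    retained set feeds all downstream statistics.

    planned = 5 sites per animal over every animal seen in either list;
    obtained = planned - missing; retained = obtained - side-excluded.
    """
    missing = [tuple(m) for m in missing_sites]
    if len(set(missing)) != len(missing):
        raise ValueError("missing_sites contains a double-listed site")
    obtained_keys = [(m.animal_id, m.site, m.side) for m in measurements]
    if len(set(obtained_keys)) != len(obtained_keys):
        raise ValueError("measurements contain a double-listed site")
    overlap = set(missing) & set(obtained_keys)
    if overlap:
        raise ValueError(f"sites listed both missing and measured: {sorted(overlap)}")

    animals = {m.animal_id for m in measurements} | {m[0] for m in missing}
    planned = 5 * len(animals)
    obtained = len(measurements)
    warnings_list = []
    if obtained + len(missing) != planned:
        warnings_list.append(
            f"obtained ({obtained}) + missing ({len(missing)}) != planned ({planned})"
        )

    side_results = side_results or {}
    excluded_keys = []
    for (animal_id, site), result in side_results.items():
        if isinstance(result, SideComparison):
            if result.outcome != "excluded":
                continue
            p = result.p
        else:
            p = float(result)
        for m in measurements:
            if m.animal_id == animal_id and m.site == site:
                m.status = "excluded_side_difference"
                m.exclusion_p = p
                excluded_keys.append((m.animal_id, m.site, m.side))

    retained = [m for m in measurements if m.status == "retained"]
    if not retained:
        warnings_list.append("no measurements retained")
    for msg in warnings_list:
        warnings.warn(msg, stacklevel=2)
    report = ExclusionReport(
        planned=planned,
        obtained=obtained,
        retained=len(retained),
        missing=missing,
        excluded=excluded_keys,
        warnings=warnings_list,
    )
    return report, retained


def histogram(values, bin_width: float = 25.0) -> HistogramSummary:
    """Fixed-width normalized histogram from 0 to ceil(max/width)*width."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot histogram an empty pixel population")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = max(1.0, np.ceil(v.max() / bin_width)) * bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    return HistogramSummary(bin_edges=edges, normalized_counts=counts / v.size)
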