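"""Scoring cluster positions against traced dendritic-spine perimeters.

A dendritic segment is described by its length (µm) and a list of spines,
each traced as a *total perimeter* polygon optionally containing a smaller
*spine head* polygon. Stubby spines lack a distinct head and carry only the
total perimeter. A cluster centroid is scored as:

* ``shaft`` — outside every spine's total perimeter;
* ``head`` — inside a spine's head perimeter;
* ``base_neck`` — inside a spine's total perimeter but outside its head;
* ``all`` — inside a stubby spine (no head traced; the cluster could be
  anywhere in head/base/neck, so it is scored as "all").

The geometry is traced from the membrane channel alone and this module
never reads cluster-channel intensities — classification is a pure
point-in-polygon decision, which keeps the scoring blind to the protein
signal by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .clusters import ClusterSet
from .exceptions import AmbiguousLocationWarning, PlausibilityWarning

__all__ = [
    "Spine",
    "SpineGeometry",
    "SpineLocalizationSummary",
    "classify_cluster_location",
    "summarize_spine_localization",
    "check_plausibility",
]

CATEGORIES = ("shaft", "head", "base_neck", "all")


@dataclass(frozen=True)
class Spine:
    """One traced spine: total perimeter and, unless stubby, a head perimeter."""

    total_perimeter: np.ndarray  # (n, 2) polygon vertices, (x, y)
    head_perimeter: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_perimeter", np.asarray(self.total_perimeter, float))
        if self.head_perimeter is not None:
            head = np.asarray(self.head_perimeter, float)
            object.__setattr__(self, "head_perimeter", head)
            if not self.total_polygon.buffer(1e-9).covers(shapely.Polygon(head)):
                raise ValueError("head perimeter must lie inside the total perimeter")

    @property
    def total_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.total_perimeter)

    @property
    def head_polygon(self) -> shapely.Polygon | None:
        return None if self.head_perimeter is None else shapely.Polygon(self.head_perimeter)

    @property
    def is_stubby(self) -> bool:
        return self.head_perimeter is None


@dataclass(frozen=True)
class SpineGeometry:
    """A dendritic segment's length and its traced spine perimeters."""

    segment_length_um: float
    spines: list[Spine]
    pixel_size_um: float = 0.11

    def __post_init__(self) -> None:
        if self.segment_length_um <= 0:
            raise ValueError("segment_length_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_spines(self) -> int:
        return len(self.spines)


def check_plausibility(geometry: SpineGeometry) -> None:
    """Warn when a segment is outside the typical traced-CA1 ranges.

    Manually traced apical-dendrite segments typically span 30–70 µm and
    carry 30–80 spines; values outside those ranges are legal (synthetic
    fixtures are deliberately small) but worth flagging on real data.
    """
    if not 30 <= geometry.segment_length_um <= 70:
        warnings.warn(
            f"segment length {geometry.segment_length_um:.1f} µm outside the "
            "typical 30-70 µm tracing range",
            PlausibilityWarning,
            stacklevel=2,
        )
    if not 30 <= geometry.n_spines <= 80:
        warnings.warn(
            f"{geometry.n_spines} spines outside the typical 30-80 range",
            PlausibilityWarning,
            stacklevel=2,
        )


def classify_cluster_location(
    centroid: tuple[float, float], geometry: SpineGeometry
) -> str:
    """Score one cluster centroid as shaft / head / base_neck / all.

    Point-in-polygon tests are boundary inclusive. If overlapping spine
    tracings both contain the centroid, the spine whose perimeter centroid
    is nearest wins and an :class:`AmbiguousLocationWarning` is emitted.
    """
    point = shapely.Point(*centroid)
    containing = [s for s in geometry.spines if s.total_polygon.covers(point)]
    if not containing:
        return "shaft"
    if len(containing) > 1:
        warnings.warn(
            f"centroid {tuple(np.round(centroid, 2))} lies inside "
            f"{len(containing)} spine perimeters; using the nearest",
            AmbiguousLocationWarning,
            stacklevel=2,
        )
        containing.sort(key=lambda s: point.distance(s.total_polygon.centroid))
    spine = containing[0]
    if spine.is_stubby:
        return "all"
    return "head" if spine.head_polygon.covers(point) else "base_neck"


@dataclass(frozen=True)
class SpineLocalizationSummary:
    """Per-segment cluster density and shaft/spine distribution.

    ``fraction_shaft + fraction_spine = 1`` over all clusters, and
    ``fraction_head + fraction_base_neck + fraction_all = 1`` over the
    spine-located clusters (NaN when there are none).
    """

    n_clusters: int
    cluster_density_per_um: float
    pct_spines_with_cluster: float
    fraction_shaft: float
    fraction_spine: float
    fraction_head: float
    fraction_base_neck: float
    fraction_all: float
    category_counts: dict[str, int]


def _centroids(clusters) -> np.ndarray:
    if isinstance(clusters, ClusterSet):
        return clusters.centroids()
    arr = np.asarray(clusters, dtype=float)
    return arr.reshape(0, 2) if arr.size == 0 else arr


def summarize_spine_localization(clusters, geometry: SpineGeometry) -> SpineLocalizationSummary:
    """Density, % spines occupied, and the shaft/head/base-neck split.

    ``clusters`` may be a :class:`ClusterSet` or an (n, 2) array of
    centroid coordinates. Density is clusters per µm of segment;
    ``pct_spines_with_cluster`` counts spines whose total perimeter
    contains at least one centroid.
    """
    pts = _centroids(clusters)
    counts = dict.fromkeys(CATEGORIES, 0)
    for xy in pts:
        counts[classify_cluster_location(tuple(xy), geometry)] += 1
    n = len(pts)
    n_spine = counts["head"] + counts["base_neck"] + counts["all"]

    occupied = 0
    if len(pts) and geometry.spines:
        points = shapely.points(pts)
        for spine in geometry.spines:
            if shapely.covers(spine.total_polygon, points).any():
                occupied += 1
    pct_occupied = 100.0 * occupied / geometry.n_spines if geometry.spines else float("nan")

    def frac(k: int, d: int) -> float:
        return k / d if d else float("nan")

    return SpineLocalizationSummary(
        n_clusters=n,
        cluster_density_per_um=n / geometry.segment_length_um,
        pct_spines_with_cluster=pct_occupied,
        fraction_shaft=frac(counts["shaft"], n),
        fraction_spine=frac(n_spine, n),
        fraction_head=frac(counts["head"], n_spine),
        fraction_base_neck=frac(counts["base_neck"], n_spine),
        fraction_all=frac(counts["all"], n_spine),
        category_counts=counts,
    )
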