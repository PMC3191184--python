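"""Punctate cluster detection and PDM-particle-based percent colocalization.

The "% of clusters containing correlated signal" statistic is computed by
(1) detecting clusters in the (background-subtracted) protein channel by
thresholding and connected-component labeling, (2) labeling particles in
the positive-PDM image — pixels where both channels exceed their ROI means
— and (3) counting a cluster as colocalized when its pixel set overlaps at
least one positive-PDM particle. Connectivity is 8-connected and particles
below ``min_area_px`` (default 4) are discarded; both choices are recorded
on the returned :class:`ClusterSet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .coloc import PDMImage
from .exceptions import EmptyClusterSetError
from .preprocessing import ChannelImage, RegionOfInterest, roi_mask

__all__ = [
    "Particle",
    "ClusterSet",
    "detect_clusters",
    "positive_pdm_particles",
    "percent_colocalized_clusters",
]


@dataclass(frozen=True)
class Particle:
    """One labeled particle: its pixel set, centroid and area."""

    pixels: np.ndarray  # (n, 2) of (row, col)
    centroid: tuple[float, float]  # (x, y)
    area_px: int


@dataclass(frozen=True)
class ClusterSet:
    """Labeled particles from a thresholded image or positive-PDM image."""

    particles: list[Particle]
    image_shape: tuple[int, int]
    source: str = "channel"
    threshold_used: float | str = "otsu"
    min_area_px: int = 4

    def __len__(self) -> int:
        return len(self.particles)

    def mask(self) -> np.ndarray:
        """Boolean union of all particle pixel sets."""
        m = np.zeros(self.image_shape, dtype=bool)
        for p in self.particles:
            m[p.pixels[:, 0], p.pixels[:, 1]] = True
        return m

    def centroids(self) -> np.ndarray:
        """(n, 2) array of particle centroids as (x, y)."""
        if not self.particles:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.particles])


def _label_particles(binary: np.ndarray, min_area_px: int) -> list[Particle]:
    labels = label(binary, connectivity=2)  # 8-connectivity
    out = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        cy, cx = region.centroid
        out.append(Particle(np.column_stack([rr, cc]), (float(cx), float(cy)), int(region.area)))
    return out


def detect_clusters(
    image: ChannelImage,
    roi: RegionOfInterest | None = None,
    threshold_method: str | float = "otsu",
    min_area_px: int = 4,
) -> ClusterSet:
    """Threshold an image within an ROI and label the bright particles.

    ``threshold_method`` is either the name ``"otsu"`` (computed from the
    ROI pixels) or an explicit numeric threshold; pixels strictly above
    the threshold are foreground. An image with nothing above threshold
    yields an empty set, not an error.
    """
    support = roi_mask(roi, image.shape) if roi is not None else np.ones(image.shape, bool)
    vals = image.pixels[support]
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        if vals.size == 0 or np.ptp(vals) == 0:
            return ClusterSet([], image.shape, "channel", float("inf"), min_area_px)
        threshold = float(threshold_otsu(vals))
    else:
        threshold = float(threshold_method)
    binary = (image.pixels > threshold) & support
    return ClusterSet(_label_particles(binary, min_area_px), image.shape, "channel", threshold, min_area_px)


def positive_pdm_particles(
    pdm: PDMImage, min_area_px: int = 4, threshold_method: str = "mask"
) -> ClusterSet:
    """Label particles in the positive-PDM image.

    By default the binary image is the positive mask itself (both channels
    above their means, equivalent to thresholding the masked PDM at 0);
    ``threshold_method="otsu"`` additionally applies an Otsu cut on the
    positive PDM values for a stricter particle definition.
    """
    binary = pdm.positive_mask.copy()
    threshold: float | str = 0.0
    if threshold_method == "otsu":
        vals = pdm.pdm[pdm.positive_mask]
        if vals.size and np.ptp(vals) > 0:
            threshold = float(threshold_otsu(vals))
            binary &= np.nan_to_num(pdm.pdm, nan=-np.inf) > threshold
    elif threshold_method != "mask":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    return ClusterSet(_label_particles(binary, min_area_px), binary.shape, "positive_pdm", threshold, min_area_px)


def percent_colocalized_clusters(clusters: ClusterSet, pdm_particles: ClusterSet) -> float:
    """Percentage of clusters whose pixel set overlaps a positive-PDM particle.

    Overlap of a single pixel suffices ("clusters containing colocalized
    signal"); returns ``100 × colocalized / total``.
    """
    if len(clusters) == 0:
        raise EmptyClusterSetError("no clusters: percentage undefined")
    if clusters.image_shape != pdm_particles.image_shape:
        raise ValueError("cluster sets come from different image shapes")
    pdm_mask = pdm_particles.mask()
    hit = sum(1 for p in clusters.particles if pdm_mask[p.pixels[:, 0], p.pixels[:, 1]].any())
    return 100.0 * hit / len(clusters)
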