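"""End-to-end colocalization workflow on a two-channel image.

Chains the standard sequence — 8-bit conversion, background subtraction
from a polygon ROI, coefficient computation over a dendrite line ROI, PDM
image, cluster detection and positive-PDM particle counting — into one
call, returning both the four coefficients and the percent of detected
clusters that contain correlated signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clusters import (
    ClusterSet,
    detect_clusters,
    percent_colocalized_clusters,
    positive_pdm_particles,
)
from .coloc import ColocalizationResult, coloc_summary, pdm_image
from .exceptions import EmptyClusterSetError
from .preprocessing import (
    ChannelImage,
    RegionOfInterest,
    convert_to_8bit,
    subtract_background_roi,
)
from .synthetic import SyntheticScene

__all__ = ["PipelineResult", "scene_rois", "run_colocalization"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything one analyzed dendrite produces."""

    coefficients: ColocalizationResult
    clusters: ClusterSet
    pdm_particles: ClusterSet
    percent_colocalized: float  # NaN when no clusters were detected


def scene_rois(
    scene: SyntheticScene, line_width_px: float = 10.0
) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Analysis and background ROIs for a synthetic scene.

    The analysis ROI is the dendrite path widened to ``line_width_px``;
    the background ROI is a rectangle along the bottom edge of the image,
    clear of the dendrite band.
    """
    p = scene.params
    analysis = RegionOfInterest(
        "polyline", p.dendrite_path, line_width_px=line_width_px, name="dendrite"
    )
    h, w = p.image_height_px, p.image_width_px
    y_low = float(p.dendrite_path[:, 1].max()) + line_width_px / 2 + 6 * p.spot_sigma_px
    y0 = min(max(y_low, h - 16.0), h - 10.0)
    rect = np.array([[8.0, y0], [w - 8.0, y0], [w - 8.0, h - 3.0], [8.0, h - 3.0]])
    background = RegionOfInterest("polygon", rect, name="background")
    return analysis, background


def run_colocalization(
    channel_a: ChannelImage,
    channel_b: ChannelImage,
    analysis_roi: RegionOfInterest,
    background_roi: RegionOfInterest,
    k_sd: float = 2.0,
    min_area_px: int = 4,
    threshold_method: str | float = "otsu",
) -> PipelineResult:
    """Coefficients + percent-colocalized-clusters for one dendrite ROI.

    Clusters are detected in channel A (the protein of interest) after
    background subtraction; the positive-PDM image is computed from both
    background-subtracted channels over the same ROI. A scene in which no
    cluster survives thresholding yields ``percent_colocalized = NaN``.
    """
    a = convert_to_8bit(channel_a)
    b = convert_to_8bit(channel_b)
    a = subtract_background_roi(a, background_roi, k_sd)
    b = subtract_background_roi(b, background_roi, k_sd)

    coefficients = coloc_summary(a, b, analysis_roi)  # already preprocessed
    pdm = pdm_image(a, b, analysis_roi)
    clusters = detect_clusters(a, analysis_roi, threshold_method, min_area_px)
    pdm_particles = positive_pdm_particles(pdm, min_area_px)
    try:
        percent = percent_colocalized_clusters(clusters, pdm_particles)
    except EmptyClusterSetError:
        percent = float("nan")
    return PipelineResult(coefficients, clusters, pdm_particles, percent)
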