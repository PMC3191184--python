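"""Covariance-profile and PDM scatter plots (matplotlib required)."""

from __future__ import annotations

import numpy as np

from .coloc import PDMImage
from .preprocessing import ChannelImage, RegionOfInterest, intensity_profile

__all__ = ["plot_intensity_profiles", "plot_pdm_scatter"]


def plot_intensity_profiles(
    channels: dict[str, ChannelImage], path: RegionOfInterest, ax=None
):
    """Overlay per-channel intensity profiles along one dendrite path.

    Coincident peaks in the two traces display the covariance of the two
    signals along the segment.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    for name, channel in channels.items():
        ax.plot(intensity_profile(channel, path), label=name, lw=1.0)
    ax.set_xlabel("distance along dendrite (px)")
    ax.set_ylabel("intensity")
    ax.legend(frameon=False)
    return ax


def plot_pdm_scatter(
    image_a: ChannelImage, image_b: ChannelImage, pdm: PDMImage, ax=None,
    labels: tuple[str, str] = ("channel A", "channel B"),
):
    """Intensity-vs-PDM scatter for both channels over the ROI.

    Correlated pixels fall to the right of the vertical zero line,
    uncorrelated pixels to the left.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    support = pdm.roi_support
    vals = pdm.pdm[support]
    ax.scatter(vals, image_a.pixels[support], s=2, alpha=0.4, label=labels[0])
    ax.scatter(vals, image_b.pixels[support], s=2, alpha=0.4, label=labels[1])
    ax.axvline(0.0, color="red", lw=1.0)
    ax.set_xlabel("PDM")
    ax.set_ylabel("pixel intensity")
    ax.legend(frameon=False, markerscale=4)
    return ax
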