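"""Pixel-intensity colocalization coefficients and the PDM image.

Four coefficients are computed over the same set of paired ROI pixels:

* **Pearson's Rr** — product-moment correlation of the paired intensities,
  in [−1, 1]; values of 0.5 and above are conventionally read as
  colocalization.
* **Mander's M1/M2** — the fraction of channel A's integrated intensity at
  pixels where channel B has signal, and vice versa, in [0, 1]. Intensities
  are assumed background-subtracted, so "has signal" means "> 0".
* **ICQ** — the intensity correlation quotient: the fraction of pixels
  whose mean-centred intensity product ``(Ai − Ā)(Bi − B̄)`` is strictly
  positive, minus 0.5. It ranges from −0.5 (segregated staining) through
  ~0 (random staining) to +0.5 (perfect covariation).
* **PDM** — the per-pixel product of the differences from the mean itself;
  its positive support localizes covarying signal. The displayed positive
  mask is restricted to pixels above the mean in *both* channels, because
  below-mean pixels are mostly (0, 0) background whose product is
  uninformatively positive.

All means are taken over the ROI pixels only — the analysis is per
dendritic segment, not per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConstantChannelError, EmptyRegionError, ZeroSignalError
from .preprocessing import (
    ChannelImage,
    PixelPairs,
    RegionOfInterest,
    convert_to_8bit,
    extract_roi_pixels,
    roi_mask,
    subtract_background_roi,
)

__all__ = [
    "ColocalizationResult",
    "PDMImage",
    "pearson",
    "manders",
    "icq",
    "pdm_image",
    "coloc_summary",
]

#: Pearson values at or above this are conventionally read as colocalization.
PEARSON_COLOC_THRESHOLD = 0.5


@dataclass(frozen=True)
class ColocalizationResult:
    """The four coefficients for one ROI on one channel pair."""

    pearson_rr: float
    manders_m1: float
    manders_m2: float
    icq: float
    n_pixels: int
    mean_a: float
    mean_b: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_rr <= 1.0 + 1e-12:
            raise ValueError("pearson_rr outside [-1, 1]")
        for m in (self.manders_m1, self.manders_m2):
            # NaN marks an all-zero channel for which overlap is undefined
            if not np.isnan(m) and not 0.0 <= m <= 1.0:
                raise ValueError("Mander's coefficients outside [0, 1]")
        if not -0.5 <= self.icq <= 0.5:
            raise ValueError("ICQ outside [-0.5, 0.5]")
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")

    @property
    def indicates_colocalization(self) -> bool:
        """Whether Rr reaches the conventional 0.5 colocalization cutoff."""
        return self.pearson_rr >= PEARSON_COLOC_THRESHOLD


@dataclass(frozen=True)
class PDMImage:
    """Per-pixel products of the differences from the mean over an ROI.

    ``pdm`` holds ``(Ai − Ā)(Bi − B̄)`` at ROI pixels and NaN elsewhere;
    ``positive_mask`` marks pixels where both channels exceed their ROI
    means (a strict subset of ``pdm > 0``).
    """

    pdm: np.ndarray
    roi_support: np.ndarray
    mean_a: float
    mean_b: float
    positive_mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.roi_support.sum())


def _check_nonconstant(pairs: PixelPairs) -> None:
    if np.ptp(pairs.a_values) == 0 or np.ptp(pairs.b_values) == 0:
        raise ConstantChannelError("coefficient undefined for a constant channel")


def pearson(pairs: PixelPairs) -> float:
    """Pearson product-moment correlation Rr of the paired intensities."""
    _check_nonconstant(pairs)
    return float(np.corrcoef(pairs.a_values, pairs.b_values)[0, 1])


def manders(pairs: PixelPairs) -> tuple[float, float]:
    """Mander's overlap coefficients (M1, M2).

    ``M1 = Σ Ai·[Bi > 0] / Σ Ai`` and symmetrically for M2. Intensities are
    post-background-subtraction, so zero means "no signal".
    """
    a, b = pairs.a_values, pairs.b_values
    if a.sum() <= 0 or b.sum() <= 0:
        raise ZeroSignalError("Mander's coefficients undefined for an all-zero channel")
    m1 = float(a[b > 0].sum() / a.sum())
    m2 = float(b[a > 0].sum() / b.sum())
    return m1, m2


def icq(pairs: PixelPairs) -> float:
    """Intensity correlation quotient.

    The fraction of pixels with strictly positive mean-centred product,
    minus 0.5. Pixels whose product is exactly zero count in the
    denominator but not the numerator.
    """
    _check_nonconstant(pairs)
    products = (pairs.a_values - pairs.a_values.mean()) * (
        pairs.b_values - pairs.b_values.mean()
    )
    return float(np.count_nonzero(products > 0) / pairs.n - 0.5)


def pdm_image(
    image_a: ChannelImage, image_b: ChannelImage, roi: RegionOfInterest
) -> PDMImage:
    """Per-pixel PDM over an ROI, with the above-the-mean positive mask."""
    if image_a.shape != image_b.shape:
        raise ValueError("channel images must have identical dimensions")
    support = roi_mask(roi, image_a.shape)
    if support.sum() < 2:
        raise EmptyRegionError("ROI selects fewer than 2 pixels")
    a = image_a.pixels.astype(float)
    b = image_b.pixels.astype(float)
    mean_a = float(a[support].mean())
    mean_b = float(b[support].mean())
    pdm = np.full(image_a.shape, np.nan)
    pdm[support] = (a[support] - mean_a) * (b[support] - mean_b)
    positive = support & (a > mean_a) & (b > mean_b)
    return PDMImage(pdm, support, mean_a, mean_b, positive)


def coloc_summary(
    image_a: ChannelImage,
    image_b: ChannelImage,
    analysis_roi: RegionOfInterest,
    background_roi: RegionOfInterest | None = None,
    k_sd: float = 2.0,
) -> ColocalizationResult:
    """All four coefficients on one channel pair after standard preprocessing.

    Order of operations is fixed: 8-bit conversion (if 16-bit input), then
    background subtraction at ``mean + k_sd·SD`` of the background ROI (if
    one is given), then pixel-pair extraction over the analysis ROI. All
    coefficients are computed on the same :class:`PixelPairs` so that N,
    Ā and B̄ are shared.
    """
    a, b = convert_to_8bit(image_a), convert_to_8bit(image_b)
    if background_roi is not None:
        a = subtract_background_roi(a, background_roi, k_sd)
        b = subtract_background_roi(b, background_roi, k_sd)
    pairs = extract_roi_pixels(a, b, analysis_roi)
    try:
        m1, m2 = manders(pairs)
    except ZeroSignalError:
        warnings.warn("all-zero channel inside ROI; Mander's reported as NaN")
        m1 = m2 = float("nan")
    return ColocalizationResult(
        pearson_rr=pearson(pairs),
        manders_m1=m1,
        manders_m2=m2,
        icq=icq(pairs),
        n_pixels=pairs.n,
        mean_a=float(pairs.a_values.mean()),
        mean_b=float(pairs.b_values.mean()),
    )
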