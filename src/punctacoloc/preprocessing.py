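"""Image/ROI containers, bit-depth conversion and ROI-based background subtraction.

Conventions used throughout the package:

* pixel coordinates are 0-based with ``x`` = column and ``y`` = row; the
  centre of pixel ``(row r, col c)`` is the point ``(x=c, y=r)``;
* a pixel belongs to a polygon ROI when its centre lies inside or on the
  boundary of the polygon (boundary inclusive);
* a pixel belongs to a polyline ROI when its centre lies within
  ``line_width_px / 2`` of the path (inclusive);
* ROI pixels are always enumerated in row-major order, so paired channel
  extractions are positionally identical.

The canonical preprocessing order for colocalization analysis is: convert
16-bit acquisitions to 8-bit, then subtract background estimated from a
user-drawn background polygon as ``mean + k·SD`` of the ROI pixels
(``k = 2`` by default; ``k = 0.5`` for in situ hybridization images, where
the diffuse probe signal calls for a gentler cut).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .exceptions import EmptyRegionError

__all__ = [
    "ChannelImage",
    "RegionOfInterest",
    "PixelPairs",
    "convert_to_8bit",
    "subtract_background_roi",
    "extract_roi_pixels",
    "intensity_profile",
    "roi_mask",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; integer camera output rounds .5 up
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel intensity raster with bit depth and pixel calibration.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities within the integer range of
        ``bit_depth``.
    bit_depth
        8 or 16.
    pixel_size_um
        Physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float = 0.11

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError("intensities outside the bit-depth range")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """A polygon or polyline (with width) in pixel coordinates.

    Vertices are ``(x, y)`` pairs. Polygons must be simple (non
    self-intersecting) with at least 3 vertices; polylines need at least 2
    vertices and a width of at least 1 pixel.
    """

    kind: str
    vertices: np.ndarray
    line_width_px: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        object.__setattr__(self, "vertices", verts)
        if self.kind == "polygon":
            if len(verts) < 3:
                raise ValueError("a polygon needs at least 3 vertices")
            if not shapely.Polygon(verts).is_simple:
                raise ValueError("polygon is self-intersecting")
        elif self.kind == "polyline":
            if len(verts) < 2:
                raise ValueError("a polyline needs at least 2 vertices")
            if self.line_width_px < 1:
                raise ValueError("line_width_px must be >= 1")
        else:
            raise ValueError(f"kind must be 'polygon' or 'polyline', got {self.kind!r}")

    def to_shapely(self):
        if self.kind == "polygon":
            return shapely.Polygon(self.vertices)
        return shapely.LineString(self.vertices)


@dataclass(frozen=True)
class PixelPairs:
    """Paired intensities of two channels sampled at identical pixel positions."""

    a_values: np.ndarray
    b_values: np.ndarray
    pixel_coords: np.ndarray = field(repr=False)  # (n, 2) of (row, col)

    def __post_init__(self) -> None:
        a = np.asarray(self.a_values, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a_values and b_values must be equal-length 1-D")
        if a.size < 2:
            raise ValueError("need at least 2 pixel pairs")
        object.__setattr__(self, "a_values", a)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "pixel_coords", np.asarray(self.pixel_coords))

    @property
    def n(self) -> int:
        return int(self.a_values.size)

    @classmethod
    def from_arrays(cls, a, b) -> "PixelPairs":
        """Pair two flat intensity sequences (synthetic positions)."""
        a = np.asarray(a, dtype=float).ravel()
        coords = np.column_stack([np.zeros_like(a, dtype=int), np.arange(a.size)])
        return cls(a, np.asarray(b, dtype=float).ravel(), coords)


def roi_mask(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels whose centres fall in *roi*.

    Polygon membership is boundary inclusive; polyline membership is
    distance-to-path ``<= line_width_px / 2``. The test is restricted to the
    ROI's bounding box for speed.
    """
    geom = roi.to_shapely()
    pad = 1.0 if roi.kind == "polygon" else roi.line_width_px / 2 + 1.0
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor(minx - pad)), 0)
    c1 = min(int(np.ceil(maxx + pad)), shape[1] - 1)
    r0 = max(int(np.floor(miny - pad)), 0)
    r1 = min(int(np.ceil(maxy + pad)), shape[0] - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(np.column_stack([cols.ravel(), rows.ravel()]).astype(float))
    if roi.kind == "polygon":
        inside = shapely.covers(geom, pts)
    else:
        inside = shapely.dwithin(geom, pts, roi.line_width_px / 2)
    mask[rows.ravel()[inside], cols.ravel()[inside]] = True
    return mask


def convert_to_8bit(image: ChannelImage) -> ChannelImage:
    """Linear min–max rescale of a 16-bit image to [0, 255].

    8-bit input passes through unchanged. A constant image maps to all
    zeros (the rescale is degenerate). Rounding is half-up, matching
    integer camera quantization.
    """
    if image.bit_depth == 8:
        return image
    px = image.pixels.astype(float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = _round_half_up(255.0 * (px - lo) / (hi - lo))
    return ChannelImage(out.astype(np.uint8), bit_depth=8, pixel_size_um=image.pixel_size_um)


def subtract_background_roi(
    image: ChannelImage, background_roi: RegionOfInterest, k_sd: float = 2.0
) -> ChannelImage:
    """Subtract a background threshold estimated inside a polygon ROI.

    The threshold is ``T = mean + k_sd * SD`` of the ROI pixels, with the
    sample (n−1) standard deviation. Every pixel becomes
    ``max(0, pixel − T)``, re-quantized to the image's integer range.
    ``k_sd = 2`` is the conventional default; ``k_sd = 0.5`` is used for
    FISH images.
    """
    if background_roi.kind != "polygon":
        raise ValueError("background ROI must be a polygon")
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    mask = roi_mask(background_roi, image.shape)
    vals = image.pixels[mask].astype(float)
    if vals.size < 2:
        raise EmptyRegionError("background ROI covers fewer than 2 pixels")
    threshold = vals.mean() + k_sd * vals.std(ddof=1)
    out = np.clip(_round_half_up(image.pixels.astype(float) - threshold), 0, image.max_value)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    return replace(image, pixels=out.astype(dtype))


def extract_roi_pixels(
    image_a: ChannelImage, image_b: ChannelImage, roi: RegionOfInterest
) -> PixelPairs:
    """Paired intensities of both channels at the ROI's pixels, row-major."""
    if image_a.shape != image_b.shape:
        raise ValueError("channel images must have identical dimensions")
    mask = roi_mask(roi, image_a.shape)
    rows, cols = np.nonzero(mask)  # nonzero scans row-major
    if rows.size == 0:
        raise EmptyRegionError("ROI does not intersect the image")
    coords = np.column_stack([rows, cols])
    return PixelPairs(
        image_a.pixels[rows, cols].astype(float),
        image_b.pixels[rows, cols].astype(float),
        coords,
    )


def intensity_profile(image: ChannelImage, path: RegionOfInterest) -> np.ndarray:
    """Intensities sampled at unit-spaced points along a polyline path.

    Sampling is nearest-pixel, in path order; two channels profiled along
    the same path share the x-axis, which is how the covariance of the two
    signals along a dendrite is displayed.
    """
    if path.kind != "polyline":
        raise ValueError("intensity_profile requires a polyline ROI")
    line = path.to_shapely()
    if line.length < 1:
        raise ValueError("path shorter than 2 px")
    distances = np.arange(0.0, np.floor(line.length) + 1.0)
    pts = shapely.line_interpolate_point(line, distances)
    xs = shapely.get_x(pts)
    ys = shapely.get_y(pts)
    rows = np.clip(_round_half_up(ys).astype(int), 0, image.shape[0] - 1)
    cols = np.clip(_round_half_up(xs).astype(int), 0, image.shape[1] - 1)
    return image.pixels[rows, cols].astype(float)
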