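"""Synthetic two-channel punctate scenes and spine geometries with ground truth.

The image generator emulates the regime of two-channel immunofluorescence
of dendrites: diffraction-limited puncta scattered as a Poisson process
along a dendrite path, a controllable fraction of channel-A puncta carrying
a co-positioned channel-B punctum (sub-resolution offset, ≤1 px), Gaussian
spot profiles, a constant background offset, optional Poisson photon noise,
Gaussian read noise, and integer quantization at 8 or 16 bits. Every scene
records its ground truth — cluster centres per channel and the list of
co-positioned (A, B) index pairs — so detection, colocalization and
percent-colocalization estimates can be scored against construction.

The spine-geometry generator builds a straight dendritic shaft with
mushroom-shaped spines (neck rectangle + head disc, traced as total and
head perimeter polygons) and stubby spines (total perimeter only), and
plants cluster centroids to realize a requested per-category plan exactly.

Defaults mirror the observed study conditions: puncta density 0.67
clusters/µm of dendrite, segments of tens of µm, tens of spines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .preprocessing import ChannelImage
from .spines import Spine, SpineGeometry, classify_cluster_location

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "SpineScenario",
    "generate_punctate_pair",
    "generate_spine_scenario",
]


def _default_path() -> np.ndarray:
    return np.array([[12.0, 48.0], [468.0, 48.0]])


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic two-channel punctate scene.

    ``coloc_fraction`` is the fraction of channel-A clusters that receive a
    co-positioned channel-B cluster (within 1 px); the remaining channel-B
    clusters are an independent Poisson process along the same path.
    ``cluster_radius_px`` is the pre-blur punctum scale (modelled as a
    Gaussian of sigma ``cluster_radius_px / 2``) which is convolved with a
    Gaussian PSF of sigma ``psf_sigma_px``. ``pixel_size_um`` defaults to
    0.11 µm/px, typical of 60×/1.25 NA sampling.
    """

    image_height_px: int = 96
    image_width_px: int = 480
    pixel_size_um: float = 0.11
    dendrite_path: np.ndarray = field(default_factory=_default_path)
    cluster_density_per_um: float = 0.67
    cluster_radius_px: float = 2.0
    amplitude_mean: float = 180.0
    amplitude_sd: float = 30.0
    coloc_fraction: float = 0.5
    psf_sigma_px: float = 1.3
    lateral_jitter_px: float = 2.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    photon_noise: bool = True
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dendrite_path", np.asarray(self.dendrite_path, float))
        if self.image_height_px < 32 or self.image_width_px < 32:
            raise ValueError("image dimensions must be at least 32 px")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for name in ("pixel_size_um", "cluster_density_per_um", "cluster_radius_px",
                     "amplitude_mean", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("amplitude_sd", "lateral_jitter_px", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        path = self.dendrite_path
        if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
            raise ValueError("dendrite_path must be an (n>=2, 2) polyline")
        if (path[:, 0] < 0).any() or (path[:, 0] > self.image_width_px - 1).any() or \
           (path[:, 1] < 0).any() or (path[:, 1] > self.image_height_px - 1).any():
            raise ValueError("dendrite_path vertices must lie inside the image")

    @property
    def path_length_px(self) -> float:
        return float(shapely.LineString(self.dendrite_path).length)

    @property
    def path_length_um(self) -> float:
        return self.path_length_px * self.pixel_size_um

    @property
    def spot_sigma_px(self) -> float:
        """Effective Gaussian sigma: pre-blur punctum convolved with the PSF."""
        return float(np.hypot(self.cluster_radius_px / 2.0, self.psf_sigma_px))


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered two-channel scene plus its construction ground truth."""

    channel_a: ChannelImage
    channel_b: ChannelImage
    truth_clusters_a: np.ndarray  # (nA, 2) of (x, y)
    truth_clusters_b: np.ndarray  # (nB, 2) of (x, y)
    truth_pairs: list[tuple[int, int]]
    params: SceneParams


def _points_along(path: np.ndarray, arc: np.ndarray, lateral: np.ndarray) -> np.ndarray:
    """Points at arc-length positions with signed lateral (normal) offsets."""
    line = shapely.LineString(path)
    pts = shapely.line_interpolate_point(line, arc)
    xy = np.column_stack([shapely.get_x(pts), shapely.get_y(pts)])
    eps = 1e-3
    ahead = shapely.line_interpolate_point(line, np.minimum(arc + eps, line.length))
    behind = shapely.line_interpolate_point(line, np.maximum(arc - eps, 0.0))
    tangent = np.column_stack(
        [shapely.get_x(ahead) - shapely.get_x(behind), shapely.get_y(ahead) - shapely.get_y(behind)]
    )
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    return xy + normal * lateral[:, None]


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    amps = rng.normal(mean, sd, size=n)
    return np.clip(amps, mean * 0.05, None)  # keep every punctum visible


def _render(
    centers: np.ndarray, amplitudes: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> ChannelImage:
    h, w = params.image_height_px, params.image_width_px
    img = np.full((h, w), float(params.background_level))
    sigma = params.spot_sigma_px
    reach = int(np.ceil(5 * sigma))
    for (cx, cy), amp in zip(centers, amplitudes):
        c0, c1 = max(int(cx) - reach, 0), min(int(cx) + reach + 1, w)
        r0, r1 = max(int(cy) - reach, 0), min(int(cy) + reach + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        g = np.exp(-((cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2) / (2 * sigma**2))
        img[r0:r1, c0:c1] += amp * g
    if params.photon_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
    max_val = 2**params.bit_depth - 1
    img = np.clip(np.floor(img + 0.5), 0, max_val)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return ChannelImage(img.astype(dtype), bit_depth=params.bit_depth,
                        pixel_size_um=params.pixel_size_um)


def generate_punctate_pair(params: SceneParams) -> SyntheticScene:
    """Render one two-channel scene with a known colocalized fraction.

    Channel-A cluster centres are a Poisson process along the dendrite path
    (rate ``cluster_density_per_um`` per µm) with uniform lateral jitter.
    ``round(coloc_fraction · nA)`` of them receive a channel-B partner
    offset by a uniform draw from the unit disc (≤1 px); the remaining
    channel-B clusters form an independent Poisson process of rate
    ``(1 − coloc_fraction) · cluster_density_per_um`` so both channels have
    matching expected densities. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    lam = params.cluster_density_per_um * params.path_length_um
    path, jit = params.dendrite_path, params.lateral_jitter_px

    n_a = int(rng.poisson(lam))
    arc_a = rng.uniform(0.0, params.path_length_px, size=n_a)
    lat_a = rng.uniform(-jit, jit, size=n_a)
    centers_a = _points_along(path, arc_a, lat_a) if n_a else np.empty((0, 2))
    amps_a = _positive_normal(rng, params.amplitude_mean, params.amplitude_sd, n_a)

    n_pairs = int(np.floor(params.coloc_fraction * n_a + 0.5))
    paired_idx = rng.choice(n_a, size=n_pairs, replace=False) if n_pairs else np.array([], int)
    radius = np.sqrt(rng.uniform(0.0, 1.0, size=n_pairs))  # uniform on the unit disc
    theta = rng.uniform(0.0, 2 * np.pi, size=n_pairs)
    offsets = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    centers_b_paired = centers_a[paired_idx] + offsets if n_pairs else np.empty((0, 2))

    n_indep = int(rng.poisson((1.0 - params.coloc_fraction) * lam))
    arc_i = rng.uniform(0.0, params.path_length_px, size=n_indep)
    lat_i = rng.uniform(-jit, jit, size=n_indep)
    centers_b_indep = _points_along(path, arc_i, lat_i) if n_indep else np.empty((0, 2))

    centers_b = np.vstack([centers_b_paired, centers_b_indep])
    amps_b = _positive_normal(rng, params.amplitude_mean, params.amplitude_sd, len(centers_b))
    truth_pairs = [(int(a), j) for j, a in enumerate(paired_idx)]

    channel_a = _render(centers_a, amps_a, params, rng)
    channel_b = _render(centers_b, amps_b, params, rng)
    return SyntheticScene(channel_a, channel_b, centers_a, centers_b, truth_pairs, params)


# ---------------------------------------------------------------------------
# spine scenarios


@dataclass(frozen=True)
class SpineScenario:
    """A spine geometry plus planted cluster centroids with true categories."""

    geometry: SpineGeometry
    truth_cluster_centroids: np.ndarray  # (n, 2) of (x, y)
    truth_categories: list[str]


def _circle(cx: float, cy: float, r: float, n: int = 24) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _mushroom_spine(x: float, y_shaft: float, side: int) -> Spine:
    """Neck rectangle + head disc; total perimeter is their union."""
    neck_half_w, neck_len, head_r = 2.0, 12.0, 5.0
    y_base = y_shaft + side * 3.0
    y_head = y_base + side * (neck_len + head_r - 1.0)
    neck = shapely.Polygon(
        [
            (x - neck_half_w, y_base),
            (x + neck_half_w, y_base),
            (x + neck_half_w, y_base + side * neck_len),
            (x - neck_half_w, y_base + side * neck_len),
        ]
    )
    head = shapely.Polygon(_circle(x, y_head, head_r))
    total = neck.union(head)
    return Spine(
        total_perimeter=np.asarray(total.exterior.coords)[:-1],
        head_perimeter=_circle(x, y_head, head_r - 1.2),
    )


def _stubby_spine(x: float, y_shaft: float, side: int) -> Spine:
    return Spine(total_perimeter=_circle(x, y_shaft + side * 6.0, 4.5))


def generate_spine_scenario(
    n_spines: int,
    segment_length_um: float,
    stubby_fraction: float = 0.15,
    cluster_plan: dict[str, int] | None = None,
    seed: int = 0,
    pixel_size_um: float = 0.11,
) -> SpineScenario:
    """Straight-shaft spine geometry with clusters planted per category.

    Spines are evenly spaced along the shaft, alternating sides;
    ``round(stubby_fraction · n_spines)`` randomly chosen spines are
    stubby (total perimeter only). ``cluster_plan`` maps categories
    (``shaft``, ``head``, ``base_neck``, ``all``) to exact counts; every
    planted centroid is verified against the classifier so the truth
    labels are correct by construction.
    """
    if n_spines < 1:
        raise ValueError("n_spines must be >= 1")
    if segment_length_um <= 0:
        raise ValueError("segment_length_um must be positive")
    if not 0.0 <= stubby_fraction <= 1.0:
        raise ValueError("stubby_fraction must lie in [0, 1]")
    plan = dict.fromkeys(("shaft", "head", "base_neck", "all"), 0)
    plan.update(cluster_plan or {})
    unknown = set(plan) - {"shaft", "head", "base_neck", "all"}
    if unknown:
        raise ValueError(f"unknown cluster categories: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_stubby = int(np.floor(stubby_fraction * n_spines + 0.5))
    if (plan["head"] > 0 or plan["base_neck"] > 0) and n_stubby == n_spines:
        raise ValueError("head/base_neck clusters requested but every spine is stubby")
    if plan["all"] > 0 and n_stubby == 0:
        raise ValueError("'all' clusters requested but no spine is stubby")

    margin = 25.0
    length_px = segment_length_um / pixel_size_um
    y_shaft = 60.0
    xs = margin + (np.arange(n_spines) + 0.5) * length_px / n_spines
    stubby_mask = np.zeros(n_spines, dtype=bool)
    stubby_mask[rng.permutation(n_spines)[:n_stubby]] = True

    spines = []
    for i, x in enumerate(xs):
        side = 1 if i % 2 == 0 else -1
        spines.append(_stubby_spine(x, y_shaft, side) if stubby_mask[i]
                      else _mushroom_spine(x, y_shaft, side))
    geometry = SpineGeometry(segment_length_um, spines, pixel_size_um)

    mushroom_ids = np.flatnonzero(~stubby_mask)
    stubby_ids = np.flatnonzero(stubby_mask)
    centroids: list[tuple[float, float]] = []
    categories: list[str] = []

    # shaft clusters: on the shaft line, midway between spine attachment points
    gaps = np.concatenate([[margin * 0.5], (xs[:-1] + xs[1:]) / 2.0, [margin + length_px]])
    for k in range(plan["shaft"]):
        centroids.append((float(gaps[k % len(gaps)]) + 0.01 * (k // len(gaps)), y_shaft))
        categories.append("shaft")
    for k in range(plan["head"]):
        spine = spines[mushroom_ids[k % len(mushroom_ids)]]
        c = shapely.Polygon(spine.head_perimeter).centroid
        centroids.append((c.x, c.y + 0.1 * (k // len(mushroom_ids))))
        categories.append("head")
    for k in range(plan["base_neck"]):
        i = mushroom_ids[k % len(mushroom_ids)]
        side = 1 if i % 2 == 0 else -1
        centroids.append((float(xs[i]), y_shaft + side * (3.0 + 5.0 + 0.2 * (k // len(mushroom_ids)))))
        categories.append("base_neck")
    for k in range(plan["all"]):
        spine = spines[stubby_ids[k % len(stubby_ids)]]
        c = spine.total_polygon.centroid
        centroids.append((c.x + 0.1 * (k // len(stubby_ids)), c.y))
        categories.append("all")

    pts = np.asarray(centroids, float).reshape(-1, 2)
    for xy, want in zip(pts, categories):
        got = classify_cluster_location(tuple(xy), geometry)
        if got != want:
            raise RuntimeError(
                f"generator planted a {want!r} cluster that classifies as {got!r}"
            )
    return SpineScenario(geometry, pts, categories)
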