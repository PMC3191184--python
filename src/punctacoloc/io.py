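"""File I/O: TIFF images, the ROI text schema, and CSV result tables.

The ROI file is a YAML document:

.. code-block:: yaml

    pixel_size_um: 0.11            # optional metadata keys at top level
    segment_length_um: 50.0
    rois:
      - name: dendrite_1
        kind: polyline             # or polygon
        line_width_px: 10.0        # polylines only
        vertices: [[12.0, 48.0], [468.0, 48.0]]

Spine geometries reuse the same schema with one polygon per perimeter,
named ``spine<i>_total`` and (for non-stubby spines) ``spine<i>_head``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .clusters import ClusterSet
from .coloc import ColocalizationResult
from .preprocessing import ChannelImage, PixelPairs, RegionOfInterest
from .spines import Spine, SpineGeometry
from .synthetic import SyntheticScene

__all__ = [
    "read_image",
    "write_images",
    "read_rois",
    "write_rois",
    "write_scene",
    "read_spine_geometry",
    "write_spine_geometry",
    "pixel_pairs_table",
    "coloc_results_table",
    "particles_table",
]


def read_image(path, pixel_size_um: float = 0.11) -> list[ChannelImage]:
    """Read a single- or multi-page grayscale TIFF as channel images."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    channels = []
    for page in pages:
        depth = 16 if page.dtype.itemsize > 1 else 8
        channels.append(ChannelImage(page, bit_depth=depth, pixel_size_um=pixel_size_um))
    return channels


def write_images(path, channels: list[ChannelImage]) -> None:
    """Write channels as a multi-page TIFF (one page per channel)."""
    dtypes = {8: np.uint8, 16: np.uint16}
    stack = np.stack([c.pixels.astype(dtypes[c.bit_depth]) for c in channels])
    tifffile.imwrite(path, stack)


def _roi_record(roi: RegionOfInterest) -> dict:
    rec = {"name": roi.name, "kind": roi.kind, "vertices": roi.vertices.tolist()}
    if roi.kind == "polyline":
        rec["line_width_px"] = float(roi.line_width_px)
    return rec


def write_rois(path, rois: list[RegionOfInterest], metadata: dict | None = None) -> None:
    doc = dict(metadata or {})
    doc["rois"] = [_roi_record(r) for r in rois]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_rois(path) -> tuple[list[RegionOfInterest], dict]:
    """Read an ROI file; returns the ROIs and any top-level metadata."""
    doc = yaml.safe_load(Path(path).read_text())
    rois = [
        RegionOfInterest(
            kind=rec["kind"],
            vertices=np.asarray(rec["vertices"], float),
            line_width_px=float(rec.get("line_width_px", 1.0)),
            name=rec.get("name", ""),
        )
        for rec in doc.pop("rois", [])
    ]
    return rois, doc


def write_scene(scene: SyntheticScene, tiff_path, truth_csv_path) -> None:
    """Write a synthetic scene: two-page TIFF plus a ground-truth sidecar CSV.

    The sidecar has one row per ground-truth cluster: ``cluster_id``,
    ``channel``, ``x``, ``y``, ``paired_with`` (partner index in the other
    channel, or empty).
    """
    write_images(tiff_path, [scene.channel_a, scene.channel_b])
    pair_of_a = {a: b for a, b in scene.truth_pairs}
    pair_of_b = {b: a for a, b in scene.truth_pairs}
    rows = []
    for i, (x, y) in enumerate(scene.truth_clusters_a):
        rows.append({"cluster_id": i, "channel": "A", "x": x, "y": y,
                     "paired_with": pair_of_a.get(i, pd.NA)})
    for j, (x, y) in enumerate(scene.truth_clusters_b):
        rows.append({"cluster_id": j, "channel": "B", "x": x, "y": y,
                     "paired_with": pair_of_b.get(j, pd.NA)})
    pd.DataFrame(rows).to_csv(truth_csv_path, index=False)


def write_spine_geometry(path, geometry: SpineGeometry) -> None:
    rois = []
    for i, spine in enumerate(geometry.spines):
        rois.append(RegionOfInterest("polygon", spine.total_perimeter, name=f"spine{i}_total"))
        if spine.head_perimeter is not None:
            rois.append(RegionOfInterest("polygon", spine.head_perimeter, name=f"spine{i}_head"))
    write_rois(path, rois, {
        "segment_length_um": float(geometry.segment_length_um),
        "pixel_size_um": float(geometry.pixel_size_um),
    })


def read_spine_geometry(path) -> SpineGeometry:
    rois, meta = read_rois(path)
    totals: dict[str, np.ndarray] = {}
    heads: dict[str, np.ndarray] = {}
    for roi in rois:
        stem, _, part = roi.name.rpartition("_")
        if part == "total":
            totals[stem] = roi.vertices
        elif part == "head":
            heads[stem] = roi.vertices
        else:
            raise ValueError(f"unrecognized spine ROI name {roi.name!r}")
    missing = set(heads) - set(totals)
    if missing:
        raise ValueError(f"head perimeter without total perimeter: {sorted(missing)}")
    spines = [Spine(totals[k], heads.get(k)) for k in sorted(totals)]
    return SpineGeometry(
        segment_length_um=float(meta["segment_length_um"]),
        spines=spines,
        pixel_size_um=float(meta.get("pixel_size_um", 0.11)),
    )


def pixel_pairs_table(pairs: PixelPairs) -> pd.DataFrame:
    """Audit export of paired ROI pixels (row, col, A, B)."""
    return pd.DataFrame({
        "row": pairs.pixel_coords[:, 0],
        "col": pairs.pixel_coords[:, 1],
        "a": pairs.a_values,
        "b": pairs.b_values,
    })


def coloc_results_table(rows: list[dict], results: list[ColocalizationResult]) -> pd.DataFrame:
    """One CSV row per analyzed ROI: identifiers + the four coefficients."""
    records = []
    for meta, res in zip(rows, results):
        rec = dict(meta)
        rec.update(pearson_rr=res.pearson_rr, manders_m1=res.manders_m1,
                   manders_m2=res.manders_m2, icq=res.icq, n_pixels=res.n_pixels)
        records.append(rec)
    return pd.DataFrame(records)


def particles_table(clusters: ClusterSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": range(len(clusters)),
            "source": clusters.source,
            "centroid_x": [p.centroid[0] for p in clusters.particles],
            "centroid_y": [p.centroid[1] for p in clusters.particles],
            "area_px": [p.area_px for p in clusters.particles],
        }
    )
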