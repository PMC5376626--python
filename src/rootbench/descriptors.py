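"""Global image descriptors for binary root images.

The descriptor set mirrors the classical outputs of whole-root-system image
analysis tools: projected area, skeleton length, visible tip count, mean
diameter, bounding extents, center of mass, convex-hull area and the
exploration ratio.  All physical quantities use the image's mm↔pixel scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.morphology import remove_small_objects, skeletonize

from rootbench.config import DESPECKLE_AREA_PX, THRESHOLD
from rootbench.raster import RasterImage

#: The eleven image descriptors, in canonical column order.
DESCRIPTOR_COLUMNS = [
    "area",
    "length",
    "tip_count",
    "diam_mean",
    "width",
    "depth",
    "width_depth_ratio",
    "com_x",
    "com_y",
    "convexhull",
    "exploration",
]

_NEIGHBORS = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass
class DescriptorRecord:
    """One image's descriptors; NaN throughout when the cleaned mask is empty."""

    area: float                # mm², projected foreground area
    length: float              # mm, skeleton length
    tip_count: float           # skeleton end points
    diam_mean: float           # mm, area / skeleton length
    width: float               # mm, horizontal foreground extent
    depth: float               # mm, vertical foreground extent
    width_depth_ratio: float
    com_x: float               # center of mass, relative to bounding box
    com_y: float
    convexhull: float          # mm²
    exploration: float         # convex hull area / projected area

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def missing(cls) -> "DescriptorRecord":
        return cls(*([math.nan] * len(DESCRIPTOR_COLUMNS)))


def preprocess(image: RasterImage, threshold: int = THRESHOLD,
               despeckle_area_px: int = DESPECKLE_AREA_PX) -> np.ndarray:
    """Binarize and clean an image; returns a boolean foreground mask.

    A global threshold separates dark roots from the light background; then
    connected foreground components smaller than ``despeckle_area_px`` are
    removed (pepper specks) and fully isolated background pixels are filled
    (salt holes).  A clean render passes through unchanged; an image left
    all-background signals "empty mask" by returning a mask with no
    foreground, which downstream descriptors turn into missing values.
    """
    mask = image.pixels < threshold
    if despeckle_area_px > 1:
        # 8-connectivity, matching the skeleton measures: a one-pixel-wide
        # diagonal stroke is a single component, not a chain of specks.
        mask = remove_small_objects(mask, max_size=despeckle_area_px - 1,
                                    connectivity=2)
    # Fill salt: background pixels whose entire 8-neighborhood is foreground.
    n_fg = ndimage.convolve(mask.astype(np.uint8), _NEIGHBORS,
                            mode="constant", cval=0)
    mask = mask | (~mask & (n_fg == 8))
    return mask


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Skeleton length in pixels: adjacent pixel pairs count 1 (axial)
    or √2 (diagonal), the standard thinning-based estimate."""
    axial = np.count_nonzero(skel[:, 1:] & skel[:, :-1]) \
        + np.count_nonzero(skel[1:, :] & skel[:-1, :])
    diag = np.count_nonzero(skel[1:, 1:] & skel[:-1, :-1]) \
        + np.count_nonzero(skel[1:, :-1] & skel[:-1, 1:])
    return axial + math.sqrt(2.0) * diag


def skeleton_metrics(mask: np.ndarray, scale: float,
                     diam_method: str = "area_over_length",
                     ) -> tuple[float, float, float]:
    """Skeleton length (mm), tip count and mean diameter (mm) of a mask.

    The mask is thinned to a one-pixel skeleton; length is the weighted
    adjacency count, tips are skeleton pixels with exactly one skeleton
    neighbor, and the mean diameter is foreground area divided by skeleton
    length (``diam_method="distance_transform"`` switches to twice the mean
    medial-axis distance instead).
    """
    if not mask.any():
        return math.nan, math.nan, math.nan
    skel = skeletonize(mask)
    length_px = _skeleton_length_px(skel)
    n_fg = ndimage.convolve(skel.astype(np.uint8), _NEIGHBORS,
                            mode="constant", cval=0)
    tip_count = float(np.count_nonzero(skel & (n_fg == 1)))
    area_px = float(mask.sum())
    if diam_method == "distance_transform":
        dist = ndimage.distance_transform_edt(mask)
        diam_px = 2.0 * float(dist[skel].mean()) if skel.any() else math.nan
    elif diam_method == "area_over_length":
        diam_px = area_px / length_px if length_px > 0 else math.nan
    else:
        raise ValueError(f"unknown diam_method {diam_method!r}")
    return length_px / scale, tip_count, diam_px / scale


def _hull_area_px(mask: np.ndarray) -> float:
    """Convex hull area (px²) over pixel *squares*, so a filled rectangle's
    hull equals its own area exactly."""
    rows = np.flatnonzero(mask.any(axis=1))
    pts = []
    for r in rows:
        cols = np.flatnonzero(mask[r])
        for c in (cols.min(), cols.max()):
            pts.extend([(r - 0.5, c - 0.5), (r - 0.5, c + 0.5),
                        (r + 0.5, c - 0.5), (r + 0.5, c + 0.5)])
    return float(ConvexHull(np.array(pts)).volume)


def geometry_metrics(mask: np.ndarray, scale: float) -> dict:
    """Whole-system geometric descriptors of a foreground mask."""
    nan = {k: math.nan for k in ("area", "width", "depth", "width_depth_ratio",
                                 "com_x", "com_y", "convexhull", "exploration")}
    if not mask.any():
        return nan
    area_px = float(mask.sum())
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h_px = rows.max() - rows.min() + 1
    w_px = cols.max() - cols.min() + 1
    cy, cx = ndimage.center_of_mass(mask)
    com_x = (cx - cols.min() + 0.5) / w_px
    com_y = (cy - rows.min() + 0.5) / h_px
    hull_px = _hull_area_px(mask)
    return {
        "area": area_px / scale**2,
        "width": w_px / scale,
        "depth": h_px / scale,
        "width_depth_ratio": w_px / h_px,
        "com_x": float(com_x),
        "com_y": float(com_y),
        "convexhull": hull_px / scale**2,
        "exploration": hull_px / area_px,
    }


def extract_descriptors(image: RasterImage,
                        diam_method: str = "area_over_length",
                        ) -> DescriptorRecord:
    """Measure all eleven descriptors on one image.

    Composes :func:`preprocess`, :func:`skeleton_metrics` and
    :func:`geometry_metrics`; an empty cleaned mask yields a record of
    missing values.
    """
    mask = preprocess(image)
    if not mask.any():
        return DescriptorRecord.missing()
    length, tip_count, diam_mean = skeleton_metrics(
        mask, image.scale_px_per_mm, diam_method=diam_method)
    geo = geometry_metrics(mask, image.scale_px_per_mm)
    return DescriptorRecord(
        area=geo["area"], length=length, tip_count=tip_count,
        diam_mean=diam_mean, width=geo["width"], depth=geo["depth"],
        width_depth_ratio=geo["width_depth_ratio"],
        com_x=geo["com_x"], com_y=geo["com_y"],
        convexhull=geo["convexhull"], exploration=geo["exploration"],
    )


def descriptor_table(images, system_ids, noise_levels=None) -> pd.DataFrame:
    """Descriptor records for many images as one DataFrame."""
    rows = []
    for i, img in enumerate(images):
        rec = extract_descriptors(img).to_dict()
        rec["system_id"] = system_ids[i]
        rec["noise"] = noise_levels[i] if noise_levels is not None else img.noise_level
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["system_id", "noise"] + DESCRIPTOR_COLUMNS]
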