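"""Rendering root systems to raster images, noise degradation, and the
vector overlap index."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image, ImageDraw
from scipy.spatial import cKDTree

from rootbench.config import DEFAULT_DPI, SALT_PEPPER_DENSITY
from rootbench.simulator import RootSystem

NOISE_LEVELS = ("null", "medium", "high")

MARGIN_MM = 5.0


@dataclass
class RasterImage:
    """A rendered root image: intensities in [0, 255] (0 = root), the
    mm↔pixel scale, the noise level tag and the seed-point pixel position."""

    pixels: np.ndarray
    scale_px_per_mm: float
    noise_level: str = "null"
    origin_offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.scale_px_per_mm <= 0:
            raise ValueError("scale_px_per_mm must be positive")
        if self.pixels.size == 0:
            raise ValueError("pixel grid must be non-empty")


def render(system: RootSystem, dpi: float = DEFAULT_DPI) -> RasterImage:
    """Render a root system as a binary-valued image (dark roots on white).

    Each polyline edge is stroked with a width equal to the local diameter
    times the scale (dpi / 25.4 px per mm), with round joints so strokes are
    continuous; no anti-aliasing.  The canvas covers the system bounding box
    plus a fixed margin.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    scale = dpi / 25.4

    xs = np.concatenate([np.asarray(r.xs) for r in system.roots])
    ys = np.concatenate([np.asarray(r.ys) for r in system.roots])
    if system.total_length() == 0:
        warnings.warn("degenerate (zero-length) root system: blank canvas")
        size = max(int(round(2 * MARGIN_MM * scale)), 1)
        pixels = np.full((size, size), 255, dtype=np.uint8)
        return RasterImage(pixels, scale, "null",
                           (size / 2.0, size / 2.0))

    x0, x1 = xs.min() - MARGIN_MM, xs.max() + MARGIN_MM
    y0, y1 = ys.min() - MARGIN_MM, ys.max() + MARGIN_MM
    w = max(int(math.ceil((x1 - x0) * scale)), 1)
    h = max(int(math.ceil((y1 - y0) * scale)), 1)

    img = Image.new("L", (w, h), 255)
    draw = ImageDraw.Draw(img)
    for root in system.roots:
        n = root.n_nodes
        for i in range(n - 1):
            ax = (root.xs[i] - x0) * scale
            ay = (root.ys[i] - y0) * scale
            bx = (root.xs[i + 1] - x0) * scale
            by = (root.ys[i + 1] - y0) * scale
            d_px = 0.5 * (root.diams[i] + root.diams[i + 1]) * scale
            wpx = max(int(round(d_px)), 1)
            draw.line([(ax, ay), (bx, by)], fill=0, width=wpx)
            if wpx > 2:  # round joint so thick consecutive strokes connect
                r = wpx / 2.0
                draw.ellipse([bx - r, by - r, bx + r, by + r], fill=0)

    pixels = np.asarray(img, dtype=np.uint8)
    return RasterImage(pixels, scale, "null", (-x0 * scale, -y0 * scale))


def apply_salt_pepper(image: RasterImage, level: str, rng_seed: int) -> RasterImage:
    """Randomize a fraction of pixels to black or white (equal probability).

    The fraction per named level comes from
    :data:`rootbench.config.SALT_PEPPER_DENSITY`; ``"null"`` is the identity.
    Deterministic given ``rng_seed``.
    """
    if level not in SALT_PEPPER_DENSITY:
        raise ValueError(
            f"unknown noise level {level!r}; expected one of {NOISE_LEVELS}"
        )
    p = SALT_PEPPER_DENSITY[level]
    if p == 0.0:
        return replace(image, pixels=image.pixels.copy(), noise_level=level)
    rng = np.random.default_rng(rng_seed)
    pixels = image.pixels.copy()
    n = pixels.size
    k = int(round(p * n))
    idx = rng.choice(n, size=k, replace=False)
    values = rng.choice(np.array([0, 255], dtype=np.uint8), size=k)
    pixels.reshape(-1)[idx] = values
    return replace(image, pixels=pixels, noise_level=level)


# ---------------------------------------------------------------------------
# Overlap index

def _point_segment_dist(p, a, b):
    """Distances from points p (k,2) to segments (a, b) (k,2 each)."""
    ab = b - a
    ap = p - a
    L2 = np.einsum("ij,ij->i", ab, ab)
    t = np.where(L2 > 0, np.einsum("ij,ij->i", ap, ab) / np.where(L2 > 0, L2, 1), 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def _segments_intersect(a0, a1, b0, b1):
    """Proper/improper intersection test for segment pairs (k,2 arrays)."""
    def cross(o, p, q):
        return (p[:, 0] - o[:, 0]) * (q[:, 1] - o[:, 1]) \
             - (p[:, 1] - o[:, 1]) * (q[:, 0] - o[:, 0])

    d1 = cross(b0, b1, a0)
    d2 = cross(b0, b1, a1)
    d3 = cross(a0, a1, b0)
    d4 = cross(a0, a1, b1)
    # Collinear overlapping pairs give zero distance anyway.
    return ((d1 * d2) <= 0) & ((d3 * d4) <= 0)


def _segment_pair_distance(a0, a1, b0, b1):
    d = np.minimum.reduce([
        _point_segment_dist(a0, b0, b1),
        _point_segment_dist(a1, b0, b1),
        _point_segment_dist(b0, a0, a1),
        _point_segment_dist(b1, a0, a1),
    ])
    d[_segments_intersect(a0, a1, b0, b1)] = 0.0
    return d


def _candidate_pairs(mid: np.ndarray, half_len: np.ndarray,
                     max_diam: float) -> np.ndarray:
    """Candidate segment pairs whose strokes could intersect.

    A single KDTree radius must cover the longest segment, which is wasteful
    when a few long axis edges coexist with many short lateral edges; the
    long tail is therefore handled by per-point ball queries instead.
    """
    n = len(mid)
    cutoff = float(np.quantile(half_len, 0.95))
    long_mask = half_len > cutoff
    short_idx = np.flatnonzero(~long_mask)
    long_idx = np.flatnonzero(long_mask)

    out = []
    if len(short_idx) >= 1:
        hs = half_len[short_idx]
        tree = cKDTree(mid[short_idx])
        if len(short_idx) > 1:
            ss = tree.query_pairs(2.0 * hs.max() + max_diam,
                                  output_type="ndarray")
            if len(ss):
                out.append(short_idx[ss])
        if len(long_idx):
            radii = half_len[long_idx] + hs.max() + max_diam
            hits = tree.query_ball_point(mid[long_idx], radii)
            for li, hit in zip(long_idx, hits):
                if hit:
                    h = short_idx[np.asarray(hit)]
                    out.append(np.column_stack([np.full(len(h), li), h]))
    if len(long_idx) > 1:
        a, b = np.triu_indices(len(long_idx), k=1)
        la, lb = long_idx[a], long_idx[b]
        bound = half_len[la] + half_len[lb] + max_diam
        keep = np.hypot(*(mid[la] - mid[lb]).T) <= bound
        if keep.any():
            out.append(np.column_stack([la[keep], lb[keep]]))
    if n == 2 and not out:  # tiny systems: brute force
        out.append(np.array([[0, 1]]))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(out, axis=0)


def overlap_index(system: RootSystem) -> float:
    """Fraction of polyline segments whose stroked areas intersect another
    segment's stroke.

    Two segments overlap when the minimal distance between them is below
    the mean of their stroke radii sum, excluding pairs that share a node
    (consecutive edges of one root) and a lateral's first edge against its
    parent's edges around the insertion point — attachment is not overlap.
    """
    p0, p1, diam, root_id, seg_idx = [], [], [], [], []
    parent_root: list[int] = []

    roots = system.roots
    rid_of = {id(r): i for i, r in enumerate(roots)}
    for ri, root in enumerate(roots):
        pr = rid_of[id(root.parent)] if root.parent is not None else -1
        n = root.n_nodes
        for i in range(n - 1):
            p0.append((root.xs[i], root.ys[i]))
            p1.append((root.xs[i + 1], root.ys[i + 1]))
            diam.append(0.5 * (root.diams[i] + root.diams[i + 1]))
            root_id.append(ri)
            seg_idx.append(i)
            parent_root.append(pr)

    n_seg = len(p0)
    if n_seg == 0:
        raise ValueError("root system has no segments")

    p0 = np.asarray(p0)
    p1 = np.asarray(p1)
    diam = np.asarray(diam)
    root_id = np.asarray(root_id)
    seg_idx = np.asarray(seg_idx)
    parent_root = np.asarray(parent_root)

    mid = 0.5 * (p0 + p1)
    half_len = 0.5 * np.hypot(*(p1 - p0).T)
    pairs = _candidate_pairs(mid, half_len, float(diam.max()))
    if len(pairs) == 0:
        return 0.0

    overlapping = np.zeros(n_seg, dtype=bool)
    for chunk in np.array_split(pairs, max(1, len(pairs) // 500_000)):
        i, j = chunk.T
        # Drop pairs sharing a node: consecutive segments of the same root.
        keep = ~((root_id[i] == root_id[j]) & (np.abs(seg_idx[i] - seg_idx[j]) <= 1))
        # Cheap midpoint bound before the exact segment distance.
        bound = half_len[i] + half_len[j] + 0.5 * (diam[i] + diam[j])
        keep &= np.hypot(*(mid[i] - mid[j]).T) <= bound
        i, j = i[keep], j[keep]
        if len(i) == 0:
            continue
        d = _segment_pair_distance(p0[i], p1[i], p0[j], p1[j])
        close = d < 0.5 * (diam[i] + diam[j])
        i, j = i[close], j[close]
        if len(i) == 0:
            continue
        # Attachment is not overlap: a lateral's first edge against its
        # parent's edges around the insertion point is excluded.
        att = np.zeros(len(i), dtype=bool)
        for a, b in ((i, j), (j, i)):
            cand = (seg_idx[a] == 0) & (parent_root[a] == root_id[b])
            if cand.any():
                reach = 2.0 * half_len[a[cand]] + 0.5 * (diam[a[cand]] + diam[b[cand]])
                near = _point_segment_dist(p0[a[cand]], p0[b[cand]],
                                           p1[b[cand]]) <= reach
                att[np.flatnonzero(cand)[near]] = True
        i, j = i[~att], j[~att]
        overlapping[i] = True
        overlapping[j] = True

    return float(overlapping.sum() / n_seg)
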