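"""Image descriptors checked against known shapes and rendered systems."""

import math

import numpy as np
import pytest

import rootbench as rb
from rootbench.config import SALT_PEPPER_DENSITY
from rootbench.descriptors import (
    DESCRIPTOR_COLUMNS,
    descriptor_table,
    geometry_metrics,
    preprocess,
    skeleton_metrics,
)
from rootbench.raster import RasterImage
from rootbench.simulator import Root, RootSystem

SCALE = 300 / 25.4  # 11.811 px per mm


def _image_from_mask(mask: np.ndarray, scale: float = SCALE) -> RasterImage:
    pixels = np.where(mask, 0, 255).astype(np.uint8)
    return RasterImage(pixels, scale)


def _single_root(depth_mm=60.0, diam=0.8) -> RootSystem:
    root = Root(0.0, 0.0, diam, order=1)
    root.set_polyline([0.0, 0.0], [0.0, depth_mm], [diam, diam])
    return RootSystem([root], "fibrous", None)


# ---------------------------------------------------------------------------
# preprocess

def test_clean_render_passes_through_unchanged():
    img = rb.render(_single_root(), dpi=300)
    assert (preprocess(img) == (img.pixels < 128)).all()


def test_despeckle_removes_small_and_keeps_roots():
    img = rb.render(_single_root(), dpi=300)
    noisy = img.pixels.copy()
    noisy[2, 2] = 0                       # a lone pepper speck
    mask = preprocess(RasterImage(noisy, img.scale_px_per_mm))
    assert not mask[2, 2]
    assert mask.sum() == (img.pixels < 128).sum()


def test_thin_diagonal_strokes_survive_despeckling():
    """A one-pixel-wide diagonal line is 8-connected; cleaning must not
    shred it into removable specks."""
    mask = np.zeros((60, 60), dtype=bool)
    idx = np.arange(5, 55)
    mask[idx, idx] = True
    cleaned = preprocess(_image_from_mask(mask))
    assert cleaned.sum() == mask.sum()


def test_salt_holes_inside_roots_are_filled():
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:30, 10:20] = True
    holed = mask.copy()
    holed[20, 15] = False
    cleaned = preprocess(_image_from_mask(holed))
    assert cleaned[20, 15]


def test_medium_noise_area_within_five_percent():
    system = _single_root(depth_mm=80.0, diam=1.5)
    img = rb.render(system, dpi=300)
    clean_area = preprocess(img).sum()
    noisy = rb.apply_salt_pepper(img, "medium", rng_seed=4)
    assert preprocess(noisy).sum() == pytest.approx(clean_area, rel=0.05)


def test_pure_noise_image_reports_missing():
    # Sparse specks only: root-free noise leaves nothing after cleaning.
    rng = np.random.default_rng(0)
    speckle = rng.random((200, 200)) < 0.005
    rec = rb.extract_descriptors(_image_from_mask(speckle))
    assert all(math.isnan(getattr(rec, c)) for c in DESCRIPTOR_COLUMNS)


# ---------------------------------------------------------------------------
# skeleton metrics

def test_horizontal_line_skeleton():
    mask = np.zeros((30, 130), dtype=bool)
    mask[15, 5:123] = True               # 118 px long, 1 px thick
    length, tips, _ = skeleton_metrics(mask, SCALE)
    assert 9.9 <= length <= 10.1
    assert tips == 2


def test_diagonal_line_skeleton_uses_sqrt2_steps():
    mask = np.zeros((120, 120), dtype=bool)
    idx = np.arange(10, 110)
    mask[idx, idx] = True
    length, tips, _ = skeleton_metrics(mask, 1.0)
    assert length == pytest.approx(99 * math.sqrt(2))
    assert tips == 2


def test_y_shape_has_three_tips():
    mask = np.zeros((60, 60), dtype=bool)
    mask[5:30, 30] = True                # stem
    for k in range(20):
        mask[30 + k, 30 - k] = True      # left arm
        mask[30 + k, 30 + k] = True      # right arm
    _, tips, _ = skeleton_metrics(mask, 1.0)
    assert tips == 3


def test_rectangle_mean_diameter():
    mask = np.zeros((40, 220), dtype=bool)
    mask[17:23, 10:210] = True           # 200 × 6 px bar
    _, _, diam = skeleton_metrics(mask, SCALE)
    assert diam * SCALE == pytest.approx(6.0, rel=0.15)


def test_distance_transform_diameter_variant():
    mask = np.zeros((40, 220), dtype=bool)
    mask[17:23, 10:210] = True
    _, _, diam = skeleton_metrics(mask, SCALE, diam_method="distance_transform")
    assert diam * SCALE == pytest.approx(6.0, rel=0.35)
    with pytest.raises(ValueError):
        skeleton_metrics(mask, SCALE, diam_method="nope")


def test_empty_mask_metrics_are_missing():
    out = skeleton_metrics(np.zeros((10, 10), dtype=bool), SCALE)
    assert all(math.isnan(v) for v in out)


# ---------------------------------------------------------------------------
# geometry metrics

def test_filled_rectangle_geometry():
    mask = np.zeros((50, 80), dtype=bool)
    mask[10:40, 20:60] = True            # 40 wide × 30 tall
    geo = geometry_metrics(mask, scale=10.0)
    assert geo["area"] == pytest.approx(40 * 30 / 100.0)
    assert geo["width"] == pytest.approx(4.0)
    assert geo["depth"] == pytest.approx(3.0)
    assert geo["width_depth_ratio"] == pytest.approx(4.0 / 3.0)
    assert geo["com_x"] == pytest.approx(0.5)
    assert geo["com_y"] == pytest.approx(0.5)
    assert geo["exploration"] == pytest.approx(1.0)
    assert geo["convexhull"] == pytest.approx(geo["area"])


def test_l_shaped_blob_explores_more_than_it_fills():
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:20] = True
    mask[40:50, 10:50] = True
    geo = geometry_metrics(mask, scale=10.0)
    assert geo["exploration"] > 1.0
    assert geo["convexhull"] > geo["area"]


def test_two_corner_dots_hull_matches_bruteforce():
    mask = np.zeros((30, 30), dtype=bool)
    mask[2, 3] = True
    mask[25, 27] = True
    geo = geometry_metrics(mask, scale=1.0)
    assert geo["com_x"] == pytest.approx(0.5)
    assert geo["com_y"] == pytest.approx(0.5)
    # Brute-force hull of the eight pixel-square corners.
    from scipy.spatial import ConvexHull

    pts = []
    for (r, c) in ((2, 3), (25, 27)):
        pts.extend([(r - .5, c - .5), (r - .5, c + .5),
                    (r + .5, c - .5), (r + .5, c + .5)])
    assert geo["convexhull"] == pytest.approx(ConvexHull(np.array(pts)).volume)


# ---------------------------------------------------------------------------
# extract_descriptors

def test_depth_matches_ground_truth_for_single_root():
    system = _single_root(depth_mm=60.0)
    gt = rb.compute_ground_truth(system)
    rec = rb.extract_descriptors(rb.render(system, dpi=300))
    assert rec.depth == pytest.approx(gt.depth, rel=0.02)


def test_skeleton_length_at_least_tip_to_base_distance(small_library):
    for system, _ in small_library[:6]:
        axis = system.axes[0]
        chord = math.hypot(axis.xs[-1] - axis.xs[0], axis.ys[-1] - axis.ys[0])
        rec = rb.extract_descriptors(rb.render(system, dpi=150))
        assert rec.length >= 0.95 * chord


def test_descriptors_are_deterministic():
    img = rb.render(_single_root(), dpi=200)
    a = rb.extract_descriptors(img).to_dict()
    b = rb.extract_descriptors(img).to_dict()
    assert a == b


def test_record_composes_the_metric_functions():
    mask = np.zeros((50, 80), dtype=bool)
    mask[10:40, 20:60] = True
    img = _image_from_mask(mask, scale=10.0)
    rec = rb.extract_descriptors(img)
    geo = geometry_metrics(mask, 10.0)
    for name in ("area", "width", "depth", "width_depth_ratio",
                 "com_x", "com_y", "convexhull", "exploration"):
        assert getattr(rec, name) == pytest.approx(geo[name])


def test_descriptor_table_layout(small_library):
    systems = [s for s, _ in small_library[:5]]
    images = [rb.render(s, dpi=150) for s in systems]
    df = descriptor_table(images, [f"s{i}" for i in range(5)])
    assert list(df.columns) == ["system_id", "noise"] + DESCRIPTOR_COLUMNS
    assert (df["noise"] == "null").all()


def test_tip_count_tracks_lateral_count(library_run):
    """More laterals in the ground truth means more visible tips in the
    rendered image."""
    df = library_run.paired
    r = np.corrcoef(df["truth_n_2plus_orders"], df["desc_tip_count"])[0, 1]
    assert r > 0.5


def test_noise_monotonically_degrades_length_and_tips():
    """For fixed systems, mean absolute error of skeleton length and tip
    count does not improve as salt-and-pepper density rises."""
    library = rb.generate_library(80, 0.5, 23)
    errors = {"length": {}, "tip_count": {}}
    for level in rb.NOISE_LEVELS:
        e_len, e_tip = [], []
        for i, (system, _) in enumerate(library):
            clean = rb.render(system, dpi=150)
            img = rb.apply_salt_pepper(clean, level, rng_seed=1000 + i)
            rec = rb.extract_descriptors(img)
            gt = rb.compute_ground_truth(system)
            e_len.append(abs(rec.length - gt.tot_root_length))
            e_tip.append(abs(rec.tip_count - gt.n_2plus_orders))
        errors["length"][level] = np.mean(e_len)
        errors["tip_count"][level] = np.mean(e_tip)
    for name in ("length", "tip_count"):
        assert errors[name]["medium"] >= errors[name]["null"]
        assert errors[name]["high"] >= errors[name]["medium"]
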