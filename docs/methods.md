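# Methods

This note records how each stage of the benchmark is computed, with the
conventions and defaults needed to interpret (or re-derive) the numbers the
package produces.

## 1. Root-system simulation

Root systems are grown in two dimensions (x horizontal, y positive
downward, millimetres) by a discrete-time architectural model.

**State.** A system is a set of `Root` polylines. Each root carries its
apical diameter, its branching order (1 = primary axis), its insertion
position on the parent (mm along the parent polyline), and per-node
diameters.

**Growth rules, per time step (default 1 day):**

- *Elongation* is proportional to apical diameter: a root of diameter `d`
  grows `elong_coeff × d × Δt` millimetres per step.
- *Determinate growth*: a root stops elongating once its age exceeds
  `300 day/mm² × d²`, so thin roots are short-lived and thick axes keep
  growing.
- *Direction*: each new segment's heading is the previous heading pulled
  toward vertical by `tropism_strength`, plus Gaussian noise
  (`direction_noise_sd_deg`). Headings are clamped to the downward
  hemisphere, so roots never grow upward.
- *Branching* is acropetal: a parent emits a lateral every
  `interbranch_mm` of its own length, behind an apical unbranched zone.
  The daughter diameter is `diam_ratio × d_parent`, multiplied by
  truncated Gaussian noise (factor limited to [0.6, 1.4]) and capped at
  half the mother diameter. Daughters thinner than `d_min_mm` are never
  created; branching stops at order 6.
- *Insertion angle* is drawn from a Gaussian
  (`insertion_angle_mean_deg ± insertion_angle_sd_deg`) relative to the
  parent's local tangent, with a random left/right side.
- *Secondary growth* (tap-rooted systems only): each existing segment
  thickens in proportion to the total root length distal to it
  (`sec_growth_coeff`), a pipe-model rule that produces the familiar
  basally-thickened taproot.

**Plant types.** Fibrous systems have several primary axes (`n_axes > 1`),
no secondary growth, and thin axes. Tap-rooted systems have one primary
axis with secondary growth. Parameter vectors are drawn uniformly from
per-type intervals stored in `src/rootbench/data/sampling_ranges.yaml`;
`generate_library(n, fibrous_fraction, base_seed)` derives one independent
seed per system from a `SeedSequence`, so libraries are reproducible and
individual systems are independent of library size.

## 2. Ground truth and RSML

`compute_ground_truth` measures 13 traits directly on the simulated
geometry (never on images): total root length; total, mean length, count
and mean diameter of the primary axes (`*_1_order*`) and of all
higher-order roots (`*_2plus_order*`); lateral branching density
(per axis, lateral count divided by axis length, averaged over axes);
mean lateral insertion angle relative to the parent tangent;
and the bounding width and depth of the system.

Systems are serialized to RSML: one XML file per system, geometry as
per-node `x`, `y` plus a `diameter` function, orders nested as child
`<root>` elements. Floats are written with Python `repr`, so a
write→read→write cycle is byte-identical. The reader accepts `cm` units
(scaling to mm) and tolerates missing diameters with a warning.

## 3. Rasterization and noise

`render` draws each polyline segment as a stroke of width equal to the
local diameter (round caps), black on white, at `scale = dpi / 25.4`
pixels per millimetre, with a small white margin. The physical scale and
the origin offset are stored in a JSON sidecar next to each PNG.

Salt-and-pepper noise (`apply_salt_pepper`) flips a fraction of pixels to
the opposite extreme: density 0 ("null"), 0.05 ("medium"), 0.15 ("high"),
seeded per image.

`overlap_index` quantifies self-occlusion in the drawn image: the fraction
of root pixels painted by more than one root, excluding each lateral's
attachment neighbourhood on its parent (those pixels overlap by
construction, not by crowding).

## 4. Image descriptors

`preprocess` binarizes at grey level 128, fills one-pixel holes, and
removes connected components smaller than 4 pixels. Component analysis
uses 8-connectivity, matching the skeleton conventions: a one-pixel-wide
diagonal stroke is a single component, not a chain of removable specks.
An image with nothing left after cleaning yields all-NaN descriptors.

Eleven descriptors are measured on the cleaned mask:

- **length** — skeletonize (medial axis thinning), then sum adjacency
  steps weighting axial neighbours 1 and diagonal neighbours √2 (the
  standard ImageJ-compatible estimate), divided by the pixel scale.
- **tip_count** — skeleton pixels with exactly one 8-neighbour.
- **diameter** — mask area divided by skeleton length (default), or the
  mean medial-axis distance-transform width (`diam_method`).
- **area, convexhull** — pixel counts / hull of pixel squares, in mm².
  The hull treats each foreground pixel as a unit square (its four
  corners), so single-pixel features have nonzero hull area.
- **depth, width, width_depth_ratio** — bounding-box extents in mm.
- **com_x, com_y** — centre of mass, normalized by width and depth.
- **exploration** — convex-hull area divided by root area.

## 5. Evaluation

`build_paired_dataset` joins ground truth (per system) with descriptors
(per system × noise level) and optionally the overlap index. On top of it:

- `mean_relative_error`: mean of `|estimate − truth| / |truth|` over rows
  where both are finite and truth ≠ 0; excluded rows are counted and
  reported (`MeanRelativeError(value, n_used, n_excluded)`).
- `r2_matrix`: squared Pearson correlation of every descriptor with every
  trait, per plant type, at one noise level; cells with < 3 complete pairs
  or constant columns are NaN.
- `mre_by_overlap_bin`: MRE of a (truth, descriptor) pair within
  equal-count bins of the overlap index, flagging empty or degenerate
  bins — how measurement error grows with self-occlusion.
- `pca_ground_truth`: PCA of the 13 standardized traits (median imputation
  for missing, constant columns dropped), returning variance fractions and
  loadings.
- `manova_type_effect`: one-way MANOVA (Pillai's trace) of the 13
  standardized traits against plant type; requires more rows per group
  than traits, and raises `ValueError` otherwise.

## 6. Random-forest calibration

`train_calibration` learns each ground-truth trait from the descriptor
vector (plus a fibrous/tap indicator):

1. Rows are split 3/4 train, 1/4 test, stratified by plant type, with a
   seeded permutation.
2. Training-set missing values are imputed (median start, then iterated
   random-forest imputation); test features are completed with training
   medians only — held-out responses are never touched.
3. For every trait and every grid cell (trees ∈ {10, 50, 100, 300} ×
   sub-forests ∈ {1, 2, 4}), the training rows are partitioned into `m`
   disjoint subsets, one forest of `n` trees is fitted per subset
   (variance-reduction split criterion, `max_features = ⌈p/3⌉`, the
   regression default of the classical random-forest implementations),
   and predictions are averaged across the `m` forests. `fit_grid`
   requires `m ≤ n_train / 10` so every sub-forest sees at least ten rows.
4. `select_model` keeps, per trait, the grid cell with the lowest RMSE on
   the held-out rows (rows with non-finite truth are dropped from the
   RMSE, never imputed).

The resulting `EnsembleModel` predicts all 13 traits for new descriptor
rows and round-trips through `save_model`/`load_model` (joblib with a
format tag).

## 7. Pipeline and reproducibility

`run_pipeline` chains the stages into one seeded workflow
(RSML + images + `ground_truth.csv` + `overlap_index.csv` +
`descriptors.csv` + report + models) and writes a `manifest.json`
containing the configuration and SHA-256 hashes of every CSV. Identical
configurations reproduce all CSVs byte-for-byte.

One file-format caveat is handled centrally: the noise level `"null"` is a
literal string that pandas would silently parse as missing data. All CSVs
produced by the package should be read back with
`rootbench.pipeline.read_table`, which keeps `"null"` and treats only
empty cells and explicit `NaN` markers as missing.
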