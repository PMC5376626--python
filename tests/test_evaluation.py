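"""Accuracy statistics: MRE, r² matrices, overlap binning, PCA, MANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

import rootbench as rb
from rootbench.descriptors import DESCRIPTOR_COLUMNS
from rootbench.rsml import TRAIT_COLUMNS


def _paired_frame(n=40, seed=0, with_overlap=True):
    """A synthetic paired table with descriptor = trait + controllable error."""
    rng = np.random.default_rng(seed)
    gt = pd.DataFrame({"system_id": [f"s{i}" for i in range(n)]})
    for t in TRAIT_COLUMNS:
        gt[t] = rng.uniform(10, 100, n)
    gt["plant_type"] = np.where(np.arange(n) % 2 == 0, "fibrous", "tap")
    desc = pd.DataFrame({"system_id": gt["system_id"], "noise": "null"})
    for d in DESCRIPTOR_COLUMNS:
        desc[d] = rng.uniform(0, 1, n)
    desc["length"] = gt["tot_root_length"].to_numpy()
    overlap = pd.DataFrame({"system_id": gt["system_id"],
                            "overlap_index": rng.uniform(0, 1, n)}) \
        if with_overlap else None
    return gt, desc, overlap


# ---------------------------------------------------------------------------
# mean relative error

def test_mre_hand_arithmetic_exact():
    m = rb.mean_relative_error([10.0, 20.0], [9.0, 22.0])
    # (|10-9|/10 + |20-22|/20) / 2 = (0.1 + 0.1) / 2
    assert abs(m.value - 0.1) < 1e-12
    assert m.n_used == 2 and m.n_excluded == 0


def test_mre_excludes_zero_truth_and_missing():
    m = rb.mean_relative_error([0.0, 10.0, math.nan, 20.0],
                               [5.0, 11.0, 3.0, math.nan])
    assert m.n_used == 1 and m.n_excluded == 3
    assert m.value == pytest.approx(0.1)


def test_mre_all_excluded_warns_and_is_nan():
    with pytest.warns(UserWarning, match="no retained pairs"):
        m = rb.mean_relative_error([0.0, 0.0], [1.0, 2.0])
    assert math.isnan(m.value) and m.n_used == 0


def test_mre_rejects_length_mismatch():
    with pytest.raises(ValueError):
        rb.mean_relative_error([1.0], [1.0, 2.0])


def test_mre_is_row_order_invariant():
    rng = np.random.default_rng(3)
    t = rng.uniform(1, 10, 50)
    e = t + rng.normal(0, 1, 50)
    perm = rng.permutation(50)
    assert rb.mean_relative_error(t, e).value == \
        pytest.approx(rb.mean_relative_error(t[perm], e[perm]).value)


# ---------------------------------------------------------------------------
# paired dataset

def test_paired_join_prefixes_and_aligns():
    gt, desc, overlap = _paired_frame()
    paired = rb.build_paired_dataset(gt, desc, overlap)
    assert len(paired) == len(desc)
    assert {"truth_tot_root_length", "desc_length", "overlap_index",
            "plant_type"} <= set(paired.columns)
    row = paired.set_index("system_id").loc["s3"]
    assert row["truth_depth"] == gt.set_index("system_id").loc["s3", "depth"]


def test_paired_join_rejects_duplicates():
    gt, desc, _ = _paired_frame()
    with pytest.raises(ValueError):
        rb.build_paired_dataset(gt, pd.concat([desc, desc]))
    with pytest.raises(ValueError):
        rb.build_paired_dataset(pd.concat([gt, gt]), desc)


# ---------------------------------------------------------------------------
# r² matrix

def test_r2_is_one_for_identical_columns():
    gt, desc, _ = _paired_frame()
    paired = rb.build_paired_dataset(gt, desc)
    mats = rb.r2_matrix(paired)
    for ptype in ("fibrous", "tap"):
        assert mats[ptype].loc["length", "tot_root_length"] == pytest.approx(1.0)


def test_r2_of_independent_noise_is_tiny():
    gt, desc, _ = _paired_frame(n=10_000, seed=1)
    paired = rb.build_paired_dataset(gt, desc)
    mats = rb.r2_matrix(paired)
    assert mats["fibrous"].loc["area", "depth"] < 0.01


def test_r2_grouping_excludes_other_plant_type():
    gt, desc, _ = _paired_frame()
    # Make the descriptor track the trait for fibrous rows only.
    fib = gt["plant_type"] == "fibrous"
    desc.loc[fib.to_numpy(), "area"] = gt.loc[fib, "width"].to_numpy()
    paired = rb.build_paired_dataset(gt, desc)
    mats = rb.r2_matrix(paired)
    assert mats["fibrous"].loc["area", "width"] == pytest.approx(1.0)
    assert mats["tap"].loc["area", "width"] < 0.5


def test_r2_matches_textbook_formula(library_run):
    """Five random cells agree with an independently coded Pearson r²."""
    rng = np.random.default_rng(11)
    paired = library_run.paired
    mats = rb.r2_matrix(paired)
    for _ in range(5):
        ptype = rng.choice(["fibrous", "tap"])
        d = rng.choice(DESCRIPTOR_COLUMNS)
        t = rng.choice(TRAIT_COLUMNS)
        sub = paired[paired["plant_type"] == ptype]
        x = sub[f"desc_{d}"].to_numpy(float)
        y = sub[f"truth_{t}"].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2 = sxy**2 / (((x - x.mean())**2).sum() * ((y - y.mean())**2).sum())
        cell = mats[ptype].loc[d, t]
        if math.isnan(cell):
            assert len(x) < 3 or x.std() == 0 or y.std() == 0
        else:
            assert cell == pytest.approx(r2, rel=1e-9)


def test_r2_values_lie_in_unit_interval(library_run):
    for mat in rb.r2_matrix(library_run.paired).values():
        vals = mat.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# overlap binning

def test_single_bin_equals_global_mre():
    gt, desc, overlap = _paired_frame()
    desc["length"] = gt["tot_root_length"] * 1.1
    paired = rb.build_paired_dataset(gt, desc, overlap)
    table = rb.mre_by_overlap_bin(paired, "tot_root_length", "length", n_bins=1)
    global_mre = rb.mean_relative_error(paired["truth_tot_root_length"],
                                        paired["desc_length"])
    assert len(table) == 1
    assert table.loc[0, "mre"] == pytest.approx(global_mre.value)
    assert table.loc[0, "n_used"] == global_mre.n_used


def test_constructed_monotone_error_gives_increasing_bins():
    gt, desc, overlap = _paired_frame(n=200, seed=5)
    ov = overlap.set_index("system_id").loc[gt["system_id"], "overlap_index"]
    desc["length"] = gt["tot_root_length"].to_numpy() * (1 + ov.to_numpy())
    paired = rb.build_paired_dataset(gt, desc, overlap)
    table = rb.mre_by_overlap_bin(paired, "tot_root_length", "length", n_bins=5)
    assert (np.diff(table["mre"]) > 0).all()


def test_empty_bins_are_flagged_not_fabricated():
    gt, desc, overlap = _paired_frame(n=20, seed=2)
    overlap["overlap_index"] = np.r_[np.full(19, 0.01), 1.0]
    paired = rb.build_paired_dataset(gt, desc, overlap)
    table = rb.mre_by_overlap_bin(paired, "tot_root_length", "length", n_bins=5)
    middle = table.iloc[1:4]
    assert (middle["n_used"] == 0).all()
    assert middle["mre"].isna().all()
    assert middle["flagged"].all()


def test_binning_rejects_bad_input():
    gt, desc, overlap = _paired_frame()
    paired = rb.build_paired_dataset(gt, desc, overlap)
    with pytest.raises(ValueError):
        rb.mre_by_overlap_bin(paired, "tot_root_length", "length", n_bins=0)
    with pytest.raises(ValueError):
        rb.mre_by_overlap_bin(paired.iloc[0:0], "tot_root_length", "length")


# ---------------------------------------------------------------------------
# PCA

def test_pca_fractions_and_loadings_are_consistent(library_run):
    fractions, loadings, scores = rb.pca_ground_truth(library_run.ground_truth)
    assert fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(fractions) <= 1e-12).all()          # sorted descending
    # Component vectors are orthonormal.
    gram = loadings.to_numpy() @ loadings.to_numpy().T
    assert np.allclose(gram, np.eye(len(fractions)), atol=1e-9)
    assert scores.shape[0] == len(library_run.ground_truth)


def test_pca_imputes_missing_by_median():
    gt, _, _ = _paired_frame(n=50, seed=8)
    gt.loc[3, "mean_2plus_order_angle"] = np.nan
    fractions, _, scores = rb.pca_ground_truth(gt)
    assert np.isfinite(scores).all()
    assert fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_drops_constant_columns_with_warning():
    gt, _, _ = _paired_frame(n=30, seed=9)
    gt["depth"] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        _, loadings, _ = rb.pca_ground_truth(gt)
    assert "depth" not in loadings.columns


def test_pca_needs_two_systems():
    gt, _, _ = _paired_frame(n=1)
    with pytest.raises(ValueError):
        rb.pca_ground_truth(gt)


# ---------------------------------------------------------------------------
# MANOVA

def test_manova_detects_separated_groups():
    rng = np.random.default_rng(4)
    n = 60
    gt = pd.DataFrame({t: rng.normal(0, 1, n) for t in TRAIT_COLUMNS})
    types = np.where(np.arange(n) < n // 2, "fibrous", "tap")
    gt.loc[types == "tap", "tot_root_length"] += 10.0
    p = rb.manova_type_effect(gt, types)
    assert p < 0.001


def test_manova_null_groups_are_not_separated():
    rng = np.random.default_rng(6)
    n = 400
    gt = pd.DataFrame({t: rng.normal(0, 1, n) for t in TRAIT_COLUMNS})
    types = np.where(rng.random(n) < 0.5, "fibrous", "tap")
    p = rb.manova_type_effect(gt, types)
    assert p > 0.001


def test_manova_requires_both_groups_and_enough_rows():
    rng = np.random.default_rng(5)
    gt = pd.DataFrame({t: rng.normal(0, 1, 40) for t in TRAIT_COLUMNS})
    with pytest.raises(ValueError):
        rb.manova_type_effect(gt, ["fibrous"] * 40)
    types = ["fibrous"] * 5 + ["tap"] * 35
    with pytest.raises(ValueError):
        rb.manova_type_effect(gt, types)
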