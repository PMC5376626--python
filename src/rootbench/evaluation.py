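"""Accuracy statistics: mean relative error, r² matrices, overlap-index
binning, PCA and MANOVA of the ground-truth trait table."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.multivariate.manova import MANOVA

from rootbench.descriptors import DESCRIPTOR_COLUMNS
from rootbench.rsml import TRAIT_COLUMNS


@dataclass
class MeanRelativeError:
    """MRE = mean over retained pairs of |truth − estimate| / truth.

    Pairs with zero truth (relative error undefined) or missing values are
    excluded; their count is always carried along.
    """

    value: float
    n_used: int
    n_excluded: int

    def __float__(self) -> float:
        return float(self.value)


def mean_relative_error(truth, estimate) -> MeanRelativeError:
    """Mean relative error between a ground-truth and an estimated vector."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError("truth and estimate must have equal length")
    keep = np.isfinite(t) & np.isfinite(e) & (t != 0)
    n_excluded = int(t.size - keep.sum())
    if not keep.any():
        warnings.warn("no retained pairs for MRE (all zero-truth or missing)")
        return MeanRelativeError(math.nan, 0, n_excluded)
    value = float(np.mean(np.abs(t[keep] - e[keep]) / t[keep]))
    return MeanRelativeError(value, int(keep.sum()), n_excluded)


def build_paired_dataset(ground_truth: pd.DataFrame,
                         descriptors: pd.DataFrame,
                         overlap: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join ground truth and descriptors into one analysis table.

    ``ground_truth`` has one row per system (``system_id``, the 13 traits,
    ``plant_type``); ``descriptors`` one row per (``system_id``, ``noise``);
    ``overlap`` optionally maps ``system_id`` to ``overlap_index``.  Trait
    columns are prefixed ``truth_``, descriptor columns ``desc_``.
    """
    gt = ground_truth.rename(columns={c: f"truth_{c}" for c in TRAIT_COLUMNS})
    de = descriptors.rename(columns={c: f"desc_{c}" for c in DESCRIPTOR_COLUMNS})
    if de.duplicated(["system_id", "noise"]).any():
        raise ValueError("duplicate (system_id, noise) rows in descriptors")
    if gt.duplicated(["system_id"]).any():
        raise ValueError("duplicate system_id rows in ground truth")
    # Descriptor tables may carry extra metadata (e.g. plant_type) that the
    # ground truth also provides; keep the ground-truth copy.
    clash = [c for c in de.columns if c in gt.columns and c != "system_id"]
    out = de.drop(columns=clash).merge(gt, on="system_id", how="inner",
                                       validate="many_to_one")
    if overlap is not None:
        out = out.merge(overlap[["system_id", "overlap_index"]], on="system_id",
                        how="left", validate="many_to_one")
    return out


def r2_matrix(data: pd.DataFrame, noise: str = "null",
              min_pairs: int = 3) -> dict[str, pd.DataFrame]:
    """Squared Pearson correlation of every descriptor against every trait.

    Computed separately per plant type on rows at the given noise level;
    cells with fewer than ``min_pairs`` complete pairs, or with a constant
    descriptor or trait, are NaN.
    """
    sub = data[data["noise"] == noise]
    out: dict[str, pd.DataFrame] = {}
    for ptype, grp in sub.groupby("plant_type"):
        mat = pd.DataFrame(index=DESCRIPTOR_COLUMNS, columns=TRAIT_COLUMNS,
                           dtype=float)
        for d in DESCRIPTOR_COLUMNS:
            dv = grp[f"desc_{d}"].to_numpy(dtype=float)
            for t in TRAIT_COLUMNS:
                tv = grp[f"truth_{t}"].to_numpy(dtype=float)
                keep = np.isfinite(dv) & np.isfinite(tv)
                if keep.sum() < min_pairs:
                    continue
                x, y = dv[keep], tv[keep]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                mat.loc[d, t] = r * r
        out[ptype] = mat
    return out


def mre_by_overlap_bin(data: pd.DataFrame, trait: str, descriptor: str,
                       n_bins: int = 5, noise: str = "null") -> pd.DataFrame:
    """MRE of a descriptor against a trait within equal-width overlap bins.

    The overlap index range is split into ``n_bins`` equal-width bins; the
    MRE is computed within each; bins with fewer than 5 retained rows are
    flagged rather than dropped.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    sub = data[data["noise"] == noise]
    if len(sub) == 0:
        raise ValueError("empty dataset")
    ov = sub["overlap_index"].to_numpy(dtype=float)
    lo, hi = np.nanmin(ov), np.nanmax(ov)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, ov, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = which == b
        mre = mean_relative_error(sub.loc[in_bin, f"truth_{trait}"],
                                  sub.loc[in_bin, f"desc_{descriptor}"]) \
            if in_bin.any() else MeanRelativeError(math.nan, 0, 0)
        rows.append({
            "bin": b, "bin_low": edges[b], "bin_high": edges[b + 1],
            "mre": mre.value, "n_used": mre.n_used,
            "n_excluded": mre.n_excluded, "flagged": mre.n_used < 5,
        })
    return pd.DataFrame(rows)


def _impute_median(values: pd.DataFrame) -> pd.DataFrame:
    return values.fillna(values.median(numeric_only=True))


def pca_ground_truth(truths: pd.DataFrame):
    """PCA of the ground-truth trait table.

    Missing trait values are imputed by the column median, variables are
    standardized to unit variance (the traits span several orders of
    magnitude), zero-variance columns are dropped with a warning.  Returns
    ``(variance_fractions, loadings, scores)`` with fractions sorted
    descending and summing to 1.
    """
    if len(truths) < 2:
        raise ValueError("PCA needs at least two systems")
    cols = [c for c in TRAIT_COLUMNS if c in truths.columns]
    x = _impute_median(truths[cols].astype(float))
    keep = [c for c in cols if x[c].std() > 0]
    if len(keep) < len(cols):
        warnings.warn(f"dropping zero-variance columns: {sorted(set(cols) - set(keep))}")
    x = x[keep]
    z = (x - x.mean()) / x.std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    fractions = pca.explained_variance_ratio_
    loadings = pd.DataFrame(pca.components_,
                            index=[f"PC{i+1}" for i in range(len(fractions))],
                            columns=keep)
    return fractions, loadings, scores


def manova_type_effect(truths: pd.DataFrame, types) -> float:
    """One-way MANOVA p-value for the plant-type effect on the traits.

    Traits are median-imputed and standardized; the Pillai trace statistic
    is converted to an approximate F probability.  Requires both plant
    types, each with more rows than there are traits.
    """
    types = pd.Series(np.asarray(types), name="plant_type")
    levels = types.unique()
    if len(levels) < 2:
        raise ValueError("MANOVA needs both plant types present")
    cols = [c for c in TRAIT_COLUMNS if c in truths.columns]
    x = _impute_median(truths[cols].astype(float).reset_index(drop=True))
    x = x.loc[:, x.std() > 0]
    n_traits = x.shape[1]
    for lev in levels:
        if (types == lev).sum() <= n_traits:
            raise ValueError(
                f"group {lev!r} needs more than {n_traits} observations"
            )
    z = (x - x.mean()) / x.std(ddof=0)
    frame = z.copy()
    frame["plant_type"] = types.to_numpy()
    formula = " + ".join(z.columns) + " ~ C(plant_type)"
    try:
        mv = MANOVA.from_formula(formula, data=frame)
        res = mv.mv_test()
    except Exception as exc:  # singular covariance (e.g., duplicated rows)
        raise ValueError(f"degenerate covariance, MANOVA undefined: {exc}") from exc
    stat = res.results["C(plant_type)"]["stat"]
    return float(stat.loc["Pillai's trace", "Pr > F"])
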