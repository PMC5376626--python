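"""Random-forest trait calibration.

Learns each ground-truth trait from the image descriptors: the paired
dataset is split into training (3/4) and testing (1/4) subsets; missing
values are imputed (median, then refined by a small random forest); for
each trait a grid of candidate models is generated, where a candidate with
parameters (t, m) partitions the training rows into m disjoint subsets,
fits one t-tree regression forest per subset and predicts with the mean of
the m forests; the candidate minimizing held-out RMSE is selected per
trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from rootbench.descriptors import DESCRIPTOR_COLUMNS
from rootbench.rsml import TRAIT_COLUMNS

DEFAULT_TREES_GRID = (10, 50, 100, 300)
DEFAULT_SPLITS_GRID = (1, 2, 4)

# Trees split on variance reduction (squared-error impurity), the regression
# analogue of the classification Gini criterion; candidate features per split
# follow the classic randomForest regression default of p/3.
_CRITERION = "squared_error"
_MAX_FEATURES = 1.0 / 3.0


@dataclass
class LearningDataset:
    """Features (descriptor space) and responses (trait space), row-aligned."""

    features: pd.DataFrame
    responses: pd.DataFrame

    def __post_init__(self):
        if len(self.features) != len(self.responses):
            raise ValueError("features and responses must have equal row counts")
        if self.features.shape[1] < 1 or self.responses.shape[1] < 1:
            raise ValueError("need at least one feature and one response column")
        for df in (self.features, self.responses):
            if df.columns.duplicated().any():
                raise ValueError("column names must be unique")

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def from_paired(cls, paired: pd.DataFrame, noise: str = "null",
                    include_type_indicator: bool = True) -> "LearningDataset":
        """Build a learning dataset from a paired analysis table at one
        noise level: 11 descriptors (plus a fibrous/tap indicator) as
        features, the 13 traits as responses."""
        sub = paired[paired["noise"] == noise].reset_index(drop=True)
        feats = sub[[f"desc_{c}" for c in DESCRIPTOR_COLUMNS]].copy()
        feats.columns = DESCRIPTOR_COLUMNS
        if include_type_indicator:
            feats["is_fibrous"] = (sub["plant_type"] == "fibrous").astype(float)
        resp = sub[[f"truth_{c}" for c in TRAIT_COLUMNS]].copy()
        resp.columns = TRAIT_COLUMNS
        return cls(feats.astype(float), resp.astype(float))


@dataclass
class SplitSpec:
    train_fraction: float = 0.75
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")

    @property
    def test_fraction(self) -> float:
        return 1.0 - self.train_fraction


@dataclass
class CandidateModel:
    """One (trees, splits) candidate for one response variable."""

    response: str
    n_trees: int
    n_splits: int
    forests: list = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        preds = [f.predict(x) for f in self.forests]
        return np.mean(preds, axis=0)


@dataclass
class TraitEnsemble:
    """The selected candidate for one trait, with its held-out RMSE."""

    response: str
    n_trees: int
    n_splits: int
    forests: list
    rmse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.mean([f.predict(x) for f in self.forests], axis=0)


@dataclass
class EnsembleModel:
    """Per-trait selected forest ensembles sharing one feature schema."""

    feature_columns: list[str]
    traits: dict[str, TraitEnsemble]

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"features lack required columns: {missing}")
        x = features[self.feature_columns].to_numpy(dtype=float)
        return pd.DataFrame({name: ens.predict(x)
                             for name, ens in self.traits.items()},
                            index=features.index)


def rmse(truth, estimate) -> float:
    """Root-mean-square error √(mean (yᵢ − ŷᵢ)²)."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError("truth and estimate must have equal length")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def split_train_test(data: LearningDataset, spec: SplitSpec
                     ) -> tuple[LearningDataset, LearningDataset]:
    """Seeded disjoint, exhaustive train/test split.

    When the feature table carries the fibrous/tap indicator the split is
    stratified on it so both plant types appear in both subsets.
    """
    n = len(data)
    if n < 8:
        raise ValueError("need at least 8 rows to split")
    rng = np.random.default_rng(spec.rng_seed)
    if "is_fibrous" in data.features.columns:
        strata = data.features["is_fibrous"].to_numpy()
    else:
        strata = np.zeros(n)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(len(idx) * spec.train_fraction))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)

    def take(ix):
        return LearningDataset(data.features.iloc[ix].reset_index(drop=True),
                               data.responses.iloc[ix].reset_index(drop=True))

    return take(train_idx), take(test_idx)


def _impute_frame(df: pd.DataFrame, rng_seed: int, n_trees: int = 10
                  ) -> pd.DataFrame:
    """Median imputation refined by a small random forest per column.

    Each missing entry is first set to its column median; then, for every
    column that had missing values, a ``n_trees``-tree forest fitted on the
    originally-observed rows (using the completed other columns) re-predicts
    the missing cells.  Observed values are never altered.
    """
    out = df.copy()
    missing_cols = [c for c in df.columns if df[c].isna().any()]
    for c in missing_cols:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
    completed = out.fillna(out.median(numeric_only=True))
    for i, c in enumerate(missing_cols):
        obs = ~df[c].isna()
        others = [k for k in df.columns if k != c]
        forest = RandomForestRegressor(
            n_estimators=n_trees, criterion=_CRITERION,
            max_features=_MAX_FEATURES,
            random_state=(rng_seed + i) % (2**31), n_jobs=1)
        forest.fit(completed.loc[obs, others].to_numpy(dtype=float),
                   df.loc[obs, c].to_numpy(dtype=float))
        out.loc[~obs, c] = forest.predict(
            completed.loc[~obs, others].to_numpy(dtype=float))
    return out


def impute_missing(data: LearningDataset, rng_seed: int = 0) -> LearningDataset:
    """Impute missing entries in both features and responses."""
    return LearningDataset(
        _impute_frame(data.features, rng_seed),
        _impute_frame(data.responses, rng_seed + 10_000),
    )


def fit_grid(train: LearningDataset,
             trees_grid=DEFAULT_TREES_GRID,
             splits_grid=DEFAULT_SPLITS_GRID,
             rng_seed: int = 0) -> dict[str, list[CandidateModel]]:
    """Fit all (trees, splits) candidates for every response variable.

    For a pair (t, m) the training rows are partitioned into m disjoint
    subsets (seeded shuffle) and one t-tree forest is fitted per subset; the
    candidate predicts with the mean of its m forests.
    """
    if not trees_grid or not splits_grid:
        raise ValueError("grids must be non-empty")
    n = len(train)
    for m in splits_grid:
        if m < 1 or m > n / 10:
            raise ValueError(
                f"number of splits {m} infeasible for {n} training rows")
    if train.features.isna().any().any() or train.responses.isna().any().any():
        raise ValueError("training data contains missing values; impute first")

    rng = np.random.default_rng(rng_seed)
    x = train.features.to_numpy(dtype=float)
    partitions = {m: np.array_split(rng.permutation(n), m) for m in splits_grid}

    candidates: dict[str, list[CandidateModel]] = {}
    for response in train.responses.columns:
        y = train.responses[response].to_numpy(dtype=float)
        cands = []
        for t in trees_grid:
            for m in splits_grid:
                forests = []
                for part in partitions[m]:
                    forest = RandomForestRegressor(
                        n_estimators=int(t), criterion=_CRITERION,
                        max_features=_MAX_FEATURES,
                        random_state=int(rng.integers(2**31)), n_jobs=1)
                    forest.fit(x[part], y[part])
                    forests.append(forest)
                cands.append(CandidateModel(response, int(t), int(m), forests))
        candidates[response] = cands
    return candidates


def select_model(candidates: dict[str, list[CandidateModel]],
                 test: LearningDataset) -> EnsembleModel:
    """Retain, per trait, the candidate with minimal held-out RMSE.

    Ties break toward fewer trees, then fewer splits.
    """
    if not candidates or any(len(v) == 0 for v in candidates.values()):
        raise ValueError("empty candidate set")
    if len(test) == 0:
        raise ValueError("test set is empty")
    x = test.features.to_numpy(dtype=float)
    traits: dict[str, TraitEnsemble] = {}
    for response, cands in candidates.items():
        y = test.responses[response].to_numpy(dtype=float)
        keep = np.isfinite(y)  # traits undefined for some systems (no laterals)
        if not keep.any():
            raise ValueError(f"no finite test responses for {response!r}")
        scored = [(rmse(y[keep], c.predict(x)[keep]), c.n_trees, c.n_splits, c)
                  for c in cands]
        best = min(scored, key=lambda s: (s[0], s[1], s[2]))
        traits[response] = TraitEnsemble(response, best[3].n_trees,
                                         best[3].n_splits, best[3].forests,
                                         best[0])
    feature_columns = list(test.features.columns)
    return EnsembleModel(feature_columns, traits)


def predict_traits(model: EnsembleModel, descriptors: pd.DataFrame
                   ) -> pd.DataFrame:
    """Predict every trait for new descriptor rows (deterministic)."""
    return model.predict(descriptors)


def train_calibration(data: LearningDataset,
                      spec: SplitSpec | None = None,
                      trees_grid=DEFAULT_TREES_GRID,
                      splits_grid=DEFAULT_SPLITS_GRID,
                      rng_seed: int = 0):
    """End-to-end calibration: split, impute, fit the grid, select.

    Returns ``(model, train, test, predictions)`` where ``predictions`` are
    the selected models' held-out estimates for the test rows.
    """
    spec = spec or SplitSpec(rng_seed=rng_seed)
    train, test = split_train_test(data, spec)
    train = impute_missing(train, rng_seed=rng_seed)
    # Test features are completed with training medians only: the held-out
    # responses are never touched.
    med = train.features.median(numeric_only=True)
    test = LearningDataset(test.features.fillna(med).reset_index(drop=True),
                           test.responses.reset_index(drop=True))
    candidates = fit_grid(train, trees_grid, splits_grid, rng_seed=rng_seed)
    model = select_model(candidates, test)
    predictions = model.predict(test.features)
    return model, train, test, predictions
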