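"""Shared fixtures.

Two session-scoped benchmark runs back the expensive statistical tests:

* ``library_run`` — a seeded 500 fibrous + 500 tap library with clean
  150-DPI renders, descriptors and overlap indices (type separation,
  geometry accuracy and overlap-binning tests).
* ``calibration_run`` — a seeded 2,000-system library with descriptors at
  all three noise levels and a trained random-forest calibration per level
  (trait-recovery tests).

Both use fixed seeds so every test sees the same libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import rootbench as rb
from rootbench.descriptors import descriptor_table
from rootbench.raster import NOISE_LEVELS

LIBRARY_SEED = 0
CALIBRATION_SEED = 1
REDUCED_DPI = 150.0


@dataclass
class BenchmarkRun:
    """A generated library with its ground truth and descriptor tables."""

    systems: list
    ids: list
    ground_truth: pd.DataFrame
    paired: pd.DataFrame                 # truth_/desc_ join (+overlap if any)
    models: dict | None = None           # noise level -> calibration results


def _build_library(n: int, seed: int, noise_levels=("null",),
                   with_overlap: bool = True) -> BenchmarkRun:
    library = rb.generate_library(n, 0.5, seed)
    systems = [s for s, _ in library]
    ids = [f"sys{i:04d}" for i in range(len(systems))]
    gt = rb.ground_truth_table(systems, system_ids=ids)

    noise_seeds = np.random.SeedSequence(seed + 1).generate_state(n) % (2**31)
    images, img_ids, img_levels = [], [], []
    for i, system in enumerate(systems):
        clean = rb.render(system, dpi=REDUCED_DPI)
        for level in noise_levels:
            images.append(rb.apply_salt_pepper(clean, level, int(noise_seeds[i])))
            img_ids.append(ids[i])
            img_levels.append(level)
    desc = descriptor_table(images, img_ids, img_levels)

    overlap = None
    if with_overlap:
        overlap = pd.DataFrame({
            "system_id": ids,
            "overlap_index": [rb.overlap_index(s) for s in systems],
        })
    paired = rb.build_paired_dataset(gt, desc, overlap)
    return BenchmarkRun(systems=systems, ids=ids, ground_truth=gt, paired=paired)


@pytest.fixture(scope="session")
def library_run() -> BenchmarkRun:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _build_library(1000, LIBRARY_SEED, noise_levels=("null",),
                              with_overlap=True)


@pytest.fixture(scope="session")
def calibration_run() -> BenchmarkRun:
    from rootbench.calibration import LearningDataset, SplitSpec, train_calibration

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run = _build_library(2000, CALIBRATION_SEED, noise_levels=NOISE_LEVELS,
                             with_overlap=False)
        run.models = {}
        for level in NOISE_LEVELS:
            data = LearningDataset.from_paired(run.paired, noise=level)
            model, train, test, preds = train_calibration(
                data, SplitSpec(train_fraction=0.75, rng_seed=CALIBRATION_SEED),
                rng_seed=CALIBRATION_SEED)
            run.models[level] = {"model": model, "train": train, "test": test,
                                 "predictions": preds}
    return run


@pytest.fixture(scope="session")
def small_library() -> list:
    """Twenty systems for cheap structural tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rb.generate_library(20, 0.5, 7)
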