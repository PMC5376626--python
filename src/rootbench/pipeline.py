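"""End-to-end seeded workflow: generate → rasterize → analyze → report →
calibrate, with a manifest recording seeds and file hashes."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from rootbench import __version__
from rootbench.calibration import (
    DEFAULT_SPLITS_GRID,
    DEFAULT_TREES_GRID,
    LearningDataset,
    SplitSpec,
    train_calibration,
)
from rootbench.config import DEFAULT_DPI
from rootbench.descriptors import DESCRIPTOR_COLUMNS, extract_descriptors
from rootbench.evaluation import (
    build_paired_dataset,
    manova_type_effect,
    mean_relative_error,
    pca_ground_truth,
    r2_matrix,
)
from rootbench.raster import NOISE_LEVELS, RasterImage, apply_salt_pepper, overlap_index, render
from rootbench.rsml import TRAIT_COLUMNS, compute_ground_truth, ground_truth_table, write_rsml
from rootbench.simulator import generate_library

log = logging.getLogger("rootbench")


@dataclass
class RunConfig:
    n: int = 100
    fibrous_fraction: float = 0.5
    dpi: float = DEFAULT_DPI
    noise_levels: tuple = NOISE_LEVELS
    sampling_ranges: str | None = None   # YAML overriding packaged intervals
    trees_grid: tuple = DEFAULT_TREES_GRID
    splits_grid: tuple = DEFAULT_SPLITS_GRID
    seed: int = 0
    out_dir: str = "rootbench_run"
    overwrite: bool = False
    train_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a benchmark CSV, keeping the literal noise level ``"null"``.

    Pandas' default NA handling would silently turn the string ``null``
    into a missing value; only empty cells and explicit NaN markers denote
    missing data in these tables.
    """
    return pd.read_csv(path, keep_default_na=False,
                       na_values=["", "NaN", "nan"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_image(image: RasterImage, path: Path) -> None:
    from PIL import Image

    Image.fromarray(image.pixels, mode="L").save(str(path))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "scale_px_per_mm": image.scale_px_per_mm,
        "noise_level": image.noise_level,
        "origin_offset_px": list(image.origin_offset_px),
    }, sort_keys=True))


def load_image(path: Path) -> RasterImage:
    from PIL import Image

    sidecar = json.loads(path.with_suffix(".json").read_text())
    pixels = np.asarray(Image.open(str(path)).convert("L"), dtype=np.uint8)
    return RasterImage(pixels, sidecar["scale_px_per_mm"],
                       sidecar.get("noise_level", "null"),
                       tuple(sidecar.get("origin_offset_px", (0.0, 0.0))))


def save_model(model, path: Path) -> None:
    joblib.dump({"format": "rootbench-ensemble", "version": __version__,
                 "feature_columns": model.feature_columns, "model": model}, path)


def load_model(path: Path):
    payload = joblib.load(path)
    if payload.get("format") != "rootbench-ensemble":
        raise ValueError(f"{path} is not a rootbench model file")
    return payload["model"]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full benchmark workflow into ``config.out_dir``.

    Produces ``rsml/``, ``images/``, ``ground_truth.csv``,
    ``overlap_index.csv``, ``descriptors.csv``, ``report/`` and (optionally)
    ``models/``, plus a ``manifest.json`` with seeds and CSV hashes.
    Re-running an identical config reproduces all CSVs byte-identically.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()):
        if not config.overwrite:
            raise FileExistsError(
                f"output directory {out} is not empty; pass overwrite=True")
    (out / "rsml").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    (out / "report").mkdir(exist_ok=True)

    ranges = None
    if config.sampling_ranges:
        from rootbench.config import load_sampling_ranges
        ranges = load_sampling_ranges(config.sampling_ranges)

    log.info("generating %d systems (seed %d)", config.n, config.seed)
    library = generate_library(config.n, config.fibrous_fraction, config.seed,
                               ranges=ranges)
    ids = [f"sys{i:05d}" for i in range(len(library))]
    for sid, (system, _) in zip(ids, library):
        write_rsml(system, out / "rsml" / f"{sid}.rsml")
    gt = ground_truth_table(library, system_ids=ids)
    gt.to_csv(out / "ground_truth.csv", index=False)
    ov = pd.DataFrame({"system_id": ids,
                       "overlap_index": [overlap_index(s) for s, _ in library]})
    ov.to_csv(out / "overlap_index.csv", index=False)

    log.info("rendering %d images at %.0f dpi", len(library), config.dpi)
    noise_seeds = np.random.SeedSequence(config.seed + 1).generate_state(
        len(library)) % (2**31)
    desc_rows = []
    for i, (sid, (system, _)) in enumerate(zip(ids, library)):
        clean = render(system, dpi=config.dpi)
        for level in config.noise_levels:
            img = apply_salt_pepper(clean, level, int(noise_seeds[i]))
            save_image(img, out / "images" / f"{sid}_{level}.png")
            rec = extract_descriptors(img).to_dict()
            rec["system_id"] = sid
            rec["noise"] = level
            desc_rows.append(rec)
    desc = pd.DataFrame(desc_rows)[["system_id", "noise"] + DESCRIPTOR_COLUMNS]
    desc.to_csv(out / "descriptors.csv", index=False)

    log.info("evaluating descriptors against ground truth")
    paired = build_paired_dataset(gt, desc, ov)
    summary: dict = {"n": config.n, "seed": config.seed}
    for level in config.noise_levels:
        for ptype, mat in r2_matrix(paired, noise=level).items():
            mat.to_csv(out / "report" / f"r2_{ptype}_{level}.csv")
    fractions, loadings, _ = pca_ground_truth(gt)
    loadings.to_csv(out / "report" / "pca_loadings.csv")
    summary["pca_variance_fractions"] = [float(f) for f in fractions]
    if gt["plant_type"].nunique() > 1:
        try:
            summary["manova_p"] = manova_type_effect(gt, gt["plant_type"])
        except ValueError as exc:   # too few systems per type for 13 traits
            log.warning("MANOVA skipped: %s", exc)
            summary["manova_p"] = None
    mre_rows = []
    for level in config.noise_levels:
        sub = paired[paired["noise"] == level]
        for trait, descr in (("tot_root_length", "length"),
                             ("n_2plus_orders", "tip_count"),
                             ("depth", "depth"), ("width", "width")):
            m = mean_relative_error(sub[f"truth_{trait}"], sub[f"desc_{descr}"])
            mre_rows.append({"noise": level, "trait": trait, "descriptor": descr,
                             "mre": m.value, "n_used": m.n_used,
                             "n_excluded": m.n_excluded})
    pd.DataFrame(mre_rows).to_csv(out / "report" / "mre_summary.csv", index=False)

    if config.train_models:
        (out / "models").mkdir(exist_ok=True)
        summary["calibration"] = {}
        for level in config.noise_levels:
            log.info("training calibration models (noise %s)", level)
            data = LearningDataset.from_paired(paired, noise=level)
            model, _, test, preds = train_calibration(
                data, SplitSpec(rng_seed=config.seed),
                trees_grid=config.trees_grid, splits_grid=config.splits_grid,
                rng_seed=config.seed)
            save_model(model, out / "models" / f"model_{level}.bin")
            summary["calibration"][level] = {
                t: {"n_trees": e.n_trees, "n_splits": e.n_splits,
                    "rmse": e.rmse}
                for t, e in model.traits.items()
            }

    with open(out / "report" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "rootbench_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "hashes": {p.name: _sha256(p)
                   for p in sorted(out.glob("*.csv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
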