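"""Versioned configuration: parameter sampling intervals and artifact constants."""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import yaml

# Raster / noise constants.  The salt-and-pepper densities are artifact
# constants (the fraction of pixels randomized at each named level), not
# measured quantities.
DEFAULT_DPI = 300
SALT_PEPPER_DENSITY = {"null": 0.0, "medium": 0.05, "high": 0.15}

# Descriptor extraction constants.
THRESHOLD = 128          # global binarization threshold on [0, 255] intensities
DESPECKLE_AREA_PX = 4    # connected components smaller than this are removed
DEFAULT_DIAMETER_MM = 0.1  # fallback when an RSML file carries no diameters


@functools.lru_cache(maxsize=8)
def _load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_sampling_ranges(path: str | Path | None = None) -> dict:
    """Return the per-plant-type parameter sampling intervals.

    Parameters
    ----------
    path
        Optional path to a YAML file overriding the packaged defaults.
    """
    if path is None:
        ref = resources.files("rootbench").joinpath("data/sampling_ranges.yaml")
        with resources.as_file(ref) as p:
            ranges = _load_yaml(str(p))
    else:
        ranges = _load_yaml(str(Path(path)))
    for plant_type in ("fibrous", "tap"):
        if plant_type not in ranges:
            raise ValueError(f"sampling ranges file lacks a '{plant_type}' section")
    return ranges
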