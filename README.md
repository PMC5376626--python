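# rootbench

Synthetic ground-truth benchmarking for root image analysis.

## The problem

Root phenotyping pipelines measure plant root systems from images:
scanned washed roots, rhizotron photographs, agar plates. The images are
skeletonized and descriptors such as total skeleton length, tip count or
projected area are reported as if they were the biological traits
themselves. But image descriptors are proxies. Roots cross and occlude
each other in a 2-D projection, thin laterals vanish at modest
resolutions, and thresholding noise creates phantom structure — so the
error of each descriptor, and how it grows with root-system size and
image quality, is usually unknown, because real images have no ground
truth to compare against.

`rootbench` closes that loop synthetically:

1. **Simulate** random two-dimensional root systems (fibrous and
   tap-rooted) with an architectural growth model, so the true morphology
   is known exactly.
2. **Serialize** each system to RSML and tabulate 13 ground-truth traits
   measured on the geometry itself.
3. **Render** the systems to raster images at a known physical scale and
   degrade them with salt-and-pepper noise.
4. **Measure** 11 classical image descriptors (skeleton length, tip
   count, diameter, area, convex hull, depth, width, …) on the images.
5. **Evaluate** descriptor fidelity against the known truth: relative
   errors, descriptor–trait correlation matrices, error growth with
   self-occlusion, multivariate separation of plant types.
6. **Calibrate**: train per-trait random-forest ensembles that predict
   the true traits from the full descriptor vector, with honest held-out
   evaluation.

Every stage is seed-deterministic; identical configurations reproduce
identical CSVs, byte for byte. See [docs/methods.md](docs/methods.md) for
the exact conventions.

## Worked example

How accurate are classical descriptors, and how fast do they fall apart
with noise? Generate 60 systems, render them at 150 DPI, measure the
descriptors, and compare with the ground truth
([examples/02_descriptor_fidelity.py](examples/02_descriptor_fidelity.py)):

```python
import rootbench as rb
from rootbench.descriptors import descriptor_table

library = rb.generate_library(n=60, fibrous_fraction=0.5, base_seed=0)
ids = [f"sys{i:03d}" for i in range(60)]
truth = rb.ground_truth_table(library, system_ids=ids)
images = [rb.render(s, dpi=150) for s, _ in library]
descriptors = descriptor_table(images, ids)
paired = rb.build_paired_dataset(truth, descriptors)

m = rb.mean_relative_error(paired["truth_tot_root_length"],
                           paired["desc_length"])
print(m.value, m.n_used)
```

Running the full example prints (real output):

```
            trait  descriptor | MRE   null MRE medium MRE   high
            depth       depth |      0.006      0.029      0.171
            width       width |      0.010      0.094      0.357
  tot_root_length      length |      0.053      0.121      0.610
   n_2plus_orders   tip_count |      0.593      6.585     49.998

best-measured traits (fibrous, clean images):
              width  best single-descriptor r² = 1.000
              depth  best single-descriptor r² = 1.000
    tot_root_length  best single-descriptor r² = 0.989

best-measured traits (tap, clean images):
              depth  best single-descriptor r² = 1.000
              width  best single-descriptor r² = 1.000
    tot_root_length  best single-descriptor r² = 0.999
```

The pattern is the scientific point: geometric extents (depth, width) are
nearly error-free on clean images; skeleton length carries a ~5 % error
already before noise; tip counts are unreliable even on clean images and
explode with noise. Calibration
([examples/03_calibration.py](examples/03_calibration.py)) then learns
the traits from all descriptors jointly — on a 2,000-system clean
library it recovers total root length with held-out r² ≈ 0.99 and mean
relative error ≈ 0.036 (see below).

The other examples:

- [examples/01_simulate_and_render.py](examples/01_simulate_and_render.py)
  — simulate, write RSML, render with noise.
- [examples/03_calibration.py](examples/03_calibration.py) — train the
  random-forest calibration and compare it with single descriptors.

## Command-line interface

The `rootbench` command wires the same library calls together:

```
rootbench generate  --n 200 --seed 0 --out-dir lib/rsml
rootbench rasterize --rsml-dir lib/rsml --dpi 300 --noise all --out-dir lib/img
rootbench analyze   --images lib/img --out lib/descriptors.csv
rootbench report    --truth lib/rsml/ground_truth.csv \
                    --descriptors lib/descriptors.csv --out-dir lib/report
rootbench train     --descriptors lib/descriptors.csv \
                    --truth lib/rsml/ground_truth.csv --out model.bin
rootbench predict   --model model.bin --descriptors lib/descriptors.csv \
                    --out predictions.csv
rootbench run       --config run.yaml   # the whole workflow, one manifest
```

Note: the clean-image noise level is the literal string `"null"`, which
pandas' defaults would parse as missing data. Read any CSV produced here
with `rootbench.pipeline.read_table`, not bare `pandas.read_csv`.

## Repository layout

```
src/rootbench/     the library (simulator, rsml, raster, descriptors,
                   evaluation, calibration, pipeline, cli)
tests/             pytest suite (unit, property and acceptance tests)
examples/          narrative walk-throughs of the workflow
scripts/           acceptance.py — headline numbers as JSON
docs/methods.md    exact computational conventions
```
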