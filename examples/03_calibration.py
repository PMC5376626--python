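"""Train the random-forest calibration and compare it with raw descriptors.

Single descriptors are proxies: the skeleton length of a crowded image
undercounts the real root length.  The calibration step learns each
ground-truth trait from the full descriptor vector instead, using small
random forests selected over a grid of ensemble sizes.  On clean images
of small systems the direct proxies are already nearly exact, so the
forest mostly matches them; its advantage appears for traits without a
single good proxy and on noisier, more occluded images.

Run from the repository root (a few minutes on one CPU):

    python examples/03_calibration.py
"""

import numpy as np

import rootbench as rb
from rootbench.descriptors import descriptor_table

N = 300
DPI = 150

library = rb.generate_library(n=N, fibrous_fraction=0.5, base_seed=0)
ids = [f"sys{i:03d}" for i in range(N)]
truth = rb.ground_truth_table(library, system_ids=ids)
images = [rb.render(system, dpi=DPI) for system, _ in library]
descriptors = descriptor_table(images, ids)

paired = rb.build_paired_dataset(truth, descriptors)
data = rb.LearningDataset.from_paired(paired, noise="null")

# 3/4 train, 1/4 held-out test; per trait, an exhaustive grid over
# (number of trees) x (number of disjoint sub-forests) picks the ensemble
# with the lowest held-out RMSE.
model, train, test, preds = rb.train_calibration(
    data, rb.SplitSpec(train_fraction=0.75, rng_seed=0),
    trees_grid=(10, 50, 100), splits_grid=(1, 2), rng_seed=0)

def sq_pearson(a, b):
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)

print(f"{'trait':>17} {'RF r²':>7} {'MRE':>7}   chosen ensemble")
for trait in ("tot_root_length", "depth", "width", "n_2plus_orders"):
    y = test.responses[trait].to_numpy()
    yhat = preds[trait].to_numpy()
    r2 = sq_pearson(y, yhat)
    mre = rb.mean_relative_error(y, yhat).value
    e = model.traits[trait]
    print(f"{trait:>17} {r2:7.3f} {mre:7.3f}   "
          f"{e.n_trees} trees x {e.n_splits} split(s)")

# Does learning from all descriptors beat the single best descriptor?
# The test features are the descriptors themselves, so compare on the
# same held-out rows.
y = test.responses["tot_root_length"].to_numpy()
best_single = max(
    sq_pearson(y, test.features[c].to_numpy()) for c in rb.DESCRIPTOR_COLUMNS)
print(f"\ntot_root_length: best single descriptor r² = {best_single:.3f}, "
      f"random forest r² = {sq_pearson(y, preds['tot_root_length'].to_numpy()):.3f}")
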