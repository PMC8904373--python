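"""Regional distribution summaries, modal peaks and KS comparisons.

Per-point metrics are grouped by AF-depth tertiles of the lamella index
(outer / middle / inner), summarised as kernel density estimates with
modal peaks, and compared between groups with two-sample
Kolmogorov-Smirnov tests (raw p-values, no multiplicity correction).
"""

import numpy as np

from fibredvc import PhantomConfig, compute_metrics, estimate_distribution, generate_volume, ks_compare, seed_points
from fibredvc.stats import group_points

config = PhantomConfig(grid_shape=(96, 144, 96), n_lamellae=6, noise_sd=0.0, depth_margin=10, rng_seed=73)
_, truth = generate_volume(config)
cloud = seed_points(truth.polylines, spacing=8.0, voxel_size=config.voxel_size)
metrics = compute_metrics(cloud)
grouped = group_points(metrics[~metrics.flag], region="phantom", n_lamellae=6)

print("orientation modes by AF depth (true families at 30 and 150 deg):")
for depth, sub in grouped.groupby("depth", sort=False):
    summ = estimate_distribution(sub["theta"].to_numpy(), "theta", group=depth)
    peaks = ", ".join(f"{p:.2f}" for p in np.sort(summ.peaks[:2]))
    print(f"  {depth:>6}: n={summ.n:5d}  peaks at {peaks} deg")

outer = grouped.loc[grouped.depth == "outer", "theta"].to_numpy()
inner = grouped.loc[grouped.depth == "inner", "theta"].to_numpy()
D, p = ks_compare(outer, inner)
print(f"KS outer vs inner orientation: D = {D:.4f}, p = {p:.3g}")
# Interpretation: identical fibre-angle construction in every lamella means
# the outer and inner distributions agree (large p); on real tissue the
# peaks converge towards 90 deg with depth and the KS test separates them.
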