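"""Infer the co-activity network of a simulated islet and classify hubs.

Computes C_ij = T_ij / sqrt(T_i T_j) for every cell pair of the binarized
raster, assesses each pair against 1000 circular-shift permutations, then
flags cells holding >= 60% of the maximum significant-link count as hubs
and draws the functional connectivity map.
"""

from pathlib import Path

import numpy as np

from isletmap import (
    IsletSimConfig,
    binarize_activity,
    build_connectivity_map,
    classify_hubs,
    coactivity_matrix,
    connectivity_summary,
    detrend_denoise,
    generate_islet_traces,
    normalize_traces,
    permutation_significance,
)

ds = generate_islet_traces(
    IsletSimConfig(n_cells=50, hub_fraction=0.1, duration_s=120.0, seed=0)
)
raster = binarize_activity(detrend_denoise(normalize_traces(ds.traces)))

coact = coactivity_matrix(raster)
coact = permutation_significance(raster, coact, n_permutations=1000, seed=1)
hubs = classify_hubs(coact, threshold_percent=60)
summary = connectivity_summary(coact)

truth = np.asarray(ds.truth_hubs)
hit = int((hubs.is_hub & truth).sum())
print(f"significant pairs        : {summary['percent_connected_pairs']:.1f}% of "
      f"{summary['n_pairs']}")
print(f"mean significant C       : {summary['mean_significant_C']:.3f}")
print(f"hubs found / planted     : {int(hubs.is_hub.sum())} / {int(truth.sum())} "
      f"({hit} correct)")
print(f"hub fraction             : {hubs.hub_fraction:.2%}")

outdir = Path("scratch") if Path("scratch").is_dir() else Path(".")
cmap = build_connectivity_map(coact, hubs, ds.traces.coords)
cmap.write(outdir / "hub_map", render=True)
print(f"map written to           : {outdir / 'hub_map'}")
# The hub fraction should sit in the few-percent range seen in islet
# recordings; the map shows hubs (red) wired across the whole islet while
# ordinary cells connect only within their local burst group.
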