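"""Simulate an islet Ca2+ recording and binarize it into an activity raster.

Generates a 50-cell, 2-minute recording at 20 Hz with 10% planted hub
cells, runs F/F_min normalization, EMD detrending and the 20% dynamic-range
threshold, then compares the recovered ON/OFF raster with the simulator's
ground truth.
"""

import numpy as np

from isletmap import (
    IsletSimConfig,
    binarize_activity,
    detrend_denoise,
    generate_islet_traces,
    normalize_traces,
)

cfg = IsletSimConfig(n_cells=50, hub_fraction=0.1, duration_s=120.0, seed=0)
ds = generate_islet_traces(cfg)

norm = normalize_traces(ds.traces)  # F/F_min per cell
den = detrend_denoise(norm)  # EMD: drop residue + slow IMFs
raster = binarize_activity(den)  # ON where > 20% of dynamic range

agreement = (raster.states == ds.truth_raster.states).mean()
print(f"cells x frames          : {raster.n_cells} x {raster.n_frames}")
print(f"truth ON fraction       : {ds.truth_raster.states.mean():.3f}")
print(f"recovered ON fraction   : {raster.states.mean():.3f}")
print(f"per-frame agreement     : {agreement:.3f}")
print(f"mean hub ON fraction    : {raster.on_fraction()[ds.truth_hubs].mean():.3f}")
print(f"mean follower ON frac.  : {raster.on_fraction()[~ds.truth_hubs].mean():.3f}")
# Agreement near 1 means the trace-processing chain reproduces the hidden
# bursting state despite 10% shot noise and baseline drift; hubs spend far
# more time ON than followers because their bursts are long and recurrent.
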