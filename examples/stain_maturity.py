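"""Quantify a nuclei stain and classify LOW/HIGH maturity cells.

Renders a synthetic transcription-factor stain with a planted 20% dim
(LOW) subpopulation, segments it (Gaussian blur -> auto-threshold ->
watershed), normalizes per-cell mean intensities to 0-100 and applies the
15-unit maturity cutoff.  Also demonstrates the two exact formulas used
alongside imaging: CTCF and the 2^-ddCt fold change.
"""

from isletmap import (
    StainSimConfig,
    classify_maturity,
    ctcf,
    fold_change_ddct,
    generate_stain_image,
    intensity_distribution,
    measure_cells,
)

image, truth = generate_stain_image(StainSimConfig(seed=0))
table = measure_cells(image)
dist = intensity_distribution(table)
labels = classify_maturity(dist)

print(f"nuclei planted / segmented : {truth.n_cells} / {table.n_cells}")
print(f"planted LOW fraction       : {100 * truth.low_fraction:.1f}%")
print(f"bottom three bins (0-15)   : {dist.frequency_percent[:3].sum():.1f}%")
print(f"cells classified LOW       : {(labels['label'] == 'LOW').mean():.1%}")

rec = ctcf(integrated_density=1000.0, roi_area=50.0, background_mean=2.0)
print(f"CTCF(1000, 50, 2)          : {rec.ctcf:.0f}")
fold = fold_change_ddct(21.0, 18.0, 22.0, 20.0)
print(f"2^-ddCt, one extra cycle   : {fold:.2f}")
# The bottom-three-bin mass recovers the planted LOW fraction; CTCF
# subtracts area-scaled background from integrated density, and one extra
# qPCR cycle on the target halves its inferred expression.
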