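"""Map all four solid-state forms along the laser line over time.

Per-pixel NNLS against the (ground-truth) library turns the hyperspectral cube
into one concentration map per form, plus the stacked area plot of the
metastable intermediates only.
"""

import numpy as np

import ramanmcr as rm

dataset = rm.realize_scenario(rm.tp4(), seed=42)
cmap, profiles = rm.unmix_scan(dataset.scan, dataset.truth_library)

print("per-form mean fraction over the whole run:")
for j, label in enumerate(cmap.labels):
    print(f"  {label:9s} {np.nanmean(cmap.values[j]):.3f}")

field = rm.field_from_map(cmap)
meta = rm.metastable_area_plot(field, ["TP MS1", "TP MS2"])
print("\nmetastable area series (every 15 min):")
print(meta.iloc[::10].round(3).to_string())

truth = dataset.truth_field.fractions.transpose(2, 0, 1)
print(f"\nmax |map - truth| = {np.nanmax(np.abs(cmap.values - truth)):.4f}")
# Each metastable series rises and falls once (unimodal), and the map error
# shows how closely pixel-wise NNLS reproduces the generating concentrations
# at the default noise level.
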