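"""Detect a residual metastable form in a multi-particle area map.

A synthetic raster scene holds two particles: one pure hydrate, one anhydrate
carrying 10% residual metastable intermediate -- invisible to the eye, but
picked up by per-pixel NNLS unmixing.
"""

import numpy as np

import ramanmcr as rm

library = rm.realize_scenario(rm.tp4(), noiseless=True).truth_library
cube, truth = rm.synthesize_area_scene(
    shape=(40, 30),
    step_um=8.0,
    patches=[
        ((slice(5, 18), slice(4, 14)), {"TP MH": 1.0}),
        ((slice(24, 36), slice(10, 26)), {"TP AH II": 0.9, "TP MS1": 0.1}),
    ],
    library=library,
    noise=rm.NoiseSpec(),
    seed=3,
)

cmap = rm.unmix_area_map(cube, library, step_um=8.0, closure=True)
ms1 = cmap.component("TP MS1")[24:36, 10:26]
print(f"raster          : {cube.shape[0]}x{cube.shape[1]} pixels at 8 um")
print(f"pixels flagged empty: {cmap.empty_mask.mean():.0%}")
print(f"metastable in anhydrate particle: mean {np.nanmean(ms1):.3f} "
      f"(ground truth 0.100)")
# The 10% admixture is quantified within a couple of percent from the map
# alone -- the area-scan analogue of spotting residual forms in real powders.
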