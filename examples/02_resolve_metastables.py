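"""Resolve the two hidden metastable spectra by constrained MCR-ALS.

The library holds the two stable forms (hydrate, anhydrate) as fixed rows and
two NaN rows for the unknowns.  The highest-SNR lateral trace is analysed; the
resolved spectra are compared against the generator's ground truth.
"""

import numpy as np

import ramanmcr as rm
from ramanmcr.preprocess import select_best_position, snr_per_position

dataset = rm.realize_scenario(rm.tp4(), seed=42)
snr = snr_per_position(dataset.scan, 0)
best = select_best_position(snr)
print(f"analysis trace: position {best} (SNR {snr[best]:.0f})")

D = dataset.scan.trace(best)
selection = rm.estimate_rank(D, 6)
print(f"lack-of-fit elbow selects k = {selection.k} components")
print(selection.table.round(3).to_string(index=False))

result = rm.mcr_als(D, dataset.stable_library)
print(f"\nMCR-ALS: {result.n_iterations} iterations, converged={result.converged}")
print(f"lack of fit {result.lof_trace[-1]:.3f}%, "
      f"averaged residual {result.avg_rel_residual:.3f}%")

truth = dataset.truth_library.spectra
for j in np.flatnonzero(~dataset.stable_library.known_mask):
    cosines = truth @ result.S[j] / (
        np.linalg.norm(truth, axis=1) * np.linalg.norm(result.S[j])
    )
    match = int(cosines.argmax())
    print(f"resolved row {j} best matches {dataset.truth_library.labels[match]} "
          f"(cosine {cosines[match]:.4f})")
# Cosines near 1 mean the hidden intermediate spectra were recovered from the
# mixture data alone; the residual percentage says how little signal is left
# unexplained by the four-component bilinear model.
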