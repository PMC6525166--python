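# ramanmcr

Constrained multivariate curve resolution and NNLS unmixing for time-resolved
line-focus Raman imaging of solid-state dehydration.

## The problem

Pharmaceutical hydrates (e.g. theophylline monohydrate, nitrofurantoin
monohydrate) shed their lattice water on heating, often passing through
short-lived **metastable intermediates** whose Raman spectra overlap heavily
with the stable forms and which cannot be isolated for reference measurements.
Line-focus Raman microscopy records hundreds of spatially separated spectra
per acquisition along a laser line on a single particle, yielding a
hyperspectral cube `(time × position × wavenumber)` during isothermal
dehydration. This package implements the chemometric side of that experiment
for spectroscopists and solid-state scientists:

* a **synthetic generator** that emulates the microscope — pseudo-Voigt band
  spectra per solid form, sequential transformation kinetics with
  defect-accelerated regions along the line, bilinear mixing, Poisson + read
  noise — with full ground truth for validation;
* **library-constrained MCR-ALS** that resolves the unknown intermediate
  spectra while the stable-form spectra stay fixed;
* **per-pixel NNLS unmixing** producing concentration profiles, chemical maps
  and metastable-only area plots for line scans and 2-D rasters.

## The model

Measured spectra follow the bilinear model

```
D = C · S + E
```

with `D` the `(observations × channels)` data, `C` the non-negative
concentration profiles (closed: rows sum to 1), `S` the non-negative component
spectra and `E` the residual. The library `S` is only partially known: stable
forms are fixed rows (equality constraint), the metastable rows are resolved
by alternating least squares under non-negativity, closure and **unimodality**
of the concentration time profiles (each transient rises to a single maximum
and decays). The number of components is chosen from the lack-of-fit elbow,

```
LoF(k) = 100 · sqrt( Σ (D − Ck·Sk)² / Σ D² ) ,
```

and the converged fit is summarised by the averaged relative residual
`100 · mean|D − C·S| / mean|D|`. Resolved spectra then serve as the NNLS
library for mapping every pixel of the full line scan or area raster.

## Worked example

Resolving the two hidden theophylline intermediates from a synthetic scan
(`python examples/02_resolve_metastables.py`):

```
analysis trace: position 167 (SNR 1447)
lack-of-fit elbow selects k = 4 components
 k  lof_percent  rel_improvement
 1       40.167            NaN
 2       14.380          0.642
 3        3.659          0.746
 4        2.063          0.436
 5        2.014          0.024

MCR-ALS: 100 iterations, converged=True
lack of fit 2.211%, averaged residual 4.296%
resolved row 1 best matches TP MS1 (cosine 0.9997)
resolved row 2 best matches TP MS2 (cosine 0.9974)
```

Reading: the elbow stops improving after four components (the hydrate, two
intermediates and the anhydrate); with the two stable spectra fixed, the two
resolved rows match the generator's hidden intermediate spectra with cosine
similarity ≥ 0.997 — recovered from mixture data alone. The remaining
lack of fit is the injected detector noise.

The other example scripts cover dataset generation (`01`), chemical maps and
metastable area plots (`03`), residual-form detection in a multi-particle area
map (`04`), and hydrate stoichiometry against thermogravimetric losses (`05`).

The same workflow is available from the shell:

```sh
ramanmcr simulate --scenario TP4 --seed 42 --out run/
ramanmcr resolve  --data run/
ramanmcr map      --data run/ --resolved run/resolved_library.csv
ramanmcr report   --run run/
```

Every figure written has a CSV twin, and every run archives its resolved
configuration and content hash, so all numeric artifacts reproduce
bit-identically.

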