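# Methods

## Scope and model

The package analyses time-resolved hyperspectral Raman line scans of a single
particle during isothermal dehydration. The data obey the bilinear mixture
model `D = C·S + E`: every measured spectrum is a non-negative combination of
the spectra of the solid-state forms present. Two ingredients make the
problem solvable even though the metastable intermediates cannot be measured
in isolation: the stable endpoint spectra (hydrate and final anhydrate) are
known and held fixed, and the concentration profiles are physically
constrained (non-negative, closed to 1, unimodal in time for a transient
species).

## Synthetic data generator

The generator replaces the microscope and defines the validation conditions.

* **Spectra.** Each form is a sum of pseudo-Voigt bands (`eta` mixes Gaussian
  and Lorentzian; both shapes reach half maximum at ±FWHM/2), evaluated on a
  350–2300 cm⁻¹ axis at 2 cm⁻¹ (976 channels; 1 cm⁻¹ available by config)
  and normalised to unit maximum. The shipped TP4/NF4 presets place the
  distinguishing marker bands at their characteristic printed positions
  (TP anhydrate II: 1690/1730 cm⁻¹; TP intermediates: opposite 1150/1230
  pattern plus a weak 1750 band; NF hydrates: 1615 vs 1605 cm⁻¹; NF
  anhydrates: distinct bands in 950–1000, 1200–1300, 1310–1400,
  1550–1650 cm⁻¹). Shared skeleton bands shift by 4–6 cm⁻¹ between forms —
  the typical magnitude of polymorph band shifts — because four forms must be
  mutually resolvable for the scenario to represent the system the method is
  designed for; with near-identical skeletons the two-unknown problem becomes
  statistically non-identifiable at realistic noise (see *Limitations*).
* **Kinetics.** No rate law is established for these dehydrations; the
  default is a sequential first-order chain `MH → MS1 → MS2 → AH`
  (TP4: k = 0.10, 0.05, 0.03 min⁻¹ at 50 °C; NF4: 0.20, 0.08, 0.05 min⁻¹ at
  120 °C), integrated with an adaptive high-order Runge–Kutta scheme
  (rtol 1e-11) and renormalised so closure holds exactly. This choice
  reproduces the observed phenomenology: monotone hydrate decay, unimodal
  intermediates, monotone anhydrate growth. Optional Avrami-type exponents
  (n ≥ 1 per step, hazard `k·n·(kt)^{n-1}`) sharpen onsets. Defect-rich
  intervals along the 1.8 mm line (220 positions) multiply all rates by a
  constant factor (default 1.5–1.6), emulating locally accelerated
  conversion; because the multiplier scales all rates equally, the chain is
  integrated once and sampled at rescaled times.
* **Sampling.** 61 time points over 90 min (1.5 min spacing) — dense enough
  to resolve the intermediate maxima while keeping desk-scale runtimes.
* **Noise.** Clean counts are `gain · C·S` with gain 10⁴; shot noise is a
  Poisson draw per channel and read noise adds zero-mean Gaussian counts
  (σ = 10). At a unit-max band this gives an amplitude SNR of ~100 (≈40 dB).
  A slowly varying baseline hump is available but off by default. Every
  stochastic call takes an explicit seed; identical configuration and seed
  give a bit-identical cube.

## Trace selection and residual maps

Profile resolution uses the single lateral position with the highest SNR,
defined as the peak intensity in a signal window divided by a robust noise
scale (1.4826 × MAD) from a signal-free window at the top of the axis
(defaults: lower 85% / top 10% of the axis span; configurable, overlap
rejected). Ties go to the lowest index.

The residual map subtracts the stable forms from every spectrum by
non-negative least squares — not plain projection, so stable contributions
cannot go negative — and reports the Euclidean norm of what remains. It is
invariant to rescaling the stable reference spectra and isolates the
metastable dynamics. Both stable forms are fitted simultaneously.

## Rank selection

`estimate_rank` computes LoF(k) for truncated-SVD fits, k = 1..k_max, and
selects the smallest k whose successor improves LoF by less than 25%
(relative); ties at the threshold resolve toward the smaller k, and any k
with LoF ≤ 1e-8% is accepted immediately as an exact fit.

## Constrained alternating least squares

Each cycle:

1. **C-step** — per-observation NNLS against the current S; closure
   normalisation (row sums 1); unimodal projection of the configured
   components' time profiles (unknowns by default, all components or none by
   option) followed by re-closure; then a single global gain g is fitted so
   that `g·C·S` matches the count-scaled data. The gain is needed because the
   known spectra are fixed at unit maximum while C is closed — without it no
   closed solution could match data in detector counts. For noiseless data
   generated from a closed field the fit with the true components is exact.
2. **S-step** — per-channel NNLS for the unknown rows only, knowns fixed
   (equality constraint); unknown rows renormalised to unit maximum with the
   scale absorbed into their C columns.

Iteration stops when the relative LoF change drops below `tol` (default
1e-6) or at `max_iter` (default 200); non-convergence returns a result with
`converged=False` plus a warning, never silently.

**Subspace refinement.** Plain alternation has a known failure mode when
component spectra overlap strongly: a small admixture of one component into a
resolved spectrum can be compensated in C, producing a long, nearly flat
valley along which ALS creeps (observed linear convergence with per-iteration
progress ~1e-5) and stalls at a spurious stationary point even on noiseless
data. After the alternation stage, each unknown spectrum is therefore
re-parameterised by its k coordinates in the rank-k right-singular basis of D
(the denoised signal subspace) and the lack of fit — with C re-solved exactly
for every candidate — is minimised jointly over those few coordinates with
Powell's method (deterministic; non-negativity and unit-max normalisation are
enforced inside the parameterisation; the refined spectra are accepted when
the subspace-restricted objective improves). On the noiseless default
scenario this drops the residual from ~2e-2% (stalled ALS) to the 1e-14%
floor. `refine=False` recovers plain ALS.

**Initialization** is deterministic: stable-form residual spectra are scored
by a norm-weighted SIMPLISMA-style purity (std/(mean + α), α = 5% of the
largest mean; norm weighting prevents pure-noise residuals from winning) and
successive picks are damped by the Gram determinant against the already
selected set; the chosen residuals are clipped to non-negative and unit-max
normalised. The selection depends on the observations only as a set.

**Unimodal projection** minimises squared error over all mode positions: an
O(n) pool-adjacent-violators sweep yields the SSE of every rising prefix fit,
the same sweep on the reversed vector the falling suffixes, and the best
split is refitted. Already-unimodal inputs (plateaus and monotone vectors
included) pass through unchanged; outputs stay non-negative because isotonic
fits average input values.

## NNLS unmixing and maps

Per-pixel unmixing solves the Lawson–Hanson problem against the resolved
library. Internally all batched solves reduce the channel dimension by a thin
QR factorisation, and for k ≤ 4 components the k×k problems are solved by
exact vectorised active-set enumeration (KKT-checked; agrees with
Lawson–Hanson to 1e-12) — the per-pixel loop over scipy would otherwise
dominate runtime. Closure at the mapping stage is optional (default on for
line-scan profiles, off for raw area maps, since the paper-style raster
scenes contain empty substrate). Pixels whose total coefficient falls below
1e-3 × the median total are flagged empty; when most of a scene is bare the
median of the positive totals is used as the reference. Area maps carry µm
axes, support rectangular ROI cropping, and follow the raster contract
`dims = floor(extent/step) + 1`.

The metastable area plot unmixes with the full library (stable forms
included, so fractions are on the closed scale) and then emits only the
metastable series, averaged over the line per time point.

## Hydrate stoichiometry

`water_mass_fraction` computes the theoretical dehydration weight loss
`n·M(H₂O) / (M(anhydrous) + n·M(H₂O))` from the molecular formula; for the
theophylline and nitrofurantoin monohydrates this gives 9.1% and 7.0%,
matching the observed thermogravimetric steps of ~9% and ~7% — the analytic
cross-check that one mole of water leaves per mole of drug.

## Numerical choices and degenerate inputs

* Closure is enforced to 1e-9; rows with zero total are set uniform.
* SNR is floored at machine precision so it is always finite; all-zero
  spectra report SNR 0.
* `estimate_rank` rejects all-zero matrices; `lack_of_fit` rejects ΣD² = 0.
* Convergence also triggers at LoF ≤ 1e-10% (exact-fit floor).
* Component-to-truth matching in tests uses the Hungarian assignment on the
  cosine matrix (label order between resolved and true components is
  arbitrary).
* Seeds: the CLI and generator take explicit integer seeds; reruns from an
  archived config reproduce every array bit-identically.

## What the synthetic validation does and does not show

Passing tests demonstrate that the algorithms recover the generator's ground
truth under the stated conditions: ideal bilinear mixing, pseudo-Voigt bands,
sequential first-order kinetics, Poisson-plus-read noise at ≈40 dB, no
cosmic rays, no baseline drift, no wavenumber miscalibration, no
depolarisation or orientation effects (the generator is orientation-free).
Real spectra violate these in ways the generator does not emulate —
fluorescence backgrounds, detector artefacts, particle movement and focus
drift — so quantitative recovery bounds do not transfer to real data;
qualitative behaviour (rank selection, unimodal transients, residual maps)
is expected to.

Known limitations:

* **Identifiability.** When the forms' spectra are strongly collinear, the
  constrained maximum-fit solution itself is displaced from the truth at
  finite SNR (verified by initialising at the truth: the optimiser walks away
  to a better-fitting point). Recovery quality is then a property of the
  spectra and noise, not the optimiser; error-covariance-weighted MCR, which
  could help, is out of scope.
* Unimodality is applied along the observation axis in the order given; data
  must be supplied in time order.
* The closure-plus-gain model assumes one global intensity scale; per-pixel
  gain drifts (e.g. focus changes) are not modelled.
* The rank-selection elbow threshold (25%) is a heuristic; the LoF table is
  always returned for audit.
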