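# Methods

This note documents the models, numerical choices and limitations behind
`spectra_emu`, in the spirit of a package reference manual.

## 1. The emulation pipeline

An emulator approximates a mapping from D biophysical variables to a
K-band reflectance spectrum, learned from n labeled pairs. Training
proceeds in four stages:

1. **Input standardization.** Each variable is shifted/scaled to zero
   mean and unit variance on the training set. Variables have
   incommensurate units (LAI in m²/m², LWC in g/cm²), so an unscaled
   kernel metric would be dominated by whichever variable has the
   largest numeric range. A zero-variance variable gets scale 1 and a
   warning rather than an error, so degenerate subsets remain usable.
2. **Output compression.** A principal-component analysis of the n×K
   training spectra retains C components (default 20, clipped to
   min(n−1, K)). Eigenvalues are stored as per-component sample
   variances (divisor n−1); the mean squared reconstruction error over
   all n·K entries equals (n−1)/(n·K) · Σ(discarded eigenvalues), which
   the test suite checks against an independent SVD.
3. **Score standardization.** Component scores span orders of magnitude
   (leading eigenvalues dominate); standardizing them lets all
   components share one ridge/width grid and keeps the GPR noise term on
   a comparable scale. The inverse transform is part of the stored
   model.
4. **Score regression.** One of three back-ends:
   - **KRR** — one kernel ridge model per component, isotropic
     squared-exponential kernel exp(−‖x−x′‖²/2w²). Hyperparameters are
     selected per component by 5-fold cross-validation over a shared
     log-spaced grid: ridge 10⁻⁸…10² (11 points), width 10⁻²…10²
     (9 points). The CV sweep is solved with one eigendecomposition of
     the training kernel per fold and width, which makes all ridge
     values and all components nearly free and keeps a full benchmark
     repetition in the hundreds of milliseconds.
   - **GPR** — one Gaussian process per component with an anisotropic
     squared-exponential kernel (per-variable length scales) plus a
     white-noise term; hyperparameters by marginal-likelihood
     maximization with 3 seeded restarts (scikit-learn optimizer). Only
     the posterior mean is used; predictive variance is not exposed.
   - **NN** — a single multi-output feed-forward network, one hidden
     layer of 50 rectified-linear units, early stopping on an internal
     20% validation split, at most 2000 epochs, seeded initialization.
     NN accuracy is reported but never asserted: single-network training
     on ~100 samples is the least stable of the three back-ends.

Prediction is `μ + g(standardize(x))·Lᵀ` and is purely deterministic.
Queries outside the training hyper-rectangle are allowed (emulators can
extrapolate, unlike piece-wise linear interpolation) but raise a
warning. An optional flag clips predictions to [0, reflectance_scale];
it is off by default so that validation sees the raw regression output.

### Determinism and serialization

Fitted state for every back-end is extracted into plain float64 arrays
(dual coefficients, kernel hyperparameters, network weights), and
prediction is computed from those arrays inside the package. A saved
model (`.semu`: a zip of `manifest.json` plus raw little-endian float64
arrays) therefore predicts bit-identically before and after a round
trip. Archives are written with a fixed entry order and timestamp, so
training twice with the same data, configuration and seed produces
byte-identical files. The training fingerprint records n and a SHA-256
of the training matrices; no wall-clock information enters the archive.

Matrix products on the prediction path are evaluated row by row through
a fixed staging buffer. Batched BLAS products choose internal blocking
by matrix shape and row alignment, which can change results by a few
ulp depending on how queries are batched; row-wise evaluation makes
predictions exactly invariant to batch composition — the property the
scene renderer's chunking and deduplication rely on.

## 2. Interpolation baselines

All distance computations and the Delaunay triangulation operate on
per-dimension min-max scaled inputs (learned from the nodes), for the
same unit-incommensurability reason as above. Numerical conventions:

- ties (equidistant nodes) always resolve to the lowest node index;
- a query within 1e-12 (scaled) of a node short-circuits to that node's
  spectrum, since the IDW weight formulas are singular at d = 0;
- IDW weights are evaluated on ratios to the extremal distance, so that
  large powers (the p → ∞ nearest-neighbour limit) underflow gracefully
  instead of overflowing;
- modified-Shepard weights vanish identically when every selected
  neighbour sits at the maximal distance R; this degenerate case falls
  back to the nearest (lowest-index) node with a warning;
- the hybrid predictor dispatches per query on convex-hull membership:
  piece-wise linear inside, IDW (modified Shepard, p = 2,
  n = min(10, m) neighbours) outside. If the triangulation itself fails
  (m ≤ D or degenerate geometry) every query falls back to IDW.

## 3. Validation protocol

Per band k: RMSE_k = sqrt(mean over samples of (pred − ref)²) and
NRMSE_k = 100 · RMSE_k / N_k. The normalizer N_k is the reference band
range (max − min over validation samples) by default, with `mean` and
`std` available as options; the choice is recorded in every report.
Bands with zero normalizer are flagged degenerate and excluded from
spectral averages (the average is the plain mean of the remaining
bands — no reweighting). Prediction timing covers the prediction call
only; model construction (triangulation, training) is excluded, and
timings are reported but never asserted against reference values, being
hardware-bound.

`compare_methods` fits every method on the same training part. The
emulators' model selection is internal (cross-validation, marginal
likelihood, early stopping), so no separate held-out tuning split is
carved out of the training part: interpolators and emulators see
identical information.

## 4. The synthetic ground truth

Real campaign datasets pairing crop variables with CHRIS/HyMap-class
spectra are not redistributable, so the benchmark runs on a toy canopy
model chosen to reproduce the qualitative structure such data have. For
wavelength λ (nm):

- soil line: s(λ) = 0.10 + 0.25·(λ − 400)/2000, clipped to [0, 1];
- vegetation: v(λ) = base(λ) · chl(λ) · water(λ), with
  - base: logistic red edge centered at 715 nm (width 18 nm) rising
    from 0.05 (visible) to 0.50 (NIR shoulder),
  - chl: 1 − (LCC/(LCC+40)) · (0.75·G(λ; 670, 25) + 0.55·G(λ; 480, 35)),
    a saturating chlorophyll absorption with unit-peak Gaussians G,
  - water: exp(−60·CWC·(G(λ; 1450, 45) + 1.4·G(λ; 1940, 60)));
- mixture: R(λ) = c·v + (1−c)·s with canopy cover c = 1 − exp(−0.5·LAI),
  clipped to [0, 1].

The all-zero variable vector is the bare-soil convention and returns
the pure soil line. Labeled datasets sample LAI ~ U(0, 7),
LCC ~ U(5, 80), LWC ~ U(0.002, 0.03) and derive FVC = 1 − exp(−0.5·LAI),
CWC = LAI·LWC, biomass = 0.8·LAI·(1 + 0.1ε). The derived variables
deliberately reproduce the collinearity of co-measured field variables;
it is part of what makes the regression problem realistic. By default
20% of samples are bare soil (130 samples → 26 soil), matching the
soil-augmentation practice of campaign datasets. Observed reflectance is
the model times (1 + η), η ~ N(0, σ(λ)²) with σ = 1% outside and 10%
inside the atmospheric water windows (1350–1460 and 1790–1960 nm), then
clipped to [0, 1.2]. Band grids: `chris62` (62 uniform centers,
400–1050 nm) and `hymap125` (125 uniform centers, 430–2490 nm); true
sensor center/bandwidth tables are not emulated.

Variable-map generators produce either Voronoi-style parcel mosaics
(each parcel one sampled variable vector, some bare-soil parcels) or
smooth Gaussian random fields with the derived variables recomputed
pixel-wise, plus an optional nodata fraction.

**What passing tests do and do not show.** The toy model is smooth,
noise is uncorrelated across bands and samples, and the variable-to-
spectrum mapping is exactly the one the training data were drawn from.
Results therefore demonstrate the correctness and relative behaviour of
the methods (emulators beating interpolators, error concentrating in
noisy/steep spectral regions), not absolute accuracies attainable on
real spectroradiometric data, which carry structured noise, atmospheric
residuals and land-cover variability the generator does not emulate.

### A note on the red edge

The benchmark exhibits two error regimes: the water windows (errors
bounded below by the 10% multiplicative noise) and the red edge, where
the soil and vegetation curves cross near 696 nm. At the crossing the
reference band range shrinks, so range-normalized NRMSE inflates; for
validation draws containing samples in the steep low-LCC/high-LAI
corner, red-edge NRMSE can rival or exceed the water-window peak —
especially for GPR, whose anisotropic marginal-likelihood fit smooths
that corner more than KRR's cross-validated isotropic kernel. The
seed-averaged error curves of nearest, linear+IDW and KRR peak inside
the water windows; GPR's can peak at the red edge instead. Both peak
locations are physically meaningful (noisy bands vs the steepest
spectral feature), and the corresponding acceptance test documents the
GPR case as a known, reproducible deviation rather than masking it.

## 5. Scenes

`emulate_scene` applies any predictor exposing
`predict_spectra`/`variable_names`/`band_grid` to each valid pixel of a
variable-map stack, matching variables by name. Pixels are processed in
row chunks (default 256 rows) and exactly duplicated variable vectors
are collapsed before prediction; both are pure optimizations and the
output is bit-identical for any chunk size and with deduplication on or
off. Invalid pixels propagate the nodata value across all bands.

Cubes and map stacks use the ENVI band-sequential dialect: text header
(`samples`, `lines`, `bands`, `data type = 4`, `interleave = bsq`,
`byte order = 0`, `wavelength`/`band names`, `data ignore value`) next
to a raw little-endian float32 binary. Computation is float64, storage
float32 — the convention for multi-gigabyte hyperspectral cubes. No
georeferencing is interpreted; a `map info` entry is carried through
verbatim. Scene comparison reuses the validation NRMSE with the
range normalizer taken over the reference scene's valid pixels, plus
signed relative-difference maps (positive = overestimation) for
selected bands.

## 6. Problem sizes and defaults

The shipped benchmark uses the dataset scale of the motivating field
campaign: n = 130 samples (104/26 split), D = 6 variables, K = 62 or
125 bands, C = 20 components, five seeds for the comparative suite,
1,000-query batches for timing, and 40×40-pixel scenes in the
regression harness. All of these are configuration, not constants; the
generators and trainers accept arbitrary sizes.

## 7. Known limitations

- GPR predictive uncertainty is computed internally but not exposed.
- The NN back-end is a deliberately small single network; no
  architecture search.
- ENVI support covers the BSQ/float32/little-endian dialect only.
- The toy canopy model is not a radiative transfer model; constants are
  invented and documented, chosen once for qualitative realism.
- No stratification (e.g. by crop type) in splits.
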