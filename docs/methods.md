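# Methods

This note documents the models, conventions and design choices behind
`nirspec-fa`: what is computed, which knobs matter, what the synthetic
generator does and does not emulate, and where the honest limitations are.

## Data model

Spectra are absorbance scans recorded as log(1/R) on a uniform wavelength
grid. The canonical grid is 1000→2500 nm in 0.5 nm steps (3001 points).
Instruments of the emulated class are sometimes described with a
constant-wavenumber grid instead; the two conventions are numerically
incompatible, and this package standardises on constant-nm because every
pretreatment window and gap parameter is naturally expressed in points on
one uniform grid. Replicate scans (two per sample in the emulated design)
are averaged arithmetically before analysis. Reference chemistry is a long
table keyed by (sample, fraction ∈ {phospholipid, total}, analyte) over a
closed vocabulary of 20 fatty acids and 4 group sums, in mg FA per 100 g
meat.

## Pretreatment operators

All operators are deterministic and grid-length-preserving; a chain applies
them in its stored order (baseline → normalization → scatter correction →
smoothing → derivative).

* **Offset** subtracts the per-spectrum minimum.
* **Area** divides by the per-spectrum L1 norm.
* **SNV** centers and scales each spectrum to mean 0, *sample* (n−1) SD 1.
  The sample-SD convention follows the originating literature; the unit-SD
  invariant is tested against the same convention.
* **Detrend (D)** removes the least-squares polynomial of degree 2 in
  wavelength (the standard SNV-detrend definition), computed via a QR basis
  on wavelengths mapped to [−1, 1] for conditioning.
* **MSC** regresses each spectrum on a reference (`x = a + b·ref`) and
  returns `(x − a)/b`; **EMSC** adds linear and quadratic wavelength terms
  to the regression and removes them too. The reference is the mean of the
  calibration spectra *at that stage of the chain* — the field default —
  fitted once on calibration data and frozen, so validation spectra never
  influence the transform.
* **SG-d-p-w** is the Savitzky–Golay derivative (derivative order d,
  polynomial order p, window w points, odd, w > p), scaled by the grid step
  so first derivatives are in absorbance·nm⁻¹. Edges are handled by
  evaluating the one-sided local polynomial fit (scipy's `mode="interp"`),
  which keeps the grid length constant and remains exact on polynomials up
  to order p everywhere. Window and gap parameters are interpreted as grid
  points, not nm.
* **NG-1-g** is the Norris gap first derivative,
  `(x[i+g] − x[i−g])/(2·g·step)`, edge points copying the nearest interior
  value. Only first order is supported (the only order used in the packaged
  configurations).

Chain strings use `|`-separated tokens (`"Offset|Area|SNV+D|SG-1-2-3"`);
`SNV+D` and `EMSC+D` expand to two steps, `None` parses to the identity.
Two irregular smoothing tokens appearing in the packaged configuration
table (`SG1-1-1`, `SG1-2-2`) are read as zeroth-derivative smoothing passes
with the stated polynomial order; their stated windows (1 and 2) are not
valid SG windows and are widened to the smallest odd window exceeding the
polynomial order. This reading is low-confidence but the resulting passes
are near-identity, so nothing downstream depends on it.

## PLS core

NIPALS PLS1: X is column-mean-centered, y mean-centered; no unit-variance
scaling of X (standard for spectra, whose variance structure is
informative). Per factor, the weight vector `w ∝ Xᵀy` is extracted
(stationary after one pass for a single response; the iteration loop with
tolerance 1e-10 and a 500-iteration cap implements the general contract),
scores `t = Xw`, loadings `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, and X, y are
deflated. The rotation `R = W(PᵀW)⁻¹` gives scores for new data and the
regression vector `b = Rq`. If the response is exhausted early (exactly
collinear data) the model keeps the factors actually extracted. At full
rank the fit coincides with ordinary least squares, which the tests verify
against a normal-equations oracle, and predictions match scikit-learn's
`PLSRegression(scale=False)` to machine precision (used in tests only, as
an independent cross-check).

**Factor selection.** Optimising calibration R² alone is degenerate (it
always picks the maximum), so automatic selection uses venetian-blind
k-fold cross-validation (k = 10, fold assignment by a seeded permutation)
with the one-standard-error rule on CV mean squared error: the smallest
factor count within one standard error of the best is chosen. This resolves
a noiseless rank-r system to exactly r factors and a pure-noise target to 1.
The packaged per-analyte factor counts can be (and in the suite are)
imposed verbatim instead.

**Hotelling screening.** `H = Σₖ tₖ²/var(tₖ)` over the model's factors,
with score variances taken from the calibration set (n−1 denominator), so
the calibration mean of H is exactly F(n−1)/n. Samples with H above the
threshold (default 10) are dropped once and the model refitted — a single
elimination pass, not iterated. Note the interaction between the two
defaults: because mean H ≈ F, a threshold of 10 flags a large fraction of
samples when F ≈ 10 (≈40% under approximately χ²_F-distributed scores).
The statistic's exact scaling in the commercial software this emulates is
not documented; the threshold is configurable wherever it appears, and the
validation metrics are computed on the untouched validation set either way.
If removal would leave fewer than F+2 samples, the original model is kept
with a warning.

## Figures of merit

* `SEC = √(SSE/(n−F−1))` on retained calibration samples — F model degrees
  of freedom plus the intercept.
* `SEP = √(Σ(r−r̄)²/(n−1))` on validation residuals (bias-corrected);
  plain RMSEP is reported alongside, so a purely biased model shows
  SEP ≈ 0 with a large RMSEP.
* R² is the squared Pearson correlation between reference and prediction
  (so an anti-correlated prediction also scores 1 — documented consequence
  of the definition; the scatter-plot usage this matches makes the
  distinction visible).
* `RPD = SD_validation/SEP`, using the validation-set SD — the choice that
  reproduces the published ratios. RPD ≥ 2 classifies a model as
  "analytical", below as "screening"; the boundary value 2.0 is analytical.
* `Consistency = SEC·100/SEP` (%).

The per-analyte report row is (analyte, n, SEC, R²c, SEP, R²p, RPD,
Consistency) with n the calibration samples retained after outlier
removal, matching the count semantics of the emulated study's tables.

Two rows of the published performance tables are internally inconsistent
with their own descriptive statistics — the total-fraction 20:1 RPD (printed
1.8; SD/SEP gives 2.35) and the total-fraction 18:1c9 Consistency (printed
88.59; SEC·100/SEP gives 89.02). The identity cross-checks exclude these
two rows and reproduce all others within 0.1 (RPD) and 0.01 (Consistency).
Similarly, four of the published phospholipid-share percentages (PUFA
74.1%, 18:1c9 9.9%, 18:1t9 9.0%, CLA 9.1%) do not equal the ratio of the
published means (73.9%, 9.0%, 5.7%, 9.2%, possibly computed per-sample on
the full data); the package reports table-mean ratios and asserts only the
nine shares that reproduce.

## Synthetic generator

The generator exists so the whole pipeline is testable at full scale
without the study's non-public data. It emulates:

* **Concentrations.** A latent per-sample "fatness" factor drives a
  Gaussian copula. Each fatty acid's phospholipid concentration is
  lognormal (moment-matched to the published phospholipid calibration
  mean/CV) with weak latent coupling (ρ = 0.3 — membrane lipid is
  physiologically buffered); the neutral part is lognormal with strong
  coupling (ρ = 0.95) and dispersion chosen so the total
  (phospholipid + neutral) matches the published total-fraction mean and
  CV. This construction guarantees phospholipid ≤ total per analyte and
  sample. Group sums are sums of constituents (the SFA sum includes the two
  aldehydes, matching the published table arithmetic; CLA is counted in
  PUFA on chemical grounds); TotalFA additionally carries the unreported
  ~7% remainder as its own lognormal component, so
  SFA + MUFA + PUFA ≤ TotalFA always holds. Lognormal marginals were chosen
  because concentrations are positive and CVs approaching 100% rule out
  Gaussian.
* **Spectra.** Beer–Lambert linear mixing over a stylised band library:
  every acid shares the main C–H overtone (1725/1765 nm) and combination
  (2280/2310/2348 nm) bands — the shared absorption that makes minor
  analytes hard — plus unsaturation bands (2145/1680 nm) weighted by
  double-bond count, a deterministic per-acid modulation of the shared
  weights and one weak satellite band for full column rank. The band
  coefficient scale puts the mean total-FA load at ~0.05 AU — the "subtle
  peaks" regime of freeze-dried meat, with the fattest samples approaching
  1.4 AU at 2500 nm. The scattering baseline rises smoothly from ~0.4
  (1000 nm) to ~1.0 (2500 nm) and deliberately contains no water bands
  (freeze-dried emulation). Per sample: multiplicative gain 1 + N(0, 0.1),
  additive offset N(0, 0.02), linear tilt N(0, 0.01); per scan: white noise
  N(0, 0.005). Default n = 332 with two scans per sample.

What it does **not** emulate: instrument noise spectra and detector
nonlinearity, temperature effects, particle-size/radiative-transfer physics
(no Kubelka–Munk), chromatography measurement error in y, breed structure,
and any nonlinearity between composition and absorbance. Consequences to
keep in mind when reading synthetic results: (i) the spectra are *exactly*
linear in composition at high SNR, so with 3001 wavelengths and ~200
samples PLS fits calibration nearly perfectly — SEC is extremely optimistic
and Consistency ≪ 100%, unlike the published 26–127% range; SEP, R²p and
RPD on the held-out set are the meaningful figures; (ii) passing the
recoverability benchmark shows the pipeline's plumbing and information flow
are correct, not that real beef calibrations would reach those numbers.
What *does* transfer qualitatively is the fraction contrast: high-variance
total-fraction targets validate far better than low-CV, weakly-coupled
phospholipid targets, reproducing the published Table-level pattern.

## Numerical and design choices

* Least-squares subproblems (MSC/EMSC, detrend) use QR/`lstsq`, never
  explicit normal equations.
* The calibration/validation split is per-sample Bernoulli(0.67) as
  literally described in the emulated protocol (no breed stratification —
  the generator has no breeds; the split threshold and seed are explicit
  everywhere).
* Wavelength selection (optional, off by default) masks coefficients below
  a magnitude quantile and keeps the reduced model only if cross-validated
  R² improves; the packaged configurations do not record selection, so the
  suite runs on the full grid.
* Outlier removal precedes validation prediction and follows factor
  selection; the order is configurable at the API level by composing the
  primitives directly.
* Degenerate inputs fail loudly: constant spectra (SNV), all-zero spectra
  (Area), zero-variance targets, |b| < 1e-12 in MSC/EMSC, empty split
  halves, chains applied before fitting.
* CSV writers print floats at 17 significant digits so write→read
  round-trips are bit-exact.

## Problem sizes

The test suite runs the full 48-model suite at the study scale
(n = 332, 3001 wavelengths, ~4 s on one CPU) and the recoverability
benchmark at n = 300; the acceptance script repeats both from scratch under
its own seed. Factor-selection cross-validation is O(folds × F_max) NIPALS
runs and is only exercised where `n_factors="auto"`.
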