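# Methods

## Scope and data model

`fiberspec` analyzes absorbance spectra of developing cotton fiber cell
walls acquired by ATR FT-IR. A *sample* is one fiber harvest (genotype,
days post anthesis, biological replicate) carrying several technical scans
collected by re-sampling the fiber bundle; all scans of a dataset share one
wavenumber grid, stored ascending (instrument exports running 4000 → 600
cm⁻¹ are flipped on read). Cellulose content (% of fiber mass, as an
Updegraff-type assay would report it) is a separate per-sample table; the
assay itself is out of scope and only its output format is consumed.

## Preprocessing

The chain is: arithmetic mean of technical scans → Savitzky–Golay smoothing
→ restriction to 1800–600 cm⁻¹ with division by the region's mean
intensity.

* **Smoothing** — local least-squares quadratic over 11 points
  (`scipy.signal.savgol_filter`). Edges use the one-sided polynomial fit
  (`mode="interp"`), chosen so the 684–650 cm⁻¹ integration window near the
  grid edge is not degraded. Whether scans are smoothed before or after
  averaging is a config flag (`smooth_before_mean`, default off: the mean
  spectrum is smoothed). Both orders are defensible; for linear filters
  they commute exactly, so the flag only matters for downstream variants.
* **Normalization** — the divisor is the signed arithmetic mean of
  absorbance over the inclusive 1800–600 cm⁻¹ region (no absolute value).
  A region mean within 10⁻¹² of zero raises rather than divides. After
  normalization the region mean is 1 by construction, which makes band
  areas comparable across samples with different contact pressure or
  deposit thickness.
* The derivative pretreatment for PCA is a separate Savitzky–Golay filter
  (window 13, order 2, first derivative per cm⁻¹) applied row-wise to the
  normalized spectra matrix, followed by column mean centering.

No ATR penetration-depth correction, baseline correction, or scatter
correction is applied; the indices are built to be robust to overall scale
instead (see below).

## Band indices

Band intensities are read by linear interpolation at the nominal band
center, not by local peak picking — reproducible and robust to grid
placement. Centers that fall within one grid spacing outside the spectrum's
span clamp to the edge point; this matters for the 1800 cm⁻¹ anchor, which
is the inclusive boundary of the normalized region but not an exact grid
point, so the nearest retained point lies a fraction of a spacing inside.

* `R = (A₁₃₁₅ − A₁₈₀₀)/(A₁₂₃₆ − A₁₈₀₀)` — the "offset to zero at 1800
  cm⁻¹" of the source protocol is implemented as subtracting the anchor's
  interpolated intensity inside the ratio, which is exactly what the
  printed formula does.
* `CI = (A₇₀₈ − A₈₀₀)/(A₇₃₀ − A₈₀₀)` — the protocol names only the three
  bands (708 crystalline Iβ, 730 amorphous Iα, 800 anchor) without printing
  a formula; this anchored crystalline-over-amorphous form mirrors the R
  value's structure. The band assignment is configurable (`bands=` argument)
  precisely because the exact historical formula is an assumption.
* Integrated intensities use the trapezoid rule over inclusive windows
  (910–875 and 684–650 cm⁻¹ from normalized spectra; 1410–1290 and
  3000–2800 cm⁻¹ for the band ratio), with window endpoints entering
  through interpolated boundary values and **no** local baseline
  subtraction — the protocol integrates normalized spectra directly.
* The 1372/2900 ratio is computed from the smoothed, *un-normalized* mean
  spectrum: its denominator window lies outside the normalized region, and
  the ratio cancels any multiplicative scale anyway. Both anchored ratios
  and this band ratio are invariant under positive scaling of the spectrum;
  the two raw areas are not, which is why they are taken from normalized
  spectra.

Degenerate cases raise: anchored denominators below 10⁻¹⁰, non-positive
2900 cm⁻¹ area, windows or centers outside the span.

## PCA

PCA is fit by SVD (scikit-learn, full solver) on the derivative-pretreated,
mean-centered matrix; explained-variance fractions are σ²ₖ/Σσ²ᵢ of that same
matrix — the variance shares refer to the matrix the model is fit on, not
to the raw spectra. Component signs are arbitrary, so each component is
oriented to give its score a non-negative Spearman correlation with DPA
(fibers mature with time; the conventional presentation has PC1 increasing
with age), falling back to making the largest-|loading| positive when DPA
is unavailable. Leave-one-out cross-validation reports PRESS per component
count using the naive project-then-reconstruct scheme; this is known to be
optimistically biased relative to row-wise schemes but is the standard
quick diagnostic, and is labelled as such.

## Regression

Cellulose content is the response, the spectral index the predictor.
Linear R² is orientation-invariant; the quadratic fit is not, and this
orientation matches the question actually asked of the data ("predict
cellulose from the spectrum"). Fits use the exact least-squares solution of
the polynomial design; a constant response yields R² = 0 with a warning
rather than NaN. Linear and quadratic fits are compared by the nested F
test, F = ΔSS/(SSres₂/(n−3)) on F(1, n−3): the source material compares
the two curves only visually, and the F test is the reproducible surrogate
(α = 0.05 is the suggested reading threshold, not enforced in code).
Reports are pooled across genotypes by default, with a per-genotype flag,
since the fitted relationship is reported for "all fiber samples".

## Synthetic data generator

The study's spectra are not publicly deposited, so the generator emulates
their statistical structure: a sum of Gaussian bands at the characteristic
cell-wall positions (the carbonyl/amide bands that fade, the CH₂/C–O
skeletal and crystallinity bands that grow, broad O–H/C–H stretches, the
adsorbed-water band), each interpolating linearly between a primary-wall
amplitude `a_pcw` and a secondary-wall amplitude `a_scw` as a developmental
latent goes 0 → 1, plus additive white Gaussian noise (sd 0.005 AU per
scan). Band centers, widths, amplitudes and grouping live in a versioned
YAML library (`fiberspec/data/band_library.yaml`), not in code.

* **Design defaults** mirror the emulated experiment: 2 genotypes × DPA
  {10, 17, 24, 28, 33, 37, 44} × 2 biological replicates, 5 technical scans
  per sample, grid 4000 → 600 cm⁻¹ at 1.92858 cm⁻¹ spacing (nominal 4 cm⁻¹
  resolution with 2× zero-filling; the grid is anchored at 4000 cm⁻¹ and
  stops at the last point ≥ 600, giving 1763 points and 622 variables in
  the fingerprint region). The genotype effect defaults to none — both
  lines show the same developmental pattern — with an optional *im*
  amplitude-deficit flag for sensitivity studies.
* **Cellulose** rises linearly from 25% at 10 DPA to a 95% plateau at 40
  DPA (mature fibers are ~88–96.5% cellulose; young elongating fibers are
  mostly non-cellulosic, and 25% is a stated generator choice, not a
  literature value), with Gaussian assay noise (sd 1.5 percentage points)
  clipped to [0, 100].
* **Single-latent mode** (default): one latent `m = clip((d−10)/30, 0, 1)`
  drives every band and cellulose alike. The indices are then ratios of
  affine functions of `m` — *near*-linear, not exactly linear, in
  cellulose, because anchors and the region-mean normalizer put `m` in the
  denominator too. Band magnitudes were set in a one-time design pass so
  those denominators vary modestly (in particular, the skeletal C–O bands
  carry a substantial primary-wall baseline — young walls' pectins and
  hemicelluloses absorb in the same 1200–900 cm⁻¹ region), giving
  noise-free linear R² ≥ 0.97 for every index, and were then frozen as
  library version 1.
* **Realistic (two-latent) mode**: a saturating composition latent `g`
  (logistic in DPA, midpoint 17 d, scale 3 d) drives the dominant skeletal
  bands, while `m` keeps driving the index-bearing bands (1315, 1236, 895,
  708, 730, 1365); cellulose mixes the two with weights 0.25/0.75. Because
  the skeletal block carries most spectral variance, PC1 tracks `g` and
  plateaus after ~24 DPA, while R and CI keep rising to 44 DPA — the
  qualitative dissociation seen in real developing fibers, asserted in the
  tests as ordered differences rather than figure values.
* **Randomness**: one root seed; sample *i* (counting through genotype ×
  DPA × replicate in config order) draws from
  `SeedSequence(seed, spawn_key=(i,))`, so any leading subset of the design
  regenerates identically and runs are bit-reproducible.

What the generator does **not** emulate: Lorentzian/Voigt line shapes,
ATR anomalous dispersion and penetration-depth wavelength dependence,
baseline drift, water-vapor lines, correlated (pink) noise, and real
biological replicate-to-replicate covariance. Passing tests therefore
demonstrate that the pipeline's algebra and statistics behave correctly on
data with the assumed structure — not that the indices would reach the same
R² on any particular instrument's output.

## Numerical choices and limitations

* Grid uniformity for Savitzky–Golay filters is checked to 10⁻⁶ relative;
  non-uniform grids raise.
* Region boundaries and integration windows are inclusive on both ends.
* Explained-variance fractions, PRESS, and regression statistics are exact
  linear-algebra computations; no iterative optimization is involved, so no
  initialization or convergence tolerances apply.
* The per-run manifest (config JSON + SHA-256 hash, seed, package versions)
  fully determines the outputs; byte-identical reproduction is covered by a
  test.
* The pipeline's 28-sample default runs in a few seconds on one CPU; the
  problem sizes in the tests (28 samples × 1763 grid points, PCA on
  28 × 622) are the package's own defaults throughout.
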