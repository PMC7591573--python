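# Methods

## The measurement model

A bright-field microscope with a linear, unsaturated sensor records, at
each pixel and camera channel `c`,

    I_c = ∫ L_c(λ) · T(λ) dλ,          L_c(λ) = S(λ) · F_c(λ)

where `S` is the source spectrum, `F_c` the channel quantum-efficiency
curve, and `T(λ) ∈ [0, 1]` the per-pixel transparency spectrum.  The model
deliberately contains no optics (PSF, defocus) and no nonlinear
light–matter interaction; exposure time and the energy-to-counts response
are absorbed into the intensity scale.  With `C = 3` channels and `w = 48`
wavelength samples the inverse problem is heavily underdetermined, so the
recovered per-pixel vectors are *quasi*-transparency spectra: feature
vectors that behave like a transparency spectrum under the forward model,
not a physical transmission measurement.

Quadrature: all integrals use a shared composite-Simpson weight vector.
The default grid has 48 samples on 450–775 nm (the instrument's UV
long-pass / IR short-pass window), i.e. 47 intervals; Simpson covers the
first 46 and the last interval is closed with a trapezoid.  On grids with
an even interval count the rule is classic composite Simpson and exact for
cubics.  Non-uniform grids fall back to trapezoid weights.

## The per-pixel loss and its spatial coupling

Pixel `m` is scored by

    F_m = Σ_c exp(|∫ L_c T_m dλ − I_mc|) − C
        + (1/N) Σ_{n∈N_m} G_mn Σ_i (T_m(λ_i) − T_n(λ_i))²

The exponential data-fit is zero iff every channel is matched exactly and
grows monotonically with each channel's residual.  `N_m` contains the
neighbours within Euclidean radius `T_ED` (default 1, i.e. the
4-neighbourhood; `N = |N_m|` counts the neighbours actually present, so
the smoothness term is a mean and border pixels are not penalized for
having fewer neighbours).

The coupling weight is

    G_mn = (1/L_mn) Π_k { 1 if pixel k is not an edge,
                          (1 − T_b)(1 − D_k) if it is }

with `L_mn` the Euclidean distance between the pixels (a length
normalization damping longer couplings), `T_b = 0.9` the edge bias and
`D_k` the normalized gradient magnitude.  The product runs over the
Bresenham raster line joining `m` and `n`; endpoints are canonically
ordered before rasterization so `G_mn = G_nm`.  **Design choice:** the
product includes the endpoint pixels themselves.  With the default
`T_ED = 1` (and even `T_ED = 1.5`) the strictly-interior Bresenham set of
any neighbour pair is empty, so an endpoint-free product could never
attenuate anything at the method's stated operating point; including the
endpoints is what lets a detected edge block smoothing into and out of
edge pixels.  A switch (`include_endpoints=False`) restores the
strictly-interior variant.

### Edge evidence

Iteration 1 has no spectral field, so edges come from the image: channel
vectors are projected onto their first principal axis (maximal-variance
grayscale), central differences per axis are merged by the Euclidean norm
and max-normalized.  From iteration 2 on, the evidence is spectral: for
each pixel the zero-lag cross-correlation ρ (cosine) of the two flanking
spectra along each axis is mapped to the dissimilarity `(1 − ρ)/2`, merged
across axes by the Euclidean norm and max-normalized.  The raw correlation
is a similarity while the coupling formula needs "large D = discontinuous",
hence the complement; a switch exposes the raw-correlation direction.
Zero-norm flanking spectra count as fully similar (no evidence of an
edge).

Edge classification applies the Canny ingredients to the gradient matrix
directly (the input is already a gradient magnitude, so re-deriving
gradients inside a stock Canny would double clean step edges into plateau
ridges): Gaussian smoothing with σ = 0.5, double-threshold hysteresis with
the high threshold at the 90th percentile of nonzero smoothed values and
low = 0.4 · high, then morphological thinning to 1-pixel lines.  Both
thresholds are configurable; the pre-thinning hysteresis mask is kept on
the edge state because its size (unlike the skeleton's) is monotone in the
thresholds.

## The mean-field loop

Each outer iteration recomputes gradients and edges (image-based first,
spectral afterwards), rebuilds the couplings, and sweeps all valid pixels
with neighbour spectra frozen from the previous sweep (Jacobi style, so
the result is independent of sweep order).  Each pixel is minimized by
CMA-ES down to the current loss tolerance:

- CMA-ES is the standard (μ/μ_w, λ) strategy with cumulative step-size
  adaptation and rank-one + rank-μ covariance updates, implemented
  in-package with a batch objective so a whole population is evaluated
  vectorized.  Box constraints are enforced by clipping candidates, which
  matches the physical bound `T ∈ [0, 1]`.
- Defaults: initial step 0.15 in [0, 1] coordinates, population
  4 + ⌊3 ln w⌋ (= 15 at w = 48), 500 evaluations per pixel per sweep.
  A pixel whose warm start already satisfies the tolerance is skipped at
  zero cost, and a sweep never replaces a spectrum by a worse one.
- Every pixel's search is seeded deterministically from
  (global seed, iteration, pixel index), so the whole pipeline is
  reproducible bit-for-bit.

The loss tolerance decreases linearly from 0.5 to 0.05 over the first 10
iterations and is constant afterwards (the endpoints are configurable; the
10× ratio keeps early sweeps cheap while the field self-organizes).  The
loop stops when the relative change of the mean per-pixel cost falls below
0.01.  The stopping test is only armed once the tolerance is constant:
while the schedule still decreases, cost changes track the schedule rather
than the field.  The mean cost trace is *not* expected to be monotone; the
per-iteration variation coefficient is recorded alongside it.

Initialization is the flat spectrum `t_i ≡ mean_c(I_c / white_c)` — the
spectrally neutral medium with the observed overall brightness.

Intensity normalization: observed counts are divided by the bit-depth full
scale, and `L_c` is rescaled so that `∫ L_c dλ` equals the per-channel
white level (given explicitly, or estimated as the 99th percentile of
valid intensities).  This makes the exponent of the data-fit O(1), so
`exp()` neither saturates nor vanishes.

Saturated pixels (ADC full scale) are excluded from optimization and
marked invalid in the cube.  The 99th-percentile bright-pixel rule is a
visualization treatment (`rendering.rescale_bright`); it can be enabled as
a reconstruction pre-mask but is off by default, because model-violating
bright pixels are better *detected* by their abnormal converged cost than
silently removed — a pixel brighter than the blank background cannot be
explained by any `T ≤ 1` and its data-fit has a strictly positive floor.

## Calibration

Sensor pixels respond inhomogeneously.  Calibration photographs a uniform
background through ≥ 2 neutral-density layers and pairs each frame with
the spectrometer spectrum of the transmitted light.  Per pixel and filter,
the knot pair is (recorded intensity `M_i`, QE-weighted spectral integral
`S_i = ∫ spectrum_i · F_c(pixel) dλ`), with the pixel's channel identity
taken from the Bayer pattern; the response map `S(M)` is the
piecewise-linear interpolant through the knots, extended linearly beyond
the measured range (extrapolated values are untrusted but not clipped).
Calibration is defined on the mosaic; if a demosaiced pipeline is wanted,
correction is applied before (bilinear) demosaicking.  Spectrometer
spectra are linearly resampled to the working grid before integration.

## Rendering

A reconstructed cube is re-illuminated per pixel:
`X, Y, Z = ∫ T(λ) E(λ) x̄/ȳ/z̄(λ) dλ` with the same Simpson weights, then
mapped to display sRGB by the standard linear matrix, gamut clip and sRGB
gamma.  The default illuminant is a Planck black body (5800 K).  The
packaged colour-matching table is generated from the piecewise-Gaussian
analytic fit of the CIE 1931 2° observer (Wyman, Sloan & Shirley 2013)
with the x̄ and z̄ curves rescaled to the CIE equal-area convention, so the
equal-energy illuminant maps to x = y = 1/3; it is an approximation
adequate for visualization and chromaticity checks, not the official
tabulation.

## Clustering and staining

Spherical k-means: vectors L2-normalized, assignment by maximal cosine,
centroid = normalized mean, k-means++ seeding, 5 restarts with the best
objective kept (ties to the earliest restart).  The cosine metric is the
method's natural choice because sample thickness scales spectral magnitude,
not shape.  The gap statistic uses within-cluster cosine dispersion
`W = Σ_r (1/2n_r) Σ_{i,i'} (1 − x_i·x_i')` (computed in O(n) via the
resultant-vector identity) against B = 20 uniform draws over the
feature-wise bounding box — the simpler of the two standard reference
variants — with standard error `sd_b(log W*) √(1 + 1/B)` and the first-max
rule for selecting k.  Digital staining projects spectra onto 3 PCA /
factor-analysis / NMF components, min-max scaled per component; components
that are numerically degenerate (rank-deficient data) are zeroed rather
than noise-amplified.

## What the phantoms emulate — and what they do not

The generator produces transparency fields that are smooth inside regions
(Gaussian-bump mixture spectra under a low-frequency multiplicative
modulation, 3% by default) and discontinuous across region borders, i.e.
exactly the sample assumptions of the method: localized gradients,
reasonable flatness, linear response.  The simulated camera applies the
forward model, per-pixel gain dispersion, offset, additive Gaussian noise
(sigma expressed as a fraction of the white level; 5% in the canonical
scene), optional Bayer mosaicking, and quantization.  The canonical study
scene is a 24×24 disc-on-background phantom with two near-orthogonal
region spectra; the low-contrast variant mixes the region spectra 70%
toward their common mean, chosen so the strongest channels separate by
only ≈ 2.6–3.9 noise sigma.  A micro-lens violation sets one pixel to 1.3×
the white level (below ADC full scale), which no `T ≤ 1` can explain.

Not emulated: optical blur and defocus, sample thickness (3-D) effects,
shot-noise statistics (noise is additive, not Poisson), chromatic effects
of the optical path.  Passing phantom tests therefore demonstrates the
correctness and self-consistency of the inverse machinery under the
model's own assumptions, not performance on real micrographs.  Because the
inverse problem is underdetermined, phantom acceptance deliberately
targets forward consistency (reprojected intensities match observations)
and region recovery (clustering the cube recovers the label map), *not*
pointwise equality of reconstructed and generating spectra — pointwise
equality is not identifiable from 3 channels.

## Problem sizes and numerical choices

The self-test and acceptance runs use 24×24 scenes with the default
solver configuration (500 CMA-ES evaluations per pixel per sweep); at this
size a full reconstruction takes on the order of a minute on one CPU, and
typically converges in 11–20 outer iterations (the stopping test arms at
iteration 11).  Unit tests use 8–12 pixel scenes with reduced budgets.
Degenerate inputs are handled explicitly: constant images yield a zero
grayscale projection (with a warning), numerically-uniform spectral flanks
carry no edge evidence, zero-norm spectra are excluded from clustering,
empty clusters are re-seeded at the worst-fit point, and an all-equal
image passes through the bright-pixel rescale unchanged.

## Known limitations

- Spectral identifiability: only the 3 effective-light projections of each
  spectrum are data-constrained; everything else is regularization-shaped.
- The exponential data-fit is scale-sensitive; the white-level
  normalization must be sane (provide it explicitly when known).
- With `T_ED = 1` the couplings react to edges only through the endpoint
  pixels; radii ≥ 2 engage the full Bresenham machinery.
- CMA-ES at w = 48 with a 500-evaluation budget refines rather than solves
  from scratch; the outer loop relies on warm starts across sweeps.
- The gap statistic's uniform-box reference is known to be conservative in
  high dimensions; it is used comparatively (cube vs raw), not absolutely.
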