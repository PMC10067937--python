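# Methods

## Distance model

The core statistic is the density of the Euclidean distance `r` between two
points whose planar coordinates each carry isotropic Gaussian localisation
error (the Churchman-style formulation used throughout single-molecule
colocalisation work). For true separation µ and *combined* two-channel
error σ (per axis):

    DD(r) = A · (r/σ²) · exp(−(µ² + r²)/(2σ²)) · I₀(rµ/σ²)

which reduces to the Rayleigh density `(r/σ²)·exp(−r²/2σ²)` as µ → 0 and
integrates over [0, ∞) to the amplitude A. Two-channel puncta data are
modelled as the sum of two components; the fitted (µ₁, µ₂) are reported
with components sorted by µ ascending.

Numerics: `I₀` overflows for `rµ/σ² ≳ 700`, so the density is evaluated as
`A·(r/σ²)·exp(−(r−µ)²/2σ²)·Ĩ₀(rµ/σ²)` with the exponentially scaled Bessel
`Ĩ₀(x) = e^(−x) I₀(x)` (`scipy.special.i0e`); the identity
`−(µ²+r²)/2σ² + rµ/σ² = −(r−µ)²/2σ²` makes the two forms exactly equal.

## Fitting, confidence intervals, degeneracy

The fit target is the *density-normalised* nearest-neighbour histogram
(right-open bins of default width 0.01 µm, chosen to resolve a ~34 nm mode
with at least three bins; counts/(n·binwidth)), so the fitted amplitudes
approximate mixture proportions. Fitting is bounded non-linear least
squares (`scipy.optimize.curve_fit`, trust-region reflective; a ≥ 0,
µ ≥ 0, σ ≥ 10⁻⁴ µm).

Bins are Poisson counts, so each bin density is weighted by its counting
standard error `sqrt(count)/(n·binwidth)` (empty bins get a one-count
floor) and the weights are treated as absolute when forming the parameter
covariance. This choice is load-bearing: with unweighted least squares and
residual-scaled covariance, the 95 % intervals for µ₁ came out roughly
five-fold too narrow (empirical coverage 8/20 instead of the nominal
95 %); with Poisson weights coverage is 18/20 on the same ensemble.
Unweighted fitting remains available (`weighted=False`) for comparison
with generic curve-fit behaviour.

Initialisation is data-driven: candidate µ values from the two most
prominent peaks of a lightly smoothed histogram (mode and 3×mode if only
one peak), σ at twice the bin width, amplitudes by nonnegative linear
least squares given (µ, σ). Up to five deterministic perturbed restarts
are attempted on non-convergence; the `converged` flag reports the honest
outcome and is never silently repaired.

CI half-widths are `1.96·sqrt(diag(cov))` (normal quantile; no degrees-of-
freedom correction). A fit is **degenerate** when any active parameter's
half-width exceeds the magnitude of its estimate, or when the covariance
is non-finite. On unpaired uniform point sets (2000 per channel in
20×20 µm) the two-component fit is flagged degenerate in ≈85–95 % of
runs: the nearest-neighbour law of a Poisson field is close to a single
Rayleigh, so the two-component split is unidentifiable.

## Nearest-neighbour distances

For each query punctum, candidate references satisfy |Δx| ≤ w AND
|Δy| ≤ w with w = 0.5 µm by default — a *square* window, so recorded
distances extend to w·√2 and the fit range covers that support. The
minimum Euclidean distance among candidates is recorded; queries with no
candidate are counted separately, never silently dropped. Matching is
many-to-one (no deduplication). The implementation uses an L∞ k-d-tree
range query and is tested for exact, tolerance-free agreement with the
brute-force all-pairs oracle.

Distances from multiple images are pooled before fitting by default
(per-image fitting is available through per-image runs): pooling matches
the single-histogram description of the workflow.

### Known limitation: density-dependent truncation of the distal mode

A nearest-neighbour distance is only the partner distance when no
unrelated reference punctum lies closer. At the default junctional
density (2000 pairs in 20×20 µm ⇒ 5 puncta/µm²) an unrelated punctum
pre-empts a 169 nm partner with probability ≈ 1 − exp(−λπµ₂²) ≈ 36 %, so
the fitted µ₂ is biased low by roughly 10–17 % (the proximal 34 nm mode
is essentially unaffected, ≈2 % pre-emption). At 1.25 puncta/µm² the
same chain recovers both modes within ~3 %. This bias is a property of
the nearest-neighbour estimator itself at high density, and applies
equally to real data analysed this way.

## Detection

The ImageJ-style chain is reproduced operator by operator, in physical
units: Gaussian blur with σ given in µm (0.015 µm ⇒ 0.75 px at
0.02 µm/px); background subtraction as grayscale opening with a non-flat
ball-height structuring element of radius 3 px (the sliding-paraboloid
refinement is approximated by the ball; verified pixel-for-pixel against
a brute-force erosion/dilation oracle); Otsu threshold on the
preprocessed image by default with a manual override; 8-connected
components; area filter 0–0.02 µm²; circularity `4πA/P²` with the
perimeter taken from the marching-squares contour and the ratio clipped
to 1 (discrete perimeters of 1–2 px objects exceed the isoperimetric
bound). Centres of mass are intensity-weighted means over the component
mask computed from the **raw** image, with a geometric-centroid fallback
for zero-intensity masks. Pixel (row, col) maps to
(x, y) = ((col+0.5)·ps, (row+0.5)·ps); all exported coordinates are µm.

Polygon region masks use even-odd membership with boundary points counted
inside (shapely `covers`).

## Synthetic data

The generator is the test bed for the whole chain and emulates exactly the
features the analysis consumes:

- **Displacements** are mechanistic: component drawn by proportion, a true
  offset of length µ in a uniformly random direction (the density depends
  only on magnitude, so isotropy is the natural completion), plus 2-D
  Gaussian noise of per-axis SD σ applied to the B point only —
  mathematically equivalent to splitting the combined error across both
  channels.
- **Default truth**: proportions 0.7/0.3, µ = 34/169 nm, σ = 10/40 nm.
  Only the two characteristic distances are published for the junctional
  fits; the proportions and dispersions are this package's choices —
  dispersions plausible for ~50 nm-resolution STED localisation, a
  dominant proximal fraction.
- **Field**: 20×20 µm at 0.02 µm/px (the pixel scale implied by
  3 px = 0.06 µm and 50 px² = 0.02 µm²); clutter is homogeneous Poisson
  per channel, default 0.05 µm⁻². Paired points that would fall outside
  the field are clipped to the boundary (a sub-nm effect at this
  geometry).
- **Rendering**: per-pixel integration of the Gaussian PSF by
  error-function differences (photon count conserved in expectation),
  PSF σ 0.021 µm (≈50 nm FWHM), 500 expected photons per punctum over a
  background of 2 counts/px, Poisson noise, clipped to 8/16-bit. Not
  modelled: 3-D structure, drift, chromatic aberration, depletion-beam
  physics, antibody linkage error. Passing tests therefore demonstrate
  correctness of the measurement chain, not robustness to those real-data
  effects.
- **Junction images**: a straight vertical ridge with Gaussian
  cross-section (true FWHM = 2√(2 ln 2)·σ_ridge) over a constant baseline
  with additive Gaussian noise. Morphometry defaults use amplitude 500,
  baseline 100, noise SD 50 — SNR 10 with the baseline far enough above
  zero that min-normalised traces stay positive.

All generators are pure functions of (parameters, seed); identical seeds
give bit-identical outputs.

## Morphometry choices

- The junction-width Gaussian includes a constant offset term: profiles
  sit on non-zero background, and omitting the offset biases FWHM upward.
- "Normalised to minimum" is read as *division* by the trace minimum;
  an additive-shift mode is deliberately not the default and the choice
  is recorded in output metadata by the pipeline configuration.
- CoV uses the sample (n−1) standard deviation (spreadsheet convention).
- Line profiles are bilinear, sampled at pixel-size spacing, averaged
  across `width_px` parallel offsets.
- The Boltzmann fit is plain least squares with endpoint-derived starting
  values; the midpoint identity y(x₀) = (A1+A2)/2 holds analytically.

## Problem sizes

Default study sizes: 2000 pairs end-to-end (one 1000×1000 px image pair,
~15 s); 20 × 10,000 distances for recovery/coverage ensembles; 20 × 2000
unpaired points for the degeneracy rate; 10⁵ draws for sampler/CDF
consistency; 50 noisy replicates for width recovery. These sizes give
Monte-Carlo errors well inside every tolerance used in the tests.
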