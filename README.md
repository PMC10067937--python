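# punctaprox

Quantification of spatial proximity between two punctate protein channels in
two-colour super-resolution (STED-class) images, plus the companion
junction-morphometry metrics used for endothelial adherens junctions.

The motivating biology: the mechanosensitive cation channel PIEZO1 forms
puncta at endothelial cell–cell junctions alongside the adhesion molecule
PECAM1. Whether two stainings merely co-occur or sit within molecular reach
of each other is decided here by the *distribution* of nearest-neighbour
distances between puncta centres, not by pixel overlap.

## The model

Each punctum centre carries isotropic 2-D Gaussian localisation error. The
distance `r` between two fluorophores with true separation µ and combined
localisation error σ then follows the Rician-type density

```
DD(r) = A · (r/σ²) · exp(−(µ² + r²)/(2σ²)) · I₀(rµ/σ²)
```

with `I₀` the modified Bessel function of integer order zero. A
nearest-neighbour distance histogram (square search window, default
±0.5 µm per axis) is fitted with the **sum of two** such components by
non-linear least squares — a frequent short-distance mode (µ₁) and an
occasional longer mode (µ₂). 95 % confidence intervals come from the fit
covariance (1.96·SE), and a fit is flagged **degenerate** when any
parameter's CI half-width exceeds the estimate itself — the behaviour
expected for unpaired (e.g. non-junctional) point patterns.

Upstream, puncta are detected with the classic ImageJ-style chain: Gaussian
blur (σ = 0.015 µm) → rolling-ball background subtraction (radius 3 px) →
threshold → connected components filtered by area (≤ 0.02 µm²) and
circularity (4πA/P², in [0, 1]) → intensity-weighted centres of mass taken
from the *raw* image. Morphometry adds junction width as the Gaussian FWHM
(2√(2 ln 2)·σ) of perpendicular line profiles, staining organisation as the
min-normalised coefficient of variance of a trace, background-normalised
junctional intensity via channel-derived masks, and the Boltzmann sigmoid
`y = A2 + (A1 − A2)/(1 + exp((x − x0)/dx))` for pressure–response curves.

Because the underlying raw images are not publicly deposited, the package
ships a first-class synthetic generator (`punctaprox.synthgen`) that
produces point patterns, rendered image pairs and junction images with
known ground truth, so every stage is testable end to end.

## Worked example

```python
import punctaprox as pp
from punctaprox.pipeline import PipelineConfig, run_proximity_pipeline

# 2000 paired puncta (true modes 34 nm and 169 nm, proportions 0.7/0.3)
# plus 0.05 µm^-2 clutter in a 20x20 µm field, rendered at 0.02 µm/px,
# detected, matched and fitted with the default settings:
report = run_proximity_pipeline(PipelineConfig(seed=0))
fit = report["fit"]
print(f"mu1 = {fit['params']['mu1']*1e3:.1f} nm "
      f"(CI ±{fit['ci95']['mu1']*1e3:.1f} nm)")
print(f"mu2 = {fit['params']['mu2']*1e3:.1f} nm "
      f"(CI ±{fit['ci95']['mu2']*1e3:.1f} nm)")
print("degenerate:", fit["degenerate"])
```

prints

```
mu1 = 33.7 nm (CI ±0.7 nm)
mu2 = 148.5 nm (CI ±4.9 nm)
degenerate: False
```

The frequent mode is recovered within ~1 % of the simulated 34 nm truth.
The occasional 169 nm mode reads ~12 % low: at 5 puncta/µm² an unrelated
punctum often sits closer than a 169 nm partner, truncating the distal
nearest-neighbour distances — an intrinsic property of the estimator at
this density (see `docs/methods.md`). A degenerate flag instead of a
confident fit is what unpaired clutter produces.

The same machinery is available from the shell:

```
punctaprox simulate --config config.yaml --out-dir run/
punctaprox detect --image run/channel_A.tif --out particles_A.csv
punctaprox nn --query particles_A.csv --reference particles_B.csv --out d.csv
punctaprox fit --distances d.csv --components 2 --out fit.json --plot fit.png
```

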