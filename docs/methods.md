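# Methods

This note documents the models, parameter choices, and numerical decisions
behind `conelearn`, in the spirit of the methods documentation of packages
like statsmodels or msprime: enough detail to reproduce, audit, or extend
every stage.

## Scene model

Real hyperspectral databases of natural scenes exhibit two regularities the
learning algorithm depends on: pixel–pixel correlation decays with spatial
distance, and band–band correlation decays with wavelength separation. The
synthetic generator reproduces both with a Gaussian-process construction:

1. Per band, draw a white-noise field and filter it in the Fourier domain
   with amplitude `|f|^-p` (DC removed), then standardize.
2. Couple bands with the kernel
   `K(Δλ) = w + (1 − w)·exp(−Δλ² / (2 s²))` via its Cholesky factor. The
   first term is a *luminance* factor shared by all bands (shading and
   illumination structure is wavelength-independent); the second a
   *reflectance* factor that decorrelates with wavelength separation. A
   single squared-exponential term cannot simultaneously match the
   near-band and far-band correlations of real scenes; the two-part kernel
   can, and mirrors the standard luminance/reflectance decomposition of
   natural-image modeling.
3. Exponentiate: `cube = m·exp(c·g − c²/2)` — log-normal radiance,
   nonnegative by construction, mean `m` independent of the contrast `c`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `spatial_exponent` p | 2.2 | inside a finite DC-free window this reproduces measured natural-scene pixel correlations (~0.99 at 1 px, ~0.85 at 10 px, ~0.6 at 20 px) |
| `spectral_corr_scale` s | 100 nm | with w=0.3, band correlations hit ~0.97 / 0.56 / 0.30 at 30 / 140 / 320 nm separation, the profile reported for natural hyperspectral databases |
| `luminance_weight` w | 0.3 | share of variance carried by the wavelength-independent luminance factor |
| `contrast` c | 0.35 | log-intensity standard deviation typical of natural scenes |
| `mean_level` m | 1.0 | arbitrary radiance unit; Pearson correlations are scale-free |
| scene size | 256 px | a 20-px patch should be a small fraction of the scene, as patches drawn from megapixel database images are; small windows truncate the low-frequency power that makes real patches smooth |

What the generator does *not* emulate: sharp material edges and occlusions
(fields are Gaussian before exponentiation), chromatic structure tied to
specific materials (e.g. the vegetation red edge), camera noise and finite
bit depth, and illuminant variation between scenes. Passing tests therefore
show the algorithm works when the two target second-order statistics hold;
they do not probe robustness to higher-order structure of real scenes.

## Mosaic

Cones sit on a rectangular side×side grid (one cone per image pixel at
stride 1; stride 2 or 4 emulates coarser cone spacing relative to image
scale). The S count is exact — `round(0.06·side²)` — so composition is
testable, and S positions are drawn by rejection sampling with a minimum
pairwise spacing of 2.5 cone units (1000 retries per cone), yielding the
quasi-regular S arrangement seen in real retinas. Non-S cells are i.i.d.
with probabilities proportional to the ratio vector. Hexagonal geometry,
eccentricity gradients, and aperture optics are out of scope.

## Spectral sensitivities

Sensitivities come from a shiftable nomogram: the Govardovskii A1 pigment
template (α and β bands), frozen at the reference peak of 558.9 nm and
translated rigidly in log-wavelength to any λmax in [400, 620] nm. Freezing
the template makes the family exactly shift-invariant, which is the only
property the algorithm needs besides realism and unimodality. A fixed
lens + macular transmittance (smooth synthetic densities: lens 1.6
exponentially decaying from 400 nm, macular Gaussian 0.35 peaked at 458 nm)
multiplies the absorbance; units are quantal, curves peak-normalized. Only
correlations enter the algorithm, so absolute sensitivity scales are
irrelevant.

## Responses and surround

Raw response: inner product of the cone's sensitivity with the spectrum at
its pixel. The suppressive surround subtracts a Gaussian-weighted sum of
neighboring cones' raw responses: σ = 2.0 cone units, support radius 5
(Euclidean), weights normalized so each cone's surround sums to 0.25.
Cones near the boundary are renormalized back to 0.25 so the contract holds
everywhere; in cone-selective mode (L suppressed only by M and vice versa;
S surrounds drawn from both L and M; S cones never contribute) a cone with
no eligible neighbor legitimately has no surround. Optional additive noise
draws i.i.d. Gaussians with σ equal to a fraction of the mean cone response
of each patch (a per-batch global mean is available as a config switch).
Responses are not normalized before correlation: Pearson correlation is
invariant to per-cone affine scaling.

## Correlation and dissimilarity

The n×n Pearson matrix is accumulated in one pass (running Σx, Σxy) over
the union of all patches; a cone whose variance is at cancellation level
(≤1e−12 of its squared mean) raises an error naming it. The dissimilarity
is `d = −ln(max(ρ, 1e-6))` with a zero diagonal. The floor handles
nonpositive correlations, which the model does not otherwise define;
clamping events are logged. For a rank-based embedding the log is strictly
redundant (any monotone transform yields the same solution); it is kept for
fidelity to the method as described.

## Non-metric MDS

SMACOF majorization alternated with isotonic (PAVA) regression of the
embedded distances on the rank order of the dissimilarities (ties broken by
pair index), minimizing STRESS1 = √(Σ(δ̂−dist)²/Σdist²). Initialization is
classical (Torgerson) scaling with a deterministic sign convention (first
non-negligible loading of each axis positive); one replicate by default,
with optional random restarts. Disparities are rescaled to the current
distance norm before each Guttman transform. Because the STRESS1
denominator moves with the configuration, a majorization step can in
principle raise STRESS1; the optimizer then reverts to the previous
configuration and stops, so the recorded stress history is non-increasing
by construction. Convergence: relative stress change < 1e−6 (max 300
iterations in the pipeline).

S cones are the minority cluster of 2-means (10 restarts, seeded); an
exactly even split raises rather than guessing. The embedding is then
rotated so the vector from the non-S mean to the S mean lies along the
negative first axis. Mosaics without S cones (tritanopes) skip both steps;
a user-supplied rotation matrix and side sign (`manual_rotation`,
`manual_s_side` on `ConeClassifier`) stand in for them, and small mosaics
that separate class on dimension 3 are handled by the same rotation.

## Flattening

One quadratic surface `z₁ = c₀ + c₁z₂ + c₂z₃ + c₃z₂² + c₄z₂z₃ + c₅z₃²` is
fit through all non-S cones jointly, minimizing the **standard deviation**
of point-to-surface distances — the σ objective prefers the surface equally
distant from every cone, keeping it centered between the per-class sheets
rather than hugging the more numerous class (minimizing the summed distance
does exactly that failure). Distance is perpendicular Euclidean distance,
computed by a vectorized, damped Newton inner solve on the foot-point
parameters with the vertical residual as a fallback upper bound. The outer
optimizer is Nelder–Mead over the six coefficients (xatol 1e−8, max 10⁴
evaluations), started from the least-squares regression and restarted from
its own solution until the objective stabilizes; distinct coordinate frames
can still settle in local optima ~1e−5 apart, which bounds the achievable
reproducibility of the objective value. Flattened values are signed
negative on the side of the surface where the mean S-cone residual lies.
With extreme class ratios the surface can over-represent the numerous
class, spreading the rare class over a wide range — a known failure mode of
the method, surfaced through per-class accuracies rather than hidden.

## Mixture selection and classification

Skew-normal components (`2/ω·φ(z)·Φ(αz)`, `z=(x−ξ)/ω`; scipy's density and
Owen's-T-based CDF) are combined into K-component mixtures fit by maximum
likelihood: L-BFGS-B on (ξ, log ω, α, weight logits), ω floored at 1e−4 of
the data range via bounds, 20 restarts (deterministic quantile-split
initialization plus seeded perturbations). Note ξ and α trade off strongly
near the optimum; component *means* are the identifiable location summary.

Model selection fits K = 1, 2, 3 in order and picks the first whose
two-sided KS p-value (asymptotic Kolmogorov distribution on
√n·sup|F̂−F_fit|) reaches 0.01; if none does, the best-p fit is returned
with an `adequate_fit=False` flag. The p-value ignores that parameters were
estimated from the same sample (no Lilliefors-type correction), making the
test anti-conservative — lone-fit p-values are biased high — which is
acceptable here because the statistic is used comparatively across K.

Per-cone labels are the argmax of weight×density (exact ties break toward
the larger-mean component); ranks are assigned by distance from the S side,
so the farthest component is the highest-λmax class. For K = 2 the explicit
decision threshold — the point between the component means where the
weighted densities are equal — is also reported; argmax labeling is the
normative rule, and the two agree whenever the densities cross once between
the means.

## Evaluation

Class-averaged (balanced) accuracy is the headline metric: the mean of
per-class correct fractions over the longer-wavelength classes, with the
pooled fraction reported alongside; percentages round to the nearest
percent. Detection compares the selected K with the true class count
(correct / under / over). Classification accuracy is scored with K forced
to the true count, so it is separable from detection, matching how the two
are reported in practice. Spatial recovery aligns the embedding's
dimensions 2–3 to the true grid by orthogonal Procrustes (rotation,
reflection, translation — no scaling) and reports the RMS residual in
embedding units. Label correspondence is fixed by the S-anchored ordering
(true classes sorted by λmax ↔ predicted ranks); no Hungarian matching is
needed or used.

## Problem sizes

The pipeline default is 10⁵ patches on a 20×20 mosaic with 8 scenes of
256 px — accuracy saturates near a few ×10⁴ patches under the synthetic
statistics, consistent with learning-curve behavior that asymptotes well
below the millions of patches a conservative run might use. Test ensembles
use 14×14 mosaics with 2.5×10⁴ patches (ablations) and 10×10 mosaics
(learning-curve trend), sizes at which every stage's behavior is already
stable.

## Determinism

Every stochastic stage (scene seeds, mosaic placement and assignment, patch
draws, noise, k-means, mixture restarts) derives from a single master seed
via `numpy.random.SeedSequence.spawn`; identical configurations produce
byte-identical reports.

## Known limitations

- The scene model is second-order only; conclusions about real-scene
  robustness require the real databases.
- The KS p-value is anti-conservative (parameters estimated from the data).
- 2-means S identification assumes the S/non-S separation dominates the
  embedding's cluster structure; scene statistics with much weaker spectral
  decorrelation can defeat it (the even-split error surfaces the ambiguous
  case but not a confidently wrong one).
- The surface fit is a non-convex optimization; the objective value is
  reproducible only to the local-minimum granularity noted above.
- K is capped at 3 longer-wavelength classes, and embedding dimensionality
  is fixed at 3.
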