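# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show.

## Colorimetry

Spectra are sampled on a 400–700 nm grid at 10 nm (configurable); all
spectra combined in one operation must share a grid, and resampling is by
linear interpolation with no extrapolation. Cone excitations are
trapezoid-rule inner products of radiance with L, M, S sensitivity
functions; chromaticity is MacLeod–Boynton: l = L/(L+M), s = S/(L+M),
with luminance L+M carried as a third coordinate.

The cone sensitivities are **smooth analytic approximations** — Gaussian
profiles peaking at 565, 535 and 445 nm with widths 52, 48 and 28 nm —
normalized so that a unit-power equal-energy spectrum has luminance 1,
l = 0.665 and s = 1 (the conventional anchor points; pinned by a
regression test). Every quantity the package computes depends only on the
relative chromatic geometry these induce (scale invariance, the linearity
of cone excitations in radiance, mixture-line convergence, ensemble
separability), not on the fine structure of a standards tabulation, so the
exact sensitivity shapes are a free choice documented here; they are
configurable wherever they enter.

## Scene model

A unit sphere fills a 7.1° × 7.1° stimulus field (angular radius 3.55°)
and is shaded analytically per pixel under orthographic projection — no
raytracing, cast shadows or inter-reflections, since the task's cue
structure needs only the per-pixel two-component mixture. Three
equal-intensity directional lights share one spectrum; default directions
(azimuth, elevation) = (−40°, 25°), (15°, 50°), (45°, 10°), chosen to
scatter distinct highlights over the upper sphere. Per pixel,

- diffuse coefficient `b = texture × Σⱼ max(0, n·lⱼ)`,
- specular coefficient `a = s·π × Σⱼ ward(n, lⱼ, v; α = 0.15)`,

with the isotropic Ward lobe `exp(−tan²θh/α²) / (4πα²√(cosθᵢcosθᵣ))`
times cos θᵢ, zero for occluded lights. The factor π folded into the
specular scale makes the specularity *s* the specular-to-diffuse albedo
ratio against an energy-conserving Lambertian base (BRDF ρ/π); without
it the diffuse term is overweighted by π and even the glossiest level
(s = 0.1) produces highlights that never dominate a pixel, contrary to
how a glossy dielectric images. With it, the brightest pixels at s = 0.1
are specular-dominated and lie near the illuminant chromaticity, while at
lower levels they remain mixtures — the behaviour the task design relies
on.

Marbled spheres modulate diffuse intensity by a volumetric marble
pattern (sinusoidal banding phase-distorted by multi-octave trigonometric
value noise, range [0.3, 1], contrast scaled by the noise amplitude);
bumpy spheres displace the radius by the noise field (amplitude 0.05 of
the radius, base frequency 6 cycles) with analytic normals
`n ∝ u − (I−uuᵀ)∇h/ρ`, validated against a finite-difference oracle.
Texture and bump fields are evaluated in object coordinates, so they
rotate rigidly with the object; patterning and bumpiness never co-occur.

Motion conditions rotate exactly one of image, object or lights about the
visual axis (VA) or the vertical axis (PA). Rotations are ±30° at 90°/s
during a dynamic period of 1/3 s (20 frames at 60 Hz; the printed 0.33 s
is treated as rounded 1/3), flanked by 0.5 s static periods, with the
spectral change linearly interpolated over the same window. Consequences
verified by tests: object rotation cannot move the highlights of a
radially symmetric marbled sphere; lights rotation moves the highlights
and not the texture; image rotation is rigid (rendering-then-rotating
equals rotating-then-rendering within interpolation tolerance). The
maximum image speed at the sphere edge under VA rotation is
ω·(angular radius) ≈ 5.58°/s. For PA rotations the package reports the
same orthographic quantity for the front pole; a perspective virtual
camera close to the sphere would magnify it, and no such camera is
modelled.

## Stimulus design and cue silencing

With only two illuminants, unconstrained reflectance pairs would let the
direction/magnitude of the *diffuse* colour change predict the class, so
reflectance pairs are selected to match the illuminant-change trials'
diffuse changes. Matching is greedy nearest-neighbour without
replacement in (direction, log₁₀ magnitude, Δlog₁₀ luminance) of the
diffuse change — direction treated circularly, unit weights. The
luminance coordinate is included deliberately: a noiseless observer fed
(Δl, Δs, Δlog lum) would otherwise read the class from the luminance
ratio alone, and chance-level performance at zero specularity would be
unattainable no matter how well the chromatic coordinates were matched.
The candidate pool is the exhaustive set of ordered reflectance pairs
under either fixed illuminant (when ≤ 600 000, else a random subsample);
exhaustive pools matter because a noiseless classifier exploits
arbitrarily small distributional mismatch — with a 30×-subsampled pool
the residual mismatch alone supported d′ ≈ 0.7 at zero specularity,
versus ≈ 0.05 with the exhaustive pool. Match quality is reported as
per-coordinate two-sample energy distances plus the worst per-trial match
distance, and an optional tolerance turns unmatched trials into an
explicit failure.

A session is 700 trials — 140 per specularity level, balanced 70/70
between change types (balance maximizes SDT estimability; only the 140
count is externally fixed) — in four blocks of 175, shuffled, with the
rotation direction drawn uniformly per trial.

## Model observers

Each observer reads one statistic per frame: the luminance-weighted mean
chromaticity of the top 0.1% of object pixels by luminance ("brightest
pixel"; the fraction is configurable, and 1.0 recovers the whole-image
mean), or the luminance-weighted mean chromaticity of all object pixels.
Only the first and last frames enter the decision. The decision feature
is the statistic's change vector (Δl, Δs, Δlog₁₀ luminance); the decision
rule is a two-class **quadratic** discriminant (equal priors, covariance
regularizer 10⁻⁴, ties toward "illuminant") trained per specularity level
and condition on a matched ensemble generated independently of the
evaluation trials. The rule must be quadratic: both change directions
occur for both classes, so the class-conditional feature means coincide
and the classes differ only in spread — the likelihood-ratio rule for
zero-mean classes compares quadratic forms, and a linear boundary is
provably at chance on this ensemble.

No internal noise is added; all performance limits arise from
stimulus-ensemble overlap. Rendering cost is kept low by caching shading
maps per (texture/bump variant, rotation sign) — the maps are independent
of the spectra, and the specular map scales linearly with specularity —
so ensembles of thousands of trials reuse a small pool of geometry
renders (8 variants by default) and only the per-trial cone-excitation
algebra varies.

## Signal-detection analysis

Illuminant-change trials are the signal class (this orientation is forced
by the bias convention: ln β > 0 must indicate a tendency toward
"reflectance" responses). d′ = z(H) − z(F) and ln β = (z(F)² − z(H)²)/2
with the 1/(2N) extreme-rate correction, which bounds measurable d′ at
2·z(1 − 1/(2N)) ≈ 4.90 for 70-per-class cells. Confidence intervals are
BCa bootstrap over within-class trial resampling (1999 resamples by
default, seeded); plain percentile intervals measured 92.5–94.5% coverage
at n = 70 because of binomial discreteness and the ceiling's skew, while
BCa restores 95–97%. Normalization to static-marbled performance divides
each observer's d′ by a per-observer scalar — the mean static-marbled d′
over the four nonzero specularity levels — because per-level division is
unstable where the reference d′ ≈ 0; a per-level variant is available
behind a flag and yields NaN at zero-reference cells by construction.
The group-level ANOVA is a classical three-way repeated-measures
partitioning (surface type × motion condition × specularity) on
complete-case observers, no sphericity correction, via statsmodels
`AnovaRM` (cross-checked against an independent implementation on the
one-factor collapse).

## Synthetic data

Illuminants come from a two-basis smooth model (broad warm component at
620 nm, broad cool component at 455 nm, each on a small pedestal,
normalized to unit mean power); the default weights give a sun-like
member with higher l and lower s than the sky-like member — a blue–yellow
separation of roughly 0.03 in l and 0.5 in s — and near-equal luminance.
Reflectances are a uniform mean level (0.15–0.65) plus four cosine
harmonics with 1/k roll-off (coefficient scale 0.22), rejection-sampled
into [0.02, 0.98]; a 500-spectrum library spans all four hue quadrants
around the neutral point. Simulated observers draw responses from the
equal-variance Gaussian model with per-cell (d′, ln β), criterion
c = ln β/d′ + d′/2.

What the generators do **not** emulate: the spectral fine structure of
measured daylights and surface databases, metamerism against realistic
sensor sets, correlated reflectance families, or observer lapses and
learning. Passing tests therefore demonstrate the internal consistency of
the machinery and the qualitative cue structure (chance at zero
specularity, specularity-driven improvement, brightest-pixel advantage),
not quantitative predictions for any particular human dataset. Analyses
of real trial-level responses use only the `sdt` stage, which makes no
distributional assumption beyond the equal-variance SDT model.

## Problem sizes and numerics

Default render resolution is 128×128 (model-observer statistics are
resolution-robust; the pipeline is tested at two resolutions), matched
ensembles of 1000 train / 1000 evaluation trials per class per level for
the headline model-observer numbers, 200 recovery replicates per true d′,
and 999–1999 bootstrap resamples. Degenerate cells (all-hit or no-alarm)
fall back to the corrected ceiling rather than an unbounded interval;
zero-radiance pixels are flagged off-mask rather than propagated as NaN;
all randomness flows from named integer seeds, and identical seeds
reproduce byte-identical outputs.
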