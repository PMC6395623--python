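# Methods

## Model and assumptions

`fibralign` treats the recentred modulus of an image's 2D DFT as an
unnormalised probability mass over frequency coordinates and summarises its
shape. The approach assumes:

- structures of interest are elongated and bright against a darker
  background, so their spectral energy concentrates along lines through the
  origin perpendicular to their spatial orientation;
- the statistic is *global*: one (ε, μ, σ) triple per image, with no
  segmentation or per-structure tracing;
- orientations are undirected (period 180°); all angular arithmetic is
  modulo a half-turn, exploiting the Hermitian symmetry of a real image's
  spectrum (antipodal frequency pixels carry equal modulus, so they are
  pooled);
- inputs are single-channel 2D images; confocal stacks must be projected
  before analysis, and RGB inputs are reduced by Rec. 601 luminance.

The pipeline stages are: central crop → FFT modulus, recentred → corner-block
noise cutoff → DC removal → second-order central moments and equivalent
covariance ellipse (ε, μ) → angular sector sums and weighted normal fit (σ).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `crop_px` | 825 | px | a common centred window makes spectra of a series comparable; odd, so the recentred spectrum has a true central DC pixel |
| `corner_px` | 64 | px | side of the four corner blocks whose maximum modulus sets the noise cutoff; must stay clear of the centre |
| `n_sectors` | 180 | — | 1° bins over the half-turn, matching degree-resolution reporting of σ |
| `window` | none | — | no apodisation by default; a separable Hann window is available because the periodic extension of a rectangular crop adds an axis-aligned "plus" artefact that can bias μ toward 0°/90° |
| `exclude_dc` | true | — | the DC term encodes mean brightness, not orientation, and its angle is undefined |

Cutoff choices follow the most conservative deterministic reading: the
*single maximum* over all four corner blocks of the *centred* spectrum (the
corners of the uncentred matrix contain the DC term and cannot estimate
noise). Both the statistic (max vs any alternative) and the blocks' size are
configurable.

## Numerical choices

- **Threshold slack.** `apply_cutoff` zeroes values below
  `cutoff·(1 − 1e-9)`. The pixel that defines a corner-max cutoff has
  modulus exactly equal to the cutoff; without the slack its retention would
  depend on floating-point rounding order, breaking exact intensity-scale
  invariance and 90°-rotation equivariance at the ~1e-5 level in ε (that
  pixel sits at maximal radius and carries the largest second-moment
  leverage per unit mass).
- **Eccentricity.** ε = √(1 − λ_min/λ_max) from the closed-form 2×2
  eigendecomposition; λ_min is clamped at 0 against rounding.
- **Orientation.** The major-axis angle is ½·atan2(2 μ₁₁, μ₂₀ − μ₀₂), mapped
  to [0°, 180°); μ adds 90° (mod 180°). When ε < 1e-3 the ellipse is
  near-circular and the result is flagged `orientation_unreliable` — the
  direction of a near-circle is noise.
- **σ on the circle.** The sector distribution is recentred so its weighted
  circular mean (computed on doubled angles) sits mid-domain, then a plain
  weighted mean and weighted sample variance are taken; this unwraps the
  half-turn circle without wrap bias, which is the only way a "normal fit"
  to angular data is well defined.
- **Even image sizes** are supported by placing DC at index ⌊N/2⌋; the
  unpaired Nyquist row/column introduces a one-pixel asymmetry, so odd crops
  are recommended (and the default) — an even `crop_px` warns.
- **Degenerate inputs.** A blank or noise-only image loses all spectral mass
  at the cutoff and raises a degenerate-spectrum error rather than returning
  a meaningless triple; batch runs isolate such failures per file.

## The phantom generator

Phantoms are fields of straight, anti-aliased fibre segments: orientations
drawn from a wrapped normal on the half-turn circle (aligned mats; the
normal-fit σ statistic makes this the natural aligned model) or uniformly on
[0°, 180°) (isotropic controls); centres uniform over the image; lengths
normal (default mean 400 px, SD 80 px in an 825 px field — structures
spanning a large fraction of the field of view, as fibre mats and extended
neurites do); width 3 px; fibre intensity 0.8 over background 0.05 with
additive Gaussian noise of SD 0.02, clipped to [0, 1]. Overlapping fibres
occlude (max-composite) rather than add. Rendering uses sub-pixel endpoints
and a 1 px coverage ramp so grid-aligned angles enjoy no special treatment.
All randomness flows from a single integer seed; identical specs give
bit-identical images.

What the generator does **not** emulate: fibre curvature and branching,
SEM speckle or confocal Poisson noise, depth-of-field blur, uneven
illumination, or cell bodies. Passing phantom tests therefore shows the
statistics respond correctly to orientation structure of bright elongated
segments under additive noise — not that they are robust to every artefact
of real micrographs.

**A finite-fibre-count limit on the isotropic ε.** For n independent uniform
orientations, the orientation order parameter q = |mean e^{2iθ}| has
expectation ≈ √π/(2√n) (≈ 0.05 for n = 300), and since the spectral
covariance anisotropy equals q when mass is carried by thin radial streaks,
the eccentricity of an isotropic phantom floors at ε ≈ √(2q) rather than 0.
Reaching the deep-isotropic regime ε < 0.2 requires the equivalent of
thousands of independent oriented structures — which dense real micrographs
contain, but a 300-fibre phantom does not. The isotropic-phantom ε reported
by `scripts/acceptance.py` is therefore seed-dependent with a floor set by
fibre count, and the benchmark's isotropic level is validated by *ordering*
(ε below every aligned level; σ at the uniform limit) rather than by an
absolute threshold.

## Validation surface

Because no reference micrographs are redistributable, correctness rests on:

- brute-force oracles: O(N⁴) DFT summation, exhaustive corner scans,
  double-loop moment and sector-binning implementations on small matrices;
- analytic limits: uniform angular weights give σ = 180/√12 ≈ 51.96°; a
  single-direction phantom gives ε ≥ 0.9; a line spectrum gives ε = 1;
- ground-truth recovery over a 60-phantom grid (σ₀ ∈ {5°, 15°, 30°, 60°,
  uniform} × μ₀ ∈ {0°, 30°, 90°, 120°} × 3 replicates): mean circular error
  of μ ≤ 5° for σ₀ ≤ 30°;
- monotonicity: mean ε strictly decreases and mean σ̂ strictly increases
  across the five dispersion levels (20 replicates per level, run at a
  reduced 275 px / 100-fibre scale);
- exact invariances: 90° grid rotations shift μ by exactly 90° and preserve
  ε; global intensity rescaling changes nothing (the cutoff scales with the
  spectrum).

σ̂ systematically exceeds the generating σ₀ for tight alignment because each
finite-length fibre's spectral streak has intrinsic angular width; σ̂ is a
property of the image's spectrum, not an unbiased estimator of the fibre
orientation SD.

## Count comparison

Marker-positive fractions (100·positive/total) and fold-changes between two
conditions are rounded half-up to one decimal (the convention that matches
hand-rounded reports; Python's banker's rounding does not). The fold of
fractions is computed from unrounded fractions and only then rounded.
Reported "±" spreads can be stored as metadata but enter no computation, and
no inferential tests are performed: summary counts carry no replicate
structure to test.

## Known limitations

- The statistic conflates orientation dispersion with everything else that
  broadens spectral streaks (structure length, width variation, noise
  surviving the cutoff); σ̂ values from different imaging modalities are not
  directly comparable.
- The default rectangular crop leaks a cross artefact into the spectrum;
  the Hann option removes it at the cost of down-weighting the image border.
- The corner-max cutoff assumes the corners are structure-free; images with
  genuine high-frequency texture reaching the corners will over-estimate
  the noise floor.
- 3D orientation is out of scope; projections of steeply tilted structures
  foreshorten and bias the in-plane statistics.
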