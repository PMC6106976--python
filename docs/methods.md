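# Methods

This note records the scientific and numerical choices behind
`liverlsm`: the models, the parameters that matter, the synthetic study
conditions, and the places where the design was genuinely open.

## Intensity conventions

Images are normalized to [0, 1] by their own min/max at load time
(idempotent; constant images map to zero). All intensity *thresholds*
operate on this scale: the region-growing tolerance W, the binarization
divisor θ, the signed pressure force, the clustering constants and the
HMRF Gaussians. Gradient-based responses are the exception: the sigmoid
constants of the preprocessing chain (κ = −1.5, β = 4) and the quadratic
edge indicator g = 1/(1 + |∇G_σ∗I|²) were calibrated for gradients on
the 8-bit gray-level scale, where a tissue edge yields |∇| ≫ 1. On [0, 1]
intensities both saturate — the binarized image comes out empty and g
never drops below ≈ 0.93 even at a full-contrast edge. Gradient
magnitudes are therefore computed on ×255-rescaled intensities
(`PreprocessParams.intensity_scale`, `edge_indicator(intensity_scale=…)`),
keeping both conventions consistent at once.

## Preprocessing chain

Perona–Malik diffusion uses the exponential conductance
g(s) = exp(−(s/conductance)²) in an explicit 4-neighbour scheme,
defaults: 10 iterations, conductance 0.1 (on [0, 1] intensities), time
step 0.125 (stable ≤ 0.25). The scale-specific gradient uses Gaussian
smoothing (γ = 0.5 px) followed by central differences with replicate
boundaries; smoothing-then-differencing and derivative-of-Gaussian
kernels agree up to discretization and the former was chosen for
simplicity. The sigmoid with κ < 0 maps flat regions bright and edges
dark; binarization thresholds at (max + min)/θ with θ > 1 (operating
range 1.1–1.5, default 1.25). Because the threshold *decreases* as θ
grows, the binary masks are nested increasing in θ; the test suite
asserts exactly this nesting.

## Region growing

Breadth-first growth over 4-neighbours from each seed, FIFO order, with
the region mean updated incrementally after every accepted pixel and the
strict criterion |v − mean| < W. The update order matters on grayscale
inputs and is fixed for determinism; 8-connectivity was considered and
rejected for diagonal-leak risk. On the binary preprocessed image the
result is provably the seed's connected component for any W ∈ (0, 1] and
any seed position inside it — the robustness property that motivates the
preprocessing. Hole filling fills background components not connected to
the image border (4-connected background).

## The unified level-set flow

The flow is the gradient descent of the distance-regularized geodesic
energy with a signed-pressure balloon:

* d_p(s) = sin(2πs)/(2πs) for s ≤ 1 (→ 1 as s → 0) and (s−1)/s for
  s ≥ 1; central differences with |∇φ| floored at 1e−10; Neumann borders.
* Dirac/Heaviside: the compact cosine pair with width ε = 1.5 px.
* Region means c₁, c₂ are recomputed from the current φ every iteration
  (the standard Chan–Vese treatment; freezing them is the alternative
  the literature does not use).
* Sign conventions: the object is {φ > 0}. The balloon is
  B = α·g·SPF with α > 0 a pure magnitude; an orientation factor
  sign(c₁ − c₂) keeps the {φ > 0} phase tracking the intensity cluster
  the contour was initialized in. This makes the same flow grow a
  contour outward onto a bright liver and inward-initialized contour
  outward into a hypodense lesion; without it a rectangle inside a dark
  lesion collapses.
* Time step Δt = 5 with μ = 0.04 (μΔt = 0.2 < 0.25, the standard
  stability bound; Δt = 5 is the canonical choice for this family). At
  Δt = 1 the contour does not reach the boundary within the fixed
  iteration budgets (liver VOE ≈ 4–5% instead of ≈ 1%; the tumor flow
  stalls at Dice ≈ 0.7).
* Defaults: μ = 0.04, λ = 5, liver balloon α = 10 with t = 100
  iterations, binary-step initialization height ω = 4 (admissible ω ≥ 2);
  tumor balloon ϑ = 3 with t = 200 iterations and no early stopping.
  An optional convergence surrogate (stop when the zero-level mask
  changes by < 0.1% of pixels for 5 consecutive iterations) replaces
  interactive termination; it is off by default so fixed-iteration
  experiments are reproducible.
* Edge-indicator smoothing σ = 1.0 px, matched to the ≈ 1 px
  partial-volume blur of real CT boundaries that the phantom generator
  emulates.

A practical property worth knowing: the double-well potential has minima
at |∇φ| = 0 *and* 1, so plateaus at ±ω/2 persist and strong balloon
forcing widens the transition band; |∇φ| ≈ 1 holds in the band |φ| ≤ ε,
not on the plateaus.

## Tumor branch

**Local intensity clustering (LIC).** Under I = b·J + n with b smooth
and J two-valued, the clustering energy uses the truncated Gaussian
kernel K (a = 1, τ = 4, ρ = 3; square support (2ρ+1)², circular
truncation). The c and b updates are the closed-form stationary points
(c_i from ratio of kernel-weighted moments, b = K∗(I·J⁽¹⁾)/K∗(J⁽²⁾)) —
verified in tests against a direct double-summation energy oracle. The
minimization schedule required care; the working scheme is:

* φ₀ is a seeded per-pixel Rademacher (±1) field, but the constants are
  seeded asymmetrically (90th/10th intensity percentiles) and the bias
  field starts from a unit-mean quadratic surface fitted to the ROI
  border band (the border is parenchyma by the ROI-selection
  convention), so the first φ step already thresholds against a locally
  corrected cluster midpoint. Starting b from the closed-form update
  with a random partition instead lets the free-form bias absorb the
  whole lesion — the kernel radius (3 px) is far smaller than a lesion —
  after which no partition can form.
* Each cycle runs {one φ step, c update, relaxed b update}; the b step
  moves fraction 0.1 of the way to its minimizer. The energy is a
  separable per-pixel quadratic in b, so the relaxed step still
  descends; damping keeps the bias estimate in step with the
  slowly-moving partition.
* The φ flow uses the Cauchy (global-support) Dirac and Δt = 0.02, and
  the clustering energy is computed on the ×255 gray scale; with the
  compact Dirac or unit-scale energies the data term cannot dominate the
  ν = 1, δ_reg = 1 regularizers and the random initialization never
  self-organizes. Hard memberships [φ > 0] are used in the closed-form
  updates (the two-phase model's regions are disjoint).
* The phase reported as tumor is the one whose mean intensity differs
  most from the 2-px ROI border band (hypodense and hyperdense lesions
  both handled).

Measured under the default study conditions (contrast 0.1, linear bias
amplitude 0.3, noise σ = 0.02): partition Dice ≈ 0.95; with the noise
removed the bias field is recovered with correlation 1.000 to the true
field.

**HMRF-EM.** Gaussian class likelihoods with a pairwise Potts prior
(8-neighbour cliques, weight 0.5 by default — the MAP algorithm and the
neighbourhood prior form are design choices; the literature states the
criterion, not the solver). MAP labels by raster-order ICM with early
exit, 15 sweeps; EM re-estimates class means/variances from posteriors
P(l|β_i) ∝ N(β_i; μ_l, σ_l²)·exp(−potts_beta·#disagreeing neighbours),
15 iterations; variances floored at 1e−6.

**Enhanced edge indicator.** g_binary is the quadratic edge indicator of
the {0,1} classification, affinely rescaled to [0, 1] so the edge band is
exactly 0 (a constant classification rescales to zeros), and
g_enhanced = max(g_binary, g). The interior of the classified lesion is
then ≈ 1 (fast propagation) while the band carries the small-but-nonzero
original g, so evolution never halts completely. Whether the "binary
result" should enter Eq-wise as the raw mask or as its edge map is
ambiguous; the edge-map construction was chosen because the raw mask
would zero the speed over the whole background.

## Synthetic study conditions

The liver phantom is a 256×256 slice with a 92×78 px elliptical liver at
intensity 0.8 on a 0.2 background, 0.8 px Gaussian partial-volume blur of
structure edges, and additive Gaussian noise σ = 0.02 — proportions
matching a liver of realistic size in a downsampled portal-phase slice.
Optional parts: discrete liver components, dark internal vessels/tumors
(excluded from the image, not from the ground-truth envelope), an
adjacent organ whose interface carries a graded intensity ramp over a
fraction of its extent (a boundary with no edge), and extra structures
outside the liver. The tumor phantom is an 80×80 ROI, parenchyma 0.6,
elliptical lesion of contrast 0.1 (hypodense by default), a strictly
positive linear or quadratic bias field of amplitude 0.3 across the ROI
(< 1% relative gradient per pixel), noise σ = 0.02, and an optional
faded-margin arc over which the lesion contrast ramps to zero at the
boundary — the ambiguous, variable margin of complex lesions. The true
image J is exactly two-valued (the clustering model's assumption); the
returned ground truth is noise-independent.

What the phantoms do *not* emulate: anatomical shape variability,
streak/beam-hardening artifacts, correlated CT noise, partial-volume
mixtures along the z axis, and multi-organ context. Passing tests
therefore demonstrate the algorithms' mechanics under controlled
difficulty, not clinical-grade performance.

The comparison experiments are run on deliberately hard fixtures:

* liver (edge/region/unified at α = 20/20/30, t = 150, Δt = 3): the
  leakage phantom combines a no-edge corridor toward a darker organ with
  a large mid-bright structure behind a weak true edge. Δt = 3 is used
  because at Δt = 5 a 20–30 balloon crosses *every* internal edge within
  150 iterations (the edge model's premise fails) while at Δt = 1 no
  front converges and only convergence deficits are measured. Measured
  ordering over noise seeds: unified VOE ≈ 2 < edge ≈ 10–12 < region ≈ 20.
* tumor (unified vs edge-only with g_enhanced vs region-only, identical
  init and iterations): two complex-lesion classes, both at contrast
  0.1, bias 0.3, noise 0.02, with a faded-margin arc (140°/10 px and
  100°/6 px) facing the bias-bright side and the lesion offset toward the
  dark side. On idealized two-phase lesions the region-only variant is
  optimal by construction, so only complex conditions can discriminate
  the models. Measured mean Dice: unified 0.89/0.95 above region
  0.89/0.94 and far above edge-only ≈ 0.31 (which escapes through the
  faded margin and never reverses).

## Degenerate inputs and guards

Empty phases in region statistics raise; SPF of a constant image is the
zero field; bias-update denominators and |∇φ| are floored at 1e−10;
HMRF variances at 1e−6; a collapsed (one-phase) LIC result raises; masks
validate {0,1} exactly; rectangles are half-open, 0-based, area ≥ 9.

## Known limitations

Fronts cannot jump disconnected components: a lesion or liver part not
reachable from the initialization is never segmented (hence one seed per
discrete part). The bias model is multiplicative and smooth at the
kernel scale; bias varying at lesion scale is unidentifiable from a
single ROI. The balloon-vs-edge equilibrium leaves a sub-pixel to ≈ 1 px
systematic under-segmentation at sharp boundaries, visible as small
negative RVD. All computations are 2D and slice-wise.
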