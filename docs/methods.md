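# Methods

`spinemorph` quantifies dendritic-spine ultrastructure from serial block-face
electron microscopy (SBEM) annotations and tests sleep/wake differences with
hierarchical mixed-effect models. This note records the models, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Serial-section surface reconstruction

Objects (dendritic shafts, spines, axon-spine interfaces) are stacks of closed
planar polygons: xy coordinates in nanometers (4 nm pixels in the emulated
protocol), one or more polygons per 50 nm section. The total surface of a
stack is the *smoothed upper bound surface* (SUBS): each traced element
contributes its smoothed perimeter `Ps` times the section thickness `T` (half
for its top face, half for its bottom face), and consecutive elements
contribute the absolute area step:

    SUBS = sum_k [ Ps(a_k) T/2 + Ps(b_k) T/2 ] + sum_k |A_k − A_{k+1}|

Choices that the formula alone does not fix:

- **Smoothing operator.** Undefined in the segmentation-tool tradition this
  mirrors; implemented as a symmetric moving average over ±`kernel_halfwidth`
  neighbouring vertices with periodic boundary (default halfwidth 2,
  `SmoothingSpec`). For convex contours smoothing can only shorten the
  perimeter (property-tested).
- **Area step sign.** The step term uses `|ΔA|`: signed differences telescope
  to ≈0 across a stack and cannot represent end or taper surface; the
  absolute value is the only reading that yields an upper bound.
- **Several polygons in one section** (in-plane branching): perimeters and
  areas are summed per section, preserving additivity.
- **Gaps** (untraced sections): every element always contributes `Ps·T` for
  its own slab; a gap of `g` sections additionally bridges the missing
  `(g−1)·T` with the mean of the two flanking perimeters. Gaps are counted
  and logged.
- **Units and coordinates.** All internal math in nm/nm²; public reports in
  µm/µm². Section `k` spans `[kT, (k+1)T)`; phantom contours are drawn at the
  slab centre.

The **apposed surface** of a quasi-2D interface sheet (the axon-spine
interface, ASI, traced one pixel wide) is `AS = (SUBS − A_first − A_last)/2`,
clamped at zero with a logged warning. Note a structural limitation verified
by the phantom tests: for a sheet tilted 45° to the cutting plane with
constant per-section trace length `L`, all `|ΔA|` terms vanish and
`AS = L·nT` — the *vertical projection*, a factor √2 below the true inclined
area. The estimator is blind to in-plane stepping, which is exactly why
oblique interfaces are excluded from measurement in this kind of data.

**Dendrite shaft measures.** Surface area is SUBS of the shaft contours only
(no spine membranes, no endcaps — shafts are truncated by the field of view;
a config switch is unnecessary because endcap areas are available from the
first/last sections if a user wants them). Length is the 3D arc length of the
per-section area-weighted centroid polyline, extrapolated half a step at each
end so `n` co-axial sections span `n·T`; diameter is that of the circle with
the mean cross-sectional area. Sampling inclusion bounds (length ≥ 3.122 µm,
diameter 0.940–1.966 µm) are warn-don't-fail validations.

**Phantom validation.** A cylinder reproduces `2πr·nT` to <0.1%. A sphere at
the 4 nm / 50 nm anisotropy matches the marching-cubes mesh of the same voxel
mask to ~4%: at this anisotropy the mesh itself is a staircase of
near-vertical ring walls plus horizontal annuli, which is the geometry SUBS
measures (analytic limit `(π+2)πr²`, ≈28% above the smooth sphere `4πr²` —
the formula is an upper bound by construction).

## Census

All protrusions are spines. A spine may carry a synapse (flag set by the
annotator; never inferred from imagery), may share a neck with ≥1 other spine
(a *branched* group; each member's synapse counts separately), or may lack a
synapse (*naked*). Naked spines are classified as: single, member of an
all-naked pair, naked member of a mixed pair, or head protrusion (a naked
protrusion off a synapsed spine's head — counted as a spine but never as a
branch-group member, since it shares a head, not a neck).

Densities are exact ratios (counts per µm² of dendrite surface or per µm of
length). Percentages are computed under two denominators, always labelled:
per *all spines* (used for the branched share of spines) and per
*spines-with-synapse* (used for organelle, oblique and incomplete rows).
Group summaries report mean ± sample SD (ddof=1), across dendrites for
densities and across mice for percentages; the pooled and mean-of-mice
conventions for the fraction of spines with a synapse are both reported. A
spine that is both oblique and branched keeps both flags: it is excluded from
ASI-based metrics (its interface cannot be traced) but included in all counts.

## Mixed-effect inference

The model is `y = Xβ + Zu + ε`, `u ~ N(0, Σ)`, `ε ~ N(0, σ²I)`. Dendrite-level
responses (densities, proportions; square-root transformed where the response
is a count density) get a mouse random intercept; synapse-level responses
(sqrt ASI) get mouse and dendrite-within-mouse random intercepts (nested — a
dendrite belongs to one mouse; the crossed alternative is meaningless) plus
dendrite diameter, centred before fitting so the intercept is reported at the
mean diameter. Condition (W spontaneous wake / EW extended wake / S sleep)
enters as a fixed effect with EW as reference.

- **Estimation** is maximum likelihood (never REML) via `statsmodels`
  `MixedLM`; the optimizer is Powell on the profiled deviance with an L-BFGS
  fallback — in this statsmodels version the gradient methods stall at the
  variance boundary, while Powell reproduces an independent direct-likelihood
  optimizer to <1e-6 in log-likelihood (test suite holds it to 1e-4 on ten
  datasets). Fits are deterministic given the data.
- **The condition test** is the asymptotic likelihood-ratio test: full vs
  condition-free reduced model, both ML, `χ² = 2Δll` (clamped at 0), df = 2.
  REML fits are refused. *Small-sample caveat:* the asymptotic test is
  anticonservative at finite sizes — null simulations here measure ~0.078
  rejection at nominal 0.05 for the study-sized world (98 dendrites, 14
  mice), ~0.067 at 180 observations / 30 mice, ~0.06 at 600 / 75 mice,
  approaching 0.05 only for much larger cohorts (the chi-square reference
  ignores the F-type denominator-df correction). The fits themselves match an
  independent direct-likelihood oracle to ~1e-8, so this is a property of the
  test, not the optimizer. p-values near 0.05 from cohorts this small deserve
  that grain of salt; the dedicated calibration test fails by design to keep
  the fact visible.
- **Post hoc contrasts** (S−W, S−EW, W−EW) use the single-step max-|z|
  adjustment: adjusted p = 1 − P(max_j |Z_j| ≤ |z_i|) under the joint normal
  with the contrasts' correlation matrix (rank 2 — handled as a singular MVN).
  The integral uses scipy's quasi-Monte-Carlo CDF with a fixed seed
  (deterministic; validated against a 10⁶-draw Monte-Carlo oracle to <0.005).
  Adjusted p is clipped to be ≥ raw p against integration noise; a degenerate
  covariance falls back to Bonferroni with a warning. The multivariate
  *normal* (not t) reference is used — it matches the large-sample behaviour
  of the standard procedure and stays deterministic; small discrepancies from
  tools that use a t reference are expected and not tuned away.
- **p-value reporting**: 4 significant figures, values below 1e-12 as bounds.
- **Diagnostics** are descriptive only: residual-vs-fitted spread, normal
  quantile correlation (flag below 0.95), optional plots.
- **Distribution shape** of ASI samples (n ≥ 100 required): bimodality is
  called only when a 2-component Gaussian mixture on the sqrt scale both wins
  by BIC *and* its fitted density has two modes (a 2-component win alone can
  reflect skewness); tail shape compares log-normal vs gamma ML fits by AIC
  on the raw scale.

## Synthetic cohort

The generator emulates the three-condition design: 4/4/6 mice (W/EW/S), 7
dendrites per mouse (≈96–98 total), dendrite length ~N(8.5, 3.3²) µm
truncated at the 3.122 µm inclusion bound, diameter ~N(1.35, 0.17²) µm
clipped to 0.940–1.966 µm, surface ≈ π·d·ℓ with 10% log-normal noise
(≈36 µm², matching ≈70 synapses per dendrite at ≈2/µm²). Per-condition
defaults are the published cerebellar values: synapse density 1.76/2.04/1.78
per µm², naked 0.08/0.13/0.19, branched synapses 0.29/0.38/0.16; ASI gamma
with mean/SD 0.187/0.109, 0.158/0.095, 0.174/0.104 µm² (gamma: strictly
positive, unimodal, right-skewed — no heavy log-normal tail); branched ASIs
scaled by 0.88; oblique 7.0/5.6/1.8% and incomplete ≈1% of synapses carry no
measurable ASI; organelle flags Bernoulli at the published per-condition
rates; 93% of branched pairs contact different presynaptic fibers; 3% of
branched groups are triples.

Counts are Poisson given dendrite area and a mouse-level effect that shifts
the *square-root* density by N(0, 0.0605) — the simplest count model
consistent with per-area densities, under which the sqrt-scale LME is
approximately variance-stabilised. Mixed naked/synapsed pairs are carved out
of both the naked and branched budgets so every configured density is met in
expectation; a configured rate of exactly 0 stays 0. One seed determines
every table bit-for-bit.

**Recovery estimand.** Because the square root of a Poisson count is concave,
the population value of E[√density] sits below √rate by an amount set by the
expected count per dendrite (≈6% for the sleep-group branched rate); the gap
does not shrink with more mice. Recovery experiments therefore measure bias
against the population sqrt-scale contrast computed from the generative model
itself (400k-draw vectorised evaluation), and report the naive
√rate-contrast alongside.

**What a green test does not establish.** Organelle flags are drawn
independently of ASI size and of each other (the real joint distribution is
unknown); spine geometry is not generated (densities and areas are, contour
stacks come from phantoms); there is no within-dendrite spatial structure and
no turnover dynamics (the generator is cross-sectional, like the data). Tests
green on this world validate the estimators and the inference chain, not any
biological claim.

## Runtime scaling in the test suite

Simulation sizes were scaled to keep the default suite within a few minutes
of CPU: generator moment-matching at 2,500 dendrites (binomial/cluster MC
bands computed for the size actually run), full-pipeline null recovery at 150
replicates, power at 40, bias at 16; the 2000-replicate LRT calibration runs
in full. No acceptance threshold was altered to absorb scaling.

## Known limitations

- Exact numerical equality with other mixed-model implementations (lme4) is
  not promised; agreement is to optimizer tolerance on the same likelihood.
- The post hoc reference (normal vs t) can differ from other tools in the
  3rd–4th significant figure of adjusted p-values.
- SUBS is an upper bound: it overestimates smooth curved surfaces (~28% for a
  sphere) and measures only the vertical projection of tilted sheets.
- The ASI "with branched" model treats the branched indicator per spine.
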