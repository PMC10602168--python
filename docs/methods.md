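# Methods

## The question and the two estimators

Transport of a solute through brain tissue combines hindered diffusion
with, possibly, convective bulk flow. Diffusion is molecular-weight
dependent; pressure-driven bulk flow is not. A 70 kD tracer (Gd-albumin)
diffuses so slowly that any appreciable spread over tens of minutes implies
convection — if the spread can be measured and compared against a purely
diffusive prediction. `tracerflow` implements both sides of that
comparison.

**Boundary-propagation ADC\*.** Within a manually drawn ROI, each serial
T1-weighted volume is split into tracer/non-tracer classes by Otsu's
threshold (256 equal-width bins over the ROI's intensity range; the
higher-intensity class is tracer; ties broken toward the lower threshold).
The tracer surface is the set of mask voxels with a face-adjacent
(6-connectivity) neighbor outside the mask, taken as voxel-center
coordinates in mm. For consecutive surfaces separated by t ms, each point
of the earlier surface contributes ADC\* = dist²/(2·3·t) with dist the
Euclidean distance to the nearest point of the later surface; per-point
values from all consecutive pairs are pooled into a mean ± SE. Pooling
per-point values (rather than averaging per-pair means first) weights each
observed surface point equally; the per-pair means are reported alongside.

**Tortuosity-scaled DTI prediction.** The diffusion tensor is estimated per
voxel by ordinary log-linear least squares on ln(S_g/S₀) = −b·gᵀDg
(no weighting, no positivity constraint; voxels with non-positive S₀ or DW
signal are masked; negative eigenvalues are clamped to zero for scalar maps
and flagged). Eigenvalues are sorted descending; FA, ADC = (λ₁+λ₂+λ₃)/3,
D_axi = λ₁ and D_rad = (λ₂+λ₃)/2 follow. The region's water ADC is scaled
to the tracer through λ² = D_water_free/ADC_water and
ADC_tracer = D_albumin_free/λ², algebraically a multiplication by
D_albumin_free/D_water_free = 8.29×10⁻⁸ / 3×10⁻⁶ ≈ 0.0276 (free constants
configurable; the albumin value is for 66 kD BSA standing in for 70 kD
Gd-albumin). The assumption that the tracer shares water's tortuosity is
conservative: a larger true tortuosity would only lower the diffusive
prediction and strengthen any bulk-flow conclusion. Standard errors scale
by the same factor (exact for a linear map).

**Group comparison.** Per region, subject-level ADC\* values and scaled
predictions are compared with a two-sided pooled-variance Student t-test
(α = 0.05; no multiple-testing correction across the two regions) and the
symmetric percent difference 100·(a−b)/((a+b)/2). With a single subject the
report is emitted with statistics marked not applicable.

## Units

All diffusivities are carried in mm²/ms with the free-diffusion constants
quoted above; simulator time runs in minutes (1 min = 6×10⁴ ms). The DW
signal model forms the exponent −b·gᵀDg numerically from b in s/mm² and
the tensor entries as stored, matching the convention in which tissue
water ADC is ~6×10⁻⁷ in these units; the tensor fit inverts the identical
expression, so the round trip is exact and the tortuosity chain consumes
the fitted values directly.

## The phantom

The synthetic experiment stands in for an intra-striatal infusion study:
a 64×64×48 grid at 0.125×0.125×0.167 mm (a rodent 7T protocol at reduced
extent) containing an isotropic grey-matter ball ("striatum", water ADC
6.2×10⁻⁷ mm²/ms) and an anisotropic white-matter slab ("callosum", axial
1.4×10⁻⁶, radial 3.7×10⁻⁷; mean 7.1×10⁻⁷), values chosen so the scaled
diffusive predictions land at 1.71×10⁻⁸ and 1.97×10⁻⁸ mm²/ms, the
magnitudes reported in vivo. The tracer diffuses with D_t = 1.7×10⁻⁸
mm²/ms (the scaled-albumin value), is emitted by a point-like source over a
20-minute window ending at the clock origin, and is imaged at 4.5, 24 and
28.5 minutes after the end of infusion. T1-like volumes are
baseline + gain·concentration + Gaussian noise; DW volumes follow the
monoexponential tensor model with Rician noise (magnitude of a complex
Gaussian perturbation). Identical spec and seed give bit-identical output.

The transport solver is an explicit flux-form finite-difference scheme:
central differences for diffusion, first-order upwinding for advection,
reflecting (no-flux) boundaries. Fluxes are antisymmetric across faces, so
total mass with the source off is conserved to round-off; the time step is
refined automatically below the diffusive limit Δt ≤ ½/(D·Σ1/h²) and the
advective CFL limit (with a 0.9 safety factor, capped at 0.25 min for
accuracy). The scheme is positivity-preserving within these limits. Known
artefact: upwinding adds numerical diffusion of order v·h/2 along the flow
axis (≈8×10⁻³ mm²/min at the default speed and spacing, versus a physical
1×10⁻³ mm²/min), acceptable here because displacement, not spreading,
carries the advective signal.

Default study design: each region is probed by its own tracer experiment
with the source at the region's center — at this desk scale a bolus
physically cannot reach a distant structure within 28.5 minutes — with
convective flow of 0.1 mm/min (~1.7 µm/s, within reported perivascular
flow speeds) in the striatum experiment and none in the slab experiment.
The speed was set so the simulated ADC\* excess over the diffusive
prediction reproduces the roughly two-fold ratio observed in vivo. The
segmentation ROI is the anatomical mask dilated by 3 mm (Euclidean), a
surrogate for manual ROIs drawn generously around the visible tracer at
every timepoint; the margin must cover the advective displacement
(≈2.9 mm over 28.5 min at the default speed). The DTI ROI is the
undilated anatomical mask. Cohorts are generated by varying the seed;
default n = 5.

## What the estimator can and cannot recover

The ADC\* statistic interprets boundary displacement as particle
displacement. For a purely diffusing blob the two differ fundamentally: an
iso-intensity contour at fraction f of the peak sits at radius
s(t)·√(2·ln(1/f)) with s(t) = √(2Dt), so between scans at t₁ and t₂ the
contour advances proportionally to √t₂ − √t₁ and

ADC\*/D ≈ (2/3)·ln(1/f) · (√t₂ − √t₁)²/(t₂ − t₁),

which is below 1 unless t₁ ≪ t₂ and the threshold is deep in the tail. At
the study's scan times (4.5 → 24 → 28.5 min after a 20-min infusion) the
time factor is ≈0.2, and Otsu lands at f ≈ 0.12–0.19 of peak (the blob's
dim outskirts dominate the ROI histogram), so a diffusion-only phantom
yields ADC\* ≈ 0.14·D — the estimator *understates* pure diffusion at
these scales, and voxel quantization (sub-voxel contour steps between the
two late scans) pushes the pooled value further down. Consequences,
verified by the test suite:

- Bulk-flow detection is **conservative**: ADC\* exceeding the diffusive
  prediction cannot be produced by diffusion alone here, since diffusion
  alone drives ADC\* *below* that prediction.
- ADC\* is not a calibrated diffusivity at these scan times. The estimator
  does approach truth in its validity regime — a test with a 25-fold
  observation-window ratio recovers D within tens of percent.
- In a flow-free region the percent difference is strongly negative; only
  the flow-bearing region reproduces the positive, significant contrast.
- Surface-intensity noise roughens both surfaces and lets them
  interpenetrate where growth is ~1 voxel, biasing ADC\* down (consistent
  with the contrast-to-noise caveat attached to the in-vivo measurement);
  the default T1 noise is therefore modest, and with advection the effect
  is negligible.
- The Otsu tracer mask encloses the 50%-max concentration region rather
  than matching it (threshold ≈ 20% of peak), another reason contour
  position and half-max position should not be conflated.

## Numerical and design choices

- 6-connectivity for boundary extraction (face-adjacent surface
  intuition); boundary = mask minus its 6-connectivity erosion, lattice
  edges counting as boundary.
- Otsu evaluates each distinct histogram partition once (runs of empty
  bins form exact objective plateaus; evaluating them repeatedly would
  break the lower-threshold tie rule through rounding noise). Otsu is
  computed per volume; constant-intensity ROIs are a degenerate-input
  error.
- Zero travel distances are retained in the ADC\* pool (dropping them
  would bias upward); distances use physical anisotropic spacing;
  direction is earlier → later only.
- Surface counts are expected to grow (N₁ < N₂ < N₃) for a spreading
  tracer; violations warn rather than fail, since noise or strong
  advection (a translating blob leaving the ROI's far side) legitimately
  break monotone growth.
- Gradient scheme: the classic six directions (±x±y, ±y±z, ±x±z
  normalized) plus one unweighted volume, b = 900 s/mm²; any ≥6-direction
  full-rank unit set is accepted.
- Eigendecomposition uses a symmetric solver with descending sort; ties
  are legal (FA is well defined under them).
- No connected-component filtering by default; `--largest-component`
  restricts the mask to its largest 26-connected component when noise
  fragments it.

## Limitations

- The phantom's advection is a uniform velocity field, not a pulsatile or
  perivascular-network model; no microanatomy, no macrophage biology.
- The T1 model is a linear gain without relaxometry; no intensity
  normalization across timepoints is attempted.
- The tensor fit is single-shell and unweighted; no motion or eddy
  correction (inputs are assumed co-registered).
- ADC\* inherits the biases above; between-group comparisons of ADC\*
  against the scaled prediction are meaningful, absolute ADC\* values at
  short windows are not.
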