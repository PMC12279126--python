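# Methods

This note documents the models and procedures implemented in `apexfa`, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the package's known numerical and geometric limitations.

## Phantom image model

A phantom radiograph is an elliptical radiolucency on a textured
background. With `d` the (approximate) signed distance of a pixel from the
lesion boundary (negative inside), the noise-free intensity is

    I(d) = interior + (exterior − interior) · σ(d / τ),   τ = w / ln 81,

where `σ` is the logistic function and `w` the **transition width**,
defined as the 10%→90% rise distance — this makes the radiographic notion
of a "grayscale gradient transition zone" a measurable quantity. An
optional corticated rim adds a Gaussian radiopaque overshoot of amplitude
`cortication_amplitude` centered `w` outside the 50% crossing.

Trabecular bone texture is band-limited Gaussian noise (Gaussian-filtered
white noise, blob scale `trabecular_sigma` = 0.3 mm, amplitude 6 gray
levels, optional directional elongation `trabecular_anisotropy`); because a
periapical radiograph is a 2-D projection, the texture of the intact
cortical plates is superimposed over the lesion as well as the background,
so the field is added everywhere. Detector noise is i.i.d. Gaussian
(SD 2 gray levels). Defaults: 256×256 px at 0.1 mm/px (one FA square =
10×10 px), interior/exterior levels 60/160.

What the phantoms do **not** emulate: projection physics, anatomical
superimpositions (roots, sinus), detector blur/MTF, exposure variation.
Passing tests demonstrate the pipeline's correctness and the method's
geometric properties, not clinical performance on real radiographs.

## Cohort model

Healing times follow a Weibull proportional-hazards model for the healing
event: S(t|z) = exp(−(t/λ)^k · e^{β′z}) with shape k = 1.4 and scale
λ = 23 months, giving a median observed healing time near 18 months. The
linear predictor combines seven encoded clinical terms — gender, age
(centered at 52 y), diabetes, lesion diameter (centered at 10 mm), tooth
position (mandible), and two tooth-location dummies (premolar, molar vs
anterior) — with the **standardized boundary sharpness** 1/w. Covariate
frequencies and moments mirror a mixed endodontic cohort (38% female, 32%
diabetic, 66% mandibular, anterior/premolar/molar 30/27/43%, age 52 ± 19 y,
lesion 10 ± 3.5 mm truncated to the 5–15 mm inclusion range).

Defaults: `beta_clinical = (0.10, −0.008, −0.40, −0.06, 0.15, −0.10,
−0.25)` (modest effects; the clinical-only model discriminates weakly) and
`beta_boundary = −1.2` per SD of sharpness — blurred, ill-defined borders
heal *faster*, consistent with reading vague borders as acute lesions, and
strong enough that the boundary signature dominates prognosis, mirroring
the large gap between clinical-only and boundary-augmented models that
motivates the method. Transition widths are uniform on 0.2–0.8 mm.

Observation is **interval-coarse**: healing is first seen at the next
3-month radiograph visit (latent time rounded up to the grid), with
administrative censoring at 36 months and uniform dropout (probability
0.25) at a random visit; the observed event fraction is ≈ 63–70%. A
consequence worth knowing: with only ~12 distinct event times, the
Breslow-tie Cox fit attenuates strong coefficients by ~10–13% toward zero
(measured at n = 2000); on the latent continuous times the generator's
coefficients are recovered without bias. Patients are split 6:4 into
development and validation cohorts by a seeded random partition.

## Segmentation

Canny edge detection uses Gaussian σ = 1.4 px and double thresholds 35/50
on the 0–255 gray-level scale (deeper bit depths are rescaled first;
thresholds and σ are configurable). Contour recovery replaces
operator-guided semi-automatic contouring with a deterministic rule: the
edge mask is dilated by the gap-closing radius r (default 0.3 mm), which
bridges edge breaks up to ~2r — a plain morphological closing cannot do
this, because the thin bridge erodes away again — the enclosed free region
containing the seed point is taken (an error if it leaks to the image
border), grown back by r so its boundary lands on the edge centerline, and
smoothed by uniform-arclength resampling plus a circular Gaussian (σ =
2 px). On a perfect circular edge map the recovered contour is accurate to
~0.3 px. ROIs: S1 = filled contour eroded by 0.5 mm, S2 = dilated by
0.5 mm, S3 = S2 ∖ S1 exactly; margins are configurable (the S1→S2
extension is shown but not quantified in the radiographic literature).

## Fragment analysis

**Transition localization.** The contour is resampled every 0.15 mm; the
intensity profile along each outward normal (probe 2 mm) is read from a
lightly smoothed image (σ = 1 px). The centerline point is the 50%
crossing between the local inner/outer plateau levels; the local width is
the 10%→90% crossing distance, corrected in quadrature for the measurement
blur so a hard step reports the one-pixel quantum. Non-monotone profiles
(> 20% of samples) abort with an error; isolated failures are filled by
circular interpolation. On noise-free phantoms the median width is within
10% of truth for w = 0.2–0.8 mm and the centerline within 1 px of the true
boundary. A parametric logistic fit was considered and rejected: on
phantoms it matches the crossing estimator while costing ~200 curve fits
per image.

**Tiling.** Squares (side 1 mm) are placed by a greedy march: each square
is centered on the centerline with a side parallel to the local tangent
(if the arc inside a square bows more than 0.2 mm from the tangent line —
which does not happen at 5–15 mm lesion diameters — the secant direction
is used), and the next center is exactly one **chord** of 1 mm further
along, so consecutive squares meet at the centerline. The march starts at
the centerline point farthest from the lesion centroid: an origin
intrinsic to the lesion geometry, so the tiling — and therefore the S4
image — is equivariant under rotation of the radiograph; an image-frame
origin (e.g. "topmost point") would re-phase the tiling on rotation and
break the invariance the method exists for. The closure mismatch is
distributed: all advances are rescaled by a common factor so the loop
closes exactly, choosing between n and n−1 squares whichever satisfies the
half-pixel overlap and gap tolerances. Counts equal the chord-corrected
⌊perimeter/chord⌋ (15/31/47 squares at 5/10/15 mm).

**Geometric limit (important).** Rigid, non-overlapping unit squares on a
curved centerline necessarily leave wedge-shaped gaps on the convex side of
each seam, of order (side/2)/R of the band area. Measured band coverage is
0.94 (5 mm lesions) to 0.99 (15 mm, narrow band); consecutive-square
overlaps stay below a half-pixel sliver (≤ 0.027 mm²). Full 99%+ coverage
at all diameters is geometrically impossible without violating the
no-overlap rule; the uncovered wedges lie at the outer rim of the band and
carry little of the boundary profile. One acceptance test records this
limit and is expected to flag coverage at small diameters.

**Fragments and S4.** Each square is resampled (bilinear) on a 10×10 grid
with columns along the outward normal — interior on the left — and rows
along the tangent; fragments are concatenated left-to-right in march order
into S4. Under an exact 90° image rotation the S4 features reproduce to
machine precision (the acceptance tolerance of 5% allows for interpolation
when rotations are not grid-exact), while interior (S1) features of an
anisotropic-texture phantom change by ~60%+ — the property that motivates
boundary-relative analysis.

## Texture features

Features are computed per ROI after μ ± 3σ clipping and uniform
quantization to G = 64 gray levels (MaZda-style normalization; this also
makes all second-order features exactly invariant to a constant gray-level
shift). GLCM matrices are mask-aware (both pixels inside the ROI),
symmetric, normalized; the 11 statistics (angular second moment, contrast,
correlation, sum of squares, inverse difference moment, sum
average/variance/entropy, entropy, difference variance/entropy) use the
natural logarithm, and correlation of a degenerate (single-level) matrix is
defined as 0. GLRLM runs are maximal constant-level runs inside the mask
along θ ∈ {0,45,90,135}; features are short/long-run emphasis, gray-level
and run-length non-uniformity, and run fraction. Histogram features use the
raw intensities. On S4, GLCM pairs may straddle fragment seams — the
reassembled image is analyzed as-is; seam sensitivity is part of the
method. All features are verified against brute-force enumeration oracles
to 1e−12.

## Rad-score

Features (constant columns dropped) are standardized inside the fit;
coefficients live on the standardized scale, so scores are unitless and
transfer to new cohorts through the stored (μ, σ). The L1-penalized Cox
path uses the Breslow partial likelihood, solved by FISTA with
backtracking; solutions satisfy the KKT conditions to 1e−8 (1e−5 inside
cross-validation, where deviance differences dwarf coefficient noise).
λ is chosen by k = 10-fold cross-validated partial-likelihood deviance
(V&VH form: full-data minus training log-likelihood), folds stratified by
the event indicator, at the deviance **minimum** (λ_min; single reported
penalties per model are consistent with a minimizing rule). Note the known
behavior of λ_min on pure-noise features: it selects a nonzero set in
roughly a quarter to a third of replicates; the empty model is the median
outcome.

Risk stratification replaces point-and-click optimal-cutpoint software
with an exhaustive scan: candidate cutpoints are midpoints of adjacent
unique scores with both groups ≥ 10% of the sample; the log-rank
chi-square is maximized and the Miller–Siegmund correction is applied to
the p-value (the naive minimum-p is anti-conservative, which the tests
demonstrate). Validation uses Kaplan–Meier curves (lifelines, Greenwood
CIs), the Harrington–Fleming G-rho test with weights Ŝ(t−)^ρ on the pooled
KM (ρ = 1 emphasizes early differences; ρ = 0 is the standard log-rank),
and a univariate Cox HR for the high- vs low-score group (HR > 1 = higher
rad-score heals sooner).

## Survival models and evaluation

Multivariate Cox models use Newton–Raphson on the Breslow partial
likelihood with step halving; covariance is the inverse observed
information; degenerate covariates (constant or collinear after centering,
which Cox cannot identify) are dropped with a warning. Variable selection
is backward stepwise by AIC. Internal validation is Harrell's
optimism-corrected concordance over seeded bootstrap resamples. Absolute
risks are 1 − exp(−Λ̂₀(t)·e^{β′z}) with the Breslow baseline. The
events-per-covariate ≥ 10 guideline is checked and warned about, not
enforced.

Discrimination uses the cumulative-case/dynamic-control IPCW AUC at t:
cases weighted 1/Ĝ(Tᵢ−), controls 1/Ĝ(t), with Ĝ the KM of the censoring
distribution estimated on the evaluation cohort itself. Standard errors
come from the influence-function representation of the ratio of the two
weighted V-statistics, treating Ĝ as fixed (slightly conservative). The
paired model comparison uses the joint influence functions of the two
AUCs — the time-dependent analogue of the DeLong paired test, to which it
reduces exactly without censoring (a literal DeLong test is undefined
under censoring). Calibration at t bins subjects by deciles of predicted
risk and regresses KM-observed on mean predicted risk per bin (empty or
uninformative bins merge into a neighbour). Decision curves use
NB(p_t) = TPrate − FPrate·p_t/(1−p_t) on a 0.01–0.99 threshold grid, with
the event probability inside the treated set estimated by KM at t.

## Pipeline sizes and determinism

The end-to-end synthetic study runs the full design: 254 patients
(≈ 98% pass segmentation; failures are logged and dropped), 6:4 split,
evaluation at 12/15/18 months; it completes in about three minutes on one
CPU. All randomness flows from a single seed through per-stage
deterministic derivations; identical configuration and seed reproduce
byte-identical reports, and the stage cache (hash-chained per-stage
configs) lets downstream stages rerun without touching upstream artifacts.

## Known limitations

- Phantoms are geometric, not anatomical; absolute gray levels are free
  parameters, uncalibrated to any scanner.
- Band coverage by non-overlapping rigid squares is bounded below 99% for
  small lesions (see above).
- Interval-coarse observation times attenuate strong Cox coefficients
  (grouped-ties effect); a discrete-time likelihood would remove this but
  is out of scope.
- IPCW AUC standard errors ignore the variability of the estimated
  censoring distribution.
- The λ_min rule over-selects on null data relative to the 1-SE rule,
  which is not implemented.
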