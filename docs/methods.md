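# Methods

This note documents the models, numerical choices and known limitations of
`bivatlas`, in the order the pipeline runs.

## Geometry and volumetrics

All coordinates are in mm; volumes in ml, mass in g, BSA in m².  A closed
labelled triangle mesh per subject carries four vertex tags (LV endo, LV
epi, RV free wall, RV septum); the two RV tags together bound one cavity.
Volumes are computed as signed tetrahedra about the origin,
V = 1/6 Σ v₁·(v₂×v₃), which is exact for any watertight, consistently
oriented polyhedron and rigid-invariant to round-off.  Validation checks
that every edge of a chamber is shared by exactly two faces, that no
triangle has (near-)zero area and that the signed volume is positive
(outward orientation).

LV mass uses the epicardial-minus-endocardial shell at ED times a
myocardial density of 1.05 g/ml (the conventional CMR constant; it is a
parameter of `compute_volumetrics`).  Mass-to-volume ratios divide this
single mass by the phase cavity volume.  BSA is consumed as a cohort-table
column; a Mosteller fallback `mosteller_bsa(height_cm, weight_kg)` is
provided when only height/weight are known.  Real chamber models include
papillary muscles and trabeculae in the blood pool; the synthetic surfaces
are smooth, so this is a semantic note, not a computation.

## RV parcellation

Every RV vertex goes to the region of its Euclidean-nearest landmark
(tricuspid valve centroid → inlet, pulmonary valve centroid → outlet, RV
apex → apical), with the deterministic tie priority inlet > outlet >
apical.  The assignment is made at ED and propagated to ES: point
correspondence makes this well defined, and reassigning at ES would compare
different material regions across phases.  Faces inherit the majority
vertex region (three-way tie → same priority).  Regional volumes are sums
of signed tetrahedra about a fixed origin (the RV ED vertex centroid); any
fixed origin gives the same exact decomposition of the total volume — the
non-closed region boundaries contribute equal and opposite internal
tetrahedra — so inlet+outlet+apical equals the total RV volume to machine
precision, and regional SV/EF follow by definition.

A note on a tempting but false monotonicity: moving the apex landmark
toward the tricuspid centroid *grows* the apical cell (the apex/tv bisector
sweeps toward tv), so only the pairwise apex-vs-tv partition is monotone.
The tests assert the correct property.

## Shape atlas

Generalized Procrustes analysis aligns the ED point sets rigidly (rotation
+ translation; **no scaling**, because size is part of the remodelling
signal): initialize the reference with subject 1, alternate
Kabsch alignment of every subject to the reference with re-averaging, stop
when the mean moves < 1e-6 mm RMS (cap 100 iterations).  Proper rotations
are enforced by the SVD sign correction.  Each subject's ED transform is
applied unchanged to its ES shape, preserving the ED→ES deformation in the
atlas frame.  The global atlas frame is arbitrary (it inherits the
initial reference's pose); all reported statistics — eigenvalues, explained
fractions, z-scores — are invariant to it, and comparisons against
template-frame quantities in the tests first quotient the frame with a
single Kabsch fit of the template to the atlas mean.

PCA runs on the mean-centred concatenated ED+ES coordinate vectors
(length 6V).  Eigenvalues are singular values squared over (n−1); modes
with explained fraction > 1 % (configurable) are retained; mode signs are
fixed by making each mode's largest-magnitude coordinate positive.
z-scores divide centred projections by √eigenvalue, so training scores
have mean 0, SD 1 (ddof = 1) exactly.  Projection of a new subject first
rigidly aligns its ED block to the atlas mean ED block.  Shape synthesis
returns mean + m·Σ d_k √λ_k φ_k split back into ED/ES meshes on the
template topology, with landmarks re-derived from recorded template vertex
indices.  No per-coordinate variance normalization is applied before PCA
(raw mm covariance), the standard choice for point-distribution models;
standardization in this package applies to discriminant features, not PCA
input.

## Calipers

The anatomical frame per phase: LV long axis = mitral centroid → LV apex
(the analogous tricuspid → RV apex axis serves the RV; a published figure
caption describing the LV height as ending at the *RV* apex is treated as
a typo); septal normal = smallest right singular vector of the centred
septal vertices, oriented LV→RV; AP axis = septal normal × LV long axis.
Widths at fraction r of the height measured from the apex (r = 1/4 apical,
3/4 basal) are extents of the plane-mesh intersection projected on the
stated axis — a rotation-invariant generalization of point-to-point
calliper distances.  Sphericity = SL width / height; eccentricity =
AP width / SL width; the RV mid-level free-wall extent parallel to the
septum uses free-wall faces only.  Displacements are ED→ES landmark
motions and are only comparable across subjects in the common atlas frame;
the pipeline computes calipers after alignment.  Mode association fits OLS
of each *standardized* calliper measure on all retained z-scores; with
standardized responses the coefficient of a mode that linearly drives a
measure is its correlation share (≈1 for a pure dependence), and |coef|
ranks the calipers a mode controls.

## Risk modelling

Features are z-scored per analysis; missing values are handled
complete-case per analysis.  The Fisher discriminant is closed-form,
w ∝ S_pooled⁻¹(μ₁−μ₀) with the intercept centring the score at the pooled
mean midpoint and the sign fixed so higher score = event class; an exactly
singular pooled covariance falls back to a ridge inverse
(λ = 1e-6·trace/d, or 1e-6 if the trace vanishes) with a logged warning.
Feature selection is an exhaustive search over subsets of size 1–3 scored
by mean stratified 4-fold CV AUC (folds seeded; reduced with a warning if
the event class is smaller than the fold count; degenerate folds that
cannot be fitted or scored are skipped).  At ≤ C(21,3) ≈ 1.6k candidate
fits the exhaustive search is cheap, reproducible and never worse than a
greedy heuristic.  Ties prefer smaller subsets, then lexicographic feature
order.

Biomarker evaluation: AUC is the Mann-Whitney statistic (ties ½); the
cut-off maximizes Youden's J over observed score values (positive if
score ≥ threshold, ties to the lower threshold); the odds ratio is exp(β)
from a univariable logistic fit of outcome on the score *as given* with a
Wald 95 % CI — the pipeline passes z-scored discriminant scores, making it
an OR per SD, while a binary 0/1 score reproduces the 2×2 cross-product
ratio exactly.  The staged analysis runs the selection on the
conventional, regional and shape pools, then on the union of the three
winning subsets.  Group tables report mean ± SD with Welch's t by default
and median (IQR) with Mood's median test for features flagged non-normal;
no multiple-testing correction is applied, matching common practice for
descriptive cohort tables.  The PRVI surrogate analysis is linear
regression (PRVI is continuous): univariable R²/p against the risk score,
RVEF and APEF; forward-selected regression on mode z-scores capped at
three modes; and an AUC comparison of the composite predictors with and
without PRVI.

## Synthetic cohort generator

The generator defines the study conditions under which everything above is
tested.  The template is built parametrically at n_theta × n_rings
resolution (default 24 × 12, ≈ 900 vertices): LV endo/epi are truncated
prolate spheroids (semi-axes 28/26/48 and 34.5/32.5/55 mm, basal cap at
0.55·c) and the RV is a loft of D-shaped sections — half-ellipse free wall
(40 mm septal offset, 54 mm lateral, 52 mm long) against a planar septum —
with a two-ring basal cap carrying the tricuspid and pulmonary landmarks.
Template volumes: LVEDV ≈ 125 ml, RVEDV ≈ 202 ml, LVM ≈ 100 g, i.e. a
volume-loaded RV typical of the target population.

Shape variation: three orthonormal displacement fields (LV basal dilation,
RV apical dilation with basal constriction, global size), each corrected
within its own vertex support to zero net translation and rotational
moment so that latent variation carries no pose component (pose is added
separately and removed by GPA), and the RV field tapered to zero at the
basal cap so landmarks — which define the contraction frame — are not
displaced by it.  Latent factors are drawn from a dedicated cohort-level
stream and whitened so each cohort realizes the prescribed diagonal latent
covariance exactly; this trades the ability to extend a cohort without
reshuffling (all other per-subject draws use counter-keyed substreams) for
exact realization of the specified population variances, which is what a
controlled synthetic study needs.  Default latent SDs (35, 25, 15) give
millimetre-scale per-vertex displacements; iid vertex noise (0.8 mm)
models correspondence error.

Contraction: ES = ED scaled radially toward each chamber's long axis by s
and longitudinally toward the base by l = 0.85 (15 % longitudinal
shortening).  Because this is affine per chamber, the volume ratio is
exactly s²l, so a per-subject EF target (default 0.52 ± 0.08, clipped to
[0.05, 0.85]) maps to s = √((1−EF)/l) without iteration.  The LV
epicardium contracts with the s that conserves shell volume, i.e. mass.
RV regions get multipliers on s (defaults 1.14/1.22/1.14 inlet/outlet/
apical, jitter 0.04/0.04/0.08), reproducing the clinical ordering
RVEF < LVEF with the outlet weakest; regional EF_r = 1 − (1−EF)·m_r² holds
up to boundary effects.  A spec whose nominal contraction would give
ESV ≥ EDV is rejected.

Outcome: Bernoulli with logit = b₀ + 0.9·(λ₁/σ₁) + 0.9·z_apical (reduced
apical contraction and LV basal dilation raise risk, mirroring the
high-risk phenotype); b₀ is solved by Gauss–Hermite quadrature so the
expected event rate equals the target (default 16/192).  PRVI =
25 + 10·(λ₂/σ₂) + N(0, 10) ml/m², clipped at 0 — the slope/noise ratio
fixes the population R² at 0.50 against the RV-dilation latent.
Pose: random rotation (SD 8°) and translation (SD 10 mm) applied
identically to both phases and landmarks.  Clinical covariates are drawn
from published cohort moments (BSA 1.59 ± 0.30 m², QRS 147 ± 23 ms,
SBP 118 ± 14, DBP 64 ± 10).

What the generator does **not** emulate: wall-thickness pathology,
trabeculation, non-rigid inter-subject topology differences, segmentation
bias, or any coupling between covariates (QRS, blood pressure) and shape.
Passing tests therefore demonstrate correctness of the *computational*
chain and recoverability of known structure — not clinical performance on
real CMR data; the published cohort's headline numbers (15 modes / 85 %
variance, AUC ladder 0.72/0.73/0.66→0.77, OR 2.06, cut-off −0.18) are
properties of unavailable patient data and are not reproduction targets.

## Problem sizes and determinism

Default analyses run at n = 192 subjects, ≈ 900 vertices/model (shape
vectors of ≈ 5 400 coordinates); the driver-recovery experiment uses 400
subjects at reduced mesh resolution (16 × 8) across replicate cohorts —
sizes chosen so the entire test suite and the acceptance script each
complete in minutes on a single CPU while keeping every statistical effect
at its intended magnitude.  One top-level seed drives everything:
per-subject substreams are spawned by counter, the latent block has its
own stream, and CV folds are seeded, so cohorts, pipelines and manifests
are bit-reproducible for a fixed seed (the pipeline manifest records
SHA-256 checksums of all text outputs).

## Known limitations

* The D-shaped RV and ellipsoidal LV are idealized; absolute calliper and
  volume values are plausible rather than anatomically exact.
* Exhaustive subset selection is the declared substitute for the original
  unspecified "automatic feature selection algorithm"; selected-model CV
  AUCs carry the usual post-selection optimism (demonstrated in the test
  suite) and should be read as model-comparison scores, not unbiased
  performance estimates.
* Whether the published composite AUC was cross-validated or in-sample is
  ambiguous; both are reported.
* Regional EF control is exact only for uniform multipliers; with regional
  variation, faces near region boundaries mix contraction factors.
* `synthesize` returns shapes on the template topology of the first
  aligned subject; landmark indices must be present (they are, for
  generated cohorts) or are approximated by nearest vertices.
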