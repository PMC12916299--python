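# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `ctenrich`.

## Surfaces and masks

All maps live on a unit icosphere (subdivided icosahedron, `10·4^s + 2`
vertices; default s = 3, 642 vertices). A per-vertex boolean validity mask
emulates the medial-wall exclusion of real cortical surfaces: invalid
vertices are excluded from smoothing averages, correlations, and cluster
searches, and invalidity propagates through rotation resampling from the
source vertex. Vertex adjacency is edge-based.

**Smoothing.** `smooth_map` iterates
`x_i += (w / d_max) · Σ_{j∈N(i)} (x_j − x_i)` over valid vertices. At a
regular (degree-`d_max`) vertex with `w = 1` this is exactly "replace by the
mean of the neighbors". The symmetric, degree-max normalization was chosen
deliberately instead of per-vertex row normalization: an icosphere always
carries 12 degree-5 vertices, and row-normalized averaging is then not
mass-conserving (the mean drifts toward the stationary, degree-weighted
average by ~1e-3·SD over tens of iterations). The symmetric operator
conserves the valid-vertex mean to machine precision, which the test suite
asserts. Stability holds for `w ∈ (0, 1]` since the iteration matrix
`I + (w/d_max)(A − D)` has spectrum in [−1, 1].

**Cluster extraction.** Connected components of a masked vertex set under
edge adjacency; components below `min_size` (default 15 vertices, the
conventional display threshold for such intersection figures) are dropped
and survivors are labeled 1..K by decreasing size, ties broken by smallest
vertex index.

**I/O.** Per-vertex maps read/write as one-column CSV (exact round-trip) or
FreeSurfer new-style binary curv (float32, via nibabel); meshes export as
ASCII OFF/PLY via trimesh.

## Synthetic data-generating process

The generator draws, per master seed:

- **Feature maps**: K = 16 maps (named after the PET-derived features the
  group screen emulates: SERT, HT1a, AChN, Glc, …), each smoothed white
  noise (4 diffusion iterations, weight 0.9), z-scored over valid vertices.
  With these settings the spin-null SD of the correlation between two
  independent maps is ≈ 0.15 on the 642-vertex sphere — the same order as
  the nulls implied by real fsaverage-resolution analyses, where observed
  |r| ≈ 0.3–0.4 is detectable.
  By default the maps are then **decorrelated** (QR over valid vertices,
  re-z-scored, sign-aligned with the raw draw). Undecorrelated smooth maps
  on a coarse sphere share chance correlations of ≈ 0.14 SD, so a deficit
  injected along one feature would be *genuinely* aligned with several
  others and per-feature ground truth would not be identifiable.
  `orthogonalize=False` restores the correlated regime (closer to real PET
  atlases, whose features are mutually correlated).
- **CT cohort**: for subject i at vertex v,

  `CT_iv = b0_v + b1·age_i + 1[AN]_i·δ_v + Σ_k a_ik F_kv + η_iv + u_i`

  with `δ_v = δ̄ + Σ_k γ_k F_kv + remainder_v`. Defaults (all in cm):
  baseline level b0 = 2.5 with smooth spatial variation SD 0.15; age slope
  b1 = −0.01/year; uniform deficit δ̄ = −0.10; alignment γ = {SERT +0.05,
  HT1a +0.042, AChN −0.047, Glc −0.053}; smooth deficit remainder SD 0.03;
  subject loadings a_ik ~ N(0, τ²), τ = 0.02; smooth per-subject noise
  η SD 0.02; global per-subject offset u_i SD 0.05. Group sizes 114/114,
  ages uniform on 12–29 years for both groups (age *matching* is emulated
  at the distribution level only — the estimators never use pairing).
- **Choice of τ and η.** These are free parameters of the synthetic world;
  they were fixed once so that ground-truth recovery is well-powered and
  clean. Two considerations drove 0.02: (i) the speCT estimator's accuracy
  depends only on the *ratio* of loading to noise scales, and (ii) the group
  contrast's sampling noise contains feature-shaped components of SD
  τ·√(2/n); at τ = 0.05 those reach ≈ 0.11 in correlation units and bleed
  genuine alignment into unrelated features, while at τ = 0.02 they are
  negligible against the ≈ 0.15 spin null. The global offset u_i exists
  because the z-scored feature and noise maps are exactly mean-zero over
  vertices; without it, per-subject global mean CT would be an exact linear
  function of intercept and age and the global-CT control models would be
  singular by construction. Real cohorts vary in overall thickness.
- **Clinical table**: baseline BMI-SDS for AN ~ N(−3.20, 1.27²) truncated
  above 0, HC ~ N(−0.085, 0.67²); restrictive/binge-purge subtype,
  comorbidity and antidepressant flags drawn at 12/114, 18/114 and 4/114.
  Symptom scales are drawn around group means (BDI-II 22.76/5.51,
  EDI subscales at the corresponding published-style moments) with the
  patient-level signal carried by standardized loadings: BDI-II is linked to
  the HT1a loading (ρ = −0.35) and the Glc loading (+0.32), body
  dissatisfaction to SERT (−0.30). Link strengths were set by a power
  analysis: after BH over four features at n = 114, ρ = 0.35 gives ≈ 87%
  detection versus ≈ 75% at 0.30; the observed partial correlations in demo
  runs land in the 0.2–0.3 range after estimation attenuation.
- **Outcome**: `ΔBMI-SDS = d0 + d1·age + d2·BMI₀ + d3·z + d4·BMI₀·z + ε`,
  with z the standardized SERT loading, defaults d = (1.85, 0, 0.25, −0.45,
  −0.15), ε SD 0.5, and 30-day follow-up masked missing at rate 21/114
  (AN only; controls have no follow-up). d3/d4 were chosen so that the
  conditional slope θ(w) = d3 + d4·w crosses zero near the patient mean
  baseline (w ≈ −3), reproducing the qualitative two-sided Johnson–Neyman
  geometry: positive slope at very low baseline weight, negative near
  normal weight.

Determinism: every stochastic stage derives a named sub-seed from the
master seed by hashing `"{seed}:{stage}"` (SHA-256, reduced below 2³¹), so
adding a stage never perturbs the randomness of the others, and a saved
`RunConfig` reproduces a run byte-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: scanner/motion/segmentation noise, hemispheric
structure (one sphere, no bilateral mirroring), surface-to-surface template
resampling, age-by-group interactions, non-Gaussian symptom distributions,
informative (non-random) loss to follow-up, and mutually correlated feature
maps (unless orthogonalization is disabled). Recovery results quantify
estimator correctness under the stated model, not robustness to these
realities.

## Statistical machinery

**Vertex-wise GLM.** Shared-design OLS across vertices (one `lstsq` for the
whole surface); df = n − 3; the group SE uses the classical per-vertex
residual variance. Rank-deficient designs (constant age, single group) are
rejected with a design-level error, since the cause is vertex-independent.
Residual maps default to the full-model residual e; the "age-only" mode
(deviation from age-predicted CT, refit without the group column) is exposed
because both readings of "deviation from age-predicted CT" are defensible —
the full-model residual is the default because it is the term the group
model actually names.

**Spin test.** The *feature* (reference) map is rotated, the empirical map
stays fixed. Rotations are uniform (quaternion method); the rotated value at
vertex v is the original value at the nearest original vertex to Rᵀv, so one
nearest-neighbor index array per rotation serves every map on the mesh, and
all features in one enrichment run share one rotation set. Vertices whose
rotated source is invalid are dropped pairwise for that rotation. The
two-sided p-value includes the +1 small-sample correction, so p ∈ (0, 1] and
the test is never anticonservative by construction; type-I calibration at
α = 0.05 is verified by simulation. No variogram-matching or generative
surrogates, and no parcel-level analysis.

**Adjusted Spearman.** Rank (average ranks for ties), residualize the x- and
y-ranks on covariate ranks by OLS with intercept, correlate the residuals;
p from the t approximation with df = n − 2 − #covariates; listwise deletion
per cell. With zero covariates this reduces exactly to tie-corrected
Spearman. BH-FDR is step-up (via statsmodels, cross-checked against a brute
force implementation in the tests). The symptom-grid FDR family defaults to
per-symptom-across-features (m = number of gated features): that family
exactly reproduces the worked adjusted p-values (0.012/0.018 → 0.036 with
m = 4; 0.043 → 0.172), whereas a per-feature family over five symptoms does
not; the alternative family remains available as an option.

**Outcome model and HC3.** OLS point estimates with
`(XᵀX)⁻¹ Xᵀ diag(e_i²/(1−h_ii)²) X (XᵀX)⁻¹` covariance, exposed as a
standalone function; leverages of 1 raise. speCT enters in raw correlation
units (bounded [−1, 1], no standardization), age uncentered. Control models:
alt1 replaces speCT with global CT (+ its baseline interaction); alt2 adds
global CT to the main model; alt3 adds global CT × speCT; alt4 additionally
global CT × baseline.

**Johnson–Neyman.** Boundaries are the real roots of the quadratic
`(β₄² − t²V₄₄)w² + 2(β₃β₄ − t²V₃₄)w + (β₃² − t²V₃₃) = 0` with t the
two-sided critical value from the t distribution on n − p df (conventional
for HC3 in small samples). Segments are classified by testing an interior
point; regions are reported over the whole real line with an `extrapolated`
flag for regions outside the observed moderator range. Degenerate cases
(β₄ ≈ 0 with negligible V₄₄) fall back to the constant-slope test; a
negative discriminant yields the whole line or the empty set according to
the leading coefficient. The closed form is verified against a 1e-4-step
grid scan of the conditional-slope t statistic.

**Gating and replication.** Downstream stages consume only features with
group-level q < α (configurable to "all"). The replication runner executes a
second cohort against the *same* atlas (as when two sites compare against
one set of reference annotations) and tabulates per-feature sign agreement
and joint significance.

## Numerical notes and edge cases

- Correlations are clipped to [−1, 1] against rounding; constant inputs
  raise explicit undefined-correlation errors rather than returning NaN; a
  constant subject deviation map yields missing scores plus a warning.
- Nearest-vertex rotation resampling is not a bijection: for a generic
  rotation ~7% of vertices on the 642-sphere fail the R-then-Rᵀ round-trip
  (Voronoi-boundary effects). Exact icosahedral symmetry rotations permute
  the vertices exactly and round-trip 100%; both behaviors are pinned in
  tests.
- Report CSVs are written with fixed `%.12g` formatting so byte-level
  determinism is well-defined across runs.
- Demo problem sizes (642 vertices, 16 features, 114 + 114 subjects,
  200–1000 rotations; 50–500 replicates in the simulation studies) were
  chosen so the whole suite and the acceptance script each run in about a
  minute on one CPU while every recovery/calibration check remains
  well-powered.

## Limitations

Single-hemisphere spherical world; nearest-vertex (not barycentric)
resampling; no mixed-effects or site covariates in the GLM; no bootstrap
intervals for the rank correlations; the 60-day endpoint present in the
clinical table schema is not modeled. The speCT regression treats the
estimated score as observed — errors-in-variables attenuation is visible in
the demo (moderation estimates shrink relative to the generating values in
standardized units), exactly as it would be in the real analysis.
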