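# Methods

## Scope

`ovoflux` reimplements an integrated workflow for studying how avian
eggshell gas exchange varies along elevational gradients: estimating
water-vapor conductance from desiccator mass-loss experiments,
quantifying eggshell pore structure from SEM images, and testing
trait–elevation relationships with phylogenetic comparative methods.
All inputs can be generated synthetically with known ground truth, so
every stage is testable end to end without field data.

## Water-vapor conductance

An egg in a desiccator at ~0% relative humidity loses water by
diffusion through shell pores. The flux is proportional to the
water-vapor pressure difference ΔP across the shell, giving the
conductance

    G_H2O = M_H2O / ΔP_H2O    [mg·day⁻¹·torr⁻¹]

where M_H2O is the magnitude of the slope of an OLS regression of egg
mass (mg) on day. ΔP equals the saturation vapor pressure at the egg's
temperature, computed from the Buck equation (hPa, converted at
1 torr = 1.333224 hPa); at 25 °C this is 23.766 torr, matching the
23.77-torr standard value used for cross-study comparability. Both ΔP
modes are provided — per-egg chamber temperature (default) and a fixed
`--standard-deltap 23.77` override — because published conductance
values conventionally standardize to 25 °C.

Quality control drops eggs with regression R² ≤ 0.8, non-negative mass
slope, or a suspected shell fracture. The fracture proxy flags any
single-day mass drop exceeding 5× the *median* single-day drop. The
median, not the fitted slope, is the reference: a fracture's step
change inflates the fitted slope enough to mask itself under a
slope-relative rule. The factor is configurable.

Species means use at most the first three QC-passing eggs in stable
input order; species aggregation happens before residualization so
regressions are at the species level. Egg volume uses Hoyt's empirical
formula V = 0.51·L·W² (cm³). Size correction regresses log conductance
on log egg mass (structural traits on log volume) and carries residuals
forward when the allometric slope is significant at 0.05; otherwise the
fit is flagged and absolute values are used. Elevation bands are
lowland 340–850 m, mid 1200–2000 m, highland 2500–3000 m; values in the
gaps go to the nearest band boundary with a logged warning.

## Pore detection

Surface SEM fields show pores as holes in a bright shell matrix:
functional pores are dark, occluded or superficial holes lighter gray.
The image is first contrast-normalized by a robust linear rescale (1st
percentile → 0, 99th percentile → 1, clipped), making detection
invariant to affine brightness/contrast changes. Candidate pixels lie
below the occluded threshold (0.5 normalized); connected components
(8-connectivity) smaller than 0.05 μm² or touching the border are
discarded (partial pores bias area estimates); surviving components are
functional if their mean interior intensity is ≤ 0.2, occluded if
≤ 0.5. Areas come from pixel counts × scale²; density is functional
pores per mm² of field.

Two numerical safeguards matter. First, the percentile normalization
needs genuinely dark content covering more than ~1% of pixels to anchor
its low end; a pore-free field would otherwise have its background
noise stretched over [0, 1]. Candidates must therefore also lie at
least 6 robust SDs (1.4826·MAD) below the image median — an
affine-invariant gate that eliminates speckle detections in blank
fields while leaving true pores untouched. Second, thresholds are fixed
defaults on normalized intensity because the functional/occluded
dichotomy is tonal; an Otsu mode is available for real images whose
histograms are less controlled.

The scale (μm/px) must always be supplied; it is never guessed from
image content. Shell thickness is measured manually upstream; the
package only averages replicate thickness values and feeds the triples
into the repeatability machinery.

## Trait evolution models

A rooted ultrametric phylogeny induces the Brownian covariance
C_ij = depth of MRCA(i, j). The other models are covariance transforms:

- **Pagel's λ** multiplies off-diagonal entries by λ ∈ [0, 1].
- **OU** (stationary form, ultrametric trees only):
  V_ij = exp(−2α(T − s_ij))·(1 − exp(−2α·s_ij))/(2α), with T the tree
  height and s_ij the MRCA depth. Non-ultrametric input is rejected
  rather than silently approximated.
- **EB** remaps every node depth d to (e^{ad} − 1)/a, a ≤ 0, applied
  elementwise to the MRCA-depth matrix.

For fixed shape parameter the root state ẑ₀ (GLS mean) and rate σ̂²
(ML, matching the common fitContinuous default) have closed forms, so
each fit is a bounded one-dimensional search: a 20-point grid pre-scan
followed by bounded Brent refinement (tolerance 1e-6) between the
bracketing grid points. Search ranges on a unit-height tree: λ ∈ [0,1],
ln α ∈ [ln 1e-4, ln 1e2], a ∈ [−10, 0]. Trees are rescaled to unit
height internally (conditions the α search) and σ², α, a are
back-transformed. Likelihood evaluations use a Cholesky factorization;
near-singular covariances get a single 1e-10·mean(diag) ridge with a
logged warning. Models are ranked by AICc (k = 2 for BM, 3 otherwise,
error variance counted within σ²) with Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).

Phylogenetic signal is the λ estimate; a likelihood-ratio test against
λ = 0 refers 2(ℓ(λ̂) − ℓ(0)) to χ²₁. The λ-LRT convention (vs. λ = 0
rather than λ = 1) is this package's choice and measures departure from
star-like independence. On a star tree λ is unidentifiable and the
result carries a degeneracy flag. The λ likelihood surface was
validated against an independent reference implementation on fixed
datasets (boundary and interior optima; log-likelihood agreement to 10
digits).

## Comparative statistics

**PGLS.** β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y via Cholesky whitening; SEs from
σ̂²(XᵀC⁻¹X)⁻¹ with σ̂² = eᵀC⁻¹e/(n−p); t tests with n−p df; R² = 1 −
eᵀC⁻¹e / e₀ᵀC⁻¹e₀ against the GLS intercept-only null. The covariance
is the best-AICc evolution model re-selected per dataset rather than
hard-coded. With C = I the fit reduces exactly to OLS.

**Phylogenetic ANOVA.** The observed one-way F is compared against a
null distribution from Brownian simulations on the tree (rate = ML
Brownian rate of the data; F is scale-invariant so the rate only fixes
units), group labels held fixed; p = (1 + #{F_null ≥ F_obs})/(nsim+1),
never exactly zero. Zero within-group variance yields an infinite F,
reported as p = 1/(nsim+1) with a degeneracy warning. The variance-
heterogeneity test applies the same simulation scheme to a Levene-type
F on absolute deviations from group medians (the underlying study names
no specific test; Levene-on-residuals is this package's choice).

**Model selection over predictor sets** fits Gaussian linear models
(treatment coding, alphabetical reference level, logged) and ranks by
AICc with the error variance counted as a parameter.

**Repeatability.** For grouped replicates, R = (MSB − MSW)/(MSB +
(k−1)·MSW) truncated to [0, 1] (k = effective replicate count for
unbalanced designs), bootstrap CI by resampling groups with replacement
(default 1000 draws), and an LRT of the between-group variance against
zero using the ½χ²₀ + ½χ²₁ boundary mixture with closed-form balanced
ML estimates. p = 1 exactly at LRT = 0 (the all-noise case), matching
how mixed-model repeatability packages report a zero variance
component.

**Conventions.** Raw per-family p-values are reported (an optional Holm
column is available); simulation p-values use the +1 convention; the
residual-then-test workflow (regress, take residuals, test on
residuals) is the default even though a joint model would be cleaner,
because it matches the workflow the pipeline reproduces.

## Synthetic data

The generator defines the study conditions:

- **Tree**: pure-birth (Yule), rescaled to height 1; ultrametric by
  construction.
- **Elevations**: band label sampled uniformly, then uniform within the
  band — stations cluster in discrete belts with gaps, as in the field
  design. An optional Brownian-threshold mode produces phylogenetically
  clumped elevations for probing confounded designs.
- **Traits**: one draw from N(z₀·1 + β·elev_km, σ²·C_model), sharing
  the covariance code path with the fitting side. Defaults: OU α = 2,
  σ² = 1, β = −0.5 per km on log conductance — an elevational decline
  strong enough to be unambiguous at n ≈ 40–60 species, comparable to
  the clear decline the workflow is designed to detect.
- **Mass series**: mass(d) = M0 − G·ΔP·d/1000 + ε, ε ~ N(0, 0.005² g²)
  (half the 0.01 g resolution of a field balance), 8 days, ΔP 23.77
  torr; optional step drop for fracture-QC testing.
- **SEM fields**: 128 px at 0.1 μm/px with speckled bright background
  (mean 0.8, sd 0.05), dark disks at 0.05 and gray disks at 0.35
  intensity, radii 4–6 px, rejection-sampled placement with minimum
  rim separation. The field size and radii guarantee that pore pixels
  exceed the 1% anchor required by the percentile normalization.

Every generator is a pure function of (parameters, seed) and each
bundle ships a ground-truth sidecar; recovery tests read truth only
from the sidecar.

What the generator does *not* emulate: temporal drift in conductance,
non-disk pore shapes, SEM charging artifacts and cuticle texture,
measurement error in elevations, unbalanced replicate designs, and
phylogenetic signal in egg size. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every field complication.

## Problem sizes in the shipped checks

The calibration experiments use 100-tip trees with 200 replicates for
parameter recovery, 500–1000 outer replicates × 1000 simulations for
ANOVA size, 200 groups × 3 replicates for ICC recovery, 100 seeded
fields for pore detection, and 200 null + 100 effect pipeline runs at
40 species. These sizes put Monte-Carlo error comfortably inside the
tolerances being checked.

## Known limitations

- OU fitting assumes the stationary covariance on ultrametric trees;
  fossil (non-ultrametric) data would need the conditional OU form.
- The ICC machinery is the one-way random-effects model only.
- Polytomies are retained, not resolved.
- Pore areas come from pixel counts; no sub-pixel contour refinement,
  so per-pore area error is bounded by discretization (~5% at radius
  4 px).
- Within-species analyses are ordinary regressions; no spatial or
  repeated-measures structure.
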