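# Methods

This note records the models, numerical choices and deliberate design
decisions behind `jdmorph`, and what the synthetic validation does and
does not establish about real data.

## Phantom geometry and ground-truth deformations

The phantom is an ellipsoid in normalized coordinates y = (x − c)/s
(semiaxes s ≈ 84/88/80% of the half grid extent). Radial shells define
tissue: a CSF ventricle (ρ < 0.28), white matter, and a cortical ribbon
from ρ = 0.78 to the surface. The GM/WM boundary is modulated by
sin(k·φ)·sin²θ with k = `cortical_fold_count` (default 6) and amplitude
0.10, so alternating azimuthal sectors form gyral crowns (thin, high
ribbon) and sulcal troughs (ribbon extending deeper). With folding
disabled the two classes have identical radial extent, which is what the
fold-free regression tests check. Two spherical "subcortical" nuclei sit
in the WM shell; grids whose ribbon would be thinner than 2 voxels are
rejected (48³ at 3 mm is the default; ~44³ is the practical minimum).

Ground-truth warps are radial maps g(ρ) built per ray with g³ piecewise
linear in ρ³ and slope equal to each shell's total volume ratio
V = (1 + r/100)^Δt. Along a ray the Jacobian of ρ ↦ g(ρ) is then exactly
V inside each shell, so the stored analytic JD integrates back to the
compartment volume ratio identically; the neglected angular derivative
terms (from the fold modulation of the boundary) only touch the numeric
JD of the sampled displacement field, which the tests show agrees with
the analytic value to ≲0.2% at compartment level. Both the forward
(baseline → follow-up) displacement and its inverse (used to resample the
template into the follow-up image) are available in closed form;
displacements taper smoothly to zero outside ρ ≈ 1.05–1.5 so no content
leaves the grid. Since atrophy is modeled as geometric (compound) volume
change, a −2 %/yr compartment scanned 2 years apart has total ratio
0.98² = 0.9604, matching the geometric annualization used downstream.

Per-subject rates are drawn from group-specific bivariate normals
(GM/WM correlation 0.8) whose defaults are the published group
distributions the generator emulates: cases GM −1.55 ± 2.19, WM
−1.49 ± 2.20; controls GM −0.55 ± 1.13, WM +0.26 ± 1.11 %/yr. Sulcal
cortex in cases atrophies faster by `sulcal_excess` = 1.065; the source
study quantifies this effect only as a mixed-model interaction of order
0.001 on the JD scale, so the default was chosen to reproduce that order
of magnitude (−(−1.55)·0.065/100 ≈ 0.001) rather than a stated effect
size. The additive scanner offset on summary JD (0.012) was sized
analytically so scanner membership explains roughly 9% of summary-JD
variance, matching the variance share the study's hierarchical
partitioning attributed to scanner. Age and sex effects on atrophy
default to zero — the study found none — but are configurable slopes for
power explorations. RNG discipline: one master seed; per-subject streams
derive from CRC32 of `"{seed}:{subject_id}"`, so cohorts are reproducible
under any evaluation order.

Focal lesions (probability 41/61 among cases) are intensity-only by
default: an ~85% signal drop with a smooth rim, stamped into the template
before warping so it appears at both time points. A config switch adds a
deformation-coupled lesion (Gaussian radial contraction with closed-form
determinant composed onto the atrophy warp); keeping the default
intensity-only isolates the claim that longitudinal JD statistics are
robust to lesions.

Neuropsychological scores (Trail Making B−A, People recall, WASI
Similarities, choice reaction time; baseline and follow-up) are generated
by a Gaussian copula against each subject's summary JD: latent Pearson
r = 2·sin(πρ/6) yields the target Spearman ρ in population, and ρ = 1
degenerates to an exact monotone coupling. Marginal means/SDs and
per-cell missingness mirror the emulated cohort's assessment table.

## Registration

A symmetric stationary-velocity demons. One velocity field v is
estimated; baseline and follow-up are pulled back by exp(−v/2) and
exp(+v/2) respectively and compared at the midpoint. Exponentiation is
scaling-and-squaring (6 steps) with trilinear field composition. Updates
are Thirion-normalized SSD forces δ = (I_b − I_f)·∇Ī / (|∇Ī|² + δI²/h²),
fluid-smoothed (σ = 2 mm) before integration and diffusion-smoothed
(σ = 1.5 mm) after, over a 3-level pyramid (50/50/25 iterations).
Iterations that fail to reduce the masked mean-squared difference are
rejected and the step halved, making the per-level objective
non-increasing by construction. Updates are suppressed where the image
gradient magnitude falls below 0.03 mm⁻¹ (`gradient_floor`): flat
interiors carry no matching information, and without the floor
noise-driven drift accumulates into a spurious large-scale velocity that
leaves compartment-mean JD intact but destroys pointwise log-JD
antisymmetry under argument swap. With it, swap antisymmetry holds to
|mean log JD sum| < 0.01 and a uniform −2 %/yr deformation is recovered
to ±0.003 of JD 0.98 at the default noise level.

Conventions: the returned full warp is exp(v) with
followup(x + u(x)) ≈ baseline(x), so JD < 1 means volume loss; the JD is
evaluated on the baseline grid by central differences (one-sided at
faces) with voxel size folded in. Folding (non-positive determinants) is
reported and masked, never clamped — clamping would bias atrophy
summaries toward zero. Annualization is geometric, exp(log JD/Δt); the
linear volumetric rate (Eq-style 100·ΔV/V/Δt) agrees to first order for
|r| ≤ 2 %/yr, and both are reported by the morphometry layer. All
phantoms share one grid, so no template construction or spatial
normalization stage exists here; statistics run in the shared space.

## Voxelwise inference

Per-voxel OLS with a single group-contrast column; t maps enhanced by
TFCE, Σ_h e(h)^E·h^H·dh with E = 0.5, H = 2, 26-connectivity and
dh = max-stat/100 (the volumetric de facto standard; the source method
names TFCE without parameters). A fixed-dh override exists for
ladder-stable comparisons. Two-sided inference enhances each sign
separately and Bonferroni-corrects over the two tails. Familywise
correction uses the permutation distribution of the maximum TFCE value:
Freedman–Lane (permute residuals of the nuisance-only model, add back the
nuisance fit, refit) in sampled mode with p = (1 + #{max ≥ obs})/(m + 1);
exhaustive mode enumerates all distinct group labelings (supported for
intercept + group designs, where relabeling is exact) and returns
p = #/m. The default m = 10 000 follows the analysis description of the
emulated study (its figure legend says 5000; both are just config
values). Validation: exhaustive vs sampled agreement within binomial
bounds on a 4+4 toy, empirical FWER 0.03 over 100 null cohorts at
α = 0.05, and detection (corrected p < 0.05 in the core) of a planted 3%
regional deficit at n = 20+20.

## Cohort statistics

- Adjusted group models: OLS of summary JD on group + age + sex + ICV +
  scanner, with explicit collinearity and constant-outcome failures.
- Hierarchical partitioning: Shapley decomposition of R² over all 2^k
  predictor subsets using the subset-size weighting s!(k−s−1)!/k!, which
  equals the average over all k! orderings (verified to 1e−10 against an
  explicit-ordering oracle); ΣI = full R² identically.
- Sulcus/gyrus model: ROI mean JD ~ group + class + covariates with
  per-subject random intercept and random class slope; the group × class
  interaction is tested by a 1-df likelihood ratio between
  maximum-likelihood fits (REML log-likelihoods are not comparable across
  fixed-effects specifications). Singular random-effects covariances
  trigger a documented fallback to intercept-only random effects;
  optimizer failures fall back lbfgs → powell → cg.
- Neuropsych correlations: Spearman ρ per test × visit (baseline,
  follow-up, change = follow-up − baseline) against GM and WM summary JD,
  pairwise-complete; BH-FDR across the 12 cells separately per tissue
  (tissue is excluded from the family, mirroring the emulated analysis).
  "Change" is the simple difference — note it is *not* invariant to
  monotone transforms of the raw scores, which is why the invariance test
  transforms the JD margin instead.
- Subgroup reruns: any statistic re-executed on a predicate-filtered
  cohort (canonically lesion-free), failing loudly if a group empties.

## Power

Cohen's d uses the pooled SD with n−1 weights; its 95% CI is the normal
approximation SE = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))) and is labelled
as such (the noncentral-t interval differs in the second decimal at these
n). The n80 sample size fixes z at the printed two-decimal constants
1.96 and 0.842 rather than recomputing at higher precision, and rounds up
(ceiling). With the published effect sizes this reproduces the published
per-arm sizes 291/374/190/233/297 exactly; the GM-volume figure is 895
from the printed d = 0.53 versus the published 894, which follows from
the authors' unrounded effect size — a known, documented ±1 discrepancy.

## Problem sizes used in validation

Test and acceptance runs use 48³ phantoms at 3 mm (one registration
≈ 15–20 s), 100-replicate permutation-null studies on 8³ maps with 99
permutations, a planted-signal study on 16³ maps with 199 permutations,
100-replicate mixed-model coverage at n = 60+30 and 200-replicate null
LRT cohorts at n = 20+10. These sizes give stable Monte-Carlo verdicts
for the properties being checked (coverage ≥ 90%, FWER within binomial
bounds of nominal) while keeping the whole suite in a few minutes.

## What passing tests do and do not show

The phantom validates the *machinery*: that the registration recovers
known compartment-level volume change to ±0.005 JD under additive noise
and smooth multiplicative bias, that the permutation/TFCE stack controls
familywise error, that the mixed model recovers a planted interaction of
the magnitude reported for real sulci, and that the power arithmetic is
exact. It does not emulate realistic MRI contrast, motion or distortion
artifacts, segmentation error, template-construction bias, or
inter-subject anatomical variability (all phantoms share one anatomy).
Patient-level results that depend on real scans — the percentage of
significant voxels, the observed R² partitions, the observed
neuropsychological ρ values — are inputs to the generator's calibration,
not outputs this package can reproduce.

## Known limitations

- The demons registration is a desk-scale tool: it assumes matched
  intensity profiles between time points (no histogram matching) and a
  shared grid (no affine pre-alignment; a rigid pre-step hook exists in
  config but defaults off).
- Geometric annualization and Eq-style linear rates diverge for large
  |r|·Δt; both are reported, the JD pathway is primary.
- The exhaustive permutation mode covers intercept + group designs only;
  with nuisance covariates there is no finite exact enumeration under
  Freedman–Lane, so sampled mode is used.
- MixedLM random-slope fits can be singular on small or degenerate
  cohorts; the fallback changes the random-effects structure and is
  flagged with a warning rather than silently accepted.
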