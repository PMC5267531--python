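# Methods

`topomark` implements a multivariate analysis chain for dual-tracer
regional PET data in aging and Alzheimer's disease: tau-tracer and
amyloid-tracer SUVR values in 42 bilateral regions of interest per
subject, together with clinical status (CDR), CSF analytes and
neuropsychological composites. This note records the models, the defaults
and why, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Topography extraction (SVD)

Each modality's subject × ROI matrix `X` (n × m) is column mean-centered
and decomposed by thin SVD, `X_c = U S Vᵀ`. Rows of `Vᵀ` are unit-norm
spatial *topographies*; subject scores are `X_c V = U S`. Each weight
vector is oriented so its coordinate sum is nonnegative (ties broken by
the first nonzero coordinate) so that reports and leave-one-out
comparisons are reproducible.

Columns are centered but **not** variance-scaled: SUVR columns share
units and scale, so scaling would only amplify low-signal regions. An
uncentered mode (`center=False`) is first-class; in that mode the leading
topography tracks the mean image, which is the natural reading of
"component 1 is the mean" descriptions of PET component structure.

**Rank estimation.** A Horn-style permutation test decides how many
components are real. Each of B permutations shuffles every column of the
centered matrix independently across subjects — destroying inter-regional
correlation while preserving each region's marginal distribution — and
the k-th observed singular value is compared with the permutation
distribution of k-th singular values. Component k's p-value uses the
add-one correction, `p_k = (1 + #{σ_k^perm ≥ σ_k}) / (B + 1)`, and the
rank estimate is the largest K with `p_1..p_K ≤ α`, stopping at the first
failure. Defaults: B = 1000, α = 0.05, seeded generator. Comparing the
k-th statistic to the k-th permuted statistic (rather than the largest)
makes the test progressively conservative for deeper components, which is
what the sequential stopping rule assumes.

**Leave-one-out stability** refits the decomposition with each subject
removed and reports the absolute Pearson correlation between the refit
and full-sample weight vector for a chosen component; the absolute value
absorbs sign flips.

## Group inference

Scores of retained components are submitted to an ANCOVA on age, CDR and
APOE ε4 carriage using Type-II sums of squares (no interactions are
modeled, and Type II is invariant to factor order). CDR enters
dichotomized (0 vs > 0) by default because impaired cells are small; an
ordinal coding is available. A zero-variance score column is reported as
F = 0, p = 1 for every factor rather than raising.

One consequence worth knowing: when clinically impaired subjects are
displaced along several planted components at once, the SVD rotates its
basis so that the displacement concentrates in the dominant component —
so the CDR effect is carried mostly by component 1's scores even when the
generative shift was applied to all components.

**Preclinical staging.** Cognitively normal (CDR 0) subjects are split at
the cohort medians of CSF Aβ42 and CSF total tau, computed over the CDR 0
subjects with CSF by default (they are the staging population; an
all-subjects option exists). Amyloid-positive means Aβ42 strictly *below*
its median — CSF Aβ42 falls as plaque burden rises — and tau-positive
means tau strictly above its median. Amyloid-positive/tau-negative is
stage 1; amyloid-positive/tau-positive is stage 2; double-negative is
healthy aging. Ties count as negative (conservative staging), and the
unnamed amyloid-negative/tau-positive cell gets its own `tau_only` label
rather than being forced into a stage.

## Cross-modal canonical correlation

With n ≈ 46 subjects and 42 regions per side, textbook CCA is degenerate
(ρ₁ = 1 identically). The estimator whitens each modality by truncated
SVD — retaining at most `whiten_rank` components, with an optional ridge
term on the singular values — and then takes the SVD of the whitened
cross-covariance `M = Z_tauᵀ Z_abeta`. Its singular values are the
canonical correlations; covariance explained by pair i is defined as
`σ_i² / Σ σ²`. Weights are mapped back to ROI space so each canonical
pair is a pair of spatial topographies, oriented so the tau weight sum is
nonnegative with both sides flipped together (the projected correlation
stays +ρ).

The pipeline sets the per-modality whitening rank to the permutation rank
estimate (2 on default synthetic cohorts), which is the smallest basis
the data themselves certify; the CLI exposes an override and every output
records the regularization actually used. With full rank and n ≫ m the
estimator coincides with the generalized-eigenvalue solution (verified in
tests against the closed form, and against scikit-learn's NIPALS CCA).

## Penalized prediction and attribution

One elastic-net model per outcome regresses a CSF analyte or a cognitive
composite on the concatenated tau + amyloid regional predictors (84
columns, z-scored over the analysis subset so coefficients are comparable
across regions and modalities). The objective is

    (1/2n)·‖y − Xβ‖² + λ·[ mix·‖β‖₁ + (1 − mix)/2·‖β‖₂² ]

with (λ, mix) chosen by K-fold cross-validation (defaults: 5 folds, mix
grid {0.1, 0.3, 0.5, 0.7, 0.9, 1.0}, 50 λ values spanning four decades
below λ_max, seeded fold assignment). The coordinate-descent solve is
delegated to scikit-learn.

**Selection rule.** λ is chosen by the one-standard-error rule: the
sparsest (largest-λ) model whose mean CV error is within one standard
error of the minimum, with sparser mixes winning ties. This matters for
inference: with p = 84 predictors and n ≈ 36–46 subjects, picking the raw
CV minimum occasionally lands on a tiny λ under *permuted* outcomes,
producing in-sample R² near 1 in the null distribution and destroying the
power of the permutation test. The 1-SE rule collapses those null draws
toward zero while changing the observed fit little. The raw minimizer
remains available (`selection="min"`).

**Significance.** R² is the in-sample squared correlation between fitted
and observed outcome, computed identically for observed and permuted
fits. The permutation null permutes the outcome vector B times (default
1000) and reruns the *entire* protocol including the CV search — fixing
hyperparameters at their observed-data values would understate the null.
Reported are the null mean and SD, `z = (R² − mean)/SD`, and the
add-one-corrected empirical p. Even with the 1-SE rule the null keeps a
heavy right tail at these sample sizes (a few permutations in a thousand
still overfit), so z-scores discriminate more sharply than extreme
p-values; strongly coupled outcomes typically show z > 4 with p in the
0.005–0.05 range at B = 199.

**Attribution.** `Σ|β_tau|` and `Σ|β_abeta|` are block sums of absolute
standardized coefficients; `tau_share` is their normalized ratio,
undefined (null) when all coefficients are zero. Attribution identifies
the signal-carrying block reliably when exactly one block carries signal;
when the two modalities' subject scores are correlated near 0.9, both
blocks are nearly equally informative and no estimator can attribute
sharply at these n — the benchmark for attribution therefore uses
uncoupled modalities.

Batteries of outcomes are corrected family-wise by Holm's method
(Bonferroni by flag), applied to the permutation p-values.

## Synthetic cohort generator

The generator is the benchmark's ground truth. Per modality,

    X = baseline + Σ_k s_k · sv_k · w_kᵀ + E,   E_ij ~ N(0, noise_sd²),

with unit-norm planted topographies orthonormalized by Gram–Schmidt:
component 1 uniform-positive, the disease component an indicator of
temporal-lobe regions for tau and of frontoparietal regions for amyloid
(after orthogonalization these become contrasts: positive in the target
lobes, mildly negative elsewhere). Subject scores are standard normal;
scores of the same component are correlated `cross_loading` across
modalities; impaired subjects are shifted by `cdr_effect`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_subjects / n_regions | 46 / 42 | cohort and parcellation size of the target study design |
| n_impaired | 10 (7 CDR 0.5, 3 CDR 1+) | impaired fraction of that design |
| rank / singular_values | 2 / (1.0, 0.6) | two components; with noise_sd 0.1 the per-component SNR is 10 and 6 (condition: ≥ 5) |
| noise_sd | 0.1 SUVR | residual regional SUVR variability after averaging within bilateral ROIs |
| cdr_effect | 2.0 score SD | large, unambiguous clinical separation for power checks |
| cross_loading | 0.9 | strong coupling of the two proteinopathies in projected scores |
| csf_coupling | tau 300+80·s, p-tau 55+15·s, Aβ42 650−110·s (noise 60/12/90 pg/mL) | plausible immunoassay ranges; Aβ42 inversely coupled |
| cognition_coupling | −0.8·tau burden − 0.1·amyloid burden + N(0, 0.6²) | tau-dominant cognition; the working-memory composite is uncoupled (pure noise) |
| n_csf / n_neuropsych | 36 / 40 | per-analysis subset sizes of the design |

A single global seed fans out to named substreams (scores, per-modality
noise, demographics, CSF, cognition, subset selection), so adding or
toggling one table never perturbs another. SUVR values are floored at
0.05 and CSF analytes at 5 pg/mL to respect positivity; at default noise
these floors are essentially never hit.

What the generator does **not** emulate: spatial autocorrelation beyond
the planted low-rank structure (residuals are i.i.d. Gaussian),
heavy-tailed or subject-specific noise, off-target tracer binding (e.g.
basal-ganglia uptake of tau tracers), longitudinal change, and
measurement floor/ceiling effects in composites. Passing tests therefore
certify the statistical machinery under its own assumptions, not fidelity
to any real cohort.

## Problem sizes used in the test suite

The suite exercises the full method at reduced search sizes chosen as
sensible test-scale defaults: permutation rank tests at B = 199–1000;
elastic-net checks with 3-fold CV, lasso-leaning mix grids and 5–20 λ
values; permutation-R² calibration over 200 replicate datasets at
B = 199 on small designs; the outcome battery over 10 seeds at B = 199.
Headline analyses use the full defaults (B = 1000, 5 folds, 6-point mix
grid, 50 λ).

## Numerical notes and degenerate inputs

* Constant matrices decompose to all-zero singular values and rank 0
  without error; constant predictor columns are flagged and their
  coefficients pinned to zero; zero-variance vectors in correlation
  utilities yield null (not NaN-propagating) results.
* Serialization writes floats at 17 significant digits; write→read
  round-trips reproduce values to 1e-12 and NaN becomes JSON null.
* Subject ordering is lexicographic by ID everywhere; reports are
  byte-identical for identical config + seed.
* The permutation test's add-one correction bounds p away from 0, so a
  noiseless planted component attains exactly p = 1/(B+1).

## Known limitations

* The permutation null for elastic-net R² is expensive (it reruns CV per
  permutation); B = 1000 with the full default grid is minutes per
  outcome on one core.
* Attribution between strongly cross-correlated predictor blocks is
  fundamentally ill-posed at small n (see above); `tau_share` should be
  read alongside the cross-modal correlation.
* The ROI registry ships a standard 42-region bilateral default
  (Desikan–Killiany cortex plus eight subcortical structures) but any
  42-label registry can be substituted; lobe tags drive only reporting
  and the generator's planted patterns.
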