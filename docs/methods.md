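# Methods

`bidirmr` implements a one-sample, bi-directional Mendelian randomization
(MR) analysis of a continuous blood trait (platelet count, 10³/μL) and a
binary disease trait (hypertension), together with the synthetic-cohort
generator and Monte-Carlo harness used to validate every stage.  This note
records the models, the defaults and why they were chosen, and what the
simulations do and do not demonstrate.

## The causal model and its estimators

A genetic variant G_j is a valid instrument for exposure X on outcome Y if
it (a) predicts X (relevance), (b) is independent of X–Y confounders
(independence), and (c) affects Y only through X (exclusion restriction).
Writing β̂_Xj and β̂_Yj for the per-variant exposure and outcome
associations, each variant yields a Wald ratio θ̂_j = β̂_Yj / β̂_Xj with
first-order delta SE se(β̂_Yj)/|β̂_Xj|.  The aggregate estimators are:

* **IVW** — θ̂ = Σ_j w_j β̂_Xj β̂_Yj / Σ_j w_j β̂_Xj², w_j = se(β̂_Yj)⁻²;
  algebraically the weighted regression of β̂_Yj on β̂_Xj through the
  origin.  Fixed-effect SE (Σ w_j β̂_Xj²)^(-1/2) by default; a
  multiplicative random-effects option inflates the SE by max(1, σ̂) from
  the weighted residual mean square.  With independent valid instruments
  IVW converges to the two-stage least squares (2SLS) estimate on the same
  individual-level data, which the tests verify directly.
* **MR-Egger** — the same weighted regression with a free intercept.
  Under InSIDE (pleiotropic effects independent of instrument strengths)
  the slope is a consistent causal estimate even when all instruments are
  pleiotropic, and the intercept estimates the average directional
  pleiotropic effect; its test is the pleiotropy diagnostic.  The residual
  variance factor is floored at 1 so SEs never drop below the fixed-effect
  level.
* **Simple / weighted median** — the ratio estimate at cumulative
  standardized weight 0.5: order the θ̂_j, form p_j = (S_j − w_j/2)/S_total
  and interpolate linearly at 0.5.  Equal weights for the simple median
  (consistent with ≥ 50% valid instruments); inverse delta-method variances
  β̂_Xj²/se(β̂_Yj)² for the weighted median (consistent with > 50% valid
  weight).  SEs come from a seeded parametric bootstrap (default 2,000
  draws of β̂ ~ N(β̂, se) on both sides), so results are bit-reproducible
  given a seed.

All 95% CIs are estimate ± 1.959964·SE and all p-values are two-sided
normal, including the median estimators (normal approximation on the
bootstrap SE) — one reporting convention across the whole table.

Instruments are harmonized before estimation: exposure and outcome
statistics are joined per SNP with effect-allele checks, and any pair with
β̂_Xj < 0 has both signs flipped.  This leaves every ratio unchanged
(orientation invariance, property-tested) but fixes the orientation
MR-Egger needs.

### Estimand with a binary outcome

The outcome GWAS is logistic, so the causal estimate is a log odds ratio
per exposure unit and is reported alongside exp(θ̂) with an exponentiated
CI.  Because the log-odds scale is non-collapsible, the one-sample MR
estimand is an attenuated conditional log-OR; simulation checks of
parameter recovery therefore use a continuous outcome, or compare
estimators against the 2SLS oracle on the same data rather than against
the raw generative θ.  In the reverse direction (binary exposure) the
analysis proceeds identically on the log-odds β̂_X scale; the resulting
estimand (outcome units per unit log-odds of exposure liability) is
reported as such, not re-scaled.

## Pipeline stages and their conventions

**QC cascade** (order fixed, each removal carries the first triggering
reason): individuals with missing-call fraction strictly above 5% →
SNPs with call rate strictly below 97% (computed over surviving
individuals) → Hardy-Weinberg exact test at α (default 1e-6, a common
genome-wide choice; the threshold is configurable and nothing downstream
depends on the default) → greedy windowed LD pruning at r² strictly above
0.8 (default window 50 SNPs, step 5; window = None compares all pairs per
chromosome).  The HWE test is the conditional exact test: given allele
counts, the probability of every admissible heterozygote count is built by
the adjacent-count ratio recurrence in log space, and the two-sided
p-value sums configurations no more probable than the observed one (ties
compared with 1e-9 relative tolerance so exact mathematical ties are not
split by floating point; mid-p is available but off by default).  A
chi-square variant exists for speed.  LD r² is the squared Pearson
correlation of unphased allele dosages over pairwise-complete entries —
the deterministic composite-LD definition, not EM-phased haplotype r²
(PLINK comparisons should use its matching dosage mode).  Pruning drops
the later-positioned SNP of an offending pair, and an all-pairs
post-condition audit over every window is part of the public API.

**Association scan**: one regression per SNP (trait ~ dosage +
covariates), complete cases determined per SNP, additive coding in
effect-allele copies, minor allele as effect allele.  Linear models use
OLS with t-based p-values in the generic fitting routine; logistic models
use IRLS (max 25 iterations, 1e-8 log-likelihood tolerance) with Wald SEs,
explicit separation detection, and a non-convergence flag rather than a
silent result.  The GWAS table itself reports two-sided *normal* p-values
on beta/se for both models — the asymptotic convention of standard GWAS
tooling — so the table's p is always consistent with its beta and se at
machine precision.  Monomorphic or non-converging SNPs are flagged
not-testable and excluded from selection.

**Instrument selection**: p < 5e-6 (strict), then a per-SNP partial
F-statistic screen at F ≥ 10 (inclusive).  F is computed by Gaussian
regression of the exposure on the SNP after covariates — also when the
exposure is binary — and equals the squared t-statistic of the SNP
coefficient (identity tested).  A joint-F alternative would test all
instruments at once; the per-SNP partial F is the primary implementation
because the screen is applied variant-wise.  An empty surviving set halts
that direction with diagnostics; the other direction is unaffected.

**One-sample design**: instruments are selected in the same cohort used
for estimation, reproducing the emulated study design.  A split-sample
mode exists in the simulation harness to quantify what this costs (below).

## The synthetic cohort generator

Genotypes are drawn per SNP as Binomial(2, maf) — exact HWE by
construction; an optional Gaussian-copula block mode creates within-block
dosage correlation purely to exercise the LD pruner (the latent
correlation attenuates on the dosage scale, so block r² is below the
latent ρ).  Missingness is injected per SNP and per individual at
configurable rates.  Traits follow the instrumental causal diagram:

* forward mode: X = Σ_j β_Xj g_ij + γᵀC_i + ε_i, and binary
  Y ~ Bernoulli(logit⁻¹(c + θX + Σ_j α_j g_ij + direct SNP effects +
  δᵀC_i)) (a continuous outcome replaces the Bernoulli with Gaussian
  noise);
* reverse mode: the binary trait is generated first from its own
  instruments and the continuous trait responds with θ_rev per case.

The two modes are mutually exclusive because the generator is acyclic; a
config requesting both effects is rejected.  Pleiotropy α_j can be an
explicit vector, balanced N(0, sd), or directional N(mean, sd).
Confounders affect both traits with configurable effects.  The binary
trait is generated directly through the logistic link rather than by
thresholding simulated blood pressures: the MR estimand of interest is a
log odds ratio, and a liability-threshold front end would add a layer the
estimators never see.  One root seed is split per stage (mafs, genotypes,
missingness, traits) in a fixed order, so any stage is independently
reproducible and identical config + seed gives bit-identical cohorts,
bootstrap included.

Cosmetic covariate defaults (age ~ N(48.7, 11²), sex ~ Bernoulli(0.498),
and seven routine blood-panel marginals) make fixtures resemble a
middle-aged East-Asian biobank cohort; they carry zero trait effects
unless a config sets them, and no test depends on them.

### What the generator does not emulate

Population stratification, cryptic relatedness, genotyping batch effects,
realistic LD beyond the copula blocks, and the composite blood-pressure /
self-report case definition.  Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions — not robustness
to the full messiness of array data.

## Simulation scenarios (design choices)

Scenario parameters are power-arithmetic design choices, fixed before the
harness is run and recorded here as the package's own conditions:

* `valid_ivs` — 5 instruments (β_X = 0.5, per-instrument F in the
  hundreds at n = 10,000), continuous outcome, θ = 0.2.  Selection at
  p < 5e-6 is essentially certain, so winner's curse cannot distort the
  recovery check; used for parameter recovery, CI coverage, the θ = 0
  type-I calibration (n = 5,000), and the IVW–2SLS agreement check.
* `directional_pleiotropy_inside` — 50 instruments, β_Xj ~ U(0.2, 1.0)
  (n = 20,000 keeps the weakest above the selection threshold), 22 of 50
  invalid with a constant direct effect α = 0.3 assigned independently of
  β_X (InSIDE holds; generative mean pleiotropy 0.132).  The invalid
  fraction (44% of instruments, expected < 50% of inverse-variance weight)
  lets one scenario check all three robustness claims: Egger slope nearly
  unbiased where IVW is displaced by ≈ E[α]·E[wβ_X]/E[wβ_X²] ≈ 0.19, Egger
  intercept centred on 0.132 with > 50% rejection power, and weighted
  median bias well below IVW's.  Intercept power is governed by
  √(f/(1−f))·√(J/(1+m²/v)) where m, v are the mean and variance of β_X —
  hence the wide β_X range and large J.
* `balanced_pleiotropy` — α_j ~ N(0, 0.15) on all instruments; the Egger
  intercept test must stay at its nominal level (checked at summary level
  over 2,000 replicates).
* `weak_instruments` — a weak/strong effect mixture at n = 2,000 so the
  F ≥ 10 screen visibly removes variants.
* `reverse_causation` — reverse-mode generation; the reverse-direction
  analysis must detect θ_rev while the forward analysis stays null.
* `winner_curse_split_compare` — marginal instruments (per-SNP discovery
  power ≈ 0.4) plus an unmeasured confounder with unit effects on both
  traits.  A measured property of the one-sample design worth stating:
  with *valid* instruments and a continuous outcome, same-sample selection
  produces no IVW bias, because the exposure-coefficient sampling error
  propagates into the outcome coefficient (β̂_Y ≈ θβ̂_X + independent
  noise) and cancels in the ratio.  The curse appears when confounding
  correlates the two scans' errors: selection then favours replicates
  whose outcome coefficient errs in the confounded direction, biasing IVW
  toward the crude association (measured +0.086 at θ = 0.2 over 200
  replicates, versus +0.008 for split-sample selection).

The headline bi-directional cohort mirrors the emulated study's shape —
a continuous exposure with its own instruments, a binary outcome
(prevalence ≈ 0.25) with six instruments of its own, null SNPs, n = 6,000
— with one added constraint: the causal effect is spread over 8
instruments (θ = 0.15, aggregate IVW z ≈ √8 × 1.6) so that each
instrument's *mediated* association with the downstream trait stays well
below the p < 5e-6 discovery threshold.  Otherwise the acausal direction's
exposure scan co-opts the other trait's instruments — the known
instrument-overlap failure mode of bi-directional MR — and fabricates a
reverse signal.  The emulated study's two instrument sets were disjoint
genes; the generator keeps them separable for the same reason.

## Numerical choices

* Logistic IRLS: linear predictor clipped at ±30; separation raised when
  coefficients diverge (|β| > 100 mid-iteration, or |β| > 15 with perfect
  classification after convergence); information-matrix Wald SEs.
* HWE exact test in log space (no overflow at biobank counts);
  p ∈ (0, 1], monomorphic tables return 1.
* Median interpolation is linear in cumulative weight; a bootstrap draw
  whose β̂_X crosses zero maps to a ±∞-ranked ratio with negligible weight
  so the median stays defined.
* Rank deficiency raises rather than pseudo-inverting; ties in LD pruning
  resolve to the earlier-positioned SNP, making results order-stable.
* TSV readers use round-trip float parsing so persisted stages reproduce
  downstream numbers exactly.

## Problem sizes

Cohort sizes and replicate counts used by the tests and the acceptance
script (n = 5,000–20,000 individuals, 6–60 SNPs, 100–1,000 replicates)
are desk-scale choices that keep every statistical check at the precision
its tolerance needs; all of them are configurable upward.

## Known limitations

Two-sample MR machinery (cross-cohort harmonization, LD-score weighting),
MR-PRESSO/mode-based/multivariable estimators, Steiger filtering, mixed
models for population structure, and relatedness/sex checks are out of
scope.  Egger estimates are imprecise when instrument strengths are
similar (visible in the valid-IV scenario's wide Egger SEs), which is a
property of the method, not of this implementation.
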