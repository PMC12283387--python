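# Methods

## Scientific setting

GLP1-receptor agonists (GLP1-RA; semaglutide, liraglutide, dulaglutide,
…) and bariatric surgery (BS; chiefly Roux-en-Y gastric bypass and
sleeve gastrectomy) are the two major weight-loss interventions, and
individual responses to both vary widely. `weightgx` implements a
multi-biobank style pharmacogenomic analysis of that variability: does a
candidate panel of genetic exposures — polygenic scores (PGS) for BMI
and T2D, missense/functional variants in *GLP1R*, *PCSK1* variants, the
*APOE* BMI-change variant, and two surgery-replication variants —
predict percentage weight change after treatment?

Because individual-level biobank data of this kind are access-gated, the
package pairs the analysis pipeline with a synthetic-data generator that
reproduces the *structure* of such data, so that every stage is testable
end to end and injected effects can be recovered.

## Outcome and phenotyping

For each person, T0 is the first qualifying GLP1-RA purchase/
prescription (ATC `A10BJ*` plus the legacy codes `A10BX04/10/13/14`) or
the first bariatric procedure. All window logic runs on integer day
offsets from T0 with closed intervals:

* **Baseline W0** — the measurement closest to T0 in `[-364, 0]` days;
  only if that window is empty, the closest in `(0, +14]`. Same-day
  duplicates are averaged before selection (the rule is symmetric; the
  source protocol is silent on ties). A "52 weeks = 364 days" lookback
  was chosen over 365; the flag `baseline_lookback_days` exposes it.
* **Follow-up mW1** — the median (primary) or minimum (sensitivity) of
  measurements in `[182, 364]` days for GLP1-RA ("26–52 weeks") or
  `[180, 1460]` days for BS; the BS window can be shortened to 12 months.
* **Outcome** — `(mW1 − W0)/W0 × 100`; negative is weight loss.
* **Persistence** — the union of `[date, date + days_supply]` coverage
  intervals must span `[T0, T0+364]` with no uncovered gap longer than
  `max_gap_days` (default 90; the source criterion names persistence
  "through prescription length / refills / purchases" without a numeric
  gap, so the cutoff is configurable). Discontinuation is simply failure
  of this rule; there is no separate stop-code logic.
* **Exclusions**, in fixed, logged order: no arm event; age < 18 at T0;
  (GLP1-RA) non-persistence; no baseline weight; no follow-up weight;
  (GLP1-RA) bariatric surgery before or within the first treatment year.
  Optional filters: follow-up measurements within 30 days of the end of
  drug coverage (on by default for GLP1-RA, interpreting "within one
  month of the last purchase"), and a ≥30-days-pre-operative baseline
  for BS. Attrition counts always sum to the input person count.

Simultaneous same-day GLP1-RA records of different types are tie-broken
by lexicographic ATC code for the medication-type covariate — a
convention, flagged in the attrition log, not a claim about clinical
intent.

## Statistical model

Per study-by-ancestry stratum, ordinary least squares of

    %weight change ~ exposure + W0 + sex + age + PC1..PC20
                     [+ medication type (GLP1-RA)] [+ T2D (variant)]

one exposure per model. SNP exposures enter as 0/1/2 dosages and require
a minor allele count ≥ 10 and ≥ 5 carriers in the stratum (the source
names the MAC criterion but no cutoff; both are configurable, and
stratum n ≥ 30 is required). PGS exposures are standardized to mean 0 /
s.d. 1 within the analysis stratum (effects are reported per 1 s.d.) and
are always eligible. T2D status is *not* in the primary model — it is a
plausible mediator between genotype and weight change — and enters only
the `t2d_adjusted` sensitivity variant. The secondary model uses mW1
itself as outcome and adds a W0-by-exposure interaction.

The engine is QR-based least squares with SEs from σ̂²(XᵀX)⁻¹ and
two-sided p-values from Student's t on n−p degrees of freedom.
Within-stratum constant covariates (e.g. a single medication type) are
pruned; genuinely collinear designs raise an error naming the columns.
Missing covariates are handled by complete-case analysis with counts.

The ancestry-contrast model replaces the genetic exposure with ancestry
indicator variables (EUR reference) within multiancestry studies,
adjusted for sex, age, W0 and medication type; genetic PCs are omitted
there because within-study ancestry labels are themselves functions of
the PCs. Table-style demographic effects come from the same design with
no exposure term (`run_covariate_model`); whether the published
multivariable coefficients included an exposure term is ambiguous, and
the covariates-only reading is used.

## Meta-analysis and multiplicity

Stratum estimates are pooled by fixed-effect inverse-variance weighting
(wᵢ = 1/seᵢ²). Heterogeneity: Cochran's Q on k−1 d.f. and
I² = max(0, (Q−df)/Q)×100, clipped to 0 when Q ≤ df or Q = 0.
Ancestry-specific pools combine strata sharing an ancestry label across
studies; the multiancestry pool combines all strata in one pass (not a
meta-analysis of meta-analyses). Pooled p-values use the normal
approximation, the standard choice for inverse-variance pooling — it
reproduces the published ancestry-contrast p (0.874/0.295 → 0.003) —
although stratum-level p-values use Student's t. Bonferroni thresholds
are α/m with m the number of exposures actually tested: 13 for GLP1-RA
after excluding the two sub-percent-frequency *GLP1R* variants
(0.05/13 ≈ 0.0038, i.e. "P < 0.004"), and 5 for the surgical panel
(0.05/5 = 0.01). The surgical panel defaults to {PGS_BMI, PGS_T2D,
rs429358, rs728996, rs17702901} — the reconstruction consistent with
five tested exposures — with the full registry available behind
`bs_full_panel=True`.

## Power calculations

* **PGS (continuous exposure)** — exact noncentral-t power of the
  two-sided single-coefficient test: df = n − k − 1, noncentrality
  (β/sd_y)·√n with the exposure standardized. With β = 0.3 %/s.d.,
  sd_y = 7.8, n = 6750, k = 25, α = 0.05 this gives 0.885. An adjusted-r²
  argument is accepted for interface compatibility with power packages
  that take one, but has no role in the noncentral-t formulation.
* **SNP (biallelic variant)** — noncentrality 2f(1−f)nβ² of a 1-d.f.
  noncentral chi-squared, with β on a unit-variance outcome scale by
  default (pass `sd_y` to rescale a raw-unit β); power is the upper-tail
  mass beyond the central level-α quantile. f is folded (f ↔ 1−f leaves
  the NCP unchanged).

## Synthetic-data generator

What it emulates: multi-study structure with configurable per-study
ancestry mixes (EUR/AFR/AMR/EAS/SAS/MID); sex, uniform age, 20 i.i.d.
standard-normal PCs; T2D from an arm-specific prevalence with a
configurable log-odds shift per T2D-PGS s.d. (default 0.5); SNP dosages
Binomial(2, MAF) under Hardy–Weinberg with per-ancestry MAFs; PGS
standard normal within ancestry; GLP1-RA refill chains (30-day supplies)
that either cover 13 months or truncate uniformly in days 30–270 with
probability `discontinuation_prob` (default 0.2); one bariatric
procedure per surgical person (RYGB/SG dominant in the mix); and a small
GLP1-to-surgery crossover (1%) to exercise that exclusion.

Weight model: true baseline weight is linear in sex, centered age and
exposures (default: +2.5 kg per BMI-PGS s.d.) around a 108 kg intercept
with 18 kg residual s.d.; after T0 the weight approaches a per-person
target percentage change exponentially,
`w(t) = W·(1 + Δ%/100·(1 − 2^(−t/half-life)))`. The target is linear in
centered baseline weight, sex, centered age and exposures with a 7.8%
between-person s.d.; default coefficients are seeded from the published
demographic estimates (GLP1-RA: −0.05 %/kg, −1.54 % female, −0.02 %/yr
around a −3.93% mean; BS: −0.14 %/kg, −2.66 % female, +0.15 %/yr around
−21.17%) plus a +0.70 %/s.d. BMI-PGS effect in the surgical arm. These
are *defaults for exercising the pipeline*, not ground truth.

Design choices worth noting:

* **Trajectory half-lives** default to 60 d (GLP1-RA) and 75 d (BS) so
  the plateau is effectively reached by the start of each outcome
  window. With slower approaches the median-window weight sits visibly
  below the plateau and every injected response coefficient is
  attenuated by the mean approach fraction, which would make
  "recover the injected value" ill-posed; with these defaults the
  median and minimum outcome definitions still genuinely differ (the
  trajectory is still moving early in the window, and measurement noise
  makes the minimum systematically lower — the flagship dataset gives
  −4.8% median-based vs −5.6% minimum-based mean change for GLP1-RA).
* **Visit process** — Poisson counts per window (defaults: 2 baseline,
  1 early, 3 outcome-window) at uniform times, plus a guarantee
  probability (0.92) of at least one baseline candidate. Real EHR visit
  processes are burstier and outcome-dependent; nothing here models
  measurement-when-sick informativeness, so passing tests say nothing
  about informative-observation bias in real data.
* **Measurement noise** — i.i.d. Gaussian, 1 kg default. Real scales,
  clothing and charting introduce heavier tails and occasional unit
  errors; the median outcome is the defense in both worlds.
* Time is generated as calendar dates (ISO-8601 in the TSVs) but all
  logic uses day offsets; same (seed, config) reruns are byte-identical.

Not emulated: genotyping error, imputation quality, relatedness,
admixture (ancestry labels are categorical and exact), free-text EHR,
dose titration, and PGS computation from weights — PGS values are drawn
directly, so PGS "validation" here checks the pipeline's regression
plumbing, not score portability.

## Baseline-adjustment (collider) bias demonstration

When a variant shifts *true* baseline weight and baseline is measured
with error, adjusting a change-score for the *measured* baseline opens a
spurious path: conditional on measured baseline, genotype and
measurement error become correlated, and the error is also part of the
change score. The induced coefficient is approximately
`b·(1+k)·σ²_e/(σ²_u+σ²_e)` (b = kg/allele on true baseline, k the true
baseline-change slope, σ_e the error s.d., σ_u the within-stratum weight
s.d.), so the demonstration needs a design where σ²_e/σ²_u is not
negligible. Defaults: 3 kg/allele, 3 kg error s.d. (a realistic EHR
figure once scale, clothing and charting variation are included), 10 kg
weight s.d., MAF 0.3, n = 2000 per replicate, 1000 replicates. The
baseline-adjusted model then rejects a true-null genotype effect at
≈18–21% instead of 5%, while the unadjusted model stays at ≈4–6% —
the rationale for reporting a no-baseline sensitivity model alongside
the primary analysis. (In the flagship simulated dataset the effect
runs the other way too: because the BMI PGS raises baseline weight and
baseline predicts response, *removing* baseline adjustment moves the
pooled surgical BMI-PGS effect from +0.67 to +0.33 %/s.d.)

## Problem sizes and numerics

The flagship analysis dataset is six studies × three ancestries,
n = 20,000 (≈9,300 GLP1-RA and ≈7,200 surgical persons after
phenotyping), chosen to give stratum sizes (≈600–4,000) in the range of
real per-biobank strata while keeping a full pipeline run around a
minute. The Monte-Carlo power cross-check uses 2,000 simulated
regressions at the full n = 6,750. Degenerate inputs are errors, not
silent fixes: non-positive SEs or empty inputs to the meta-analysis,
constant PGS groups, rank-deficient designs, under-18 windows, and
missing (ancestry, SNP) MAFs all raise with the offending field named.
Strata failing eligibility are skipped and logged, never imputed.

## Known limitations

* The linear probability model is used for the binary T2D trait in PGS
  validation (keeps one engine everywhere; logistic would be the
  conventional choice and coefficients are not odds ratios).
* No random-effects meta-analysis; I² and Q are reported but a common
  effect is always assumed for pooling.
* Study-specific covariates (genotyping batch etc.) are supported as
  generic reference-coded indicators only.
* The generator's persistence behavior is refill-chain truncation only;
  real discontinuation (switching, stockpiling, dose splitting) is
  richer than any gap rule.
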