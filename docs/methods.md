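# Methods

## Scope and model

`cvhmr` estimates the causal effect θ of a scored exposure (the 12-point
cardiovascular-health composite or one of its components) on a
quantitative outcome (epigenetic age acceleration, or any numeric trait)
using genetic variants as instrumental variables. Two regimes are
supported: one-sample (individual-level genotypes, covariates, raw
metrics, outcomes) and two-sample (per-SNP GWAS summary statistics from
non-overlapping exposure and outcome samples).

## CVH scoring

Six metrics are each classified poor/intermediate/ideal (0/1/2) and
summed to 0–12. Thresholds, with lower bounds inclusive and upper bounds
exclusive:

| metric | poor (0) | intermediate (1) | ideal (2) |
|---|---|---|---|
| BMI (kg/m²) | ≥ 27 | 24 ≤ BMI < 27 | < 24 |
| Smoking | current | former, quit < 6 months | never, or former quit ≥ 6 months |
| Physical activity | never | between | regular (≥ 30 min thrice weekly) |
| Total cholesterol (mg/dL) | ≥ 240 | 200 ≤ TC < 240 | < 200 |
| Fasting glucose (mg/dL) | ≥ 126 | 100 ≤ FG < 126 | < 100 |
| Blood pressure (mmHg) | SBP ≥ 140 or DBP ≥ 90 | otherwise | SBP < 120 and DBP < 80 |

Blood pressure is implemented poor-first, ideal-second, else
intermediate; a case analysis over the compound boundaries shows this is
equivalent to the two-clause intermediate definition while leaving no
gaps or overlaps. The diet metric is out of scope (the "12-point"
variant). Outcomes on arbitrary scales (e.g. DNAm-based PAI-1 in pg/mL)
can be standardized with `zscore`, which uses the sample (n−1) standard
deviation — stated explicitly because either convention is defensible.

## Genotype QC and GWAS

SNPs are filtered on call rate ≥ 0.95, Hardy–Weinberg exact-test
p ≥ 5.7×10⁻⁷ and minor-allele frequency strictly > 0.01 (the boundary
value is excluded). The HWE test conditions on the allele counts and sums
the probabilities of all heterozygote counts no more probable than the
observed one (two-sided by probability mass), computed in log space; this
is the exact formulation conventional at genome-wide thresholds, not the
chi-square approximation. MAF is always recomputed from the dosages,
never trusted from metadata.

The association scan fits, per SNP, ordinary least squares of the
phenotype on dosage plus covariates (additive allelic model) and reports
the dosage coefficient with a two-sided t-test. Missing dosages are
dropped per SNP (complete case); SNPs degenerate after removal are
flagged, not fatal. Ordinal scores are treated as continuous phenotypes.

Clumping is greedy: the smallest-p unclaimed SNP below 5×10⁻⁸ becomes an
index and claims every unclaimed SNP on its chromosome within 10,000 kb
with r² ≥ 0.01 (squared Pearson correlation of dosages). Ties on p break
by (chromosome, position, id). Defaults mirror standard stringent
practice; all three thresholds are configurable.

## Instrument construction and validation

The weighted genetic risk score is wGRSᵢ = Σⱼ ŵⱼ gᵢⱼ with weights from an
independent base-data GWAS. Each weight's effect allele is reconciled
with the genotype matrix: matching A1 uses the dosage, swapped alleles
use 2 − dosage, anything else is rejected. Missing dosages are
mean-imputed as 2·MAF so the sample size is constant across SNP subsets.

Assumption audit: relevance is the partial F statistic of the wGRS in the
first-stage regression (reducing to (n−2)R²/(1−R²) without covariates;
F > 10 is flagged as "strong"); independence is tested per confounder
(two-sample t-test for binary, Pearson correlation test otherwise);
exclusion is the Wald p of the wGRS in a regression of the outcome on
wGRS + exposure + confounders. All checks use α = 0.05.

When a check fails, the pruning loop scores every current SNP against the
violated variable — Cochran–Armitage trend test (scores 0/1/2,
multinomial-variance Z) for binary/categorical variables, one-way ANOVA
across genotype groups for continuous ones, and the same adjusted
regression with the single SNP in place of the wGRS for the exclusion
check — removes the single most-associated SNP, rebuilds the score and
repeats. Removals are logged (check, variable, p-values) and the log
replays deterministically to the final SNP set. The loop aborts, naming
the unresolved check, rather than pruning below `min_snps` (default 2).

## One-sample 2SLS

Stage 1 regresses exposure on instrument (+ covariates); stage 2
regresses outcome on the predicted exposure (+ covariates). The reported
standard error uses structural residuals y − Xb with the observed
exposure — the consistent IV variance — while the naive stage-2 OLS
standard error is kept in the diagnostics for comparison (with
individual-level data the two can differ in either direction, so both are
exposed). Inference is normal-based. Covariates, when supplied, enter
both stages; this is configurable because base-GWAS adjustment does not
dictate the 2SLS stages. A first-stage F below 10 triggers a
`WeakInstrumentWarning` rather than an error.

## Two-sample estimators

Harmonization intersects exposure and outcome tables on SNP id, flips the
outcome beta (and complements its allele frequency) when alleles are
swapped, resolves strand complements, and handles palindromic (A/T, C/G)
variants by allele frequency: kept/flipped when both frequencies are
outside 0.5 ± 0.08, dropped otherwise (policy `drop` discards them all).
Every intersected SNP is accounted for by exactly one action.

- **IVW**: weighted regression of β̂_Y on β̂_X through the origin, weights
  σ_Y⁻². Fixed-effect SE = (Σ β̂²_X σ_Y⁻²)^(−1/2); in `auto-random` mode the
  SE is inflated by √max(1, Q/(J−1)) — multiplicative random effects —
  whenever heterogeneity is present. With one SNP the estimate and SE
  collapse to the Wald ratio and its delta-method SE.
- **Cochran's Q**: Σ wⱼ(ratioⱼ − β̂)² with wⱼ = (σ_Yj/|β̂_Xj|)⁻², χ²_{J−1}.
- **Weighted median**: per-SNP ratios ordered, normalized inverse-variance
  weights accumulated, the ordered ratios interpolated at cumulative
  weight 0.5; SE by parametric bootstrap (default 1000 draws, explicit
  seed). Consistent when valid instruments carry > 50% of the weight.
- **MR-Egger**: pairs oriented so β̂_X ≥ 0, weighted regression with an
  intercept; the slope is the causal estimate, the intercept p-value the
  directional-pleiotropy test. Inference on t with J−2 df and a
  multiplicative overdispersion factor floored at 1.
- **MR-PRESSO**: observed residual sum of squares with leave-one-out IVW
  predictions; null distribution from parametric simulation of outcome
  betas (default 1000 draws); per-SNP outlier p-values Bonferroni-adjusted
  over J and flagged below 0.05; corrected estimate = IVW on unflagged
  SNPs; distortion test against removals of random same-size subsets.
- **BH-FDR**: step-up q-values, grouped within outcome across exposures.
- **Multivariable IVW**: weighted least squares of outcome betas on the
  SNP × exposure effect matrix, no intercept, weights σ_Y⁻²; coefficients
  are direct effects conditional on the other exposures; residual
  heterogeneity reported as Q with J − K df. Instrument selection takes
  the union of genome-wide-significant SNPs across exposures, clumps by
  the smallest per-SNP p, and harmonizes everything to the first
  exposure's orientation against an explicit LD reference panel. An
  exposure whose instrument effects are identically zero is dropped from
  the fit and flagged inestimable rather than failing the whole model.

## Synthetic-data generator

Genotypes are drawn per SNP from Hardy–Weinberg proportions
((1−p)², 2p(1−p), p²) of the minor-allele count; missingness is
completely at random. Continuous CVH components are
baseline + Σⱼ effectⱼ·gⱼ + confounder effects + Gaussian noise, with
baselines centred near the intermediate boundaries (TC 200 ± 35 mg/dL,
FG 100 ± 15 mg/dL, SBP 120 ± 15 / DBP 78 ± 10 mmHg, BMI 24 ± 3.5 kg/m²)
so genetic effects move individuals across score categories; smoking and
physical activity are categorical draws (70/10/20% never/former/current;
45/25/30% never/between/regular). Confounders: age ~ Normal(50, 11)
truncated to [30, 70], sex and drinking Bernoulli (0.5, 0.07), education
uniform integer 1–7 — these distributional forms are declared defaults,
chosen to resemble a middle-aged community cohort, not estimated from any
dataset. Outcomes follow
EAA = θ·CVH + confounder effects + Σⱼ αⱼ gⱼ + noise, so θ and every
violating path (horizontal pleiotropy αⱼ acts on the outcome directly,
never through other components) are known exactly and recorded in a truth
object.

The two-sample generator draws β̂_X ~ N(β_X, σ_X) and
β̂_Y ~ N(θβ_X + α, σ_Y), with configurable directional/balanced
pleiotropy, planted outliers (default 20·σ_Y), and a configurable
fraction of palindromic allele pairs. The default exposure SE (0.01
against effects of 0.05–0.2) keeps every simulated instrument at
genome-wide significance, which is what instrument selection at
p < 5×10⁻⁸ implies; weaker settings reintroduce regression-dilution
attenuation in IVW, visible if σ_X is raised.

What the generator does **not** emulate: linkage disequilibrium beyond an
optional block-pair mode used to exercise clumping, imputation
uncertainty, population stratification, assortative mating, and
selection. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to those
real-data complications.

## Numerical choices and problem sizes

All randomness flows from explicit integer seeds; pipeline stages derive
per-stage seeds via CRC-mixed seed sequences, so reruns are bit-identical.
Normal-based 95% intervals use the exact 1.96 quantile; Egger uses t
quantiles. Degenerate inputs (constant SNPs, empty trait groups,
rank-deficient designs) are flagged or rejected with named errors rather
than silently propagated.

The statistical test suite uses simulation sizes chosen as the package's
own verification budget: 1000 replicates for type-I calibration of
Cochran's Q and the Egger intercept (bands [0.03, 0.07]), 500 replicates
for IVW and 2SLS coverage (bands [0.92, 0.98]), 200 replicates for
bias-removal, weighted-median robustness and MR-PRESSO outlier-detection
rates, with cohorts of 2,000–6,000 individuals and 10–30 SNPs. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping the whole suite under a minute.

## Known limitations

No LIML or weak-instrument-robust (Anderson–Rubin) intervals; no MR-RAPS,
mode-based or contamination-mixture estimators; no Steiger directionality
filtering; no MVMR-Egger or conditional F statistics; no kinship pruning,
ancestry PC computation or genotype imputation (principal components are
consumed as ready-made covariates). The Cochran–Armitage variance uses
the multinomial (unconditional) form; at the sample sizes involved the
difference from the hypergeometric form is below 1%.
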