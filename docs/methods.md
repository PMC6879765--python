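# Methods

## The measurement problem

Bulk tumour RNA-seq cannot tell directly which copy of a female X chromosome
a somatic mutation sits on. What it can measure is whether the *mutant
allele* appears in mRNA at the position where the exome caller reported it.
The RNA-mutated allele frequency (RMAF) captures this: the fraction of RNA
reads overlapping the mutated position that carry the alternate allele. In a
clonal tumour with random X-inactivation (Xi) fixed at the founding cell,
a female X mutation is either on the active copy (RMAF near 1 in a pure
tumour), on the inactive copy (RMAF near 0 while the gene is still expressed
from the other copy), or in a gene escaping Xi (RMAF near the escape
expression fraction, typically near 0.5). A male X mutation is hemizygous
and should always be expressed.

## Classification rules

A mutation's status is decided per patient and position:

1. **Adequate coverage** (≥ 10 RNA reads, the boundary counting as
   adequate): RMAF = alt / (ref + alt). RMAF ≤ 0.20 → NEM
   (non-expressed), RMAF ≥ 0.75 → EM (expressed), both thresholds
   inclusive; anything strictly between is *intermediate*. Intermediates
   are reported but excluded from NEM/EM statistics: the two threshold
   classes are deliberately conservative with respect to tumour purity and
   subclonality, and the zone between them is uninformative about Xi.
2. **Low coverage** (< 10 reads, including no pileup at all): absence of
   reads is only meaningful if the gene is otherwise expressed. The gene
   must reach ≥ 5 CPM in a strict majority (> 50%) of the patient's cohort
   — same sex, same cancer type — to proceed; otherwise the mutation is
   discarded (`not_expressed_gene`). If the patient's own expression of the
   gene is at least 4 SD below the cohort mean, the mutation is read as
   having knocked the gene down and is assigned RMAF = 1
   (`knockdown_assigned`, an EM); otherwise it is discarded
   (`insufficient_info`).
3. **Gene-level resolution**: when a patient carries several mutations in
   one gene, the highest-RMAF mutation represents the gene; exact ties go
   to the smaller genomic position so output is independent of input order.

Numerical choices in the fallback:

* The z-score is computed on log2(CPM + 1), which stabilises the variance
  of expression values across the dynamic range; raw CPM would let a few
  high-expression samples dominate the SD.
* The query sample is excluded from the reference mean/SD. With it
  included, |z| is algebraically bounded by (n−1)/√n, so a true knockdown
  in a cohort smaller than ~18 samples could never reach the −4 cut.
* Cohorts smaller than 3 samples are refused a z-score (SD too unstable)
  and the mutation is discarded as unassessable.
* Fewer than 10 reads uses the fallback; exactly 10 uses the quotient.

## Incidence integration

For each cancer and sex, the population frequency of mutant-TP53 cancer per
100,000 is the registry incidence rate times the cohort mutation frequency
n_mut/n_total, and the disparity ratio is the male/female quotient of those.
Every derived quantity is carried at full precision and rounded
(half-away-from-zero) only for display: with the packaged 13-cancer inputs,
rounding the per-100k values before taking the ratio changes the rendered
liver-cancer ratio from 4.9 to 5.0 and the kidney ratio from 1.1 to 1.0.
Cancers qualify for the analysis only with at least five patients in each
of the four sex × TP53-status cells. Registry rates are consumed as given
(they are age-adjusted upstream); no further standardisation is applied.

## Propensity weights and balance

Sex comparisons are reweighted by matching weights derived from a logistic
propensity model e = P(male | age, race, smoking, stage), fitted within each
cancer type (covariate mixes differ radically across cancers). The matching
weight min(e, 1−e)/Pr(observed sex) is bounded by 1, equals 1 exactly at
e = 0.5, and emulates 1:1 matching without discarding anyone. Age is
median-imputed; categoricals get an explicit "missing" level. Balance is
judged by the standardized mean difference of every design column between
sexes after weighting, against the conventional |SMD| < 0.1; the pooled SD
in the denominator is always the unweighted one so before/after are
comparable. If any covariate stays unbalanced the model is enriched —
squared terms for the offending numeric columns and pairwise interactions
involving the offending covariates — and refit, up to `max_iter` rounds
(default 5). Failure to balance is flagged in the report, never silent.
In practice the main-effects round already balances first moments of
included covariates extremely well (a known property of matching weights);
the enrichment round matters when the true propensity is strongly
nonlinear in a covariate. A tiny ridge (C = 10⁶) stabilises the fit;
complete separation — all fitted probabilities extreme — raises an error
naming the remedy (drop the offending covariate).

## Weighted gene tests

Per gene, patients' gene-level NEM/EM calls form a 2×2 sex × status table
whose cells are sums of matching weights. The Pearson chi-squared statistic
(1 df) is computed without continuity correction — weighted cells are
non-integer and the Yates correction is ill-defined for them. Genes with a
zero row or column marginal are untestable and excluded from the BH family;
the family is all testable genes in the analysis. The chi-score is the
signed square root of the statistic, positive when the weighted female NEM
proportion exceeds the male one; under the null it is asymptotically
standard normal, which the calibration suite verifies empirically, and a
designated gene set is compared against the remaining genes by a two-sided
Wilcoxon rank-sum test on chi-scores.

Burden models are weighted Poisson log-linear regressions of per-patient
mutation counts on sex (rate ratio = exp(β_female), Wald 95% CI). The
mutation-level RMAF sex comparison is a weighted linear model on
logit(RMAF) with sex and cancer-type terms; RMAF is clipped to
[0.01, 0.99] because the logit is undefined at the boundaries, and the
cancer term is dropped when only one cancer is present.

## Survival

Kaplan–Meier product-limit curves and the standard two-group log-rank test
(via lifelines), with strata from TP53 status (unknown status excluded) or
from a median expression split. Values exactly at the median go to the
bottom stratum — deterministic and order-independent. Follow-up windows
(14 years for status strata, 10 for expression strata by convention, both
configurable) are applied as administrative censoring before testing. No propensity
weighting is applied inside survival analyses.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular tumour biology:

* **Cohort layout**: 13 cancer types, both sexes; per-cancer, per-sex TP53
  mutation probabilities and registry rates default to the packaged
  published table.
* **Burden**: per-patient X-mutation counts are Poisson with female rate
  4.0 and male rate 2.0 per exome (the twofold female excess from two X
  copies); autosomal counts are Poisson(30) in both sexes, giving
  near-parity genome-wide burden. Mutations are placed on genes
  proportionally to gene length, with positions inside the gene span.
* **Xi**: each female X mutation is silenced with probability 0.5 unless
  its gene escapes Xi (15% of genes), in which case both copies express
  and the mutant fraction is 0.5. Xi is drawn per mutation, not as a
  per-cell mosaic: bulk RNA-seq of a clonal tumour effectively fixes one
  active copy per locus. The silencing probability is an exposed parameter
  rather than an asserted biological constant.
* **Coverage**: read depth at each mutated position is negative binomial
  (mean 50, dispersion 5 — realistic RNA-coverage overdispersion with two
  parameters), so a few percent of positions fall under the 10-read cut
  and exercise the fallback. Mutant reads are binomial in the expressed
  allele fraction (0 silenced / 1 active / 0.5 escape).
* **Knockdowns**: 2% of non-silenced mutations abolish their gene's
  expression — zero reads at the position and a 64-fold suppressed counts
  column — exercising the z ≤ −4 rule.
* **Covariates**: age (males +3 years on average) and smoking (60% vs 35%)
  are sex-confounded so propensity weighting has real work to do; race and
  stage are drawn from shared distributions.
* **Survival**: exponential with median 5 years for wild-type TP53 and a
  hazard ratio of 1.6 for mutant, uniformly censored within a 14-year
  window.
* **Counts matrix**: gene baselines are log-normal (median ≈ 40 CPM-scale
  units, so nearly all genes pass the 5-CPM rule), with log-normal library
  sizes and NB counts noise.

A truth table records each simulated mutation's Xi state, knockdown flag
and implied expected status, enabling parameter-recovery tests: with the
defaults, deep-coverage mutations classify to their truth state
essentially always, the female NEM fraction among threshold-classified
mutations converges to 0.5 and the male EM fraction to 1.

What passing these tests shows — and does not. The generator contains no
tumour purity gradients, copy-number change, mutational signatures,
per-cell Xi mosaicism or expression-dependent mutation calling. Recovery
and calibration results therefore validate the pipeline's logic and
statistics under its own model assumptions; they do not certify the
thresholds against the messier allele-frequency distributions of real
tumours, where purity and subclonality compress RMAF toward the middle.
That is precisely why the 0.2/0.75 thresholds are conservative.

## Problem sizes

The study-scale runs use 2002 simulated patients (77 per cancer per sex),
2000 replicates for null calibration of the weighted chi-squared, 561
simulated genes for the chi-score normality and FDR checks (40 replicates
of 511 null + 50 signal genes), and 100 replicates for Poisson CI
coverage. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the default test run fast.

## Known limitations

* Indels are treated as "reads supporting the non-reference allele at the
  anchor position"; the pileup table abstracts the caller's allele
  matching, and core code never reads BAMs.
* The per-gene test pools cancers (with weights) rather than stratifying;
  cancer-stratified testing would need a combining rule the pooled design
  avoids.
* Pseudoautosomal genes are not treated specially; the generator's escape
  flag is the only stand-in for escape biology.
* No copy-number or purity correction of RMAF.
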