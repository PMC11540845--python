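# Methods

This note documents the models behind `pgspart`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Variant partitioning

Given harmonized summary statistics for a target disorder and an anchor
trait, every variant receives exactly one label:

* `noEA` if the anchor p-value exceeds the threshold (default 0.05);
* `concordant` if anchor-significant and the disorder and anchor effects
  share sign;
* `discordant` if anchor-significant and the signs oppose.

The rule is applied per SNP with no LD pruning, and no threshold on the
*disorder's* p-value — weakly-estimated disorder effects enter with their
noisy sign, which is intentional: the partition describes the scoring
weights actually used, not a curated causal set.  A variant with an
exactly zero effect and a significant anchor p (possible only in
synthetic, noise-free input) carries no sign information and is assigned
to `noEA` with a logged count.  Derived sets: `EA` = concordant ∪
discordant, `all`, and the *shared subset* — the intersection of one
trait's set with another's (e.g. disorder-1-discordant ∩
disorder-2-concordant), scored separately with each trait's own weights.

Harmonization details: the variant key is
`chrom:pos:<canonical allele pair>`, where the canonical pair is the
lexicographic minimum of the sorted allele pair and its strand
complement, so swapped-allele and opposite-strand records share a key;
rsID sets differ across GWAS releases, which is why positions anchor the
key.  Swapped records get β := −β and f := 1 − f; strand flips are
complemented; palindromic (A/T, C/G) variants are dropped by default with
no frequency-based rescue (simplest defensible rule; a toggle exists);
allele pairs that cannot be reconciled are dropped with reason
`allele mismatch`.  When a genotype panel is supplied it fixes the
reference orientation and the authoritative allele frequency, since
scoring happens in that panel.  Coordinates are 1-based throughout,
matching VCF.

## 2. Scoring

Scores are plain weighted dosage sums over a variant set, with per-variant
mean imputation of missing dosages (keeps the exact additivity
`score(all) = score(noEA) + score(concordant) + score(discordant)`), and
standardization to mean 0 / SD 1 (sample SD, n−1) within each genotyping
wave.  Default weights are the raw harmonized betas.  A greedy LD
clumping + p-thresholding preparation is provided for sparser weights.  A
continuous-shrinkage posterior (PRS-CS-style) is **not** reimplemented;
the scoring engine accepts any external per-SNP weight vector.  This is
the package's largest deliberate departure from the motivating analyses:
raw-beta weights change absolute PGS R² but not the sign structure the
partitioning is designed to expose.

## 3. Association models

Grades are 4 ordered categories (D < C < B < A, coded 0..3; letters only
at I/O).  The proportional-odds model
`P(grade ≤ k | x) = logit⁻¹(α_k − x'β)` is fit by maximum likelihood via
`statsmodels`' `OrderedModel`, subclassed with the analytic score of the
cumulative-logit likelihood (`pgspart._ordinal_fast`) because the base
class differentiates numerically — with ~70 parameters (20 PCs + school
indicators) that is ~20× slower at identical estimates; the test suite
verifies the analytic gradient against numerical differentiation and the
MLE against an independent Nelder-Mead optimizer to 1e-4.

The multilevel school structure is approximated by **fixed school
indicators** when every school stratum has ≥ 20 observations, and omitted
otherwise (`school_mode="auto"`); a random-intercept ordinal model would
need adaptive quadrature and, at 45 schools with ~100 children each and a
modest between-school SD, differs from the fixed-indicator fit only in
second order.  This is the biggest modelling approximation in the
package.  Wald CIs and p-values are used throughout; complete cases only,
with dropped counts logged.

Variance explained is Nagelkerke's pseudo-R² increase between nested
ordinal models with and without the PGS, computed against the
intercept-only log-likelihood `Σ n_k log(n_k/n)`; across waves the
unweighted mean of per-wave increases is reported (whether the original
analyses weighted by wave n is unstated; unweighted was chosen and
flagged).  Quintile contrasts replace the continuous PGS by five
equal-size groups (ties broken by stable sort on value then position, for
determinism) with the lowest quintile as reference.  Predicted category
probabilities fix covariates at their mean (modal value for binary
indicators).  Symptom scales are square-root transformed (they are
skewed, nonnegative) and fit by OLS.

## 4. Pooling, multiplicity, stratified checks

Per-wave effects are pooled by fixed-effects inverse-variance weighting;
Cochran's Q is reported but never switches the model to random effects.
BH step-up FDR controls each family of results (one family per results
table — all PGS × outcomes of an analysis block); the mediation family is
Bonferroni-corrected with m = 3 subjects × 2 partitions = 6, threshold
0.05/6 ≈ 8.3e−3.  Sex-stratified contrasts use the Wald z on the
difference of independent stratum estimates.  The "bootstrap" procedure
for unequal stratum sizes is subsampling *without* replacement of the
larger group at the smaller group's n (the name is kept from the field's
usage), re-running the analysis per draw.

## 5. Mediation

Three-model procedure per wave, each path pooled across waves before any
decision: `a` (PGS → mediator, linear on the sqrt scale), `b` and `c'`
(one ordinal model of the outcome on PGS + mediator), `c` (ordinal model
without the mediator).  The mediator enters models as its sqrt-transform
z-scored per wave, which makes path `b` per-SD and every classification
invariant to positive rescaling of the scale.  Gating: pooled `a` and `b`
significant at 0.05 (wave-level gating would be noisier; pooled was
chosen).  Classification at the Bonferroni threshold:

* *inconsistent/suppression*: adjusting increases |effect|
  (|c'| > |c|), or flips its sign **with a significant flipped direct
  effect** — the significance guard matters because under full mediation
  c' ≈ 0 and its sign is noise;
* *full*: c significant, c' not;
* *partial*: both significant, attenuated, same sign;
* *none*: otherwise, or gate failed.

Proportion mediated is `1 − c'/c` on the linear-predictor (log-odds)
scale — the attenuation convention, since the motivating analyses report
attenuation percentages without printing a formula; `a·b/c` is available
behind a flag for sensitivity.  No bootstrap CI for the indirect effect
is produced (point classification only).

## 6. Stratified LD-score analyses

With partitioned LD scores `l(j,c) = Σ_{k∈c} r²(j,k)` (panel-based, with
the small-sample adjustment `r̃² = r² − (1−r²)/(n−2)`, or analytic under
the block model), heritability coefficients solve the weighted regression
`E[χ²_j] = 1 + N Σ_c τ_c l(j,c)` with a free intercept; category
heritability aggregates `h²(C) = Σ_{j∈C} Σ_c τ_c a_jc`; standard errors
come from a delete-a-block jackknife (default 200 contiguous blocks).
Weights are `1/max(l_total, 1)` (heteroscedasticity only, no two-step
intercept).  The design matrix is column-equilibrated before solving —
`N·l` columns are ~10⁶ times the intercept — and a condition-number check
rejects genuinely collinear annotation sets.  Negative category estimates
are reported as-is with a warning; they indicate a near-null category or
model misspecification and masking them would bias shares.  Enrichment is
reported as (h² share)/(SNP share), with the reciprocal also emitted
because the field's prose sometimes prints the inverse.

Cross-trait covariance uses the stratified cross-trait regression
`E[z₁ⱼz₂ⱼ] = √(N₁N₂) Σ_c ρ_c l(j,c)/M_c + intercept`, the free intercept
absorbing phenotypic correlation in overlapping samples.  This replaces a
method-of-moments annotation-stratified covariance estimator with a
regression estimator of the same estimand; per-annotation M_c is used for
normalization.  Estimates with fewer than 200 shared variants are
refused.  GWS-hit enrichment is a Pearson χ² of observed hits per
partition against expectation proportional to partition size.
Cell-type-style conditional enrichment builds `target = partition ∩
annotation` and a reference (`anti-target`: annotation outside the
partition; `control`: the rest of the partition), makes them disjoint,
and one-sidedly tests τ_target > τ_reference using the jackknife
covariance of the two coefficients.  MHC/HapMap3-style restrictions are
variant-mask options, not built-in data.

## 7. The synthetic-data generator

**Genotypes.** Equal-size LD blocks; within a block all SNPs share a MAF
(drawn uniformly from `maf_range`) and a constant pairwise dosage
correlation; blocks are independent.  Each haplotype allele is the
threshold indicator of an equicorrelated Gaussian whose latent
correlation is calibrated (Owen's-T closed form + root finding) so the
*dosage* correlation hits the target exactly; dosages are sums of two
haplotypes, marginally Binomial(2, f).  By default the per-block
correlation is heterogeneous, drawn from `rho_block_range = (0.2, 0.8)`:
constant LD scores across SNPs would make stratified LD-score regression
unidentifiable (the regressor would be collinear with the intercept),
and real genomes are strongly heterogeneous in LD.  The block model gives
analytically known LD scores `l = 1 + (B−1)ρ_b²` used to cross-check the
panel-based estimator.

**Effects and summary statistics.** Effects live on the
standardized-genotype scale and are rescaled so the population
heritability `β'Rβ` equals the spec exactly under the block LD matrix.
Anchor and target causal sets are independent Bernoulli draws; on the
intersection the target sign agrees with the anchor with probability
`q_concordant`.  A second disorder can be drawn sharing the anchor, with
its own concordance probability — this is what produces the negative
correlation between one disorder's discordant score and the other's
concordant score.  Summary statistics for the scoring pipeline are
`β̂ ~ N(β, 1/N)` (independent noise; LD convolution is irrelevant to
per-SNP sign/threshold classification), emitted on the per-allele dosage
scale (`β/√(2f(1−f))`) with two-sided normal p-values.  For LD-score
analyses a separate routine draws `z = √N·Rβ + ε, ε ~ MVN(0, R)` — the
marginal-association model stratified regression assumes.  Default GWAS
sizes follow the large published studies the design emulates (anchor
≈ 766k; disorder 1 ≈ 226k; disorder 2 ≈ 46k).

**Cohort.** Latent liability per subject area =
`γ_conc·S_conc + γ_disc·S_disc + b_med·mediator + covariate terms +
school intercept + noise`, with `S_conc`/`S_disc` the z-scored true-effect
scores over concordant/discordant causal SNPs and the mediator latent
`a_med·z(S_conc+S_disc) + noise` (unit variance).  Grades cut the
z-scored liability at the normal quantiles of the cumulative category
probabilities (defaults 15/30/35/20% for D/C/B/A).  The observed symptom
scale is the mediator latent shifted by +4 and truncated at zero
(shift-truncate was chosen over exponentiation to keep the sqrt-linear
approximation good).  Defaults: n = 4278 children, 3 waves, 45 schools,
school SD 0.15, age ~ N(10.03, 2.95), 43.7% female, 20 null PCs.  The
liability loadings are a calibration choice, not a published value: with
`γ_conc = +0.18, γ_disc = −0.12, a_med = 0.25, b_med = −0.20` the total
concordant and discordant PGS effects are ≈ +0.13 / −0.17 on the latent
scale, so each partition score explains ~1–3% of latent variance, the
mediated share of the discordant effect is ~25–30%, and the mediated
component *opposes* the direct concordant effect — reproducing,
qualitatively, the partial-mediation and suppression patterns the
dissection is meant to reveal.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic human LD (block-equicorrelated
copula only), imputation error and INFO scores, ancestry structure (PCs
are null noise), X chromosome, assortative mating and dynastic effects,
genotyping batch effects beyond the wave label, and missing data.

## 8. Problem sizes and numerics

The test suite and acceptance script run at desk scale by design:
partition checks at M = 2,000, the demo at M = 1,500 SNPs / 75 blocks,
sign-pattern power at 8 replicates of n = 4,000, stratified h² and
covariance recovery at M = 20,000 with 30–50 replicates.  Ordinal fits
use BFGS with the analytic score (fallback to Nelder-Mead restarts),
declare quasi-separation when a slope exceeds 30 or its SE is not finite,
and require strictly increasing thresholds.  All randomness flows from
explicit integer seeds; every pipeline run is bit-reproducible from its
config, and a run manifest echoes the full configuration.  The command
line deliberately exposes only three verbs — `simulate`, `run` (config
driven) and `demo` — because each analysis stage is a plain library
function; per-stage shell commands would duplicate the pipeline's stage
logic without adding capability.

## 9. Known limitations

* School random intercepts approximated by fixed indicators (see §3).
* Raw-beta default weights; no shrinkage prior (see §2).
* No liability-scale conversion of h²; estimates are on the observed
  (z-score) scale of the simulated GWAS.
* Mediation is associational; no counterfactual identification or
  sensitivity analysis is attempted.
* Indels, multi-allelic sites and genome-build liftover are out of scope
  for harmonization.
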