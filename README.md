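# pgspart

Dissecting the polygenic contribution of neurodevelopmental disorders to
an ordinal outcome by their relationship with an anchor trait.

## The scientific problem

Attention-deficit/hyperactivity disorder (ADHD) and autism spectrum
disorder (ASD) are both genetically correlated with educational attainment
(EA), but in opposite and mixed ways: most ADHD risk alleles push EA down,
while ASD risk alleles push it in both directions.  When a disorder's
polygenic score (PGS) mixes variants whose EA effects oppose each other,
its association with school outcomes can cancel to zero.  `pgspart`
implements the dissection strategy that resolves this: split a disorder's
GWAS variants by their relationship with the *anchor* trait and score each
part separately.

For each variant *j* with harmonized disorder effect β<sub>D,j</sub>,
anchor effect β<sub>EA,j</sub> and anchor p-value p<sub>EA,j</sub>:

* **noEA**: p<sub>EA,j</sub> > 0.05 — not associated with the anchor;
* **concordant**: p<sub>EA,j</sub> ≤ 0.05 and
  sign(β<sub>D,j</sub>) = sign(β<sub>EA,j</sub>);
* **discordant**: p<sub>EA,j</sub> ≤ 0.05 and
  sign(β<sub>D,j</sub>) ≠ sign(β<sub>EA,j</sub>).

Partition scores PGS<sub>i</sub> = Σ<sub>j∈set</sub> w<sub>j</sub>
d<sub>ij</sub> (dosages d, per-SNP weights w), standardized to mean 0 /
SD 1 within each genotyping wave, are then related to 4-level school
grades (D < C < B < A) with proportional-odds models

P(grade ≤ k | x) = logit⁻¹(α<sub>k</sub> − x'β),

so exp(β<sub>PGS</sub>) is the odds of a *better* grade per PGS standard
deviation, adjusted for age, sex, socioeconomic status, 20 genetic PCs and
school.  Per-wave fits are pooled by fixed-effects inverse-variance
meta-analysis; variance explained is the increase in Nagelkerke pseudo-R²;
families of tests are controlled by Benjamini–Hochberg FDR.  The package
also implements three-model mediation through symptom scales
(full / partial / inconsistent-suppression classification), stratified
LD-score regression for per-partition SNP-heritability, χ² enrichment of
genome-wide significant hits, and annotation-stratified cross-trait
genetic covariance with a free intercept for sample overlap.

Because individual-level cohorts of this kind are not public, the package
ships a first-class synthetic-data module: LD-blocked dosage genotypes,
anchor+disorder GWAS with controlled effect-sign concordance, and a cohort
whose latent liability loads on the concordant/discordant score components
with a mediating symptom scale — every downstream stage is exercised
against known ground truth.

## Worked example

```bash
pgspart demo --seed 1 --out demo_out
```

simulates two disorders sharing an anchor (one mostly discordant with it,
one balanced), a cohort of 4278 children in 3 waves and 45 schools, and
runs the full pipeline.  The mathematics rows of the printed meta-analysis
table (seed 1, abridged):

```
     outcome    pgs_set       OR   ci_low  ci_high          p   p_adjusted  delta_R2    n
 mathematics        all 0.940181 0.889201 0.994084  3.011e-02    3.474e-02  0.001424 4278
 mathematics       noEA 0.993504 0.939801 1.050276  8.182e-01    8.182e-01  0.000243 4278
 mathematics         EA 0.897893 0.849315 0.949249  1.474e-04    2.457e-04  0.003446 4278
 mathematics concordant 1.141979 1.080243 1.207244  2.840e-06    6.087e-06  0.005242 4278
 mathematics discordant 0.788969 0.745785 0.834653  1.542e-16    1.156e-15  0.015936 4278

Spearman(trait1 discordant, trait2 concordant) rho = -0.161 (p = 3.91e-26)

Mediation of PGS effects by symptoms:
  mathematics        concordant inconsistent/suppression proportion -37%
  mathematics        discordant partial                  proportion 27%
```

Read: one SD of discordant genetic load lowers the odds of a better
mathematics grade by ~21% (OR 0.79) and explains ~1.6% of latent variance,
while concordant load *raises* the odds (OR 1.14); the undissected score
(`all`, OR 0.94) washes most of this out because the components cancel.
The discordant score of disorder 1 and the concordant score of disorder 2
correlate negatively (ρ = −0.16) because their variant sets overlap with
opposite-signed weights.  Symptoms partially mediate the discordant effect
(~27% in mathematics) and act as a suppressor of the concordant one, and
the LD-score stage recovers the partition-resolved heritability and
cross-trait covariance of the generating model.

## Layout

| module | contents |
| --- | --- |
| `pgspart.synthetic_data` | genotype / GWAS / cohort generator with truth records |
| `pgspart.sumstats` | GWAS table reading, validation, filtering (MAF/INFO/HWE), allele harmonization, dosage VCF I/O |
| `pgspart.partition` | anchor-significance + sign-concordance classification, shared subsets |
| `pgspart.pgs` | scoring, per-wave standardization, clumping+thresholding, Spearman |
| `pgspart.assoc` | proportional-odds and linear models, Nagelkerke ΔR², quintiles, predicted probabilities |
| `pgspart.inference` | fixed-effects IVW meta-analysis, BH-FDR/Bonferroni, sex-stratified Wald test, subsampling |
| `pgspart.mediation` | three-model mediation with full/partial/suppression classification |
| `pgspart.ldscore` | LD scores, stratified h², GWS-hit enrichment, cross-trait covariance, cell-type-style conditional enrichment |
| `pgspart.pipeline`, `pgspart.cli` | end-to-end orchestration, `pgspart` command |

See `docs/methods.md` for the models, defaults, and known limitations.
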