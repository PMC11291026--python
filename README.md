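# diurnalgwas

Time-of-day aware genetic association testing for quantitative biomarkers.

Standard GWAS of a biomarker such as serum glucose assumes a variant's
per-allele effect is constant over the day. For rhythmically regulated
traits this can be badly wrong: a variant whose effect is *positive in the
morning and negative in the evening* averages out to nothing in a marginal
association test, yet has a real, clinically meaningful diurnal effect.
`diurnalgwas` implements three complementary tests for such time-dependent
genetic effects, plus the phenotype-derivation pipeline biobank biomarker
GWAS use, and a synthetic-cohort generator so every stage is testable
without access-controlled individual-level data.

Intended users: statistical geneticists and biobank analysts who have
per-sample biomarker values with draw timestamps and genotype dosages, and
want to scan for genotype-by-time-of-day interactions.

## The models

With `t ∈ [0,1)` the fraction of the day elapsed at blood draw
(`t = (hh·3600 + mm·60 + ss)/86400`), `G` the allele dosage, and `y` the
adjusted phenotype:

**Cosinor interaction scan** (primary test). Per variant,

```
y = α + covariates + β_s·sin(2πt) + β_c·cos(2πt)
      + β_G·G + β_GS·G·sin(2πt) + β_GC·G·cos(2πt) + ε
```

The 2-df Wald chi-square on `(β_GS, β_GC)` tests any single-harmonic
time-dependence of the variant's effect, corrected for its time-constant
additive effect. The pair converts to an amplitude
`A = √(β_GS² + β_GC²)` and acrophase (clock time of maximal positive
per-allele effect). A `separate` mode fits the two interactions in two
single-interaction models, mirroring association engines that accept one
interaction term per run.

**Windowed heterogeneity scan.** Samples are split into clock-time bins
(presets: six 2-hour bins 08:00–20:00, hourly bins 09:00–19:00, or 24
hourly bins); `y ~ covariates + G` is fitted per bin; estimates are pooled
by inverse-variance fixed-effect meta-analysis and tested for cross-bin
heterogeneity with Cochran's Q (`Q = Σ wₖ(bₖ − b_meta)²`, `wₖ = 1/seₖ²`,
df = k−1). Unlike the cosinor model, Q assumes no waveform.

**Spline trajectory test.** Raw (mmol/L) glucose is modelled as a natural
cubic spline of `t` with genotype as a 3-class factor and
genotype-by-spline interactions; the nested-model F test against a
shared-curve null detects genotype-dependent trajectories of any smooth
shape.

**Phenotype derivation.** Raw biomarker → log → one large OLS
residualization on declarative covariates (categorical, continuous, or
quantile-binned factors with pairwise interactions) → rank-based
inverse-normal transform with Blom offset,
`Φ⁻¹((rank − 3/8)/(n + 1/4))`.

## Worked example

```python
import numpy as np
import diurnalgwas as dg

# a cohort carrying a purely diurnal variant: no time-constant effect,
# homozygotes differ by 0.05 mmol/L at 09:00, draws 08:00-20:00
cfg = dg.scenario("mtnr1b_like", n_samples=100_000, seed=1)
geno, samples = dg.simulate_cohort(cfg)

adj = dg.PhenotypeAdjuster(covariates=[dg.CovariateSpec("sex"),
                                       dg.CovariateSpec("age", kind="continuous")])
samples = adj.fit_transform(samples)

res = dg.cosinor_test(geno.dosages[:, 0], samples["glucose_int"],
                      samples["t"].to_numpy())
print(f"marginal p={res.p_main:.2f}  joint interaction p={res.p_joint:.2e}  "
      f"amplitude={res.amplitude:.3f}  acrophase={res.acrophase_h:.1f}h")

scan = dg.WindowedScan(binning="paper6").fit(geno, samples)
row = scan.results_.iloc[0]
print(f"morning beta={row['beta_[08:00,10:00)']:.3f}  "
      f"evening beta={row['beta_[18:00,20:00)']:.3f}  p_het={row['p_het']:.2e}")
```

Output (seed 1):

```
marginal p=0.56  joint interaction p=2.03e-48  amplitude=0.095  acrophase=7.8h
morning beta=0.078  evening beta=-0.099  p_het=3.41e-44
```

Read: the ordinary GWAS test sees nothing (p = 0.56) while the cosinor
interaction is overwhelming, the per-allele effect on the inverse-normal
scale is ≈ +0.08 SD in the morning bin and ≈ −0.09 SD in the evening bin,
and the heterogeneity test confirms the effect is not constant over the
day. The fitted acrophase (~08:00) matches the generating peak time.

The same analyses are available from the shell and compose through files:

```sh
diurnalgwas simulate --scenario mtnr1b_like --n-samples 50000 --seed 1 --out-prefix cohort
diurnalgwas adjust   --pheno cohort.samples.tsv --out adjusted.tsv
diurnalgwas cosinor  --vcf cohort.vcf --pheno adjusted.tsv --covariates sex,age --out cosinor.tsv
diurnalgwas windowed --vcf cohort.vcf --pheno adjusted.tsv --covariates sex,age --out-prefix win
diurnalgwas trajectory --vcf cohort.vcf --pheno adjusted.tsv --covariates sex,age \
    --phenotype-col glucose_raw --out-prefix traj
diurnalgwas stratify --vcf cohort.vcf --pheno adjusted.tsv --covariates sex,age \
    --phenotype-col glucose_adj --out strat.tsv
```

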