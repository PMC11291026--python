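# Methods

## Statistical models

### Cosinor genotype-by-time interaction

Time of day enters as the single-harmonic pair `sin(2πt)`, `cos(2πt)` with
`t` the fraction of the day elapsed since midnight at blood draw. The
per-variant model is

    y = α + Zγ + β_s sin(2πt) + β_c cos(2πt) + β_G G
        + β_GS G·sin(2πt) + β_GC G·cos(2πt) + ε

with `Z` the covariate design and `G` the allele dosage (used as-is, no
hard-calling). The environment main effects `sin`, `cos` are *always*
included in both modes: omitting them would let the interaction columns
absorb the population-level rhythm and invalidate the test. The default
test is the joint 2-df Wald chi-square `b̂ᵀV⁻¹b̂` on `(β_GS, β_GC)`; the
`separate` mode fits two models with one interaction term each and reports
per-term Wald p-values, for fidelity to association engines that accept a
single interaction covariate per run. Amplitude is `√(β_GS² + β_GC²)`;
acrophase is the clock time of the maximum positive per-allele effect,
`atan2(β_GS, β_GC)/2π · 24 h`. Any interaction of the single-harmonic form
can be written this way, so shifting the time origin by Δ is an exact
rotation of the coefficient pair: amplitude and the joint statistic are
invariant, and the acrophase shifts by exactly Δ (verified to 1e-6
relative).

### Windowed association, meta-analysis, heterogeneity

Samples are assigned to half-open clock-time bins `[start, end)`. Three
presets ship: `paper6` (six 2-hour bins, 08:00–20:00), `hourly` (ten
1-hour bins, 09:00–19:00) and `estbb24` (24 hourly bins); both of the
first two appear in the literature this design follows and neither is
privileged here. Each bin is fitted independently by OLS
(`y ~ covariates + G`), pooled by inverse-variance fixed-effect
meta-analysis (`w_k = 1/se_k²`), and tested for heterogeneity with
Cochran's Q against chi-square with `k−1` df. Fixed-effect (not
random-effects) pooling is deliberate: heterogeneity is the *object* of
the test, so the fixed-effect model is the natural null frame. I² is
reported as a descriptive companion. Bins below a minimum sample count
(default 50, and never fewer than columns + 11) are reported as unfit and
excluded from pooling.

### Spline trajectory test

Unadjusted glucose (mmol/L) is regressed on a fixed-df natural cubic
spline of `t` (knots at empirical quantiles; default df = 5), covariates,
genotype as a 3-class factor, and genotype-by-spline interaction columns.
The diurnal-genotype test is the nested-model F test of the interaction
block against the shared-curve null. Fixed-df splines with an F test were
chosen over penalised smoothing: the procedure is deterministic,
dependency-light, and df = 5 comfortably captures a one- or two-peaked
daily curve on a 12-hour support. Genotype is a factor (not a dosage) so
non-additive trajectories are representable. A homozygote class below
`min_class_n` (default 100) is folded into the heterozygotes (dominance
coding) with a warning. Curves are predicted at covariate means with
pointwise ±1.96 SE bands; extrapolation beyond the observed time support
is refused, since a natural spline is linear there and silently plausible-
looking.

Note on basis properties: the natural-spline space contains all linear
functions exactly but *not* general cubics (the natural boundary
constraints set second derivatives to zero at the boundary knots); tests
therefore check exact linear containment and 1e-3-level recovery of smooth
sinusoids, not cubic reproduction.

### Phenotype derivation

Raw biomarker → optional plausibility filter (off by default;
`(1, 15]` mmol/L for clinical-registry style glucose) → log transform →
one OLS residualization on a declarative covariate design → rank-based
inverse-normal transform. Covariates may be categorical (one-hot, first
sorted level dropped), continuous, or quantile-binned factors (rank-based
bins; ties share an average rank and land in one bin deterministically),
plus pairwise products of encoded blocks. Collinear columns are dropped by
pivoted-QR rank detection, earliest-column-wins, and recorded. The
inverse-normal transform uses the Blom offset,
`Φ⁻¹((r − 3/8)/(n − 2·3/8 + 1))` with average ranks for ties — the
GWAS-standard convention; the residualization source material does not
state an offset, so Blom is this package's choice. Because the log
transform turns scaling into an additive shift absorbed by the intercept,
the whole pipeline is invariant to the biomarker's measurement unit.

### Stratified contrasts and interaction tests

Morning (`< 11:00`) and evening (`≥ 17:00`) windows, optionally restricted
to samples fasting at least 6/8/12 h ("at least", cumulative), are fitted
independently; a sign flip of the per-allele effect across windows is
flagged. The genotype-by-sleep-trait test enters ordered trait categories
as factor indicators (not numeric scores — the category spacings are not
interval-scaled) and tests the `G × level` block with a joint chi-square,
also reporting the trait main effects. Variance explained by time of day
is the R² of an hourly bin factor (24 levels), reported for all samples
and the fasting subset.

### OLS engine

All tests reduce to one engine: complete-case filtering, pivoted-QR
collinearity handling, SVD least squares, model-based (homoskedastic)
covariance. Model-based rather than sandwich SEs are the one deliberate
methodological simplification relative to whole-genome-regression
pipelines; with unrelated simulated samples and Gaussian noise the tests
are equivalent, and an independent normal-equations oracle confirms
estimates and SEs to 1e-8 relative in the test suite. P-values that would
underflow are reported as log10(p).

## The synthetic cohort generator

The generator produces exactly the structure the analyses assume:

    log glucose = mesor + A_pop·cos(2πt − φ_pop)
                + G·(β_add + β_sin sin 2πt + β_cos cos 2πt)
                + covariate effects + N(0, σ²)

- **Genotypes**: hard calls under Hardy–Weinberg at the configured MAF
  (no LD, relatedness, or imputation noise — out of scope).
- **Draw times**: continuous seconds, uniform on a configurable window
  (default 08:00–20:00, the daytime concentration typical of assessment-
  centre cohorts; 00:00–24:00 for clinical-registry style scenarios).
- **Covariates**: sex, age, centre, array, 10 PCs, fasting hours
  (rounded gamma, mean ≈ 4.5 h), with mean-centred effects so the median
  trajectory is exactly `exp(mesor + rhythm)`.
- **Sleep traits**: six ordered categoricals with population-style
  frequencies, drawn independently of genotype by default; a
  `sleep_amp_factor` option scales the diurnal genotype effect within
  chosen trait levels for power studies.

Defaults: mesor = log(5.0) (≈ 5 mmol/L), population rhythm amplitude 0.03
log-units peaking at 10:00, residual σ = 0.10 log-units. The population
rhythm shape in real cohorts is only known graphically, so these are
configurable conventions, not calibrated estimates.

Named scenarios freeze the study conditions used throughout testing:

- **`mtnr1b_like`** — the diurnal-signature scenario. `β_add = 0`; the
  per-allele effect peaks at 08:00, which makes it integrate to ~0 over
  the 08:00–20:00 draw window — the condition under which a marginal GWAS
  is genuinely null while every diurnal test fires; amplitude solved
  exactly so homozygotes differ by 0.05 mmol/L at 09:00 on the raw scale
  (≈ 0.005 log-units per allele at the peak); MAF 0.3; σ = 0.05
  log-units, representing residual spread after covariate adjustment.
- **`variance_calibration`** — full-day window, no genetic or covariate
  effects, rhythm amplitude `σ·√2/3` so the rhythm accounts for exactly
  10% of variance (`A²/2 / (A²/2 + σ²)`); the hourly-bin R² recovers this
  within ±0.02 (binning attenuates the harmonic by sinc²(π/24) ≈ 0.997).
- **`constant_effect`** and **`null`** — positive and negative controls.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: LD and allelic heterogeneity, relatedness
and population structure, non-Gaussian residuals (postprandial glucose is
right-skewed beyond lognormal), meal-timing confounding between draw time
and fasting state, seasonal/annual structure, and any correlation between
sleep traits and draw time. The sign-reversal *signature* is therefore a
property of the method, demonstrated under its assumptions, not a
reproduction of any cohort-specific estimate.

## Numerical and calibration notes

- Reproducibility: one integer seed fans out to independent streams for
  genotypes, times, and phenotype; identical seeds give bit-identical
  cohorts, and scans are deterministic given inputs.
- Rank detection tolerance 1e-9 relative to the leading QR diagonal;
  dropped columns are recorded on every fit.
- Ties: average ranks everywhere (quantile bins, inverse-normal
  transform) for determinism.
- Cochran's Q uses estimated inverse-variance weights; with ~300 samples
  per bin its empirical size at the 5% level sits near 0.055 (2000-rep
  calibration runs) — the classical small-stratum behaviour of Q, inside
  the binomial 95% interval and left uncorrected.
- Acrophase precision depends on the interaction signal-to-noise: at
  amplitude/σ = 1 and n = 10⁴ (full-day window) the peak time is
  recovered within 30 clock-minutes essentially always; at the
  `mtnr1b_like` amplitude (interaction z ≈ 4–5 at n = 3×10⁴) it is only
  localised to a couple of hours.
- Problem sizes used by the test suite and acceptance script: 2000 null
  fits at n = 2000 for calibration; 20 seeds at n = 10⁵ for the
  signature; 200 replicates at n = 10⁴ for recovery; n = 6×10⁴ for the
  variance-explained calibration.

## Known limitations

- Single-harmonic cosinor only; multi-peaked effect profiles are visible
  to the windowed and spline tests but under-modelled by the cosinor scan.
- Quantitative traits only; no mixed models, Firth/score tests, or
  binary-trait interaction scans.
- The per-variant loop is plain Python over vectorised fits — adequate for
  thousands of variants, not for genome-wide dosage panels.
- The ambiguity of whether residualization should precede or follow
  ancestry-subsetting in the source procedure is resolved here by making
  the filter a flag on the adjuster rather than committing to one order.
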