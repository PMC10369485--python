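# Methods

## Generative model

The simulator produces case-ascertained parent–offspring trios plus an
unscreened population control pool.

**Genotypes.** Variants carry uniform allele frequencies on a configurable
range (default 0.05–0.5) and are grouped into LD blocks. Haplotypes are
drawn from a one-factor equicorrelated Gaussian per block (latent
correlation `within_block_r`, default 0.8) thresholded at the AF quantile,
which preserves marginal frequencies exactly while inducing positive LD
within blocks. Children inherit one parental haplotype per block
(recombination-free blocks), so Mendelian consistency holds by
construction and the blocks give clumping something real to remove.
Controls are founders drawn from the same distribution.

**Discovery weights.** The "GWAS" effect estimate for each variant is its
true weight plus N(0, `gwas_noise_sd`²) noise (default SD 1, i.e. a
noisy, realistically attenuated discovery study); the p-value is the
two-sided normal tail of the estimate over that SD, so significance
ordering follows |beta|.

**Liability.** With standardized polygenic values G (founder-referenced),
child liability is

    L = a·G_child + b·(G_father + G_mother)/√2 + e·ε,
    a = √h2_direct,  b = b_nurture,
    e² = 1 − a² − b² − √2·a·b   (Var L = 1; cov(G_child, midparent sum) = 1/√2)

Configurations where e² < 0 are rejected. Cases exceed the analytic
Gaussian quantile at 1 − prevalence (default 5%); the threshold is
analytic, not empirical, for reproducibility. Because `b_nurture` acts on
the *full* parental values, the nontransmitted half of parental liability
carries effect — this is what makes the pure-nurture configuration
(a = 0, b > 0) the positive control for the NT-versus-controls contrast
and a true null for the pTDT.

**Clinical phenotypes.** Symptom counts (hyperactive-impulsive,
inattentive, conduct), IQ, age, sex and SES binaries are generated with
fixed loadings on liability (e.g. severity = 0.6·L + 0.8·noise; IQ loads
−0.35 on L), chosen once to mimic a clinically ascertained ADHD-like
cohort: elevated hyperactive/conduct symptoms and below-average IQ among
ascertained cases, ~14% female, age ≈ N(10.4, 2.8). Low SES is drawn
independently of severity so that its configured missingness effect stays
a clean conditional parameter.

**Missingness.** Trio incompleteness follows a family-level logistic
model, log-odds = `missing_intercept` + `missing_beta_severity`·severity_z
+ `missing_beta_ses`·low_ses (defaults log 1.3 and log 2.35, the emulated
clinical magnitudes). Within incomplete families the father is the missing
parent ~97% of the time and the mother ~41% (at least one always),
mirroring the strong father-skew of clinical trio cohorts. A small
fraction (default 4.5% per parent) of provided samples fail genotyping;
genotypes of unavailable or failed parents are set to the missing
sentinel. The family-level draw (rather than two independent per-parent
logistic draws) makes the configured SES coefficient exactly the
generative incompleteness log-odds, so parameter recovery is well defined.

**Randomness.** All draws descend from a single seed through fixed
per-stage `SeedSequence` spawn keys; identical configurations give
byte-identical cohorts.

### What the generator does not emulate

Real genotyping error, imputation uncertainty, cryptic relatedness,
assortative mating, sibling environmental effects, X-chromosome loci, and
realistic effect-size/AF coupling are all absent. Passing tests therefore
demonstrate the *statistical machinery* — that the pipeline recovers known
direct and nurture effects, is calibrated under the null, and applies the
stated filters — not that any particular real-data effect size would be
reproduced.

## Trio status and parentage

Families partition into complete (both parents provided DNA and parentage
confirmed, regardless of later QC), incomplete (any parent without DNA)
and unclassified (DNA provided but genotyping failure — or a failed
check — prevented confirming parenthood). Parentage is confirmed by the
Mendelian-error rate: the fraction of fully observed loci whose
transmission is impossible, confirmed when ≤ 1% (default; an invented but
conservative threshold, since the error-free simulator gives true trios
rate 0 while unrelated substitutes show the analytic HWE expectation,
~7–8% at intermediate frequencies). Fewer than 50 informative loci gives
an indeterminate result. The transmission-analysis set additionally
requires all three members genotyped on one array and keeps only the
oldest proband per family, ties broken lexicographically by sample id for
determinism.

## Pseudo-controls

One composite NT pseudo-sample per trio (dosage arithmetic F + M − C)
rather than two phased pseudo-haplotype individuals: every downstream use
is an additive score, for which the composite is sufficient and exactly
linear, and it avoids phasing ambiguity. Mendelian-inconsistent triples
are nulled per locus (not per trio) to preserve sample size; the error
tally is reported per variant.

## Scoring

Clumping is greedy by ascending p-value (ties by variant id): each index
variant removes unretained variants within 250 kb whose squared
correlation in the control LD panel exceeds 0.1 (defaults; configurable).
Monomorphic variants get r² = 0 with a warning. Scores at the seven
default thresholds {5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5} sum
beta-weighted dosages; missing dosages contribute 2·(control AF)·beta.
The exact thresholds and clumping parameters of any given published
analysis are rarely stated in full; these defaults are explicit,
conventional stand-ins. PRS-PCA takes PC1 of the column-standardized score
matrix, sign-oriented to correlate positively with the mean standardized
column so that "higher = more aggregate liability" is stable. Scores are
standardized on the control mean/SD (control subset then has mean 0,
SD 1 to 1e-9) or z-scored when no controls are given.

Ancestry PCs are computed on centered/scaled founder dosages only and
offspring are projected onto the founder loadings — a deliberate,
documented substitution for kinship-aware PCA, which is out of scope; the
projection avoids the distortion families cause in a joint PCA. The top
10 PCs are residualized out of the scores (ordinary least squares with
intercept; rank-deficient covariates fall back to the minimum-norm
solution with a warning) before every analysis except the pTDT, whose
statistic is invariant to shared affine maps and robust to stratification.

## pTDT

Deviations use the sample (n−1) SD of the midparent distribution (the
divisor is not fixed by convention; n−1 is chosen and logged). Trios with
any missing member score are dropped listwise. Zero midparent spread is an
error (degenerate cohort); zero deviation variance flags the p-value as
undefined. Child and parent scores enter on a shared raw scale; whether
one standardizes them jointly beforehand is consequence-free because the
statistic is invariant to shared affine transforms.

## GEE comparisons

All contrasts use generalized estimating equations with an independence
working correlation and the cluster-aggregated sandwich variance
(statsmodels' GEE), so point estimates equal ordinary GLM solutions while
standard errors remain valid under within-family correlation. Wald 95%
intervals use 1.96. Trio-status contrasts are logistic with complete = 0
and incomplete = 1 (OR > 1 means more of the variable in incomplete
trios) and proband age as the default covariate; group-versus-control
score contrasts use the identity link with families as clusters and
controls clustering as themselves. A father group smaller than 20 is
skipped rather than compared (clinical cohorts rarely retain enough
fathers in incomplete trios for a meaningful contrast). Perfect separation
is reported as an explicit error (diverging coefficients), as is a
single-cluster design.

BH-FDR q-values are computed per analysis block (one block per results
table), not pooled across blocks; a per-run flag disables correction for
replication-style runs whose results are only read against the primary
analysis.

## Validation experiments and problem sizes

`triopgs.experiments` holds the end-to-end checks the test suite and
`scripts/acceptance.py` share:

* **Null calibration** — 1,000 replicates of 328 unascertained trios at 60
  variants each; any weighting is null without ascertainment, and the
  rejection rate at α = 0.05 is checked against [0.03, 0.07].
* **Discriminant validity** — full pipeline runs at 2,000 variants, 328
  trios, 2,000 controls with top-5% ascertainment: `h2_direct = 0.3`
  yields overtransmission with NT at control level; `b_nurture = 0.55`
  (a deliberately strong nurture effect — no consensus magnitude exists
  for a null-result construct) yields the reverse. Missingness is disabled
  there so the full 328 families reach the transmission analysis.
* **Missingness recovery** — 6,000 ascertained families (prevalence 0.3
  for generation efficiency; incompleteness does not depend on it) recover
  the configured low-SES odds ratio 2.35 by cluster-robust GEE.
* **Sandwich vs bootstrap** — 500 clusters of 3 with Gaussian-copula
  outcome correlation (marginally exact logistic, true OR 2) against a
  2,000-rep cluster bootstrap of GLM refits.
* **Composition margins** — a fixture (`triopgs.examples`, labelled
  synthetic) constructed so classification and filters yield 367 complete
  / 454 incomplete / 36 unclassified probands and 328 eligible trios after
  39 oldest-proband exclusions.

These sizes are the package's chosen validation conditions: large enough
that Monte-Carlo error is small against each check's tolerance, small
enough to run routinely.

## Known limitations

The control pool shares the simulated founder distribution, so no
ancestry mismatch between cohort and controls is represented; the PRS-PCA
component is computed jointly over all samples (cases, parents, NT,
controls) rather than per discovery phenotype; no genotyping-error model
means the parentage check's false-reject rate is effectively zero; and the
GEE father-skip threshold, Mendelian threshold and clumping defaults are
conventional choices, not estimates.
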