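# Methods

## The analysis

`gxescan` implements a genome-wide gene x environment (G x E) interaction
scan in which the environment is daily alcohol consumption (DAC, grams of
ethanol per day) and the outcomes are liver tests (LT): natural-log AST,
ALT and GGT, plus the raw AST/ALT ratio. For each variant with alt-allele
dosage G, the nested ordinary-least-squares models

    H0:  Y = b0 + bG G + bE E + C g
    H1:  Y = b0 + bG G + bE E + bGE G.E + C g

are fitted on identical rows (C: age, sex, BMI and the top five principal
components of the standardized dosage matrix), and the interaction
coefficient `bGE` is tested with the 1-df likelihood-ratio statistic under
the Gaussian likelihood with the variance profiled out:

    LRT = n log(RSS0 / RSS1)  ~  chi-square(1).

Per-cohort summary statistics are pooled by fixed-effect inverse-variance
meta-analysis (weights 1/SE^2) with Cochran's Q, I^2 and a heterogeneity
P-value, and genomic control is applied. Variants with corrected
P < 5e-8 are genome-wide significant and P < 1e-5 suggestive; suggestive
variants are greedily clumped into loci (lead = smallest P; members within
1 Mb and dosage R^2 >= 0.1, both configurable — the locus definition is a
package choice, since clumping rules are conventions rather than part of
the statistical model).

The same interaction machinery supports three sensitivity analyses:
dropping BMI (a heritable covariate, hence a potential collider), adding
G x {age, sex, BMI} and E x {age, sex, BMI} product terms to both nested
models, and sex-restricted scans (the sex covariate is dropped
automatically). Sex heterogeneity of an effect is tested by meta-analyzing
the male and female estimates of one cohort and reading Cochran's Q with
1 df.

### Numerical notes

- The genome scan projects all variant-independent columns (intercept,
  covariates, E) out of Y, G and G.E once per cohort by QR decomposition;
  per variant only closed-form 1- and 2-column regressions remain. This is
  algebraically identical to refitting both full models per variant, and a
  test asserts agreement with the `statsmodels` OLS route to 1e-6.
- A null model that fits to machine precision (zero-noise data) makes the
  profiled-variance ratio 0/0; the LRT is defined as 0 (P = 1) there.
- Monomorphic or collinear variants are flagged in the scan output, never
  silently dropped; single-variant fits raise a `CollinearityError` naming
  the offending column.
- Genomic control uses lambda = median(chi2) / median(chi-square 1 df)
  with a bootstrap percentile 95% CI over variants; correction divides
  statistics by max(lambda, 1), i.e. deflation only. By default it is
  applied at the meta-analysis stage only (corrected z^2); applying it
  per-cohort before pooling (SEs inflated by sqrt(lambda)) or at both
  stages is configurable, since either order is defensible and published
  pipelines differ.
- Missing dosages are handled complete-case per variant.

## Exposure harmonization

Questionnaire answers are converted deterministically: six frequency
categories map to 0/0.5/1.5/3.5/5.5/7 days per week; weekly beverage
volumes convert linearly to grams of ethanol from per-serving reference
contents (180 ml sake = 23 g, 180 ml shochu = 36 g, 180 ml chu-hai =
12.96 g, 633 ml beer = 23 g, 30 ml whisky = 10 g, 100 ml wine = 12 g);
WAC is the weekly sum, DAC = WAC/7, and standard drinks = DAC/14 g.
Subjects are stratified into five tiers by drinks/day: <0.1, [0.1,1),
[1,2), [2,3), >=3. Only status "current drinker" counts as exposed: any
other status forces DAC = 0 and tier 0 regardless of reported volumes
(the status field is authoritative).

Subject exclusions, in priority order (one primary reason recorded per
dropped subject): missing age/sex/BMI/alcohol/LT; any raw LT strictly
outside mean +/- 4 SD, with bounds computed per trait and per cohort on
the post-missingness sample and frozen (re-applying the filter with the
frozen bounds removes nobody, making the rule deterministic); flagged
liver illness. Whether the source screen was per cohort or pooled, raw or
log scale, is unstated; per-cohort raw-scale is this package's documented
choice. GGT/AST/ALT are then natural-log transformed; the AST/ALT ratio is
computed from the raw values and analyzed untransformed.

## Variant QC

Retained variants need call rate >= 0.95, Hardy-Weinberg exact-test
P >= 1e-6, MAF >= 0.01 and (when recorded) imputation R^2 >= 0.8; each
removal is logged with its first failing rule. The HWE exact test computes
the conditional null distribution of the heterozygote count given the
allele counts by a cumulative log-ratio recurrence and sums the
probabilities of outcomes no more likely than observed (plain exact, no
mid-P). The test runs on hard calls (rounded dosages); call rate and MAF
are computed on dosages — one pathway covering both array and imputed
data at package scale. Sample-level QC (call rate, sex mismatch, kinship,
ancestry) is out of scope; the synthetic cohorts are generated clean.

Principal components come from a randomized SVD of the per-variant
standardized, mean-imputed dosage matrix, with a deterministic sign
convention (largest-magnitude loading positive) and zero-variance
components flagged degenerate.

## Stratified (bar-plot) analysis

For the representative variant of the top locus, each raw-scale LT is
regressed on age, sex, BMI and genotype dosage over GG/GA subjects
(minor-allele homozygotes excluded as rare), and the adjusted value is the
grand mean plus the residual — so adjusted values average exactly to the
raw mean. Within each genotype group the across-tier trend uses the
Jonckheere-Terpstra test (two-sided by default; the published trend is
directionless) and each tier is compared with tier 0 by Wilcoxon's
rank-sum test with star bands at 0.05/0.01/0.001. The JT statistic is the
sum of pairwise Mann-Whitney counts (ties counted 1/2); P comes from
exhaustive enumeration over group assignments when total n <= 12 and the
arrangement count is tractable (<= 200,000), otherwise from the normal
approximation with the tie-corrected variance. The rank-sum test is exact
for small tie-free samples and otherwise uses the normal approximation
with tie and continuity corrections; fully tied samples return P = 1.
Means are arithmetic means of adjusted raw-scale values (back-transformed
log-scale means would be an alternative reading; this choice is
documented, not derivable from the source).

## Power simulation

Each iteration draws, for two cohorts of 3878 and 3978 subjects, exposure
E ~ Normal(11.9, 23.2) and Normal(10.5, 21.1) g/day with negative draws
truncated to 0 (the truncation rate is reported), genotype G ~
Binomial(2, MAF) with MAF in {0.2, 0.5}, and

    LT = bE E + fold * bE * G.E + noise,   fold in {0.25, 0.5, 1.0, 2.5}.

The interaction is fitted per cohort, meta-analyzed, and a hit recorded
when pooled P < alpha (default 1e-5, the suggestive level); power is the
hit rate over 1000 iterations. Two deliberate additions to the emulated
procedure: Gaussian noise (default SD 0.5 on the log-trait scale) because
the noiseless model makes the test degenerate, and an explicit default
bE = 0.005 per g/day because the emulated procedure estimated bE from
cohort data without publishing it — both are exposed parameters, and
reported powers are conditional on them. All folds at one MAF share a
random stream (the draws do not depend on the fold), so the power curve
is monotone in fold up to boundary noise rather than resampling noise.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes,
with two sub-cohorts (defaults: n = 3878/3978; female fraction 0.640/
0.683; age 63.1 +/- 9.9 / 59.5 +/- 11.9 y; BMI 23.4 +/- 3.4/3.5 kg/m^2;
current-drinker fraction 0.442/0.480).

Genotypes: one causal biallelic variant at MAF 0.18 on 12q24 is drawn as
two haplotype allele vectors; each of the (default 3) LD partners copies
those haplotypes and resamples each allele with probability
eps = 1 - sqrt(target R^2), giving dosage correlation 1 - eps, with
targets drawn from [0.62, 0.95]. Background variants are independent
binomials at MAFs uniform on [0.05, 0.5]. All variants are generated
under Hardy-Weinberg.

Exposure: the drinker probability is allele-aware — multiplied by 0.7 per
causal alt allele, emulating behavioural avoidance of alcohol by
intolerant carriers; the magnitude is a placeholder (the avoidance effect
is qualitatively documented but unquantified) and must stay modest or the
heterozygote drinker strata empty out. Drinker daily intake is log-normal
(median 16 g/day, sigma 0.9), chosen so the cohort-level mean and SD of
DAC land near 11-12 +/- 21-23 g/day at ~45% drinker prevalence. Weekly
grams are split 80/20 over a primary and secondary beverage and converted
to volumes, so the harmonization pipeline recovers the latent intake
exactly; the drinking-frequency answer is sampled independently of volume
(a simplification: real frequency and volume correlate).

Phenotypes, on the natural-log scale:

    log T = center + age, sex, BMI effects + bE E + bGE G.E . s(sex) + noise

with defaults bE = {ALT 0.0008, AST 0.0015, GGT 0.006} per g/day,
bGE(ALT) = -0.011 per g/day per alt allele in men and s(female) = 0.5 —
together these give heterozygote drinkers a ~20% ALT reduction at tier 3
once the sex mix is accounted for, and a much larger male than female
interaction. bGE(AST) = -0.0015 cancels the AST alcohol effect in
carriers, so heterozygote AST is flat in drinking while the GG AST trend
remains; bGE(GGT) = 0. AST and ALT noise share correlation 0.5 (both
hepatocellular enzymes), which also keeps the AST/ALT ratio's dispersion
realistic; the ratio is never simulated directly — it derives from the
two simulated traits. Gaussian noise SDs (log scale): ALT 0.40, AST 0.30,
GGT 0.55. A configurable fraction of subjects (default 2%) loses one
required field at random and 3% carry a liver-illness flag, exercising
the exclusion machinery.

What the generator does **not** emulate: genome-wide LD structure beyond
the planted partners, imputation uncertainty (dosages are hard calls),
population stratification (PCs are estimated but carry no confounding
signal by default), frequency-volume correlation, non-Gaussian trait
tails beyond log-normality, and relatedness. Passing end-to-end tests
therefore demonstrates the statistical machinery under the assumed model,
not robustness to those real-data features.

## Problem sizes used in the shipped tests

The test suite exercises the pipeline at the sizes the package targets
for routine use: null calibration at one cohort of 7856 subjects x
10,000 variants; parameter recovery over 50 replicates of n = 8000 at
the causal variant; the end-to-end rediscovery run at the default two
cohorts x 5000 variants; power grids at reduced cohort sizes (2 x 1000)
and 400 iterations. Larger runs are configuration changes, not code
changes.

## Known limitations

- Fixed-effect meta-analysis only; no random-effects model, no
  sample-overlap correction.
- No robust (sandwich) standard errors: heteroskedasticity induced by a
  true interaction inflates the genome-wide null (visible as lambda > 1
  for ALT and the AST/ALT ratio in the shipped end-to-end run) and is
  handled by genomic control rather than modelled away.
- Strand-ambiguous (A/T, C/G) variants are flagged during cross-cohort
  allele alignment, not resolved.
- Exact Jonckheere-Terpstra enumeration is capped by arrangement count;
  very unbalanced many-group layouts at n <= 12 fall back to the normal
  approximation.
- The adjustment regression codes genotype additively (dosage restricted
  to GG/GA); a genotype-indicator coding would differ only via the
  excluded AA group.
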