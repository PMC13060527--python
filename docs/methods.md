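# Methods

## The model

Each analysis slice regresses a blood-pressure trait Y (SBP, DBP, or pulse
pressure, mmHg) on genotype dosage G in [0, 2], a binary alcohol-exposure
indicator Alc, their product, and covariates C:

    E(Y) = b0 + bAlc*Alc + bG*G + bGxAlc*(G x Alc) + bC*C          (Model 1)
    E(Y) = b0 + bG*G + bC*C                                        (Model 2)

fitted by ordinary least squares with model-based (homoscedastic)
covariance. The 1df interaction test is the Wald chi-square of bGxAlc; the
2df joint test is

    chi2_2df = (bG, bGxAlc) Omega^-1 (bG, bGxAlc)^T,

with Omega the 2x2 covariance of the pair, significant when either the main
or the interaction effect is present. Model 2 supplies the marginal
association used by the two-step screen. Wald p-values use the
normal/chi-square approximation rather than t/F; at GWAS sample sizes the
difference is negligible, and it matches the convention of the
meta-analysed summary statistics the pipeline exchanges.

Fitting across many variants uses the Frisch-Waugh-Lovell decomposition:
the fixed design (intercept, Alc, covariates) is residualized out of Y, G,
and G x Alc once per slice via a QR factorization, leaving a 2x2 solve per
variant. Coefficients, standard errors, and cov(bG, bGxAlc) are exactly
those of the full OLS fit (verified against a generic least-squares solver
to 1e-8 relative in the tests). A variant is skipped, with a recorded
reason, when its dosage is (near-)constant overall or within either
exposure stratum, or when the 2x2 system is numerically singular; both
stratum-constant cases make the design exactly collinear.

## Synthetic cohorts

The simulator generates the structures the analysis assumes, not realistic
genomes:

* **Genotypes.** Hard genotypes are Binomial(2, f) per variant
  (Hardy-Weinberg, no LD); variants are placed 1 Mb apart across 22
  chromosomes so they are unlinked and clump-separable. Imputation noise is
  a convex blend of the hard genotype with an independent draw from the
  same law; the blend weight w solves corr^2(dosage, hard) = R2, namely
  w = s/(1+s) with s = sqrt(R2/(1-R2)). Dosages therefore stay in [0, 2]
  and the achieved quality matches the target in expectation.
* **Exposure.** Drinks per week are a sex-specific two-part mixture: a
  point mass at zero (default 40% of females, 25% of males) and a
  lognormal among drinkers (medians 4 and 7 drinks/week). With the
  default parameters roughly a fifth of drinkers of each sex exceed the
  heavy-drinking cutoff, a plausible mid-risk cohort.
* **Blood pressure.** Latent SBP is the Model 1 linear predictor (age,
  age^2, sex, exposure, per-variant main and interaction effects) plus
  Gaussian noise (default SD 15 mmHg); DBP reuses the shared terms scaled
  by 0.6 with its own noise (SD 10). The exposure entering the generative
  interaction is the binary indicator of a designated contrast (default
  CURDRINK, i.e. dpw >= 1).
* **Medication.** Treatment probability is logistic in latent SBP centred
  at 140 mmHg; treated individuals' observed BP is reduced by 20/12 mmHg
  (SBP/DBP). Because the analysis adds back only +15/+10, the adjustment
  is a partial correction, as it is in practice. The true reduction is not
  identified by the analysis and is configurable.

All randomness flows from one `numpy` generator in a fixed draw order
(sex, age, drinks, hard genotypes, dosage noise, SBP noise, DBP noise,
medication), so a configuration is a complete, bit-reproducible
specification of a cohort.

What the simulator deliberately omits: LD structure (beyond what a test
constructs explicitly), realistic allele-frequency spectra, relatedness and
family structure, the X chromosome, population stratification, and
missing data. Passing tests therefore demonstrate the statistical
machinery — estimator correctness, calibration, pooling identities,
screening logic — not robustness to confounding or cryptic structure in
real cohorts.

## Harmonization

Order of operations: medication adjustment (+15 mmHg SBP, +10 mmHg DBP for
treated individuals) -> pulse pressure = SBP_adj - DBP_adj -> exclusion of
very heavy drinkers -> 6-SD winsorization of each trait. Winsorization uses
sex-combined moments of the cohort being processed; its position after the
exposure exclusion keeps the capping moments free of rows that never enter
any analysis. The very-heavy rule drops individuals with dpw >= mean + 6 SD
where the moments are computed among current drinkers (dpw >= 1), in the
individual's sex stratum or sex-combined, on the pre-exclusion sample; with
the zero mass of abstainers included, the SD would be dominated by the
mixture and the rule would essentially never fire.

Exposure contrasts: never (<1 dpw), light (1-7 dpw females, 1-14 males,
boundaries inclusive), heavy (above light). CURDRINK codes current drinkers
(dpw >= 1) against everyone else; the pairwise contrasts exclude the third
category. Standard-drink conversion supports fl oz + ABV, grams of
ethanol, and ml + ABV (volume x ABV x 0.78945 g/ml / 14 g).

## Quality control and genomic control

Variant filters: imputation quality < 0.5, and MAC x R2 < 20 in the
exposed, unexposed, or total sample (MAC computed from dosages as
sum min(d, 2-d), never rounded). Slice filters: fewer than 100 individuals
or fewer than 50 in either exposure arm.

The genomic-control inflation factor is the median 1df Wald chi-square
divided by 0.45494 (the chi-square(1) median, fixed to 5 decimals). Lambda
is estimated separately for the interaction test, the genetic main effect,
and the marginal test of each file; where lambda > 1 the corresponding SEs
are inflated by sqrt(lambda) and p-values recomputed (no deflation when
lambda < 1). The 2df statistic is then rebuilt from the corrected
components, with cov(bG, bGxAlc) scaled by sqrt(lambda_G x lambda_int) so
the correlation structure of the pair is preserved. After correction the
recomputed lambda is exactly 1 by construction.

## Meta-analysis

Fixed effects only. The 1df interaction and marginal effects are pooled by
inverse-variance weighting; the (bG, bGxAlc) pair is pooled by
inverse-covariance weighting (precisions add; the pooled 2df Wald
chi-square uses the pooled precision). Cochran's Q on the interaction
effect quantifies heterogeneity across studies and, at the second stage,
across populations. Population-level records carry the IVW interaction
estimate (for the 1df test) and, separately, the joint-pooled interaction
component with its covariance (for the 2df stage); the cross-population
meta-analysis pools population records with the same estimators, which
makes one-population CPMA an exact identity. Cohort effect alleles are
aligned to the first cohort's orientation (effect signs and EAF flipped on
a swap; the main/interaction covariance is invariant under the joint
flip); strand-ambiguous A/T and C/G variants are kept but logged. At least
two studies must contribute to a variant within a population.
Reportability thresholds: N > 5,000 (AFR, BRA, HIS, SAS), N > 20,000
(EUR, EAS), and for CPMA N > 20,000 with at least two populations.

## Discovery

* **Tier A**: interaction P < 5e-8 and Benjamini-Hochberg FDR < 5% within
  the scan (one scan = one population x trait x contrast x sex group).
* **Tier B**: two-step screen — variants with marginal P < 1e-5 are tested
  for interaction at 0.05/Meff plus FDR < 5% among the screened set. Meff
  is the simpleM-style effective number of tests: the smallest count of
  leading eigenvalues of the screened variants' dosage-correlation matrix
  reaching 99.5% of total variance (threshold configurable); screened
  variants missing from the reference panel count as independent tests.
  The screen is valid because the marginal and interaction statistics are
  (approximately) uncorrelated under the null, which the tests check
  empirically.
* **Tier C**: among clumped loci with genome-wide significant 2df joint
  effects (M_2df of them, counted per scan), leads with interaction
  P < 0.05/M_2df.
* **Tier D**: 2df-significant leads without interaction evidence
  (interaction P > 0.05 by default; a switch uses 0.05/M_2df instead, as
  the two conventions differ).

Clumping is greedy by ascending p-value (ties: smaller position, then
allele): a variant joins the first locus whose lead it is correlated with
(r2 >= 0.1 in the reference dosage panel); a variant with no usable r2
joins a locus whose lead is within 500 kb on the same chromosome, else
founds a new locus. A locus is novel iff every member is more than 500 kb
from every cataloged variant (the 500 kb bound itself counts as near) or
in linkage equilibrium (r2 < 0.1) with all cataloged variants nearby; a
nearby catalog variant with unknown r2 renders the locus known
(conservative). Sex heterogeneity uses the two-sample Z-test
(beta_M - beta_F)/sqrt(se_M^2 + se_F^2) with Bonferroni correction over
the tested leads; the effect decomposition reports the unexposed effect
b0 = bG, the exposed effect b1 = bG + bGxAlc with
Var(b1) = se_G^2 + se_int^2 + 2 cov, and their ratio (the fold-change of
the genetic effect under exposure). The enrichment of nominal interactions
among a set of loci is the one-sided exact binomial tail P(X >= k),
X ~ Binomial(n, 0.05), evaluated through the regularized incomplete beta
function so far tails (1e-40) are exact.

## Problem sizes and numerical conventions

The test suite and the acceptance script run everything at desk scale:
null calibration uses 2,000 independent variants in a 1,500-person cohort;
genomic control uses a 5,000 x 5,000 null cohort; meta-vs-mega uses three
homogeneous 5,000-person cohorts; fold-change recovery uses 100 replicates
of a 50,000-person cohort with one causal variant (frequency 0.25,
bG = 0.35, bGxAlc = 1.75, i.e. a generative fold of 6 with an exposed
effect of ~2 mmHg per allele, the magnitude of the strong East-Asian
12q24 signals). The demo pipeline (six cohorts in two populations, 2,000
variants) plants one deliberately exaggerated causal variant (bG = 2,
bGxAlc = 6 mmHg) so a discovery is visible at these sample sizes; real
effect sizes would require consortium-scale N.

Numerical conventions: positions are 1-based and distance bounds
inclusive; dosages are never rounded; the chi-square(1) median constant is
0.45494; clumping ties break deterministically; fold-change is undefined
(NaN) when |b0| < 1e-12; degenerate inputs (zero-variance winsorization,
single-study Cochran Q, empty scans) return unchanged data or missing
values rather than raising.

## Known limitations

Relatedness (mixed models), X-chromosome analysis, score tests,
random-effects meta-analysis, sample-overlap correction, conditional
secondary-signal analysis, and annotation/druggability layers are out of
scope. The LD reference panel is the simulator's own dosage matrix; real
panels with strand flips and missing variants would exercise the
allele-harmonization and fallback paths more heavily than the synthetic
data can.
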