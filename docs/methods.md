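# Methods

This note documents the statistical models behind `cgstats`, the
conventions and numerical choices the implementation makes where several
are defensible, and what the synthetic-data generator does and does not
emulate.

## Hardy-Weinberg departure

Departure at a biallelic locus is measured by

    f = (p_CC − p_C²) / (p_C (1 − p_C)),

where p_C is the frequency of the reference allele C and p_CC the
frequency of the C/C homozygote.  f = 0 at Hardy-Weinberg proportions,
f < 0 under heterozygote excess, f > 0 under heterozygote deficiency; at
allele frequency p the feasible range is max(−p/(1−p), −(1−p)/p) ≤ f ≤ 1.
f is undefined at a monomorphic locus and the estimator refuses such
input rather than returning a sentinel.  The associated test statistic is
the exact identity χ² = n·f², which equals the usual 1-df Pearson HWE
chi-square.

Two p-values are reported.  The asymptotic one is the χ²₁ upper tail.
Because genotype counts in groups of a few hundred make that tail
approximate, a numeric null is also computed: M parametric multinomial
draws of n genotypes from HW proportions at the *estimated* allele
frequency, each reduced to its own n·f̂², with the add-one empirical
p-value (r+1)/(M+1).  The parametric (rather than permutation) null is
the natural choice for a one-sample test; M defaults to 10,000.  Draws
that come out monomorphic carry no evidence of departure and enter the
null with statistic 0, which is conservative.

The CI for f is a subject-level nonparametric percentile bootstrap
(default B = 10,000): subjects' genotype categories are resampled with
replacement and f re-estimated; monomorphic resamples are redrawn (an
error is raised if more than half of attempts fail).  A bootstrap is used
because no exact interval for f is standard at these sample sizes; the
coverage of the interval at n ≈ 336 is verified by simulation in the test
suite (≥ 90/100 replicates).

## Case-control association

The hypothesis that cases and controls share one genotype distribution is
tested by Pearson χ² on the 2×3 table; genotype classes empty in both
groups are dropped and the df reduced.  For small tables an empirical p
referred to M multinomial draws under the pooled genotype distribution is
available through the same add-one rule.

The additive (per-allele) model is realised as the allelic 2×2 odds
ratio: each subject contributes two alleles, OR = (a·d)/(b·c), with the
Woolf log-scale 95% CI, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  When any
cell is zero the Haldane-Anscombe 0.5 correction is applied to all four
cells and flagged on the result.  A Cochran-Armitage trend test with
scores (0, 1, 2) is provided as the alternative reading of "additive";
the two agree closely except under strong HWE departure, and the allelic
OR is the default because an odds ratio with a CI is the effect measure
the analysis reports.

Stratified analysis collapses the HLA-DRB1\*15:01 dose to carrier
(dose ≥ 1) versus non-carrier and repeats the association tests within
each stratum; empty strata yield a missing result with a warning, strata
under 10 subjects are logged as small.  Covariate-adjusted logistic
regression is deliberately out of scope — the pipeline reports unadjusted
ORs per stratum.

## Haplotype estimation and testing

For two biallelic SNPs the four haplotypes (AB, Ab, aB, ab) induce nine
unphased genotype classes; only the double heterozygote is
phase-ambiguous, with class probability 2·h_AB·h_ab + 2·h_Ab·h_aB.  The
EM estimator starts at linkage equilibrium (products of observed allele
frequencies), splits the double-heterozygote count each E-step in ratio
h_AB·h_ab : h_Ab·h_aB, and renormalises expected haplotype counts each
M-step.  Convergence is declared when the log-likelihood gain falls below
1e-10 (at most 1,000 iterations); iteration count, convergence flag and
the per-iteration log-likelihood trace are returned, and the likelihood
is asserted non-decreasing.  The log-likelihood is the multinomial kernel
Σ n_c log P_c (no combinatorial constant), so it scales linearly in the
counts and a class observed with zero induced probability yields −∞
explicitly.

One degenerate input needs a documented tie-break: data consisting solely
of double heterozygotes, where the likelihood has two symmetric ridges
(all-cis, all-trans) and the LE start sits exactly on the saddle.  The
start is perturbed by +1e-6 toward the cis configuration and the result
flagged `tie_broken`.

Group differences are tested by LRS = 2(LL_cases + LL_controls −
LL_combined) with df = 3 (four haplotypes minus one), p from the χ²₃
tail.  Values in (−1e-9, 0) from finite EM tolerance are clamped to zero;
anything more negative raises, since the pooled fit can never beat the
sum of group fits.  Generalisation beyond two SNPs is out of scope; the
9-class decomposition is hard-coded and exhaustively testable.

LD is reported as D = h_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)) and
D′ = D/D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A·p_B, (1−p_A)(1−p_B)) for D < 0.

## Power

Power of the 1-df allelic χ² test uses the noncentral chi-square: with
control MAF p₀ and per-allele OR, the case allele frequency is
p₁ = OR·p₀/(1−p₀+OR·p₀); the noncentrality is
(p₁−p₀)² / (p̄(1−p̄)(1/(2N_ca)+1/(2N_co))) with p̄ the pooled allele
frequency, and power is the probability the noncentral χ²₁ exceeds the
central critical value.  The approximation is validated against a
10,000-replicate Monte-Carlo oracle (±0.02) in the test suite.  Note the
formula conditions on allele counts being binomial, i.e. it assumes HWE
within groups.

## Expression arm

Replicate Cts are averaged per (subject, gene) *before* the exponential
transform; pairs with replicate SD above a threshold (default 0.5
cycles), or resting on a single replicate, are flagged but never silently
dropped.  Relative expression is 2^−ΔCt = 2^−(Ct_target − Ct_ref),
computed separately against HPRT and GAPDH; no inter-plate calibrator
normalisation and no amplification-efficiency correction is modelled.
Group summaries are median, Q1/Q3 (linear interpolation between order
statistics), min, max, and the Sn robust scale

    Sn = med_i { med_j |x_i − x_j| },

the inner median running over all j = 1..n including j = i.  Sn is
reported uncorrected by default (it is then a typical difference between
two randomly chosen observations); the 1.1926 normal-consistency factor
is available behind a flag.

## Multivariate tests

The bivariate vector (2^−ΔCt vs HPRT, 2^−ΔCt vs GAPDH) is compared
between groups with Hotelling's T² using the pooled covariance; the exact
conversion F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)) with df (p, n₁+n₂−p−1) supplies
the p-value, and both the T² and F forms are reported to avoid ambiguity
between the two conventions.  With a univariate response the F equals the
squared pooled-variance t.  A pooled covariance with condition number
above 1e12 is treated as singular and rejected with a pointer to check
for collinear responses.

Multi-factor designs (genotype, HLA status, sex, disease status) use a
Pillai-trace MANOVA, V = tr(H(H+E)⁻¹), with *sequential* (type I) sums of
cross products in a configurable term order, and the standard F
approximation F = (df₂/df₁)·V/(s−V) with s = min(p, q),
df₁ = s(2m+s+1), df₂ = s(2n'+s+1), m = (|p−q|−1)/2, n' = (ν_E−p−1)/2.
For a single two-level factor Pillai and Hotelling give identical
p-values (verified exactly in tests, as is agreement with statsmodels'
MANOVA on multi-factor designs).  Disease-progression analysis treats
(EDSS, MSSS) exactly as the expression pair.  Any test can attach a
permutation p-value (response rows shuffled against the design, add-one
rule).

Age-of-onset contrasts use the classical one-way ANOVA F with df
(k−1, n−k).

## Synthetic cohorts

The generator's defaults describe the study conditions the pipeline is
meant for: 336 cases / 322 controls in the association arm, 39/40 in the
expression arm, control haplotype frequencies (0.03275, 0.08725, 0.10725,
0.77275) — minor-allele frequencies 0.12 and 0.14 with r² ≈ 0.02, i.e.
essentially unlinked candidate SNPs — per-allele ORs of 1.0 (the null the
study could not reject), an HLA-DRB1\*15:01 carrier frequency of 0.24
with carrier OR 2.66, and a −0.5 log2 case shift in expression.
MAF 0.12 at these group sizes gives the allelic test ≈ 84% power against
OR 1.59 and ≈ 30% against OR 1.26, matching the scale of sensitivity such
a study has.

Sampling is retrospective, as in a case-control design: controls draw two
haplotypes from the control frequencies; case genotype probabilities are
the control probabilities tilted by OR^(risk-allele dose) per SNP and
renormalised, which keeps the per-allele OR the estimand of the allelic
2×2 table.  The HLA dose is drawn from HW proportions implied by the
carrier frequency and tilted the same way for cases.  Haplotype-pair
sampling is HWE by construction, so a nonzero within-locus departure
`hwe_f` switches that group to independent per-SNP genotype draws with
P(CC) = p² + f·p·q, P(Cc) = 2pq(1−f), P(cc) = q² + f·p·q — in that mode
the two SNPs are generated independently (no LD).

Expression is lognormal (multiplicative on 2^−ΔCt): the target gene's
true Ct is a baseline (25 cycles) plus N(0, expr_sd²) biological noise,
shifted by −expr_log2_shift for cases; reference genes sit at fixed means
(22, 18 cycles); every replicate of every gene adds technical noise with
SD expr_sd/2, so expr_sd = 0 produces identical triplicates.  A
multiplicative model was chosen because qPCR quantities are inherently
exponential in Ct; the split of one noise parameter into biological and
half-sized technical components is a modelling convenience, not a claim
about any instrument.  Clinical scores (EDSS, MSSS, age of onset, RR
duration) are independent truncated normals/exponentials attached to
cases only — placeholders with realistic ranges, not a disease model.

The generator does **not** emulate: genotyping error or missingness
(missing data handling is tested through the IO layer instead),
population stratification, covariance between clinical scores and
genotype, plate effects or amplification-efficiency differences in qPCR,
or methylation data.  Passing tests therefore demonstrate correctness of
the estimators and calibration of the tests under clean, well-specified
sampling — not robustness to the artefacts of real laboratory data.

Reproducibility: each cohort uses one `numpy` Generator keyed by `seed`;
the expression simulator spawns one child stream per subject from the
seed, so subsetting a cohort leaves the remaining subjects' Ct values
unchanged.

## Numerical conventions

- Empirical p-values always use the add-one rule (r+1)/(M+1), ties
  counting as extreme; p is never exactly 0.
- Tail probabilities come from scipy's `chi2.sf` / `f.sf` (verified
  against numerical integration to 1e-8 in the tests).
- Quartiles use linear interpolation between order statistics
  (`numpy.percentile` default).
- Genotypes are unordered allele pairs with a canonical sorted
  representation; "G/A" and "A/G" are one heterozygote.
- Subjects missing a genotype are excluded per locus, per analysis, with
  counts logged; they are never imputed.
- Test problem sizes (replicate counts for null calibration, bootstrap
  sizes in coverage checks) are chosen so the full suite completes in
  well under a minute per file while keeping binomial error bands tight
  enough to detect real miscalibration.
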