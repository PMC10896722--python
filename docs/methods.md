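# Methods

`rvarch` analyses the genetic architecture of a case-control disease
cohort in which both rare coding variants (aggregated per gene) and
common variants contribute risk. The motivating setting is a
youth-onset type 2 diabetes cohort of 3,005 cases matched to 9,777
external adult controls across ancestry clusters, compared against a
much larger adult-onset study with which it shares controls. This note
documents the models, the estimators, the synthetic-data generator, and
the numerical choices; it states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

`synthetic.simulate_cohort` draws individuals from a finite background
population under a latent-liability threshold model. Liability is

    L = sum(genetic effects) + cluster offset + e,

disease occurs when `L` exceeds the `(1 - K)` quantile of the noise
distribution, and `K = 0.08` (8% prevalence) by default. The noise `e`
is **standard logistic** and the threshold is `logit(1 - K)`. This is a
deliberate choice: with logistic noise, a carrier effect `b` on the
liability is *exactly* the conditional log-odds-ratio of disease for
carriers, so the generator's declared effects live on the same scale the
Firth logistic association and burden modules estimate. With Gaussian
noise the generating scale and the estimated scale differ by a
prevalence-dependent factor (a liability effect of 1.0 at K = 0.08
implies a log-OR near 1.8), which would make "simulate log-OR b,
recover b" tests meaningless without an extra conversion layer.

Rare variants are grouped into genes; each variant belongs to one of the
seven deleteriousness strata (below) and contributes its gene-mask
effect once per carrier (dominant carrier coding, matching the carrier
aggregation of a burden test). Common variants contribute additively
per allele. Population structure is controlled by per-cluster
allele-frequency multipliers, optional cluster liability offsets
(default 0), and PC surrogates drawn around cluster centroids.
Case/control sampling is by rejection from a background population
capped at 50x the requested cohort; an unattainable case count raises an
error rather than silently resampling.

Defaults mirror the target study: 3,005 cases, 9,777 controls, K = 0.08,
and (when no panel is specified) 20 null genes of 8 rare variants each
plus five common variants with modest odds ratios (OR 1.1-1.3). The
generator reproduces the marginal prevalence, per-cluster MAFs, null
calibration of downstream tests, and recovery of spiked effects — it
does **not** emulate linkage disequilibrium, haplotype structure,
sequencing error, missingness or genotype-quality processes (QC fields
that depend on those processes are inputs, set to passing values for
simulated data). Passing tests therefore validate the statistical
machinery, not robustness to artefacts real exome data can carry.

`spike_truth` re-draws phenotypes Bernoulli-conditionally on the
modified linear predictor; case/control counts become random, which is
intended (the function exists for direction/recovery experiments, not
for re-balancing a fixed design).

## Variant QC

Six rules (thresholds are the package defaults): differential
missingness P >= 1e-4; Hardy-Weinberg P >= 1e-4; a genotype-quality /
call-rate branch (GQ >= 95 with CR >= 0.95, or GQ < 95 with CR >= 0.99
and both P values >= 1e-3); a read-depth branch (depth >= 50, or the
four P values — missingness, HWE overall/in cases/in controls — all
>= 1e-3); Firth P >= 0.05 x Fisher exact P; and a gnomAD random-forest
pass flag (an input column). Both small-count tests are exact:
differential missingness uses Fisher's exact test on the called/missing
2x2 table, and HWE uses the exact conditional distribution of the
heterozygote count given the allele counts (plain P, no mid-P). Missing
fields fail the branch that consumes them; filtering is idempotent and
per-rule monotone.

## External-control matching

Samples are clustered on genetic PCs with Gaussian mixtures (full
covariance, model order by BIC up to `max_k`). Within a cluster,
prospective controls are ranked by the Euclidean norm of their residual
after projection onto the span of the top right-singular directions of
the standardized case genotype matrix (standardization: case mean/SD per
variant; `k` defaults to the smallest number of directions explaining
90% of squared singular values). Control selection scans 100 quantiles
of the residual-norm distribution from most to least inclusive and
returns the largest set whose case-vs-controls null scan has genomic
inflation lambda < 2.0 with more than a minimum number of controls
(default 500; exposed as a parameter so the logic is testable at small
n). Lambda is `median(chi2) / 0.455`; the built-in null scan is a
per-variant allele-count chi-squared, which is fast and adequate for a
gate, but any per-variant test can be injected.

## Single-variant association and meta-analysis

Firth's penalized logistic regression maximizes the log-likelihood plus
`0.5 log det(X'WX)` (Jeffreys prior) by Newton scoring with
step-halving; convergence when every component of the modified score is
below 1e-6, cap 100 iterations. P values come from the penalized
likelihood-ratio test in its **profile** form: the tested coefficient is
constrained to zero while the penalty keeps the full design's
information determinant. This matters — comparing penalized likelihoods
across designs of different dimension offsets the statistic by the
penalty difference and badly inflates the null; the profile form is
calibrated (null KS P = 0.25 over 400 low-carrier-count replicates in
the test suite).

Covariates (PC1-PC10, cluster indicators) are pre-screened by univariate
logistic P < 0.005. Monomorphic variants are skipped with a reason;
variants with fewer than two carriers are tested but flagged
low-confidence. Per-cluster estimates are combined by fixed-effects
inverse-variance weighting (`w = 1/SE^2`), with two-sided normal P;
heterogeneity is not modelled. Significance flags: coding P < 4.3e-7,
non-coding P < 5.0e-8 (strict).

## Gene-level burden testing

Variants are assigned first-match-wins to seven mutually exclusive
strata ordered from most to least stringent: LOFTEE high-confidence LoF;
all 16 predictor calls; 11 of 11; 5 of 5; low-confidence LoF /
high-impact at max MAF < 1%; >= 1 of 5 at moderate impact and MAF < 1%;
0 of 5 at moderate impact and MAF < 1%. Mask `m` aggregates strata
`1..m` (nesting). Each predictor call is a precomputed boolean input;
the package does not recompute annotations.

The burden statistic is the per-sample mask allele count (0/1/2 summed
over mask variants), tested by the same profile Firth LRT with PC and
cluster adjustment. Per-mask P values are consolidated by a minimum-P
test corrected for the effective number of independent masks:
`P_gene = 1 - (1 - min P)^Meff` (Sidak form, chosen over Bonferroni
multiplication to keep P <= 1 without clipping). `Meff` is the Li-Ji
eigenvalue count on the correlation matrix of per-sample mask burden
scores (constant columns dropped): `sum(1(l >= 1) + frac(l))` over
eigenvalues `l`. One mask or perfectly correlated masks give Meff = 1;
seven independent scores give Meff ~ 7. Under permuted/null phenotypes
the consolidated P has QQ slope 1.00 and a slightly conservative centre
(median ~0.55 at 500 genes) from the combination of Sidak over
positively dependent masks and small-count discreteness; the 5% tail is
calibrated-to-conservative, which is the operative property for
discovery. The gene-level significance threshold is `alpha / n_genes`
(0.05 / 19,020 = 2.6e-6 by default).

`qq_slope` — the calibration summary used in tests and the acceptance
script — is the least-squares slope of the sorted observed P values on
uniform plotting positions. The linear scale is used deliberately: the
log-scale slope is dominated by the few smallest P values and has SD
~0.06 at n = 500 even under perfect uniformity, while the linear-scale
slope has SD ~0.02.

## Winner's-curse correction

For effects ascertained at a z-threshold `c`, the conditional likelihood
of the observed effect is the normal density divided by
`Phi(b/s - c) + Phi(-b/s - c)` (two-tailed ascertainment; a one-tailed
variant is available). The corrected effect is the 1-D conditional MLE
(bounded optimization on `[-|b_obs| - 10s, |b_obs| + 10s]`); confidence
intervals solve the chi-squared(1) log-likelihood-ratio equation by
bracketed root finding. For set-level statistics, uncertainty is
propagated by sampling a chi-squared(1) log-likelihood drop per variant
per replicate, solving for the effect attaining that likelihood (side of
the MLE by fair coin — the likelihood has two such roots and nothing
disambiguates them), and taking replicate quantiles (default 1,000
replicates, 95% level).

A property worth knowing: the conditional MLE *overcorrects* on average
in the moderate-power regime. At truth 0.3, s = 0.1, c = 1.96
(selection retains ~85%), the selected-draw mean is +0.027 biased while
the corrected-estimate mean is -0.029 biased (exact integration; the
test suite measures the same thing by simulation). The correction
removes the sign of the curse and bounds its magnitude, but estimates
just above threshold are aggressively shrunk. Rank-ascertained variants
receive `c` equal to the z-score of the realized rank cutoff.

## Liability variance explained

A site with genotype frequencies `(p_AA, p_Aa, p_aa)`, relative risks
`(1, RR1, RR2)` and prevalence `K` implies penetrances
`f_i = K RR_i / sum(p_j RR_j)`; with threshold `T = Phi^-1(1 - K)` the
genotype mean liabilities are `mu_i = T - Phi^-1(1 - f_i)` and

    LVE = V / (V + 1),  V = sum(p_i mu_i^2) - (sum(p_i mu_i))^2

(the raw between-genotype variance `V` is also exposed). The formula is
validated against a 10^7-draw Monte-Carlo liability simulation (relative
error well under 5%) and reproduces the prevalence it is anchored to.
Odds ratios convert to relative risks under an additive log-odds model;
with a MAF supplied, the non-carrier penetrance solves the marginal
constraint `sum(p_i f_i) = K` by bisection, otherwise baseline risk is
anchored at `K` (exact in the rare-variant limit).

Estimated effects inflate LVE by sampling noise. The corrected estimate
subtracts a term equal to the sign-symmetrised LVE a truly null variant
would show with `|effect| = SE` — to second order, exactly the expected
noise inflation (`E[LVE(b_hat)] ~ LVE(b) + k SE^2` for locally quadratic
LVE). Null simulations confirm mean-unbiasedness; negative corrected
values are reported, not clipped, so set sums stay unbiased.

Gene-level signals are treated as pseudo-variants at their cumulative
allele frequency (carriers split by Hardy-Weinberg), with SE inflated to
match the Meff-corrected P (corrected P -> two-sided z -> SE = |b|/z)
and the winner's-curse-corrected effect used when the gene was
ascertained by P. Architecture comparisons report the ratio of summed
LVE between two sets, with a CI from joint likelihood sampling over both
sets.

## Cross-study calibration

Comparing effects between two case-control studies that share controls
and differ in size requires a calibrated null. The module simulates the
two studies jointly: binomial genotypes at each variant's MAF, shared
controls carrying identical genotypes in both studies, phenotype coded 0
for cases and 1 for controls, and per-variant ordinary least squares for
effects and P values. (Sign conventions from that coding are handled at
the reporting layer.) The implementation works from multinomial
genotype-count sufficient statistics — closed-form OLS beta/SE/P —
verified against an explicit per-sample regression; this makes 1,000
replicates of study pairs with tens of thousands of samples essentially
free. Defaults mirror the empirical pair: 3,005/9,777 vs 29,791/24,440
with 9,777 shared controls and 17 variants.

Summaries are the expected sign concordance and the expected fraction of
variants with larger |effect| in study 1, with SEs across replicates
(the across-replicate convention is a documented choice), under no
selection, P-threshold selection, or top-k rank selection in either
study. Exact-zero estimates (possible on the integer genotype-count
lattice) count 1/2 toward concordance so the no-sharing null expectation
is exactly 0.5. Note that with *unequal* study sizes the larger-|effect|
fraction is genuinely above 0.5 for the smaller study even under the
null — that asymmetry is precisely what the calibration quantifies.
Observed counts are then tested against the calibrated null proportion
with a one-sided binomial tail (one-sided by design: the directional
hypothesis is enrichment in the smaller, earlier-onset study).

## Gene-set enrichment and tiers

Two tests per set: (1) upper-tail hypergeometric overlap of the set with
the top-K (default 50) gene-level associations, with Benjamini-Hochberg
q values across sets and significance at q < 0.01; (2) a one-sided
Wilcoxon rank-sum test that set genes have lower consolidated P values
than background genes matched 50-fold (5-fold for cluster-level sets) on
nearest-neighbour distance in (log variant count, log cumulative allele
frequency) space, each axis scaled to unit variance, sampled without
replacement. The exact rank-sum distribution is used when the combined
sample size is at most 20. Fold enrichment is the set's representation
in the background's top association decile relative to 10%. Genes
absent from the association universe are dropped from sets (and logged)
before testing.

Tier assignment: tier 3 = top-K association and membership in at least
two significantly enriched sets; tier 4 = membership in at least one
enriched set plus nominal association (P < 0.05).

## Contribution scores

The common-variant score is a weighted risk-allele sum, z-standardized
within ancestry and multiplied by the ancestry's log-odds effect per SD
of score (defaults 0.89 European, 0.37 African American, 0.91 Latino —
external calibration constants, supplied as inputs). The rare-variant
score weights each carried variant by the "unique"-fit effect of its
most stringent containing mask — the mask effect re-estimated by Firth
regression on the variants not already captured by stricter masks — with
winner's-curse correction applied to effects of genes selected by P.
The combined score is the sum, so all three are log-odds and the high-
risk cut `OR >= 3` is `score >= ln 3`. Both components are kept on the
beta (log-odds) scale before adding, for unit consistency.

High-risk categories are mutually exclusive with precedence monogenic
carrier > rare > common > combined; percentages are rounded half-up to
one decimal from exact rational ratios. Score-phenotype associations
are per-SD linear regressions (optionally excluding monogenic carriers);
group mean contrasts use a Gaussian GLM.

## Pipeline

`run_pipeline` chains simulate -> QC -> single-variant association
(common variants) -> burden -> winner's curse -> LVE -> enrichment ->
scores under one seed, embeds the configuration snapshot in the report,
and halts on stage failure with a stage-scoped error. Default
thresholds throughout are the package defaults listed above. The
pipeline and `scripts/acceptance.py` use reduced problem sizes chosen to
keep Monte-Carlo error well inside the assertion tolerances: 500 null
genes at 400/1,200 for calibration, 20 seeds at 3,000/9,800 for effect
recovery, 1,000 replicates for the cross-study and propagation nulls,
10^7 draws for the LVE oracle.

## Known limitations

- The simulator has no LD, no haplotypes, and no sequencing artefact
  model; QC fields tied to those processes are passthrough inputs.
- The conditional-MLE winner's-curse correction overcorrects on average
  at moderate power (see above); it is implemented as specified, and the
  propagation machinery quantifies (but does not remove) that bias.
- Meta-analysis is fixed-effects only; cross-cluster heterogeneity is
  not modelled.
- The minimum-P consolidation is slightly conservative in the
  mid-distribution for small carrier counts.
- `or_to_rr` assumes the additive log-odds model it documents; dominance
  at the penetrance level is expressible only through the explicit
  three-genotype `LiabilityModel`.
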