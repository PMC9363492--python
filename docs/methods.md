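# Methods

## Transferability model

A published locus is represented by an LD-proxy credible set rather than by
its sentinel alone: the sentinel plus every variant with r² ≥ 0.8 to it
within ±50 kb (inclusive) whose discovery p-value is below 100× the
sentinel's. This is an LD-based stand-in for the set of variants likely to
contain the causal one; it is *not* a Bayesian posterior credible set, and
no fine-mapping is performed. r² is computed from reference-panel dosages
(composite LD), which needs no phasing and matches how practitioners run
proxy searches. Proxies present in the panel but absent from the discovery
statistics are excluded, because their p-value condition cannot be checked.
Overlapping loci (shared members, or sentinels within one window) are
resolved greedily by ascending sentinel p-value, with ties broken by
(chromosome, position, allele) so results are order-independent.

A locus is called transferable when at least one credible-set member is
associated at two-sided p < 0.05 in the target population with the sign of
its target effect matching the sign of *that member's own* discovery effect
(not the sentinel's). Loci with no member present in the target statistics
are kept in the denominator and in the expected count, flagged "untestable";
a strict mode excluding them is available via the call records.

## Replication power

Power uses the non-centrality parameter of the marginal association test:
λ = β²·2f(1−f)·N with β the discovery effect on a unit-variance phenotype
(log odds ratio for binary traits), f the target effect-allele frequency
and N the target sample size — the effective sample size
4/(1/N_cases + 1/N_controls) for case-control designs. The rejection rule
mirrors the transferability call: two-sided p < α *and* direction match,
giving power = Φ(√λ − z₁₋α/₂) with a floor of α/2 at β = 0. The analytic
form is validated against explicit cohort simulation (genotype ~
Binomial(2, f), marginal OLS, 10⁵ replicates per grid point) to within
±0.01 across a 3×3 grid of effect sizes and sample sizes.

Quantitative-trait effects are assumed to be on a standardized scale; for
traits published on raw scales the caller must supply standardized
estimates (e.g. from a normalised re-analysis). No winner's-curse
correction is applied to discovery effects. Per-locus expected counts use
the lead (sentinel) variant's power; the per-member flagging rule uses each
member's own discovery effect. When the target frequency is missing, the
panel frequency is substituted with a logged warning.

## The PAT ratio and its test

PAT = O/E where O is the observed transferable count and E = Σ power. The
binomial test is the *lower* tail P(X ≤ O) with X ~ Binomial(n, E/n),
regardless of whether O exceeds E: the test asks specifically for a deficit
of transferability, so a surplus yields p near 1. Collapsing heterogeneous
per-locus powers to their mean is deliberate (it is what a binomial test
means here); an exact Poisson-binomial lower tail over the per-locus powers
is available behind the `exact=True` flag for sensitivity analysis, and
matches direct convolution by construction.

Well-powered non-transferable loci are flagged when the best member power
exceeds 0.80, every member present in the target has p ≥ 0.05, and every
target variant within 50 kb of the locus span has p ≥ 10⁻³ (a nearby
independent signal rescues the locus).

## Mendelian randomisation

Three instrument-selection strategies reflect the trans-ancestry setting:
published loci at p < 5×10⁻⁸ in the discovery GWAS; transferable loci (the
subset passing the transferability call, retaining discovery effect sizes
*and* standard errors — the discovery values are the more precise ones and
the target call only gates validity); and ancestry-matched loci at
p < 5×10⁻⁸ with a permissive 5×10⁻⁵ fallback when too few reach
genome-wide significance, LD-clumped to r² < 0.2 within 50 kb.

The primary estimator is IVW with first-order Wald-ratio SEs and a
multiplicative random-effects model: the fixed-effect SE is inflated by
√max(1, Q/(n−1)), never deflated — the default behaviour of the standard
two-sample MR tooling. Cochran's Q is referred to χ²(n−1). MR-Egger
regresses outcome on exposure effects with weights 1/se_y², after orienting
every instrument to a positive exposure effect (which also makes all
estimators invariant to joint sign flips); its intercept estimates average
directional pleiotropy, with the same floored over-dispersion. The weighted
median uses interpolated weighted percentiles; the weighted mode a Gaussian
kernel density with the modified Silverman bandwidth
h = φ·0.9·min(sd, mad)·n^(−1/5), φ = 1 by default. Both get SEs from a
parametric bootstrap of the per-instrument effects with a fixed seed.
Multivariable MR is weighted least squares of outcome effects on the K
exposure-effect columns without intercept (weights 1/se_y²); with K = 1 the
point estimate equals fixed-effect IVW exactly, and the same floored
over-dispersion factor nests the random-effects model. MR-PRESSO is not
implemented; reports state it was not run.

## PGS evaluation

Scores are weighted sums of effect-allele dosages, orientation-corrected
through the same allele-harmonization rules as the summary statistics
(swapped storage contributes 2 − d). Incremental R²/AUC compare the full
model (standardized PGS + sex, age, age², 10 PCs) to the covariate-only
model, fitted in-sample as is standard for these cohort evaluations (a
cross-validated variant can be built from the same pieces but is not the
default). AUC is the Mann–Whitney rank statistic on fitted probabilities.
Relative accuracy is the ratio of incremental metrics between populations;
its CI pairs the two independent bootstrap distributions draw-by-draw.
Quantile odds ratios use cut-points computed among controls and applied to
everyone (ties to the lower quantile), with the middle quantile as
reference, from a logistic model with the same covariates. NRI is
P(up|case) − P(down|case) + P(down|noncase) − P(up|noncase), categorical
(10% high-risk threshold by default) or continuous (any risk change);
bootstrap CIs resample individuals jointly, not stratified by case status.
All bootstraps are seeded and bit-reproducible.

## Synthetic data

The generator emulates the analysis inputs at the scale of the motivating
study design: a large discovery meta-analysis (N = 300,000 default) read
out in a community-biobank-scale target cohort (N = 16,000 default, or a
case-control split), with a 500-sample LD reference panel. Loci are AR(1)
LD blocks (25 variants, ρ = 0.97, 2 kb spacing) with one causal variant at
the block centre; one allele frequency is drawn per block from U(0.05,
0.95), so the within-block Markov-chain haplotype model has exactly the
AR(1) correlation. Summary z-scores are drawn jointly as MVN(μ, R) with
μᵢ = r_ic·√(2f(1−f)N)·β and R the block LD matrix — drawing them jointly
rather than independently matters because the transferability call is a
maximum over correlated member tests. Target causal effects equal discovery
effects with probability `sharing`, else zero; target frequencies follow a
Balding–Nichols perturbation with F = 0.01, emulating modest continental
divergence. Effect sizes are N(0, 0.04) by default, or a fixed magnitude
via `effect_size`.

Cohort simulation draws dosages Binomial(2, f), a quantitative trait whose
true-weight PGS explains a configured variance fraction (0.05 default, with
a 0.10 covariate share), and a binary outcome from a liability threshold at
the configured prevalence. A target marginal odds ratio per SD of PGS can
be requested instead of a liability variance; the conversion is the KL
projection of the liability-threshold risk curve onto the logistic family,
computed by Gauss–Hermite quadrature and inverted by root finding.

What the simulations do *not* capture: realistic demography (no coalescent,
no population-specific LD — the two populations share one LD structure),
imputation error, phenotype missingness, relatedness, or selection of
published loci through genome-wide significance in a finite discovery study
(discovery power is near 1 at the default scale, so winner's curse is
negligible; at much smaller discovery sizes it would not be). Passing tests
therefore demonstrate correctness of the statistics under the stated model,
not robustness to every property of real cohort data.

## Calibration behaviour and known limitations

With full sharing and identical effect sizes the PAT ratio is calibrated to
a few percent (mean ≈ 1.03 across seeded replicates at 500 loci). The small
upward residual is structural, not a bug: the observed call is "any
credible-set member significant", a maximum over correlated tests, while
the expected count uses lead-variant power alone. The inflation is
concentrated at low-power loci — with effects drawn from N(0, 0.04) many
loci sit near the α/2 power floor where the set-level maximum roughly
doubles the per-variant chance rate — and partially offset by mild
winner's-curse inflation of the sentinel's estimated effect entering E.
Consequently, a sharing deficit among loci that are mostly under-powered is
compressed toward 1; the ratio is informative about sharing only where
power is substantial, which is exactly the statistic's premise. At near-1
power the ratio tracks the sharing fraction to within Monte-Carlo error.

Other limitations by design: no effect-size heterogeneity testing between
populations (transferability is a yes/no call on direction-consistent
association), no genomic-control or meta-analysis of inputs, no liftover
(one genome build per run), and palindromic variants with both frequencies
in [0.4, 0.6] are dropped rather than guessed. Numerical conventions:
windows are inclusive at both ends; p-values are floored at 10⁻³⁰⁰ when
converting extreme z-scores; monomorphic panel variants raise on direct r²
queries and are skipped (NaN) in vectorised scans; all stochastic routines
take explicit seeds and identical seeds give byte-identical outputs.
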