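# Methods

This note documents the statistical machinery behind `mirmaster`: the models
and estimators, the default parameters and why they were chosen, what the
synthetic cohort does and does not emulate, and the numerical conventions
that pin down otherwise ambiguous behaviour.

## Differential expression

Two-group comparison on log2 values; the reported `log2_fc` is the case-group
mean minus the reference-group mean. The t-statistic uses an empirical-Bayes
variance squeeze: per-feature pooled variances s² (d = n₁+n₂−2 df) are shrunk
toward a scaled inverse-chi-square prior (d₀, s₀²) fitted by moment matching
on log s² (mean and excess variance of log s² identify s₀² and d₀ through
digamma/trigamma relations; the trigamma inverse is solved by Newton
iteration). The moderated statistic is

    t = (mean₁ − mean₂) / sqrt(s̃² (1/n₁ + 1/n₂)),   s̃² = (d₀s₀² + ds²)/(d₀+d)

referred to a t distribution with d + d₀ df. With a single feature no prior
can be fitted and the statistic reduces to the ordinary pooled-variance t;
`prior_df` can force either limit (0 → ordinary t; ∞ → common-variance
z-like statistic). The unit test suite verifies the statistic against the R
`limma` implementation to ~1e-6 relative error.

Missing values are rejected rather than imputed. BH correction runs
separately within the miRNA table and the gene table, since the two families
are tested separately. Selection thresholds use strict inequalities
(log2 FC < −0.5 for regulators, > 0.25 for targets, adj. p < 0.05 for both),
so boundary features are excluded.

Duplicate features mapping to one symbol keep the row with the maximal mean
expression; exact ties keep the lexicographically smallest original id.

## Mutual information and network filtering

**Estimator.** Maximum-likelihood plug-in MI in nats on equal-frequency
(quantile) bins of average-ranked data, with n_bins = round(√n) by default.
Rank binning makes the estimate invariant under monotone transforms; ties
share a bin. A constant vector has zero MI with anything. The estimator is
exactly symmetric (the term matrix of (y, x) is the transpose of that of
(x, y); terms are summed in sorted order so the floating-point sum is
order-invariant).

**Permutation stage.** For each regulator, `n_perm` permutations of its
sample labels are scored against all T candidate targets and pooled into one
null (n_perm × T values). Two p-values are reported per pair:

* the empirical permutation p, `(1 + count_ge/T) / (1 + n_perm)`, whose
  smallest achievable value is 1/(1+n_perm);
* a continuous tail p from a gamma distribution moment-fitted to the same
  pooled null.

Edge *selection* applies BH (globally by default, per regulator by flag) to
the **gamma-fitted** p at `alpha = 0.01`. The reason is arithmetic: the
empirical p is floored at 1/(1+n_perm), and BH over R×T ≈ 10³–10⁴ pairs needs
p·m/k < α at the floor, which is unreachable at any practical permutation
count — a count-based permutation p simply cannot express the far tail that
genuinely coupled pairs occupy. The gamma family contains the asymptotic
null of the plug-in MI (a scaled chi-square with (n_bins−1)² df), so the fit
extends the tail smoothly while remaining calibrated: on fully independent
matrices the BH-controlled retention stays below α (verified in tests).

**Bootstrap stage.** Each of `n_boot = 100` resamples (samples drawn with
replacement) rescoring every surviving edge; an edge is *supported* in a
resample when its MI exceeds the 95th percentile of a per-regulator
permutation null computed on that same resample. The null permutes the
regulator in the original sample space and then applies the same bootstrap
indices — a resample's duplicated samples inflate MI by themselves, and the
null must share that duplicate structure or pure-noise edges would appear
supported. Edges are kept at `consensus = 0.95` support.

**DPI stage.** For every triplet (m₁, m₂, g) with both regulator–target
edges present and the regulator–regulator MI available, the regulator–target
edge with the smallest MI is marked when it is smaller than each of the
other two values by factor (1 − eps); marked edges are removed only after
the full scan (simultaneous removal), and regulator–regulator entries are
never deleted. With `eps = 0` exact ties for the minimum remove nothing
(conservative). An independent brute-force triplet enumeration validates the
implementation on random networks.

One master seed drives the permutation and bootstrap streams through
independently spawned substreams, so results are bit-reproducible.

## Master regulator analysis

Upper-tail hypergeometric over-representation of the signature inside each
regulon, computed in log space (log-binomial coefficients via log-gamma,
tail accumulated from the top of the support with `logaddexp`). The universe
is the candidate target-gene set used for inference and is user-settable;
regulons must exceed `min_regulon = 15` genes strictly (a 15-gene regulon is
excluded); BH runs over exactly the tested regulons. The worked example —
P(X ≥ 19 | N=1530, K=46, n=187) = 4.0e-7 and P(X ≥ 11 | N=1530, K=46,
n=115) = 3.8e-4 — reproduces to two significant figures, and the
implementation matches exact integer enumeration for every parameter
combination with N ≤ 60.

## Target prioritization and methylation

A direct target must lie in all four of: the inferred regulon, the
signature, and both physical prediction databases (consumed as offline
GMT/gene-list files; their internal confidence scores are taken as given).
Each prioritized (miRNA, gene) pair carries the Spearman ρ (average-rank
ties, p from the t approximation) between the two expression profiles.
Prioritized genes missing an expression profile are reported as
missing-profile rows, never dropped silently.

The promoter-methylation screen tests, per regulator: a two-sided Wilcoxon
rank-sum (normal approximation, tie-corrected) of methylation beta-values
between subtypes, and the Spearman association between methylation and the
regulator's own expression. Promoter-to-miRNA mapping is input metadata.

## Survival analysis

Quantile stratification uses the linear-interpolation quantile (the numpy
default); values ≥ threshold are High, values < threshold Low — the tie-at-
threshold rule is pinned to High because a strict-inequality reading on
both sides would leave boundary samples unassigned. Kaplan–Meier is the
product-limit estimator; the log-rank test reports U (observed − expected
events in group A), its hypergeometric variance V, χ² = U²/V and the 1-df
chi-square p.

Univariate Cox regression maximizes the partial likelihood with Efron tie
handling (Breslow by flag) by damped Newton iteration (step halving on
likelihood decrease) to a gradient tolerance of 1e-8, with the covariate
internally centred and unit-scaled for conditioning (estimates are rescaled,
so results are exactly translation-invariant and sign-equivariant).
Standard errors come from the observed information; CI = exp(β ± 1.96·se);
Wald = (β/se)². Non-convergence and monotone likelihood (separation) raise
diagnostics rather than returning garbage. The covariate is continuous
expression by default (hazard ratios are per log2 unit), with a flag for the
dichotomized High/Low indicator. The implementation agrees with `lifelines`
to ~1e-6 and recovers a planted log-hazard of 0.5 within ±0.1 at n = 500.

## Drug-sensitivity screening

Cell lines are median-split per gene (ties at the median go High, matching
the survival convention); a two-sided Welch t-test (pooled-variance by flag)
compares IC50 between halves, oriented High − Low. The predictive AUC labels
a line *resistant* when its IC50 exceeds the across-line mean and scores
expression as a ranking statistic for the resistant class via the
Mann–Whitney formulation with midrank ties — equal to the fraction of
(resistant, sensitive) pairs ordered correctly with half-credit for ties.
IC50 values are used on the scale provided (a log flag is available).
Compounds measured on fewer than four lines are skipped with a warning
count; BH runs across the whole gene × compound grid.

## The synthetic cohort

The generator emulates, on the log2 scale, the statistical structure the
pipeline is designed to detect; defaults mirror a 149-sample cohort with a
31-sample squamous minority, 44 candidate miRNAs and 1486 candidate genes,
two master miRNAs with 40 targets each, a 46-gene signature half of which
are true targets, 26 cell lines and 8 compounds (half coupled to target
expression).

* **Expression** is Gaussian on the log2 scale (all downstream statistics
  act on log values; no count-level simulation). Master miRNAs are shifted
  down by `mirna_shift` (default 1.0) in squamous samples; each planted
  target g of master m follows E[g | m] = baseline − β·(m − baseline_m)
  with `repression_beta = 1.5` and residual sd `noise_sd = 0.5`, so planted
  pairs are strongly inversely correlated and targets come out up-regulated
  in the squamous group.
* **Nuisance structure** makes selection realistic: eight decoy miRNAs are
  mildly down-shifted (U(0.6, 0.9)) but regulate nothing, and 30% of
  non-target genes are up-shifted with fold changes spanning U(0.3, 1.2) —
  wide enough that the candidate universe stays much larger than the
  planted-target set across fold-change cutoffs, which is what makes the
  enrichment analysis discriminative and threshold-stable. Decoy-gene noise
  is inflated in proportion to the shift so their subtype-driven correlation
  with the masters stays weak at every fold change (high-fold-change genes
  are high-variance genes, as in real cohorts).
* **Signature**: `signature_overlap_frac` of the signature are true targets;
  the remainder are decoy up-regulated genes.
* **Physical databases**: each contains every planted edge plus an equal
  number of independently sampled decoys per regulator, so the four-set
  intersection is discriminative.
* **Methylation**: beta-values; exactly one master's promoter is negatively
  coupled to its expression through the within-subtype residual (so the
  coupling does not induce a subtype difference in methylation); all other
  promoters are Beta(2, 5) noise.
* **Survival**: exponential event times with hazard h₀·exp(γ·z), h₀ set for
  a 500-day baseline median, z the standardized mean planted-target
  expression, `surv_gamma = 0.5`; censoring marks each sample independently
  with probability `surv_censor_rate = 0.3` and uniformly truncates its
  time.
* **Cell lines**: planted targets share one latent activity axis across
  cell lines (they are co-regulated in tumors, so their cell-line profiles
  are correlated too); log-scale IC50 of coupled compounds increases in the
  standardized mean target expression with slope `ic50_slope = 0.8`.

Not emulated: read counts and library-size effects, batch effects, tumor
purity and stromal admixture, the probe structure of methylation arrays,
dose–response curve fitting. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure of realistic effect size
under Gaussian noise — not robustness to the technical artefacts of real
TCGA/CCLE data.

## Problem sizes used in tests

The default recovery benchmark runs the full 149 × (44 miRNA, 1486 gene)
cohort with 250 permutations, 100 bootstraps and consensus 0.95 (about five
seconds end to end); null-calibration checks use 50 × 50 independence grids
averaged over ten seeds; Cox recovery uses 50 simulations at n = 500 and 200
null simulations for CI coverage. These sizes give stable Monte-Carlo
margins while keeping the suite fast.

## Known limitations

* MI uses a fixed √n binning rule; very small cohorts (n < 50) leave few
  bins and low power. The plug-in estimate is biased upward, but all
  filtering decisions compare against nulls computed with the same
  estimator, so the bias cancels where it matters.
* The gamma tail extension of the permutation null is an approximation; its
  far-tail p-values should be read as selection scores, not literal
  probabilities (the reported empirical permutation p is the honest,
  floored, quantity).
* Mode of action is not inferred: edges are undirected associations pruned
  for indirectness, interpreted as repression only through the selection
  design (regulators down, targets up).
* Univariate Cox only; no multivariate adjustment, proportional-hazards
  diagnostics or competing risks.
* The number of cell lines in public PDAC panels is ambiguous in the
  motivating literature (21 vs 26); the generator defaults to 26.
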