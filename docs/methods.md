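# Methods

This note documents the statistical procedures implemented in
`pairstab`, the conventions adopted where the underlying definitions
leave freedom, and what the synthetic-data experiments do and do not
demonstrate.

## Contingency-table conventions

All three statistics consume phenotype-by-genotype count tables: 2 × 3
for a single SNP, 2 × 9 for a pair with column index v = 3·g₁ + g₂ after
canonicalising the pair to (min index, max index). Row 0 is controls,
row 1 cases. Samples with a missing call are deleted pairwise — dropped
only from tables that involve the missing SNP — so different pairs may
rest on slightly different sample counts. This is the standard GWAS
treatment; it is a documented choice, as the protocol itself does not
prescribe one.

## Pearson χ²

X² = Σ (O − E)²/E over cells with E > 0; cells with E = 0 contribute 0
and the degrees of freedom stay fixed at V − 1 (2 univariate, 8
bivariate) regardless of empty genotype columns. The fixed-df convention
keeps scores comparable across pairs, at the price of conservatism for
pairs of rare-allele SNPs whose tables have structurally empty cells
(see *Null calibration* below). p-values use the upper regularized
incomplete gamma Q(df/2, X²/2); every df in the package is even, so the
exact finite-sum log-space form −x/2 + logsumexp_{i<df/2}(i·ln(x/2) −
ln i!) is used and log p stays finite for arbitrarily large statistics
(cohorts of 10⁶ samples produce X² ~ 10⁶ whose p underflows any float).

## Log-linear interaction LRT (BOOST-style)

The saturated 3 × 3 × 2 model is compared with the homogeneous-
association log-linear model [X₁X₂][X₁Y][X₂Y] — all two-way margins, no
three-way term — which is the log-linear equivalent of testing the
interaction term of a logistic regression of phenotype on two
categorical SNPs. The null fit uses iterative proportional fitting,
cycling over the three two-way margins until the largest absolute margin
discrepancy falls below 1e-8 or 200 cycles elapse; at that tolerance the
LRT is stable well past 1e-6, which the tests verify against an
independent Poisson-GLM (IRLS) fit of the same design. LRT = 2 Σ n
ln(n/μ̂) with 0·ln 0 := 0, clamped at ≥ 0, df = 4. No pseudocounts are
added anywhere; zero margins simply force zero fitted cells.

The Kirkwood superposition approximation
μ ∝ p(g₁,g₂)p(g₁,y)p(g₂,y)/(p(g₁)p(g₂)p(y)), renormalised to the grand
total, gives a screening value 2 Σ n ln(n/μ) that empirically upper-
bounds the exact LRT; scans accept an optional screening threshold below
which the exact fit is skipped. Screening is off by default at desk
scale — it is a runtime optimisation, not part of the statistic.

## GSS

The per-genotype prevalence φ_v = cases_v/(cases_v + controls_v) orders
the genotype cells; cumulative control/case counts along that order
trace the ROC curve. Conventions: ties in φ are broken by ascending
control count then column index; empty cells are dropped (they cannot
move the curve); consecutive duplicate vertices are collapsed. The null
hypothesis — separation achievable from univariate association alone —
is the upper convex hull of the union of the two single-SNP curves'
vertices together with (0,0) and (1,1).

For each pair-ROC vertex with cumulative counts (FP, TP) strictly above
the hull (tolerance 1e-12), the procedure maximises
log Pr[Bin(n_cases, v) ≥ TP] + log Pr[Bin(n_controls, u) ≤ FP] over hull
points (u, v), evaluated at the hull vertices plus 64 evenly spaced
points per edge; the pair's p-value is the minimum over vertices of the
maximised probability, clamped to (0, 1]. Vertices on or below the hull
contribute p = 1, so a pair whose curve never escapes the hull (e.g. one
SNP constant) scores exactly p = 1. The 64-points-per-edge
discretisation was checked against a 2,000-point dense scan of the full
hull: agreement to better than three significant figures on random small
tables. Binomial tails come from scipy's regularized-incomplete-beta
implementation; where those underflow to −∞ (p below ~1e-308) a
geometric-series bound from the boundary pmf substitutes, so log p
remains finite and rankable at any cohort size. The ranking score is
−log₁₀ p.

## Exhaustive scan

Every unordered pair is scored once; a bounded min-queue keyed by
(score, −i, −j) retains the k best under the total order "score
descending, ties by ascending pair index". Tie determinism matters:
categorical data at a few thousand samples produces many exactly tied
scores, and reproducible lists are a precondition for comparing folds.
Contingency tables for all pairs sharing a left SNP are tallied in one
vectorised pass, and χ²/LRT are evaluated block-wise; GSS is evaluated
per pair (its hull geometry does not vectorise across pairs). Pairs
whose table is degenerate (an empty phenotype row after missing-data
deletion) are logged and skipped but still counted.

## Incomplete-list Spearman ρ and ZIC

For lists A (length n_a) and B (n_b) with union size m, elements keep
their own rank in a list that contains them and all elements absent from
a list share the midrank (n + 1 + m)/2 — the fractional (average) rank
of the tail positions they must occupy, which preserves the mean rank
(m + 1)/2. ρ is the Pearson correlation of the two extended vectors; a
constant vector (possible only for m ≤ 1) is treated as undefined and
reported as 0 by `spearman_incomplete`.


The ZIC search walks the exact per-k sequence (not a display grid) using
an O(k_max) incremental closed form valid for equal prefix lengths, and
returns the smallest k ≥ τ with ρ ≤ 0. "≤" rather than "<" makes exact-
zero degenerate cases terminate; an undefined ρ never triggers a
crossing (otherwise two identical lists would "cross" at k = 1). When no
crossing exists the result is censored at k_max and flagged — summaries
include censored values at k_max rather than dropping them, which would
bias the mean downward. The library default τ = 100 suits full-scale
lists (k ~ 10⁵–10⁶); the desk-scale experiments below use τ = 10 with
k = 100–150 lists, keeping the same ratio of floor to list length.
Display curves default to a grid of 1..200 then geometric ×1.1 steps.

ZIC summaries over repeated splits report mean ± t₀.₉₇₅,n₋₁·sd/√n — the
standard small-sample interval for ~10 splits.

## Cross-validation protocol

Splits are stratified random halves (per-class fold sizes differ by at
most one); stratification preserves the case:control ratio that all
three statistics condition on. Each repeat scans both folds
independently, then records the ρ and Jaccard curves, ZIC, per-fold hub
counts (pairs involving a univariately Bonferroni-significant SNP), and
per-fold Bonferroni/Benjamini–Hochberg threshold ranks with T = C(M, 2)
(the tests actually performed) and α = 0.05. Ranks saturate at the
retained list length and are flagged when they do. Optional pruning
removes univariately significant SNPs (p ≤ α/M) before any scanning.

## Synthetic data

The generator draws biallelic genotypes independently per SNP under
Hardy–Weinberg equilibrium with MAF ~ Uniform(0.05, 0.5) by default, and
assigns disease through a liability model on the log-odds scale:
logit P(case) = logit(0.1) + Σ g_s·ln(OR_s) + Σ offsets[g_i, g_j].
Individuals are drawn in batches and kept until the case and control
quotas are met exactly (bounded attempt budget). Main-effect "hub" SNPs
default to MAF 0.3. Planted pair presets provide log-odds offset tables:
`xor` (ln θ on odd-genotype-sum cells), `threshold` (ln θ when both
genotypes carry a minor allele), `multiplicative` (g₁·g₂·ln θ); explicit
3 × 3 tables are interpreted on the same log-odds scale. The xor preset
forces MAF 0.5 on its two SNPs because the odd-sum event has probability
½ conditional on either genotype only at MAF 0.5 — that is what makes
the planted SNPs exactly univariately null ("pure epistasis") and the
pruning-invariance experiments meaningful.

What the generator does **not** emulate: linkage disequilibrium,
population structure, genotyping error, and realistic allele-frequency
spectra. Passing tests therefore demonstrate the behaviour of the
statistics under clean HWE genotypes with planted effects, not
performance on real cohorts, where LD alone creates correlated blocks of
pairs.

## Desk-scale experiment sizes

The validation experiments run at sizes chosen so the full suite
completes comfortably on one CPU while keeping every threshold intact:

* **Null calibration**: ~10,000 bivariate χ² p-values pooled from four
  independent null datasets (71 SNPs, 1,000/1,000 samples each),
  Kolmogorov–Smirnov distance to Uniform(0,1) < 0.05. Pooling matters:
  pairs sharing one rare SNP deviate as a correlated block under the
  fixed-df convention, so a single dataset's KS reflects its particular
  MAF draw more than the statistic's calibration.
* **Hub effect**: 60 SNPs, one hub (OR 2.0, MAF 0.3), 1,000/1,000
  samples, top-100 lists, five seeds. The hub's pair-membership count
  exceeds the 99th percentile of other SNPs' counts under χ² and not
  under GSS/BOOST.
* **Pruning invariance**: 60 SNPs, one hub (OR 2.5), ten xor pairs with
  θ graded 3.2 → 1.8 (reliably- to marginally-detectable at fold size
  400/400), k = 150, τ = 10, 10 repeats, two seeds. The graded ladder
  gives the fold-vs-fold crossing genuine split-to-split variance, the
  regime in which "unchanged within the CI half-width" is informative; a
  handful of uniformly strong pairs would pin the ZIC to a constant.
  Under these conditions pruning moves the χ² mean ZIC by an order of
  magnitude more than its CI half-width while GSS and BOOST move by a
  fraction of theirs.
* **Epistasis recovery**: 40 SNPs, three xor pairs (θ = 3), 1,000/1,000
  samples, k = 50, 5 repeats × 3 seeds; all planted pairs must appear in
  both folds' lists in ≥ 80% of repeats for GSS and BOOST.
* **ZIC vs multiple testing on null data**: 40 SNPs, 400/400 samples;
  the crossing (≥ τ by construction) always sits above the Bonferroni
  rank (~0 under the null).

## Numerical and degenerate-input policy

* IPF: tolerance 1e-8 on margins, ≤ 200 cycles; non-convergence is
  flagged on the result and the achieved value is ranked.
* Degenerate tables (an empty phenotype row): χ²/LRT raise; GSS returns
  p = 1; the scanner logs and skips such pairs.
* All p-values are carried in natural-log form; the exponentiated
  `p_value` field clamps to the smallest positive float rather than 0.
* PLINK 1 .bed decoding maps bit pairs 00→0, 10→1, 11→2, 01→missing
  (SNP-major, little-endian bit pairs); round trips are bit-exact.

## Known limitations

* GSS evaluates ~10³ binomial tails per pair in Python/NumPy; scans
  beyond ~10⁴ pairs per fold are slow. The χ² and LRT paths are
  block-vectorised and handle 10⁴–10⁵ pairs per second.
* The deep-tail geometric bound for binomial log-tails is a bound, not
  an exact value; it only engages below p ≈ 1e-308, where it affects
  ranking granularity, not significance calls.
* The homogeneous-association LRT's χ²(4) reference is asymptotic;
  sparse pair tables (rare alleles, small folds) inherit the usual
  likelihood-ratio small-sample conservatism.
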