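# pairstab

Stability analysis of exhaustive SNP-pair (bivariate) association scans in
case-control GWAS.

## The problem

Exhaustive bivariate GWAS scores every pair of SNPs for joint association
with a binary phenotype — for a typical array of ~500,000 markers that is
C(500,000, 2) ≈ 1.25 × 10¹¹ pairs. With no reference set of true SNP-SNP
interactions to validate against, a practical quality criterion for a
pair-selection statistic is *stability*: does it pick the same pairs, in
the same order, when the cohort is split in half? `pairstab` implements
that protocol end to end for researchers studying epistasis detection:
simulate (or load) case-control genotype data, scan all pairs with one of
three statistics, and quantify fold-vs-fold agreement of the resulting
top-k lists.

## Statistics

Each SNP has genotype g ∈ {0, 1, 2} (minor-allele count); a pair is
summarised by a 2 × 9 phenotype-by-genotype-combination contingency table
(pairwise deletion of missing calls).

* **χ²** — Pearson's test for association on the 2 × 9 table,
  X² = Σ (O − E)²/E with df = 8; a feature-selection baseline that
  measures *total* association, main effects included.
* **BOOST-style LRT** — likelihood-ratio test of the saturated 3 × 3 × 2
  log-linear model against the homogeneous-association model
  [X₁X₂][X₁Y][X₂Y] (equivalently, the interaction term of a logistic
  regression of Y on both SNPs). The null model is fitted by iterative
  proportional fitting; LRT = 2 Σ n ln(n/μ̂), df = 4. A Kirkwood
  superposition screen that upper-bounds the LRT can skip the exact fit
  in large scans.
* **GSS** (gain in sensitivity and specificity) — each genotype cell gets
  a sample prevalence φ_v = cases_v/(cases_v + controls_v); ordering
  cells by φ and accumulating counts yields a ROC curve for the pair and
  for each member SNP. The null — cases and controls separated only by
  univariate association — is the convex hull of the two single-SNP
  curves. For every pair-ROC vertex (FP, TP) strictly above the hull the
  statistic takes max over hull operating points (u, v) of
  Pr[Bin(n₁, v) ≥ TP] · Pr[Bin(n₀, u) ≤ FP], and the reported p-value is
  the minimum over vertices of that maximum.

## Stability measures

Two half-cohort scans give two top-k lists that rarely contain the same
pairs. The incomplete-list Spearman ρ extends both lists over the union
of their elements — anything absent from a length-n list is assigned the
shared midrank (n + 1 + m)/2 for a union of size m — and correlates the
extended rank vectors. Unrelated lists anticorrelate under this
extension, so the smallest prefix size k ≥ τ where ρ(top-k, top-k) ≤ 0,
the **Zero Index Crossing (ZIC)**, acts as a data-driven size of the
stably selected pair set. Jaccard and union-scaled overlap fractions are
provided alongside, plus Bonferroni/Benjamini–Hochberg threshold ranks
for comparison with classical multiple-testing selection.

## Worked example

```python
from pairstab import PairStability, SimConfig, simulate

cfg = SimConfig(
    n_snps=40, n_cases=800, n_controls=800,
    main_effects=[(30, 2.5)],                          # one hub SNP, OR 2.5
    pairs=[(0, 1, "xor", 3.0), (2, 3, "xor", 2.5)],    # pure epistasis
    seed=7,
)
matrix, phenotype, truth = simulate(cfg)

model = PairStability(matrix, phenotype, statistic="gss",
                      k=100, tau=10, n_repeats=10)
results = model.fit(seed=1)
print(results.summary())
for e in results.full_list.entries[:2]:
    print(e.id1, e.id2, round(e.score, 2), e.p_value)
```

prints

```
Pair-selection stability (repeated 2-fold cross-validation)
============================================================
statistic:            gss
SNPs / pairs scanned: 40 / 780
top-k retained:       100
splits (repeats):     10  (seed 1)
ZIC threshold tau:    10
------------------------------------------------------------
ZIC mean [95% CI]:    10.0  [10.0, 10.0]
censored ZICs:        0 (at k_max)
hub pairs / fold:     5.2
Bonferroni rank:      1.4   BH rank: 1.8   (alpha 0.05, T = C(M,2))
============================================================
snp0000 snp0001 12.17 6.734220764682756e-13
snp0002 snp0003 7.8 1.5842060669324333e-08
```

GSS ranks the two planted pure-epistasis pairs first and keeps the hub
SNP out of its list (5.2 hub pairs per fold, mostly noise). Refitting the
same data with `statistic="chi2"` shows the confounding the toolkit is
designed to expose: the top five χ² pairs all involve the hub SNP
(`snp0014 snp0030`, `snp0030 snp0033`, ... with scores 136–127), 39 of
the top 100 pairs contain it, and 39.5 pairs per fold pass the
Bonferroni threshold — main-effect association masquerading as bivariate
signal. Removing univariately significant SNPs first
(`PairStability(..., prune_alpha=0.05)`) eliminates the effect for χ²
while leaving GSS and BOOST rankings essentially unchanged.

The same workflow is available from the shell:

```sh
pairstab simulate --config sim.json --out data --truth truth.json
pairstab scan --stat gss --k 1000 --in data --out gss.tsv
pairstab stability --stat chi2 --k 100 --repeats 10 --tau 10 \
    --seed 1 --in data --out report/
pairstab compare --a fold0.tsv --b fold1.tsv --tau 10 --out cmp.json
```

Inputs are PLINK 1 binary (.bed/.bim/.fam) or a simple genotype TSV;
every command writes a manifest (config, seed, version, input checksums)
for provenance.

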