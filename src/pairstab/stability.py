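"""Cross-validation stability of exhaustive SNP-pair selection.

The protocol: split the cohort into two stratified halves, run the
exhaustive pair scan independently on each half, and compare the two
top-k lists with the incomplete-list Spearman rho, the Jaccard index and
the Zero Index Crossing; repeat for several random splits and summarise
the ZICs with a Student-t 95% confidence interval.  A full-data scan is
kept alongside the per-split scans for cross-statistic comparisons, and
each fold also records how many pairs involve univariately significant
SNPs (hub counts) and where the Bonferroni / Benjamini-Hochberg
multiple-testing thresholds fall in the ranked list.

The protocol is exposed statsmodels-style: :class:`PairStability` is the
model (data + design), ``fit()`` runs the splits and returns a
:class:`StabilityResults` carrying the estimates, their uncertainty and a
``summary()`` table.  :func:`run_stability` is the functional equivalent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.stats import t as t_dist

from .io import GenotypeMatrix, Phenotype
from .ranking import (
    RankedPairList,
    RhoCurve,
    ZicResult,
    default_grid,
    jaccard_topk,
    overlap_fractions,
    rho_curve,
    zic,
)
from .scan import exhaustive_scan, hub_count, prune_univariate, univariate_scan

__all__ = [
    "CvPlan",
    "MtcRanks",
    "SplitOutcome",
    "StabilityResults",
    "PairStability",
    "make_splits",
    "run_stability",
    "zic_summary",
    "mtc_ranks",
    "compare_statistics",
]

logger = logging.getLogger(__name__)


@dataclass
class CvPlan:
    """Stratified 2-fold split assignments for each repeat."""

    n_repeats: int
    seed: int
    assignments: np.ndarray  # (n_repeats, n_samples) of fold ids {0, 1}
    n_folds: int = 2

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=np.int8)
        if a.shape[0] != self.n_repeats or not np.isin(a, (0, 1)).all():
            raise ValueError("assignments must be (n_repeats, n_samples) fold ids in {0, 1}")
        self.assignments = a


def make_splits(phenotype: Phenotype, n_repeats: int = 10, seed: int = 0) -> CvPlan:
    """Stratified random halves: per-class fold sizes differ by at most 1."""
    y = phenotype.labels
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        if int((y == cls).sum()) < 2:
            raise ValueError("each phenotype class needs at least 2 samples to split")
    assignments = np.empty((n_repeats, len(y)), dtype=np.int8)
    for r in range(n_repeats):
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            perm = rng.permutation(idx)
            half = len(perm) // 2
            assignments[r, perm[:half]] = 0
            assignments[r, perm[half:]] = 1
    return CvPlan(n_repeats=n_repeats, seed=seed, assignments=assignments)


@dataclass
class MtcRanks:
    """Where multiple-testing thresholds fall in one ranked p-value list.

    ``bonferroni_rank``: pairs with p <= alpha / T (family-wise control);
    ``bh_rank``: largest j with p_(j) <= j * alpha / T (Benjamini-Hochberg
    false-discovery control); ``T`` is the number of tests performed.
    Ranks saturate at the retained list length (``saturated`` flags it).
    """

    bonferroni_rank: int
    bh_rank: int
    T: int
    alpha: float
    saturated: bool = False


def mtc_ranks(p_values, T: int, alpha: float = 0.05) -> MtcRanks:
    """Bonferroni and Benjamini-Hochberg ranks on an ascending p-value list."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    if T < n:
        raise ValueError("T (number of tests) must be at least the list length")
    bonf = int((p <= alpha / T).sum())
    j = np.arange(1, n + 1)
    passing = np.flatnonzero(p <= j * alpha / T)
    bh = int(passing[-1] + 1) if passing.size else 0
    return MtcRanks(
        bonferroni_rank=bonf,
        bh_rank=bh,
        T=T,
        alpha=alpha,
        saturated=(bh >= n > 0),
    )


def zic_summary(zic_values) -> tuple:
    """(mean, lower95, upper95) of ZIC values via a Student-t interval."""
    v = np.asarray(
        [z.value if isinstance(z, ZicResult) else z for z in zic_values], dtype=float
    )
    if len(v) < 2:
        raise ValueError("need at least 2 ZIC values to summarise")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(t_dist.ppf(0.975, len(v) - 1)) * sd / np.sqrt(len(v))
    return (mean, mean - half, mean + half)


@dataclass
class SplitOutcome:
    """Everything measured on one random split (one pair of folds)."""

    repeat: int
    lists: tuple                 # (fold-0 RankedPairList, fold-1 RankedPairList)
    rho: RhoCurve
    jaccard: np.ndarray          # Jaccard index on rho.ks
    zic: ZicResult
    hub_counts: tuple            # per fold
    significant_snps: tuple      # per fold: univariately significant ids
    mtc: tuple                   # per fold MtcRanks


@dataclass
class StabilityResults:
    """Fitted stability protocol: per-split measures plus ZIC summary."""

    statistic: str
    k: int
    tau: int
    alpha: float
    plan: CvPlan
    splits: list
    full_list: RankedPairList | None
    n_snps: int
    failures: list = field(default_factory=list)

    @property
    def zic_values(self) -> np.ndarray:
        """Per-split ZIC, censored splits included at their k_max."""
        return np.asarray([s.zic.value for s in self.splits], dtype=float)

    @property
    def n_censored(self) -> int:
        return sum(1 for s in self.splits if s.zic.censored)

    def zic_summary(self) -> tuple:
        if self.n_censored:
            warnings.warn(
                f"{self.n_censored} censored ZIC value(s) included at k_max",
                stacklevel=2,
            )
        return zic_summary(self.zic_values)

    def summary(self) -> str:
        mean, lo, hi = zic_summary(self.zic_values)
        hubs = np.asarray([s.hub_counts for s in self.splits], dtype=float)
        bonf = np.asarray([[m.bonferroni_rank for m in s.mtc] for s in self.splits], float)
        bh = np.asarray([[m.bh_rank for m in s.mtc] for s in self.splits], float)
        lines = [
            "Pair-selection stability (repeated 2-fold cross-validation)",
            "=" * 60,
            f"statistic:            {self.statistic}",
            f"SNPs / pairs scanned: {self.n_snps} / {comb(self.n_snps, 2)}",
            f"top-k retained:       {self.k}",
            f"splits (repeats):     {len(self.splits)}  (seed {self.plan.seed})",
            f"ZIC threshold tau:    {self.tau}",
            "-" * 60,
            f"ZIC mean [95% CI]:    {mean:.1f}  [{lo:.1f}, {hi:.1f}]",
            f"censored ZICs:        {self.n_censored} (at k_max)",
            f"hub pairs / fold:     {hubs.mean():.1f}",
            f"Bonferroni rank:      {bonf.mean():.1f}   BH rank: {bh.mean():.1f}"
            f"   (alpha {self.alpha}, T = C(M,2))",
            "=" * 60,
        ]
        if self.failures:
            lines.append(f"failed repeats: {sorted(self.failures)}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_rho(self, ax=None):
        """Per-split rho curves vs prefix size, with ZIC markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.splits:
            ax.plot(s.rho.ks, s.rho.rhos, alpha=0.6, lw=1)
            if not s.zic.censored:
                ax.axvline(s.zic.zic, color="red", alpha=0.2, ls="--")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("number of top pairs k")
        ax.set_ylabel(r"Spearman $\rho$ (incomplete lists)")
        ax.set_title(f"{self.statistic}: fold-vs-fold rank stability")
        return ax

    def plot_jaccard(self, ax=None):
        """Per-split Jaccard index vs prefix size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.splits:
            ax.plot(s.rho.ks, s.jaccard, alpha=0.6, lw=1)
        ax.set_xscale("log")
        ax.set_xlabel("number of top pairs k")
        ax.set_ylabel("Jaccard index")
        ax.set_title(f"{self.statistic}: fold-vs-fold set overlap")
        return ax


class PairStability:
    """Model object for the cross-validation stability protocol.

    Parameters
    ----------
    matrix, phenotype
        The case-control genotype data.
    statistic
        One of ``chi2``, ``gss``, ``boost``.
    k
        Top-k list length retained by each exhaustive scan.
    tau
        Minimum prefix size for the Zero Index Crossing.
    n_repeats
        Number of random 2-fold splits.
    alpha
        Significance level for the univariate hub test and the
        multiple-testing ranks.
    prune_alpha
        When set, univariately significant SNPs (Bonferroni level
        ``prune_alpha``) are removed before any scanning.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        phenotype: Phenotype,
        statistic: str = "gss",
        k: int = 1000,
        tau: int = 100,
        n_repeats: int = 10,
        alpha: float = 0.05,
        prune_alpha: float | None = None,
    ) -> None:
        self.matrix = matrix
        self.phenotype = phenotype
        self.statistic = statistic
        self.k = k
        self.tau = tau
        self.n_repeats = n_repeats
        self.alpha = alpha
        self.prune_alpha = prune_alpha
        self.removed_snp_ids: list = []
        if prune_alpha is not None:
            self.matrix, self.removed_snp_ids = prune_univariate(
                matrix, phenotype, prune_alpha
            )

    @classmethod
    def from_plink(cls, prefix, **kwargs) -> "PairStability":
        from .io import read_plink

        matrix, phenotype = read_plink(prefix)
        return cls(matrix, phenotype, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "PairStability":
        from .io import read_tsv

        matrix, phenotype = read_tsv(path)
        return cls(matrix, phenotype, **kwargs)

    def fit(self, seed: int = 0, plan: CvPlan | None = None, include_full: bool = True) -> StabilityResults:
        """Run all splits (and optionally the full-data scan)."""
        if plan is None:
            plan = make_splits(self.phenotype, self.n_repeats, seed)
        return run_stability(
            self.matrix,
            self.phenotype,
            statistic=self.statistic,
            k=self.k,
            plan=plan,
            tau=self.tau,
            alpha=self.alpha,
            include_full=include_full,
        )


def _fold_measures(matrix, phenotype, statistic, k, alpha):
    ranked = exhaustive_scan(matrix, phenotype, statistic=statistic, k=k)
    uni = univariate_scan(matrix, phenotype)
    threshold = alpha / matrix.n_snps
    sig_ids = [matrix.snp_ids[s] for s, r in enumerate(uni) if r.p_value <= threshold]
    hubs = hub_count(ranked, sig_ids)
    ranks = mtc_ranks(ranked.p_values(), T=comb(matrix.n_snps, 2), alpha=alpha)
    return ranked, sig_ids, hubs, ranks


def run_stability(
    matrix: GenotypeMatrix,
    phenotype: Phenotype,
    statistic: str,
    k: int,
    plan: CvPlan,
    tau: int = 100,
    alpha: float = 0.05,
    include_full: bool = True,
) -> StabilityResults:
    """Scan both folds of every split and measure fold-vs-fold stability."""
    if plan.assignments.shape[1] != matrix.n_samples:
        raise ValueError("plan does not match the number of samples")
    splits: list[SplitOutcome] = []
    failures: list[int] = []
    for r in range(plan.n_repeats):
        try:
            per_fold = []
            for fold in (0, 1):
                sel = plan.assignments[r] == fold
                per_fold.append(
                    _fold_measures(
                        matrix.subset_samples(sel), phenotype.subset(sel), statistic, k, alpha
                    )
                )
            (la, sa, ha, ma), (lb, sb, hb, mb) = per_fold
            k_eff = min(len(la), len(lb))
            grid = default_grid(k_eff)
            rho = rho_curve(la, lb, grid)
            jac = np.asarray([jaccard_topk(la, lb, int(kk)) for kk in grid])
            z = zic(la, lb, tau=tau, k_max=k_eff)
            splits.append(
                SplitOutcome(
                    repeat=r,
                    lists=(la, lb),
                    rho=rho,
                    jaccard=jac,
                    zic=z,
                    hub_counts=(ha, hb),
                    significant_snps=(sa, sb),
                    mtc=(ma, mb),
                )
            )
        except Exception:
            logger.exception("repeat %d failed; continuing", r)
            failures.append(r)

    full_list = None
    if include_full:
        full_list = exhaustive_scan(matrix, phenotype, statistic=statistic, k=k)

    return StabilityResults(
        statistic=statistic,
        k=k,
        tau=tau,
        alpha=alpha,
        plan=plan,
        splits=splits,
        full_list=full_list,
        n_snps=matrix.n_snps,
        failures=failures,
    )


def compare_statistics(res_a: StabilityResults, res_b: StabilityResults, k_grid=None) -> dict:
    """Union-scaled overlap between two statistics' full-data lists.

    Both results must have been fitted on identical splits (same plan) so
    their ZIC markers are comparable.  Returns per-k (only_a, both,
    only_b) fractions plus each statistic's mean ZIC.
    """
    if res_a.plan.seed != res_b.plan.seed or not np.array_equal(
        res_a.plan.assignments, res_b.plan.assignments
    ):
        raise ValueError("results were built on different cross-validation splits")
    if res_a.full_list is None or res_b.full_list is None:
        raise ValueError("both results need a full-data scan (include_full=True)")
    k_eff = min(len(res_a.full_list), len(res_b.full_list))
    if k_grid is None:
        k_grid = default_grid(k_eff)
    k_grid = np.asarray(sorted(set(int(x) for x in k_grid)), dtype=np.int64)
    fracs = np.asarray(
        [overlap_fractions(res_a.full_list, res_b.full_list, int(kk)) for kk in k_grid]
    )
    return {
        "ks": k_grid,
        "only_a": fracs[:, 0],
        "both": fracs[:, 1],
        "only_b": fracs[:, 2],
        "statistic_a": res_a.statistic,
        "statistic_b": res_b.statistic,
        "zic_mean_a": float(np.mean(res_a.zic_values)),
        "zic_mean_b": float(np.mean(res_b.zic_values)),
    }
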