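"""Exhaustive SNP-pair scanning with bounded top-k retention.

Every unordered SNP pair (i < j) is scored exactly once with the chosen
statistic; only the k best-scoring pairs are kept, in a bounded priority
queue keyed by (score descending, pair index ascending) so repeated runs
produce byte-identical lists.  Contingency tables for a whole block of
pairs sharing the left SNP are tallied in one vectorised pass, and the
chi-squared and log-linear LRT statistics are evaluated on the block at
once; GSS (hull geometry per pair) is evaluated pairwise.

Also here: the univariate chi-squared scan, Bonferroni pruning of
univariately significant SNPs, and hub counting (how many listed pairs
involve a given set of SNPs — strong-main-effect "hub" SNPs pair
promiscuously under the plain chi-squared ranking).
"""

from __future__ import annotations

import heapq
import logging

import numpy as np

from .io import GenotypeMatrix, Phenotype, build_single_table
from .ranking import PairEntry, RankedPairList
from .stats import (
    StatResult,
    _chi2_logsf_vec,
    chi2_logsf,
    chi2_test,
    gss_log_p_from_counts,
)

__all__ = [
    "STATISTICS",
    "exhaustive_scan",
    "univariate_scan",
    "prune_univariate",
    "hub_count",
]

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)

STATISTICS = ("chi2", "gss", "boost")


def _pair_counts_block(G: np.ndarray, y: np.ndarray, i: int) -> np.ndarray:
    """2x9 tables for all pairs (i, j), j > i, as a (M-i-1, 2, 9) array."""
    gi = G[:, i]
    right = G[:, i + 1 :]
    P = right.shape[1]
    ok = (gi[:, None] >= 0) & (right >= 0)
    # 18 cells per pair: v = 3*gi + gj, offset by 9 for cases
    v = (3 * gi[:, None] + right) + 9 * y[:, None]
    flat = np.where(ok, v + 18 * np.arange(P)[None, :], 18 * P)
    counts = np.bincount(flat.ravel(), minlength=18 * P + 1)[: 18 * P]
    return counts.reshape(P, 2, 9)


def _chi2_block(counts: np.ndarray):
    """Vectorised Pearson X^2 (df 8) over a (P, 2, 9) block."""
    c = counts.astype(float)
    n = c.sum(axis=(1, 2))
    row = c.sum(axis=2)
    col = c.sum(axis=1)
    ok = (row > 0).all(axis=1) & (n > 0)
    safe_n = np.where(n > 0, n, 1.0)
    expected = row[:, :, None] * col[:, None, :] / safe_n[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (c - expected) ** 2 / expected, 0.0)
    x2 = cells.sum(axis=(1, 2))
    log_p = _chi2_logsf_vec(x2, 8)
    return x2, log_p, ok


def _ipf_block(cube: np.ndarray, tol: float, max_iter: int):
    """Vectorised IPF of [X1X2][X1Y][X2Y] over a (P, 3, 3, 2) block."""
    m12 = cube.sum(axis=3)
    m1y = cube.sum(axis=2)
    m2y = cube.sum(axis=1)
    mu = np.ones_like(cube)
    converged = np.zeros(cube.shape[0], dtype=bool)
    for _ in range(max_iter):
        for margin, axis in ((m12, 3), (m1y, 2), (m2y, 1)):
            cur = mu.sum(axis=axis)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, margin / np.where(cur > 0, cur, 1.0), 0.0)
            mu *= np.expand_dims(ratio, axis)
        disc = np.maximum(
            np.abs(mu.sum(axis=3) - m12).max(axis=(1, 2)),
            np.maximum(
                np.abs(mu.sum(axis=2) - m1y).max(axis=(1, 2)),
                np.abs(mu.sum(axis=1) - m2y).max(axis=(1, 2)),
            ),
        )
        converged = disc < tol
        if converged.all():
            break
    return mu, converged


def _boost_block(counts: np.ndarray, screen_threshold=None):
    """Vectorised log-linear LRT (df 4) over a (P, 2, 9) block.

    With a screening threshold, pairs whose Kirkwood screen value falls
    below it skip the exact fit (masked out of the results).
    """
    from .stats import IPF_MAX_ITER, IPF_TOL, ksa_screen

    c = counts.astype(float)
    n = c.sum(axis=(1, 2))
    row = c.sum(axis=2)
    ok = (row > 0).all(axis=1) & (n > 0)
    cube = c.reshape(-1, 2, 3, 3).transpose(0, 2, 3, 1)

    if screen_threshold is not None and np.isfinite(screen_threshold):
        keep = np.zeros(len(c), dtype=bool)
        for p in np.flatnonzero(ok):
            keep[p] = ksa_screen(cube[p]) >= screen_threshold
        ok = ok & keep

    mu, converged = _ipf_block(cube, IPF_TOL, IPF_MAX_ITER)
    pos = cube > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pos, cube * np.log(np.where(pos, cube, 1.0) / np.where(mu > 0, mu, 1.0)), 0.0)
    lrt = np.maximum(2.0 * terms.sum(axis=(1, 2, 3)), 0.0)
    log_p = _chi2_logsf_vec(lrt, 4)
    return lrt, log_p, ok, converged


def _gss_block(counts: np.ndarray):
    scores = np.empty(len(counts))
    log_ps = np.empty(len(counts))
    ok = np.ones(len(counts), dtype=bool)
    for p in range(len(counts)):
        n0 = counts[p, 0].sum()
        n1 = counts[p, 1].sum()
        if n0 == 0 or n1 == 0:
            ok[p] = False
            continue
        lp = gss_log_p_from_counts(counts[p])
        log_ps[p] = lp
        scores[p] = -lp / _LN10
    return scores, log_ps, ok


def exhaustive_scan(
    matrix: GenotypeMatrix,
    phenotype: Phenotype,
    statistic: str = "chi2",
    k: int = 10_000,
    screen_threshold: float | None = None,
) -> RankedPairList:
    """Score all C(M, 2) SNP pairs, keeping the top k.

    Ranking key: score descending (X^2 / LRT value; -log10 p for GSS),
    ties broken by ascending pair index.  Pairs whose statistic cannot be
    evaluated (degenerate tables) are logged and skipped but still counted
    in ``total_pairs_scanned``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if matrix.n_snps < 2:
        raise ValueError("need at least two SNPs to scan pairs")
    if k < 1:
        raise ValueError("k must be >= 1")
    if phenotype.n_cases == 0 or phenotype.n_controls == 0:
        raise ValueError("both cases and controls are required")
    if matrix.n_samples != phenotype.n_samples:
        raise ValueError("genotype matrix and phenotype have different sample counts")

    G = matrix.genotypes
    y = phenotype.labels
    M = matrix.n_snps
    heap: list = []
    n_skipped = 0
    worst = None

    for i in range(M - 1):
        counts = _pair_counts_block(G, y, i)
        if statistic == "chi2":
            scores, log_ps, ok = _chi2_block(counts)
        elif statistic == "boost":
            scores, log_ps, ok, _conv = _boost_block(counts, screen_threshold)
        else:
            scores, log_ps, ok = _gss_block(counts)
        for idx in range(counts.shape[0]):
            j = i + 1 + idx
            if not ok[idx]:
                n_skipped += 1
                continue
            score = float(scores[idx])
            key = (score, -i, -j)
            if len(heap) < k:
                heapq.heappush(heap, (key, i, j, score, float(log_ps[idx])))
                worst = heap[0][0]
            elif key > worst:
                heapq.heapreplace(heap, (key, i, j, score, float(log_ps[idx])))
                worst = heap[0][0]

    if n_skipped:
        logger.warning("%d of %d pairs skipped (degenerate or screened)", n_skipped, M * (M - 1) // 2)

    items = sorted(heap, key=lambda t: (-t[3], t[1], t[2]))
    ids = matrix.snp_ids
    entries = [
        PairEntry(i, j, ids[i], ids[j], score, float(np.exp(log_p)))
        for (_, i, j, score, log_p) in items
    ]
    return RankedPairList(
        entries=entries,
        k_requested=k,
        statistic_name=statistic,
        total_pairs_scanned=M * (M - 1) // 2,
    )


def univariate_scan(matrix: GenotypeMatrix, phenotype: Phenotype) -> list:
    """Univariate chi-squared (df 2) on every SNP's 2x3 table."""
    results = []
    for s in range(matrix.n_snps):
        table = build_single_table(matrix, phenotype, s)
        results.append(chi2_test(table))
    return results


def prune_univariate(matrix: GenotypeMatrix, phenotype: Phenotype, alpha: float = 0.05):
    """Drop SNPs that are univariately significant at the Bonferroni level.

    A SNP is removed when its univariate chi-squared p-value is at most
    alpha / n_snps.  Returns the reduced matrix and the removed SNP ids.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    threshold = alpha / matrix.n_snps
    results = univariate_scan(matrix, phenotype)
    removed = [s for s, r in enumerate(results) if r.p_value <= threshold]
    if len(removed) == matrix.n_snps:
        raise ValueError("pruning would remove every SNP")
    removed_ids = [matrix.snp_ids[s] for s in removed]
    keep = np.setdiff1d(np.arange(matrix.n_snps), np.asarray(removed, dtype=int))
    return matrix.subset_snps(keep), removed_ids


def hub_count(ranked: RankedPairList, significant_snp_ids) -> int:
    """Number of listed pairs involving at least one SNP from the given set."""
    sig = set(significant_snp_ids)
    return sum(1 for e in ranked.entries if e.id1 in sig or e.id2 in sig)
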