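"""Pair-association statistics for case-control contingency tables.

Three statistics rank SNP pairs by how strongly their joint genotype
distribution separates cases from controls:

* :func:`chi2_test` — Pearson's goodness-of-fit test on the 2x3 or 2x9
  table (df = V-1 for V genotype columns);
* :func:`boost_lrt` — likelihood-ratio test of the saturated 3x3x2
  log-linear model against the homogeneous-association model
  [X1X2][X1Y][X2Y] (all two-way margins, no three-way term), which is
  equivalent to testing the interaction term of a logistic regression on
  the two SNPs.  The null model is fitted by iterative proportional
  fitting (:func:`fit_main_effects`); df = 4.  A cheap Kirkwood
  superposition screen (:func:`ksa_screen`) upper-bounds the LRT and can
  skip the exact fit during large scans;
* :func:`gss_test` — the gain in sensitivity and specificity: the pair's
  ROC curve (built from per-genotype case prevalences) is compared with
  the convex hull of the two single-SNP ROC curves, which represents the
  null that cases and controls differ only through univariate
  association.  The p-value is a min-max of two binomial tail
  probabilities: for every pair-ROC vertex strictly above the hull, the
  most favourable (maximal) probability over hull operating points of
  drawing at least that many cases and at most that many controls; the
  reported p is the minimum over vertices.

All p-values are computed in log space so extreme associations remain
finite and rankable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .io import PairTable, SingleTable

__all__ = [
    "StatResult",
    "RocCurve",
    "LoglinearFit",
    "chi2_test",
    "boost_lrt",
    "fit_main_effects",
    "ksa_screen",
    "prevalence_map",
    "roc_from_table",
    "hull_union",
    "gss_test",
    "chi2_logsf",
]

_LN10 = np.log(10.0)

#: Iterative-proportional-fitting defaults: margin tolerance and cycle cap.
IPF_TOL = 1e-8
IPF_MAX_ITER = 200

#: Points interpolated on each hull edge (plus the vertices) in gss_test.
GSS_EDGE_POINTS = 64


@dataclass
class StatResult:
    """One statistic's outcome for one SNP or SNP pair.

    ``statistic`` is the ranking score (the X^2 / LRT value; for GSS the
    score is -log10 p), ``log_p`` the natural-log p-value, ``df`` the
    degrees of freedom where the statistic has one.
    """

    statistic: float
    p_value: float
    log_p: float
    df: int | None = None
    converged: bool = True


@dataclass
class RocCurve:
    """Monotone ROC step curve with the cumulative counts behind it."""

    points: np.ndarray        # (T, 2) of (fpr, tpr), (0,0) ... (1,1)
    cum_counts: np.ndarray    # (T, 2) of (cum_controls, cum_cases)
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (T, 2)")
        if (np.diff(pts[:, 0]) < -1e-12).any() or (np.diff(pts[:, 1]) < -1e-12).any():
            raise ValueError("ROC vertices must be non-decreasing")
        self.points = pts
        self.cum_counts = np.asarray(self.cum_counts, dtype=np.int64)


@dataclass
class LoglinearFit:
    """IPF fit of the homogeneous-association log-linear model."""

    fitted: np.ndarray  # 3x3x2 expected counts
    loglik: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi2_logsf(x: float, df: int) -> float:
    """log of the upper chi-squared tail Q(df/2, x/2), exact for even df.

    For even df the regularized upper incomplete gamma is a finite sum,
    Q(k, t) = e^-t * sum_{i<k} t^i / i!, evaluated with logsumexp so the
    result is finite for any finite statistic.
    """
    x = float(x)
    if x <= 0:
        return 0.0
    if df % 2 == 0:
        k = df // 2
        t = x / 2.0
        i = np.arange(k)
        return float(-t + logsumexp(i * np.log(t) - gammaln(i + 1)))
    from scipy.stats import chi2 as _chi2dist

    return float(_chi2dist.logsf(x, df))


def _chi2_logsf_vec(x: np.ndarray, df: int) -> np.ndarray:
    # vectorised even-df variant used by the scanner
    x = np.asarray(x, dtype=float)
    k = df // 2
    t = np.where(x > 0, x / 2.0, 1.0)
    i = np.arange(k)
    with np.errstate(divide="ignore"):
        terms = i * np.log(t)[..., None] - gammaln(i + 1)
    out = -t + logsumexp(terms, axis=-1)
    return np.where(x > 0, out, 0.0)


def chi2_stat_from_counts(counts: np.ndarray):
    """(X^2, df, log_p) from a 2xV count table; zero-expected cells add 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    row = counts.sum(axis=1)
    if n <= 0 or (row > 0).sum() < 2:
        raise ValueError("degenerate table: need counts in both phenotype rows")
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    x2 = float(cells.sum())
    df = counts.shape[1] - 1  # (2-1) * (V-1)
    return x2, df, chi2_logsf(x2, df)


def chi2_test(table) -> StatResult:
    """Pearson's test for association on a SingleTable (df 2) or PairTable (df 8)."""
    if isinstance(table, (SingleTable, PairTable)):
        counts = table.counts
    else:
        counts = np.asarray(table)
    x2, df, log_p = chi2_stat_from_counts(counts)
    return StatResult(statistic=x2, p_value=float(np.exp(log_p)), log_p=log_p, df=df)


# ---------------------------------------------------------------------------
# BOOST-style log-linear likelihood ratio
# ---------------------------------------------------------------------------

def _as_cube(table) -> np.ndarray:
    """2x9 PairTable counts -> 3x3x2 (g1, g2, phenotype) cube."""
    if isinstance(table, PairTable):
        counts = table.counts
    else:
        counts = np.asarray(table)
    if counts.shape == (2, 9):
        return counts.reshape(2, 3, 3).transpose(1, 2, 0).astype(float)
    if counts.shape == (3, 3, 2):
        return np.asarray(counts, dtype=float)
    raise ValueError(f"expected a 2x9 table or 3x3x2 cube, got shape {counts.shape}")


def fit_main_effects(table, tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER) -> LoglinearFit:
    """Fit [X1X2][X1Y][X2Y] by iterative proportional fitting.

    Cycles over the three two-way margins until the largest absolute margin
    discrepancy falls below ``tol``.  Zero observed margins force zero
    fitted cells; cells backed by positive margins stay positive.
    """
    n = _as_cube(table)
    total = n.sum()
    if total <= 0:
        raise ValueError("empty table")
    m12 = n.sum(axis=2)
    m1y = n.sum(axis=1)
    m2y = n.sum(axis=0)

    mu = np.ones_like(n)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        cur = mu.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu *= np.where(cur > 0, m12 / np.where(cur > 0, cur, 1.0), 0.0)[:, :, None]
        cur = mu.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu *= np.where(cur > 0, m1y / np.where(cur > 0, cur, 1.0), 0.0)[:, None, :]
        cur = mu.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu *= np.where(cur > 0, m2y / np.where(cur > 0, cur, 1.0), 0.0)[None, :, :]
        disc = max(
            np.abs(mu.sum(axis=2) - m12).max(),
            np.abs(mu.sum(axis=1) - m1y).max(),
            np.abs(mu.sum(axis=0) - m2y).max(),
        )
        if disc < tol:
            converged = True
            break

    pos = n > 0
    loglik = float((n[pos] * np.log(mu[pos] / total)).sum())
    return LoglinearFit(fitted=mu, loglik=loglik, iterations=iterations, converged=converged)


def boost_lrt(table) -> StatResult:
    """Saturated vs homogeneous-association LRT on the 3x3x2 cube, df = 4.

    LRT = 2 * sum n * ln(n / mu_hat) with 0*ln 0 := 0, clamped at >= 0.
    A non-converged IPF fit is flagged (``converged=False``) and ranked by
    the value achieved.
    """
    n = _as_cube(table)
    fit = fit_main_effects(n)
    pos = n > 0
    lrt = float(2.0 * (n[pos] * np.log(n[pos] / fit.fitted[pos])).sum())
    lrt = max(lrt, 0.0)
    log_p = chi2_logsf(lrt, 4)
    return StatResult(
        statistic=lrt,
        p_value=float(np.exp(log_p)),
        log_p=log_p,
        df=4,
        converged=fit.converged,
    )


def ksa_screen(table) -> float:
    """Kirkwood superposition screening statistic (upper bound on the LRT).

    The Kirkwood approximation mu(g1,g2,y) proportional to
    p(g1,g2) p(g1,y) p(g2,y) / (p(g1) p(g2) p(y)), renormalised to the
    grand total, gives 2 * sum n ln(n / mu) >= LRT, so pairs whose screen
    value falls below a threshold cannot reach that LRT and may skip the
    exact fit.
    """
    n = _as_cube(table)
    total = n.sum()
    if total <= 0:
        raise ValueError("empty table")
    p12 = n.sum(axis=2) / total
    p1y = n.sum(axis=1) / total
    p2y = n.sum(axis=0) / total
    p1 = n.sum(axis=(1, 2)) / total
    p2 = n.sum(axis=(0, 2)) / total
    py = n.sum(axis=(0, 1)) / total
    denom = p1[:, None, None] * p2[None, :, None] * py[None, None, :]
    num = p12[:, :, None] * p1y[:, None, :] * p2y[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    s = mu.sum()
    if s <= 0:
        return 0.0
    mu *= total / s
    pos = n > 0
    return float(2.0 * (n[pos] * np.log(n[pos] / mu[pos])).sum())


# ---------------------------------------------------------------------------
# GSS: prevalence mapping, ROC construction, hull, min-max binomials
# ---------------------------------------------------------------------------

def prevalence_map(table) -> np.ndarray:
    """Per-genotype sample prevalence phi_v = cases_v / (cases_v + controls_v).

    Empty genotype cells get phi = 0 (and sort last in the ROC ordering).
    """
    counts = table.counts if isinstance(table, (SingleTable, PairTable)) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(tot > 0, counts[1] / np.where(tot > 0, tot, 1.0), 0.0)
    return phi


def _roc_arrays(counts: np.ndarray):
    """ROC vertices from a 2xV table: (fpr, tpr, cum_controls, cum_cases).

    Genotype columns are sorted by descending prevalence, ties broken by
    ascending control count then column index; empty columns are dropped
    (they cannot move the curve).  Consecutive duplicate vertices are
    collapsed.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n0 = int(counts[0].sum())
    n1 = int(counts[1].sum())
    tot = counts.sum(axis=0)
    live = np.flatnonzero(tot > 0)
    phi = counts[1, live] / tot[live]
    order = live[np.lexsort((live, counts[0, live], -phi))]
    cum0 = np.concatenate(([0], np.cumsum(counts[0, order])))
    cum1 = np.concatenate(([0], np.cumsum(counts[1, order])))
    fpr = cum0 / n0 if n0 else np.zeros_like(cum0, dtype=float)
    tpr = cum1 / n1 if n1 else np.zeros_like(cum1, dtype=float)
    # collapse duplicate vertices (zero-count steps)
    keep = np.ones(len(fpr), dtype=bool)
    keep[1:] = (np.diff(cum0) > 0) | (np.diff(cum1) > 0)
    return fpr[keep], tpr[keep], cum0[keep], cum1[keep], n0, n1


def roc_from_table(table) -> RocCurve:
    """Build the prevalence-ordered ROC curve of a SingleTable or PairTable."""
    counts = table.counts if isinstance(table, (SingleTable, PairTable)) else np.asarray(table)
    fpr, tpr, cum0, cum1, n0, n1 = _roc_arrays(counts)
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC construction needs both cases and controls")
    return RocCurve(
        points=np.column_stack([fpr, tpr]),
        cum_counts=np.column_stack([cum0, cum1]),
        n_cases=n1,
        n_controls=n0,
    )


def _upper_hull(points: np.ndarray) -> np.ndarray:
    """Upper concave chain (ROC convex hull) of a point set incl. (0,0),(1,1)."""
    pts = np.vstack([points, [[0.0, 0.0], [1.0, 1.0]]])
    pts = np.unique(pts, axis=0)  # sorts lexicographically by (x, y)
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:  # a is on or below chord o->p: not on the upper hull
                hull.pop()
            else:
                break
        hull.append(p)
    arr = np.asarray(hull)
    # keep the initial vertical rise at fpr=0 and the terminal vertex (1,1)
    if arr[0][0] == 0.0 and arr[0][1] > 0.0:
        arr = np.vstack([[0.0, 0.0], arr])
    return arr


def hull_union(r1: RocCurve, r2: RocCurve) -> RocCurve:
    """Convex hull (in ROC space) of the union of two curves' vertices."""
    if (r1.n_cases, r1.n_controls) != (r2.n_cases, r2.n_controls):
        raise ValueError("ROC curves come from different case/control totals")
    hull = _upper_hull(np.vstack([r1.points, r2.points]))
    cum = np.column_stack([
        np.rint(hull[:, 0] * r1.n_controls).astype(np.int64),
        np.rint(hull[:, 1] * r1.n_cases).astype(np.int64),
    ])
    return RocCurve(points=hull, cum_counts=cum, n_cases=r1.n_cases, n_controls=r1.n_controls)


def _hull_height(hull: np.ndarray):
    """Interpolatable hull upper boundary: unique fpr -> max tpr."""
    x = hull[:, 0]
    y = hull[:, 1]
    ux = np.unique(x)
    uy = np.array([y[x == v].max() for v in ux])
    return ux, uy


def _hull_grid(hull: np.ndarray, n_edge: int):
    """Hull vertices plus ``n_edge`` evenly spaced points on each edge."""
    us = [hull[:, 0]]
    vs = [hull[:, 1]]
    t = np.linspace(0.0, 1.0, n_edge + 2)[1:-1]
    for a, b in zip(hull[:-1], hull[1:]):
        us.append(a[0] + t * (b[0] - a[0]))
        vs.append(a[1] + t * (b[1] - a[1]))
    return np.concatenate(us), np.concatenate(vs)


def _binom_logsf_ge(c: int, n: int, p: np.ndarray) -> np.ndarray:
    """log Pr[Bin(n, p) >= c], elementwise over p, finite in the deep tail."""
    if c <= 0:
        return np.zeros_like(p)
    if c > n:
        return np.full_like(p, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = binom.logsf(c - 1, n, p)
        # deep-tail fallback: geometric bound from the boundary pmf
        deep = ~np.isfinite(out) & (p > 0) & (p < 1)
        if deep.any():
            pd = p[deep]
            lp = binom.logpmf(c, n, pd)
            ratio = (n - c) * pd / ((c + 1) * (1.0 - pd))
            corr = np.where(ratio < 1, -np.log1p(-np.minimum(ratio, 1 - 1e-12)), 0.0)
            out[deep] = lp + corr
    return out


def _binom_logcdf_le(c: int, n: int, p: np.ndarray) -> np.ndarray:
    """log Pr[Bin(n, p) <= c], elementwise over p, finite in the deep tail."""
    if c >= n:
        return np.zeros_like(p)
    if c < 0:
        return np.full_like(p, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = binom.logcdf(c, n, p)
        deep = ~np.isfinite(out) & (p > 0) & (p < 1)
        if deep.any():
            pd = p[deep]
            lp = binom.logpmf(c, n, pd)
            ratio = c * (1.0 - pd) / ((n - c + 1) * pd)
            corr = np.where(ratio < 1, -np.log1p(-np.minimum(ratio, 1 - 1e-12)), 0.0)
            out[deep] = lp + corr
    return out


def gss_log_p_from_counts(counts: np.ndarray, n_edge: int = GSS_EDGE_POINTS) -> float:
    """Natural-log GSS p-value from a 2x9 pair count table."""
    counts = np.asarray(counts, dtype=np.int64)
    n0 = int(counts[0].sum())
    n1 = int(counts[1].sum())
    if n0 == 0 or n1 == 0:
        return 0.0  # degenerate: p = 1
    cube = counts.reshape(2, 3, 3)
    s1 = cube.sum(axis=2)
    s2 = cube.sum(axis=1)

    f1, t1, *_ = _roc_arrays(s1)
    f2, t2, *_ = _roc_arrays(s2)
    hull = _upper_hull(
        np.vstack([np.column_stack([f1, t1]), np.column_stack([f2, t2])])
    )
    hx, hy = _hull_height(hull)
    us, vs = _hull_grid(hull, n_edge)

    fp_, tp_, cum0, cum1, _, _ = _roc_arrays(counts)
    best = 0.0
    for fpr_t, tpr_t, f_cnt, c_cnt in zip(fp_, tp_, cum0, cum1):
        if tpr_t <= np.interp(fpr_t, hx, hy) + 1e-12:
            continue  # on or below the null hull: no gain at this vertex
        log_p_t = float(
            np.max(
                _binom_logsf_ge(int(c_cnt), n1, vs)
                + _binom_logcdf_le(int(f_cnt), n0, us)
            )
        )
        best = min(best, log_p_t)
    return min(best, 0.0)


def gss_test(pair_table, n_edge: int = GSS_EDGE_POINTS) -> StatResult:
    """Gain-in-sensitivity-and-specificity test on a 2x9 pair table.

    Score is -log10 p (larger = more significant); degenerate tables get
    p = 1.
    """
    counts = pair_table.counts if isinstance(pair_table, PairTable) else np.asarray(pair_table)
    log_p = gss_log_p_from_counts(counts, n_edge=n_edge)
    p = float(np.exp(log_p))
    if p <= 0.0:
        p = float(np.nextafter(0, 1))
    return StatResult(statistic=-log_p / _LN10, p_value=p, log_p=log_p, df=None)
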