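"""Comparing ranked top-k SNP-pair lists.

Two exhaustive scans of different sample halves produce two top-k lists
that usually do not contain the same pairs, so classical rank correlation
does not apply directly.  The extension used here completes both lists
over the union of their elements: an element absent from a list must rank
beyond that list's end, and all absent elements share the fractional
midrank of the tail positions, (n + 1 + m) / 2 for a list of length n and
a union of size m.  Spearman's rho is then the Pearson correlation of the
two extended rank vectors.

Because two independent draws of k pairs from a huge pair universe share
almost nothing, rho between unrelated lists is *negative* (each list's
elements sit early in itself and late in the other).  The Zero Index
Crossing (ZIC) exploits this: it is the smallest prefix size k at or
beyond a minimum threshold tau where rho(top-k, top-k) drops to or below
zero — a data-driven size for the stably selected pair set.

Set-based measures (Jaccard index, union-scaled overlap fractions) are
provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "PairEntry",
    "RankedPairList",
    "RhoCurve",
    "ZicResult",
    "extend_ranks",
    "spearman_incomplete",
    "rho_curve",
    "default_grid",
    "zic",
    "jaccard_topk",
    "overlap_fractions",
]


class PairEntry(NamedTuple):
    """One scored SNP pair; ``i < j`` are variant indices (-1 if unknown)."""

    i: int
    j: int
    id1: str
    id2: str
    score: float
    p_value: float

    @property
    def key(self) -> tuple:
        return (self.id1, self.id2)


@dataclass
class RankedPairList:
    """Top-k list of scored SNP pairs, sorted most-significant first."""

    entries: list
    k_requested: int
    statistic_name: str = ""
    total_pairs_scanned: int = 0

    def __post_init__(self) -> None:
        if len(self.entries) > self.k_requested:
            raise ValueError("more entries than k_requested")
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pairs in ranked list")
        for a, b in zip(self.entries, self.entries[1:]):
            if b.score > a.score:
                raise ValueError("ranked list must be sorted by descending score")
            if b.score == a.score and a.i >= 0 and b.i >= 0 and (b.i, b.j) < (a.i, a.j):
                raise ValueError("ties must be ordered by ascending pair index")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def keys(self) -> list:
        """Pair identities (snp_id_1, snp_id_2) in rank order."""
        return [e.key for e in self.entries]

    def p_values(self) -> np.ndarray:
        return np.asarray([e.p_value for e in self.entries], dtype=float)


@dataclass
class RhoCurve:
    """Incomplete-list Spearman rho evaluated on a grid of prefix sizes."""

    ks: np.ndarray
    rhos: np.ndarray
    k_max: int


@dataclass
class ZicResult:
    """Zero Index Crossing: first prefix size >= tau with rho <= 0."""

    zic: int
    censored: bool
    tau: int
    k_max: int

    @property
    def value(self) -> int:
        """The crossing, or k_max when censored (callers should check)."""
        return self.zic


def _as_keys(x) -> list:
    if isinstance(x, RankedPairList):
        return x.keys()
    return list(x)


def extend_ranks(a, b):
    """Extend two top-k lists to rank vectors over their element union.

    Elements present in a list keep their rank 1..n; elements absent from a
    list of length n all receive the midrank (n + 1 + m) / 2, where m is
    the union size, preserving the fractional-ranking mean (m + 1) / 2.

    Returns ``(ranks_a, ranks_b, union)`` with the union ordered as a's
    elements followed by b-only elements in b order.
    """
    ka, kb = _as_keys(a), _as_keys(b)
    pos_a = {key: r for r, key in enumerate(ka, start=1)}
    pos_b = {key: r for r, key in enumerate(kb, start=1)}
    union = ka + [key for key in kb if key not in pos_a]
    m = len(union)
    mid_a = (len(ka) + 1 + m) / 2.0
    mid_b = (len(kb) + 1 + m) / 2.0
    ranks_a = np.asarray([pos_a.get(key, mid_a) for key in union], dtype=float)
    ranks_b = np.asarray([pos_b.get(key, mid_b) for key in union], dtype=float)
    return ranks_a, ranks_b, union


def spearman_incomplete(a, b) -> float:
    """Spearman's rho between two (possibly non-overlapping) top-k lists.

    Pearson correlation of the extended rank vectors; 0.0 when a rank
    vector is constant (degenerate one-element case).
    """
    ka, kb = _as_keys(a), _as_keys(b)
    if not ka and not kb:
        raise ValueError("both lists are empty")
    ranks_a, ranks_b, _ = extend_ranks(ka, kb)
    da = ranks_a - ranks_a.mean()
    db = ranks_b - ranks_b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va <= 0 or vb <= 0:
        return 0.0
    return float((da @ db) / np.sqrt(va * vb))


def _prefix_rho_stream(ka: list, kb: list, k_max: int):
    """Yield (k, rho or None) for equal prefix sizes k = 1..k_max in O(k_max).

    Uses the closed form of the extended-rank correlation for equal-length
    prefixes: with c common elements the union has m = 2k - c elements,
    absent elements share the midrank (k + 1 + m) / 2, and the sums over
    the extension reduce to running sums over elements as they enter both
    prefixes.  rho is None where the extension is constant (m <= 1).
    """
    pos_a = {key: r for r, key in enumerate(ka[:k_max], start=1)}
    pos_b = {key: r for r, key in enumerate(kb[:k_max], start=1)}
    # common element joins the intersection once both prefixes contain it
    events: dict[int, list] = {}
    for key, ra in pos_a.items():
        rb = pos_b.get(key)
        if rb is not None:
            events.setdefault(max(ra, rb), []).append((ra, rb))

    S = T = U = 0.0  # sums of ra*rb, ra, rb over the joined intersection
    c = 0
    for k in range(1, k_max + 1):
        for ra, rb in events.get(k, ()):
            S += ra * rb
            T += ra
            U += rb
            c += 1
        m = 2 * k - c
        if m <= 1:
            yield k, None
            continue
        mid = (k + 1 + m) / 2.0
        mean = (m + 1) / 2.0
        tri = k * (k + 1) / 2.0
        sum_ab = S + (tri - T) * mid + (tri - U) * mid
        sumsq = k * (k + 1) * (2 * k + 1) / 6.0 + (m - k) * mid * mid
        var = sumsq - m * mean * mean
        if var <= 0:
            yield k, None
            continue
        yield k, (sum_ab - m * mean * mean) / var  # var_a == var_b == var


def default_grid(k_max: int, dense_to: int = 200, factor: float = 1.1) -> np.ndarray:
    """Prefix-size grid: 1..200 linear, then geometric (x1.1) to k_max."""
    ks = list(range(1, min(dense_to, k_max) + 1))
    k = float(dense_to)
    while ks[-1] < k_max:
        k *= factor
        ks.append(min(int(np.ceil(k)), k_max))
    return np.unique(np.asarray(ks, dtype=np.int64))


def rho_curve(a, b, grid=None) -> RhoCurve:
    """Incomplete-list rho between top-k prefixes for each k in ``grid``."""
    ka, kb = _as_keys(a), _as_keys(b)
    k_max = min(len(ka), len(kb))
    if k_max < 1:
        raise ValueError("both lists must be non-empty")
    if grid is None:
        grid = default_grid(k_max)
    grid = np.asarray(sorted(set(int(k) for k in grid)), dtype=np.int64)
    if grid[0] < 1 or grid[-1] > k_max:
        raise ValueError("grid must lie within [1, min(len(a), len(b))]")
    want = set(grid.tolist())
    rhos = {}
    for k, rho in _prefix_rho_stream(ka, kb, int(grid[-1])):
        if k in want:
            rhos[k] = 0.0 if rho is None else rho
    return RhoCurve(ks=grid, rhos=np.asarray([rhos[k] for k in grid]), k_max=k_max)


def zic(a, b, tau: int = 100, k_max: int | None = None) -> ZicResult:
    """Zero Index Crossing of the exact per-k rho sequence.

    Searches every prefix size k = tau..k_max (not a display grid) for the
    first rho <= 0; censored at k_max when no crossing exists.  Undefined
    rho (constant extension, only possible at k <= 1) never crosses.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    ka, kb = _as_keys(a), _as_keys(b)
    limit = min(len(ka), len(kb))
    if k_max is not None:
        limit = min(limit, int(k_max))
    if limit < 1:
        raise ValueError("both lists must be non-empty")
    for k, rho in _prefix_rho_stream(ka, kb, limit):
        if k >= tau and rho is not None and rho <= 0:
            return ZicResult(zic=k, censored=False, tau=tau, k_max=limit)
    return ZicResult(zic=limit, censored=True, tau=tau, k_max=limit)


def jaccard_topk(a, b, k: int) -> float:
    """|A_k intersect B_k| / |A_k union B_k| for the top-k prefixes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sa = set(_as_keys(a)[:k])
    sb = set(_as_keys(b)[:k])
    union = sa | sb
    if not union:
        raise ValueError("both lists are empty")
    return len(sa & sb) / len(union)


def overlap_fractions(a, b, k: int):
    """Union-scaled (only_a, both, only_b) fractions of the top-k prefixes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sa = set(_as_keys(a)[:k])
    sb = set(_as_keys(b)[:k])
    union = sa | sb
    if not union:
        raise ValueError("both lists are empty")
    m = len(union)
    return (len(sa - sb) / m, len(sa & sb) / m, len(sb - sa) / m)
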