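"""Synthetic case-control GWAS data with planted main effects and pairs.

The generator emulates the statistical structure the stability analysis
relies on, at desk scale: biallelic SNPs in Hardy-Weinberg equilibrium
with minor-allele frequencies drawn uniformly from a configurable range,
a handful of strong-main-effect "hub" SNPs, and planted SNP pairs whose
joint association exceeds their marginal associations.

Disease risk follows a liability (logistic) model on the log-odds scale:

    logit P(case) = logit(baseline) + sum_s g_s * ln(OR_s) + sum_pairs off[g_i, g_j]

where ``g`` is the minor-allele count and ``off`` is a 3x3 table of
log-odds offsets.  The ``xor`` preset raises odds by ``theta`` exactly on
the odd-genotype-sum cells; with both SNPs at MAF 0.5 (enforced) the
case and control marginal genotype distributions of each planted SNP are
identical, giving pure bivariate association with no main effect — the
construction that makes pruning-invariance claims testable.

Individuals are drawn and assigned by rejection sampling until the case
and control quotas are met exactly, so the realised sample sizes always
match the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .io import MISSING, GenotypeMatrix, Phenotype
from .io import write_plink  # re-exported: simulation output is PLINK-writable

__all__ = [
    "SimConfig",
    "PlantedPair",
    "TruthTable",
    "preset_penetrance",
    "simulate",
    "write_plink",
]

PENETRANCE_PRESETS = ("xor", "threshold", "multiplicative")


def preset_penetrance(name: str, theta: float) -> np.ndarray:
    """3x3 log-odds offset table for a named interaction pattern.

    * ``xor``: ln(theta) on cells with odd genotype sum — pure epistasis
      (flat marginals at MAF 0.5);
    * ``threshold``: ln(theta) when both genotypes carry a minor allele;
    * ``multiplicative``: g1 * g2 * ln(theta).

    ``theta = 1`` gives the all-zero (null) table.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if name == "xor":
        return np.where((g1 + g2) % 2 == 1, np.log(theta), 0.0)
    if name == "threshold":
        return np.where((g1 >= 1) & (g2 >= 1), np.log(theta), 0.0)
    if name == "multiplicative":
        return g1 * g2 * np.log(theta)
    raise ValueError(f"unknown penetrance preset {name!r}; expected one of {PENETRANCE_PRESETS}")


@dataclass
class PlantedPair:
    """A planted SNP pair: preset name (or explicit 3x3 offsets) and strength."""

    i: int
    j: int
    preset: str | np.ndarray = "xor"
    theta: float = 2.0

    def offsets(self) -> np.ndarray:
        if isinstance(self.preset, str):
            return preset_penetrance(self.preset, self.theta)
        off = np.asarray(self.preset, dtype=float)
        if off.shape != (3, 3):
            raise ValueError("explicit pair offsets must be a 3x3 table")
        return off


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_snps: int
    n_cases: int
    n_controls: int
    maf_range: tuple = (0.05, 0.5)
    main_effects: list = field(default_factory=list)  # (snp_index, odds_ratio)
    pairs: list = field(default_factory=list)         # PlantedPair or (i, j, preset, theta)
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0
    main_effect_maf: float | None = 0.3  # forced MAF of planted main-effect SNPs

    def planted_pairs(self) -> list:
        out = []
        for p in self.pairs:
            if isinstance(p, PlantedPair):
                out.append(p)
            else:
                out.append(PlantedPair(*p))
        return out

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("invalid sizes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for s, or_ in self.main_effects:
            if not 0 <= s < self.n_snps:
                raise ValueError(f"main-effect SNP {s} out of range")
            if or_ <= 0:
                raise ValueError("odds ratios must be > 0")
        for p in self.planted_pairs():
            if not (0 <= p.i < self.n_snps and 0 <= p.j < self.n_snps) or p.i == p.j:
                raise ValueError(f"planted pair ({p.i}, {p.j}) out of range")
            p.offsets()  # shape/validity check


@dataclass
class TruthTable:
    """What was planted, for scoring recovery downstream."""

    mafs: np.ndarray
    main_effects: list          # (snp_index, odds_ratio)
    pairs: list                 # (i, j, offsets 3x3)
    n_cases: int
    n_controls: int

    def pair_keys(self, snp_ids) -> list:
        """Planted pairs as canonical (snp_id_1, snp_id_2) identities."""
        keys = []
        for i, j, _ in self.pairs:
            a, b = sorted((i, j))
            keys.append((snp_ids[a], snp_ids[b]))
        return keys


def simulate(config: SimConfig):
    """Draw a dataset under ``config``.

    Returns (GenotypeMatrix, Phenotype, TruthTable); fully reproducible
    from ``config.seed``.  Raises after a bounded attempt budget if the
    case/control quotas are unreachable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    M = config.n_snps

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=M)
    planted = config.planted_pairs()
    for p in planted:
        if isinstance(p.preset, str) and p.preset == "xor":
            # flat marginals for the xor pattern require MAF exactly 0.5
            mafs[p.i] = 0.5
            mafs[p.j] = 0.5
    if config.main_effect_maf is not None:
        for s, _ in config.main_effects:
            mafs[s] = config.main_effect_maf

    # HWE genotype probabilities per SNP (genotype = minor-allele count)
    q = mafs
    p0 = (1 - q) ** 2
    p1 = 2 * q * (1 - q)
    thresh0 = p0
    thresh1 = p0 + p1

    beta0 = float(logit(config.baseline_prevalence))
    beta = np.zeros(M)
    for s, or_ in config.main_effects:
        beta[s] += np.log(or_)
    pair_terms = [(p.i, p.j, p.offsets()) for p in planted]

    need_cases = config.n_cases
    need_controls = config.n_controls
    rows: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    got_cases = got_controls = 0
    batch = max(1024, min(1 << 14, 4 * (need_cases + need_controls + 1)))
    max_batches = 2000

    for _ in range(max_batches):
        if got_cases >= need_cases and got_controls >= need_controls:
            break
        u = rng.random((batch, M))
        g = (u > thresh0).astype(np.int8) + (u > thresh1).astype(np.int8)
        eta = beta0 + g @ beta
        for i, j, off in pair_terms:
            eta += off[g[:, i], g[:, j]]
        is_case = rng.random(batch) < expit(eta)

        take_case = np.flatnonzero(is_case)[: max(0, need_cases - got_cases)]
        take_ctrl = np.flatnonzero(~is_case)[: max(0, need_controls - got_controls)]
        take = np.sort(np.concatenate([take_case, take_ctrl]))
        if take.size:
            rows.append(g[take])
            labels.append(is_case[take].astype(np.int8))
            got_cases += take_case.size
            got_controls += take_ctrl.size
    else:
        raise RuntimeError(
            f"could not meet quotas ({got_cases}/{need_cases} cases, "
            f"{got_controls}/{need_controls} controls) within the attempt budget"
        )

    geno = np.vstack(rows) if rows else np.empty((0, M), dtype=np.int8)
    y = np.concatenate(labels) if labels else np.empty(0, dtype=np.int8)

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno = np.where(mask, np.int8(MISSING), geno)

    width = max(4, len(str(M)))
    snp_ids = [f"snp{s:0{width}d}" for s in range(M)]
    sample_ids = [f"sample{r:06d}" for r in range(geno.shape[0])]
    matrix = GenotypeMatrix(geno, snp_ids, sample_ids)
    phenotype = Phenotype(y)
    truth = TruthTable(
        mafs=mafs,
        main_effects=list(config.main_effects),
        pairs=[(i, j, off) for i, j, off in pair_terms],
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )
    return matrix, phenotype, truth
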