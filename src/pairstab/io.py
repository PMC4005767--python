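"""Genotype/phenotype containers, contingency tables, and file formats.

Case-control GWAS data is held as a samples x SNPs matrix of genotype codes
(0/1/2 = count of the second allele, ``MISSING`` = -1) plus a binary
phenotype vector (0 = control, 1 = case).  Every association statistic in
:mod:`pairstab.stats` consumes 2x3 (single SNP) or 2x9 (SNP pair)
phenotype-by-genotype contingency tables built here; row 0 is always the
control row, row 1 the case row, and the nine pair columns are ordered
``v = 3*g1 + g2`` for the canonical (lower index first) SNP pair.

Supported on-disk formats:

* PLINK 1 binary (.bed/.bim/.fam), SNP-major, magic bytes ``6C 1B 01``;
* a plain TSV dialect (``sample_id  phenotype  g g g ...`` with ``NA`` for
  missing genotypes);
* ranked SNP-pair lists as TSV (rank, snp_id_1, snp_id_2, score, p_value).

Samples with a missing genotype are dropped pairwise, i.e. only from the
tables that involve the missing SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Phenotype",
    "SingleTable",
    "PairTable",
    "read_plink",
    "write_plink",
    "read_tsv",
    "write_tsv",
    "build_single_table",
    "build_pair_table",
    "write_ranked_list",
    "read_ranked_list",
]

#: Sentinel genotype code for a missing call.
MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK v1 2-bit codes (SNP-major, least-significant bit pair first):
#   00 -> 0 copies of A2, 10 -> 1 copy, 11 -> 2 copies, 01 -> missing.
_CODE_TO_BITS = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}
_BITS_TO_CODE = np.full(4, MISSING, dtype=np.int8)
for _code, _bits in _CODE_TO_BITS.items():
    _BITS_TO_CODE[_bits] = _code

# 256 -> 4 genotype codes lookup for fast .bed decoding.
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_LUT[_b, _s] = _BITS_TO_CODE[(_b >> (2 * _s)) & 0b11]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype codes with SNP and sample identifiers."""

    genotypes: np.ndarray
    snp_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(np.asarray(self.genotypes), dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs array")
        valid = (g == 0) | (g == 1) | (g == 2) | (g == MISSING)
        if not valid.all():
            bad = np.unique(np.asarray(self.genotypes)[~valid])
            raise ValueError(f"invalid genotype codes {bad!r}; expected 0/1/2/{MISSING}")
        self.genotypes = g
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.snp_ids) != g.shape[1]:
            raise ValueError("snp_ids length does not match genotype columns")
        if len(self.sample_ids) != g.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_samples(self, index) -> "GenotypeMatrix":
        """Row subset; `index` is any numpy-compatible row indexer."""
        idx = np.arange(self.n_samples)[index]
        return GenotypeMatrix(
            self.genotypes[idx],
            self.snp_ids,
            [self.sample_ids[i] for i in idx],
        )

    def subset_snps(self, index) -> "GenotypeMatrix":
        """Column subset; `index` is any numpy-compatible column indexer."""
        idx = np.arange(self.n_snps)[index]
        return GenotypeMatrix(
            self.genotypes[:, idx],
            [self.snp_ids[i] for i in idx],
            self.sample_ids,
        )


@dataclass
class Phenotype:
    """Per-sample binary disease status: 0 = control, 1 = case."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        y = np.ascontiguousarray(np.asarray(self.labels), dtype=np.int8)
        if y.ndim != 1:
            raise ValueError("phenotype labels must be 1-D")
        if not ((y == 0) | (y == 1)).all():
            raise ValueError("phenotype labels must be 0 (control) or 1 (case)")
        self.labels = y

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.labels.sum())

    def subset(self, index) -> "Phenotype":
        return Phenotype(self.labels[np.arange(self.n_samples)[index]])


@dataclass
class SingleTable:
    """2x3 phenotype-by-genotype counts for one SNP (row 0 controls)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 3) or (c < 0).any():
            raise ValueError("SingleTable needs non-negative 2x3 counts")
        self.counts = c

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PairTable:
    """2x9 phenotype-by-genotype-pair counts; column ``v = 3*g1 + g2``."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 9) or (c < 0).any():
            raise ValueError("PairTable needs non-negative 2x9 counts")
        self.counts = c

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def marginal(self, which: int) -> SingleTable:
        """Marginalise onto one SNP of the pair (0 = first, 1 = second).

        The result counts only samples that are non-missing at *both* SNPs,
        so it can differ from the SNP's own :class:`SingleTable`.
        """
        cube = self.counts.reshape(2, 3, 3)
        if which == 0:
            return SingleTable(cube.sum(axis=2))
        if which == 1:
            return SingleTable(cube.sum(axis=1))
        raise ValueError("which must be 0 or 1")


def build_single_table(matrix: GenotypeMatrix, phenotype: Phenotype, snp_index: int) -> SingleTable:
    """Tally one SNP's 2x3 table over samples with a non-missing call."""
    _check_paired(matrix, phenotype)
    g = matrix.genotypes[:, snp_index]
    ok = g >= 0
    counts = np.bincount(3 * phenotype.labels[ok].astype(np.int64) + g[ok], minlength=6)
    return SingleTable(counts.reshape(2, 3))


def build_pair_table(matrix: GenotypeMatrix, phenotype: Phenotype, i: int, j: int) -> PairTable:
    """Tally a SNP pair's 2x9 table; the pair is canonicalised to (min, max).

    Samples missing at either SNP are excluded (pairwise deletion).
    """
    _check_paired(matrix, phenotype)
    if i == j:
        raise ValueError("a SNP pair needs two distinct SNPs")
    i, j = (i, j) if i < j else (j, i)
    gi = matrix.genotypes[:, i]
    gj = matrix.genotypes[:, j]
    ok = (gi >= 0) & (gj >= 0)
    v = 3 * gi[ok].astype(np.int64) + gj[ok]
    counts = np.bincount(9 * phenotype.labels[ok].astype(np.int64) + v, minlength=18)
    return PairTable(counts.reshape(2, 9))


def _check_paired(matrix: GenotypeMatrix, phenotype: Phenotype) -> None:
    if matrix.n_samples != phenotype.n_samples:
        raise ValueError("genotype matrix and phenotype have different sample counts")
    if phenotype.n_cases == 0 or phenotype.n_controls == 0:
        raise ValueError("both cases and controls are required")


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def write_plink(matrix: GenotypeMatrix, phenotype: Phenotype, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam in SNP-major PLINK 1 layout.

    Phenotype is written as 1 (control) / 2 (case) in .fam column 6.
    """
    if matrix.n_samples != phenotype.n_samples:
        raise ValueError("genotype matrix and phenotype have different sample counts")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed, bim, fam = (prefix.parent / (prefix.name + ext) for ext in (".bed", ".bim", ".fam"))

    n, m = matrix.n_samples, matrix.n_snps
    # 2-bit encode: pad samples to a multiple of 4, low bit pair = first sample.
    bits = np.zeros((m, 4 * ((n + 3) // 4)), dtype=np.uint8)
    enc = np.empty(4, dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        enc[code & 0b11] = b  # index MISSING (-1) as 3
    bits[:, :n] = enc[(matrix.genotypes.T & 0b11)]
    quads = bits.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    with open(bim, "w") as fh:
        for k, sid in enumerate(matrix.snp_ids):
            fh.write(f"1\t{sid}\t0\t{k + 1}\tA\tB\n")

    with open(fam, "w") as fh:
        for sid, y in zip(matrix.sample_ids, phenotype.labels):
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{1 + int(y)}\n")


def read_plink(bed_path, bim_path=None, fam_path=None):
    """Read PLINK 1 binary files into (GenotypeMatrix, Phenotype).

    ``bed_path`` may be a prefix; .bim/.fam default to sibling files.
    Samples whose .fam phenotype is not 1/2 are excluded with a warning.
    """
    bed_path = Path(bed_path)
    if bed_path.suffix != ".bed":
        bed_path = bed_path.parent / (bed_path.name + ".bed")
    stem = bed_path.parent / bed_path.name[: -len(".bed")]
    bim_path = Path(bim_path) if bim_path else stem.parent / (stem.name + ".bim")
    fam_path = Path(fam_path) if fam_path else stem.parent / (stem.name + ".fam")

    snp_ids = []
    with open(bim_path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{bim_path}: expected 6 columns, got {len(fields)}")
            snp_ids.append(fields[1])

    sample_ids = []
    phen_raw = []
    with open(fam_path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{fam_path}: expected 6 columns, got {len(fields)}")
            sample_ids.append(fields[1])
            phen_raw.append(fields[5])

    n, m = len(sample_ids), len(snp_ids)
    bytes_per_snp = (n + 3) // 4
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed_path}: bad magic bytes (not SNP-major PLINK 1 .bed)")
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(f"{bed_path}: size mismatch for {n} samples x {m} SNPs")
    geno = _BYTE_LUT[body.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n].T

    keep, labels = [], []
    for idx, token in enumerate(phen_raw):
        if token == "1":
            keep.append(idx)
            labels.append(0)
        elif token == "2":
            keep.append(idx)
            labels.append(1)
        else:
            warnings.warn(
                f"{fam_path}: sample {sample_ids[idx]!r} has phenotype {token!r}; excluded",
                stacklevel=2,
            )
    if not keep:
        raise ValueError(f"{fam_path}: no sample has a 1/2 phenotype")

    matrix = GenotypeMatrix(geno[keep], snp_ids, [sample_ids[i] for i in keep])
    return matrix, Phenotype(np.asarray(labels, dtype=np.int8))


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_tsv(matrix: GenotypeMatrix, phenotype: Phenotype, path) -> None:
    """Write the simple TSV dialect readable by :func:`read_tsv`."""
    if matrix.n_samples != phenotype.n_samples:
        raise ValueError("genotype matrix and phenotype have different sample counts")
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(matrix.snp_ids) + "\n")
        for sid, y, row in zip(matrix.sample_ids, phenotype.labels, matrix.genotypes):
            tokens = ["NA" if g == MISSING else str(int(g)) for g in row]
            fh.write(f"{sid}\t{int(y)}\t" + "\t".join(tokens) + "\n")


def read_tsv(path):
    """Read the TSV dialect: header of SNP ids, rows of sample/phenotype/genotypes."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ValueError(f"{path}: header must list sample_id, phenotype, SNP ids")
        snp_ids = cols[2:]

        sample_ids, labels, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 + len(snp_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {2 + len(snp_ids)} columns, got {len(fields)}"
                )
            sample_ids.append(fields[0])
            if fields[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: phenotype must be 0 or 1, got {fields[1]!r}")
            labels.append(int(fields[1]))
            row = np.empty(len(snp_ids), dtype=np.int8)
            for k, token in enumerate(fields[2:]):
                if token == "NA":
                    row[k] = MISSING
                elif token in ("0", "1", "2"):
                    row[k] = int(token)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: column {snp_ids[k]!r}: bad genotype {token!r}"
                    )
            rows.append(row)

    geno = np.asarray(rows, dtype=np.int8).reshape(len(rows), len(snp_ids))
    matrix = GenotypeMatrix(geno, snp_ids, sample_ids)
    return matrix, Phenotype(np.asarray(labels, dtype=np.int8))


# ---------------------------------------------------------------------------
# Ranked pair lists
# ---------------------------------------------------------------------------

def write_ranked_list(ranked, path) -> None:
    """Write a :class:`~pairstab.ranking.RankedPairList` as TSV."""
    with open(path, "w") as fh:
        fh.write("rank\tsnp_id_1\tsnp_id_2\tscore\tp_value\n")
        for rank, e in enumerate(ranked.entries, start=1):
            fh.write(f"{rank}\t{e.id1}\t{e.id2}\t{e.score:.17g}\t{e.p_value:.17g}\n")


def read_ranked_list(path, statistic_name: str = ""):
    """Read a ranked pair list TSV back into a RankedPairList.

    Rows must be sorted most-significant first (non-increasing score) with no
    duplicate pairs; otherwise a format error is raised.
    """
    from .ranking import PairEntry, RankedPairList

    path = Path(path)
    entries = []
    seen = set()
    prev_score = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["rank", "snp_id_1", "snp_id_2", "score", "p_value"]:
            raise ValueError(f"{path}: unexpected ranked-list header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            rank, id1, id2, score, p = fields
            if int(rank) != len(entries) + 1:
                raise ValueError(f"{path}:{lineno}: ranks must be consecutive from 1")
            key = frozenset((id1, id2))
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair ({id1}, {id2})")
            seen.add(key)
            score = float(score)
            if prev_score is not None and score > prev_score:
                raise ValueError(f"{path}:{lineno}: scores must be non-increasing")
            prev_score = score
            entries.append(PairEntry(-1, -1, id1, id2, score, float(p)))
    return RankedPairList(
        entries=entries,
        k_requested=max(len(entries), 1),
        statistic_name=statistic_name,
        total_pairs_scanned=len(entries),
    )
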