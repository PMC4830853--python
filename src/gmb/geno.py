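"""Genotype and trait containers, SNP quality control, and file I/O.

Genotypes are coded -1 / 0 / +1 for the two homozygotes and the heterozygote,
with :data:`MISSING` (-9) as the missing sentinel.  After mean imputation the
code matrix becomes real-valued and carries no missing entries.

Supported on-disk formats: a TSV dialect (individuals x SNPs, ``NA`` for
missing, SNP metadata in a sidecar ``.snps.tsv``) and binary PLINK
.bed/.bim/.fam (SNP-major, 2 bits per genotype).  The PLINK bit mapping used
here is 00 -> -1 (homozygous A1), 10 -> 0 (heterozygote), 11 -> +1
(homozygous A2), 01 -> missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyPanelError, FormatError, GmbError

MISSING = -9

_PLINK_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK genotype -> internal code (index = bit pair value)
_BED_DECODE = np.array([-1, MISSING, 0, 1], dtype=np.int8)
_BED_ENCODE = {-1: 0b00, MISSING: 0b01, 0: 0b10, 1: 0b11}


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes with per-SNP metadata.

    ``codes`` is int8 with the MISSING sentinel, or float64 (no missing)
    after :func:`impute_missing_mean`.
    """

    codes: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray  # 1-based, .bim convention
    individual_ids: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.codes.shape
        if len(self.individual_ids) != n:
            raise FormatError(
                f"{len(self.individual_ids)} individual ids for {n} genotype rows"
            )
        if not (len(self.snp_ids) == len(self.chromosomes) == len(self.positions) == m):
            raise FormatError("SNP metadata length does not match genotype columns")
        if len(set(self.snp_ids)) != m:
            raise FormatError("duplicate SNP ids")
        if np.issubdtype(self.codes.dtype, np.integer):
            valid = np.isin(self.codes, (-1, 0, 1, MISSING))
            if not valid.all():
                bad = np.unique(self.codes[~valid])
                raise FormatError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def is_imputed(self) -> bool:
        return np.issubdtype(self.codes.dtype, np.floating)

    def missing_mask(self) -> np.ndarray:
        if self.is_imputed:
            return np.isnan(self.codes)
        return self.codes == MISSING

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP id {snp_id!r} not in panel")
        return int(hits[0])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            codes=self.codes[:, keep],
            snp_ids=self.snp_ids[keep],
            chromosomes=self.chromosomes[keep],
            positions=self.positions[keep],
        )


@dataclass
class TraitRecords:
    """Pseudophenotypes (deregressed-proof scale) with EDC information weights.

    The effective daughter contribution (EDC) of bull *i* enters the models as
    a residual weight: residual variance of observation *i* is sigma2_eps /
    edc_i, i.e. D_ii = 1/edc_i.
    """

    individual_ids: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    trait: str = "trait"

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.individual_ids) == len(self.values) == len(self.weights)):
            raise FormatError("trait record columns have unequal lengths")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise FormatError("duplicate individual ids in trait records")
        if not (self.weights > 0).all():
            raise FormatError("EDC weights must be strictly positive")

    def aligned_to(self, individual_ids: np.ndarray) -> "TraitRecords":
        """Reorder records to a genotype matrix's individual order."""
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        missing = [iid for iid in individual_ids if iid not in pos]
        if missing:
            raise AlignmentError(
                f"{len(missing)} individuals lack trait records: {missing[:5]}"
            )
        idx = np.array([pos[iid] for iid in individual_ids])
        return TraitRecords(
            np.asarray(individual_ids, dtype=object),
            self.values[idx],
            self.weights[idx],
            self.trait,
        )


# ---------------------------------------------------------------------------
# QC statistics


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of one SNP column, ignoring missing entries.

    Dosage d = code + 1 in {0, 1, 2}; allele frequency f = mean(d)/2;
    MAF = min(f, 1 - f).  An all-missing column yields NaN (distinguishable
    from a true MAF of 0).
    """
    column = np.asarray(column)
    obs = column[~_missing_of(column)]
    if obs.size == 0:
        return float("nan")
    f = (np.mean(obs.astype(float)) + 1.0) / 2.0
    return float(min(f, 1.0 - f))


def call_rate(column: np.ndarray) -> float:
    """Fraction of non-missing genotypes in a SNP column."""
    column = np.asarray(column)
    if column.size == 0:
        raise GmbError("empty genotype column")
    return float(1.0 - _missing_of(column).mean())


def _missing_of(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.isnan(arr)
    return arr == MISSING


def compute_maf_all(geno: GenotypeMatrix) -> np.ndarray:
    """Vectorized per-SNP MAF (NaN for all-missing columns)."""
    miss = geno.missing_mask()
    n_obs = (~miss).sum(axis=0).astype(float)
    dosage = geno.codes.astype(float) + 1.0
    dosage[miss] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f = dosage.sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)
    maf[n_obs == 0] = np.nan
    return maf


def call_rate_all(geno: GenotypeMatrix) -> np.ndarray:
    return 1.0 - geno.missing_mask().mean(axis=0)


def apply_qc(
    geno: GenotypeMatrix, maf_min: float = 0.01, cr_min: float = 0.90
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain SNPs with MAF >= maf_min and call rate >= cr_min (inclusive).

    Returns the filtered matrix and a per-SNP log with removal reasons.
    Raises :class:`EmptyPanelError` if nothing survives.
    """
    if not (0 <= maf_min <= 1 and 0 <= cr_min <= 1):
        raise GmbError("QC thresholds must lie in [0, 1]")
    maf = compute_maf_all(geno)
    cr = call_rate_all(geno)
    low_maf = ~(maf >= maf_min)  # NaN MAF counts as failing
    low_cr = cr < cr_min
    keep = ~(low_maf | low_cr)
    reasons = []
    for j in range(geno.n_snps):
        r = []
        if low_maf[j]:
            r.append("low_maf")
        if low_cr[j]:
            r.append("low_call_rate")
        reasons.append(";".join(r) if r else "")
    log = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "maf": maf,
            "call_rate": cr,
            "kept": keep,
            "removal_reason": reasons,
        }
    )
    if not keep.any():
        raise EmptyPanelError(
            f"all {geno.n_snps} SNPs removed by QC (maf_min={maf_min}, cr_min={cr_min})"
        )
    return geno.subset_snps(keep), log


def impute_missing_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing genotype by its SNP's observed mean code.

    Column means are unchanged; output codes are float64 with no missing.
    """
    miss = geno.missing_mask()
    codes = geno.codes.astype(float)
    codes[miss] = np.nan
    col_mean = np.nanmean(np.where(miss, np.nan, codes), axis=0)
    if np.isnan(col_mean).any():
        bad = geno.snp_ids[np.isnan(col_mean)]
        raise GmbError(f"all-missing columns cannot be imputed: {bad[:5].tolist()}")
    rows, cols = np.nonzero(miss)
    codes[rows, cols] = col_mean[cols]
    return replace(geno, codes=codes)


# ---------------------------------------------------------------------------
# TSV I/O


def save_genotypes_tsv(geno: GenotypeMatrix, prefix: str) -> None:
    """Write ``<prefix>.geno.tsv`` (codes, NA for missing) and ``<prefix>.snps.tsv``."""
    codes = geno.codes
    df = pd.DataFrame(codes, index=geno.individual_ids, columns=geno.snp_ids)
    df = df.where(~geno.missing_mask(), other=np.nan)
    df.index.name = "individual_id"
    df.to_csv(f"{prefix}.geno.tsv", sep="\t", na_rep="NA")
    meta = pd.DataFrame(
        {"snp_id": geno.snp_ids, "chromosome": geno.chromosomes, "position": geno.positions}
    )
    meta.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def load_genotypes_tsv(prefix: str) -> GenotypeMatrix:
    df = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}.snps.tsv", sep="\t")
    if list(meta["snp_id"]) != list(df.columns):
        raise FormatError(f"{prefix}.snps.tsv SNP ids do not match {prefix}.geno.tsv columns")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        codes = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    elif np.all(values == np.round(values)) and np.isin(
        np.unique(values), (-1, 0, 1, MISSING)
    ).all():
        codes = values.astype(np.int8)
    else:
        codes = values  # already-imputed real codes
    return GenotypeMatrix(
        codes=codes,
        snp_ids=meta["snp_id"].to_numpy(),
        chromosomes=meta["chromosome"].to_numpy(),
        positions=meta["position"].to_numpy(),
        individual_ids=df.index.to_numpy(),
    )


def save_traits_tsv(traits: TraitRecords, path: str) -> None:
    pd.DataFrame(
        {
            "id": traits.individual_ids,
            "trait": traits.trait,
            "value": traits.values,
            "edc": traits.weights,
        }
    ).to_csv(path, sep="\t", index=False)


def load_traits_tsv(path: str, trait: str | None = None) -> TraitRecords:
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "trait", "value", "edc"):
        if col not in df.columns:
            raise FormatError(f"trait file {path} lacks column {col!r}")
    if trait is not None:
        df = df[df["trait"] == trait]
        if df.empty:
            raise FormatError(f"trait {trait!r} not present in {path}")
    elif df["trait"].nunique() > 1:
        raise FormatError(f"{path} holds multiple traits; pass trait=")
    return TraitRecords(
        df["id"].to_numpy(),
        df["value"].to_numpy(),
        df["edc"].to_numpy(),
        str(df["trait"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam


def save_genotypes_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write SNP-major PLINK .bed with matching .bim and .fam."""
    if geno.is_imputed:
        raise FormatError("PLINK bed stores discrete codes; write TSV for imputed data")
    n, m = geno.codes.shape
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        lut[code % 256] = bits
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        bits = lut[geno.codes.astype(np.int16).astype(np.uint8)]  # (n, m)
        nbytes = (n + 3) // 4
        for j in range(m):
            col = np.zeros(nbytes * 4, dtype=np.uint8)
            col[:n] = bits[:, j]
            packed = (
                col[0::4] | (col[1::4] << 2) | (col[2::4] << 4) | (col[3::4] << 6)
            )
            fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": geno.chromosomes,
            "snp_id": geno.snp_ids,
            "cm": 0,
            "pos": geno.positions,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", index=False, header=False)
    fam = pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "sire": 0,
            "dam": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", index=False, header=False)


def load_genotypes_plink(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    nbytes = (n + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise FormatError(
                f"{prefix}.bed: bad magic {magic!r} (expected SNP-major PLINK bed)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != nbytes * m:
        raise FormatError(
            f"{prefix}.bed holds {raw.size} data bytes; .bim/.fam imply {nbytes * m}"
        )
    raw = raw.reshape(m, nbytes)
    pairs = np.empty((m, nbytes * 4), dtype=np.uint8)
    pairs[:, 0::4] = raw & 0b11
    pairs[:, 1::4] = (raw >> 2) & 0b11
    pairs[:, 2::4] = (raw >> 4) & 0b11
    pairs[:, 3::4] = (raw >> 6) & 0b11
    codes = _BED_DECODE[pairs[:, :n]].T  # (n, m)
    return GenotypeMatrix(
        codes=np.ascontiguousarray(codes),
        snp_ids=bim["snp_id"].to_numpy(),
        chromosomes=bim["chrom"].to_numpy(),
        positions=bim["pos"].to_numpy(),
        individual_ids=fam["iid"].to_numpy(),
    )


def load_genotypes(prefix_or_path: str) -> GenotypeMatrix:
    """Dispatch on extension: PLINK prefix if ``<p>.bed`` exists, else TSV prefix."""
    import os

    if os.path.exists(f"{prefix_or_path}.bed"):
        return load_genotypes_plink(prefix_or_path)
    if os.path.exists(f"{prefix_or_path}.geno.tsv"):
        return load_genotypes_tsv(prefix_or_path)
    raise FormatError(f"no genotype files found under prefix {prefix_or_path!r}")
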