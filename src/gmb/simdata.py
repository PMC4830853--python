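"""Synthetic populations with the structure the four GWAS models assume.

The generator emulates a progeny-tested dairy-bull design: paternal half-sib
families, chip genotypes with blockwise linkage disequilibrium, and
pseudophenotypes on the deregressed-proof scale whose residual variance is
heterogeneous through lognormal effective-daughter-contribution (EDC)
weights.  Default sizes match the reference design (2,601 bulls, 46,267
post-QC SNPs); tests and demos pass smaller explicit sizes.

Haplotypes follow a first-order Markov chain along the chromosome: the
conditional allele probability at SNP j is tilted by the allele carried at
SNP j-1 so that the allele-level adjacent correlation equals ``adjacent_ld``
while each site keeps its configured marginal frequency.  Two independent
haplotypes are summed and recoded to -1/0/+1; genotype-level adjacent
correlation equals the haplotype-level one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, GmbError, PedigreeError
from .geno import MISSING, GenotypeMatrix, TraitRecords

ARCHITECTURES = ("major_gene", "polygenic", "low_h2", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic population.

    Defaults reproduce the reference design scale; ``sigma2_alpha`` /
    ``sigma2_eps`` are on the (arbitrary) deregressed-proof scale with the
    residual variance of bull i equal to sigma2_eps / edc_i.
    """

    n_individuals: int = 2601
    n_snps: int = 46267
    n_families: int = 100
    adjacent_ld: float = 0.4
    maf_range: tuple[float, float] = (0.01, 0.5)
    missing_rate: float = 0.01
    architecture: str = "polygenic"
    major_gene_index: Optional[int] = None
    major_gene_variance_fraction: float = 0.0
    sigma2_alpha: float = 0.3
    sigma2_eps: float = 1.0
    mu: float = 0.0
    edc_log_mean: float = 4.0
    edc_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range {self.maf_range} must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.adjacent_ld < 1.0):
            raise ConfigError("adjacent_ld must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(
                f"architecture {self.architecture!r} not one of {ARCHITECTURES}"
            )
        if self.architecture == "major_gene":
            if self.major_gene_index is None or not (
                0 <= self.major_gene_index < self.n_snps
            ):
                raise ConfigError("major_gene architecture needs a valid major_gene_index")
            if not (0.0 < self.major_gene_variance_fraction < 1.0):
                raise ConfigError("major_gene_variance_fraction must lie in (0, 1)")
        if self.sigma2_alpha < 0 or self.sigma2_eps <= 0:
            raise ConfigError("need sigma2_alpha >= 0 and sigma2_eps > 0")


@dataclass
class Pedigree:
    """(individual, sire, dam) records; ``None`` marks an unknown parent."""

    ids: list
    sires: list
    dams: list

    def __post_init__(self):
        if not (len(self.ids) == len(self.sires) == len(self.dams)):
            raise PedigreeError("pedigree columns have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")

    def __len__(self) -> int:
        return len(self.ids)

    def topological_order(self) -> list[int]:
        """Indices with parents before offspring; raises on a cycle."""
        pos = {iid: k for k, iid in enumerate(self.ids)}
        parents = []
        for s, d in zip(self.sires, self.dams):
            pp = []
            for p in (s, d):
                if p is not None:
                    if p not in pos:
                        raise PedigreeError(f"parent {p!r} not in pedigree")
                    pp.append(pos[p])
            parents.append(pp)
        order, state = [], [0] * len(self.ids)  # 0 new, 1 active, 2 done
        for start in range(len(self.ids)):
            if state[start]:
                continue
            stack = [(start, 0)]
            while stack:
                node, k = stack.pop()
                if k == 0:
                    if state[node] == 1:
                        raise PedigreeError(
                            f"pedigree cycle through {self.ids[node]!r}"
                        )
                    if state[node] == 2:
                        continue
                    state[node] = 1
                    stack.append((node, 1))
                    for p in parents[node]:
                        if state[p] == 1:
                            raise PedigreeError(
                                f"pedigree cycle through {self.ids[p]!r}"
                            )
                        if state[p] == 0:
                            stack.append((p, 0))
                else:
                    state[node] = 2
                    order.append(node)
        return order


@dataclass
class RelationshipMatrix:
    """Numerator (additive) relationship matrix with its id index."""

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise GmbError("relationship matrix shape does not match id index")
        if not np.allclose(self.values, self.values.T):
            raise GmbError("relationship matrix is not symmetric")

    def aligned_to(self, individual_ids) -> "RelationshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        missing = [iid for iid in individual_ids if iid not in pos]
        if missing:
            raise GmbError(
                f"relationship matrix lacks {len(missing)} individuals: {missing[:5]}"
            )
        idx = np.array([pos[iid] for iid in individual_ids])
        return RelationshipMatrix(
            self.values[np.ix_(idx, idx)], np.asarray(individual_ids, dtype=object)
        )


@dataclass
class TraitTruth:
    """True simulated effects kept for recovery tests."""

    g: np.ndarray
    alpha: np.ndarray


# ---------------------------------------------------------------------------


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate -1/0/+1 chip genotypes with first-order Markov LD.

    At site j with allele frequency f_j the conditional allele probability is
    f_j + rho * sqrt(f_j q_j / f_{j-1} q_{j-1}) * (a_{j-1} - f_{j-1}), which
    gives adjacent allele correlation rho with the marginal frequency
    preserved (up to clipping of the conditional probability into [0, 1],
    negligible inside the default MAF range).
    """
    if config.n_snps < 2 or config.n_individuals < 2:
        raise ConfigError("need n_snps >= 2 and n_individuals >= 2")
    rng = _rng(config, 1)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    rho = config.adjacent_ld

    n_hap = 2 * n
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    sd = np.sqrt(freqs * (1.0 - freqs))
    for j in range(1, m):
        p_cond = freqs[j] + rho * (sd[j] / sd[j - 1]) * (H[:, j - 1] - freqs[j - 1])
        np.clip(p_cond, 0.0, 1.0, out=p_cond)
        H[:, j] = rng.random(n_hap) < p_cond
    codes = (H[0::2] + H[1::2] - 1).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = MISSING

    width = len(str(m))
    snp_ids = np.array([f"snp{j:0{width}d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(
        codes=codes,
        snp_ids=snp_ids,
        chromosomes=np.repeat("1", m),
        positions=np.arange(1, m + 1) * 1000,
        individual_ids=_individual_ids(n),
    )


def _individual_ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"id{k:0{width}d}" for k in range(n)], dtype=object)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Paternal half-sib pedigree: founder sires, offspring with unknown dams."""
    if config.n_families < 1:
        raise ConfigError("need n_families >= 1")
    if config.n_families > config.n_individuals:
        raise ConfigError("n_families cannot exceed n_individuals")
    rng = _rng(config, 2)
    ids = list(_individual_ids(config.n_individuals))
    n_sires = config.n_families
    sires: list = [None] * n_sires
    n_offspring = config.n_individuals - n_sires
    assigned = rng.integers(0, n_sires, size=n_offspring)
    sires += [ids[k] for k in assigned]
    dams: list = [None] * config.n_individuals
    return Pedigree(ids=ids, sires=sires, dams=dams)


def relationship_from_pedigree(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a(sire, dam)/2; a_ij = (a_{j,sire(i)} + a_{j,dam(i)})/2 for j
    processed before i, with unknown parents contributing zero.
    """
    order = ped.topological_order()
    n = len(ped)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    rank = np.empty(n, dtype=int)  # original index -> position in tabular order
    for r, i in enumerate(order):
        rank[i] = r
    A = np.zeros((n, n))
    for r, i in enumerate(order):
        s = ped.sires[i]
        d = ped.dams[i]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        prev = order[:r]
        row = np.zeros(len(prev))
        if si is not None:
            row += 0.5 * A[si, prev]
        if di is not None:
            row += 0.5 * A[di, prev]
        A[i, prev] = row
        A[prev, i] = row
        a_sd = A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return RelationshipMatrix(A, np.asarray(ped.ids, dtype=object))


def simulate_trait(
    geno: GenotypeMatrix,
    A: RelationshipMatrix,
    config: SimulationConfig,
    g: Optional[np.ndarray] = None,
) -> tuple[TraitRecords, TraitTruth]:
    """Simulate y_i = mu + sum_j z_ij g_j + alpha_i + eps_i.

    alpha ~ N(0, A * sigma2_alpha) (zeroed for the ``null`` architecture),
    eps_i ~ N(0, sigma2_eps / w_i) with EDC weights w_i ~ lognormal.  For
    ``major_gene`` the causal SNP's effect is scaled so its variance
    contribution is ``major_gene_variance_fraction`` of the total; an
    explicit ``g`` vector (e.g. drawn from the all-SNP shrinkage prior)
    overrides the architecture's effect vector.
    """
    n, m = geno.n_individuals, geno.n_snps
    if len(A.ids) != n or not np.array_equal(A.ids, geno.individual_ids):
        A = A.aligned_to(geno.individual_ids)
    rng = _rng(config, 3)

    w = rng.lognormal(config.edc_log_mean, config.edc_log_sd, size=n)

    # complete design matrix for the generative sum (mean-impute any missing)
    Z = geno.codes.astype(float)
    miss = geno.missing_mask()
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, Z), axis=0)
        rr, cc = np.nonzero(miss)
        Z[rr, cc] = col_mean[cc]

    mean_resid_var = config.sigma2_eps * float(np.mean(1.0 / w))
    use_alpha = config.architecture != "null" and config.sigma2_alpha > 0
    alpha_var = config.sigma2_alpha * float(np.mean(np.diag(A.values))) if use_alpha else 0.0

    if g is not None:
        g = np.asarray(g, dtype=float)
        if g.shape != (m,):
            raise ConfigError(f"g has shape {g.shape}, expected ({m},)")
    elif config.architecture == "major_gene":
        j = config.major_gene_index
        var_col = float(np.var(Z[:, j]))
        if var_col <= 0:
            raise GmbError(f"major-gene SNP {geno.snp_ids[j]!r} is monomorphic")
        frac = config.major_gene_variance_fraction
        beta2 = frac * (alpha_var + mean_resid_var) / ((1.0 - frac) * var_col)
        g = np.zeros(m)
        g[j] = np.sqrt(beta2)
    else:
        g = np.zeros(m)

    if use_alpha:
        try:
            L = np.linalg.cholesky(A.values)
        except np.linalg.LinAlgError as exc:
            raise GmbError(
                "relationship matrix A is not positive definite; "
                "cannot draw the polygenic effect"
            ) from exc
        alpha = np.sqrt(config.sigma2_alpha) * (L @ rng.standard_normal(n))
    else:
        alpha = np.zeros(n)

    eps = rng.standard_normal(n) * np.sqrt(config.sigma2_eps / w)
    y = config.mu + Z @ g + alpha + eps
    traits = TraitRecords(geno.individual_ids.copy(), y, w, trait=config.architecture)
    return traits, TraitTruth(g=g, alpha=alpha)


# ---------------------------------------------------------------------------
# pedigree / relationship-matrix TSV I/O


def save_pedigree_tsv(ped: Pedigree, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "id": ped.ids,
            "sire": ["0" if s is None else s for s in ped.sires],
            "dam": ["0" if d is None else d for d in ped.dams],
        }
    ).to_csv(path, sep="\t", index=False)


def load_pedigree_tsv(path: str) -> Pedigree:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file {path} lacks column {col!r}")
    none_if_zero = lambda v: None if v in ("0", "NA", "", None) or pd.isna(v) else v
    return Pedigree(
        ids=list(df["id"]),
        sires=[none_if_zero(v) for v in df["sire"]],
        dams=[none_if_zero(v) for v in df["dam"]],
    )


def save_relationship_tsv(A: RelationshipMatrix, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(A.values, index=A.ids, columns=A.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def load_relationship_tsv(path: str) -> RelationshipMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(dtype=float), df.columns.to_numpy(dtype=object))
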