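"""CAR scores (model M3): correlation-adjusted marginal correlations.

omega = P^{-1/2} P_xy, where P_xy is the vector of marginal SNP-phenotype
correlations and P = lambda * I + (1 - lambda) * R_empirical is the shrunken
SNP-SNP correlation matrix.  P^{-1/2} Mahalanobis-decorrelates the
predictors, so omega_j measures the contribution of SNP j net of the LD it
shares with other SNPs.

The inverse square root is never formed as an m x m matrix: after shrinking
toward the identity, P has at most rank(Z) non-unit-direction eigenvalues,
all carried by the right singular vectors of the standardized genotype
matrix, so omega is computed from an economy SVD (the "dual trick").

Significance uses the classical correlation transform t = omega *
sqrt((kappa - 1) / (1 - omega^2)) against a Student t with kappa - 1 degrees
of freedom, kappa playing the role of an effective sample size fitted from
the null bulk of the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, GmbError
from .geno import GenotypeMatrix, TraitRecords

_SING_TOL = 1e-10


@dataclass(frozen=True)
class CARParameters:
    lam: float  # shrinkage intensity lambda in [0, 1]
    kappa: float  # null effective-sample-size parameter, > 1

    def __post_init__(self):
        object.__setattr__(self, "lam", float(np.clip(self.lam, 0.0, 1.0)))
        if not self.kappa > 1:
            raise ConfigError(f"kappa must exceed 1, got {self.kappa}")


def _standardize(X: np.ndarray) -> np.ndarray:
    """Column-standardize with the unbiased (ddof=1) standard deviation."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise GmbError(
            "zero-variance genotype column; run QC before computing CAR scores"
        )
    return Xc / sd


def _matrix_and_y(geno: GenotypeMatrix, traits: TraitRecords):
    if geno.missing_mask().any():
        raise GmbError("genotypes contain missing entries; impute before fitting")
    traits = traits.aligned_to(geno.individual_ids)
    return geno.codes.astype(float), traits.values


def marginal_correlations(geno: GenotypeMatrix, traits: TraitRecords) -> np.ndarray:
    """Pearson correlation of each SNP column with the pseudophenotype."""
    X, y = _matrix_and_y(geno, traits)
    n = len(y)
    if n < 3:
        raise GmbError("need at least 3 individuals for correlations")
    yc = y - y.mean()
    sy = yc.std(ddof=1)
    if sy <= 0:
        raise GmbError("constant trait: marginal correlations undefined")
    Z = _standardize(X)
    return (Z.T @ (yc / sy)) / (n - 1)


def estimate_lambda(geno: GenotypeMatrix) -> float:
    """Analytic variance-minimizing shrinkage of the SNP correlation matrix
    toward the identity (James-Stein-type):

        lambda = sum_{i != j} Var_hat(r_ij) / sum_{i != j} r_ij^2,

    clipped to [0, 1].  Computed through the n x n Gram matrix, so the m x m
    correlation matrix is never materialized.
    """
    if geno.n_individuals < 3 or geno.n_snps < 2:
        raise GmbError("need n >= 3 individuals and m >= 2 SNPs to estimate lambda")
    X = geno.codes.astype(float)
    Z = _standardize(X)
    n, m = Z.shape
    G = Z @ Z.T
    frob2 = float(np.sum(G * G))  # ||Z'Z||_F^2
    sum_r2_off = (frob2 - m * (n - 1) ** 2) / (n - 1) ** 2
    rowsq = np.sum(Z * Z, axis=1)  # per-individual sum over SNPs
    sum_w2_all = float(np.sum(rowsq**2))  # sum_k (sum_i z_ki^2)^2
    sum_z4 = float(np.sum(Z**4))
    sum_w2_off = sum_w2_all - sum_z4
    sum_wbar2_off = frob2 / n**2 - m * (n - 1) ** 2 / n**2
    var_sum = n / (n - 1) ** 3 * (sum_w2_off - n * sum_wbar2_off)
    if sum_r2_off <= 0:
        return 1.0
    return float(np.clip(var_sum / sum_r2_off, 0.0, 1.0))


def car_scores(
    geno: GenotypeMatrix, traits: TraitRecords, params: CARParameters
) -> np.ndarray:
    """omega = P^{-1/2} P_xy with P = lam*I + (1-lam)*R_empirical.

    Uses the economy SVD of the standardized genotype matrix: writing
    Zs = Z/sqrt(n-1) = U S V', the eigenvalues of P are lam + (1-lam) s_k^2
    on the columns of V and exactly lam on the orthogonal complement, so

        omega = lam^{-1/2} r + V [(lam + (1-lam) s^2)^{-1/2} - lam^{-1/2}] V' r.
    """
    X, y = _matrix_and_y(geno, traits)
    r = marginal_correlations(geno, traits)
    lam = params.lam
    Zs = _standardize(X) / np.sqrt(len(y) - 1)
    # economy SVD: right singular vectors carry R's non-trivial eigenspace
    _, s, Vt = np.linalg.svd(Zs, full_matrices=False)
    ev = lam + (1.0 - lam) * s**2
    m = Zs.shape[1]
    if lam < _SING_TOL:
        rank = int(np.sum(s**2 > _SING_TOL))
        if rank < m:
            raise GmbError(
                "empirical correlation matrix is singular at lambda = 0; "
                "use a shrinkage intensity lambda > 0"
            )
        return (Vt.T * ev**-0.5) @ (Vt @ r)
    coef = ev**-0.5 - lam**-0.5
    return lam**-0.5 * r + (Vt.T * coef) @ (Vt @ r)


def car_pvalues(omega: np.ndarray, kappa: float) -> np.ndarray:
    """Two-sided p values for CAR scores.

    t = omega * sqrt((kappa - 1) / (1 - omega^2)) referred to Student t with
    (kappa - 1) degrees of freedom.  |omega| >= 1 is a boundary case mapped
    to p = 0 with a warning.
    """
    if not kappa > 1:
        raise ConfigError(f"kappa must exceed 1, got {kappa}")
    omega = np.asarray(omega, dtype=float)
    boundary = np.abs(omega) >= 1.0
    if boundary.any():
        warnings.warn(
            f"{int(boundary.sum())} CAR score(s) at |omega| >= 1; p set to 0",
            stacklevel=2,
        )
    om = np.where(boundary, 0.0, omega)
    t = om * np.sqrt((kappa - 1.0) / (1.0 - om**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=kappa - 1.0)
    p[boundary] = 0.0
    return p


def car_statistic(omega: np.ndarray, kappa: float) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    om = np.clip(omega, -1 + 1e-15, 1 - 1e-15)
    return om * np.sqrt((kappa - 1.0) / (1.0 - om**2))


def estimate_kappa(omega: np.ndarray, n_individuals: int | None = None) -> float:
    """Fit the null degrees-of-freedom parameter kappa from the score bulk.

    Under the null, omega = t / sqrt(kappa - 1 + t^2) with t ~ Student
    t_{kappa-1}, so the interquartile range of the null omega distribution is
    a strictly decreasing function of kappa.  Assuming most SNPs are null,
    kappa is chosen to match the observed IQR of the scores.  Degenerate
    inputs (fewer than 50 scores, zero IQR, IQR outside the attainable
    range) fall back to kappa = n (the sample size when known, else the
    number of scores) with a warning.
    """
    omega = np.asarray(omega, dtype=float)
    fallback = float(n_individuals if n_individuals is not None else len(omega))
    fallback = max(fallback, 2.0)
    if len(omega) < 50:
        warnings.warn("fewer than 50 scores; falling back to kappa = n", stacklevel=2)
        return fallback

    q75, q25 = np.percentile(omega, [75, 25])
    obs_iqr = q75 - q25

    def theo_iqr(kappa: float) -> float:
        q = stats.t.ppf(0.75, df=kappa - 1.0)
        return 2.0 * q / np.sqrt(kappa - 1.0 + q**2)

    lo, hi = 1.0 + 1e-6, 1e9
    if not (theo_iqr(hi) < obs_iqr < theo_iqr(lo)):
        warnings.warn(
            "score IQR outside the attainable null range; falling back to kappa = n",
            stacklevel=2,
        )
        return fallback
    kappa = optimize.brentq(lambda k: theo_iqr(k) - obs_iqr, lo, hi, xtol=1e-6)
    return float(max(kappa, 1.0 + 1e-6))
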