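"""Single-SNP association models.

M1: per-SNP weighted least squares, y = mu + x beta + eps, with EDC weights
(weight w_i multiplies the information of observation i; equivalently the
residual variance of i is sigma2 / w_i).

M2: per-SNP mixed model y = mu + x beta + alpha + eps with a random polygenic
effect alpha ~ N(0, A sigma2_alpha) and eps ~ N(0, D sigma2_eps), D_ii =
1/EDC_i.  With the variance components plugged in, the fixed-effect estimates
from Henderson's mixed model equations coincide with generalized least
squares under V = A sigma2_alpha + D sigma2_eps; V is factorized once and
reused across all SNPs.

Both models report a Wald statistic beta_hat / SE referred to the standard
normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigError, GmbError
from .geno import GenotypeMatrix, TraitRecords
from .simdata import RelationshipMatrix

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """Plug-in variance components (estimated outside this package)."""

    sigma2_alpha: float = 0.0
    sigma2_eps: float = 1.0
    sigma2_a: float = 0.0  # total additive genic variance, for the all-SNP model

    def __post_init__(self):
        for name in ("sigma2_alpha", "sigma2_eps", "sigma2_a"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v}")
        if self.sigma2_eps <= 0:
            raise ConfigError("sigma2_eps must be > 0")
        if self.sigma2_alpha < 0 or self.sigma2_a < 0:
            raise ConfigError("variance components must be non-negative")


def wald_pvalue(statistic) -> np.ndarray | float:
    """Two-sided tail probability of a Wald statistic under N(0, 1)."""
    z = np.asarray(statistic, dtype=float)
    if not np.all(np.isfinite(z)):
        raise GmbError("non-finite Wald statistic")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if np.isscalar(statistic) else p


def _design(geno: GenotypeMatrix, traits: TraitRecords):
    if geno.missing_mask().any():
        raise GmbError("genotypes contain missing entries; impute before fitting")
    traits = traits.aligned_to(geno.individual_ids)
    X = geno.codes.astype(float)
    return X, traits


def m1_scan(X: np.ndarray, Y: np.ndarray, weights: np.ndarray):
    """Vectorized per-SNP WLS of intercept + SNP code.

    ``Y`` may be a vector (one phenotype) or an (n, R) matrix of phenotype
    replicates sharing the genotype matrix; all replicates are fitted in one
    pass.  Returns (beta, se, z, p), each (m,) or (m, R); columns with zero
    weighted variance come back NaN.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    y2d = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # (n, R)
    n = X.shape[0]
    sw = w.sum()
    xm = (w @ X) / sw  # (m,)
    ym = (w @ y2d) / sw  # (R,)
    Sxx = (w @ X**2) - sw * xm**2  # (m,)
    Syy = (w @ y2d**2) - sw * ym**2  # (R,)
    Sxy = X.T @ (w[:, None] * y2d) - sw * np.outer(xm, ym)  # (m, R)
    ok = Sxx > _ZERO_VAR_TOL * n
    Sxx_safe = np.where(ok, Sxx, np.nan)
    beta = Sxy / Sxx_safe[:, None]
    rss = np.maximum(Syy[None, :] - beta * Sxy, 0.0)
    s2 = rss / (n - 2)
    se = np.sqrt(s2 / Sxx_safe[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    # Exact finite-sample reference for a WLS slope with estimated residual
    # variance; indistinguishable from the standard normal at the reference
    # design's sample size (thousands of bulls) but calibrated at desk scale.
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    if np.asarray(Y).ndim == 1:
        return beta[:, 0], se[:, 0], z[:, 0], p[:, 0]
    return beta, se, z, p


def m1_paired_scan(X: np.ndarray, Y: np.ndarray, weights: np.ndarray):
    """WLS of phenotype replicate j on SNP j (diagonal pairing).

    Simulation-study helper: column j of ``Y`` is fitted against column j of
    ``X`` only, so the resulting statistics are independent across j when
    the (x_j, y_j) pairs are.  Returns (beta, se, z, p)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = X.shape[0]
    sw = w.sum()
    xm = (w @ X) / sw
    ym = (w @ Y) / sw
    Sxx = (w @ X**2) - sw * xm**2
    Syy = (w @ Y**2) - sw * ym**2
    Sxy = (w[:, None] * X * Y).sum(axis=0) - sw * xm * ym
    ok = Sxx > _ZERO_VAR_TOL * n
    Sxx_safe = np.where(ok, Sxx, np.nan)
    beta = Sxy / Sxx_safe
    s2 = np.maximum(Syy - beta * Sxy, 0.0) / (n - 2)
    se = np.sqrt(s2 / Sxx_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    return beta, se, z, p


def m2_paired_scan(
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray,
    A: np.ndarray,
    vc: VarianceComponents,
):
    """Mixed-model (GLS) fit of phenotype replicate j on SNP j.

    V = A sigma2_alpha + D sigma2_eps is factorized once and shared across
    all pairs.  Returns (beta, se, z, p) with the standard-normal Wald p."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = X.shape[0]
    V = vc.sigma2_alpha * A + vc.sigma2_eps * np.diag(1.0 / w)
    cho = linalg.cho_factor(V, lower=True)
    one = np.ones(n)
    Vi_one = linalg.cho_solve(cho, one)
    Vi_Y = linalg.cho_solve(cho, Y)
    Vi_X = linalg.cho_solve(cho, X)
    a11 = one @ Vi_one
    a12 = X.T @ Vi_one
    a22 = np.einsum("ij,ij->j", X, Vi_X)
    b1 = one @ Vi_Y  # (m,) per replicate
    b2 = np.einsum("ij,ij->j", X, Vi_Y)
    det = a11 * a22 - a12**2
    ok = det > _ZERO_VAR_TOL * a11
    det_safe = np.where(ok, det, np.nan)
    beta = (a11 * b2 - a12 * b1) / det_safe
    se = np.sqrt(a11 / det_safe)
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, z, p


def fit_m1(geno: GenotypeMatrix, traits: TraitRecords) -> pd.DataFrame:
    """Model M1: weighted least squares, one SNP at a time."""
    X, traits = _design(geno, traits)
    beta, se, z, p = m1_scan(X, traits.values, traits.weights)
    return _result_table(geno, "M1", beta, se, z, p)


def fit_m2(
    geno: GenotypeMatrix,
    traits: TraitRecords,
    A: RelationshipMatrix,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Model M2: per-SNP fixed effect with a random polygenic background.

    Solved as GLS with V = A sigma2_alpha + D sigma2_eps factorized once;
    identical to the mixed-model-equations fixed-effect block.
    """
    X, traits = _design(geno, traits)
    A = A.aligned_to(geno.individual_ids)
    n = geno.n_individuals
    V = vc.sigma2_alpha * A.values + vc.sigma2_eps * np.diag(1.0 / traits.weights)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise GmbError(
            "phenotypic covariance V = A*sigma2_alpha + D*sigma2_eps is not "
            "positive definite (check the relationship matrix A)"
        ) from exc
    one = np.ones(n)
    Vi_one = linalg.cho_solve(cho, one)
    Vi_y = linalg.cho_solve(cho, traits.values)
    Vi_X = linalg.cho_solve(cho, X)
    a11 = one @ Vi_one
    a12 = X.T @ Vi_one  # (m,)
    a22 = np.einsum("ij,ij->j", X, Vi_X)  # (m,)
    b1 = one @ Vi_y
    b2 = X.T @ Vi_y  # (m,)
    det = a11 * a22 - a12**2
    ok = det > _ZERO_VAR_TOL * a11
    det_safe = np.where(ok, det, np.nan)
    beta = (a11 * b2 - a12 * b1) / det_safe
    se = np.sqrt(a11 / det_safe)
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return _result_table(geno, "M2", beta, se, z, p)


def mme_fixed_effects(
    X_snp: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    A: np.ndarray,
    vc: VarianceComponents,
):
    """Fixed-effect block of Henderson's mixed model equations for one SNP.

    Dense assembly of the full (mu, beta, alpha) system; kept as the
    reference route for the GLS shortcut used by :func:`fit_m2`.  Returns
    (beta_hat, se_beta).
    """
    n = len(y)
    W = np.column_stack([np.ones(n), X_snp])  # fixed design
    Dinv = np.diag(weights)  # D^{-1} sigma_eps^{-2} up to the scalar
    Ainv = np.linalg.inv(A)
    lam = vc.sigma2_eps / vc.sigma2_alpha
    top = np.hstack([W.T @ Dinv @ W, W.T @ Dinv])
    bot = np.hstack([Dinv @ W, Dinv + lam * Ainv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([W.T @ Dinv @ y, Dinv @ y])
    C = np.linalg.inv(lhs)
    sol = C @ rhs
    se = np.sqrt(C[1, 1] * vc.sigma2_eps)
    return sol[1], se


def _result_table(geno, model, beta, se, z, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "model": model,
            "estimate": beta,
            "se": se,
            "stat": z,
            "p_nominal": p,
            "p_adjusted": np.nan,
        }
    )
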