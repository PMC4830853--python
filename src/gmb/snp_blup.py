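"""All-SNP ridge model (M4, "SNP-BLUP") fitted by Gauss-Seidel with residual
update, plus Wald testing of the shrunken effects.

Model: y = mu + Z g + eps with g ~ N(0, I sigma2_a / m) and eps ~ N(0,
D sigma2_eps), D_ii = 1/EDC_i.  The normal equations are the ridge system

    (Zc' D^{-1} Zc + lam* I) g = Zc' D^{-1} yc,    lam* = sigma2_eps * m / sigma2_a,

with mu carried as an unshrunken effect re-estimated each sweep (equivalent
to weighted centering of y and the columns of Z at convergence).  The solver
visits SNPs in fixed ascending index order and updates the residual vector in
place after every coordinate move, so the full coefficient matrix is never
formed.

Wald testing is a separate dense step: PEV_j = [C^{-1}]_jj sigma2_eps with C
the (centered) coefficient matrix; the default standard error uses the
estimator variance Var(g_hat_j) = sigma2_g - PEV_j, under which the statistic
is standard normal when the data really come from the model's own prior.
A PEV-only standard error is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigError, ConvergenceError, GmbError
from .geno import GenotypeMatrix, TraitRecords
from .single_snp import VarianceComponents

try:  # compiled inner sweep; the numpy fallback is numerically equivalent
    import numba

    @numba.njit(cache=True)
    def _gsru_sweep(Zc, WZ, d, denom, g, e):  # pragma: no cover - compiled
        n, m = Zc.shape
        max_change = 0.0
        for j in range(m):
            num = d[j] * g[j]
            for i in range(n):
                num += WZ[i, j] * e[i]
            g_new = num / denom[j]
            delta = g_new - g[j]
            if delta != 0.0:
                for i in range(n):
                    e[i] -= Zc[i, j] * delta
                g[j] = g_new
                ad = abs(delta)
                if ad > max_change:
                    max_change = ad
        return max_change

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class GSRUSettings:
    """Gauss-Seidel residual-update solver settings."""

    max_iterations: int = 50_000
    tolerance: float = 1e-8  # relative L-infinity change in g per sweep
    track_convergence: bool = True

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")


@dataclass
class M4Fit:
    g: np.ndarray
    mu: float
    n_sweeps: int
    convergence: pd.DataFrame  # columns: sweep, max_change
    ridge: float  # lam* actually used
    weighted: bool


def _prepare(geno: GenotypeMatrix, traits: TraitRecords, weighted: bool):
    if geno.missing_mask().any():
        raise GmbError("genotypes contain missing entries; impute before fitting")
    traits = traits.aligned_to(geno.individual_ids)
    Z = geno.codes.astype(float)
    w = traits.weights if weighted else np.ones(geno.n_individuals)
    return Z, traits.values, w


def fit_m4_gsru(
    geno: GenotypeMatrix,
    traits: TraitRecords,
    vc: VarianceComponents,
    settings: GSRUSettings = GSRUSettings(),
    weighted: bool = True,
) -> M4Fit:
    """Solve the all-SNP ridge system by Gauss-Seidel with residual update.

    Per-SNP update: g_j <- (z_j' W e + d_j g_j) / (d_j + lam*) with
    d_j = z_j' W z_j, followed by an in-place residual correction.  Raises
    :class:`ConvergenceError` (carrying the convergence log) if the relative
    change criterion is not met within ``max_iterations`` sweeps.
    """
    if vc.sigma2_a <= 0:
        raise ConfigError("sigma2_a must be > 0 for the all-SNP model")
    Z, y, w = _prepare(geno, traits, weighted)
    n, m = Z.shape
    lam = vc.sigma2_eps * m / vc.sigma2_a
    if lam <= 0:
        raise ConfigError(f"ridge parameter lam* = {lam} must be > 0")
    sw = w.sum()
    # Work on weighted-centered columns: with mu re-estimated every sweep the
    # joint stationarity conditions reduce to the centered ridge system, and
    # centering removes the slowly-converging intercept/allele-frequency mode.
    Zc = np.asfortranarray(Z - (w @ Z) / sw)
    WZ = np.asfortranarray(w[:, None] * Zc)
    d = np.einsum("ij,ij->j", Zc, WZ)  # d_j = z_j' W z_j
    g = np.zeros(m)
    e = y - float((w @ y) / sw)  # centered residual  yc - Zc g
    log = []
    denom = d + lam
    for sweep in range(1, settings.max_iterations + 1):
        if _HAVE_NUMBA:
            max_change = _gsru_sweep(Zc, WZ, d, denom, g, e)
        else:
            max_change = 0.0
            for j in range(m):
                num = WZ[:, j] @ e + d[j] * g[j]
                g_new = num / denom[j]
                delta = g_new - g[j]
                if delta != 0.0:
                    e -= Zc[:, j] * delta
                    g[j] = g_new
                    ad = abs(delta)
                    if ad > max_change:
                        max_change = ad
        scale = max(float(np.max(np.abs(g))), 1e-300)
        rel = max_change / scale
        if settings.track_convergence:
            log.append((sweep, rel))
        if rel < settings.tolerance:
            conv = pd.DataFrame(log, columns=["sweep", "max_change"])
            mu = float((w @ (y - Z @ g)) / sw)  # unshrunken mean, raw coding
            return M4Fit(g=g, mu=mu, n_sweeps=sweep, convergence=conv,
                         ridge=lam, weighted=weighted)
    conv = pd.DataFrame(log, columns=["sweep", "max_change"])
    raise ConvergenceError(
        f"GSRU did not converge in {settings.max_iterations} sweeps "
        f"(last relative change {rel:.3e})",
        log=conv,
    )


def dense_ridge_solve(
    geno: GenotypeMatrix,
    traits: TraitRecords,
    vc: VarianceComponents,
    weighted: bool = True,
) -> tuple[np.ndarray, float]:
    """Direct dense solve of the same centered ridge system (reference route)."""
    if vc.sigma2_a <= 0:
        raise ConfigError("sigma2_a must be > 0 for the all-SNP model")
    Z, y, w = _prepare(geno, traits, weighted)
    m = Z.shape[1]
    lam = vc.sigma2_eps * m / vc.sigma2_a
    sw = w.sum()
    Zc = Z - (w @ Z) / sw
    yc = y - (w @ y) / sw
    C = Zc.T @ (w[:, None] * Zc) + lam * np.eye(m)
    g = linalg.solve(C, Zc.T @ (w * yc), assume_a="pos")
    mu = float((w @ (y - Z @ g)) / sw)
    return g, mu


def m4_wald(
    geno: GenotypeMatrix,
    traits: TraitRecords,
    vc: VarianceComponents,
    fit: M4Fit,
    se_mode: str = "estvar",
) -> pd.DataFrame:
    """Wald test of the shrunken SNP effects.

    ``se_mode="estvar"`` (default): Var(g_hat_j) = sigma2_g - PEV_j, the
    marginal variance of the BLUP itself; standard normal when the generative
    model matches the prior.  ``se_mode="pev"``: SE = sqrt(PEV_j).  SNPs with
    non-positive variance under the chosen mode are flagged not-testable
    (NaN statistics).
    """
    if se_mode not in ("estvar", "pev"):
        raise ConfigError(f"se_mode must be 'estvar' or 'pev', got {se_mode!r}")
    Z, y, w = _prepare(geno, traits, fit.weighted)
    m = Z.shape[1]
    sw = w.sum()
    Zc = Z - (w @ Z) / sw
    C = Zc.T @ (w[:, None] * Zc) + fit.ridge * np.eye(m)
    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise GmbError("ridge coefficient matrix C is not positive definite") from exc
    pev = np.diag(linalg.cho_solve(cho, np.eye(m))).copy() * vc.sigma2_eps
    sigma2_g = vc.sigma2_a / m
    if se_mode == "estvar":
        var = sigma2_g - pev
    else:
        var = pev
    ok = var > 1e-14 * sigma2_g
    se = np.sqrt(np.where(ok, var, np.nan))
    with np.errstate(invalid="ignore"):
        z = fit.g / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "model": "M4",
            "estimate": fit.g,
            "se": se,
            "stat": z,
            "p_nominal": p,
            "p_adjusted": np.nan,
        }
    )


def m4_pev(
    geno: GenotypeMatrix,
    traits: TraitRecords,
    vc: VarianceComponents,
    fit: M4Fit,
) -> np.ndarray:
    """Prediction error variances PEV_j = [C^{-1}]_jj * sigma2_eps."""
    Z, _, w = _prepare(geno, traits, fit.weighted)
    m = Z.shape[1]
    sw = w.sum()
    Zc = Z - (w @ Z) / sw
    C = Zc.T @ (w[:, None] * Zc) + fit.ridge * np.eye(m)
    cho = linalg.cho_factor(C, lower=True)
    return np.diag(linalg.cho_solve(cho, np.eye(m))) * vc.sigma2_eps
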