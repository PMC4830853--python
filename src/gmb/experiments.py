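"""Benchmark experiments over the synthetic study design.

Each function simulates data under stated conditions, runs the relevant
models through the public package surface, and returns the measured
quantities.  They are the computational core behind the numbered analysis
scripts and the acceptance runner; all randomness flows from one integer
seed so every experiment is exactly repeatable.

Problem sizes are desk-scale versions of the reference design (hundreds to a
few thousand individuals, 500-5,000 SNPs) chosen so that a full run of every
experiment completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import car, simdata, single_snp, snp_blup
from .selection import bonferroni_adjust, select_significant
from .simdata import SimulationConfig
from .single_snp import VarianceComponents, fit_m1, fit_m2, m1_scan


def _child_seed(seed: int, stream: int, rep: int = 0) -> int:
    return int(np.random.SeedSequence([seed, stream, rep]).generate_state(1)[0] % (2**31))


def m4_selection_calibration(seed: int, n_reps: int = 50, n: int = 500, m: int = 2000):
    """Fraction of SNPs the all-SNP model calls significant at nominal 0.001
    when the data really come from its own prior.

    Traits are y = mu + Z g + eps with g ~ N(0, I sigma2_a/m) and
    EDC-weighted noise; the Wald statistic with the estimator-variance
    standard error is standard normal under this generative model, so the
    expected selected fraction is exactly 0.1%.
    """
    sigma2_a = 1.0
    fractions = []
    for rep in range(n_reps):
        s = _child_seed(seed, 1, rep)
        cfg = SimulationConfig(
            n_individuals=n, n_snps=m, n_families=max(n // 20, 1),
            missing_rate=0.0, architecture="null", sigma2_alpha=0.0, seed=s,
        )
        g = simdata.simulate_genotypes(cfg)
        A = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg))
        rng = np.random.default_rng(s)
        g_true = rng.normal(0.0, np.sqrt(sigma2_a / m), size=m)
        traits, _ = simdata.simulate_trait(g, A, cfg, g=g_true)
        vc = VarianceComponents(0.0, cfg.sigma2_eps, sigma2_a=sigma2_a)
        fit = snp_blup.fit_m4_gsru(g, traits, vc)
        res = snp_blup.m4_wald(g, traits, vc, fit)
        fractions.append(float((res["p_nominal"] <= 0.001).mean()))
    return {
        "mean_fraction_pct": 100.0 * float(np.mean(fractions)),
        "per_rep_fraction_pct": [100.0 * f for f in fractions],
        "n_reps": n_reps, "n": n, "m": m,
    }


def bonferroni_fwer(seed: int, n_reps: int = 5000, n: int = 200, m: int = 1000):
    """Family-wise error rate of M1 + Bonferroni at 0.001 under the global
    null: fraction of phenotype replicates with at least one selected SNP.

    One LD-structured genotype panel is simulated; phenotype replicates are
    pure EDC-weighted noise, fitted by the vectorized per-SNP WLS scan.
    """
    cfg = SimulationConfig(
        n_individuals=n, n_snps=m, n_families=max(n // 20, 1),
        missing_rate=0.0, architecture="null", sigma2_alpha=0.0,
        seed=_child_seed(seed, 2),
    )
    g = simdata.simulate_genotypes(cfg)
    X = g.codes.astype(float)
    rng = np.random.default_rng(_child_seed(seed, 3))
    w = rng.lognormal(cfg.edc_log_mean, cfg.edc_log_sd, size=n)
    Y = rng.standard_normal((n, n_reps)) * np.sqrt(cfg.sigma2_eps / w)[:, None]
    _, _, _, p = m1_scan(X, Y, w)
    p_adj = np.minimum(1.0, m * p)
    any_hit = (p_adj <= 0.001).any(axis=0)
    return {
        "fwer": float(any_hit.mean()),
        "n_hit_replicates": int(any_hit.sum()),
        "n_reps": n_reps, "n": n, "m": m,
    }


def oracle_equivalences(seed: int):
    """Maximum absolute disagreement between the fast solvers and their dense
    reference routes on one mid-size instance each."""
    out = {}
    # GSRU vs dense ridge solve, n = 200, m = 500
    cfg = SimulationConfig(
        n_individuals=200, n_snps=500, n_families=10, missing_rate=0.0,
        architecture="polygenic", sigma2_alpha=0.2, seed=_child_seed(seed, 4),
    )
    g = simdata.simulate_genotypes(cfg)
    A = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg))
    traits, _ = simdata.simulate_trait(g, A, cfg)
    vc = VarianceComponents(0.2, 1.0, sigma2_a=0.5)
    fit = snp_blup.fit_m4_gsru(g, traits, vc)
    g_dense, _ = snp_blup.dense_ridge_solve(g, traits, vc)
    out["gsru_vs_dense_max_abs"] = float(np.max(np.abs(fit.g - g_dense)))

    # M2 (GLS with factorized V) vs dense per-SNP GLS, small panel
    cfg2 = SimulationConfig(
        n_individuals=150, n_snps=40, n_families=8, missing_rate=0.0,
        architecture="polygenic", sigma2_alpha=0.3, seed=_child_seed(seed, 5),
    )
    g2 = simdata.simulate_genotypes(cfg2)
    A2 = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg2))
    t2, _ = simdata.simulate_trait(g2, A2, cfg2)
    vc2 = VarianceComponents(0.3, 1.0)
    res2 = fit_m2(g2, t2, A2, vc2)
    V = vc2.sigma2_alpha * A2.values + vc2.sigma2_eps * np.diag(1.0 / t2.weights)
    Vi = np.linalg.inv(V)
    X = g2.codes.astype(float)
    diffs = []
    for j in range(g2.n_snps):
        W = np.column_stack([np.ones(g2.n_individuals), X[:, j]])
        cov = np.linalg.inv(W.T @ Vi @ W)
        beta = (cov @ (W.T @ Vi @ t2.values))[1]
        diffs.append(abs(beta - res2["estimate"][j]))
    out["m2_vs_dense_gls_max_abs"] = float(np.max(diffs))

    # CAR dual trick vs dense eigendecomposition, m <= 50, n <= 30
    rng = np.random.default_rng(_child_seed(seed, 6))
    codes = rng.choice([-1, 0, 1], size=(30, 50), p=[0.25, 0.5, 0.25]).astype(float)
    y = rng.standard_normal(30)
    from .geno import GenotypeMatrix, TraitRecords

    gm = GenotypeMatrix(
        codes=codes, snp_ids=np.array([f"s{j}" for j in range(50)], dtype=object),
        chromosomes=np.repeat("1", 50), positions=np.arange(1, 51),
        individual_ids=np.array([f"i{k}" for k in range(30)], dtype=object),
    )
    tr = TraitRecords(gm.individual_ids, y, np.ones(30))
    lam = 0.4
    omega = car.car_scores(gm, tr, car.CARParameters(lam=lam, kappa=2.0))
    Z = (codes - codes.mean(0)) / codes.std(0, ddof=1)
    R = Z.T @ Z / 29
    P = lam * np.eye(50) + (1 - lam) * R
    evals, evecs = np.linalg.eigh(P)
    r = Z.T @ ((y - y.mean()) / y.std(ddof=1)) / 29
    omega_dense = evecs @ np.diag(evals**-0.5) @ evecs.T @ r
    out["car_dual_vs_dense_max_abs"] = float(np.max(np.abs(omega - omega_dense)))
    return out


def model_reductions(seed: int):
    """Structural limits: M2 -> M1 at zero polygenic variance, CAR scores ->
    marginal correlations at full shrinkage, Hayes-Goddard M -> 0 at p = 1/2."""
    cfg = SimulationConfig(
        n_individuals=200, n_snps=80, n_families=10, missing_rate=0.0,
        architecture="polygenic", sigma2_alpha=0.3, seed=_child_seed(seed, 7),
    )
    g = simdata.simulate_genotypes(cfg)
    A = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg))
    traits, _ = simdata.simulate_trait(g, A, cfg)
    m1 = fit_m1(g, traits)
    m2 = fit_m2(g, traits, A, VarianceComponents(0.0, 1.0))
    omega = car.car_scores(g, traits, car.CARParameters(lam=1.0, kappa=2.0))
    r = car.marginal_correlations(g, traits)
    from .selection import hayes_goddard_m

    return {
        "m2_equals_m1_max_abs": float(
            np.max(np.abs(m1["estimate"] - m2["estimate"]))
        ),
        "car_lam1_equals_marginal_max_abs": float(np.max(np.abs(omega - r))),
        "hayes_goddard_m_at_p_half": hayes_goddard_m(10.0, ne=1),
    }


def major_gene_recovery(seed: int, n_reps: int = 20, n: int = 2000, m: int = 2000):
    """Power to recover a major-gene SNP carrying 20% of the trait variance.

    Per replicate: does M2 + Bonferroni (0.001) select the causal SNP, and
    does it rank in the all-SNP model's top-5 |z|?
    """
    causal = m // 2
    m2_hits = 0
    m4_hits = 0
    for rep in range(n_reps):
        s = _child_seed(seed, 8, rep)
        cfg = SimulationConfig(
            n_individuals=n, n_snps=m, n_families=max(n // 25, 1),
            missing_rate=0.0, architecture="major_gene", major_gene_index=causal,
            major_gene_variance_fraction=0.2, sigma2_alpha=0.3, seed=s,
        )
        g = simdata.simulate_genotypes(cfg)
        A = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg))
        traits, _ = simdata.simulate_trait(g, A, cfg)
        vc = VarianceComponents(0.3, 1.0, sigma2_a=0.4)
        res2 = fit_m2(g, traits, A, vc)
        res2["p_adjusted"] = bonferroni_adjust(res2["p_nominal"].to_numpy(), m)
        sel2 = select_significant(res2, threshold=0.001)
        if g.snp_ids[causal] in sel2.snp_ids:
            m2_hits += 1
        fit = snp_blup.fit_m4_gsru(g, traits, vc)
        res4 = snp_blup.m4_wald(g, traits, vc, fit)
        z = np.abs(np.nan_to_num(res4["stat"].to_numpy()))
        if causal in np.argsort(-z)[:5]:
            m4_hits += 1
    return {
        "m2_selection_rate_pct": 100.0 * m2_hits / n_reps,
        "m4_top5_rate_pct": 100.0 * m4_hits / n_reps,
        "n_reps": n_reps, "n": n, "m": m,
    }


def null_calibration(seed: int, n: int = 500, m: int = 5000):
    """Kolmogorov-Smirnov uniformity of M1 and M2 p values under the global
    null, plus the M1/M2 inflation ratio under strong family structure.

    M1 is checked under its own assumptions (unrelated individuals, no
    polygenic term); M2 under half-sib structure with a true polygenic
    background, which it models through A.  Each null SNP is paired with
    its own independent phenotype replicate: the Kolmogorov-Smirnov test
    needs independent observations, and p values computed against one
    shared phenotype are dependent through it (an unusual draw for a
    high-EDC individual shifts every test at once), as are p values of
    SNPs in LD.  The structure-inflation arm keeps the shared-phenotype,
    LD-structured design.
    """
    cfg1 = SimulationConfig(
        n_individuals=n, n_snps=m, n_families=n, adjacent_ld=0.0,
        missing_rate=0.0,
        architecture="null", sigma2_alpha=0.0, seed=_child_seed(seed, 9),
    )
    g1 = simdata.simulate_genotypes(cfg1)
    rng1 = np.random.default_rng(_child_seed(seed, 12))
    w1 = rng1.lognormal(cfg1.edc_log_mean, cfg1.edc_log_sd, size=n)
    Y1 = rng1.standard_normal((n, m)) * np.sqrt(cfg1.sigma2_eps / w1)[:, None]
    _, _, _, p1 = single_snp.m1_paired_scan(g1.codes.astype(float), Y1, w1)
    ks1 = stats.kstest(p1[~np.isnan(p1)], "uniform")

    cfg2 = SimulationConfig(
        n_individuals=n, n_snps=m, n_families=n // 2, adjacent_ld=0.0,
        missing_rate=0.0,
        architecture="polygenic", sigma2_alpha=0.3, seed=_child_seed(seed, 10),
    )
    g2 = simdata.simulate_genotypes(cfg2)
    A2 = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg2))
    rng2 = np.random.default_rng(_child_seed(seed, 13))
    w2 = rng2.lognormal(cfg2.edc_log_mean, cfg2.edc_log_sd, size=n)
    L2 = np.linalg.cholesky(A2.values)
    alpha2 = np.sqrt(cfg2.sigma2_alpha) * (L2 @ rng2.standard_normal((n, m)))
    Y2 = alpha2 + rng2.standard_normal((n, m)) * np.sqrt(cfg2.sigma2_eps / w2)[:, None]
    vc2 = VarianceComponents(cfg2.sigma2_alpha, cfg2.sigma2_eps)
    _, _, _, p2 = single_snp.m2_paired_scan(
        g2.codes.astype(float), Y2, w2, A2.values, vc2
    )
    ks2 = stats.kstest(p2[~np.isnan(p2)], "uniform")

    # strong structure: few, large half-sib families; M1 ignores them
    cfg3 = SimulationConfig(
        n_individuals=n, n_snps=3000, n_families=5, missing_rate=0.0,
        architecture="polygenic", sigma2_alpha=0.8, seed=_child_seed(seed, 11),
    )
    g3 = simdata.simulate_genotypes(cfg3)
    A3 = simdata.relationship_from_pedigree(simdata.simulate_pedigree(cfg3))
    t3, _ = simdata.simulate_trait(g3, A3, cfg3)
    z1 = fit_m1(g3, t3)["stat"].to_numpy()
    z2 = fit_m2(g3, t3, A3, VarianceComponents(0.8, 1.0))["stat"].to_numpy()
    inflation = float(np.median(z1**2) / np.median(z2**2))
    return {
        "m1_ks_pvalue": float(ks1.pvalue),
        "m2_ks_pvalue": float(ks2.pvalue),
        "m1_over_m2_median_z2_strong_structure": inflation,
        "n": n, "m": m,
    }
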