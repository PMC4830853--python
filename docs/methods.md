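# Methods

## Data model

All models operate on a panel of biallelic SNPs coded −1/0/+1 (homozygote /
heterozygote / alternative homozygote) for `n` genotyped bulls, and a
pseudophenotype vector on the deregressed-proof scale. Deregression itself
is not modelled: pseudophenotypes are generated directly from the additive
model that the downstream estimators assume. Each bull carries an effective
daughter contribution (EDC) `w_i > 0`; throughout the package the residual
of bull `i` has variance `sigma2_e / w_i`, i.e. the residual covariance is
`D sigma2_e` with `D_ii = 1/w_i`. This one convention is used identically
in the WLS weights of M1, the GLS covariance of M2, and the weighted
normal equations of M4 (M4 also accepts an unweighted fit).

Variance components (`sigma2_alpha` for the polygenic effect, `sigma2_e`
residual, `sigma2_a` total additive genic variance for the all-SNP prior)
are plug-in inputs, as in routine genomic evaluation; the package performs
no REML.

## The four models

**M1 — single-SNP weighted regression.** For each SNP, `y = mu + x b + e`
fitted by WLS with weights `w_i`. The residual variance is estimated per
SNP from the weighted residual sum of squares on `n − 2` degrees of
freedom, and the Wald statistic `b/SE(b)` is referred to Student
t(n − 2). The t reference (rather than the asymptotic standard normal) is
deliberate: with an estimated residual scale the t distribution is the
exact finite-sample null, and at desk-scale n the normal reference
measurably breaks Bonferroni FWER control (at n in the thousands the two
are indistinguishable). M2 and M4 keep the standard normal because their
plug-in variance components leave no estimated scale in the statistic.

**M2 — single-SNP mixed model.** `y = mu + x b + a + e` with polygenic
`a ~ N(0, A sigma2_alpha)`, A the numerator relationship matrix from the
pedigree (tabular method). With known variance components the fixed-effect
solutions of Henderson's mixed model equations coincide with GLS under
`V = A sigma2_alpha + D sigma2_e`; the implementation factorizes V once
(Cholesky) and reuses it across all SNPs, turning the scan into one
`O(n^3)` factorization plus `O(n^2)` per SNP. The dense MME assembly is
retained (`mme_fixed_effects`) as a reference route and is checked against
the GLS shortcut in the tests.

**M3 — CAR scores.** `omega = P^{-1/2} P_xy`, where `P_xy` is the vector
of marginal SNP-phenotype Pearson correlations and
`P = lambda I + (1 − lambda) R` is the shrunken SNP-SNP correlation
matrix. `P^{-1/2}` is never materialized: after shrinking toward the
identity, P's non-unit eigenvalues live on the right-singular-vector space
of the standardized genotype matrix, so `omega` is computed from an
economy SVD (cost `O(n^2 m)` instead of `O(m^3)`), and the dense
eigendecomposition route is used as the oracle in tests.

* `lambda` is estimated by the analytic variance-minimizing
  (James–Stein-type) formula `sum var(r_ij) / sum r_ij^2` over off-diagonal
  pairs, computed through the n×n Gram matrix, clipped to [0, 1]; it can
  be overridden (`--lambda`).
* Significance uses the correlation t-transform
  `t = omega sqrt((kappa − 1)/(1 − omega^2))` against t(kappa − 1). The
  transform is written with `(kappa − 1)` in the numerator — the form that
  is real-valued for `kappa > 1` and consistent with the stated degrees of
  freedom. `kappa` acts as a null effective sample size; it is fitted by
  matching the interquartile range of the observed scores to the null
  IQR implied by `omega = t/sqrt(kappa − 1 + t^2)` (assuming most SNPs are
  null), with a logged fallback `kappa = n` when the fit is degenerate and
  a `--kappa` override. Scores at `|omega| >= 1` map to p = 0 with a
  warning rather than an error.

**M4 — SNP-BLUP / genomic selection model.** `y = mu + Z g + e` with
`g ~ N(0, I sigma2_a/m)`, solved by Gauss–Seidel with residual update
(GSRU) on the ridge system `(Zc' D^{-1} Zc + lam I) g = Zc' D^{-1} yc`,
`lam = sigma2_e m / sigma2_a`. `mu` is an unshrunken effect re-estimated
each sweep; the solver works on weighted-centred columns, which is exactly
the system the joint `(mu, g)` stationarity conditions reduce to and
removes a slowly-converging intercept mode. SNPs are visited in fixed
ascending order; the residual vector is updated after every coordinate
move; convergence is declared when the relative L∞ change in `g` per
sweep falls below 1e-8 (at most 50,000 sweeps — the cap is generous
because heavy EDC weights make the effective noise small and slow the
iteration; a non-convergent run raises an error carrying the sweep log).
The inner sweep is JIT-compiled when numba is available, with an
equivalent numpy fallback.

Wald testing of the shrunken effects is a separate dense step
(`O(m^3)`, practical to a few thousand SNPs): `PEV_j = [C^{-1}]_jj
sigma2_e`. The default standard error is the estimator-variance form
`Var(g_hat_j) = sigma2_g − PEV_j`, under which `g_hat_j/SE` is exactly
standard normal when the data are generated from the model's own prior —
this is what makes the "nominal 0.001 selects 0.1% of SNPs" behaviour a
checkable calibration statement. The PEV-only alternative
(`z = g_hat/sqrt(PEV)`) is available via `se_mode="pev"`. C is built from
the weighted-centred Z, matching the estimator actually computed. SNPs
with no data contribution (zero centred variance) have
`Var(g_hat) = 0` and are flagged not-testable rather than dropped.

## Selection and comparison

Significance threshold 0.001 throughout, boundary inclusive (p ≤ 0.001).
M1/M2 p values are Bonferroni-adjusted (`min(1, m p)` over the post-QC
panel — adjusting the p values rather than the threshold so per-SNP
adjusted values can be reported); M3/M4 use nominal p. Selected sets are
compared by Venn-region counts, mean minor allele frequency, and mean
pairwise LD. "Pairwise correlation" is reported primarily as mean |r|
(sign-free, on the scale of the usual published values) with mean r²
alongside. Empty or singleton selections yield NaN summaries, never 0.
The Hayes–Goddard gene-count estimator `M = N ln((1−p)/p)`, `p = 1/(2Ne)`
is provided; at the standard dairy-cattle inputs (N = 10.73 heterozygous
QTL, Ne = 103) it evaluates to 57.12 by direct computation.

## Synthetic data generator

The generator emulates a progeny-tested dairy-bull design; its defaults are
the reference scale (2,601 bulls, 46,267 post-QC SNPs, lognormal EDC weights
with log-mean 4 and log-sd 1 — median ≈ 55 effective daughters), while
tests and demos pass smaller explicit sizes.

* **Genotypes.** Haplotypes follow a first-order Markov chain: at SNP j the
  conditional allele probability is
  `f_j + rho sqrt(f_j q_j / f_{j-1} q_{j-1}) (a_{j-1} − f_{j-1})`, which
  yields adjacent allele correlation `rho` (default 0.4) while preserving
  each site's marginal frequency (up to clipping into [0, 1], negligible
  inside the default MAF range 0.01–0.5). Two independent haplotypes are
  summed and recoded; genotype-level adjacent correlation equals the
  haplotype-level one. Missingness is MCAR at rate 0.01.
* **Pedigree.** Founder sires plus offspring with unknown dams (paternal
  half-sib design); offspring are assigned to sires uniformly at random.
  The tabular-method A matrix accepts any acyclic two-parent pedigree.
* **Traits.** `y = mu + Z g + a + e` with `a ~ N(0, A sigma2_alpha)`
  (Cholesky draw), `e_i ~ N(0, sigma2_e/w_i)`. Architectures: `major_gene`
  (the designated SNP's effect is scaled so its expected variance
  contribution is the requested fraction of the total, computed from the
  realized column variance, `sigma2_alpha · mean diag(A)` and
  `sigma2_e · mean(1/w)`), `polygenic`, `low_h2` (a label; set a small
  `sigma2_alpha`), and `null` (g = 0, a = 0). An explicit effect vector
  `g` can be supplied instead, which is how the all-SNP model's own prior
  is simulated for the calibration experiments. True `g` and `a` are
  returned for recovery tests.

What the generator does **not** emulate: coalescent/forward population
genetics (no drift, selection, or realistic long-range LD decay), genotype
calling error, informative missingness, the deregression step itself, or
multi-trait correlation structure. Tests passing on these simulations
therefore validate the estimators and selection rules under their stated
assumptions, not the full complexity of real chip data.

## Benchmark experiments and problem sizes

The experiment drivers (`gmb.experiments`) use desk-scale versions of the
design, chosen so the whole battery runs in minutes on one CPU:
oracle equivalences at n = 200/m = 500 (GSRU), n = 150/m = 40 (M2),
n = 30/m = 50 (CAR); FWER over 5,000 global-null phenotype replicates at
n = 200/m = 1,000 (one shared LD panel, vectorized WLS scan); M4
calibration over 50 replicates at n = 500/m = 2,000; major-gene recovery
over 20 replicates at n = 2,000/m = 2,000; null-calibration KS at 5,000
SNPs, n = 500.

For the KS uniformity checks each null SNP is paired with its own
independent phenotype replicate. This matters: p values computed against
one shared phenotype are mutually dependent through it (a single unusual
draw for a high-EDC bull shifts all tests at once) and p values of SNPs in
LD are dependent too, so a KS test over them is not a valid uniformity
test — it rejects perfectly calibrated scans. The paired design
(`m1_paired_scan` / `m2_paired_scan`, with the GLS covariance factorized
once) makes the p values exactly iid uniform under the null. M1 is checked
under its own assumptions (unrelated bulls, no polygenic term); M2 under
half-sib structure with a true polygenic background. The companion
inflation experiment keeps the shared-phenotype LD design and shows the
naive regression's median z² roughly doubling relative to the mixed model
under strong (5-family) structure.

## Numerical choices and degenerate inputs

* MAF is computed on non-missing entries only, before imputation; QC
  boundaries are inclusive (`MAF >= 0.01`, `call rate >= 0.90`); an
  all-missing column gets MAF = NaN, distinguishable from a true 0.
  QC removing every SNP raises an explicit empty-panel error.
* Mean imputation preserves column means; models refuse unimputed input.
* Zero-variance SNP columns are flagged not-estimable (NaN statistics),
  never silently dropped; selection never picks NaN rows.
* A non-positive-definite A (or V, or ridge C) raises an error naming the
  offending matrix.
* `lambda = 0` with a singular empirical correlation matrix (m > n − 1)
  raises an error advising `lambda > 0`.
* Ridge shrinkage monotonicity holds for the coefficient norm on any
  design, and per-coordinate only on orthogonal designs — with correlated
  predictors individual |g_j| can transiently grow as the penalty
  increases; the tests assert exactly these properties.
* One master seed drives every stage; stage seeds are derived through
  `numpy.random.SeedSequence` spawning, so runs are bit-reproducible and
  sub-experiments are statistically independent.

## Known limitations

Dense O(m³) Wald testing limits M4 standard errors to a few thousand SNPs
(the GSRU fit itself never forms the coefficient matrix and scales to the
full 46k panel). The CAR `kappa` fit assumes a mostly-null score vector and
will overstate significance when a large fraction of SNPs carry signal.
PLINK I/O covers the standard SNP-major .bed layout only (no sample-major
variant).
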