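"""Independent reference implementations used to check the package's fast
paths.  Everything here is deliberately naive: dense algebra, explicit loops,
Monte Carlo — written from the defining formulas, not from the code under
test."""

import numpy as np


def wls_slope(x, y, w):
    """Weighted least squares of y on [1, x] via the dense normal equations.

    Returns (beta, se) with the residual variance estimated from the
    weighted residual sum of squares on n - 2 degrees of freedom.
    """
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ coef
    s2 = (w * resid**2).sum() / (len(y) - 2)
    cov = s2 * np.linalg.inv(XtWX)
    return coef[1], np.sqrt(cov[1, 1])


def gls_slope(x, y, V):
    """Generalized least squares of y on [1, x] with known covariance V."""
    X = np.column_stack([np.ones_like(x), x])
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    coef = cov @ (X.T @ Vi @ y)
    return coef[1], np.sqrt(cov[1, 1])


def car_scores_dense(X, y, lam):
    """CAR scores by dense eigendecomposition of the shrunken correlation
    matrix: omega = P^{-1/2} r with P = lam I + (1 - lam) R."""
    Xc = X - X.mean(axis=0)
    Z = Xc / Xc.std(axis=0, ddof=1)
    yc = y - y.mean()
    yz = yc / yc.std(ddof=1)
    n = len(y)
    r = Z.T @ yz / (n - 1)
    R = Z.T @ Z / (n - 1)
    P = lam * np.eye(R.shape[0]) + (1 - lam) * R
    evals, evecs = np.linalg.eigh(P)
    P_isqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    return P_isqrt @ r


def shrinkage_lambda_loops(X):
    """Schafer-Strimmer shrinkage intensity toward the identity target,
    computed pairwise with explicit loops (O(n m^2))."""
    n, m = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    num = 0.0
    den = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            wk = Z[:, i] * Z[:, j]
            wbar = wk.mean()
            num += n / (n - 1) ** 3 * ((wk - wbar) ** 2).sum()
            r_ij = wk.sum() / (n - 1)
            den += r_ij**2
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def ridge_solve_dense(Z, y, w, lam):
    """Weighted-centered ridge system solved densely: returns (g, mu)."""
    sw = w.sum()
    Zc = Z - (w @ Z) / sw
    yc = y - (w @ y) / sw
    C = Zc.T @ np.diag(w) @ Zc + lam * np.eye(Z.shape[1])
    g = np.linalg.solve(C, Zc.T @ (w * yc))
    mu = float((w @ (y - Z @ g)) / sw)
    return g, mu


def gene_dropping_relationship(ped, n_rep, seed):
    """Monte Carlo numerator relationship matrix by gene dropping.

    Each founder gets two unique alleles; every descendant inherits one
    random allele from each known parent (a fresh unique allele stands in
    for an unknown parent).  The relationship a_ij is estimated as twice the
    probability that a random allele of i is identical by descent to a
    random allele of j (4 x mean of the 4 allele-pair IBD indicators);
    diagonal: 1 + P(the two alleles of i are IBD).
    """
    rng = np.random.default_rng(seed)
    ids = list(ped.ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    order = ped.topological_order()
    n = len(ids)
    acc = np.zeros((n, n))
    for _ in range(n_rep):
        alleles = np.zeros((n, 2), dtype=np.int64)
        counter = [0]

        def fresh():
            counter[0] += 1
            return counter[0]

        for i in order:
            inherited = []
            for parent in (ped.sires[i], ped.dams[i]):
                if parent is None:
                    inherited.append(fresh())
                else:
                    p = pos[parent]
                    inherited.append(alleles[p, rng.integers(2)])
            alleles[i] = inherited
        a = alleles
        ibd = (
            (a[:, None, 0] == a[None, :, 0]).astype(float)
            + (a[:, None, 0] == a[None, :, 1])
            + (a[:, None, 1] == a[None, :, 0])
            + (a[:, None, 1] == a[None, :, 1])
        ) / 2.0
        np.fill_diagonal(ibd, 1.0 + (a[:, 0] == a[:, 1]))
        acc += ibd
    return acc / n_rep
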