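"""Variance-component association tests.

The model is y ~ N(X alpha, sigma2_e I + sigma2_g K) with K = phi phi^T
built per gene by :mod:`fikat.kernels`.  The null hypothesis is
sigma2_g = 0, tested one-sided two ways:

* a score test whose statistic follows a mixture of chi-square(1)
  variables weighted by the eigenvalues of phi^T P phi (P the
  covariate-projection), with tail probabilities from Ruben's central
  chi-square series and a saddlepoint fallback in the extreme tail;
* a restricted likelihood-ratio test (RLRT) under REML, whose
  nonstandard boundary null law is sampled exactly via the
  Crainiceanu-Ruppert profiled-criterion construction and summarized by
  a parametric mixture pi * chi2_0 + (1 - pi) * a * chi2_d fitted to
  pooled null statistics.

The two-stage sLRT runs the score test genome-wide and computes the
RLRT only for genes whose score p falls below the trigger threshold t.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kernels import KernelFactor

__all__ = [
    "NullModel",
    "LmmFit",
    "NullMixture",
    "GeneTestRecord",
    "fit_null_ols",
    "score_test",
    "pvalue_chi2_mixture",
    "fit_lmm_reml",
    "rlrt_stat",
    "sample_rlrt_null",
    "fit_null_mixture",
    "mixture_pvalue",
    "slrt",
    "cauchy_combine",
    "single_variant_test",
    "lambda_gc",
    "derive_seed",
]

EIG_REL_TOL = 1e-10  # eigenvalues below this fraction of the max are noise
ZERO_STAT_EPS = 1e-8  # RLRT statistics at/below this count as boundary zeros
P_FLOOR = 1e-300


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable per-(gene, test) seed below 2**31, independent of gene order."""
    h = hashlib.sha256(
        ":".join([str(master_seed), *map(str, parts)]).encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# null model


@dataclass
class NullModel:
    """OLS fit of y on X (the sigma2_g = 0 null of the mixed model)."""

    coef: np.ndarray
    sigma2_e: float
    residuals: np.ndarray  # r = P y
    q_basis: np.ndarray  # orthonormal basis of col(X), for applying P
    n: int
    q: int
    y: np.ndarray
    X: np.ndarray

    def project(self, v: np.ndarray) -> np.ndarray:
        """Apply P = I - X (X^T X)^{-1} X^T to a vector or matrix."""
        return v - self.q_basis @ (self.q_basis.T @ v)


def fit_null_ols(y: np.ndarray, X: np.ndarray) -> NullModel:
    """Least-squares null model; residual variance uses divisor n - q."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if n <= q:
        raise ValueError("need n > q observations")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < max(n, q) * np.finfo(float).eps * diag.max()
    if bad.any():
        raise ValueError(f"design matrix rank-deficient in columns {np.where(bad)[0].tolist()}")
    coef = np.linalg.solve(R, Q.T @ y)
    r = y - Q @ (Q.T @ y)
    sigma2_e = float(r @ r) / (n - q)
    return NullModel(coef, sigma2_e, r, Q, n, q, y, X)


# ---------------------------------------------------------------------------
# chi-square mixture tail probabilities


def _ruben_tail(
    q: float, lam: np.ndarray, acc: float, max_terms: int
) -> tuple[float, float]:
    """P(sum lam_s chi2_1 > q) by Ruben's central chi-square series.

    With beta = min lam, the quadratic form's distribution expands as a
    nonnegative mixture sum_j a_j chi2_{k+2j}(q / beta) whose weights
    a_j sum to one, so the tail is computed additively (no cancellation)
    and the truncation error is bounded by the unassigned weight.
    Returns (p, truncation bound); the bound is infinite when the series
    has not converged within ``max_terms``.
    """
    lam = np.sort(lam)
    beta = lam[0]
    k = lam.size
    c = 1.0 - beta / lam  # in [0, 1)
    a = np.empty(max_terms + 1)
    a[0] = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    total = a[0]
    b = np.empty(max_terms + 1)
    cpow = c.copy()
    n_terms = 1
    for j in range(1, max_terms + 1):
        b[j] = cpow.sum()
        cpow *= c
        a[j] = 0.5 / j * float(b[1 : j + 1][::-1] @ a[:j])
        total += a[j]
        n_terms = j + 1
        if 1.0 - total < acc:
            break
    else:
        return np.nan, np.inf
    dfs = k + 2 * np.arange(n_terms)
    p = float(a[:n_terms] @ stats.chi2.sf(q / beta, dfs))
    return p, 1.0 - total


def _saddlepoint_tail(q: float, lam: np.ndarray) -> float:
    """Kuonen's saddlepoint approximation to P(sum lam_s chi2_1 > q)."""
    lam = np.asarray(lam, dtype=float)
    mean = lam.sum()
    if abs(q - mean) < 1e-12 * max(1.0, mean):
        return 0.5
    lmax = lam.max()

    def kprime_minus_q(z):
        return float(np.sum(lam / (1.0 - 2.0 * z * lam)) - q)

    upper = 1.0 / (2.0 * lmax)
    if q > mean:
        lo, hi = 0.0, upper * (1 - 1e-12)
        while kprime_minus_q(hi) < 0:  # push toward the pole
            hi = upper - (upper - hi) * 0.1
            if upper - hi < 1e-300:
                return P_FLOOR
    else:
        lo = -1.0
        while kprime_minus_q(lo) > 0:
            lo *= 10.0
            if lo < -1e12:
                return 1.0
        hi = 0.0
    zeta = optimize.brentq(kprime_minus_q, lo, hi, xtol=1e-14)
    K = -0.5 * float(np.sum(np.log1p(-2.0 * zeta * lam)))
    Kpp = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * zeta * lam) ** 2))
    w = np.sign(zeta) * np.sqrt(max(2.0 * (zeta * q - K), 0.0))
    v = zeta * np.sqrt(Kpp)
    if w == 0.0 or v == 0.0:
        return 0.5
    p = stats.norm.sf(w + np.log(v / w) / w)
    return float(min(max(p, P_FLOOR), 1.0))


def pvalue_chi2_mixture(
    q: float, lambdas: np.ndarray, acc: float = 1e-7, max_terms: int = 5000
) -> float:
    """Tail probability of a positively weighted chi-square(1) mixture.

    Ruben's series at absolute accuracy ``acc``; the saddlepoint
    approximation takes over in the extreme tail (where only it retains
    relative accuracy) and when the series fails to converge within
    ``max_terms`` (severely spread eigenvalue spectra).
    """
    lam = np.asarray(lambdas, dtype=float).ravel()
    lam = lam[lam > EIG_REL_TOL * lam.max()] if lam.size and lam.max() > 0 else lam
    if lam.size == 0 or np.any(lam <= 0):
        raise ValueError("need at least one positive eigenvalue")
    if q <= 0:
        return 1.0
    p, err = _ruben_tail(float(q), lam, acc, max_terms)
    if not np.isfinite(p) or p <= max(10 * acc, 10 * err) or p > 1.0:
        return _saddlepoint_tail(float(q), lam)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# score test


def score_test(null: NullModel, phi: KernelFactor) -> tuple[float, float]:
    """Variance-component score test of sigma2_g = 0.

    With r = P y, the statistic is r^T phi phi^T r / sigma2_e and its
    null law is sum_s lambda_s chi2_1 over eigenvalues of phi^T P phi.
    """
    mat = phi.matrix
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("kernel factor has no columns")
    Pphi = null.project(mat)
    if not np.any(np.abs(Pphi) > 1e-12):
        raise ValueError("kernel factor numerically zero after projection")
    u = Pphi.T @ null.residuals
    q_score = float(u @ u) / null.sigma2_e
    lam = np.linalg.eigvalsh(Pphi.T @ Pphi)
    lam = lam[lam > EIG_REL_TOL * lam.max()]
    p = pvalue_chi2_mixture(q_score, lam)
    return q_score, p


def single_variant_test(null: NullModel, g: np.ndarray) -> tuple[float, float, float]:
    """Single-variant score test with effect size on the phenotype scale.

    Returns (beta, se, p): beta and se from regressing the residualized
    phenotype on the residualized dosage, p from the chi2_1 score test.
    """
    g = np.asarray(g, dtype=float).ravel()
    gp = null.project(g - np.nanmean(g))
    ss = float(gp @ gp)
    if ss <= 0:
        raise ValueError("monomorphic or covariate-collinear genotype")
    u = float(gp @ null.residuals)
    beta = u / ss
    se = np.sqrt(null.sigma2_e / ss)
    t2 = u**2 / (null.sigma2_e * ss)
    p = float(stats.chi2.sf(t2, 1))
    return beta, se, max(p, P_FLOOR)


# ---------------------------------------------------------------------------
# REML fit and RLRT


@dataclass
class LmmFit:
    sigma2_e: float
    sigma2_g: float
    reml_loglik: float
    converged: bool = True


def _spectral_setup(null: NullModel, phi: KernelFactor):
    """Eigen-structure of phi^T P phi plus the data projections needed by
    the profiled REML criterion."""
    Pphi = null.project(phi.matrix)
    M = Pphi.T @ Pphi
    mu, V = np.linalg.eigh(M)
    order = np.argsort(mu)[::-1]
    mu, V = mu[order], V[:, order]
    keep = mu > EIG_REL_TOL * max(mu[0], 0.0) if mu.size else np.zeros(0, bool)
    mu, V = mu[keep], V[:, keep]
    if mu.size == 0:
        raise ValueError("kernel factor has no nonzero eigenvalues")
    u = Pphi.T @ null.residuals
    z = (V.T @ u) / np.sqrt(mu)
    rss0 = float(null.residuals @ null.residuals)
    resid2 = max(rss0 - float(z @ z), 0.0)
    return mu, z**2, resid2, rss0


def _lambda_grid(mu_max: float, n_grid: int = 128) -> np.ndarray:
    grid = np.concatenate([[0.0], np.logspace(-5, 5, n_grid) / mu_max])
    return grid


def _criterion(lam_grid, mu, z2, resid2, n_minus_q):
    """Profiled RLRT criterion, vectorized over draws and grid points.

    z2: (B, K) squared spherical contrasts; resid2: (B,); returns (B, L)
    values of (n-q) log(rss0 / D(lam)) - sum log(1 + lam mu).
    """
    shrink = 1.0 / (1.0 + lam_grid[None, :, None] * mu[None, None, :])  # (1,L,K)
    D = (z2[:, None, :] * shrink).sum(axis=2) + resid2[:, None]  # (B,L)
    rss0 = z2.sum(axis=1) + resid2  # (B,)
    pen = np.log1p(lam_grid[:, None] * mu[None, :]).sum(axis=1)  # (L,)
    return n_minus_q * (np.log(rss0)[:, None] - np.log(D)) - pen[None, :]


def _sup_criterion(mu, z2, resid2, n_minus_q, n_grid=128, refine_iter=40):
    """Supremum of the profiled criterion over lambda >= 0 per draw.

    Grid search over {0} and log-spaced ratios, refined by golden-section
    around the grid argmax (vectorized across draws).
    Returns (statistics, argmax lambdas).
    """
    grid = _lambda_grid(mu.max(), n_grid)
    vals = _criterion(grid, mu, z2, resid2, n_minus_q)  # (B, L)
    idx = np.argmax(vals, axis=1)
    B = z2.shape[0]
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, grid.size - 1)]
    # golden-section on the bracket (monotone-safe: bracket contains argmax)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)

    def f(lams):
        shrink = 1.0 / (1.0 + lams[:, None] * mu[None, :])
        D = (z2 * shrink).sum(axis=1) + resid2
        rss0 = z2.sum(axis=1) + resid2
        pen = np.log1p(lams[:, None] * mu[None, :]).sum(axis=1)
        return n_minus_q * (np.log(rss0) - np.log(D)) - pen

    fc, fd = f(c), f(d)
    for _ in range(refine_iter):
        go_left = fc > fd
        b = np.where(go_left, d, b)
        a = np.where(go_left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    lam_hat = 0.5 * (a + b)
    stat = np.maximum(np.maximum(f(lam_hat), vals[np.arange(B), idx]), 0.0)
    # keep the grid argmax when refinement did not improve on it
    lam_hat = np.where(f(lam_hat) >= vals[np.arange(B), idx], lam_hat, grid[idx])
    # boundary fits: snap numerical noise to the exact zero atom
    at_zero = stat <= ZERO_STAT_EPS
    stat[at_zero] = 0.0
    lam_hat[at_zero] = 0.0
    return stat, lam_hat


def fit_lmm_reml(y: np.ndarray, X: np.ndarray, phi: KernelFactor) -> LmmFit:
    """REML fit of the one-variance-component mixed model.

    The restricted likelihood is profiled to a 1-D search over the
    variance ratio lambda = sigma2_g / sigma2_e using the spectral
    decomposition of phi^T P phi.
    """
    null = fit_null_ols(y, X)
    mu, z2, resid2, rss0 = _spectral_setup(null, phi)
    nq = null.n - null.q
    stat, lam_hat = _sup_criterion(mu, z2[None, :], np.array([resid2]), nq)
    lam = float(lam_hat[0])
    D = float((z2 / (1.0 + lam * mu)).sum() + resid2)
    sigma2_e = D / nq
    sigma2_g = lam * sigma2_e
    # restricted log-likelihood up to an additive constant shared by the
    # null and alternative (the |X^T X| term)
    pen = float(np.log1p(lam * mu).sum())
    ll = -0.5 * (nq * (np.log(2 * np.pi * sigma2_e) + 1.0) + pen)
    return LmmFit(sigma2_e, sigma2_g, ll)


def rlrt_stat(y: np.ndarray, X: np.ndarray, phi: KernelFactor) -> float:
    """RLRT statistic: twice the restricted-log-likelihood gain of the
    alternative over the null, clipped at 0."""
    null = fit_null_ols(y, X)
    mu, z2, resid2, _ = _spectral_setup(null, phi)
    stat, _ = _sup_criterion(mu, z2[None, :], np.array([resid2]), null.n - null.q)
    return float(stat[0])


def sample_rlrt_null(
    phi: KernelFactor,
    X: np.ndarray,
    n_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Exact finite-sample draws from the RLRT null distribution.

    Under sigma2_g = 0, the spherical contrasts z_s are iid standard
    normal, so the profiled criterion depends on the data only through
    independent chi2_1 draws along the nonzero eigenvalues mu_s of
    phi^T P phi and a chi2_{n-q-K} remainder; the statistic is the
    supremum of the criterion over lambda >= 0.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    Q, _ = np.linalg.qr(X)
    Pphi = phi.matrix - Q @ (Q.T @ phi.matrix)
    mu = np.linalg.eigvalsh(Pphi.T @ Pphi)
    mu = np.sort(mu)[::-1]
    mu = mu[mu > EIG_REL_TOL * max(mu[0], 0.0)]
    if mu.size == 0:
        raise ValueError("kernel factor has no nonzero eigenvalues")
    K = mu.size
    rng = np.random.default_rng(seed)
    z2 = rng.chisquare(1.0, size=(n_samples, K))
    resid2 = rng.chisquare(n - q - K, size=n_samples) if n - q - K > 0 else np.zeros(n_samples)
    stat, _ = _sup_criterion(mu, z2, resid2, n - q)
    return stat


# ---------------------------------------------------------------------------
# pooled parametric null mixture


@dataclass
class NullMixture:
    """Parametric null law pi * chi2_0 + (1 - pi) * a * chi2_d."""

    pi: float
    a: float
    d: float
    n_statistics: int = 0
    group: str = ""
    degenerate: bool = False

    def sf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.where(
            x <= 0, 1.0, (1.0 - self.pi) * stats.chi2.sf(x / self.a, self.d)
        )
        return out


def fit_null_mixture(
    statistics: np.ndarray,
    top_fraction: float = 0.1,
    group: str = "",
    min_recommended: int = 1000,
) -> NullMixture:
    """Fit the pooled parametric RLRT null distribution.

    pi is the fraction of boundary zeros; (a, d) come from least squares
    between log empirical survival probabilities and the log model
    survival (1 - pi) * S_chi2_d(t / a) over the top-decile order
    statistics.
    """
    s = np.asarray(statistics, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("no statistics to fit")
    if s.size < min_recommended:
        import warnings

        warnings.warn(
            f"fitting null mixture on only {s.size} statistics", stacklevel=2
        )
    pi = float((s <= ZERO_STAT_EPS).mean())
    nz = s[s > ZERO_STAT_EPS]
    if nz.size == 0:
        return NullMixture(1.0, 1.0, 1.0, s.size, group, degenerate=True)

    k = max(int(np.ceil(top_fraction * s.size)), 3)
    k = min(k, s.size)
    top = np.sort(s)[::-1][:k]
    # empirical survival at the i-th largest of n statistics
    surv = (np.arange(1, k + 1) - 0.5) / s.size
    log_surv = np.log(surv)

    # moment start from the nonzero component (approximately a * chi2_d)
    m1, v1 = nz.mean(), max(nz.var(), 1e-12)
    d0 = max(2.0 * m1**2 / v1, 1e-2)
    a0 = m1 / d0

    def resid(theta):
        a, d = np.exp(theta)
        model = (1.0 - pi) * stats.chi2.sf(top / a, d)
        return np.log(np.maximum(model, 1e-320)) - log_surv

    sol = optimize.least_squares(resid, x0=np.log([a0, d0]), method="lm", max_nfev=2000)
    a, d = np.exp(sol.x)
    return NullMixture(pi, float(a), float(d), s.size, group)


def mixture_pvalue(stat: float, mixture: NullMixture, floor: float = P_FLOOR) -> float:
    """p-value from the fitted mixture: 1 at the boundary, otherwise the
    continuous-component tail, floored to keep logs finite."""
    if not (0.0 <= mixture.pi <= 1.0) or mixture.a <= 0 or mixture.d <= 0:
        raise ValueError("invalid mixture parameters")
    if stat < 0:
        raise ValueError("statistic must be nonnegative")
    if stat <= ZERO_STAT_EPS:
        return 1.0
    p = (1.0 - mixture.pi) * float(stats.chi2.sf(stat / mixture.a, mixture.d))
    return float(min(max(p, floor), 1.0))


# ---------------------------------------------------------------------------
# sLRT, Cauchy combination, genomic inflation


@dataclass
class GeneTestRecord:
    gene_id: str
    category: str
    test_type: str  # "gbvc" | "kernel"
    design: str = ""
    score_stat: float = np.nan
    score_p: float = np.nan
    rlrt: float | None = None
    null_stats: np.ndarray | None = None
    final_p: float | None = None
    lrt_triggered: bool = False
    combined_with_plof: bool = False
    conditioned: bool = False
    flags: set[str] = field(default_factory=set)
    n_variants: int = 0
    n_carriers: int = 0


def slrt(
    y: np.ndarray,
    X: np.ndarray,
    phi: KernelFactor,
    gene_id: str = "?",
    category: str = "?",
    test_type: str = "kernel",
    t: float = 0.1,
    n_null: int = 100,
    seed: int = 0,
    null: NullModel | None = None,
) -> GeneTestRecord:
    """Two-stage score/RLRT test for one gene and kernel design.

    Computes the score test; below the trigger threshold ``t`` it also
    computes the RLRT statistic and ``n_null`` exact null draws, leaving
    the final p-value to pooled-null finalization.  Otherwise the score
    p is final.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("trigger threshold t must lie in (0, 1)")
    if null is None:
        null = fit_null_ols(y, X)
    q_score, p_score = score_test(null, phi)
    rec = GeneTestRecord(
        gene_id, category, test_type, phi.design,
        score_stat=q_score, score_p=p_score, n_variants=phi.g,
    )
    if p_score < t:
        rec.lrt_triggered = True
        rec.rlrt = rlrt_stat(null.y, null.X, phi)
        rec.null_stats = sample_rlrt_null(phi, null.X, n_null, seed)
    else:
        rec.final_p = p_score
    return rec


def cauchy_combine(p_values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Cauchy combination test for dependent p-values.

    T = sum w_i tan((0.5 - p_i) pi); combined p = 0.5 - arctan(T) / pi,
    with the 1 / (pi T) tail form for numerical stability when any input
    (or the combination) is extreme.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p >= 1)):
        import warnings

        warnings.warn("p-values clipped into (0, 1) for Cauchy combination", stacklevel=2)
        p = np.clip(p, P_FLOOR, 1.0 - 1e-16)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        w = w / w.sum()
    small = p < 1e-15
    terms = np.empty_like(p)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    terms[small] = 1.0 / (p[small] * np.pi)
    T = float(w @ terms)
    if T > 1e15:
        return float(max(1.0 / (np.pi * T), P_FLOOR))
    return float(min(max(0.5 - np.arctan(T) / np.pi, P_FLOOR), 1.0))


CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi2_1 quantile of the observed
    p-values over the theoretical null median."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_1_MEDIAN)
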