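"""Kinship-corrected single-marker association for inbred strain panels.

The model is the standard variance-component mixed model

    y = mu + x beta + u + e,    Var(u) = sigma_g^2 K,   Var(e) = sigma_e^2 I,

where ``K`` is the identity-by-state (IBS) relatedness matrix of the panel.
Restricted maximum likelihood over the single ratio ``delta = sigma_e^2 /
sigma_g^2`` is made cheap by a one-time spectral decomposition of the
projected kinship (the "efficient mixed-model association" trick): the
restricted log-likelihood becomes a smooth scalar function of delta that is
maximised on a log grid plus local refinement.  Each marker is then tested
by generalized least squares under the fitted covariance with a standard
F-test of beta != 0.

Two scan modes are provided:

* ``exact``   -- re-estimate delta per SNP with the SNP in the fixed design
                 (the exact method; default);
* ``null_approx`` -- estimate delta once under the intercept-only model and
                 reuse it for every SNP (a documented, much faster
                 approximation whose accuracy is property-tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import AssociationRecord, GenotypeMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300          # keeps -log10(p) finite for perfect signals
DELTA_GRID_LO = 1e-5
DELTA_GRID_HI = 1e5
DELTA_GRID_POINTS = 100
_EIG_FLOOR = -1e-8        # tolerated numerical negativity of eigenvalues


@dataclass
class KinshipMatrix:
    """Strain-by-strain IBS relatedness; symmetric, unit diagonal."""

    strains: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.strains)
        if self.K.shape != (n, n):
            raise ValueError("K must be square over the strain list")
        if not np.allclose(self.K, self.K.T, atol=1e-12):
            raise ValueError("K must be symmetric")

    def subset(self, idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(idx)
        return self.K[np.ix_(idx, idx)]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    converged: bool
    at_boundary: bool = False


def compute_ibs_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """IBS kinship: K_ij = mean over shared nonmissing SNPs of 1 - |g_i - g_j|/2.

    A heterozygous dosage counts as half-matching against either homozygote.
    The diagonal is exactly 1.
    """
    if G.n_strains < 2 or G.n_snps < 1:
        raise ValueError("need at least 2 strains and 1 SNP for kinship")
    D = G.dosage
    n = G.n_strains
    present = ~np.isnan(D)
    Df = np.where(present, D, 0.0)
    P = present.astype(float)
    # sum over shared SNPs of |g_i - g_j| via an explicit strain loop: panels
    # have ~100 strains, so this is n x (n x m) and fast enough.
    K = np.empty((n, n), dtype=float)
    for i in range(n):
        diff = np.abs(Df[i] - Df)                    # (n, m); garbage where missing
        shared = present[i] & present                # (n, m)
        cnt = shared.sum(axis=1).astype(float)
        if np.any(cnt == 0):
            j = int(np.nonzero(cnt == 0)[0][0])
            raise ValueError(
                f"strains {G.strains[i]!r} and {G.strains[j]!r} share no "
                "nonmissing SNPs"
            )
        sim = np.where(shared, 1.0 - diff / 2.0, 0.0).sum(axis=1) / cnt
        K[i] = sim
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return KinshipMatrix(strains=list(G.strains), K=K)


def stabilize_kinship(K: np.ndarray) -> np.ndarray:
    """Add 1e-6 to the diagonal if the smallest eigenvalue is below 1e-8."""
    w = np.linalg.eigvalsh(K)
    if w.min() < 1e-8:
        K = K + 1e-6 * np.eye(K.shape[0])
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8:
            raise ValueError("kinship not positive semi-definite after stabilization")
    return K


# ------------------------------------------------------------------- REML


def _projected_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigen-spectrum of S K S with S the residual-maker of X, and the
    projections eta = U' y over the retained (n - p) directions."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    if np.linalg.matrix_rank(R) < p:
        raise ValueError("design matrix X is rank deficient")
    SKS = K - Q @ (Q.T @ K)
    SKS = SKS - (SKS @ Q) @ Q.T
    SKS = (SKS + SKS.T) / 2.0
    w, U = np.linalg.eigh(SKS)
    order = np.argsort(w)[::-1][: n - p]
    xi = w[order]
    if xi.min() < _EIG_FLOOR * max(1.0, abs(xi).max()):
        raise ValueError("projected kinship has substantially negative eigenvalues")
    xi = np.maximum(xi, 0.0)
    eta = U[:, order].T @ y
    return xi, eta


def _reml_loglik(log10_delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    delta = 10.0 ** log10_delta
    q = xi.size
    denom = xi + delta
    rss = float(np.sum(eta2 / denom))
    return 0.5 * (
        q * np.log(q / (2.0 * np.pi))
        - q
        - q * np.log(rss)
        - float(np.sum(np.log(denom)))
    )


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray,
             assume_stabilized: bool = False) -> VarianceComponents:
    """REML estimate of (sigma_g^2, sigma_e^2) for y = X b + u + e.

    The restricted log-likelihood is profiled down to the scalar
    delta = sigma_e^2 / sigma_g^2, evaluated on a 100-point log grid over
    [1e-5, 1e5], and every local maximum is refined by bounded scalar
    optimization to |d log10(delta)| < 1e-6.  Grid-end optima are returned
    with ``at_boundary=True`` (still ``converged``).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X row counts differ")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("y and X must be complete cases (drop missing first)")
    if K.shape != (n, n):
        raise ValueError("K must be n x n aligned with y")
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} fixed effects")
    if not assume_stabilized:
        K = stabilize_kinship(np.asarray(K, dtype=float))
    xi, eta = _projected_spectrum(y, X, K)
    eta2 = eta**2
    grid = np.linspace(np.log10(DELTA_GRID_LO), np.log10(DELTA_GRID_HI),
                       DELTA_GRID_POINTS)
    # vectorized grid evaluation of the profiled restricted log-likelihood
    q = xi.size
    denom = xi[:, None] + 10.0 ** grid[None, :]
    rss = (eta2[:, None] / denom).sum(axis=0)
    ll = 0.5 * (
        q * np.log(q / (2.0 * np.pi)) - q
        - q * np.log(rss)
        - np.log(denom).sum(axis=0)
    )
    best_x = grid[int(np.argmax(ll))]
    best_ll = ll.max()
    at_boundary = int(np.argmax(ll)) in (0, grid.size - 1)
    # refine every local maximum bracket, including the grid ends
    for i in range(grid.size):
        lo = ll[i - 1] if i > 0 else -np.inf
        hi = ll[i + 1] if i < grid.size - 1 else -np.inf
        if ll[i] >= lo and ll[i] >= hi:
            res = optimize.minimize_scalar(
                lambda g: -_reml_loglik(g, xi, eta2),
                bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > best_ll:
                best_ll = -res.fun
                best_x = float(res.x)
                at_boundary = i in (0, grid.size - 1)
    delta = 10.0**best_x
    q = xi.size
    sigma_g2 = float(np.sum(eta2 / (xi + delta))) / q
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=best_ll,
        converged=True,
        at_boundary=at_boundary,
    )


def reml_loglik_at(delta: float, y: np.ndarray, X: np.ndarray,
                   K: np.ndarray) -> float:
    """Restricted log-likelihood at an arbitrary delta (for diagnostics and
    brute-force checks)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = stabilize_kinship(np.asarray(K, dtype=float))
    xi, eta = _projected_spectrum(y, X, K)
    return _reml_loglik(np.log10(delta), xi, eta**2)


# -------------------------------------------------------------------- GLS


def _gls_ftest(y: np.ndarray, X: np.ndarray, Kw: np.ndarray, KU: np.ndarray,
               delta: float):
    """GLS fit of y on X under Sigma propto (K + delta I), given eigen(K).

    Returns (beta_snp, F, p, residuals) where the tested coefficient is the
    last column of X; F has (1, n - p) degrees of freedom.
    """
    n, p = X.shape
    scale = 1.0 / np.sqrt(Kw + delta)
    yt = (KU.T @ y) * scale
    Xt = (KU.T @ X) * scale[:, None]
    XtX = Xt.T @ Xt
    Xty = Xt.T @ yt
    beta = np.linalg.solve(XtX, Xty)
    resid_t = yt - Xt @ beta
    rss = float(resid_t @ resid_t)
    df = n - p
    XtX_inv = np.linalg.inv(XtX)
    se2 = rss / df * XtX_inv[-1, -1]
    if se2 <= 0:
        f = np.inf
    else:
        f = beta[-1] ** 2 / se2
    pval = float(stats.f.sf(f, 1, df))
    pval = max(pval, P_FLOOR)
    resid = y - X @ beta     # fixed-effect residuals on the original scale
    return float(beta[-1]), float(f), pval, resid, beta


def association_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    mode: Literal["exact", "null_approx"] = "exact",
    phenotype_id: str = "phenotype",
) -> list[AssociationRecord]:
    """Single-marker mixed-model scan of one phenotype over all SNPs.

    ``y`` is aligned with ``K.strains`` (and ``G.strains`` must equal
    ``K.strains``).  Strains with missing phenotype are dropped once;
    strains with a missing genotype are dropped per SNP (casewise
    deletion).  SNPs monomorphic after deletion are skipped with a log
    entry.  MAF filtering is the caller's responsibility.
    """
    if list(G.strains) != list(K.strains):
        raise ValueError("genotype and kinship strain lists differ")
    y = np.asarray(y, dtype=float)
    if y.shape != (G.n_strains,):
        raise ValueError("y must align with the strain list")
    keep = ~np.isnan(y)
    idx_all = np.nonzero(keep)[0]
    if idx_all.size < 3:
        raise ValueError("fewer than 3 strains with nonmissing phenotype")
    y0 = y[idx_all]
    K0 = stabilize_kinship(K.subset(idx_all))
    Kw0, KU0 = np.linalg.eigh(K0)
    Kw0 = np.maximum(Kw0, 0.0)
    delta0 = None
    if mode == "null_approx":
        delta0 = reml_fit(y0, np.ones((y0.size, 1)), K0).delta
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    records: list[AssociationRecord] = []
    dosage0 = G.dosage[idx_all, :]
    for j in range(G.n_snps):
        g = dosage0[:, j]
        present = ~np.isnan(g)
        if present.all():
            yj, gj, Kj = y0, g, None
            Kwj, KUj = Kw0, KU0
        else:
            if present.sum() < 3:
                logger.info("SNP %s skipped: <3 strains after deletion",
                            G.snp_ids[j])
                continue
            yj = y0[present]
            gj = g[present]
            Kj = stabilize_kinship(K0[np.ix_(present.nonzero()[0],
                                             present.nonzero()[0])])
            Kwj, KUj = np.linalg.eigh(Kj)
            Kwj = np.maximum(Kwj, 0.0)
        if np.all(gj == gj[0]):
            logger.info("SNP %s skipped: monomorphic after casewise deletion",
                        G.snp_ids[j])
            continue
        X = np.column_stack([np.ones_like(yj), gj])
        if mode == "exact":
            Ksub = K0 if Kj is None else Kj
            delta = reml_fit(yj, X, Ksub, assume_stabilized=True).delta
        else:
            delta = delta0
        beta, f, pval, _, _ = _gls_ftest(yj, X, Kwj, KUj, delta)
        records.append(
            AssociationRecord(
                phenotype_id=phenotype_id,
                snp_id=str(G.snp_ids[j]),
                chrom=str(G.chrom[j]),
                pos=int(G.pos[j]),
                beta=beta,
                f_stat=f,
                p_value=pval,
                n_used=int(yj.size),
            )
        )
    return records


def variance_explained(y: np.ndarray, g: np.ndarray, K: np.ndarray,
                       delta: Optional[float] = None) -> float:
    """Fraction of phenotype variance explained by one marker.

    Defined as 1 - var(residuals)/var(y), with residuals from the fixed
    effects only (intercept + SNP, coefficients fitted by GLS under the
    mixed-model covariance).  May be negative for null markers; the value
    is returned unclamped.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    present = ~(np.isnan(y) | np.isnan(g))
    y, g = y[present], g[present]
    idx = np.nonzero(present)[0]
    Kfull = np.asarray(K, dtype=float)
    Ksub = stabilize_kinship(Kfull[np.ix_(idx, idx)])
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    X = np.column_stack([np.ones_like(y), g])
    if delta is None:
        delta = reml_fit(y, X, Ksub).delta
    Kw, KU = np.linalg.eigh(Ksub)
    Kw = np.maximum(Kw, 0.0)
    _, _, _, resid, _ = _gls_ftest(y, X, Kw, KU, delta)
    return 1.0 - float(np.var(resid) / np.var(y))


def genomic_inflation(pvalues: Sequence[float]) -> float:
    """Genomic-control lambda: median chi-square implied by the p-values over
    the null median (0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def ols_scan(y: np.ndarray, G: GenotypeMatrix,
             phenotype_id: str = "phenotype") -> list[AssociationRecord]:
    """Naive per-SNP OLS F-test (no kinship correction); the uncorrected
    baseline the mixed model is calibrated against."""
    I = KinshipMatrix(strains=list(G.strains), K=np.eye(G.n_strains))
    return association_scan(y, G, I, mode="null_approx",
                            phenotype_id=phenotype_id)
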