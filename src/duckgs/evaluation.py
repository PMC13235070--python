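"""Single-kernel animal model: REML variance components and BLUP EBVs.

Model:  y* = 1*mu + u + e,  u ~ N(0, sigma2_g * K),  e ~ N(0, sigma2_e * I)

with K either the pedigree numerator matrix A or the genomic matrix G.
The restricted likelihood is maximized by the eigendecomposition trick:
with K = U diag(d) U', rotating y* and the intercept by U' makes the
covariance diagonal, V = sigma2_p * (h2 * d + (1 - h2)).  The residual
variance profile is then concentrated out analytically, leaving a 1-D
bracketed maximization over h2 in [1e-4, 0.9999].  This is exact (no
AI/EM iterations) and costs one O(n^3) factorization per kernel.

Breeding values are the conditional means

    u_hat = sigma2_g * K[:, train] * V_train^{-1} * (y* - mu_hat),

which coincide with Henderson's mixed-model-equation solution and extend
to phenotype-masked individuals through their relationship-matrix rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .relatedness import RelationshipMatrix

H2_BOUNDS = (1e-4, 0.9999)
H2_TOL = 1e-6


class KernelEigen:
    """Cached eigendecomposition of a relationship matrix restricted to an
    id set; reusable across traits sharing the same phenotyped set."""

    def __init__(self, K: RelationshipMatrix, ids=None):
        sub = K.subset(ids) if ids is not None else K
        d, U = eigh(sub.values)
        if d[0] < -1e-6:
            raise ValueError(
                f"{K.kind}-matrix is not positive semi-definite "
                f"(min eigenvalue {d[0]:.3e}); regularize it first")
        self.ids = sub.ids
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.kind = K.kind


@dataclass
class VarianceComponents:
    """REML estimates for one trait and one relationship matrix."""

    sigma2_genetic: float
    sigma2_residual: float
    h2: float
    h2_se: float
    loglik: float
    matrix_kind: str
    converged: bool
    boundary: bool = False


def _align(y: pd.Series, eigen: KernelEigen) -> np.ndarray:
    y = y.dropna()
    if set(y.index) != set(eigen.ids):
        raise ValueError("phenotyped ids do not match the kernel id set")
    return y.reindex(eigen.ids).to_numpy(dtype=np.float64)


def reml_loglik(y: pd.Series, eigen: KernelEigen,
                sigma2_g: float, sigma2_e: float) -> float:
    """REML log-likelihood kernel at fixed variance components:
    -0.5 * [log|V| + log|X'V^{-1}X| + y'Py] with X the intercept column
    (additive constants omitted)."""
    yv = _align(y, eigen)
    yt = eigen.U.T @ yv
    xt = eigen.U.T @ np.ones_like(yv)
    w = sigma2_g * eigen.d + sigma2_e
    if np.any(w <= 0):
        return -np.inf
    xtvx = float(np.sum(xt * xt / w))
    beta = float(np.sum(xt * yt / w)) / xtvx
    r = yt - xt * beta
    ypy = float(np.sum(r * r / w))
    return -0.5 * (float(np.sum(np.log(w))) + np.log(xtvx) + ypy)


def _profile_loglik(h2, yt, xt, d):
    """Profile REML log-likelihood over h2 with sigma2_p concentrated out."""
    n = len(yt)
    w = h2 * d + (1.0 - h2)
    xtvx = float(np.sum(xt * xt / w))
    beta = float(np.sum(xt * yt / w)) / xtvx
    r = yt - xt * beta
    quad = float(np.sum(r * r / w))
    s2p = quad / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(s2p) + float(np.sum(np.log(w)))
                 + np.log(xtvx) + (n - 1))
    return ll, s2p


def fit_reml(y_star: pd.Series, K: RelationshipMatrix | None = None,
             eigen: KernelEigen | None = None,
             bounds: tuple = H2_BOUNDS, tol: float = H2_TOL) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_e, h2) by exact profile REML.

    Parameters
    ----------
    y_star
        Adjusted phenotypes indexed by individual id (phenotyped set).
    K
        Relationship matrix covering at least the phenotyped ids.
    eigen
        Optional precomputed :class:`KernelEigen` for the phenotyped set
        (saves the O(n^3) factorization when fitting several traits on
        the same kernel).

    The heritability standard error comes from the numerical curvature of
    the profile REML log-likelihood at the optimum (observed information
    on the h2 scale).
    """
    if eigen is None:
        if K is None:
            raise ValueError("provide a relationship matrix or its eigendecomposition")
        eigen = KernelEigen(K, ids=y_star.dropna().index.to_numpy())
    yv = _align(y_star, eigen)
    n = len(yv)
    if n < 30:
        raise ValueError(f"need at least 30 phenotyped individuals, got {n}")
    yt = eigen.U.T @ yv
    xt = eigen.U.T @ np.ones(n)

    res = minimize_scalar(lambda h: -_profile_loglik(h, yt, xt, eigen.d)[0],
                          bounds=bounds, method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    ll, s2p = _profile_loglik(h2, yt, xt, eigen.d)
    boundary = (h2 - bounds[0] < 1e-3) or (bounds[1] - h2 < 1e-3)

    # observed information on the h2 scale by central differences
    step = 1e-3
    lo = max(bounds[0], h2 - step)
    hi = min(bounds[1], h2 + step)
    f0 = _profile_loglik(h2, yt, xt, eigen.d)[0]
    f_lo = _profile_loglik(lo, yt, xt, eigen.d)[0]
    f_hi = _profile_loglik(hi, yt, xt, eigen.d)[0]
    # non-uniform central second difference
    h1, h2_ = h2 - lo, hi - h2
    curv = 2.0 * (h1 * f_hi + h2_ * f_lo - (h1 + h2_) * f0) / (h1 * h2_ * (h1 + h2_))
    h2_se = float(np.sqrt(-1.0 / curv)) if curv < 0 else np.nan

    return VarianceComponents(
        sigma2_genetic=h2 * s2p, sigma2_residual=(1.0 - h2) * s2p,
        h2=h2, h2_se=h2_se, loglik=float(ll),
        matrix_kind=eigen.kind, converged=bool(res.success), boundary=boundary)


def variance_component_table(vc_by_trait: dict) -> pd.DataFrame:
    """Tabulate marker vs pedigree heritabilities per trait.

    ``vc_by_trait`` maps trait -> {"G": VarianceComponents, "A": ...}
    (either kind may be absent).  Columns: h2_G, se_G, h2_A, se_A and the
    ratio h2_G / h2_A.
    """
    rows = []
    for trait, kinds in vc_by_trait.items():
        g, a = kinds.get("G"), kinds.get("A")
        rows.append({
            "trait": trait,
            "h2_G": g.h2 if g else np.nan, "se_G": g.h2_se if g else np.nan,
            "h2_A": a.h2 if a else np.nan, "se_A": a.h2_se if a else np.nan,
            "ratio": (g.h2 / a.h2) if (g and a and a.h2 > 0) else np.nan})
    return pd.DataFrame(rows)


@dataclass
class EBVResult:
    """BLUP breeding values for every individual covered by the kernel."""

    ebv: pd.Series               # indexed by id, trait units
    phenotyped: pd.Series        # boolean, same index
    matrix_kind: str
    mu: float


def predict_ebv(y_star_training: pd.Series, K_full: RelationshipMatrix,
                vc: VarianceComponents) -> EBVResult:
    """BLUP of breeding values for all individuals in ``K_full``.

    Training individuals contribute phenotypes; phenotype-masked
    individuals are predicted through their relationship-matrix rows.
    ``vc`` should come from the training fit with the same matrix kind.
    """
    y = y_star_training.dropna()
    idx_t = K_full.index_of(y.index.to_numpy())
    yv = y.to_numpy(dtype=np.float64)
    n = len(yv)
    Ktt = K_full.values[np.ix_(idx_t, idx_t)]
    V = vc.sigma2_genetic * Ktt + vc.sigma2_residual * np.eye(n)
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"training covariance matrix not positive definite "
            f"({vc.matrix_kind}-matrix); apply ridge regularization") from exc
    piv = np.diag(cf[0])
    if piv.min() <= 0 or (piv.min() / piv.max()) ** 2 < 1e-10:
        raise ValueError(
            f"training covariance matrix is numerically singular "
            f"({vc.matrix_kind}-matrix); apply ridge regularization")
    ones = np.ones(n)
    vi_y = cho_solve(cf, yv)
    vi_1 = cho_solve(cf, ones)
    mu = float(ones @ vi_y) / float(ones @ vi_1)
    alpha = cho_solve(cf, yv - mu * ones)
    ebv = vc.sigma2_genetic * (K_full.values[:, idx_t] @ alpha)
    phenotyped = pd.Series(False, index=K_full.ids)
    phenotyped.loc[y.index] = True
    return EBVResult(ebv=pd.Series(ebv, index=K_full.ids),
                     phenotyped=phenotyped, matrix_kind=vc.matrix_kind, mu=mu)
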