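"""Pedigree (A) and genomic (G) relationship matrices, plus genotype PCA.

The numerator relationship matrix A is built with the tabular method over
a generation-sorted pedigree; its diagonal is 1 + F (the inbreeding
coefficient).  The genomic relationship matrix follows VanRaden's first
method, G = ZZ' / (2 * sum_j p_j (1 - p_j)), with Z the allele-frequency
centered dosage matrix.  A small ridge can be added to the diagonal when
a matrix is numerically singular; this is the only conditioning device
used (no blending with A, no weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.decomposition import PCA as _PCA

from .containers import GenotypeMatrix
from .simulate import validate_pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix aligned to an ordered id index."""

    ids: np.ndarray
    values: np.ndarray
    kind: str                    # "A" (pedigree) or "G" (markers)
    ridge_applied: float = 0.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimensions do not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        missing = [v for v in np.asarray(ids) if v not in lookup]
        if missing:
            raise KeyError(f"ids absent from {self.kind}-matrix: {missing[:10]}")
        return np.array([lookup[v] for v in np.asarray(ids)], dtype=np.intp)

    def subset(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(np.asarray(ids), self.values[np.ix_(idx, idx)],
                                  self.kind, self.ridge_applied)

    def to_long_frame(self) -> pd.DataFrame:
        """Lower triangle (incl. diagonal) in long ``id_1 id_2 value`` form."""
        i, j = np.tril_indices(len(self.ids))
        return pd.DataFrame({"id_1": self.ids[i], "id_2": self.ids[j],
                             "value": self.values[i, j]})


def build_a_matrix(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Processing individuals parents-before-offspring (sorted by
    generation):  A_jj = 1 + 0.5 * A_sire(j),dam(j)  and for i != j
    A_ij = 0.5 * (A_i,sire(j) + A_i,dam(j)), with unknown parents
    contributing zero.  Output rows follow the input pedigree order.
    """
    validate_pedigree(ped)
    n = len(ped)
    order = np.argsort(ped["generation"].to_numpy(), kind="stable")
    ids_sorted = ped["id"].to_numpy()[order]
    row_of = {v: i for i, v in enumerate(ids_sorted)}
    sires = np.array([row_of.get(s, -1) for s in ped["sire"].to_numpy()[order]])
    dams = np.array([row_of.get(d, -1) for d in ped["dam"].to_numpy()[order]])

    A = np.zeros((n, n))
    zero = np.zeros(n)
    for j in range(n):
        s, d = sires[j], dams[j]
        rs = A[s] if s >= 0 else zero
        rd = A[d] if d >= 0 else zero
        row = 0.5 * (rs + rd)
        A[j, :] = row
        A[:, j] = row
        f = 0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[j, j] = 1.0 + f

    inv = np.argsort(order)
    return RelationshipMatrix(ped["id"].to_numpy(), A[np.ix_(inv, inv)], kind="A")


def build_g_matrix(geno: GenotypeMatrix,
                   freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    ``Z = M - 2P`` with M the dosage matrix (missing calls mean-imputed
    per SNP) and P the row of allele frequencies; then
    ``G = ZZ' / (2 * sum_j p_j (1 - p_j))``.  By default the frequencies
    are observed in the supplied (full analysis) set.
    """
    M = geno.dosages.astype(np.float64)
    obs = geno.called_mask()
    p = np.asarray(freqs, dtype=np.float64) if freqs is not None \
        else geno.allele_frequencies()
    if len(p) != geno.n_snps:
        raise ValueError("frequency vector length does not match SNP count")
    p = np.nan_to_num(p, nan=0.0)
    M = np.where(obs, M, 2.0 * p[None, :])
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # exact symmetry against rounding
    return RelationshipMatrix(geno.ids, G, kind="G")


def regularize(K: RelationshipMatrix, ridge: float = 0.01,
               min_eigenvalue: float = 1e-8) -> RelationshipMatrix:
    """Add ``ridge`` to the diagonal iff the smallest eigenvalue is below
    ``min_eigenvalue``; otherwise return the matrix unchanged."""
    lam = eigh(K.values, eigvals_only=True, subset_by_index=(0, 0))[0]
    if lam >= min_eigenvalue:
        return K
    if ridge > 0:
        warnings.warn(
            f"{K.kind}-matrix smallest eigenvalue {lam:.3e} < {min_eigenvalue:g}; "
            f"adding ridge {ridge} to the diagonal", stacklevel=2)
    return RelationshipMatrix(K.ids, K.values + ridge * np.eye(len(K.ids)),
                              K.kind, ridge_applied=K.ridge_applied + ridge)


@dataclass
class PCAResult:
    """Principal components of the (centered) dosage matrix."""

    component_scores: np.ndarray       # individuals x k
    variance_explained: np.ndarray     # percent of total, non-increasing
    ids: np.ndarray = field(default=None)
    degenerate: bool = False


def pca(geno: GenotypeMatrix, k: int = 10, standardize: bool = False) -> PCAResult:
    """PCA of the column-centered dosage matrix (visualization use).

    With ``standardize=True`` columns are additionally scaled by
    ``sqrt(2 p (1 - p))``.  Missing calls are mean-imputed.  ``k`` is
    truncated (with a warning) if it exceeds the data rank bound.
    """
    if geno.n_individuals < 2 or geno.n_snps < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 SNPs")
    M = geno.dosages.astype(np.float64)
    obs = geno.called_mask()
    p = np.nan_to_num(geno.allele_frequencies(), nan=0.0)
    M = np.where(obs, M, 2.0 * p[None, :])
    X = M - M.mean(axis=0, keepdims=True)
    if standardize:
        scale = np.sqrt(2.0 * p * (1.0 - p))
        X = np.divide(X, scale[None, :], out=np.zeros_like(X),
                      where=scale[None, :] > 0)
    total_var = X.var(axis=0, ddof=1).sum()
    if total_var == 0.0:
        return PCAResult(np.zeros((geno.n_individuals, 1)), np.array([0.0]),
                         ids=geno.ids, degenerate=True)
    kmax = min(geno.n_individuals - 1, geno.n_snps)
    if k > kmax:
        warnings.warn(f"k={k} exceeds rank bound; truncating to {kmax}",
                      stacklevel=2)
        k = kmax
    fit = _PCA(n_components=k, svd_solver="full").fit(X)
    scores = fit.transform(X)
    return PCAResult(scores, 100.0 * fit.explained_variance_ratio_, ids=geno.ids)
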