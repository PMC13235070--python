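"""Relationship matrices: tabular A vs recursive oracle, VanRaden G, PCA."""

import functools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

import duckgs as dg
from duckgs.containers import GenotypeMatrix
from duckgs.simulate import UNKNOWN

from conftest import toy_pedigree


def recursive_a_oracle(ped: pd.DataFrame) -> np.ndarray:
    """Slow textbook recursion for the numerator relationship matrix."""
    ids = ped["id"].to_numpy()
    gen = dict(zip(ped["id"], ped["generation"]))
    par = {r.id: (r.sire, r.dam) for r in ped.itertuples()}

    @functools.lru_cache(maxsize=None)
    def a(i, j):
        if i == j:
            s, d = par[i]
            f = 0.5 * a(s, d) if (s != UNKNOWN and d != UNKNOWN) else 0.0
            return 1.0 + f
        if gen[i] > gen[j]:
            i, j = j, i
        s, d = par[j]
        out = 0.0
        if s != UNKNOWN:
            out += 0.5 * a(i, s)
        if d != UNKNOWN:
            out += 0.5 * a(i, d)
        return out

    n = len(ids)
    A = np.empty((n, n))
    for x in range(n):
        for y in range(x, n):
            A[x, y] = A[y, x] = a(ids[x], ids[y])
    return A


def _geno(ids, dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    return GenotypeMatrix(np.asarray(ids), dosages, np.ones(m, dtype=int),
                          np.arange(1, m + 1),
                          np.array([f"s{j}" for j in range(m)], dtype=object))


# ---------------------------------------------------------------------------
# A-matrix
# ---------------------------------------------------------------------------

def test_unrelated_founders_give_identity():
    ped = toy_pedigree([(i, 0, 0, 1, "M") for i in range(1, 6)])
    A = dg.build_a_matrix(ped)
    assert np.array_equal(A.values, np.eye(5))


def test_textbook_relationships():
    # 1,2 founders; 3,4 their full sibs; 5 offspring of 1 with founder 6
    ped = toy_pedigree([
        (1, 0, 0, 1, "M"), (2, 0, 0, 1, "F"), (6, 0, 0, 1, "F"),
        (3, 1, 2, 2, "M"), (4, 1, 2, 2, "F"), (5, 1, 6, 2, "M"),
    ])
    A = dg.build_a_matrix(ped)
    i = {v: k for k, v in enumerate(A.ids)}
    assert A.values[i[1], i[3]] == pytest.approx(0.5)    # parent-offspring
    assert A.values[i[3], i[4]] == pytest.approx(0.5)    # full sibs
    assert A.values[i[3], i[5]] == pytest.approx(0.25)   # half sibs


def test_full_sib_mating_inbreeding():
    ped = toy_pedigree([
        (1, 0, 0, 1, "M"), (2, 0, 0, 1, "F"),
        (3, 1, 2, 2, "M"), (4, 1, 2, 2, "F"),
        (5, 3, 4, 3, "M"),
    ])
    A = dg.build_a_matrix(ped)
    i = {v: k for k, v in enumerate(A.ids)}
    assert A.values[i[5], i[5]] == pytest.approx(1.25)   # F = 0.25


def test_tabular_method_equals_recursive_oracle():
    for seed in (1, 2, 3):
        cfg = dg.SimConfig(n_generations=4, gen_sizes=(15, 15, 15, 15),
                           n_lines=1, n_chromosomes=1, snps_per_chromosome=5,
                           sires_per_pen=2, dams_per_pen=3, seed=seed)
        ped = dg.simulate_pedigree(cfg)
        A = dg.build_a_matrix(ped)
        assert np.allclose(A.values, recursive_a_oracle(ped), atol=1e-12)


def test_a_matrix_rejects_inconsistent_pedigree():
    bad = toy_pedigree([(1, 2, 3, 1, "M"), (2, 0, 0, 1, "M"), (3, 0, 0, 1, "F")])
    with pytest.raises(ValueError):
        dg.build_a_matrix(bad)


# ---------------------------------------------------------------------------
# G-matrix
# ---------------------------------------------------------------------------

def test_vanraden_hand_example():
    """Two individuals, one SNP with p = 0.5 and dosages (2, 0):
    Z = (1, -1), denominator 2 * 0.25 = 0.5, so G = [[2,-2],[-2,2]]."""
    geno = _geno([1, 2], [[2], [0]])
    G = dg.build_g_matrix(geno, freqs=np.array([0.5]))
    assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])


def test_duplicated_individuals_have_identical_rows():
    rng = np.random.default_rng(0)
    dos = rng.integers(0, 3, (10, 40))
    dos[1] = dos[0]
    G = dg.build_g_matrix(_geno(np.arange(10), dos))
    assert np.allclose(G.values[0], G.values[1])
    assert np.allclose(G.values[:, 0], G.values[:, 1])


def test_monomorphic_panel_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        dg.build_g_matrix(_geno([1, 2], [[2, 2], [2, 2]]))


def test_centered_columns_sum_to_zero():
    """With observed frequencies, every column of Z = M - 2P sums to 0,
    so the rows and columns of G each sum to zero."""
    rng = np.random.default_rng(5)
    dos = rng.integers(0, 3, (30, 50))
    G = dg.build_g_matrix(_geno(np.arange(30), dos))
    assert np.allclose(G.values.sum(axis=0), 0.0, atol=1e-9)


def test_unrelated_diagonal_near_one():
    cfg = dg.SimConfig(n_generations=1, gen_sizes=(1000,), n_lines=1,
                       n_chromosomes=2, snps_per_chromosome=250, fst=0.0,
                       seed=9)
    ped = dg.simulate_pedigree(cfg)
    geno, freqs = dg.simulate_genotypes(ped, cfg)
    G = dg.build_g_matrix(geno, freqs=freqs["A"])
    assert abs(G.values.diagonal().mean() - 1.0) < 0.03


def test_parent_offspring_marker_relationship_near_half():
    cfg = dg.SimConfig(n_generations=2, gen_sizes=(500, 500), n_lines=1,
                       n_chromosomes=3, snps_per_chromosome=80, seed=17)
    ped = dg.simulate_pedigree(cfg)
    geno, _ = dg.simulate_genotypes(ped, cfg)
    G = dg.build_g_matrix(geno)
    row = {v: i for i, v in enumerate(G.ids)}
    off = ped[ped["generation"] == 2]
    vals = [G.values[row[r.id], row[r.sire]] for r in off.itertuples()]
    assert abs(np.mean(vals) - 0.5) < 0.05


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def test_regularize_leaves_positive_definite_untouched():
    K = dg.RelationshipMatrix(np.arange(4), np.eye(4), "A")
    out = dg.regularize(K)
    assert out.ridge_applied == 0.0
    assert np.array_equal(out.values, np.eye(4))


def test_regularize_shifts_singular_spectrum():
    rng = np.random.default_rng(1)
    dos = rng.integers(0, 3, (8, 30))
    dos[1] = dos[0]                       # duplicate -> singular G
    K = dg.build_g_matrix(_geno(np.arange(8), dos))
    with pytest.warns(UserWarning, match="ridge"):
        out = dg.regularize(K, ridge=0.05)
    lam = np.linalg.eigvalsh(out.values).min()
    assert lam >= 0.05 - 1e-8
    assert out.ridge_applied == 0.05


def test_unregularized_singular_matrix_breaks_the_solver():
    rng = np.random.default_rng(2)
    dos = rng.integers(0, 3, (40, 60))
    dos[1] = dos[0]
    K = dg.build_g_matrix(_geno(np.arange(40), dos))
    y = pd.Series(rng.normal(0, 1, 40), index=K.ids)
    vc = dg.VarianceComponents(1.0, 1e-12, 1.0, 0.0, 0.0, "G", True)
    with pytest.raises((ValueError, np.linalg.LinAlgError)):
        dg.predict_ebv(y, K, vc)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_identical_individuals_degenerate():
    geno = _geno([1, 2, 3], [[1, 2, 0]] * 3)
    res = dg.pca(geno, k=2)
    assert res.degenerate


def test_pca_variance_explained_monotone(two_line_data):
    _, _, geno = two_line_data
    res = dg.pca(geno, k=5)
    v = res.variance_explained
    assert (np.diff(v) <= 1e-9).all()
    assert v.sum() <= 100.0 + 1e-9


def test_pca_separates_diverged_lines(two_line_data):
    _, ped, geno = two_line_data
    res = dg.pca(geno, k=2)
    labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
        res.component_scores[:, :1])
    truth = (ped["line"] == "A").to_numpy().astype(int)
    agree = max((labels == truth).mean(), (labels != truth).mean())
    assert agree == 1.0


def test_pca_truncates_excess_components():
    rng = np.random.default_rng(4)
    geno = _geno(np.arange(5), rng.integers(0, 3, (5, 20)))
    with pytest.warns(UserWarning, match="rank"):
        res = dg.pca(geno, k=10)
    assert res.component_scores.shape[1] == 4
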