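"""Simulator: pedigree structure, gene dropping, trait generation, masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import duckgs as dg
from duckgs.simulate import UNKNOWN


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def test_single_generation_is_all_founders():
    ped = dg.simulate_pedigree(dg.SimConfig(
        n_generations=1, gen_sizes=(10,), n_lines=1,
        n_chromosomes=1, snps_per_chromosome=5))
    assert len(ped) == 10
    assert (ped["sire"] == UNKNOWN).all() and (ped["dam"] == UNKNOWN).all()


def test_line_a_shaped_pedigree_counts():
    """Line-A-shaped program: 9,579 training birds in generations 1-5
    predicting a 4,066-bird final generation."""
    ped = dg.simulate_pedigree(dg.SimConfig.line_a())
    assert len(ped) == 13645
    assert (ped["generation"] == 6).sum() == 4066
    assert (ped["generation"] < 6).sum() == 9579


def test_parents_come_from_previous_generation(small_data):
    ped, _, _ = small_data
    gen_of = dict(zip(ped["id"], ped["generation"]))
    nonfounders = ped[ped["sire"] != UNKNOWN]
    for _, row in nonfounders.iterrows():
        assert gen_of[row["sire"]] == row["generation"] - 1
        assert gen_of[row["dam"]] == row["generation"] - 1
    dg.validate_pedigree(ped)  # acyclicity + generation monotonicity


def test_sexes_roughly_balanced(small_data):
    ped, _, _ = small_data
    frac_m = (ped["sex"] == "M").mean()
    assert 0.45 < frac_m < 0.55


def test_single_sex_generation_cannot_breed():
    cfg = dg.SimConfig(n_generations=2, gen_sizes=(1, 5), n_lines=1,
                       n_chromosomes=1, snps_per_chromosome=5)
    with pytest.raises(ValueError, match="lacks at least one"):
        dg.simulate_pedigree(cfg)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(n_gen=st.integers(1, 4),
       size=st.integers(4, 20),
       seed=st.integers(0, 10_000))
def test_pedigree_invariants_hold_for_random_configs(n_gen, size, seed):
    cfg = dg.SimConfig(n_generations=n_gen, gen_sizes=(size,) * n_gen,
                       n_lines=2, n_chromosomes=1, snps_per_chromosome=5,
                       seed=seed)
    ped = dg.simulate_pedigree(cfg)
    dg.validate_pedigree(ped)
    assert ped.groupby("line").size().eq(n_gen * size).all()


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def test_fixed_allele_propagates(small_config):
    ped = dg.simulate_pedigree(small_config)
    m = small_config.n_chromosomes * small_config.snps_per_chromosome
    freqs = {"A": np.ones(m)}
    geno, _ = dg.simulate_genotypes(ped, small_config, founder_freqs=freqs)
    assert (geno.dosages == 2).all()


def test_gamete_is_copy_of_a_parental_allele(small_config):
    """Allele-count conservation per meiosis: wherever a parent is
    homozygous, the transmitted allele must equal the parent's allele."""
    ped = dg.simulate_pedigree(small_config)
    geno, _, hap = dg.simulate_genotypes(ped, small_config,
                                         return_haplotypes=True)
    row_of = {v: i for i, v in enumerate(ped["id"])}
    nonf = ped[ped["sire"] != UNKNOWN]
    for _, row in nonf.head(20).iterrows():
        i = row_of[row["id"]]
        for parent, gamete in ((row["sire"], hap[i, 0]), (row["dam"], hap[i, 1])):
            p = row_of[parent]
            hom = hap[p, 0] == hap[p, 1]
            assert np.array_equal(gamete[hom], hap[p, 0][hom])
    assert np.array_equal(geno.dosages, hap.sum(axis=1))


def test_offspring_regression_on_parent_dosage_is_half():
    """Mendelian expectation: regressing offspring dosage on one parent's
    dosage gives slope 1/2 under random mating."""
    cfg = dg.SimConfig(n_generations=2, gen_sizes=(500, 500), n_lines=1,
                       n_chromosomes=3, snps_per_chromosome=25, seed=21)
    ped = dg.simulate_pedigree(cfg)
    geno, _ = dg.simulate_genotypes(ped, cfg)
    row_of = {v: i for i, v in enumerate(ped["id"])}
    off = ped[ped["generation"] == 2]
    oi = [row_of[i] for i in off["id"]]
    si = [row_of[s] for s in off["sire"]]
    o = geno.dosages[oi].astype(float)
    s = geno.dosages[si].astype(float)
    slopes = []
    for j in range(geno.n_snps):
        vs = s[:, j].var()
        if vs > 0:
            slopes.append(np.cov(o[:, j], s[:, j], ddof=1)[0, 1] / s[:, j].var(ddof=1))
    assert abs(np.mean(slopes) - 0.5) < 0.05


def test_allele_frequencies_conserved_down_the_pedigree():
    """Drift is mean-zero: offspring frequencies scatter around the
    realized founder frequencies without systematic displacement."""
    cfg = dg.SimConfig(n_generations=2, gen_sizes=(400, 400), n_lines=1,
                       n_chromosomes=3, snps_per_chromosome=40, seed=5)
    ped = dg.simulate_pedigree(cfg)
    geno, _ = dg.simulate_genotypes(ped, cfg)
    founders = ped["generation"] == 1
    pf = geno.dosages[founders.to_numpy()].mean(axis=0) / 2.0
    po = geno.dosages[(~founders).to_numpy()].mean(axis=0) / 2.0
    n_off = int((~founders).sum())
    se = np.sqrt(np.maximum(pf * (1 - pf), 1e-12) / (2 * n_off))
    z = (po - pf) / se
    # family structure inflates the binomial SE, so allow a wider band
    # per SNP but insist the mean standardized drift is near zero
    assert abs(z.mean()) < 3.0 / np.sqrt(len(z)) * 3
    assert (np.abs(po - pf) < 3 * 3 * se).mean() > 0.95


def test_empty_marker_map_rejected(small_data):
    ped, _, _ = small_data
    with pytest.raises(ValueError):
        dg.SimConfig(n_generations=3, gen_sizes=(60, 60, 80), n_lines=1,
                     n_chromosomes=0, snps_per_chromosome=10).validate()


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _arch(**kw):
    base = dict(trait_name="T", target_h2=0.3, phenotypic_mean=100.0,
                phenotypic_sd=10.0, n_causal=50)
    base.update(kw)
    return dg.TraitArchitecture(**base)


def test_h2_one_means_no_residual(small_data):
    ped, geno, _ = small_data
    arch = _arch(target_h2=1.0, fixed_effect_sizes={})
    ph, truth = dg.simulate_phenotypes(ped, geno, [arch], seed=1)
    expected = arch.phenotypic_mean + truth["T"].tbv.to_numpy()
    assert np.allclose(ph["T"].to_numpy(), expected)


def test_h2_zero_means_no_genetic_variance(small_data):
    ped, geno, _ = small_data
    ph, truth = dg.simulate_phenotypes(ped, geno, [_arch(target_h2=0.0)], seed=1)
    assert truth["T"].tbv.var() == 0.0
    assert (truth["T"].causal_effects == 0).all()


def test_tbv_is_centered_dosage_weighted_sum(small_data):
    ped, geno, _ = small_data
    ph, truth = dg.simulate_phenotypes(ped, geno, [_arch()], seed=3)
    tv = truth["T"]
    raw = geno.dosages[:, tv.causal_index].astype(float) @ tv.causal_effects
    assert np.allclose(tv.tbv.to_numpy(), raw - raw.mean())
    assert np.isclose(tv.tbv.to_numpy().var(), 0.3 * 10.0 ** 2)


def test_realized_phenotypic_sd_near_target():
    cfg = dg.SimConfig(n_generations=2, gen_sizes=(400, 400), n_lines=1,
                       n_chromosomes=2, snps_per_chromosome=50, seed=2)
    ped = dg.simulate_pedigree(cfg)
    geno, _ = dg.simulate_genotypes(ped, cfg)
    sds = []
    for seed in range(5):
        ph, _ = dg.simulate_phenotypes(ped, geno, [_arch()], seed=seed)
        sds.append(ph["T"].std())
    assert abs(np.mean(sds) - 10.0) / 10.0 < 0.10


def test_ordinal_traits_are_five_point_scores(small_data):
    ped, geno, _ = small_data
    arch = _arch(trait_name="GAIT", phenotypic_mean=3.15, phenotypic_sd=0.66,
                 ordinal=True)
    ph, _ = dg.simulate_phenotypes(ped, geno, [arch], seed=4)
    assert set(np.unique(ph["GAIT"])) <= {1, 2, 3, 4, 5}


def test_invalid_h2_rejected(small_data):
    with pytest.raises(ValueError):
        _arch(target_h2=1.5).validate()


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def masked_setup(small_data):
    ped, geno, _ = small_data
    ph, _ = dg.simulate_phenotypes(ped, geno, [_arch()], seed=6)
    return ped, geno, ph


def test_forward_split_partitions_phenotyped_birds(masked_setup):
    ped, _, ph = masked_setup
    split = dg.mask_validation(ph, ped, target_generation=3)
    tr, ma = set(split.training_ids), set(split.masked_ids)
    assert tr.isdisjoint(ma)
    assert tr | ma == set(ph["id"])
    assert len(ma) == (ped["generation"] == 3).sum()


def test_forward_split_rejects_first_generation(masked_setup):
    ped, _, ph = masked_setup
    with pytest.raises(ValueError):
        dg.mask_validation(ph, ped, target_generation=1)
    with pytest.raises(ValueError):
        dg.mask_validation(ph, ped, target_generation=9)


def test_genotype_masking_hides_only_offpanel_snps(masked_setup):
    ped, geno, _ = masked_setup
    panel = np.arange(0, geno.n_snps, 4)
    before = geno.dosages.copy()
    mask = dg.mask_genotypes_for_imputation(geno, n_individuals=20,
                                            panel_snp_index=panel, seed=0)
    assert np.array_equal(geno.dosages, before)        # truth untouched
    rows = mask.masked.row_index(mask.masked_ids)
    offpanel = np.setdiff1d(np.arange(geno.n_snps), panel)
    assert (mask.masked.dosages[np.ix_(rows, offpanel)] == dg.MISSING).all()
    assert (mask.masked.dosages[np.ix_(rows, panel)] >= 0).all()
    other = np.setdiff1d(np.arange(geno.n_individuals), rows)
    assert (mask.masked.dosages[other] >= 0).all()


def test_full_panel_masks_nothing(masked_setup):
    ped, geno, _ = masked_setup
    mask = dg.mask_genotypes_for_imputation(
        geno, 10, np.arange(geno.n_snps), seed=1)
    assert np.array_equal(mask.masked.dosages, geno.dosages)
    acc = dg.imputation_accuracy(geno, mask.masked.dosages.astype(float),
                                 mask.masked_ids)
    assert acc.genome_mean == pytest.approx(1.0)


def test_masking_more_individuals_than_available_fails(masked_setup):
    ped, geno, _ = masked_setup
    with pytest.raises(ValueError):
        dg.mask_genotypes_for_imputation(geno, geno.n_individuals + 1,
                                         [0], seed=1)


def test_parent_average_imputer_beats_population_mean():
    """The pedigree-aware baseline must dominate the frequency-only one
    on families, since parents carry half the offspring's alleles.

    Compared on the pooled correlation over all hidden entries: the
    population-mean fill is constant per SNP across masked birds, so its
    per-SNP correlations are degenerate by construction.
    """
    wins = 0
    for rep in range(10):
        cfg = dg.SimConfig(n_generations=2, gen_sizes=(60, 60), n_lines=1,
                           n_chromosomes=2, snps_per_chromosome=30,
                           seed=100 + rep)
        ped = dg.simulate_pedigree(cfg)
        geno, _ = dg.simulate_genotypes(ped, cfg)
        offspring = ped[ped["generation"] == 2]["id"].to_numpy()
        mask = dg.mask_genotypes_for_imputation(
            geno, 30, panel_snp_index=np.arange(0, 60, 10), seed=rep,
            candidate_ids=offspring)
        pa = dg.impute_parent_average(mask.masked, ped)
        pm = dg.impute_population_mean(mask.masked)
        rows = geno.row_index(mask.masked_ids)
        hidden = np.setdiff1d(np.arange(geno.n_snps), mask.panel_index)
        truth = geno.dosages[np.ix_(rows, hidden)].astype(float).ravel()
        r_pa = np.corrcoef(truth, pa[np.ix_(rows, hidden)].ravel())[0, 1]
        r_pm = np.corrcoef(truth, pm[np.ix_(rows, hidden)].ravel())[0, 1]
        wins += r_pa > r_pm
    assert wins >= 8
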