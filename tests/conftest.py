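import pandas as pd
import pytest

import duckgs as dg


@pytest.fixture(scope="session")
def small_config():
    return dg.SimConfig(n_generations=3, gen_sizes=(60, 60, 80), n_lines=1,
                        n_chromosomes=3, snps_per_chromosome=40, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config):
    ped = dg.simulate_pedigree(small_config)
    geno, freqs = dg.simulate_genotypes(ped, small_config)
    return ped, geno, freqs


@pytest.fixture(scope="session")
def two_line_data():
    cfg = dg.SimConfig(n_generations=3, gen_sizes=(80, 80, 80), n_lines=2,
                       n_chromosomes=3, snps_per_chromosome=60, fst=0.25,
                       seed=13)
    ped = dg.simulate_pedigree(cfg)
    geno, freqs = dg.simulate_genotypes(ped, cfg)
    return cfg, ped, geno


def toy_pedigree(rows):
    """Hand-built pedigree: rows of (id, sire, dam, generation, sex)."""
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex"])
    df["line"] = "A"
    return df[["id", "sire", "dam", "generation", "line", "sex"]]
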