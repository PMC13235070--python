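"""Breeding-program simulator for a pedigreed meat-duck nucleus.

The generator emulates the data structure of a commercial two-line duck
breeding program in which every bird is genotyped for parentage: discrete
non-overlapping generations, open-pen mating (each offspring draws one
sire and one dam from the pens of the previous generation of its own
line), gene-dropped SNP genotypes with Haldane recombination on a uniform
genetic map, and quantitative traits built from a finite set of causal
markers plus environmental fixed effects (combined sex-by-hatch factor,
dam-age class, feeding pen) and residual noise.

Two lines are modelled as independently drifted founder pools
(Balding-Nichols allele frequencies around a shared ancestral frequency),
which reproduces the qualitative two-cluster PCA separation seen in
genetically distinct selection lines.

All randomness is driven by integer seeds; a given configuration and seed
fully determine every draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import MISSING, GenotypeMatrix

#: pedigree code for an unknown parent (PLINK convention)
UNKNOWN = 0


def is_unknown_parent(value) -> bool:
    """True for the unknown-parent code (``0``, also as a string)."""
    return value == UNKNOWN or value == "0"

_LINE_LABELS = ("A", "D", "B", "C", "E", "F", "G", "H")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated breeding program.

    ``gen_sizes`` applies per line: every line gets the same per-generation
    cohort sizes.  Generations are numbered 1..n_generations; generation 1
    holds the founders (both parents unknown).
    """

    n_generations: int = 6
    gen_sizes: tuple = (1915, 1916, 1916, 1916, 1916, 4066)
    n_lines: int = 2
    n_chromosomes: int = 32
    snps_per_chromosome: int = 1500
    founder_maf_range: tuple = (0.05, 0.5)
    morgans_per_chromosome: float = 1.0
    mating: str = "open_pen"
    sires_per_pen: int = 5
    dams_per_pen: int = 30
    fst: float = 0.10
    seed: int = 2024

    def validate(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.gen_sizes) != self.n_generations:
            raise ValueError("gen_sizes length must equal n_generations")
        if any(int(s) <= 0 for s in self.gen_sizes):
            raise ValueError("all generation sizes must be positive")
        if self.n_lines < 1 or self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range bounds must satisfy 0 < low <= high <= 0.5")
        if self.sires_per_pen < 1 or self.dams_per_pen < 1:
            raise ValueError("pen sizes must be positive")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")

    @classmethod
    def line_a(cls, **overrides) -> "SimConfig":
        """Single line shaped like line A: 9,579 training birds in
        generations 1-5 predicting 4,066 birds in generation 6.

        Per-generation counts for generations 1-5 are an even split of the
        9,579 training total (the published per-generation breakdown is
        not usable; only the totals are).
        """
        base = dict(n_generations=6,
                    gen_sizes=(1915, 1916, 1916, 1916, 1916, 4066),
                    n_lines=1)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def line_d(cls, **overrides) -> "SimConfig":
        """Single line shaped like line D: 8,134 training birds in
        generations 1-4 predicting 4,885 in generation 5."""
        base = dict(n_generations=5,
                    gen_sizes=(2033, 2034, 2033, 2034, 4885),
                    n_lines=1)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def demo(cls, **overrides) -> "SimConfig":
        """Small two-line configuration for smoke tests and examples."""
        base = dict(n_generations=3, gen_sizes=(100, 100, 100), n_lines=2,
                    n_chromosomes=4, snps_per_chromosome=125)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic and environmental architecture of one simulated trait.

    ``fixed_effect_sizes`` maps factor name -> {level: effect}.  ``None``
    requests auto-generated level effects (zero-mean normal with SD
    ``0.15 * phenotypic_sd`` per level); an empty dict turns fixed effects
    off entirely.

    Ordinal traits (gait, foot-pad score) are generated as Gaussian
    liabilities and cut into ``n_classes`` ordinal scores at equiprobable
    thresholds of the generating normal distribution.
    """

    trait_name: str
    target_h2: float
    phenotypic_mean: float
    phenotypic_sd: float
    n_causal: int = 300
    ordinal: bool = False
    n_classes: int = 5
    fixed_effect_sizes: dict = None

    def validate(self, n_snps: int | None = None) -> None:
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError(f"target_h2 must be in [0, 1], got {self.target_h2}")
        if self.phenotypic_sd <= 0:
            raise ValueError("phenotypic_sd must be positive")
        if self.n_causal < 1:
            raise ValueError("n_causal must be positive")
        if n_snps is not None and self.n_causal > n_snps:
            raise ValueError("n_causal exceeds the number of simulated SNPs")


def _arch_table(rows, seven_traits=("JW", "BW", "BD", "PRF", "GAIT", "ADG", "FPD")):
    out = {}
    for name, (h2, mean, sd) in zip(seven_traits, rows):
        out[name] = TraitArchitecture(
            trait_name=name, target_h2=h2, phenotypic_mean=mean,
            phenotypic_sd=sd, ordinal=name in ("GAIT", "FPD"))
    return out


# Default trait panels: juvenile weight (g), slaughter body weight (g),
# breast muscle depth (mm), primary feather length (mm), gait score (1-5),
# average daily gain (g/day), foot-pad dermatitis score (1-5).  Means/SDs
# and pedigree heritability targets follow the published descriptive
# statistics of the two commercial lines.
LINE_A_TRAITS = _arch_table([
    (0.41, 567.15, 86.27),    # JW
    (0.31, 4009.88, 361.95),  # BW
    (0.22, 17.85, 2.34),      # BD
    (0.31, 78.84, 11.53),     # PRF
    (0.10, 3.15, 0.66),       # GAIT
    (0.13, 144.53, 18.99),    # ADG
    (0.30, 1.99, 0.80),       # FPD
])

LINE_D_TRAITS = _arch_table([
    (0.46, 524.21, 66.12),
    (0.50, 3204.60, 294.20),
    (0.21, 21.56, 2.88),
    (0.26, 105.12, 11.85),
    (0.10, 3.10, 0.61),
    (0.31, 96.80, 15.85),
    (0.25, 1.94, 0.66),
])


@dataclass
class TrueValues:
    """Simulation ground truth for one trait (for recovery tests only)."""

    trait: str
    tbv: pd.Series                 # true breeding value per id, centered
    causal_index: np.ndarray       # column positions of causal SNPs
    causal_effects: np.ndarray     # allele substitution effects (scaled)
    fixed_effects: dict            # factor -> {level: effect}


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sexes = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2), dtype=object)
    rng.shuffle(sexes)
    return sexes


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Simulate a multi-line pedigree with discrete generations.

    Returns a DataFrame with columns ``id, sire, dam, generation, line,
    sex``; unknown parents are coded ``0``.  Open-pen mating: the previous
    generation of each line is partitioned into pens holding
    ``sires_per_pen`` males and ``dams_per_pen`` females, each offspring
    is placed in a random pen and draws its sire and dam uniformly within
    that pen.

    Raises ``ValueError`` if a generation that must produce offspring
    contains no male or no female.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    rows = []
    next_id = 1
    for iline in range(config.n_lines):
        line = _LINE_LABELS[iline] if iline < len(_LINE_LABELS) else f"L{iline + 1}"
        prev = None  # (ids, sexes) of previous generation
        for g, size in enumerate(config.gen_sizes, start=1):
            size = int(size)
            ids = np.arange(next_id, next_id + size)
            next_id += size
            sexes = _balanced_sexes(size, rng)
            if g == 1:
                sires = np.full(size, UNKNOWN)
                dams = np.full(size, UNKNOWN)
            else:
                prev_ids, prev_sexes = prev
                males = prev_ids[prev_sexes == "M"]
                females = prev_ids[prev_sexes == "F"]
                if len(males) == 0 or len(females) == 0:
                    raise ValueError(
                        f"line {line} generation {g - 1} lacks at least one "
                        "male and one female; cannot produce offspring")
                sires, dams = _open_pen_mating(males, females, size, config, rng)
            for i in range(size):
                rows.append((ids[i], sires[i], dams[i], g, line, sexes[i]))
            prev = (ids, sexes)
    ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "line", "sex"])
    return ped


def _open_pen_mating(males, females, n_offspring, config, rng):
    n_pens = max(1, min(len(males) // config.sires_per_pen,
                        len(females) // config.dams_per_pen))
    male_pen = rng.permutation(len(males)) % n_pens
    female_pen = rng.permutation(len(females)) % n_pens
    pens_m = [males[male_pen == p] for p in range(n_pens)]
    pens_f = [females[female_pen == p] for p in range(n_pens)]
    pen_of = rng.integers(0, n_pens, n_offspring)
    sires = np.empty(n_offspring, dtype=np.int64)
    dams = np.empty(n_offspring, dtype=np.int64)
    for i, p in enumerate(pen_of):
        sires[i] = rng.choice(pens_m[p])
        dams[i] = rng.choice(pens_f[p])
    return sires, dams


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check pedigree structural invariants.

    Ids unique; parents unknown exactly in the first generation of their
    line; every known parent appears in a strictly earlier generation
    (which rules out cycles, since generations are totally ordered).
    """
    if ped["id"].duplicated().any():
        raise ValueError("duplicate ids in pedigree")
    gen_of = dict(zip(ped["id"], ped["generation"]))
    first_gen = ped.groupby("line")["generation"].transform("min")
    unknown_s = ped["sire"].map(is_unknown_parent)
    unknown_d = ped["dam"].map(is_unknown_parent)
    founders = unknown_s & unknown_d
    if not (founders == (ped["generation"] == first_gen)).all():
        raise ValueError("parents must be unknown exactly for first-generation birds")
    for col in ("sire", "dam"):
        known = ped[~ped[col].map(is_unknown_parent)]
        for pid, gen in zip(known[col], known["generation"]):
            pg = gen_of.get(pid)
            if pg is None:
                raise ValueError(f"{col} {pid} not in pedigree")
            if pg >= gen:
                raise ValueError(f"{col} {pid} not in a strictly earlier generation")


# ---------------------------------------------------------------------------
# genotypes (gene dropping)
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig, rng: np.random.Generator):
    """Random marker positions: per chromosome, strictly increasing bp on
    [1, 1e8] mapped to genetic distance at 1 cM/Mb (scaled so each
    chromosome spans ``morgans_per_chromosome``)."""
    chrom, pos, gen_pos, snp_ids = [], [], [], []
    m = config.snps_per_chromosome
    for c in range(1, config.n_chromosomes + 1):
        bp = np.sort(rng.integers(1, 10 ** 8, m)) + np.arange(m)  # strictly increasing
        chrom.append(np.full(m, c))
        pos.append(bp)
        gen_pos.append(bp / 1e8 * config.morgans_per_chromosome)
        snp_ids.append(np.array([f"snp{c}_{i + 1}" for i in range(m)], dtype=object))
    return (np.concatenate(chrom), np.concatenate(pos),
            np.concatenate(gen_pos), np.concatenate(snp_ids))


def _founder_frequencies(config: SimConfig, lines, rng):
    """Ancestral allele frequencies plus per-line Balding-Nichols drift."""
    m = config.n_chromosomes * config.snps_per_chromosome
    lo, hi = config.founder_maf_range
    maf = rng.uniform(lo, hi, m)
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, maf, 1.0 - maf)
    freqs = {}
    f = config.fst
    for line in lines:
        if f > 0:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p = rng.beta(a, b)
        else:
            p = p_anc.copy()
        freqs[line] = np.clip(p, 1e-3, 1 - 1e-3)
    return p_anc, freqs


def _gamete(h0, h1, chrom_slices, gen_pos, lengths, rng):
    """One recombined gamete under the Haldane (no-interference) model:
    per chromosome, crossovers are a Poisson process of rate 1/Morgan."""
    m = h0.shape[0]
    src = np.empty(m, dtype=np.int8)
    for (s, e), L in zip(chrom_slices, lengths):
        k = rng.poisson(L)
        phase = rng.integers(2)
        if k == 0:
            src[s:e] = phase
        else:
            x = np.sort(rng.uniform(0.0, L, k))
            src[s:e] = (phase + np.searchsorted(x, gen_pos[s:e])) % 2
    return np.where(src == 0, h0, h1)


def simulate_genotypes(ped: pd.DataFrame, config: SimConfig,
                       founder_freqs: dict | None = None,
                       return_haplotypes: bool = False):
    """Gene-drop SNP genotypes down a pedigree.

    Founder haplotype alleles are drawn per SNP from the line's founder
    frequency; every descendant receives one recombined gamete from each
    parent.  Dosages are complete (no missing values).

    Parameters
    ----------
    founder_freqs
        Optional ``{line: array of ALT frequencies}`` overriding the
        Balding-Nichols draw (useful for fixed-allele tests).

    Returns
    -------
    (GenotypeMatrix, founder_freqs) or, with ``return_haplotypes=True``,
    (GenotypeMatrix, founder_freqs, haplotypes) where ``haplotypes`` is an
    ``(n, 2, m)`` int8 array in pedigree row order.
    """
    config.validate()
    validate_pedigree(ped)
    if config.n_chromosomes * config.snps_per_chromosome == 0:
        raise ValueError("empty marker map")
    rng = np.random.default_rng([int(config.seed), 1])
    chrom, pos, gen_pos, snp_ids = _marker_map(config, rng)
    m = len(snp_ids)
    lines = list(dict.fromkeys(ped["line"]))
    if founder_freqs is None:
        _, founder_freqs = _founder_frequencies(config, lines, rng)
    else:
        for line in lines:
            if line not in founder_freqs:
                raise ValueError(f"no founder frequencies for line {line!r}")

    # per-chromosome slices into the concatenated marker arrays
    chrom_slices, lengths = [], []
    start = 0
    for c in dict.fromkeys(chrom):
        e = start + int((chrom == c).sum())
        chrom_slices.append((start, e))
        lengths.append(config.morgans_per_chromosome)
        start = e
    # genetic positions relative to chromosome start
    gp = gen_pos.copy()

    n = len(ped)
    row_of = {v: i for i, v in enumerate(ped["id"].to_numpy())}
    hap = np.empty((n, 2, m), dtype=np.int8)
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    line_arr = ped["line"].to_numpy()
    for i in range(n):
        if is_unknown_parent(sires[i]):
            p = founder_freqs[line_arr[i]]
            hap[i] = rng.random((2, m)) < p
        else:
            s, d = row_of[sires[i]], row_of[dams[i]]
            hap[i, 0] = _gamete(hap[s, 0], hap[s, 1], chrom_slices, gp, lengths, rng)
            hap[i, 1] = _gamete(hap[d, 0], hap[d, 1], chrom_slices, gp, lengths, rng)

    geno = GenotypeMatrix(ped["id"].to_numpy(), hap.sum(axis=1, dtype=np.int8),
                          chrom, pos, snp_ids)
    if return_haplotypes:
        return geno, founder_freqs, hap
    return geno, founder_freqs


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _level_effects(levels, sd, rng):
    return {lev: float(rng.normal(0.0, sd)) for lev in levels}


def simulate_phenotypes(ped: pd.DataFrame, geno: GenotypeMatrix,
                        archs, seed: int,
                        n_hatches: int = 4, n_damage_classes: int = 5,
                        n_pens: int = 10):
    """Simulate phenotypes for one or more trait architectures.

    Each phenotype is ``mean + fixed effects + TBV + residual``.  The true
    breeding value is a dosage-weighted sum of causal-SNP effects, centered
    and rescaled so its realized variance is exactly
    ``target_h2 * phenotypic_sd**2``; the residual SD is
    ``phenotypic_sd * sqrt(1 - target_h2)``.  Environmental factors
    (sexhatch = pedigree sex x random hatch batch, dam-age class, feeding
    pen) are assigned once per bird and shared across traits.

    Returns ``(phenotypes, truth)`` where ``phenotypes`` has columns
    ``id, line, generation, sexhatch, damage, pen`` plus one column per
    trait, and ``truth`` maps trait name -> :class:`TrueValues`.
    """
    if isinstance(archs, TraitArchitecture):
        archs = [archs]
    rng = np.random.default_rng([int(seed), 2])
    n = len(ped)
    if not np.array_equal(ped["id"].to_numpy(), geno.ids):
        raise ValueError("pedigree and genotype matrix must share id order")

    hatch = rng.integers(1, n_hatches + 1, n)
    sexhatch = np.array([f"{s}{h}" for s, h in zip(ped["sex"], hatch)], dtype=object)
    damage = rng.integers(1, n_damage_classes + 1, n)
    pen = rng.integers(1, n_pens + 1, n)

    out = pd.DataFrame({"id": ped["id"].to_numpy(),
                        "line": ped["line"].to_numpy(),
                        "generation": ped["generation"].to_numpy(),
                        "sexhatch": sexhatch, "damage": damage, "pen": pen})
    factor_values = {"sexhatch": sexhatch, "damage": damage, "pen": pen}
    truth: dict[str, TrueValues] = {}
    dos = geno.dosages.astype(np.float64)

    for arch in archs:
        arch.validate(n_snps=geno.n_snps)
        sd, h2 = arch.phenotypic_sd, arch.target_h2
        causal = np.sort(rng.choice(geno.n_snps, arch.n_causal, replace=False))
        u = rng.normal(0.0, 1.0, arch.n_causal)
        tbv = dos[:, causal] @ u
        tbv -= tbv.mean()
        v = tbv.var()
        if h2 == 0.0 or v == 0.0:
            tbv[:] = 0.0
            u[:] = 0.0
        else:
            c = np.sqrt(h2 * sd ** 2 / v)
            tbv *= c
            u *= c

        if arch.fixed_effect_sizes is None:
            fe_maps = {
                "sexhatch": _level_effects(sorted(set(sexhatch)), 0.15 * sd, rng),
                "damage": _level_effects(range(1, n_damage_classes + 1), 0.15 * sd, rng),
                "pen": _level_effects(range(1, n_pens + 1), 0.15 * sd, rng),
            }
        else:
            fe_maps = arch.fixed_effect_sizes
        fe = np.zeros(n)
        for factor, levels in fe_maps.items():
            vals = factor_values[factor]
            fe += np.array([levels.get(v, 0.0) for v in vals])

        resid = rng.normal(0.0, sd * np.sqrt(max(0.0, 1.0 - h2)), n)
        y = arch.phenotypic_mean + fe + tbv + resid
        if arch.ordinal:
            qs = np.arange(1, arch.n_classes) / arch.n_classes
            thresholds = arch.phenotypic_mean + sd * norm.ppf(qs)
            y = 1 + (y[:, None] > thresholds[None, :]).sum(axis=1)
        out[arch.trait_name] = y
        truth[arch.trait_name] = TrueValues(
            trait=arch.trait_name,
            tbv=pd.Series(tbv, index=out["id"].to_numpy()),
            causal_index=causal, causal_effects=u, fixed_effects=fe_maps)
    return out, truth


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

@dataclass
class MaskedSplit:
    """Forward-prediction split: phenotypes of the target generation are
    withheld; genotypes and pedigree links are kept for everyone."""

    training: pd.DataFrame
    masked: pd.DataFrame

    @property
    def training_ids(self) -> np.ndarray:
        return self.training["id"].to_numpy()

    @property
    def masked_ids(self) -> np.ndarray:
        return self.masked["id"].to_numpy()


def mask_validation(phenotypes: pd.DataFrame, ped: pd.DataFrame,
                    target_generation: int) -> MaskedSplit:
    """Split phenotyped birds into training (earlier generations) and a
    phenotype-masked validation set (the target generation).

    Generations after the target, if any, belong to neither set.
    """
    gen = phenotypes.merge(ped[["id", "generation"]], on="id",
                           suffixes=("", "_ped"))
    gcol = "generation_ped" if "generation_ped" in gen.columns else "generation"
    gens = gen[gcol]
    if target_generation not in set(ped["generation"]):
        raise ValueError(f"generation {target_generation} not present in pedigree")
    masked = phenotypes[gens == target_generation]
    training = phenotypes[gens < target_generation]
    if len(masked) == 0:
        raise ValueError(f"target generation {target_generation} has no phenotyped birds")
    if len(training) == 0:
        raise ValueError("no training generations earlier than the target")
    return MaskedSplit(training=training.reset_index(drop=True),
                       masked=masked.reset_index(drop=True))


@dataclass
class ImputationMask:
    """A low-density-panel view of the genotypes plus the hidden truth."""

    masked: GenotypeMatrix        # selected birds keep only panel SNPs
    truth: GenotypeMatrix         # untouched original matrix
    masked_ids: np.ndarray
    panel_index: np.ndarray


def mask_genotypes_for_imputation(geno: GenotypeMatrix, n_individuals: int,
                                  panel_snp_index, seed: int,
                                  candidate_ids=None) -> ImputationMask:
    """Hide the off-panel genotypes of ``n_individuals`` randomly chosen
    birds, mimicking a low-density-panel imputation validation design."""
    panel = np.unique(np.asarray(panel_snp_index, dtype=np.intp))
    if panel.size and (panel.min() < 0 or panel.max() >= geno.n_snps):
        raise ValueError("panel SNP index out of range")
    pool = np.asarray(candidate_ids) if candidate_ids is not None else geno.ids
    if n_individuals > len(pool):
        raise ValueError(f"cannot mask {n_individuals} of {len(pool)} individuals")
    rng = np.random.default_rng([int(seed), 3])
    chosen = rng.choice(pool, n_individuals, replace=False)
    masked = geno.copy()
    rows = masked.row_index(chosen)
    hide = np.ones(geno.n_snps, dtype=bool)
    hide[panel] = False
    masked.dosages[np.ix_(rows, np.where(hide)[0])] = MISSING
    return ImputationMask(masked=masked, truth=geno, masked_ids=chosen,
                          panel_index=panel)


def _observed_column_means(masked: GenotypeMatrix) -> np.ndarray:
    d = masked.dosages.astype(np.float64)
    obs = masked.called_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(np.where(obs, d, np.nan), axis=0)
    return np.nan_to_num(col_mean, nan=0.0)


def impute_population_mean(masked: GenotypeMatrix) -> np.ndarray:
    """Fill missing calls with the per-SNP mean dosage of observed calls."""
    d = masked.dosages.astype(np.float64)
    obs = masked.called_mask()
    return np.where(obs, d, _observed_column_means(masked)[None, :])


def impute_parent_average(masked: GenotypeMatrix, ped: pd.DataFrame) -> np.ndarray:
    """Naive pedigree imputer: a missing call becomes the mean of the
    parents' observed dosages (the Mendelian expectation), falling back to
    the population mean when a parent is unknown or itself unobserved.

    A baseline evaluator fixture, not a production imputation method.
    """
    d = masked.dosages.astype(np.float64)
    obs = masked.called_mask()
    col_mean = _observed_column_means(masked)
    out = np.where(obs, d, col_mean[None, :])
    row_of = {v: i for i, v in enumerate(masked.ids)}
    parents = ped.set_index("id")[["sire", "dam"]]
    for i, ind in enumerate(masked.ids):
        miss = ~obs[i]
        if not miss.any() or ind not in parents.index:
            continue
        sire, dam = parents.loc[ind]
        pv = []
        for p in (sire, dam):
            if is_unknown_parent(p) or p not in row_of:
                pv.append(col_mean)
            else:
                r = row_of[p]
                pv.append(np.where(obs[r], d[r], col_mean))
        exp = 0.5 * (pv[0] + pv[1])
        out[i, miss] = exp[miss]
    return out
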