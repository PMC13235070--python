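"""SNP quality control and trait descriptive statistics.

QC follows the standard pre-analysis protocol for imputed SNP-array data:
remove SNPs with minor allele frequency below 0.05 and SNPs failing the
exact Hardy-Weinberg equilibrium test at p < 1e-6.  Both thresholds are
strict inequalities (a SNP sitting exactly on a threshold is retained)
and configurable.  No call-rate or per-individual filters are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .containers import GenotypeMatrix

DEFAULT_MAF_MIN = 0.05
DEFAULT_HWE_P = 1e-6


def allele_frequency(dosages) -> float:
    """Frequency of the counted allele: sum(dosages) / (2 * n_called).

    Missing calls (negative dosage) are ignored; raises if every call is
    missing.
    """
    d = np.asarray(dosages)
    called = d >= 0
    n = int(called.sum())
    if n == 0:
        raise ValueError("allele frequency undefined: all calls missing")
    return float(d[called].sum() / (2.0 * n))


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (the standard two-sided exact HWE
    test; no mid-p correction).  The conditional distribution is

        P(n_het | n, n_rare) ∝ n! / (n_hr! n_het! n_hc!) * 2**n_het,

    evaluated here through log-gamma weights for numerical stability.
    Monomorphic SNPs return p = 1 by convention.
    """
    counts = (int(n_hom1), int(n_het), int(n_hom2))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes observed")
    n_hom1, n_het, n_hom2 = counts
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logw = (gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1) + hets * np.log(2.0))
    w = np.exp(logw - logw.max())
    obs = w[np.searchsorted(hets, n_het)]
    p = w[w <= obs * (1.0 + 1e-12)].sum() / w.sum()
    return float(min(1.0, p))


def filter_snps(geno: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN,
                hwe_threshold: float = DEFAULT_HWE_P):
    """Apply MAF and exact-HWE filters to every SNP.

    Returns ``(kept_index, summary)``: positions of retained SNPs in the
    original (stable) order, and a per-SNP summary table with columns
    ``snp_id, chromosome, maf, hwe_p, n_called, kept``.  A SNP is removed
    iff ``maf < maf_min`` or ``hwe_p < hwe_threshold`` (strict).  SNPs with
    no calls are flagged and removed.  Raises if nothing survives.
    """
    if geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    n0, n1, n2 = geno.genotype_counts()
    n_called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    hwe_p = np.ones(geno.n_snps)
    for j in range(geno.n_snps):
        if n_called[j] > 0:
            hwe_p[j] = hwe_exact_test(n0[j], n1[j], n2[j])
    callable_ = n_called > 0
    kept = callable_ & (maf >= maf_min) & (hwe_p >= hwe_threshold)
    summary = pd.DataFrame({
        "snp_id": geno.snp_ids, "chromosome": geno.chrom,
        "maf": np.where(callable_, maf, np.nan),
        "hwe_p": np.where(callable_, hwe_p, np.nan),
        "n_called": n_called, "kept": kept,
    })
    if not kept.any():
        raise ValueError(
            f"all {geno.n_snps} SNPs removed by QC "
            f"(maf_min={maf_min}, hwe_threshold={hwe_threshold})")
    return np.where(kept)[0], summary


@dataclass
class TraitSummary:
    """Descriptive statistics of one trait vector.

    ``std`` is the sample SD (n-1 denominator), ``skewness`` and
    ``kurtosis`` are the bias-corrected sample estimators with kurtosis
    reported as excess, ``cv = 100 * std / mean`` and ``se = std / sqrt(n)``.
    """

    trait: str
    n: int
    mean: float
    std: float
    skewness: float
    kurtosis: float
    cv: float
    se: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"trait": self.trait, "n": self.n, "mean": self.mean,
                "std": self.std, "skewness": self.skewness,
                "kurtosis": self.kurtosis, "cv": self.cv, "se": self.se}


def describe_trait(values, trait: str = "") -> TraitSummary:
    """Descriptive statistics for a complete trait vector (n > 3)."""
    x = np.asarray(values, dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("trait vector contains missing values")
    n = len(x)
    if n <= 3:
        raise ValueError("need more than 3 observations")
    mean = float(x.mean())
    std = float(x.std(ddof=1))
    if std == 0.0:
        return TraitSummary(trait, n, mean, 0.0, np.nan, np.nan,
                            0.0 if mean != 0 else np.nan, 0.0, degenerate=True)
    cv = 100.0 * std / mean if mean != 0 else np.nan
    return TraitSummary(
        trait=trait, n=n, mean=mean, std=std,
        skewness=float(_skew(x, bias=False)),
        kurtosis=float(_kurtosis(x, fisher=True, bias=False)),
        cv=cv, se=std / np.sqrt(n))


def trait_summary_table(phenotypes: pd.DataFrame, traits) -> pd.DataFrame:
    """Stack :func:`describe_trait` over several phenotype columns."""
    rows = []
    for t in traits:
        vals = phenotypes[t].dropna().to_numpy()
        rows.append(describe_trait(vals, trait=t).to_dict())
    return pd.DataFrame(rows)
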