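"""Forward-prediction metrics: accuracy, dispersion bias, and the
imputation-accuracy evaluator.

Forward validation mimics commercial selection: breeding values of the
newest generation are predicted with its phenotypes masked, then judged
against (i) the adjusted phenotypes of that generation (predictive
correlation r, and accuracy r / sqrt(h2) with h2 from the training
generations) and (ii) the "true" EBV re-estimated with every phenotype
unmasked (dispersion slope b of whole-data EBV on masked-data EBV, and
its standardized form b_std).

b_std is 1 - b for b < 1 and 1/b - 1 for b >= 1: zero means no
dispersion bias, positive values flag overestimated (overdispersed)
EBVs, negative values underestimation.  The map is continuous at b = 1.
For b <= 0 the first branch applies but the result leaves the nominal
(-1, 1] range; a warning is emitted rather than clipping silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

REPORT_METRICS = ("h2", "se", "r", "acc", "b", "b_std")


def prediction_accuracy(ebv_masked: pd.Series, y_star_validation: pd.Series,
                        h2_training: float) -> tuple[float, float]:
    """Predictive correlation and accuracy over the validation set.

    ``r`` is the Pearson correlation between predicted EBV and adjusted
    phenotype over validation individuals; accuracy divides r by the
    square root of the training-generations heritability.
    """
    common = ebv_masked.index.intersection(y_star_validation.index)
    if len(common) < 30:
        raise ValueError(f"need >= 30 validation individuals, got {len(common)}")
    if not h2_training > 0:
        raise ValueError("accuracy undefined for non-positive heritability")
    e = ebv_masked.loc[common].to_numpy(dtype=float)
    y = y_star_validation.loc[common].to_numpy(dtype=float)
    if e.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input to predictive correlation")
    r = float(np.corrcoef(e, y)[0, 1])
    return r, r / float(np.sqrt(h2_training))


def dispersion_bias(ebv_whole: pd.Series, ebv_partial: pd.Series,
                    validation_ids) -> float:
    """OLS slope of whole-data EBV on masked-data EBV over the validation
    individuals (same matrix kind for both fits); 1 means no dispersion."""
    ids = np.asarray(validation_ids)
    w = ebv_whole.loc[ids].to_numpy(dtype=float)
    p = ebv_partial.loc[ids].to_numpy(dtype=float)
    vp = p.var()
    if vp == 0:
        raise ValueError("masked-data EBVs have zero variance; slope undefined")
    return float(np.cov(w, p, ddof=1)[0, 1] / p.var(ddof=1))


def standardized_bias(b: float) -> float:
    """Piecewise standardization of the dispersion slope:
    1 - b for b < 1 and 1/b - 1 for b >= 1."""
    if not np.isfinite(b):
        raise ValueError("dispersion slope must be finite")
    if b <= 0:
        warnings.warn(
            f"dispersion slope b={b:g} is non-positive; standardized bias "
            "leaves its nominal (-1, 1] range", stacklevel=2)
    return 1.0 - b if b < 1.0 else 1.0 / b - 1.0


@dataclass
class ImputationAccuracy:
    """Per-SNP imputation concordance over masked individuals."""

    per_snp: pd.DataFrame        # snp_id, chromosome, correlation
    chromosome_mean: pd.Series
    genome_mean: float
    n_undefined: int


def imputation_accuracy(true_geno: GenotypeMatrix, imputed: np.ndarray,
                        masked_ids) -> ImputationAccuracy:
    """Pearson correlation of true vs imputed dosages per SNP across the
    masked individuals; per-chromosome and genome-wide means ignore SNPs
    whose true or imputed vector is constant (correlation undefined)."""
    ids = np.asarray(masked_ids)
    if len(ids) == 0:
        raise ValueError("no masked individuals")
    rows = true_geno.row_index(ids)
    t = true_geno.dosages[rows].astype(np.float64)
    imp = np.asarray(imputed, dtype=np.float64)
    if imp.shape != true_geno.dosages.shape:
        raise ValueError("imputed matrix shape does not match the truth")
    x = imp[rows]
    tc = t - t.mean(axis=0)
    xc = x - x.mean(axis=0)
    st = tc.std(axis=0)
    sx = xc.std(axis=0)
    defined = (st > 0) & (sx > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (tc * xc).mean(axis=0) / (st * sx)
    corr = np.where(defined, corr, np.nan)
    per_snp = pd.DataFrame({"snp_id": true_geno.snp_ids,
                            "chromosome": true_geno.chrom,
                            "correlation": corr})
    chrom_mean = per_snp.dropna().groupby("chromosome")["correlation"].mean()
    genome_mean = float(np.nanmean(corr)) if defined.any() else np.nan
    return ImputationAccuracy(per_snp=per_snp, chromosome_mean=chrom_mean,
                              genome_mean=genome_mean,
                              n_undefined=int((~defined).sum()))


def assemble_report(records) -> pd.DataFrame:
    """Assemble the per-trait, per-matrix validation report.

    ``records`` is an iterable of dicts with keys ``trait, matrix_kind,
    h2, se, r, acc, b, b_std``.  Output: one row per trait with a
    ``G_*`` column block followed by an ``A_*`` block, in the order
    h2, se, r, acc, b, b_std.  Missing matrix kinds leave NaN blocks.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no validation records")
    traits = list(dict.fromkeys(df["trait"]))
    cols = {}
    for kind in ("G", "A"):
        sub = df[df["matrix_kind"] == kind].set_index("trait")
        for metric in REPORT_METRICS:
            cols[f"{kind}_{metric}"] = [
                sub[metric].get(t, np.nan) if metric in sub.columns else np.nan
                for t in traits]
    out = pd.DataFrame({"trait": traits, **cols})
    return out


def render_report(report: pd.DataFrame) -> str:
    """Fixed-width human-readable rendering of the validation report."""
    lines = []
    header = "trait " + " ".join(
        f"{kind}_{m:<5}" for kind in ("G", "A") for m in REPORT_METRICS)
    lines.append(header)
    for _, row in report.iterrows():
        vals = " ".join(
            f"{row[f'{kind}_{m}']:7.2f}" if pd.notna(row[f"{kind}_{m}"]) else "     NA"
            for kind in ("G", "A") for m in REPORT_METRICS)
        lines.append(f"{row['trait']:<5} {vals}")
    return "\n".join(lines)
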