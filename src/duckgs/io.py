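"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (biallelic, GT field; read through cyvcf2) or
PLINK text PED/MAP; pedigree, phenotype, relationship-matrix and report
tables as TSV with headers.  Missing parents are coded ``0``, missing
genotypes ``./.`` (VCF) or ``0 0`` (PED).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pedigree_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t")
    required = {"id", "sire", "dam", "generation", "line", "sex"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    return ped


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError("phenotype table must carry an 'id' column")
    return df


def write_relationship_long(K, path) -> None:
    write_tsv(K.to_long_frame(), path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal biallelic VCF 4.2 with GT calls."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=duckgs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(geno.chrom):
            length = int(geno.pos[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        samples = "\t".join(str(i) for i in geno.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(geno.n_snps):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                     f"{geno.ref[j]}\t{geno.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix (ALT-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    chrom, pos, snp_ids, ref, alt, rows = [], [], [], [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        snp_ids.append(v.ID if v.ID else f"{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        rows.append(remap[v.gt_types])
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    dosages = np.vstack(rows).T
    return GenotypeMatrix(ids, dosages, np.array(chrom, dtype=object),
                          np.array(pos), np.array(snp_ids, dtype=object),
                          np.array(ref, dtype=object), np.array(alt, dtype=object))


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(geno: GenotypeMatrix, ped: pd.DataFrame, prefix) -> None:
    """Write PLINK text files ``<prefix>.ped`` and ``<prefix>.map``.

    Family id = line, phenotype column = -9; alleles come from the
    marker's ref/alt labels, missing genotypes are ``0 0``.
    """
    prefix = Path(prefix)
    info = ped.set_index("id")
    sexcode = {"M": 1, "F": 2}
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in enumerate(geno.ids):
            key = ind if ind in info.index else type(info.index[0])(ind)
            row = info.loc[key]
            fields = [str(row["line"]), str(ind), str(row["sire"]),
                      str(row["dam"]), str(sexcode.get(row["sex"], 0)), "-9"]
            d = geno.dosages[i]
            for j in range(geno.n_snps):
                a, b = geno.ref[j], geno.alt[j]
                g = {0: f"{a} {a}", 1: f"{a} {b}", 2: f"{b} {b}"}.get(int(d[j]), "0 0")
                fields.append(g)
            fh.write(" ".join(fields) + "\n")
    with open(f"{prefix}.map", "w") as fh:
        for j in range(geno.n_snps):
            fh.write(f"{geno.chrom[j]} {geno.snp_ids[j]} 0 {geno.pos[j]}\n")


def read_ped_map(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK text PED/MAP; returns (genotypes, pedigree-ish table).

    PED files carry no REF/ALT orientation, so the counted allele is made
    deterministic: at each marker the lexicographically smaller allele
    label is REF and the larger one is the counted ALT.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"])
    m = len(mp)
    ids, fams, sires, dams, sexes, genos = [], [], [], [], [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError("PED row length does not match MAP")
            fams.append(parts[0])
            ids.append(parts[1])
            sires.append(parts[2])
            dams.append(parts[3])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            genos.append(parts[6:])
    alleles = [set() for _ in range(m)]
    for g in genos:
        for j in range(m):
            for a in (g[2 * j], g[2 * j + 1]):
                if a != "0":
                    alleles[j].add(a)
    ref, alt = [], []
    for j in range(m):
        labs = sorted(alleles[j])
        if len(labs) > 2:
            raise ValueError(f"marker {mp['snp_id'][j]} is not biallelic: {labs}")
        ref.append(labs[0] if labs else "A")
        alt.append(labs[1] if len(labs) > 1 else "G")
    dosages = np.full((len(ids), m), MISSING, dtype=np.int8)
    for i, g in enumerate(genos):
        for j in range(m):
            a, b = g[2 * j], g[2 * j + 1]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == alt[j]) + (b == alt[j])
    geno = GenotypeMatrix(np.array(ids, dtype=object), dosages,
                          mp["chrom"].to_numpy(), mp["pos"].to_numpy(),
                          mp["snp_id"].to_numpy(),
                          np.array(ref, dtype=object), np.array(alt, dtype=object))
    fam = pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                        "line": fams, "sex": sexes})
    return geno, fam
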