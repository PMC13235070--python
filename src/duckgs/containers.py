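"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel for a missing genotype call in a dosage matrix
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNP matrix of ALT-allele dosages.

    Dosages are coded 0/1/2 (copies of the counted allele) with ``-1``
    marking a missing call.  Marker metadata (chromosome, position, id,
    alleles) is carried alongside so the matrix can round-trip through
    VCF and PLINK text formats.

    Parameters
    ----------
    ids
        Individual identifiers, one per row.
    dosages
        ``(n_individuals, n_snps)`` integer array.
    chrom, pos, snp_ids
        Per-SNP chromosome label, base-pair position and marker name.
    ref, alt
        Per-SNP allele labels; default to ``A``/``G`` if omitted.
    """

    ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray
    ref: np.ndarray = field(default=None)
    alt: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids)
        m = self.dosages.shape[1]
        if self.ref is None:
            self.ref = np.full(m, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(m, "G", dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosages.shape != (len(self.ids), m):
            raise ValueError("dosage matrix shape does not match ids")
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("snp_ids", self.snp_ids), ("ref", self.ref),
                          ("alt", self.alt)):
            if len(arr) != m:
                raise ValueError(f"{name} length does not match number of SNPs")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in genotype matrix")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages >= 0

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted (ALT) allele among called genotypes.

        SNPs with no calls get ``nan``.
        """
        called = self.called_mask()
        n_called = called.sum(axis=0)
        sums = np.where(called, self.dosages, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = sums / (2.0 * n_called)
        p[n_called == 0] = np.nan
        return p

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-SNP counts of dosage 0, 1 and 2 genotypes (missing excluded)."""
        d = self.dosages
        return ((d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0))

    def row_index(self, ids) -> np.ndarray:
        """Row positions of ``ids``, raising on any id not present."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[v] for v in np.asarray(ids)], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix") from None

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        rows = self.row_index(ids)
        return GenotypeMatrix(self.ids[rows], self.dosages[rows].copy(),
                              self.chrom, self.pos, self.snp_ids, self.ref, self.alt)

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.ids, self.dosages[:, index].copy(),
                              self.chrom[index], self.pos[index],
                              self.snp_ids[index], self.ref[index], self.alt[index])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids.copy(), self.dosages.copy(),
                              self.chrom.copy(), self.pos.copy(),
                              self.snp_ids.copy(), self.ref.copy(), self.alt.copy())
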