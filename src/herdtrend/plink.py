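"""Genotype container and PLINK-style text I/O (.ped/.map).

Genotypes are held as allele dosages (0/1/2 copies of the A2 allele) in a
dense float matrix with NaN for missing calls, which is what the kinship and
association code consumes directly.  The .ped/.map writer emits the classic
six-column-header whitespace text format with alleles coded A/B and missing
as ``0 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_plink", "write_plink"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with marker metadata."""

    dosage: np.ndarray  # (n, m) float, values {0, 1, 2, NaN}
    individuals: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.individuals) != n or len(self.snp_ids) != m:
            raise ValueError("metadata lengths do not match the dosage matrix")
        if self.chrom is None:
            self.chrom = np.ones(m, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency (folded to [0, 0.5])."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, mask],
            individuals=self.individuals,
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
        )


def write_plink(geno: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix.ped`` and ``prefix.map`` text files."""
    with open(f"{prefix}.map", "w") as fh:
        for c, s, p in zip(geno.chrom, geno.snp_ids, geno.pos):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    codes = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in enumerate(geno.individuals):
            row = geno.dosage[i]
            alleles = " ".join("0 0" if np.isnan(d) else codes[d] for d in row)
            fh.write(f"FAM {ind} 0 0 0 -9 {alleles}\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read ``prefix.ped``/``prefix.map`` written by :func:`write_plink`.

    Alleles are re-coded to dosages of the B allele; any non-zero allele
    symbols are accepted (first symbol seen per SNP becomes allele A).
    """
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"])
    individuals = []
    rows = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6:
                continue
            individuals.append(parts[1])
            alleles = parts[6:]
            rows.append(alleles)
    m = len(mp)
    n = len(rows)
    dosage = np.full((n, m), np.nan)
    # allele A = alphabetically first symbol observed at the SNP, so dosages
    # are stable regardless of row order and round-trip with write_plink
    seen: list[set] = [set() for _ in range(m)]
    arr = np.array(rows, dtype=object)
    if arr.size and arr.shape[1] != 2 * m:
        raise ValueError(f"ped rows have {arr.shape[1]} alleles, expected {2 * m}")
    for j in range(m):
        for a in np.unique(arr[:, [2 * j, 2 * j + 1]]):
            if a != "0":
                seen[j].add(a)
    ref = [min(s) if s else "A" for s in seen]
    for i in range(n):
        for j in range(m):
            a1, a2 = arr[i, 2 * j], arr[i, 2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 != ref[j]) + (a2 != ref[j])
    return GenotypeMatrix(
        dosage=dosage,
        individuals=np.array(individuals, dtype=object),
        snp_ids=mp["snp"].to_numpy(dtype=object),
        chrom=mp["chrom"].to_numpy(),
        pos=mp["pos"].to_numpy(),
    )
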