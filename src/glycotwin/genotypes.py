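"""Genotype dosage container with plain-TSV and minimal-VCF round trips."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "write_dosage_tsv", "read_dosage_tsv",
           "write_vcf", "read_vcf"]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (copies of the ALT allele, 0/1/2) for n individuals x m SNPs."""

    individuals: list[str]
    snp_ids: list[str]
    dosages: np.ndarray                   # shape (n, m), values in {0, 1, 2}
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.individuals) or m != len(self.snp_ids):
            raise ValueError("dosage matrix dimensions do not match labels")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if not self.ref:
            self.ref = ["A"] * m
        if not self.alt:
            self.alt = ["G"] * m
        if not self.chrom:
            self.chrom = ["1"] * m
        if not self.pos:
            self.pos = list(range(1, m + 1))

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def alt_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    def standardized(self) -> np.ndarray:
        """Dosages centred at 2p and scaled by sqrt(2pq) per SNP."""
        p = self.alt_freq
        denom = np.sqrt(2.0 * p * (1.0 - p))
        if np.any(denom == 0):
            raise ValueError("monomorphic SNP cannot be standardized")
        return (self.dosages - 2.0 * p) / denom

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snp_ids=[self.snp_ids[i] for i in idx],
            dosages=self.dosages[:, idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=[self.pos[i] for i in idx],
        )

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)].astype(float)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.individuals, columns=geno.snp_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        individuals=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=np.int8),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with unphased diploid GT only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        for j in range(geno.n_snps):
            gts = "\t".join(_GT[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\t"
                     f"{geno.ref[j]}\t{geno.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a :class:`GenotypeMatrix` (cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snp_ids, ref, alt, chrom, pos, rows = [], [], [], [], [], []
    for v in vcf:
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        g = np.asarray(v.genotypes)[:, :2].sum(axis=1)
        rows.append(g)
    return GenotypeMatrix(
        individuals=individuals, snp_ids=snp_ids,
        dosages=np.asarray(rows, dtype=np.int8).T,
        ref=ref, alt=alt, chrom=chrom, pos=pos,
    )
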