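"""Readers and writers for the variant panel formats the pipeline consumes.

VCF v4.2 (biallelic SNPs, GT only) is read with :mod:`cyvcf2`; BED 6+2
(chrom, start, end, gene id, score, strand, class, label) with pandas.
VCF positions are 1-based and converted to the package's 0-based half-open
convention at this boundary.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .popgen import MISSING, GeneInterval, GenotypePool

CONTIGS = [f"Chr{i:02d}" for i in range(1, 15)]
CONTIG_LENGTH = 50_000_000

BED_COLUMNS = ["chrom", "start", "end", "gene", "score", "strand", "class", "label"]


def write_bed(intervals: Sequence[GeneInterval], path: str) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, iv.gene_id, 0, "+", iv.gene_class, iv.label)
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> list[GeneInterval]:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, dtype={"chrom": str})
    return [
        GeneInterval(
            gene_id=str(r.gene),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            gene_class=str(r["class"]),
            label=str(r.label),
        )
        for _, r in df.iterrows()
    ]


def write_vcf(
    records: Sequence[tuple[str, int, np.ndarray]],
    samples: Sequence[str],
    path: str,
    contigs: Sequence[str] = CONTIGS,
) -> None:
    """Write biallelic SNP records as plain-text VCF v4.2.

    ``records``: (chrom, pos0, genotype vector over samples with entries
    0/1/2/-1) tuples; positions are 0-based here and serialized 1-based.
    Records are sorted by (contig order, position).  REF/ALT are fixed A/T:
    downstream statistics only consume the derived-allele dosage.
    """
    order = {c: i for i, c in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r[0], len(order)), r[1]))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coldsig\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={CONTIG_LENGTH}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos0, geno in recs:
            gts = "\t".join(gt_map[int(g)] for g in geno)
            fh.write(f"{chrom}\t{pos0 + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_pools(
    path: str, pool_samples: Mapping[str, Sequence[str]]
) -> dict[str, GenotypePool]:
    """Load a VCF into one GenotypePool per pool (all contigs concatenated).

    ``pool_samples`` maps pool name -> sample names; every listed sample must
    be present in the VCF header.  Positions are stored 0-based; the contig
    of each site is kept in a parallel array on the returned pools via a
    composite coordinate: sites retain their chromosome in
    ``pool.site_chroms`` (attached attribute) so interval queries filter on
    chromosome.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    idx = {s: i for i, s in enumerate(samples)}
    for pool, names in pool_samples.items():
        missing = [s for s in names if s not in idx]
        if missing:
            raise ValueError(f"pool {pool!r}: samples absent from VCF: {missing}")
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        gt = np.asarray(variant.genotype.array())[:, :2]
        dosage = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        chroms.append(variant.CHROM)
        positions.append(variant.POS - 1)
        rows.append(dosage.astype(np.int8))
    geno = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    pos = np.asarray(positions, dtype=np.int64)
    chrom_arr = np.asarray(chroms, dtype=object)
    pools: dict[str, GenotypePool] = {}
    for pool, names in pool_samples.items():
        cols = [idx[s] for s in names]
        gp = GenotypePool(name=pool, genotypes=geno[:, cols], positions=pos)
        gp.site_chroms = chrom_arr  # type: ignore[attr-defined]
        pools[pool] = gp
    return pools


def pool_view(pool: GenotypePool, interval: GeneInterval) -> GenotypePool:
    """Restrict a multi-contig pool to one gene's chromosome and window."""
    chroms = getattr(pool, "site_chroms", None)
    if chroms is None:
        mask = np.ones(len(pool.positions), dtype=bool)
    else:
        mask = chroms == interval.chrom
    sub = GenotypePool(
        name=pool.name,
        genotypes=pool.genotypes[mask],
        positions=pool.positions[mask],
        chrom=interval.chrom,
    )
    return sub


def pools_from_sample_names(samples: Sequence[str]) -> dict[str, list[str]]:
    """Group sample names of the form ``<pool>_<i>`` by pool prefix."""
    out: dict[str, list[str]] = {}
    for s in samples:
        pool = s.rsplit("_", 1)[0]
        out.setdefault(pool, []).append(s)
    return out


def vcf_sample_names(path: str) -> list[str]:
    return list(VCF(path).samples)
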