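"""Synthetic study-shaped inputs: pooled genotype panels, freeze-test
conductivity tables, qPCR Ct tables, and sequences evolved along known trees.

The generator emulates the data model of a nine-pool *Juglans* cold-hardiness
panel: a handful of diploid genomes per species pool, a few dozen candidate
cold-responsive genes (DREB/CBF/ICE1/ZAT-family labels) against a random-gene
background, sweep-like diversity loss in selected pools, and an F1-hybrid
pool with excess intermediate-frequency variation.  All randomness flows
from a single seed through per-gene/per-pool substreams, so identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coalescent, panelio
from .coalescent import (
    Genealogy,
    HaplotypeSet,
    apply_regime,
    drop_mutations,
    pair_into_diploids,
    simulate_genealogy,
)
from .popgen import MISSING, GeneInterval

#: functional labels seen on candidate cold-hardy genes (UniProt-style)
CANDIDATE_LABELS = [
    "DRE1B_ARATH",
    "DREB3_ARATH",
    "DRE2D_ARATH",
    "ERF12_ARATH",
    "ERF80_ARATH",
    "ZAT10_ARATH",
    "ZAT4_ARATH",
    "ICE1_ARATH",
    "EF103_ARATH",
    "EF2_ARATH",
    "CBF1_ARATH",
]

#: labels for background genes, deliberately outside the keyword vocabulary
BACKGROUND_LABELS = [
    "PPO_JUGRE",
    "ACT7_ARATH",
    "TBB1_ARATH",
    "RBL_JUGNI",
    "GAPC_ARATH",
    "HSP70_JUGRE",
    "UBQ10_ARATH",
    "PSBA_JUGRE",
]


@dataclass(frozen=True)
class PoolSpec:
    name: str
    n_diploids: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_diploids <= 16:
            raise ValueError(f"pool {self.name}: n_diploids must be in 1..16")


@dataclass
class GeneSpec:
    gene_id: str
    length: int = 1500
    gene_class: str = "random"  # candidate | random
    label: str = ""
    regimes: Mapping[str, str] = field(default_factory=dict)  # pool -> regime

    def regime_for(self, pool: str) -> str:
        return self.regimes.get(pool, "neutral")


@dataclass
class SimConfig:
    """Full specification of one synthetic panel."""

    seed: int
    pools: Sequence[PoolSpec]
    genes: Sequence[GeneSpec]
    theta: float = 5.0  # 4*N*mu*L per gene per pool
    sweep_scale: float = 0.1
    balancing_boost: float = 5.0
    el_noise_sd: float = 0.01  # relative conductivity noise
    ct_noise_sd: float = 0.2  # Ct cycles
    subs_rate_ladder: Sequence[float] = (0.01, 0.02, 0.05, 0.1)
    hybrid_mode: str = "balancing"  # balancing | admixed
    hybrid_divergence: float = 2.0  # coalescent units, admixed mode only

    def __post_init__(self) -> None:
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError("pool names must be unique")
        gids = [g.gene_id for g in self.genes]
        if len(set(gids)) != len(gids):
            raise ValueError("gene ids must be unique")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0 < self.sweep_scale <= 1:
            raise ValueError("sweep_scale must be in (0, 1]")
        if self.balancing_boost < 1:
            raise ValueError("balancing_boost must be >= 1")
        if self.hybrid_mode not in ("balancing", "admixed"):
            raise ValueError("hybrid_mode must be 'balancing' or 'admixed'")

    def sample_names(self) -> list[str]:
        return [f"{p.name}_{i + 1}" for p in self.pools for i in range(p.n_diploids)]


def layout_genes(genes: Sequence[GeneSpec], spacing: int = 10_000) -> list[GeneInterval]:
    """Place genes round-robin on Chr01..Chr14 with fixed spacing."""
    offsets = {c: 0 for c in panelio.CONTIGS}
    intervals = []
    for i, g in enumerate(genes):
        chrom = panelio.CONTIGS[i % len(panelio.CONTIGS)]
        start = offsets[chrom] + spacing
        offsets[chrom] = start + g.length
        intervals.append(
            GeneInterval(
                gene_id=g.gene_id,
                chrom=chrom,
                start=start,
                end=start + g.length,
                gene_class=g.gene_class,
                label=g.label,
            )
        )
    return intervals


def _simulate_admixed(n_diploids: int, divergence: float, theta: float, rng):
    """Hybrid pool alternative: one haplotype from each of two diverged
    source populations per diploid, plus fixed differences accumulated over
    2 x divergence of independent evolution."""
    if n_diploids < 2:
        raise ValueError("admixed mode needs >= 2 diploids")
    half_theta = theta / 2.0
    hapsets = []
    for _ in range(2):
        tree = simulate_genealogy(n_diploids, rng)
        hapsets.append(drop_mutations(tree, half_theta, rng).haplotypes)
    n_a = hapsets[0].shape[1]
    n_b = hapsets[1].shape[1]
    n_fix = rng.poisson(theta / 2.0 * 2.0 * divergence)
    total = n_a + n_b + n_fix
    haps = np.zeros((2 * n_diploids, total), dtype=np.int8)
    haps[0::2, :n_a] = hapsets[0]  # side A haplotypes
    haps[1::2, n_a : n_a + n_b] = hapsets[1]  # side B haplotypes
    haps[0::2, n_a + n_b :] = 1  # fixed differences, derived on side A
    return haps


def simulate_gene_pool(
    gene: GeneSpec,
    pool: PoolSpec,
    config: SimConfig,
    rng,
) -> np.ndarray:
    """Genotype matrix (sites x diploids) for one gene in one pool.

    Returns raw derived-allele dosages; site positions are assigned at the
    panel level so that positions are unique within each gene.
    """
    regime = gene.regime_for(pool.name)
    if regime == "balancing" and config.hybrid_mode == "admixed":
        haps = _simulate_admixed(pool.n_diploids, config.hybrid_divergence, config.theta, rng)
        geno = haps[0::2] + haps[1::2]
        return geno.T.astype(np.int8)
    n_hap = 2 * pool.n_diploids
    tree = simulate_genealogy(n_hap, rng)
    tree = apply_regime(tree, regime, config.sweep_scale, config.balancing_boost)
    haps = drop_mutations(tree, config.theta, rng)
    return pair_into_diploids(haps, rng)


def emit_panel(
    config: SimConfig,
    vcf_path: str,
    bed_path: str,
) -> tuple[list[GeneInterval], dict]:
    """Simulate every gene x pool and write the VCF + BED panel.

    One biallelic SNP record per segregating site; sites are private to the
    pool in which they arose (all other pools carry the ancestral 0/0 call),
    which is what makes the pools differentiated.  Returns the gene
    intervals and an in-memory map gene id -> {pool: genotype matrix} for
    round-trip checks.
    """
    intervals = layout_genes(config.genes)
    samples = config.sample_names()
    sample_offset = {}
    off = 0
    for p in config.pools:
        sample_offset[p.name] = off
        off += p.n_diploids
    n_samples = off

    root_ss = np.random.SeedSequence(config.seed)
    gene_seeds = root_ss.spawn(len(config.genes))

    records = []
    in_memory: dict[str, dict[str, np.ndarray]] = {}
    for g_idx, (gene, interval) in enumerate(zip(config.genes, intervals)):
        streams = gene_seeds[g_idx].spawn(len(config.pools) + 1)
        pos_rng = np.random.default_rng(streams[-1])
        pool_genos = {}
        total_sites = 0
        for p_idx, pool in enumerate(config.pools):
            rng = np.random.default_rng(streams[p_idx])
            geno = simulate_gene_pool(gene, pool, config, rng)
            pool_genos[pool.name] = geno
            total_sites += geno.shape[0]
        if total_sites > gene.length:
            raise ValueError(
                f"{gene.gene_id}: {total_sites} segregating sites exceed gene length"
            )
        offsets = np.sort(pos_rng.choice(gene.length, size=total_sites, replace=False))
        offsets = pos_rng.permutation(offsets)
        k = 0
        mem_entry = {}
        for pool in config.pools:
            geno = pool_genos[pool.name]
            n_sites = geno.shape[0]
            site_pos = np.sort(offsets[k : k + n_sites])
            k += n_sites
            mem_entry[pool.name] = (site_pos, geno)
            for s in range(n_sites):
                row = np.zeros(n_samples, dtype=np.int8)
                row[sample_offset[pool.name] : sample_offset[pool.name] + pool.n_diploids] = geno[
                    s
                ]
                records.append((interval.chrom, interval.start + int(site_pos[s]), row))
        in_memory[gene.gene_id] = mem_entry
    panelio.write_vcf(records, samples, vcf_path)
    panelio.write_bed(intervals, bed_path)
    return intervals, in_memory


# ---------------------------------------------------------------------------
# electrolyte leakage


EL_COLUMNS = [
    "genotype",
    "species",
    "temperature",
    "replicate",
    "ec_i_frozen",
    "ec_f_frozen",
    "ec_i_control",
    "ec_f_control",
]


def simulate_el_table(
    true_di: pd.DataFrame,
    el_noise_sd: float = 0.01,
    seed=0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Generate a freeze-trial conductivity table from known damage indices.

    ``true_di`` columns: genotype, species (optional), temperature, di with
    di in [0, 100].  For each replicate a control leakage ratio R_o is drawn
    Uniform(0.05, 0.25) and the frozen ratio solves
    R_t = R_o + (di/100) (1 - R_o), so that the damage-index formula
    inverts exactly at zero noise.  Conductivities get multiplicative
    Gaussian noise with relative s.d. ``el_noise_sd``.
    """
    if (true_di["di"] < 0).any() or (true_di["di"] > 100).any():
        raise ValueError("true di must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in true_di.iterrows():
        for rep in range(1, replicates + 1):
            r_o = rng.uniform(0.05, 0.25)
            r_t = r_o + rec["di"] / 100.0 * (1.0 - r_o)
            ec_f_frozen = rng.uniform(500.0, 1500.0)
            ec_f_control = rng.uniform(500.0, 1500.0)
            vals = np.array(
                [r_t * ec_f_frozen, ec_f_frozen, r_o * ec_f_control, ec_f_control]
            )
            if el_noise_sd > 0:
                vals = vals * (1.0 + rng.normal(0.0, el_noise_sd, size=4))
            vals = np.abs(vals)
            # leakage before autoclave cannot exceed the autoclaved total
            vals[0] = min(vals[0], vals[1])
            vals[2] = min(vals[2], vals[3])
            rows.append(
                {
                    "genotype": rec["genotype"],
                    "species": rec.get("species", rec["genotype"]),
                    "temperature": rec["temperature"],
                    "replicate": rep,
                    "ec_i_frozen": vals[0],
                    "ec_f_frozen": vals[1],
                    "ec_i_control": vals[2],
                    "ec_f_control": vals[3],
                }
            )
    return pd.DataFrame(rows, columns=EL_COLUMNS)


# ---------------------------------------------------------------------------
# qPCR


CT_COLUMNS = [
    "sample",
    "species",
    "gene_role",
    "gene",
    "condition",
    "bio_rep",
    "tech_rep",
    "ct",
]


def simulate_ct_table(
    true_fold: pd.DataFrame,
    ct_noise_sd: float = 0.2,
    replicates: tuple[int, int] = (3, 3),
    seed=0,
    control_condition: float = 4.0,
    target_gene: str = "DREB1",
    reference_gene: str = "actin",
) -> pd.DataFrame:
    """Generate a Ct table whose relative-quantification analysis recovers
    known fold changes.

    ``true_fold`` columns: sample, species (optional), condition, fold
    (fold > 0, relative to ``control_condition``).  The treated-condition
    target Ct is shifted by delta-delta-Ct = -log2(fold) relative to the
    control; reference-gene Ct stays flat.  ``replicates`` =
    (biological, technical); every Ct measurement receives N(0, ct_noise_sd)
    noise.  Control-condition rows are emitted for every sample.
    """
    if (true_fold["fold"] <= 0).any():
        raise ValueError("fold changes must be > 0")
    n_bio, n_tech = replicates
    if n_bio < 1 or n_tech < 1:
        raise ValueError("need at least one replicate of each kind")
    rng = np.random.default_rng(seed)
    base_ref = 20.0
    base_target_offset = 5.0  # control-condition delta-Ct
    rows = []

    def emit(sample, species, condition, ddct):
        for role, gene, base in (
            ("target", target_gene, base_ref + base_target_offset + ddct),
            ("reference", reference_gene, base_ref),
        ):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = base + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sample": sample,
                            "species": species,
                            "gene_role": role,
                            "gene": gene,
                            "condition": condition,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": ct,
                        }
                    )

    seen_controls = set()
    for _, rec in true_fold.iterrows():
        sample = rec["sample"]
        species = rec.get("species", sample)
        if sample not in seen_controls:
            emit(sample, species, control_condition, 0.0)
            seen_controls.add(sample)
        if rec["condition"] == control_condition:
            continue
        ddct = -math.log2(rec["fold"])
        emit(sample, species, rec["condition"], ddct)
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# sequence evolution


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def evolve_sequences(tree, length: int, seed) -> dict[str, str]:
    """Evolve site-independent sequences along a tree of
    :class:`coldsig.phylo.Clade` nodes.

    Each node's ``branch_length`` is interpreted as the per-site
    substitution probability on the branch above it (Jukes-Cantor style:
    a substituted site switches to one of the three other bases uniformly).
    Probabilities must lie in [0, 0.75).  Returns {leaf name: sequence}.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    out: dict[str, str] = {}

    def walk(node, seq):
        p = node.branch_length
        if not 0 <= p < 0.75:
            raise ValueError("substitution probability must be in [0, 0.75)")
        if p > 0:
            hit = rng.random(length) < p
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
            seq = seq.copy()
            seq[hit] = (seq[hit] + shift) % 4
        if node.is_leaf:
            out[node.name] = _BASES[seq].tobytes().decode()
        for c in node.children:
            walk(c, seq)

    walk(tree, root_seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
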