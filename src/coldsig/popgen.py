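"""Per-gene population-genetic statistics for pooled diploid panels.

Implements the per-gene, per-pool summary statistics used in selection
scans of candidate genes: segregating sites, nucleotide diversity (pi),
Watterson's theta, Tajima's D, observed heterozygosity, and a
multi-population Weir & Cockerham (1984) F_ST with a Hudson-style pairwise
estimator available as a cross-check.

Conventions
-----------
* Genotypes are derived-allele counts per diploid: 0, 1, 2, or -1 (missing).
* Coordinates are 0-based half-open internally; VCF positions are converted
  at the reader boundary (see :mod:`coldsig.panelio`).
* pi and heterozygosity are reported per bp of the full gene interval
  (invariant sites contribute zero), which is the scale on which per-gene
  heterozygosity in the 0.007-0.03 range is quoted for these panels.
* Tajima's D is undefined when there is no variation or when fewer than 4
  usable alleles are sampled; the two cases are distinguished
  (``no_variation`` vs ``insufficient_samples``) and serialized as "nan"
  and "NA" respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

NA_NO_VARIATION = "no_variation"
NA_INSUFFICIENT = "insufficient_samples"

#: serialization of the two NA flavours in output tables
NA_SERIALIZATION = {NA_NO_VARIATION: "nan", NA_INSUFFICIENT: "NA"}


@dataclass
class GenotypePool:
    """One species pool's diploid genotype matrix over biallelic sites."""

    name: str
    genotypes: np.ndarray  # (sites, diploids) in {0,1,2,MISSING}
    positions: np.ndarray  # (sites,) 0-based coordinates
    chrom: str = ""

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be sites x diploids")
        if self.genotypes.shape[0] != len(self.positions):
            raise ValueError("positions and genotype rows disagree")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or missing (-1)")

    @property
    def n_diploids(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class GeneInterval:
    """An annotated gene window (candidate cold-hardy or random background)."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    gene_class: str = "random"  # candidate | random
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's D for a sample of n alleles."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Closed-form constants of Tajima's D for ``n`` sampled alleles.

    a1 and a2 are harmonic sums; the variance constants e1/e2 are finite for
    n >= 4 (for n in {2, 3} the D variance is undefined but a1 is still
    usable for Watterson's theta).
    """
    if n < 2:
        raise ValueError("need at least 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def _site_mask(pool: GenotypePool, interval: GeneInterval) -> np.ndarray:
    m = (pool.positions >= interval.start) & (pool.positions < interval.end)
    if pool.chrom and interval.chrom:
        if pool.chrom != interval.chrom:
            return np.zeros(len(pool.positions), dtype=bool)
    return m


def _site_summaries(geno: np.ndarray):
    """Per-site non-missing counts, derived-allele counts and het counts."""
    nm = geno != MISSING
    n_nm = nm.sum(axis=1)  # diploids with data per site
    derived = np.where(nm, geno, 0).sum(axis=1)
    het = (geno == 1).sum(axis=1)
    return n_nm, derived, het


def segregating_sites(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> tuple[int, int]:
    """Count segregating sites in ``interval`` for one pool.

    Returns ``(S, n_snps)``: S counts sites where, among non-missing
    diploids, both alleles are present; n_snps additionally requires the
    missing-call fraction to be <= ``max_missing``.  An interval with no
    overlapping sites yields (0, 0).
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    mask = _site_mask(pool, interval)
    geno = pool.genotypes[mask]
    if geno.size == 0:
        return 0, 0
    n_nm, derived, _ = _site_summaries(geno)
    seg = (n_nm > 0) & (derived > 0) & (derived < 2 * n_nm)
    miss_frac = 1.0 - n_nm / pool.n_diploids
    passing = seg & (miss_frac <= max_missing)
    return int(seg.sum()), int(passing.sum())


def _usable_sites(pool: GenotypePool, interval: GeneInterval, max_missing: float):
    """Genotypes at segregating sites passing the missingness filter."""
    mask = _site_mask(pool, interval)
    geno = pool.genotypes[mask]
    if geno.size == 0:
        return geno.reshape(0, pool.n_diploids)
    n_nm, derived, _ = _site_summaries(geno)
    seg = (n_nm > 0) & (derived > 0) & (derived < 2 * n_nm)
    miss_frac = 1.0 - n_nm / pool.n_diploids
    return geno[seg & (miss_frac <= max_missing)]


def _pi_total(geno: np.ndarray) -> float:
    """Sum over sites of expected pairwise differences (unbiased form)."""
    n_nm, derived, _ = _site_summaries(geno)
    m = 2 * n_nm  # alleles with data
    ok = m >= 2
    j = derived[ok].astype(float)
    mm = m[ok].astype(float)
    return float(np.sum(2.0 * j * (mm - j) / (mm * (mm - 1.0))))


def nucleotide_diversity(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> float:
    """Nucleotide diversity pi per bp of the gene interval.

    Per site pi = 2 j (m - j) / (m (m - 1)) with j the derived-allele count
    among the m non-missing alleles; summed over filtered segregating sites
    and divided by the interval length.  NaN when no site has >= 2 usable
    alleles and the pool is entirely missing.
    """
    geno = _usable_sites(pool, interval, max_missing)
    if geno.shape[0] == 0:
        # no variation: pi is zero unless there is literally no data
        if (pool.genotypes[_site_mask(pool, interval)] != MISSING).sum() == 0 and _site_mask(
            pool, interval
        ).sum() > 0:
            return float("nan")
        return 0.0
    return _pi_total(geno) / interval.length


def watterson_theta(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> float:
    """Watterson's theta (S / a1) per bp over the gene interval."""
    geno = _usable_sites(pool, interval, max_missing)
    S = geno.shape[0]
    if S == 0:
        return 0.0
    n = _usable_allele_count(geno, pool)
    if n < 2:
        return float("nan")
    return S / tajima_constants(n).a1 / interval.length


def _usable_allele_count(geno: np.ndarray, pool: GenotypePool) -> int:
    """Single usable allele count for a gene: median across sites of twice
    the non-missing diploid count (one n for the whole window, as in
    windowed VCF implementations)."""
    if geno.shape[0] == 0:
        return 2 * pool.n_diploids
    n_nm = (geno != MISSING).sum(axis=1)
    return int(np.floor(np.median(2 * n_nm)))


@dataclass
class TajimaDResult:
    value: float  # nan when undefined
    na_reason: str | None = None  # NA_NO_VARIATION | NA_INSUFFICIENT | None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None

    def serialized(self) -> str:
        if self.na_reason is not None:
            return NA_SERIALIZATION[self.na_reason]
        return repr(self.value)


def tajimas_d(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> TajimaDResult:
    """Tajima's D for one gene in one pool.

    D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1)) with the constants
    evaluated at the gene's usable allele count.  Returns an NA result with
    reason ``insufficient_samples`` when fewer than 4 usable alleles are
    available, or ``no_variation`` when S = 0.
    """
    geno = _usable_sites(pool, interval, max_missing)
    n = _usable_allele_count(geno, pool)
    if n < 4:
        return TajimaDResult(float("nan"), NA_INSUFFICIENT)
    S = geno.shape[0]
    if S == 0:
        return TajimaDResult(float("nan"), NA_NO_VARIATION)
    const = tajima_constants(n)
    pi_total = _pi_total(geno)
    var = const.e1 * S + const.e2 * S * (S - 1)
    return TajimaDResult((pi_total - S / const.a1) / math.sqrt(var))


def observed_heterozygosity(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> float:
    """Observed heterozygosity per bp over the gene interval.

    (heterozygous calls / non-missing calls at variant sites) scaled by
    (variant sites / interval length).  Zero when the gene is monomorphic;
    NaN when every call is missing.
    """
    mask = _site_mask(pool, interval)
    all_geno = pool.genotypes[mask]
    if all_geno.size > 0 and (all_geno != MISSING).sum() == 0:
        return float("nan")
    geno = _usable_sites(pool, interval, max_missing)
    n_sites = geno.shape[0]
    if n_sites == 0:
        return 0.0
    nm_calls = int((geno != MISSING).sum())
    het_calls = int((geno == 1).sum())
    return het_calls / nm_calls * n_sites / interval.length


@dataclass
class FstResult:
    gene_id: str
    fst: float  # nan if undefined; may be slightly negative
    estimator: str = "weir_cockerham"
    n_sites: int = 0

    @property
    def is_na(self) -> bool:
        return math.isnan(self.fst)


def _wc_site_components(counts_per_pool):
    """Weir & Cockerham (1984) a, b, c variance components for one site.

    ``counts_per_pool``: list of (n_i diploids with data, derived count,
    het count) per pool; pools with no data are excluded by the caller.
    """
    r = len(counts_per_pool)
    n = np.array([c[0] for c in counts_per_pool], dtype=float)
    p = np.array([c[1] for c in counts_per_pool], dtype=float) / (2.0 * n)
    h = np.array([c[2] for c in counts_per_pool], dtype=float) / n
    nbar = n.mean()
    if nbar <= 1 or r < 2:
        return None
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fst_multi_pool(
    pools: Sequence[GenotypePool],
    interval: GeneInterval,
    max_missing: float = 0.5,
    gene_id: str | None = None,
) -> FstResult:
    """Weir & Cockerham multi-population F_ST for one gene.

    Per-site a, b, c variance components are computed across all pools with
    data at the site; the gene value is the "weighted" ratio of summed
    numerators to summed denominators, sum(a) / sum(a+b+c).  Sites are the
    union of positions segregating across the joint panel; sites where fewer
    than 2 pools carry data, or with excess missingness in every pool, are
    skipped.  Negative estimates are reported unclamped; NA when no usable
    site remains.
    """
    gid = gene_id if gene_id is not None else interval.gene_id
    # union of in-interval positions
    pos_union = sorted(
        set().union(*[set(p.positions[_site_mask(p, interval)].tolist()) for p in pools])
    )
    num = 0.0
    den = 0.0
    used = 0
    for pos in pos_union:
        counts = []
        total_j = 0
        total_m = 0
        for p in pools:
            idx = np.nonzero((p.positions == pos) & _site_mask(p, interval))[0]
            if len(idx) == 0:
                g = np.zeros(p.n_diploids, dtype=np.int8)  # monomorphic ancestral
            else:
                g = p.genotypes[idx[0]]
            nm = g != MISSING
            n_i = int(nm.sum())
            if n_i == 0:
                continue
            if 1.0 - n_i / p.n_diploids > max_missing:
                continue
            j = int(g[nm].sum())
            het = int((g[nm] == 1).sum())
            counts.append((n_i, j, het))
            total_j += j
            total_m += 2 * n_i
        if len(counts) < 2 or total_j == 0 or total_j == total_m:
            continue
        comp = _wc_site_components(counts)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
        used += 1
    if used == 0 or den == 0:
        return FstResult(gid, float("nan"), "weir_cockerham", 0)
    return FstResult(gid, num / den, "weir_cockerham", used)


def fst_hudson_pairwise(
    pools: Sequence[GenotypePool],
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> float:
    """Hudson-style F_ST averaged over pool pairs (cross-check estimator).

    For each pair, per site: numerator (p1-p2)^2 - p1 q1/(m1-1) - p2 q2/(m2-1),
    denominator p1 q2 + p2 q1 (allele-frequency form); ratio of sums across
    sites, then an unweighted mean across pairs with data.
    """
    vals = []
    for i in range(len(pools)):
        for j in range(i + 1, len(pools)):
            p1, p2 = pools[i], pools[j]
            pos_union = sorted(
                set(p1.positions[_site_mask(p1, interval)].tolist())
                | set(p2.positions[_site_mask(p2, interval)].tolist())
            )
            num = den = 0.0
            for pos in pos_union:
                freqs = []
                for p in (p1, p2):
                    idx = np.nonzero((p.positions == pos) & _site_mask(p, interval))[0]
                    g = (
                        p.genotypes[idx[0]]
                        if len(idx)
                        else np.zeros(p.n_diploids, dtype=np.int8)
                    )
                    nm = g != MISSING
                    m = 2 * int(nm.sum())
                    if m < 2 or 1.0 - nm.sum() / p.n_diploids > max_missing:
                        freqs = None
                        break
                    freqs.append((int(g[nm].sum()) / m, m))
                if freqs is None:
                    continue
                (f1, m1), (f2, m2) = freqs
                num += (f1 - f2) ** 2 - f1 * (1 - f1) / (m1 - 1) - f2 * (1 - f2) / (m2 - 1)
                den += f1 * (1 - f2) + f2 * (1 - f1)
            if den > 0:
                vals.append(num / den)
    return float(np.mean(vals)) if vals else float("nan")


def gene_stats(
    pool: GenotypePool,
    interval: GeneInterval,
    max_missing: float = 0.5,
) -> dict:
    """All per-gene-per-pool statistics as a flat record."""
    S, n_snps = segregating_sites(pool, interval, max_missing)
    d = tajimas_d(pool, interval, max_missing)
    return {
        "chrom": interval.chrom,
        "gene": interval.gene_id,
        "label": interval.label,
        "class": interval.gene_class,
        "pool": pool.name,
        "S": S,
        "n_snps": n_snps,
        "pi_per_bp": nucleotide_diversity(pool, interval, max_missing),
        "theta_w_per_bp": watterson_theta(pool, interval, max_missing),
        "tajima_d": d.value,
        "tajima_d_na_reason": d.na_reason or "",
        "het_obs_per_bp": observed_heterozygosity(pool, interval, max_missing),
    }


def stats_table(
    pools_by_gene: Mapping[str, Sequence[GenotypePool]] | None = None,
    intervals: Iterable[GeneInterval] = (),
    *,
    pools: Sequence[GenotypePool] | None = None,
    max_missing: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long stats table (one row per gene x pool) plus per-gene F_ST table.

    Either pass ``pools`` (one GenotypePool per pool spanning all genes, as
    loaded from a VCF) or ``pools_by_gene`` mapping gene id -> pool list.
    """
    stat_rows = []
    fst_rows = []
    intervals = list(intervals)
    for interval in intervals:
        if pools_by_gene is not None:
            gene_pools = pools_by_gene[interval.gene_id]
        else:
            assert pools is not None
            gene_pools = pools
        for pool in gene_pools:
            stat_rows.append(gene_stats(pool, interval, max_missing))
        fst = fst_multi_pool(gene_pools, interval, max_missing)
        fst_rows.append(
            {
                "gene": interval.gene_id,
                "chrom": interval.chrom,
                "label": interval.label,
                "class": interval.gene_class,
                "fst": fst.fst,
                "estimator": fst.estimator,
                "n_sites": fst.n_sites,
            }
        )
    stats_df = pd.DataFrame(stat_rows)
    fst_df = pd.DataFrame(fst_rows)
    return stats_df, fst_df


def serialize_stats(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Apply the two-symbol NA policy to the tajima_d column for CSV output."""
    out = stats_df.copy()
    col = []
    for v, reason in zip(out["tajima_d"], out["tajima_d_na_reason"]):
        col.append(NA_SERIALIZATION.get(reason, f"{v:.6g}") if reason else f"{v:.6g}")
    out["tajima_d"] = col
    return out
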