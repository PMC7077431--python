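"""Independent literal-formula oracles used to validate the statistics.

Every function here is a deliberately naive transcription of the published
formulas (explicit loops, no vectorization, no code shared with the
package) so that agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def oracle_tajima_constants(n):
    a1 = 0.0
    a2 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
        a2 += 1.0 / (i * i)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def site_alleles(genotype_row):
    """Expand diploid dosages into a flat allele list, dropping missing."""
    alleles = []
    for g in genotype_row:
        if g == MISSING:
            continue
        if g == 0:
            alleles += [0, 0]
        elif g == 1:
            alleles += [0, 1]
        else:
            alleles += [1, 1]
    return alleles


def oracle_segregating(geno, max_missing):
    """(S, n_snps) by per-column scan."""
    s = 0
    n_pass = 0
    n_dip = geno.shape[1]
    for row in geno:
        alleles = site_alleles(row)
        if alleles and 0 < sum(alleles) < len(alleles):
            s += 1
            n_missing = sum(1 for g in row if g == MISSING)
            if n_missing / n_dip <= max_missing:
                n_pass += 1
    return s, n_pass


def passing_rows(geno, max_missing):
    rows = []
    n_dip = geno.shape[1]
    for row in geno:
        alleles = site_alleles(row)
        if not alleles or not 0 < sum(alleles) < len(alleles):
            continue
        if sum(1 for g in row if g == MISSING) / n_dip > max_missing:
            continue
        rows.append(row)
    return rows


def oracle_pi_total(geno, max_missing):
    """Sum over sites of the average pairwise allele difference
    (brute-force double loop over all allele pairs)."""
    total = 0.0
    for row in passing_rows(geno, max_missing):
        alleles = site_alleles(row)
        m = len(alleles)
        if m < 2:
            continue
        diff = 0
        pairs = 0
        for i in range(m):
            for j in range(i + 1, m):
                pairs += 1
                if alleles[i] != alleles[j]:
                    diff += 1
        total += diff / pairs
    return total


def oracle_usable_n(geno, max_missing, n_diploids):
    rows = passing_rows(geno, max_missing)
    if not rows:
        return 2 * n_diploids
    counts = sorted(len(site_alleles(r)) for r in rows)
    mid = len(counts)
    if mid % 2 == 1:
        med = counts[mid // 2]
    else:
        med = (counts[mid // 2 - 1] + counts[mid // 2]) / 2.0
    return int(math.floor(med))


def oracle_tajimas_d(geno, max_missing, n_diploids):
    """Returns D or the string 'no_variation' / 'insufficient_samples'."""
    n = oracle_usable_n(geno, max_missing, n_diploids)
    if n < 4:
        return "insufficient_samples"
    rows = passing_rows(geno, max_missing)
    S = len(rows)
    if S == 0:
        return "no_variation"
    c = oracle_tajima_constants(n)
    pi = oracle_pi_total(geno, max_missing)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi - S / c["a1"]) / math.sqrt(var)


def oracle_het_per_bp(geno, max_missing, length):
    rows = passing_rows(geno, max_missing)
    if not rows:
        return 0.0
    het = 0
    called = 0
    for row in rows:
        for g in row:
            if g == MISSING:
                continue
            called += 1
            if g == 1:
                het += 1
    return het / called * len(rows) / length


def oracle_wc_fst(pool_genos, max_missing):
    """Weir & Cockerham (1984) theta-hat, literal site-by-site transcription.

    ``pool_genos``: list of (sites x diploids) matrices over a shared site
    index (same rows in every pool).  Returns ratio of summed a components
    to summed a+b+c, or nan.
    """
    n_sites = pool_genos[0].shape[0]
    num = 0.0
    den = 0.0
    for s in range(n_sites):
        ns = []
        ps = []
        hs = []
        for geno in pool_genos:
            row = geno[s]
            alleles = site_alleles(row)
            n_i = len(alleles) // 2
            if n_i == 0:
                continue
            if sum(1 for g in row if g == MISSING) / len(row) > max_missing:
                continue
            ns.append(n_i)
            ps.append(sum(alleles) / len(alleles))
            hs.append(sum(1 for g in row if g == 1) / n_i)
        r = len(ns)
        if r < 2:
            continue
        total_derived = sum(p * 2 * n for p, n in zip(ps, ns))
        total_alleles = sum(2 * n for n in ns)
        if total_derived == 0 or abs(total_derived - total_alleles) < 1e-12:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        cc = hbar / 2.0
        num += a
        den += a + b + cc
    if den == 0:
        return float("nan")
    return num / den


def random_panel(rng, n_sites=None, n_diploids=None, missing_rate=0.1):
    """A random small genotype matrix with occasional missing calls."""
    if n_sites is None:
        n_sites = int(rng.integers(1, 25))
    if n_diploids is None:
        n_diploids = int(rng.integers(4, 9))
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    geno = np.zeros((n_sites, n_diploids), dtype=np.int8)
    for s in range(n_sites):
        geno[s] = rng.binomial(2, freqs[s], size=n_diploids)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING
    return geno
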