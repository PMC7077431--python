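"""Kingman coalescent genealogies with infinite-sites mutation.

Time is measured in units of 2N generations, so the expected pairwise
coalescence time is 1 and the expected number of pairwise differences per
gene equals the scaled mutation rate ``theta`` (= 4N mu L).  Genes are short
enough (a few kb) that recombination within a gene is ignored: one genealogy
per gene per pool.

Three demographic "regimes" distort the genealogy to emulate the footprints
seen in per-gene selection scans:

``neutral``
    The genealogy is left untouched.
``sweep``
    A recent selective sweep leaves a star-like genealogy: all lineages
    coalesce almost simultaneously at a small fraction (``sweep_scale``) of
    the neutral tree height, so nearly every mutation is a rare variant and
    Tajima's D is strongly negative while diversity is purged.
``balancing``
    Balancing selection (or interspecific heterozygosity in an F1 hybrid
    pool) maintains two deep allelic classes: the deepest coalescence is
    stretched by ``balancing_boost``, enriching intermediate-frequency
    variants and pushing Tajima's D positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIMES = ("neutral", "sweep", "balancing")


@dataclass
class Genealogy:
    """A binary coalescent tree over ``n_leaves`` haploid lineages.

    Nodes ``0..n-1`` are leaves (time 0); nodes ``n..2n-2`` are internal,
    created in coalescence order, so a parent always has a larger index than
    its children and node ``2n-2`` is the root.
    """

    n_leaves: int
    parent: np.ndarray  # shape (2n-1,), parent index, -1 at the root
    time: np.ndarray  # shape (2n-1,), node ages (leaves at 0)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lengths

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def height(self) -> float:
        return float(self.time[self.root])

    def leaf_descendants(self) -> np.ndarray:
        """Boolean matrix (n_nodes, n_leaves): leaves below each node."""
        below = np.zeros((self.n_nodes, self.n_leaves), dtype=bool)
        below[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for v in range(self.n_nodes):  # children precede parents by index
            p = self.parent[v]
            if p >= 0:
                below[p] |= below[v]
        return below

    def copy(self) -> "Genealogy":
        return Genealogy(self.n_leaves, self.parent.copy(), self.time.copy())


@dataclass
class HaplotypeSet:
    """Binary haplotypes over the segregating sites of one gene in one pool.

    Rows are haplotypes (2 per diploid), columns are sites; ``positions`` are
    strictly increasing 0-based offsets within the gene interval.  Every
    column is segregating by construction (each mutation falls on a branch
    below the root, so 1 <= derived count <= n-1).
    """

    haplotypes: np.ndarray  # (n_haplotypes, S) in {0, 1}
    positions: np.ndarray  # (S,) increasing ints
    pool: str = ""

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype columns and positions disagree")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genealogy(n_haplotypes: int, seed) -> Genealogy:
    """Simulate a neutral Kingman coalescent tree for ``n_haplotypes`` lineages.

    While k lineages remain, the waiting time to the next coalescence is
    Exponential with rate k(k-1)/2 (time in units of 2N generations) and the
    coalescing pair is uniform among the k choose 2 pairs.

    ``seed`` may be an int, a ``numpy.random.SeedSequence``-compatible value
    or an existing ``numpy.random.Generator`` (consumed in place).
    """
    if n_haplotypes < 2:
        raise ValueError("degenerate sample: need at least 2 haplotypes")
    rng = _as_rng(seed)
    n = n_haplotypes
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        # keep ordering deterministic: drop j first (larger index)
        del active[j], active[i]
        active.append(nxt)
        nxt += 1
    return Genealogy(n, parent, time)


def apply_regime(
    tree: Genealogy,
    regime: str,
    sweep_scale: float = 0.1,
    balancing_boost: float = 5.0,
) -> Genealogy:
    """Return a copy of ``tree`` distorted according to ``regime``.

    neutral: identity.  sweep: every internal coalescence time is set to
    ``sweep_scale`` times the original root height, collapsing the genealogy
    into a star (zero-length internal branches, all mutations on terminal
    branches).  balancing: the root age is multiplied by ``balancing_boost``,
    deepening the basal split.
    """
    if regime not in REGIMES:
        raise ValueError(f"invalid regime {regime!r}; expected one of {REGIMES}")
    out = tree.copy()
    if regime == "neutral":
        return out
    if regime == "sweep":
        if not (0 < sweep_scale <= 1):
            raise ValueError("sweep_scale must be in (0, 1]")
        star_height = tree.height() * sweep_scale
        out.time[tree.n_leaves :] = star_height
        return out
    # balancing
    if balancing_boost < 1:
        raise ValueError("balancing_boost must be >= 1")
    out.time[out.root] *= balancing_boost
    return out


def drop_mutations(
    tree: Genealogy,
    theta: float,
    seed,
    length: int | None = None,
) -> HaplotypeSet:
    """Scatter infinite-sites mutations on ``tree`` at scaled rate ``theta``.

    Each branch receives Poisson(theta/2 x branch length) mutations; every
    mutation creates a new segregating column whose derived allele is carried
    by the leaves under that branch.  If ``length`` is given, site positions
    are drawn uniformly without replacement from ``[0, length)`` and sorted;
    otherwise positions are 0..S-1.  Requires S <= length.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = _as_rng(seed)
    lengths = tree.branch_lengths()
    counts = rng.poisson(theta / 2.0 * lengths)
    counts[tree.root] = 0
    total = int(counts.sum())
    below = tree.leaf_descendants()
    cols = np.zeros((tree.n_leaves, total), dtype=np.int8)
    order = []  # branch index per column, in node order
    c = 0
    for v in range(tree.n_nodes):
        for _ in range(int(counts[v])):
            cols[:, c] = below[v]
            order.append(v)
            c += 1
    if length is None:
        positions = np.arange(total, dtype=np.int64)
    else:
        if total > length:
            raise ValueError("more mutations than available positions")
        positions = np.sort(rng.choice(length, size=total, replace=False))
        # assign positions to mutations in a random order so that a branch's
        # mutations are not spatially clustered
        perm = rng.permutation(total)
        cols = cols[:, perm]
    return HaplotypeSet(haplotypes=cols, positions=positions.astype(np.int64))


def pair_into_diploids(haps: HaplotypeSet, rng) -> np.ndarray:
    """Randomly pair haplotypes into diploid genotypes (sites x diploids).

    Entries are derived-allele counts in {0, 1, 2}.  ``haps`` must contain an
    even number of haplotype rows.  No inbreeding structure: pairing is a
    uniform random perfect matching.
    """
    n = haps.n_haplotypes
    if n % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    rng = _as_rng(rng)
    perm = rng.permutation(n)
    h = haps.haplotypes[perm]
    geno = h[0::2] + h[1::2]  # (n/2, S)
    return geno.T.astype(np.int8)
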