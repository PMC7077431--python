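"""Distance-based phylogenies: alignment-free k-mer distances, similarity
matrix conversion, neighbor joining, Newick I/O and clade queries.

The k-mer route mirrors assembly-and-alignment-free genome phylogenies:
each taxon is reduced to its set of canonical k-mers and the pairwise
distance is d = -ln(F)/k where F is the fraction of shared k-mers relative
to the smaller set.  Trees are built with Saitou & Nei neighbor joining,
which recovers additive distance matrices exactly.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerProfile:
    """Canonical k-mer content of one taxon's sequence set."""

    label: str
    k: int
    kmers: frozenset
    total: int  # k-mers counted (with multiplicity) before set reduction


def kmer_profile(sequences, k: int = 25, label: str = "") -> KmerProfile:
    """Build the canonical k-mer set of a sequence collection.

    ``sequences`` is an iterable of DNA strings (or a single string); k must
    be odd so a k-mer can never equal its own reverse complement.  K-mers
    containing characters outside ACGT are skipped.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    if isinstance(sequences, str):
        sequences = [sequences]
    kmers = set()
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if not _VALID.issuperset(kmer):
                continue
            kmers.add(canonical_kmer(kmer))
            total += 1
    if not kmers:
        raise ValueError("no usable k-mers in input sequences")
    return KmerProfile(label=label, k=k, kmers=frozenset(kmers), total=total)


def kmer_profile_from_fasta(path: str, k: int = 25, label: str | None = None) -> KmerProfile:
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]
    if label is None:
        label = path
    return kmer_profile(seqs, k=k, label=label)


def aaf_distance(a: KmerProfile, b: KmerProfile, d_max: float = 1.0) -> float:
    """Logarithmic shared-k-mer distance between two profiles.

    F = |A intersect B| / min(|A|, |B|); d = -(1/k) ln F.  Identical sets
    give 0; disjoint sets are mapped to the cap ``d_max``.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    shared = len(a.kmers & b.kmers)
    if shared == 0:
        return d_max
    f = shared / min(len(a.kmers), len(b.kmers))
    return -math.log(f) / a.k


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)

    @classmethod
    def from_profiles(cls, profiles: Sequence[KmerProfile], d_max: float = 1.0):
        n = len(profiles)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = aaf_distance(profiles[i], profiles[j], d_max)
        return cls([p.label for p in profiles], m)

    @classmethod
    def read_csv(cls, path: str):
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def similarity_to_distance(similarity: pd.DataFrame | DistanceMatrix) -> DistanceMatrix:
    """Convert a non-negative similarity matrix to distances.

    d(i, j) = 1 - s(i, j)/max(s); the diagonal is forced to zero.  The input
    must be symmetric to 1e-6 and have a positive maximum.
    """
    if isinstance(similarity, DistanceMatrix):
        labels, s = similarity.labels, similarity.values
    else:
        labels, s = list(similarity.columns), similarity.to_numpy(dtype=float)
    if not np.allclose(s, s.T, atol=1e-6):
        raise ValueError("similarity matrix is not symmetric")
    if (s < 0).any():
        raise ValueError("similarities must be non-negative")
    smax = s.max()
    if smax <= 0:
        raise ValueError("similarity matrix has no positive entries")
    d = 1.0 - s / smax
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d.clip(min=0.0))


# ---------------------------------------------------------------------------
# trees


@dataclass
class Clade:
    """A rooted tree node; trees from NJ are interpreted as unrooted."""

    name: str = ""
    branch_length: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list:
        return [l.name for l in self.leaves()]


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary root, plus NJ metadata."""

    root: Clade
    negative_branches_clamped: int = 0

    def leaf_names(self) -> list:
        return self.root.leaf_names()

    def splits(self) -> set:
        """Non-trivial bipartitions as frozensets of the smaller side's names."""
        all_leaves = frozenset(self.leaf_names())
        out = set()

        def walk(node):
            below = frozenset(node.leaf_names())
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        names = sorted(self.leaf_names())
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node):
            """Return {leaf: depth below node}; accumulate cross distances."""
            if node.is_leaf:
                return {node.name: 0.0}
            merged: dict = {}
            for c in walk_children(node):
                for a, da in merged.items():
                    for b, db in c.items():
                        d = da + db
                        dist[index[a], index[b]] = dist[index[b], index[a]] = d
                merged.update(c)
            return merged

        def walk_children(node):
            for c in node.children:
                sub = walk(c)
                yield {k: v + c.branch_length for k, v in sub.items()}

        walk(self.root)
        return DistanceMatrix(names, dist)

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.branch_length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(parse_newick(text))


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+|:")


def parse_newick(text: str) -> Clade:
    """Parse a Newick string (leaf names + branch lengths, no inner labels)."""
    tokens = [t for t in _TOKEN.findall(text.strip()) if t.strip()]
    pos = 0

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            if tokens[pos] != ")":
                raise ValueError("unbalanced parentheses in newick")
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),;:":
            node.name = tokens[pos]
            pos += 1
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 1
            node.branch_length = float(tokens[pos])
            pos += 1
        return node

    root = parse_clade()
    if pos >= len(tokens) or tokens[pos] != ";":
        raise ValueError("newick string must end with ';'")
    return root


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor joining with a deterministic tie-break.

    Among pairs minimizing the Q criterion (ties at 1e-12), the pair whose
    (lexicographically sorted) smallest-leaf-label key is lowest is joined.
    Negative branch lengths are clamped to zero and counted.  Exact on
    additive matrices.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes = [Clade(name=str(l)) for l in matrix.labels]
    keys = [min(str(l) for l in c.leaf_names()) for c in nodes]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = Clade(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [new]
        keys = [keys[x] for x in keep] + [min(k for k in (keys[i], keys[j]))]

    a, b = nodes
    d_ab = clamp(D[0, 1])
    # attach the remaining edge: root the unrooted tree along it
    if a.is_leaf and not b.is_leaf:
        a, b = b, a
    if b.is_leaf:
        b.branch_length = d_ab
        a.children.append(b)
        root = a
    else:
        a.branch_length = d_ab / 2.0
        b.branch_length = d_ab / 2.0
        root = Clade(children=[a, b])
    root.branch_length = 0.0
    return PhyloTree(root=root, negative_branches_clamped=clamped)


def clade_check(tree: PhyloTree, focal_label: str, group_labels: Iterable[str]) -> bool:
    """True iff some edge bisection isolates ``focal`` with exactly ``group``.

    The query side must equal {focal} union group; all remaining leaves fall
    on the other side.  Unknown labels raise.
    """
    group = set(group_labels)
    all_leaves = set(tree.leaf_names())
    unknown = ({focal_label} | group) - all_leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    want = frozenset({focal_label} | group)
    if want == frozenset(all_leaves):
        return True
    complement = frozenset(all_leaves - want)
    target = min(want, complement, key=lambda s: (len(s), sorted(s)))
    if len(want) == 1 or len(complement) == 1:
        # trivial pendant split: focal alone never groups with a non-empty set
        return len(complement) == 1
    return target in tree.splits()


def random_additive_tree(labels: Sequence[str], rng) -> tuple[PhyloTree, DistanceMatrix]:
    """Random binary tree with positive branch lengths and its path metric.

    Used as the NJ correctness oracle: NJ must reconstruct the generating
    topology and path-length matrix from the returned additive matrix.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nodes = [Clade(name=str(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.branch_length = float(rng.uniform(0.1, 1.0))
        b.branch_length = float(rng.uniform(0.1, 1.0))
        merged = Clade(children=[b, a])
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)] + [merged]
    for c in nodes:
        c.branch_length = float(rng.uniform(0.1, 1.0))
    tree = PhyloTree(root=Clade(children=list(nodes)))
    return tree, tree.leaf_distance_matrix()
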