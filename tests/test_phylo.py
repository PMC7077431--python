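"""K-mer distances, similarity conversion, NJ correctness, clade queries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coldsig import phylo
from coldsig.phylo import (
    Clade,
    DistanceMatrix,
    PhyloTree,
    aaf_distance,
    clade_check,
    kmer_profile,
    neighbor_joining,
    parse_newick,
    random_additive_tree,
    similarity_to_distance,
)
from coldsig.simulate import evolve_sequences


class TestKmerProfile:
    def test_acgt_k3_collapses_to_single_canonical_kmer(self):
        # "ACGT" has 3-mers ACG and CGT, which are reverse complements
        prof = kmer_profile("ACGT", k=3)
        assert len(prof.kmers) == 1

    def test_reverse_complement_gives_identical_profile(self):
        seq = "ACGTTGCAATCGGCTAAGCTT"
        rc = phylo.reverse_complement(seq)
        assert kmer_profile(seq, k=5).kmers == kmer_profile(rc, k=5).kmers

    def test_ambiguous_bases_skipped(self):
        prof = kmer_profile("ACGNNACG", k=3)
        assert all("N" not in k for k in prof.kmers)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_profile("ACGTACGT", k=4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            kmer_profile("NNNN", k=3)


class TestAafDistance:
    def test_identical_profiles_give_zero(self):
        p = kmer_profile("ACGTACGTTGCA" * 10, k=5)
        assert aaf_distance(p, p) == 0.0

    def test_disjoint_profiles_capped(self):
        a = kmer_profile("AAAAAAAAAA", k=3, label="a")
        b = kmer_profile("CCCCCCCCCC", k=3, label="b")
        assert aaf_distance(a, b, d_max=1.0) == 1.0

    def test_symmetry_and_nonnegativity(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=300)) for _ in range(4)]
        profs = [kmer_profile(s, k=7, label=str(i)) for i, s in enumerate(seqs)]
        for a in profs:
            for b in profs:
                assert aaf_distance(a, b) == pytest.approx(aaf_distance(b, a))
                assert aaf_distance(a, b) >= 0

    def test_k_mismatch_rejected(self):
        a = kmer_profile("ACGTACGT", k=3)
        b = kmer_profile("ACGTACGT", k=5)
        with pytest.raises(ValueError, match="k mismatch"):
            aaf_distance(a, b)

    def test_distance_monotone_in_substitution_rate(self):
        rates = [0.005, 0.01, 0.02, 0.04, 0.08, 0.16]
        dists = []
        for rate in rates:
            tree = Clade(children=[
                Clade(name="anchor", branch_length=0.0),
                Clade(name="leaf", branch_length=rate),
            ])
            seqs = evolve_sequences(tree, 20000, seed=12345)
            anchor = kmer_profile(seqs["anchor"], k=15, label="anchor")
            leaf = kmer_profile(seqs["leaf"], k=15, label="leaf")
            dists.append(aaf_distance(anchor, leaf))
        assert all(b > a for a, b in zip(dists, dists[1:]))
        assert sps.spearmanr(rates, dists).statistic > 0.95


class TestSimilarityConversion:
    def test_identity_similarity_gives_unit_distances(self):
        s = pd.DataFrame(np.eye(4) * 7.0, columns=list("abcd"), index=list("abcd"))
        d = similarity_to_distance(s)
        off = d.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_constant_max_similarity_gives_zero_distances(self):
        s = pd.DataFrame(np.full((3, 3), 4.2), columns=list("abc"), index=list("abc"))
        assert np.allclose(similarity_to_distance(s).values, 0.0)

    def test_hand_worked_matrix(self):
        s = pd.DataFrame(
            [[10.0, 5.0, 2.0, 1.0],
             [5.0, 10.0, 4.0, 2.0],
             [2.0, 4.0, 10.0, 8.0],
             [1.0, 2.0, 8.0, 10.0]],
            columns=list("abcd"), index=list("abcd"),
        )
        d = similarity_to_distance(s)
        assert d.values[0, 1] == pytest.approx(0.5)
        assert d.values[0, 3] == pytest.approx(0.9)
        assert d.values[2, 3] == pytest.approx(0.2)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_asymmetric_matrix_rejected(self):
        s = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], columns=list("ab"), index=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            similarity_to_distance(s)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(a,b)=3, d(a,c)=4, d(b,c)=5 -> la=1, lb=2, lc=3
        dm = DistanceMatrix(list("abc"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = neighbor_joining(dm)
        pat = tree.leaf_distance_matrix()
        assert np.allclose(pat.values, dm.values)
        lengths = {l.name: l.branch_length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(100):
            true_tree, dm = random_additive_tree(labels, rng)
            est = neighbor_joining(dm)
            assert est.splits() == true_tree.splits()
            est_d = est.leaf_distance_matrix()
            assert np.allclose(est_d.values, dm.values, atol=1e-9)

    def test_label_order_invariance(self, rng):
        labels = [f"t{i}" for i in range(7)]
        _, dm = random_additive_tree(labels, rng)
        perm = rng.permutation(len(labels))
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm).splits() == neighbor_joining(dm2).splits()

    def test_agrees_with_dendropy_on_random_matrix(self, rng):
        dendropy = pytest.importorskip("dendropy")
        labels = [f"t{i}" for i in range(8)]
        _, dm = random_additive_tree(labels, rng)
        mine = neighbor_joining(dm)
        csv = "," + ",".join(dm.labels) + "\n"
        for i, lab in enumerate(dm.labels):
            csv += lab + "," + ",".join(str(v) for v in dm.values[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        ref = pdm.nj_tree()
        ref.encode_bipartitions()
        ref_splits = set()
        all_taxa = frozenset(t.label for t in ref.taxon_namespace)
        for edge in ref.preorder_edge_iter():
            if edge.bipartition:
                side = frozenset(
                    t.label for t in edge.bipartition.leafset_taxa(ref.taxon_namespace)
                )
                if 1 < len(side) < len(all_taxa) - 1:
                    other = all_taxa - side
                    ref_splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert mine.splits() == ref_splits

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(list("ab"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_negative_branches_clamped_and_flagged(self):
        # a non-additive matrix known to produce a negative NJ branch
        vals = np.array(
            [[0, 2, 2, 2.0],
             [2, 0, 0.1, 2],
             [2, 0.1, 0, 2],
             [2, 2, 2, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), vals))
        lengths = []

        def collect(node):
            lengths.append(node.branch_length)
            for c in node.children:
                collect(c)

        collect(tree.root)
        assert min(lengths) >= 0.0


class TestNewick:
    def test_round_trip(self, rng):
        _, dm = random_additive_tree([f"t{i}" for i in range(6)], rng)
        tree = neighbor_joining(dm)
        text = tree.newick()
        back = PhyloTree.from_newick(text)
        assert back.splits() == tree.splits()
        assert np.allclose(
            back.leaf_distance_matrix().values,
            tree.leaf_distance_matrix().values,
            atol=1e-9,
        )

    def test_parse_rejects_missing_terminator(self):
        with pytest.raises(ValueError):
            parse_newick("(a:1,b:2)")


class TestCladeCheck:
    def _tree(self):
        return PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);")

    def test_cherry_partner_detected(self):
        assert clade_check(self._tree(), "a", ["b"])

    def test_cross_clade_grouping_rejected(self):
        assert not clade_check(self._tree(), "a", ["c"])

    def test_pendant_complement_is_a_valid_bisection(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        assert clade_check(tree, "a", ["b", "c", "d"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            clade_check(self._tree(), "zz", ["a"])

    def test_recovers_generating_topology_from_sequences(self, rng):
        hits = 0
        reps = 30
        for i in range(reps):
            tree = Clade(children=[
                Clade(branch_length=0.04, children=[
                    Clade(name="a1", branch_length=0.02),
                    Clade(name="a2", branch_length=0.02),
                ]),
                Clade(branch_length=0.04, children=[
                    Clade(name="b1", branch_length=0.02),
                    Clade(name="b2", branch_length=0.02),
                ]),
            ])
            seqs = evolve_sequences(tree, 30000, seed=1000 + i)
            profs = [kmer_profile(s, k=15, label=n) for n, s in sorted(seqs.items())]
            est = neighbor_joining(DistanceMatrix.from_profiles(profs))
            if clade_check(est, "a1", ["a2"]):
                hits += 1
        assert hits / reps >= 0.95


class TestEvolveSequences:
    def test_zero_probability_keeps_sequences_identical(self):
        tree = Clade(children=[Clade(name="x"), Clade(name="y")])
        seqs = evolve_sequences(tree, 500, seed=3)
        assert seqs["x"] == seqs["y"]

    def test_invalid_probability_rejected(self):
        tree = Clade(children=[Clade(name="x", branch_length=0.8)])
        with pytest.raises(ValueError):
            evolve_sequences(tree, 100, seed=0)
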