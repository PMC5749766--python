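import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from panmeta.phylogeny import (
    ConcatenatedAlignment,
    DistanceMatrix,
    align_core_cluster,
    bootstrap_support,
    concatenate,
    neighbor_joining,
    poisson_distance,
    tree_bipartitions,
)
from panmeta.seqio import GeneRecord
from panmeta.synthetic_data import generate_planted_tree

from _oracles import gotoh_oracle
from test_clustering import blosum


def to_common_namespace(reference: dendropy.Tree, other: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=other.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=reference.taxon_namespace,
        preserve_underscores=True,
    )


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    b = to_common_namespace(a, b)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestAlignCoreCluster:
    def test_identical_sequences_no_gaps(self):
        seq = "MKVLITGAGSGIG"
        records = [GeneRecord(f"g{i}", f"s{i}", seq) for i in range(4)]
        aligned = align_core_cluster(records)
        assert all(r.sequence == seq for r in aligned)

    def test_single_gap_optimal(self):
        records = [GeneRecord("a", "s1", "ACDE"), GeneRecord("b", "s2", "ACE")]
        aligned = align_core_cluster(records)
        by_id = {r.id: r.sequence for r in aligned}
        assert len(by_id["a"]) == len(by_id["b"]) == 4
        assert by_id["a"] == "ACDE"
        assert by_id["b"].count("-") == 1
        # non-gap columns identical
        for x, y in zip(by_id["a"], by_id["b"]):
            if y != "-":
                assert x == y
        # the pairwise alignment score is optimal per the exhaustive DP oracle
        score, _, _ = gotoh_oracle("ACDE", "ACE", blosum)
        realized = 0
        gap_run = 0
        for x, y in zip(by_id["a"], by_id["b"]):
            if y == "-" or x == "-":
                gap_run += 1
            else:
                realized += blosum(x, y)
        realized -= 11 + gap_run  # one gap of length 1
        assert realized == score

    def test_single_sequence_warning(self, caplog):
        records = [GeneRecord("a", "s1", "ACDE")]
        with caplog.at_level("WARNING"):
            assert align_core_cluster(records) == records
        assert any("single sequence" in r.message for r in caplog.records)

    def test_prealigned_validation(self):
        records = [GeneRecord("a", "s1", "AC-E"), GeneRecord("b", "s2", "ACDE")]
        assert align_core_cluster(records, prealigned=True) == records
        bad = [GeneRecord("a", "s1", "ACE"), GeneRecord("b", "s2", "ACDE")]
        with pytest.raises(ValueError, match="unequal"):
            align_core_cluster(bad, prealigned=True)

    def test_empty(self):
        with pytest.raises(ValueError):
            align_core_cluster([])


class TestConcatenate:
    def _alignments(self):
        return {
            "c1": [
                GeneRecord("g1", "s1", "A" * 10),
                GeneRecord("g2", "s2", "C" * 10),
            ],
            "c2": [
                GeneRecord("g3", "s1", "D" * 15),
                GeneRecord("g4", "s2", "E" * 15),
            ],
        }

    def test_widths_and_boundaries(self):
        concat = concatenate(self._alignments(), ["s1", "s2"], ["c1", "c2"])
        assert concat.width == 25
        assert concat.boundaries == [(0, 10), (10, 25)]
        assert concat.sequences["s1"] == "A" * 10 + "D" * 15

    def test_missing_strain_named(self):
        alignments = self._alignments()
        alignments["c2"] = alignments["c2"][:1]  # drop s2 from c2
        with pytest.raises(ValueError, match=r"c2.*s2"):
            concatenate(alignments, ["s1", "s2"], ["c1", "c2"])

    def test_duplicate_strain(self):
        alignments = {"c1": [GeneRecord("g1", "s1", "AA"), GeneRecord("g2", "s1", "CC")]}
        with pytest.raises(ValueError, match="more than once"):
            concatenate(alignments, ["s1"], ["c1"])

    def test_order_permutation_same_distances(self):
        alignments = self._alignments()
        d1 = poisson_distance(concatenate(alignments, ["s1", "s2"], ["c1", "c2"]))
        d2 = poisson_distance(concatenate(alignments, ["s1", "s2"], ["c2", "c1"]))
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_total_width_is_sum(self):
        rng = np.random.default_rng(2)
        alignments = {}
        widths = []
        for i in range(20):
            w = int(rng.integers(5, 40))
            widths.append(w)
            alignments[f"c{i:02d}"] = [
                GeneRecord(f"g{i}a", "s1", "A" * w),
                GeneRecord(f"g{i}b", "s2", "A" * w),
            ]
        concat = concatenate(alignments, ["s1", "s2"], sorted(alignments))
        assert concat.width == sum(widths)


class TestPoissonDistance:
    def test_identical_rows(self):
        concat = ConcatenatedAlignment(
            {"s1": "ACDE", "s2": "ACDE"}, [(0, 4)], ["c1"]
        )
        dm = poisson_distance(concat)
        assert dm["s1", "s2"] == 0.0

    def test_closed_form(self):
        # p = 0.3  ->  d = -ln(0.7)
        seq_a = "A" * 10
        seq_b = "C" * 3 + "A" * 7
        dm = poisson_distance(
            ConcatenatedAlignment({"s1": seq_a, "s2": seq_b}, [(0, 10)], ["c1"])
        )
        assert dm["s1", "s2"] == pytest.approx(-math.log(0.7), abs=1e-9)
        assert dm["s1", "s2"] == pytest.approx(0.356675, abs=1e-6)

    def test_pairwise_deletion_bookkeeping(self):
        concat = ConcatenatedAlignment(
            {"s1": "AAAA", "s2": "AA--", "s3": "CCAA"}, [(0, 4)], ["c1"]
        )
        dm = poisson_distance(concat)
        # pair (s1, s2) uses 2 shared columns, both matching -> p = 0
        assert dm["s1", "s2"] == 0.0
        # pair (s2, s3) uses 2 columns, both mismatching -> saturated
        assert dm.saturated[dm.labels.index("s2"), dm.labels.index("s3")]

    def test_zero_shared_columns_error(self):
        concat = ConcatenatedAlignment(
            {"s1": "AA--", "s2": "--AA"}, [(0, 4)], ["c1"]
        )
        with pytest.raises(ValueError, match="s1.*s2"):
            poisson_distance(concat)

    def test_d_geq_p(self):
        rng = np.random.default_rng(4)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {
            f"s{i}": "".join(rng.choice(alphabet, 200)) for i in range(5)
        }
        dm = poisson_distance(ConcatenatedAlignment(seqs, [(0, 200)], ["c"]))
        mats = np.array(
            [np.frombuffer(seqs[f"s{i}"].encode(), dtype=np.uint8) for i in range(5)]
        )
        for i in range(5):
            for j in range(i + 1, 5):
                p = np.mean(mats[i] != mats[j])
                assert dm.values[i, j] >= p - 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        values = np.array(
            [[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]]
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], values))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        # three-point formulas: a = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(3.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(6.0)

    def test_four_taxon_additive_recovery(self):
        # planted topology ((A,B),(C,D)) with branches 1, 2, 5(internal), 3, 4
        labels = ["A", "B", "C", "D"]
        values = np.array(
            [
                [0.0, 3.0, 9.0, 10.0],
                [3.0, 0.0, 10.0, 11.0],
                [9.0, 10.0, 0.0, 7.0],
                [10.0, 11.0, 7.0, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels, values))
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == pytest.approx([5.0])

    def test_consistency_on_additive_matrices(self):
        for seed in range(10):
            tree, dm = generate_planted_tree(8, seed=seed)
            assert rf_distance(tree, neighbor_joining(dm)) == 0

    def test_taxon_order_invariance(self):
        tree, dm = generate_planted_tree(7, seed=9)
        perm = np.random.default_rng(0).permutation(7)
        labels = [dm.labels[i] for i in perm]
        values = dm.values[np.ix_(perm, perm)]
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(DistanceMatrix(labels, values))
        assert rf_distance(t1, t2) == 0
        total1 = sum(e.length for e in t1.preorder_edge_iter() if e.length)
        total2 = sum(e.length for e in t2.preorder_edge_iter() if e.length)
        assert total1 == pytest.approx(total2, abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
            )

    def test_saturated_entries_rejected(self):
        values = np.array(
            [[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(DistanceMatrix(["A", "B", "C"], values))


def two_group_alignment() -> ConcatenatedAlignment:
    """8 strains in two clean 4-strain groups with within-group structure."""
    strains = [f"s{i}" for i in range(1, 9)]
    cols = {s: [] for s in strains}
    for _ in range(60):  # group split: s1-4 vs s5-8
        for s in strains:
            cols[s].append("A" if s in {"s1", "s2", "s3", "s4"} else "C")
    for _ in range(30):  # cherry {s1, s2}
        for s in strains:
            cols[s].append("D" if s in {"s1", "s2"} else "E")
    for _ in range(30):  # cherry {s5, s6}
        for s in strains:
            cols[s].append("F" if s in {"s5", "s6"} else "G")
    for _ in range(20):  # constant columns
        for s in strains:
            cols[s].append("K")
    width = 140
    return ConcatenatedAlignment(
        {s: "".join(c) for s, c in cols.items()}, [(0, width)], ["c1"]
    )


class TestBootstrap:
    def test_clean_group_split_support_100(self):
        concat = two_group_alignment()
        tree, supports = bootstrap_support(concat, n_replicates=100, seed=42)
        group1 = frozenset({"s1", "s2", "s3", "s4"})
        key = min(
            group1,
            frozenset(concat.sequences) - group1,
            key=lambda s: tuple(sorted(s)),
        )
        assert supports[key] == 100.0

    def test_seed_determinism(self):
        concat = two_group_alignment()
        _, a = bootstrap_support(concat, 50, seed=7)
        _, b = bootstrap_support(concat, 50, seed=7)
        assert a == b

    def test_single_replicate_support_binary(self):
        concat = two_group_alignment()
        _, supports = bootstrap_support(concat, n_replicates=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_column_order_invariance(self):
        concat = two_group_alignment()
        rng = np.random.default_rng(1)
        perm = rng.permutation(concat.width)
        shuffled = ConcatenatedAlignment(
            {
                s: "".join(seq[i] for i in perm)
                for s, seq in concat.sequences.items()
            },
            [(0, concat.width)],
            ["c1"],
        )
        _, a = bootstrap_support(concat, 100, seed=5)
        _, b = bootstrap_support(shuffled, 100, seed=5)
        everyone = frozenset(concat.sequences)

        def norm(side):
            return min(side, everyone - side, key=lambda s: tuple(sorted(s)))

        # clean signal: the planted bipartitions reach 100 either way
        for side in (frozenset({"s1", "s2"}), frozenset({"s5", "s6"})):
            assert a[norm(side)] == 100.0
            assert b[norm(side)] == 100.0

    def test_narrow_alignment_rejected(self):
        concat = ConcatenatedAlignment({"s1": "A", "s2": "C", "s3": "A"}, [(0, 1)], ["c"])
        with pytest.raises(ValueError, match="2 columns"):
            bootstrap_support(concat, 10, seed=1)

    def test_support_attached_to_tree_labels(self):
        concat = two_group_alignment()
        tree, supports = bootstrap_support(concat, 10, seed=2)
        labeled = [
            n.label
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert labeled  # at least one internal node carries a support label
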