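"""Classification: residue rules, distances, neighbor joining, clades."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquasig.classify import (DistanceMatrix, assign_by_clade,
                              classify_by_residues, neighbor_joining,
                              pdistance_matrix, tip_subtype)
from aquasig.errors import AnalysisError, ValidationError
from aquasig.seqio import Alignment, ProteinRecord, alignment_from_strings
from aquasig.synth import GROUP_IDS, make_reference_panel

from .oracles import (best_topology_by_ls, phylo_tree_splits,
                      random_additive_tree, tree_splits)


class TestResidueClassification:
    def test_group_fixtures_get_intended_classes(self, extractions):
        expected = {
            "FaPIP1;1": "PIP1", "FaPIP1;2": "PIP1", "FaPIP1;3": "PIP1",
            "FaPIP2;1(a)": "PIP2", "FaPIP2;1(b)": "PIP2", "FaPIP2;2": "PIP2",
            "FaTIP(a)": "TIP", "FaTIP(b)": "TIP",
        }
        for gid, ext in extractions.items():
            assert classify_by_residues(ext).class_name == expected[gid], gid

    def test_unknown_filter_yields_unknown(self, extractions):
        # NIP-like Ar/R filters match no rule and stay unclassified
        ext = extractions["FaPIP1;1"]
        mutated = dict(ext.positions)
        for name, res in zip(("arr.H2", "arr.H5", "arr.LE1", "arr.LE2"), "WVAR"):
            coord, qc, _ = mutated[name]
            mutated[name] = (coord, qc, res)
        ext2 = type(ext)(query_id="mut", class_hint=ext.class_hint,
                         positions=mutated, annotation=ext.annotation)
        assert classify_by_residues(ext2).class_name == "unknown"

    @pytest.mark.parametrize("window,expected", [
        ("RKSTAR", "alpha-TIP"),
        ("TEGR", "delta-TIP"),
        ("GTSGG", "other"),        # conserved Thr, motifs absent
    ])
    def test_tip_subtype_motifs(self, window, expected):
        assert tip_subtype(window) == expected


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = alignment_from_strings([("a", "AAAA"), ("b", "AAAA"),
                                      ("c", "AAAA")])
        assert np.allclose(pdistance_matrix(aln).matrix, 0)

    def test_quarter_mismatch(self):
        aln = alignment_from_strings([("a", "AAAA"), ("b", "AAAT"),
                                      ("c", "AAAA")])
        assert pdistance_matrix(aln).matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        aln = alignment_from_strings([("a", "A-AA"), ("b", "AGAT"),
                                      ("c", "AAAA")])
        assert pdistance_matrix(aln).matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors(self):
        aln = alignment_from_strings([("a", "A--"), ("b", "-GG"),
                                      ("c", "AGG")])
        with pytest.raises(AnalysisError, match="a.*b"):
            pdistance_matrix(aln)

    def test_invariant_to_row_order(self):
        rows = [("a", "AAGT"), ("b", "ACGT"), ("c", "TTGT"), ("d", "AAGG")]
        base = pdistance_matrix(alignment_from_strings(rows))
        for perm in itertools.permutations(range(4)):
            shuffled = pdistance_matrix(
                alignment_from_strings([rows[i] for i in perm]))
            for i, j in itertools.combinations(range(4), 2):
                assert shuffled.matrix[i, j] == pytest.approx(
                    base.matrix[perm[i], perm[j]])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(("a", "b", "c"),
                           np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        tree = neighbor_joining(d)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_additive_four_taxon_exact(self):
        # from ((a:1,b:2):1,(c:3,d:1)); the ab|cd split with exact lengths
        m = np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                      [5, 6, 0, 4], [3, 4, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), m))
        splits = phylo_tree_splits(tree, ["a", "b", "c", "d"])
        assert frozenset({"a", "b"}) in splits
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0}

    def test_duplicated_taxon_zero_cherry(self):
        m = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 1], [1, 1, 1, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), m))
        splits = phylo_tree_splits(tree, ["a", "b", "c", "d"])
        assert frozenset({"a", "b"}) in splits

    def test_negative_branch_lengths_clamped(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 5
            m = rng.uniform(0.1, 1.0, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = neighbor_joining(DistanceMatrix(tuple("abcde"), m))

            def walk(node):
                assert node.length >= 0
                for ch in node.children:
                    walk(ch)
            walk(tree.root)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        m = np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                      [5, 6, 0, 4], [3, 4, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), m))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set("abcd")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 8))
    def test_recovers_random_additive_topologies(self, seed, n):
        # property: NJ is consistent on additive distances
        taxa = [f"t{i}" for i in range(n)]
        rng = np.random.default_rng(seed)
        gen_tree, _, d = random_additive_tree(taxa, rng)
        mine = neighbor_joining(DistanceMatrix(tuple(taxa), d))
        assert phylo_tree_splits(mine, taxa) == tree_splits(gen_tree, taxa)

    def test_matches_exhaustive_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        for n in (4, 5):
            taxa = [f"t{i}" for i in range(n)]
            for _ in range(10):
                _, _, d = random_additive_tree(taxa, rng)
                mine = neighbor_joining(DistanceMatrix(tuple(taxa), d))
                assert phylo_tree_splits(mine, taxa) == best_topology_by_ls(taxa, d)


class TestCladeAssignment:
    @staticmethod
    def _padded_alignment(records):
        L = max(len(r.seq) for r in records)
        return Alignment(tuple(ProteinRecord(r.id, r.seq + "-" * (L - len(r.seq)))
                               for r in records))

    def test_fixture_panel_recovers_classes(self, group_fixtures):
        panel = make_reference_panel(3, 0.05, seed=7)
        labels = {rec.id: lab for rec, lab in panel}
        queries = [group_fixtures["FaTIP(b)"], group_fixtures["FaPIP1;3"]]
        aln = self._padded_alignment([r for r, _ in panel] + queries)
        tree = neighbor_joining(pdistance_matrix(aln))
        out = assign_by_clade(tree, labels)
        assert out["FaTIP(b)"].class_name == "TIP"
        assert out["FaPIP1;3"].class_name == "PIP1"

    def test_clade_and_residue_methods_agree_on_fixtures(self, group_fixtures,
                                                         extractions):
        panel = make_reference_panel(3, 0.05, seed=7)
        labels = {rec.id: lab for rec, lab in panel}
        aln = self._padded_alignment(
            [r for r, _ in panel] + list(group_fixtures.values()))
        tree = neighbor_joining(pdistance_matrix(aln))
        clade = assign_by_clade(tree, labels)
        for gid in GROUP_IDS:
            residue_label = classify_by_residues(extractions[gid]).class_name
            assert clade[gid].class_name == residue_label, gid

    def test_missing_query_errors(self):
        m = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), m))
        with pytest.raises(AnalysisError, match="absent"):
            assign_by_clade(tree, {"a": "PIP1", "b": "PIP1", "c": "PIP2"},
                            queries=["zz"])

    def test_query_sister_to_whole_panel_is_unknown(self):
        # panel has one pure clade per class; a query equidistant from all
        # classes attaches outside every pure clade
        taxa = ("p1a", "p1b", "p2a", "p2b", "ta", "tb", "q")
        d = np.array([
            [0, .1, 1, 1, 1, 1, 2],
            [.1, 0, 1, 1, 1, 1, 2],
            [1, 1, 0, .1, 1, 1, 2],
            [1, 1, .1, 0, 1, 1, 2],
            [1, 1, 1, 1, 0, .1, 2],
            [1, 1, 1, 1, .1, 0, 2],
            [2, 2, 2, 2, 2, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        labels = {"p1a": "PIP1", "p1b": "PIP1", "p2a": "PIP2",
                  "p2b": "PIP2", "ta": "TIP", "tb": "TIP"}
        assert assign_by_clade(tree, labels)["q"].class_name == "unknown"


class TestValidation:
    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        d = DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(AnalysisError):
            neighbor_joining(d)
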