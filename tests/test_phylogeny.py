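"""Translation, supermatrix assembly, p-distances, NJ and bootstrap."""

import numpy as np
import pytest
from dendropy.calculate import treecompare

from mitokit.errors import (
    DistanceMatrixError, FrameError, NewickError, ParameterError,
)
from mitokit.phylogeny import (
    DistanceMatrix, Partition, ProteinAlignment, bootstrap_support,
    clade_support, concatenate_pcgs, neighbor_joining, p_distance_matrix,
    parse_newick, translate_cds, write_newick,
)


class TestTranslate:
    def test_table5_basics(self):
        assert translate_cds("ATGAAATAA") == "MK"       # terminal stop trimmed
        assert translate_cds("ATATGATCT") == "MWS"      # ATA=M, TGA=W under table 5

    def test_internal_stop_flagged(self):
        with pytest.warns(UserWarning, match="codon index 1"):
            out = translate_cds("ATGTAAAAATAA")
        assert out == "M*K"

    def test_frame_violation(self):
        with pytest.raises(FrameError):
            translate_cds("ATGA")

    def test_generator_proteins_round_trip(self, synthetic_genome):
        _, truth = synthetic_genome
        for rec in truth["pcgs"].values():
            assert translate_cds(rec["cds"]) == rec["protein"]


class TestConcatenate:
    def test_lengths_and_partition_map(self):
        a = ProteinAlignment(("x", "y", "z"), ("AAAAA", "CCCCC", "DDDDD"))
        b = ProteinAlignment(("x", "y", "z"), ("EEEEEEE", "FFFFFFF", "GGGGGGG"))
        sup = concatenate_pcgs({"COI": b, "ND2": a})
        assert sup.length == 12
        # canonical order puts ND2 before COI regardless of input order
        assert sup.partitions == (Partition("ND2", 1, 5), Partition("COI", 6, 12))
        assert sup.row("x") == "AAAAA" + "EEEEEEE"

    def test_order_independence(self, evolved_alignment):
        genes, _ = evolved_alignment
        fwd = concatenate_pcgs(genes)
        rev = concatenate_pcgs(dict(reversed(list(genes.items()))))
        assert fwd.rows == rev.rows and fwd.partitions == rev.partitions

    def test_total_length_is_sum_of_genes(self, evolved_alignment):
        genes, _ = evolved_alignment
        sup = concatenate_pcgs(genes)
        assert sup.length == sum(a.length for a in genes.values())

    def test_missing_taxon_gap_filled(self):
        a = ProteinAlignment(("x", "y"), ("AAA", "CCC"))
        b = ProteinAlignment(("x",), ("EE",))
        with pytest.warns(UserWarning, match="missing"):
            sup = concatenate_pcgs({"ND2": a, "COI": b})
        assert sup.row("y") == "CCC--"


class TestPDistance:
    def test_identical_rows(self):
        aln = ProteinAlignment(("a", "b"), ("MKV", "MKV"))
        assert p_distance_matrix(aln).get("a", "b") == 0.0

    def test_hand_count(self):
        aln = ProteinAlignment(("a", "b"), ("AAAA", "AAAT"))
        assert p_distance_matrix(aln).get("a", "b") == pytest.approx(0.25)

    def test_gapped_columns_excluded(self):
        aln = ProteinAlignment(("a", "b"), ("AA-A", "AT-T"))
        assert p_distance_matrix(aln).get("a", "b") == pytest.approx(2 / 3)

    def test_matches_per_column_tally(self):
        rng = np.random.default_rng(9)
        rows = tuple("".join(rng.choice(list("ACDEFG-"), size=200))
                     for _ in range(4))
        aln = ProteinAlignment(("a", "b", "c", "d"), rows)
        dm = p_distance_matrix(aln)
        for i in range(4):
            for j in range(i + 1, 4):
                both = [(x, y) for x, y in zip(rows[i], rows[j])
                        if x != "-" and y != "-"]
                want = sum(1 for x, y in both if x != y) / len(both)
                assert dm.values[i, j] == pytest.approx(want)

    def test_no_comparable_columns_is_error(self):
        aln = ProteinAlignment(("a", "b"), ("A-", "-A"))
        with pytest.raises(DistanceMatrixError):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d01, d02, d12 = 0.3, 0.4, 0.5
        dm = DistanceMatrix(("A", "B", "C"), np.array(
            [[0, d01, d02], [d01, 0, d12], [d02, d12, 0]]))
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((d01 + d02 - d12) / 2)
        assert lengths["B"] == pytest.approx((d01 + d12 - d02) / 2)
        assert lengths["C"] == pytest.approx((d02 + d12 - d01) / 2)

    def test_four_taxon_additive_recovery(self):
        # distances additive on ((A:1,B:2):1,(C:3,D:4))
        taxa = ("A", "B", "C", "D")
        M = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     dtype=float)
        tree = neighbor_joining(DistanceMatrix(taxa, M))
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                assert pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) == \
                    pytest.approx(M[i, j])

    def test_additive_matrices_recovered_exactly(self, additive_tree_factory):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            truth, taxa, M = additive_tree_factory(n, rng)
            nj = neighbor_joining(DistanceMatrix(taxa, M),
                                  taxon_namespace=truth.taxon_namespace)
            truth.encode_bipartitions()
            nj.encode_bipartitions()
            assert treecompare.symmetric_difference(truth, nj) == 0

    def test_agrees_with_independent_nj_implementation(self, additive_tree_factory):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        import dendropy

        rng = np.random.default_rng(33)
        for _ in range(5):
            truth, taxa, M = additive_tree_factory(7, rng)
            mine = neighbor_joining(DistanceMatrix(taxa, M))
            other = skbio_nj(skbio.DistanceMatrix(M, ids=list(taxa)))
            tns = dendropy.TaxonNamespace(list(taxa))
            t1 = parse_newick(write_newick(mine), taxon_namespace=tns)
            t2 = parse_newick(str(other), taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            assert treecompare.symmetric_difference(t1, t2) == 0

    def test_too_few_taxa(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ParameterError):
            neighbor_joining(dm)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(("A", "B", "C"), np.array(
                [[0, 1, 2], [1, 0, -3], [2, -3, 0.0]]))
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0.0]]))


class TestBootstrap:
    def test_saturated_clade_support(self):
        # two clearly separated clades with many diagnostic columns
        rows = {
            "a1": "A" * 40 + "C" * 40, "a2": "A" * 40 + "C" * 39 + "D",
            "b1": "W" * 40 + "C" * 40, "b2": "W" * 40 + "C" * 39 + "E",
            "c": "Y" * 40 + "M" * 40,
        }
        aln = ProteinAlignment.from_dict(rows)
        result = bootstrap_support(aln, n_reps=100, seed=0)
        assert clade_support(result.tree, ["a1", "a2"]) == pytest.approx(100.0)
        assert clade_support(result.tree, ["b1", "b2"]) == pytest.approx(100.0)

    def test_zero_replicates_rejected(self, evolved_alignment):
        genes, _ = evolved_alignment
        aln = concatenate_pcgs(genes)
        with pytest.raises(ParameterError):
            bootstrap_support(aln, n_reps=0, seed=1)

    def test_same_seed_reproduces_supports(self, evolved_alignment):
        genes, _ = evolved_alignment
        aln = concatenate_pcgs(genes)
        r1 = bootstrap_support(aln, n_reps=30, seed=4)
        r2 = bootstrap_support(aln, n_reps=30, seed=4)
        assert write_newick(r1.tree) == write_newick(r2.tree)

    def test_supports_invariant_to_taxon_input_order(self, evolved_alignment):
        genes, _ = evolved_alignment
        aln = concatenate_pcgs(genes)
        permuted = aln.reordered(tuple(reversed(aln.taxa)))
        r1 = bootstrap_support(aln, n_reps=30, seed=4)
        r2 = bootstrap_support(permuted, n_reps=30, seed=4)
        assert write_newick(r1.tree) == write_newick(r2.tree)


class TestNewick:
    def test_round_trip_is_canonical(self):
        text = "(A:1,B:1,(C:1,D:1):0.5);"
        once = write_newick(parse_newick(text))
        twice = write_newick(parse_newick(once))
        assert once == twice

    def test_supports_preserved(self):
        tree = parse_newick("(A,B,(C,D)95);")
        out = write_newick(tree)
        assert "95" in out

    def test_random_trees_round_trip(self, additive_tree_factory):
        rng = np.random.default_rng(55)
        for _ in range(10):
            truth, taxa, _ = additive_tree_factory(int(rng.integers(4, 12)), rng)
            text = write_newick(truth)
            back = parse_newick(text, taxon_namespace=truth.taxon_namespace)
            truth.encode_bipartitions()
            back.encode_bipartitions()
            assert treecompare.symmetric_difference(truth, back) == 0
            assert back.length() == pytest.approx(truth.length())

    def test_malformed_text(self):
        with pytest.raises(NewickError):
            parse_newick("(A,(B,C);")
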