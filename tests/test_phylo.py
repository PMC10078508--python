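"""Supermatrix preparation, partition tiling, and the NJ sanity tree."""

import pytest
from hypothesis import given, strategies as st

from mitochar.divergence import OrthologAlignmentSet
from mitochar.phylo import (
    FrameError, Supermatrix, concatenate, distance_tree, filter_columns,
    nexus_sets_block, nj_tree, pairwise_distance, raxml_partitions, strip_stops,
    write_fasta_matrix, write_phylip,
)
from mitochar.synthetic import DivergenceScenario, random_cds, simulate_on_tree


def _aln(seqs, taxa=None, gene="cox1"):
    taxa = taxa or [f"t{i}" for i in range(len(seqs))]
    return OrthologAlignmentSet(gene=gene, taxa=taxa, sequences=seqs)


class TestStripStops:
    def test_terminal_stop_column_removed(self):
        aln = strip_stops(_aln(["ATGGCTTAA", "ATGGCATAG"]))
        assert aln.length == 6

    def test_stop_free_alignment_unchanged(self):
        aln = strip_stops(_aln(["ATGGCT", "ATGGCA"]))
        assert aln.length == 6

    def test_internal_stop_names_taxon_and_position(self):
        seqs = ["ATGGCTGCAATT", "ATGTAAGCAATT"]
        with pytest.raises(FrameError, match=r"taxon 'taxB' at codon 2"):
            strip_stops(_aln(seqs, taxa=["taxA", "taxB"]))

    def test_gap_only_terminal_codons_ignored(self):
        aln = strip_stops(_aln(["ATGGCTTAA", "ATGGCA---"]))
        assert aln.length == 6


class TestFilterColumns:
    def test_gap_free_alignment_unchanged(self):
        aln = filter_columns(_aln(["ATGGCT", "ATGGCA"]))
        assert aln.sequences == ["ATGGCT", "ATGGCA"]

    def test_strict_mode_drops_any_gapped_codon_column(self):
        aln = filter_columns(_aln(["ATGGCTAAA", "ATG--TAAA"]), 0.0)
        assert aln.length == 6
        assert aln.sequences[0] == "ATGAAA"

    def test_five_codon_alignment_with_two_gapped_columns(self):
        # codon columns 2 and 4 carry gaps -> 3 codons (9 columns) remain
        s1 = "ATG" + "GC-" + "AAA" + "T-T" + "GGA"
        s2 = "ATG" + "GCA" + "AAG" + "TTT" + "GGG"
        aln = filter_columns(_aln([s1, s2]), 0.0)
        assert aln.length == 9
        assert aln.sequences == ["ATGAAAGGA", "ATGAAGGGG"]

    def test_threshold_keeps_minority_gapped_columns(self):
        seqs = ["ATGGCT", "ATG---", "ATGGCA", "ATGGCC"]
        assert filter_columns(_aln(seqs), 0.25).length == 6
        assert filter_columns(_aln(seqs), 0.0).length == 3

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            filter_columns(_aln(["ATG", "ATG"]), 1.5)


class TestConcatenate:
    def test_two_genes_partition_arithmetic(self):
        a = _aln(["ATGGCT", "ATGGCA"], taxa=["x", "y"], gene="cox1")
        b = _aln(["ATGGCTAAA", "ATGGCAAAG"], taxa=["x", "y"], gene="nad2")
        sm = concatenate([a, b])
        assert sm.length == 15
        assert sm.partitions == [("cox1", 1, 6), ("nad2", 7, 15)]

    def test_single_gene_is_identity(self):
        a = _aln(["ATGGCT", "ATGGCA"], taxa=["x", "y"])
        sm = concatenate([a])
        assert sm.sequences == a.sequences
        assert sm.partitions == [("cox1", 1, 6)]

    def test_missing_taxon_block_filled_with_gaps(self):
        a = _aln(["ATGGCT", "ATGGCA"], taxa=["x", "y"], gene="cox1")
        b = _aln(["ATGAAA", "ATGAAG"], taxa=["x", "z"], gene="nad2")
        sm = concatenate([a, b])
        row_y = sm.sequences[sm.taxa.index("y")]
        assert row_y.endswith("------")
        assert len({len(s) for s in sm.sequences}) == 1

    def test_input_order_irrelevant_given_canonical_order(self):
        a = _aln(["ATGGCT", "ATGGCA"], taxa=["x", "y"], gene="cox1")
        b = _aln(["ATGAAA", "ATGAAG"], taxa=["x", "y"], gene="nad2")
        assert concatenate([a, b]).sequences == concatenate([b, a]).sequences

    def test_duplicate_taxa_rejected(self):
        a = _aln(["ATGGCT", "ATGGCA"], taxa=["x", "y"], gene="cox1")
        with pytest.raises(ValueError):
            concatenate([a], taxa=["x", "x"])

    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=8))
    def test_partitions_tile_without_gaps_or_overlap(self, codon_counts):
        alns = [
            _aln(["ATG" * k, "ATG" * k], taxa=["x", "y"], gene=f"g{i}")
            for i, k in enumerate(codon_counts)
        ]
        sm = concatenate(alns)
        covered = []
        for _, start, end in sm.partitions:
            covered.extend(range(start, end + 1))
        assert covered == list(range(1, sm.length + 1))


def test_partition_file_formats():
    sm = Supermatrix(taxa=["x"], sequences=["ATGGCTAAA"],
                     partitions=[("cox1", 1, 6), ("nad2", 7, 9)])
    assert raxml_partitions(sm) == "DNA, cox1 = 1-6\nDNA, nad2 = 7-9\n"
    nexus = nexus_sets_block(sm)
    assert "charset cox1 = 1-6;" in nexus and nexus.startswith("#NEXUS")
    assert write_phylip(sm).splitlines()[0] == "1 9"
    assert write_fasta_matrix(sm) == ">x\nATGGCTAAA\n"


def test_mistiled_partitions_rejected():
    with pytest.raises(ValueError):
        Supermatrix(taxa=["x"], sequences=["ATGGCT"],
                    partitions=[("cox1", 1, 3), ("nad2", 5, 6)])


def _split(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, via dendropy-free parsing."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    leaves = frozenset(t.name for t in tree.get_terminals())
    splits = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=sorted))
    return splits


class TestDistanceTree:
    def test_nj_recovers_topology_from_additive_distances(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:4)) -> split {A,B}|{C,D}
        taxa = ["A", "B", "C", "D"]
        d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        m = [[0.0] * 4 for _ in range(4)]
        for (u, v), val in d.items():
            i, j = taxa.index(u), taxa.index(v)
            m[i][j] = m[j][i] = float(val)
        newick = nj_tree(taxa, m)
        assert _split(newick) == {frozenset({"A", "B"})}

    def test_three_taxa_unique_topology(self):
        newick = nj_tree(["A", "B", "C"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        assert _split(newick) == set()
        assert sorted(x for x in ("A", "B", "C") if x in newick) == ["A", "B", "C"]

    def test_identical_sequences_zero_distances(self):
        sm = Supermatrix(taxa=["x", "y", "z"], sequences=["ATG"] * 3,
                         partitions=[("g", 1, 3)])
        assert distance_tree(sm) is not None
        assert pairwise_distance("ATG", "ATG") == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        sm = Supermatrix(taxa=["x", "y"], sequences=["ATG", "ATG"],
                         partitions=[("g", 1, 3)])
        with pytest.raises(ValueError):
            distance_tree(sm)

    def test_jc_distance_exceeds_p_distance(self):
        p = pairwise_distance("AAAATTTT", "AAAATTAC")
        jc = pairwise_distance("AAAATTTT", "AAAATTAC", model="JC")
        assert jc > p


def test_simulated_five_taxon_tree_recovered_end_to_end():
    """Full data path: simulate orthologs on a known tree, strip, filter,
    concatenate, and check NJ recovers the generating topology."""
    root = random_cds(250, seed=21)
    tree = ([([("A", 0.05), ("B", 0.05)], 0.15),
             ([("C", 0.1), ([("D", 0.05), ("E", 0.05)], 0.1)], 0.05)], 0.0)
    aln = simulate_on_tree(root, tree, DivergenceScenario(omega=0.2, seed=5))
    prepared = filter_columns(strip_stops(aln))
    sm = concatenate([prepared])
    newick = distance_tree(sm, model="JC")
    assert _split(newick) == _split("((A,B),(C,(D,E)));")
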