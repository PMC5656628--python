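import numpy as np
import pytest
import dendropy

from its2delim.distances import (
    DistanceMatrix,
    between_group_distance,
    conservation_profile,
    nj_tree,
    p_distance_matrix,
    within_group_distance,
)
from its2delim.formats_io import AlignedRow, StructuredAlignment


def seq_aln(rows):
    return StructuredAlignment(
        [AlignedRow(rid, res, "".join("." if c != "-" else "-" for c in res)) for rid, res in rows]
    )


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(seq_aln([("a", "ACGU"), ("b", "ACGU")]))
        assert dm.d[0, 1] == 0.0 and dm.n_sites_used == 4

    def test_single_mismatch_quarter(self):
        dm = p_distance_matrix(seq_aln([("a", "ACGU"), ("b", "ACGA")]))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_hand_example(self):
        # column 3 contains a gap in row 1 and is removed globally;
        # d(row1, row3) = 1 mismatch / 3 retained columns
        dm = p_distance_matrix(seq_aln([("r1", "AC-U"), ("r2", "ACGU"), ("r3", "AAGU")]))
        assert dm.n_sites_used == 3
        assert dm.get("r1", "r3") == pytest.approx(1 / 3)
        assert dm.get("r2", "r3") == pytest.approx(1 / 3)
        assert dm.get("r1", "r2") == 0.0

    def test_invariant_to_all_gap_columns(self):
        base = [("a", "ACGUACGU"), ("b", "ACGAACGA")]
        padded = [("a", "ACGU--ACGU"), ("b", "ACGA--ACGA")]
        d1 = p_distance_matrix(seq_aln(base))
        d2 = p_distance_matrix(seq_aln(padded))
        assert d1.d[0, 1] == d2.d[0, 1]
        assert d1.n_sites_used == d2.n_sites_used

    def test_ambiguity_treated_as_missing(self):
        dm = p_distance_matrix(seq_aln([("a", "ACGU"), ("b", "ACNU")]))
        assert dm.n_sites_used == 3 and dm.d[0, 1] == 0.0

    def test_agrees_with_naive_counter_on_gapfree(self):
        rng = np.random.default_rng(17)
        rows = [
            (f"s{i}", "".join(rng.choice(list("ACGU"), 60))) for i in range(5)
        ]
        dm = p_distance_matrix(seq_aln(rows))
        for i in range(5):
            for j in range(5):
                naive = sum(a != b for a, b in zip(rows[i][1], rows[j][1])) / 60
                assert dm.d[i, j] == pytest.approx(naive)

    def test_all_columns_removed_is_error(self):
        with pytest.raises(ValueError):
            p_distance_matrix(seq_aln([("a", "A-"), ("b", "-A")]))

    def test_pairwise_deletion_mode(self):
        dm = p_distance_matrix(
            seq_aln([("a", "AC-U"), ("b", "ACGU"), ("c", "AAGU")]), pairwise_deletion=True
        )
        assert dm.get("b", "c") == pytest.approx(0.25)  # all 4 columns comparable
        assert dm.get("a", "c") == pytest.approx(1 / 3)


class TestGroupDistances:
    def _dm(self):
        d = np.array(
            [[0, 0.1, 0.4, 0.5], [0.1, 0, 0.3, 0.6], [0.4, 0.3, 0, 0.2], [0.5, 0.6, 0.2, 0]]
        )
        return DistanceMatrix(["a", "b", "c", "d"], d, 100)

    def test_singleton_groups_give_single_distance(self):
        assert between_group_distance(self._dm(), ["a"], ["c"]) == pytest.approx(0.4)

    def test_mean_and_max(self):
        dm = self._dm()
        assert between_group_distance(dm, ["a", "b"], ["c", "d"]) == pytest.approx(
            (0.4 + 0.5 + 0.3 + 0.6) / 4
        )
        assert between_group_distance(dm, ["a", "b"], ["c", "d"], stat="max") == 0.6

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            between_group_distance(self._dm(), ["a", "b"], ["b", "c"])

    def test_identical_sequence_groups_zero(self):
        dm = p_distance_matrix(seq_aln([("a", "ACGU"), ("b", "ACGU"), ("c", "ACGU")]))
        assert between_group_distance(dm, ["a"], ["b", "c"]) == 0.0

    def test_within_group(self):
        dm = self._dm()
        assert within_group_distance(dm, ["a", "b"]) == pytest.approx(0.1)
        assert within_group_distance(dm, ["a"]) == 0.0


class TestConservationProfile:
    def test_invariant_column(self):
        prof = conservation_profile(seq_aln([("a", "A"), ("b", "A"), ("c", "A"), ("d", "A")]))
        assert prof.consensus == "A" and prof.max_fraction[0] == 1.0

    def test_split_column_gets_iupac(self):
        prof = conservation_profile(
            seq_aln([("a", "A"), ("b", "A"), ("c", "G"), ("d", "G")]), threshold=0.7
        )
        assert prof.consensus == "R"

    def test_threshold_one_concrete_only_at_invariant(self):
        prof = conservation_profile(
            seq_aln([("a", "AC"), ("b", "AC"), ("c", "AU")]), threshold=1.0
        )
        assert prof.consensus[0] == "A"
        assert prof.consensus[1] == "Y"  # C/U observed

    def test_gaps_excluded_from_fractions(self):
        prof = conservation_profile(seq_aln([("a", "A-"), ("b", "AC"), ("c", "AC")]))
        assert prof.consensus == "AC"


def patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-built additive tree: ((a:2,b:3):1,(c:4,d:5)) with internal edge 1
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        ) / 10.0  # scale into [0, 1]
        dm = DistanceMatrix(taxa, d, 10)
        dist = patristic(nj_tree(dm))
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                assert dist(a, b) == pytest.approx(dm.get(a, b), abs=1e-9)

    def test_three_taxon_star_resolved_deterministically(self):
        d = np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
        n1 = nj_tree(DistanceMatrix(["a", "b", "c"], d, 10))
        n2 = nj_tree(DistanceMatrix(["a", "b", "c"], d.copy(), 10))
        assert n1 == n2

    def test_duplicate_taxon_zero_length_cherry(self):
        d = np.array(
            [[0, 0.0, 0.5, 0.5], [0.0, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.2], [0.5, 0.5, 0.2, 0]]
        )
        newick = nj_tree(DistanceMatrix(["a", "a2", "c", "d"], d, 10))
        dist = patristic(newick)
        assert dist("a", "a2") == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]), 10))

    def test_recovers_random_additive_trees(self):
        """Topology (and leaf-to-leaf path lengths) of random additive trees
        with 6-10 leaves are reproduced exactly."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            taxa = [f"t{i}" for i in range(n)]
            sim = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            for leaf, name in zip(sim.leaf_node_iter(), taxa):
                leaf.taxon.label = name
            for e in sim.preorder_edge_iter():
                if e.length is None:
                    e.length = 0.0
                e.length = float(rng.uniform(0.01, 0.1))
            pdm = sim.phylogenetic_distance_matrix()
            tx = {t.label: t for t in sim.taxon_namespace if t.label in taxa}
            d = np.zeros((n, n))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i != j:
                        d[i, j] = pdm.distance(tx[a], tx[b])
            dm = DistanceMatrix(taxa, d, 100)
            dist = patristic(nj_tree(dm))
            for i, a in enumerate(taxa):
                for b in taxa[i + 1 :]:
                    assert dist(a, b) == pytest.approx(dm.get(a, b), abs=1e-6)

    def test_against_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(29)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        # random (non-additive) symmetric matrix
        m = rng.uniform(0.05, 0.5, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = dendropy.Tree.get(
            data=nj_tree(DistanceMatrix(taxa, d, 10)), schema="newick",
            preserve_underscores=True,
        )
        import io as _io

        buf = _io.StringIO()
        skbio_nj(SkbioDM(d, ids=taxa)).write(buf)
        theirs = dendropy.Tree.get(
            data=buf.getvalue(), schema="newick", preserve_underscores=True,
            taxon_namespace=ours.taxon_namespace,
        )
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ours, theirs) == 0
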