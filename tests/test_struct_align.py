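import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from its2delim.folding import fold_optimal
from its2delim.formats_io import RnaSequence, SecondaryStructure, parse_dotbracket
from its2delim.struct_align import (
    AlignScoring,
    SEQUENCE_ONLY,
    align_pair,
    decode,
    encode,
    progressive_msa,
    transfer_structure,
)


def rec(seq_str, db=None, rid="r"):
    s = RnaSequence(rid, seq_str)
    if db is None:
        db = "." * len(seq_str)
    return s, parse_dotbracket(db, s)


class TestEncoding:
    def test_direct_product(self):
        s, struct = rec("GACGU", "(...)")
        assert encode(s, struct) == "gACGZ"

    def test_all_unpaired_is_plain_bases(self):
        s, struct = rec("ACGU")
        assert encode(s, struct) == "ACGU"

    @settings(deadline=None, max_examples=100)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=30))
    def test_decode_inverts_encode(self, residues):
        s = RnaSequence("x", residues)
        struct = fold_optimal(s).structure
        back_seq, back_db = decode(encode(s, struct))
        assert back_seq.residues == residues
        assert back_db == struct.dotbracket

    def test_ambiguity_at_paired_position_rejected(self):
        s = RnaSequence("x", "NACGU")
        struct = SecondaryStructure(RnaSequence("y", "GACGC"), [4, -1, -1, -1, 0])
        with pytest.raises(ValueError):
            encode(s, struct)


def brute_force_align(x, y, scoring):
    """Independent oracle: exhaustive enumeration of all global alignments
    with affine gap costs (gap of length L costs open + extend*(L-1))."""
    S = scoring.matrix()

    best = [-1e30]

    def go(i, j, score, last):  # last: 0 sub, 1 gap-in-y, 2 gap-in-x
        if i == len(x) and j == len(y):
            best[0] = max(best[0], score)
            return
        if i < len(x) and j < len(y):
            go(i + 1, j + 1, score + S[x[i], y[j]], 0)
        if i < len(x):
            cost = scoring.gap_extend if last == 1 else scoring.gap_open
            go(i + 1, j, score + cost, 1)
        if j < len(y):
            cost = scoring.gap_extend if last == 2 else scoring.gap_open
            go(i, j + 1, score + cost, 2)

    go(0, 0, 0.0, -1)
    return best[0]


class TestAlignPair:
    def test_identical_inputs_gapless_full_match(self):
        x = rec("GGGAAACCC", "(((...)))")
        aln, score = align_pair(x, (x[0].with_id("y"), x[1]))
        assert score == 9 * AlignScoring().match
        assert all("-" not in r.residues for r in aln.rows)

    def test_agrees_with_brute_force_on_random_pairs(self):
        from its2delim.struct_align import _to_ints

        rng = np.random.default_rng(5)
        scoring = AlignScoring()
        for _ in range(40):
            a = rec("".join(rng.choice(list("ACGU"), 6)), rid="a")
            b = rec("".join(rng.choice(list("ACGU"), 6)), rid="b")
            _, score = align_pair(a, b, scoring)
            expected = brute_force_align(_to_ints(*a), _to_ints(*b), scoring)
            assert score == pytest.approx(expected)

    def test_score_symmetric(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rec("".join(rng.choice(list("ACGU"), 8)), rid="a")
            b = rec("".join(rng.choice(list("ACGU"), 8)), rid="b")
            _, s_ab = align_pair(a, b)
            _, s_ba = align_pair(b, a)
            assert s_ab == pytest.approx(s_ba)

    def test_structure_states_penalised(self):
        # same bases, different pairing states: score drops by the state penalty
        x = rec("GGGAAACCC", "(((...)))", rid="x")
        y = rec("GGGAAACCC", rid="y")
        _, s_same = align_pair(x, (x[0].with_id("x2"), x[1]))
        _, s_diff = align_pair(x, y)
        assert s_diff < s_same

    def test_empty_input_rejected(self):
        x = rec("ACGU")
        with pytest.raises(Exception):
            align_pair(x, (RnaSequence("e", ""), None))

    def test_degap_round_trip(self):
        a = rec("GGGAAACCCAAAA", "(((...)))....", rid="a")
        b = rec("GGGAAACCC", "(((...)))", rid="b")
        aln, _ = align_pair(a, b)
        for row, (seq, struct) in zip(aln.rows, [a, b]):
            back = row.degap()
            assert back.seq.residues == seq.residues
            assert back.dotbracket == struct.dotbracket


class TestProgressiveMsa:
    def test_identical_sequences_align_gapless(self):
        base = rec("GGGAAACCC", "(((...)))")
        records = [(base[0].with_id(f"s{i}"), base[1]) for i in range(3)]
        aln = progressive_msa(records)
        assert aln.n_cols == 9
        assert all(r.residues == "GGGAAACCC" for r in aln.rows)

    def test_duplicated_inputs_get_identical_rows(self, dataset):
        records, truth = dataset
        seqs = [RnaSequence(st.id, st.its2_seq) for st in truth.strains[:3]]
        structs = [parse_dotbracket(st.its2_db, s) for st, s in zip(truth.strains, seqs)]
        recs = list(zip(seqs, structs))
        recs.append((seqs[0].with_id("dup"), structs[0]))
        aln = progressive_msa(recs)
        assert aln.row(seqs[0].id).residues == aln.row("dup").residues

    def test_row_order_equals_input_order(self, dataset):
        records, truth = dataset
        recs = [
            (RnaSequence(st.id, st.its2_seq), parse_dotbracket(st.its2_db, RnaSequence(st.id, st.its2_seq)))
            for st in truth.strains[:5]
        ]
        aln = progressive_msa(recs)
        assert aln.ids == [r[0].id for r in recs]

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([rec("ACGUA")])

    def test_unknown_guide_tree_leaf_rejected(self):
        records = [rec("GGGAAACCC", rid=f"s{i}") for i in range(3)]
        with pytest.raises(ValueError, match="unknown leaf"):
            progressive_msa(records, guide_tree="(s0:1,(s1:1,BAD:1):1);")

    def test_planted_homologous_columns_recovered(self, dataset):
        """Positions derived from the same template site should co-align.

        Measured over all strain pairs on the planted-truth structures;
        the generator's indels are confined to declared variable regions so
        conserved positions must line up almost perfectly.
        """
        records, truth = dataset
        from its2delim.synthetic_data import SimConfig, make_template, _copy_sites, _Site

        cfg = SimConfig(seed=1)
        tpl, *_ = make_template(cfg)

        def pos_map(stt):
            sites = _copy_sites(tpl.sites)
            for op in stt.ops:
                if op["op"] == "del":
                    members = [s for s in sites if s.region == op["region"]]
                    for s in members[: op["n"]]:
                        sites.remove(s)
                elif op["op"] == "ins":
                    if op["region"] == "lineage_insertion":
                        anchor = tpl.region_index["sp3"][0].tpos
                        pos = next(k for k, s in enumerate(sites) if s.tpos == anchor)
                    else:
                        members = [s for s in sites if s.region == op["region"]]
                        pos = sites.index(members[0])
                    for ch in op["chars"]:
                        sites.insert(pos, _Site(ch, op["region"], None))
            return {s.tpos: k for k, s in enumerate(sites) if s.tpos is not None}

        seqs = [RnaSequence(st.id, st.its2_seq) for st in truth.strains]
        structs = [parse_dotbracket(st.its2_db, s) for st, s in zip(truth.strains, seqs)]
        aln = progressive_msa(list(zip(seqs, structs)))
        # seq position -> column per row
        col_of = {}
        for row in aln.rows:
            cols = [c for c, ch in enumerate(row.residues) if ch != "-"]
            col_of[row.id] = cols
        maps = {st.id: pos_map(st) for st in truth.strains}
        # positions inside length-variable poly-A regions (and the spacer
        # receiving the lineage insertion) have no well-defined homology:
        # any gap placement within a homopolymer run is equivalent
        ambiguous = {
            s.tpos
            for s in tpl.sites
            if s.region in {"helixI_tip", "helixII_tip", "IIIa", "sp3"}
        }
        agree = total = 0
        ids = [st.id for st in truth.strains]
        for a, b in itertools.combinations(ids, 2):
            for tpos, pa in maps[a].items():
                if tpos in ambiguous:
                    continue
                pb = maps[b].get(tpos)
                if pb is None:
                    continue
                total += 1
                agree += col_of[a][pa] == col_of[b][pb]
        assert agree / total >= 0.98


class TestTransferStructure:
    def test_identical_sequence_gets_identical_structure(self):
        x = rec("GGGGAAAACCCCAAA", "((((....))))...")
        out = transfer_structure(x, x[0].with_id("copy"))
        assert out.dotbracket == x[1].dotbracket

    def test_broken_pair_dropped_and_no_lonely_pairs_left(self):
        ref = rec("GGGGAAAACCCC", "((((....))))")
        # target mutates one strand base so one pair becomes invalid
        target = RnaSequence("t", "GGAGAAAACCCC")
        out = transfer_structure(ref, target)
        pairs = set(out.pairs())
        assert (2, 9) not in pairs
        for (i, j) in pairs:
            assert (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs

    def test_insertion_in_target_leaves_structure_intact(self):
        ref = rec("GGGGAAAACCCCAAA", "((((....))))...")
        target = RnaSequence("t", "GGGGAAAACCCCAAAAAAA")  # extra tail
        out = transfer_structure(ref, target)
        assert out.n_pairs() == 4
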