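import pytest

from its2delim.folding import FoldCandidate, FoldParams, enumerate_suboptimal, fold_optimal
from its2delim.formats_io import RnaSequence, parse_dotbracket
from its2delim.hallmarks import (
    annotate_helices,
    check_hallmarks,
    select_structure,
    select_structures_dataset,
)
from its2delim.synthetic_data import SimConfig, make_template


@pytest.fixture(scope="module")
def template():
    return make_template(SimConfig(seed=1))


class TestAnnotateHelices:
    def test_template_labels_match_planted_design(self, template):
        tpl, seq, struct, ann = template
        labels = [h.label for h in ann.helices]
        assert labels == ["I", "II", "III", "IV"]
        by_label = {}
        for seg in ann.segments:
            if seg.label:
                by_label.setdefault(seg.label, 0)
                by_label[seg.label] += seg.length
        # planted stack sizes: I=9, II=4+5 across the Y-Y loop, III=5+7, IIIa=3, IV=6
        assert by_label == {"I": 9, "II": 9, "III": 12, "IIIa": 3, "IV": 6}
        # annotated pairs agree with the generator's own pair bookkeeping
        planted = {
            lab: len(pairs) for lab, pairs in tpl.helix_pairs.items() if pairs
        }
        assert by_label == {**planted, "III": planted["III"]}

    def test_single_hairpin_gets_only_helix_I(self):
        seq = RnaSequence("h", "GGGGAAAACCCC")
        s = parse_dotbracket("((((....))))", seq)
        ann = annotate_helices(s)
        assert [h.label for h in ann.helices] == ["I"]
        assert ann.missing == ["II", "III", "IV"]
        rep = check_hallmarks(ann, seq)
        assert not rep.yy_mismatch["found"] and not rep.yrry["found"]
        assert rep.agg_score == 0.0

    def test_lateral_branch_of_helix_III_is_IIIa(self, template):
        _tpl, _seq, struct, ann = template
        iiia = ann.get("IIIa")
        assert iiia is not None and iiia.length == 3
        h3 = ann.get("III")
        # IIIa nests inside helix III's basal stack
        assert h3.outer[0] < iiia.outer[0] and iiia.outer[1] < h3.outer[1]

    def test_spacer_lengths(self, template):
        _tpl, _seq, _struct, ann = template
        assert ann.spacers[("I", "II")] == 4
        assert ann.spacers[("II", "III")] == 5
        assert ann.spacers[("B9", "I")] == 5

    def test_invariant_under_sequence_id(self, template):
        _tpl, seq, struct, _ann = template
        renamed = parse_dotbracket(struct.dotbracket, seq.with_id("other"))
        a1 = annotate_helices(struct)
        a2 = annotate_helices(renamed)
        assert [(h.label, h.pairs) for h in a1.segments] == [
            (h.label, h.pairs) for h in a2.segments
        ]


class TestCheckHallmarks:
    def test_template_shows_uu_and_uggu(self, template):
        _tpl, seq, _struct, ann = template
        rep = check_hallmarks(ann, seq)
        assert rep.yy_mismatch["found"] and rep.yy_mismatch["bases"] == ("U", "U")
        assert rep.yrry["found"] and rep.yrry["motif"] == "UGGU"
        assert all(rep.spacer_ok.values())
        assert rep.agg_score == 10.0
        assert set(rep.first_two_bp) == {"I", "II", "III"}

    def test_cu_mismatch_variant(self, template):
        # a C x U pyrimidine mismatch (the clade-A6 pattern) is still found
        _tpl, seq, struct, ann = template
        pos = ann.get("II")
        res = list(seq.residues)
        rep0 = check_hallmarks(ann, seq)
        res[rep0.yy_mismatch["position"] - 1] = "C"
        mutated = RnaSequence(seq.id, "".join(res))
        rep = check_hallmarks(ann, mutated)
        assert rep.yy_mismatch["bases"] == ("C", "U")

    def test_uaau_variant(self, template):
        # guanidines of the YRRY box replaced by adenines (the NIES-2756
        # pattern): both pair partners swapped so the structure is unchanged
        tpl, seq, struct, ann = template
        res = list(seq.residues)
        rep0 = check_hallmarks(ann, seq)
        p = rep0.yrry["position"] - 1  # 0-based position of the U of UGGU
        for offset in (1, 2):  # the two G's
            i = p + offset
            j = int(struct.partner[i])
            assert res[i] == "G" and res[j] == "C"
            res[i], res[j] = "A", "U"
        rep = check_hallmarks(ann, RnaSequence(seq.id, "".join(res)))
        assert rep.yrry["motif"] == "UAAU"

    def test_purine_purine_loop_is_not_a_yy_mismatch(self, template):
        _tpl, seq, struct, ann = template
        rep0 = check_hallmarks(ann, seq)
        res = list(seq.residues)
        res[rep0.yy_mismatch["position"] - 1] = "A"
        rep = check_hallmarks(ann, RnaSequence(seq.id, "".join(res)))
        assert not rep.yy_mismatch["found"]

    def test_agg_score_monotone_in_satisfied_hallmarks(self, template):
        """Adding a satisfied hallmark never decreases the aggregate score."""
        _tpl, seq, struct, ann = template
        full = check_hallmarks(ann, seq).agg_score
        res = list(seq.residues)
        rep0 = check_hallmarks(ann, seq)
        res[rep0.yy_mismatch["position"] - 1] = "A"  # destroy Y-Y only
        broken = check_hallmarks(ann, RnaSequence(seq.id, "".join(res))).agg_score
        assert broken < full


class TestSelectStructure:
    def test_single_candidate_returned_unchanged(self, template):
        _tpl, seq, struct, _ann = template
        cand = FoldCandidate(struct, 1, 0)
        chosen, rep = select_structure([cand], seq)
        assert chosen is struct

    def test_hallmark_rich_suboptimal_beats_bare_optimum(self, template):
        # candidate 1: the four-helix template structure (lower fold score);
        # candidate 2: an unpaired "structure" with a better fold score field
        _tpl, seq, struct, _ann = template
        from its2delim.formats_io import SecondaryStructure

        bare = SecondaryStructure.all_unpaired(seq)
        cands = [FoldCandidate(bare, 999, 0), FoldCandidate(struct, 1, 1)]
        chosen, rep = select_structure(cands, seq)
        assert chosen is struct and rep.agg_score == 10.0

    def test_fold_score_breaks_hallmark_ties(self):
        seq = RnaSequence("t", "GGGGAAAACCCC")
        s1 = parse_dotbracket("((((....))))", seq)
        s2 = parse_dotbracket(".(((....))).", seq)
        chosen, _ = select_structure(
            [FoldCandidate(s2, 9, 0), FoldCandidate(s1, 12, 1)], seq
        )
        assert chosen is s1

    def test_empty_candidate_list_rejected(self, template):
        _tpl, seq, _struct, _ann = template
        with pytest.raises(ValueError):
            select_structure([], seq)


class TestDatasetSelection:
    def test_structure_recovery_on_generator_replicates(self):
        """Across seeded replicates, hallmark+homology selection recovers the
        planted structure for >= 95% of strains (default mutation rates)."""
        from its2delim.synthetic_data import simulate

        total = exact = 0
        for seed in (1, 2, 3, 4, 5):
            records, truth = simulate(SimConfig(seed=seed))
            seqs = [RnaSequence(st.id, st.its2_seq) for st in truth.strains]
            chosen = select_structures_dataset(seqs)
            for st in truth.strains:
                total += 1
                exact += chosen[st.id][0].dotbracket == st.its2_db
        assert exact / total >= 0.95
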