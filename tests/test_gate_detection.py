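import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gatescan.errors import InputError
from gatescan.evaluation import brute_force_global_score
from gatescan.gate_detection import (
    GateParams,
    call_gate,
    call_insertions,
    conserved_cleavage_fraction,
    cut_site_logo,
    global_align,
    map_active_site,
    score_gate,
)
from gatescan.io_formats import ProteinRecord
from gatescan.synthetic_data import (
    InsertionSpec,
    child_rng,
    default_insertions,
    make_gated_sequence,
    mutate_sequence,
    random_protein,
)


class TestGlobalAlign:
    def test_self_alignment_is_gap_free_with_diagonal_score(self):
        seq = "MKWVTFISLLFLFSSAYS"
        aln = global_align(seq, seq)
        assert aln.aligned_query == seq and aln.aligned_reference == seq
        from gatescan.gate_detection import _BLOSUM62
        from gatescan.profile_search import AA_INDEX

        expected = sum(_BLOSUM62[AA_INDEX[c], AA_INDEX[c]] for c in seq)
        assert aln.score == expected

    def test_rows_degap_to_inputs(self):
        rng = child_rng(3, "degap")
        q = random_protein(rng, 40)
        r = random_protein(rng, 55)
        aln = global_align(q, r)
        assert aln.aligned_query.replace("-", "") == q
        assert aln.aligned_reference.replace("-", "") == r
        assert len(aln.aligned_query) == len(aln.aligned_reference)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_short_pairs(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "ACDE"
        lq, lr = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        q = "".join(alphabet[i] for i in rng.integers(0, 4, lq))
        r = "".join(alphabet[i] for i in rng.integers(0, 4, lr))
        assert global_align(q, r).score == brute_force_global_score(q, r)

    def test_implanted_block_yields_single_reference_gap(self):
        rng = child_rng(5, "block")
        ref = random_protein(rng, 120)
        ins = "".join("PESQK"[i % 5] for i in range(20))
        query = ref[:60] + ins + ref[60:]
        aln = global_align(query, ref)
        gaps = [c for c in aln.aligned_reference if c == "-"]
        assert len(gaps) == 20
        runs = call_insertions(aln, min_len=10)
        assert runs == [(61, 80)]

    def test_nonstandard_residue_treated_as_x(self):
        aln = global_align("MKLZV", "MKLAV")
        assert len(aln.aligned_query) == 5

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            global_align("", "MKL")


class TestCallInsertions:
    def test_gap_free_alignment_empty(self):
        seq = "MKWVTFISLLFL"
        assert call_insertions(global_align(seq, seq)) == []

    def test_min_len_filters_short_runs(self):
        rng = child_rng(6, "short")
        ref = random_protein(rng, 100)
        query = ref[:50] + "PQSE" + ref[50:]
        aln = global_align(query, ref)
        assert call_insertions(aln, min_len=10) == []
        assert call_insertions(aln, min_len=4) == [(51, 54)]

    def test_nearby_runs_merged(self):
        # two gap runs separated by fewer than merge_gap aligned columns
        # merge into one interval spanning both (built by hand to pin the
        # gap geometry exactly)
        from gatescan.gate_detection import AlignmentResult

        q = "MKLVA" + "PPPPPPPP" + "WY" + "SSSSSSSS" + "HEDNC"
        r = "MKLVA" + "--------" + "WY" + "--------" + "HEDNC"
        aln = AlignmentResult("q", "r", q, r, 0.0, 11, 1)
        merged = call_insertions(aln, min_len=10, merge_gap=3)
        assert merged == [(6, 23)]
        split = call_insertions(aln, min_len=8, merge_gap=1)
        assert split == [(6, 13), (16, 23)]

    def test_splice_out_restores_reference_at_zero_divergence(self):
        rng = child_rng(8, "splice")
        ref = random_protein(rng, 250)
        gated, iv, _ = make_gated_sequence(ref, default_insertions("I"), rng)
        called = call_insertions(global_align(gated, ref))
        assert called == iv
        spliced = list(gated)
        for s, e in sorted(called, reverse=True):
            del spliced[s - 1: e]
        assert "".join(spliced) == ref


class TestMapActiveSite:
    def test_identity_maps_to_self(self):
        seq = "MKWVTFISLLFLFSSAYS"
        aln = global_align(seq, seq)
        assert map_active_site(aln, [1, 5, 18]) == [1, 5, 18]

    def test_positions_shift_past_insertion(self):
        rng = child_rng(9, "shift")
        ref = random_protein(rng, 100)
        gated, iv, _ = make_gated_sequence(
            ref, [InsertionSpec(40, 15, "I", 8)], rng
        )
        aln = global_align(gated, ref)
        assert map_active_site(aln, [10, 80]) == [10, 95]

    def test_deleted_region_maps_to_absent(self):
        rng = child_rng(10, "del")
        ref = random_protein(rng, 100)
        query = ref[:30] + ref[50:]  # residues 31..50 deleted
        aln = global_align(query, ref)
        mapped = map_active_site(aln, [40])
        assert mapped == [None]

    def test_out_of_range_column_rejected(self):
        seq = "MKWVTFISLL"
        aln = global_align(seq, seq)
        with pytest.raises(InputError):
            map_active_site(aln, [11])


class TestScoreGate:
    def test_no_insertions_scores_zero(self):
        assert score_gate([], [50], "M" * 100) == (0.0, False)

    def test_two_ile_insertions_flanking_active_site_gated(self):
        # canonical trypsin-partner geometry: two long Ile-bearing
        # insertions within the proximity window of the active site
        rng = child_rng(11, "hamlike")
        ref = random_protein(rng, 300)
        gated, iv, cuts = make_gated_sequence(ref, default_insertions("I"), rng)
        active = [95, 98, 247]
        score, is_gated = score_gate(iv, active, gated, {"I"})
        assert is_gated
        assert score == 6.0  # both insertions pass all three components

    def test_gly_cleavage_with_expected_g_gated(self):
        rng = child_rng(12, "canlike")
        ref = random_protein(rng, 300)
        gated, iv, cuts = make_gated_sequence(ref, default_insertions("G"), rng)
        active = [95, 98, 247]
        _, gated_g = score_gate(iv, active, gated, {"G"})
        assert gated_g

    def test_distal_insertion_not_gated(self):
        rng = child_rng(13, "far")
        ref = random_protein(rng, 300)
        gated, iv, _ = make_gated_sequence(
            ref, [InsertionSpec(250, 20, "I", 10)], rng
        )
        score, is_gated = score_gate(iv, [10], gated, {"I"}, GateParams(prox_window=30))
        assert not is_gated
        assert score == 2.0  # length and residue pass, proximity fails

    def test_overlapping_insertions_rejected(self):
        with pytest.raises(InputError):
            score_gate([(10, 30), (25, 40)], [5], "M" * 100)


class TestCallGateEndToEnd:
    def test_gated_candidate_called(self):
        rng = child_rng(14, "e2e")
        ref_seq = random_protein(rng, 300)
        evolved = mutate_sequence(ref_seq, 0.1, rng)
        gated, iv, cuts = make_gated_sequence(evolved, default_insertions("I"), rng)
        call = call_gate(
            ProteinRecord("q", gated),
            ProteinRecord("ref", ref_seq),
            (95, 98, 205),
            expected_residues={"I"},
        )
        assert call.gated
        assert call.insertions == iv
        called_cut_positions = [p for p, _ in call.cut_sites]
        for c in cuts:
            assert c in called_cut_positions
        assert all(x is not None for x in call.active_site_query_positions)

    def test_ungated_candidate_not_called(self):
        rng = child_rng(15, "neg")
        ref_seq = random_protein(rng, 300)
        evolved = mutate_sequence(ref_seq, 0.15, rng)
        call = call_gate(
            ProteinRecord("q", evolved),
            ProteinRecord("ref", ref_seq),
            (95, 98, 205),
        )
        assert not call.gated
        assert call.insertions == []
        assert call.gate_score == 0.0


class TestCleavageLogo:
    def test_pure_column_information(self):
        seqs = ["AIA", "CIC", "DID"]
        logo = cut_site_logo(seqs, anchor_column=2, flank=0,
                             small_sample_correction=False)
        assert logo.information[0] == pytest.approx(math.log2(20))

    def test_half_half_column_information(self):
        seqs = ["AIA", "AIA", "AGA", "AGA"]
        logo = cut_site_logo(seqs, anchor_column=2, flank=0,
                             small_sample_correction=False)
        assert logo.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_small_sample_correction_subtracts(self):
        seqs = ["AIA", "CIC", "DID", "EIE"]
        raw = cut_site_logo(seqs, 2, flank=0, small_sample_correction=False)
        corr = cut_site_logo(seqs, 2, flank=0, small_sample_correction=True)
        e_n = 19.0 / (2 * math.log(2) * 4)
        assert corr.information[0] == pytest.approx(raw.information[0] - e_n)

    def test_all_gap_column_flagged_zero(self):
        seqs = ["A-A", "C-C"]
        logo = cut_site_logo(seqs, 2, flank=0)
        assert logo.all_gap[0]
        assert logo.information[0] == 0.0

    def test_information_bounds_property(self):
        rng = child_rng(16, "logo")
        seqs = [random_protein(rng, 30) for _ in range(10)]
        logo = cut_site_logo(seqs, 15, flank=10, small_sample_correction=True)
        assert np.all(logo.information >= 0.0)
        assert np.all(logo.information <= math.log2(20) + 1e-12)
        assert np.allclose(logo.frequencies[~logo.all_gap].sum(axis=1), 1.0)

    def test_conserved_cleavage_fractions(self):
        seqs = ["AIA", "AIA", "AGA", "AGA"]
        logo = cut_site_logo(seqs, 2, flank=0)
        assert conserved_cleavage_fraction(logo, {"I"}) == pytest.approx(0.5)
        assert conserved_cleavage_fraction(logo, {"I", "G"}) == pytest.approx(1.0)
        assert conserved_cleavage_fraction(logo, {"M"}) == 0.0

    def test_generator_cut_site_column_is_conserved(self):
        # gated family members share the cut-site residue at the anchor
        # column at the generator's conservation setting (default 1.0)
        rng = child_rng(17, "fam")
        ref = random_protein(rng, 200)
        members = []
        cut = None
        for i in range(12):
            mrng = child_rng(17, "member", i)
            evolved = mutate_sequence(ref, 0.1, mrng)
            gated, iv, cuts = make_gated_sequence(
                evolved, [InsertionSpec(100, 21, "I", 11)], mrng
            )
            members.append(gated)
            cut = cuts[0]
        logo = cut_site_logo(members, cut, flank=3)
        k = logo.anchor_index()
        from gatescan.profile_search import AA_INDEX

        assert logo.frequencies[k].argmax() == AA_INDEX["I"]
        assert conserved_cleavage_fraction(logo, {"I"}) == pytest.approx(1.0)
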