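import pytest

from gatescan.errors import InputError
from gatescan.io_formats import GeneFeature, GenomeAnnotation
from gatescan.neighborhood import (
    FusionCall,
    check_motif,
    classify_locus,
    detect_fusion,
    extract_neighborhood,
    island_score,
)
from gatescan.profile_search import HitRecord


def _hit(pid, fam, score, start, end):
    return HitRecord(protein_id=pid, family_name=fam, bit_score=score,
                     start=start, end=end, evalue=1e-9)


def _genome(n_genes=8, gap=200, gene_len=900, genome_id="g", strand="+"):
    feats = []
    pos = 1
    for i in range(n_genes):
        feats.append(
            GeneFeature(f"g{i}", "c1", pos, pos + gene_len - 1, strand, f"p{i}")
        )
        pos += gene_len + gap
    return GenomeAnnotation(genome_id=genome_id, contigs={"c1": feats})


class TestExtractNeighborhood:
    def test_contig_end_truncates_without_error(self):
        ann = _genome(5)
        nb = extract_neighborhood(ann, "p3", window_genes=10, window_kb=100)
        assert [m.gene_id for m in nb.members] == [f"g{i}" for i in range(5)]
        assert nb.anchor.gene_id == "g3"

    def test_window_zero_gives_anchor_only(self):
        ann = _genome(5)
        nb = extract_neighborhood(ann, "p2", window_genes=0, window_kb=100)
        assert [m.gene_id for m in nb.members] == ["g2"]

    def test_kb_window_constrains(self):
        ann = _genome(9)
        # each gene+gap spans 1.1 kb; a 1.2 kb window reaches one gene away
        nb = extract_neighborhood(ann, "p4", window_genes=10, window_kb=1.2)
        assert [m.gene_id for m in nb.members] == ["g3", "g4", "g5"]

    def test_unknown_anchor_rejected(self):
        ann = _genome(3)
        with pytest.raises(InputError):
            extract_neighborhood(ann, "missing")


class TestDetectFusion:
    def test_n_terminal_protease_plus_partner(self):
        hits = [
            _hit("p1", "trypsin", 200.0, 5, 150),
            _hit("p1", "HamA", 300.0, 180, 400),
        ]
        fc = detect_fusion(hits, protein_length=420)
        assert fc is not None
        assert fc.n_terminal_family == "trypsin"
        assert fc.c_terminal_family == "HamA"
        assert fc.boundary == 150

    def test_single_domain_gives_none(self):
        assert detect_fusion([_hit("p1", "trypsin", 200.0, 5, 150)],
                             protein_length=160) is None
        assert detect_fusion([_hit("p1", "HamA", 200.0, 5, 200)],
                             protein_length=220) is None

    def test_overlapping_hits_resolved_by_bit_score(self):
        # partner hit overlapping the protease loses; no C-terminal partner
        # remains, so no fusion is called
        hits = [
            _hit("p1", "trypsin", 300.0, 5, 150),
            _hit("p1", "HamA", 100.0, 100, 250),
        ]
        assert detect_fusion(hits, protein_length=260) is None

    def test_protease_outside_n_margin_gives_none(self):
        hits = [
            _hit("p1", "trypsin", 200.0, 250, 400),
            _hit("p1", "HamA", 300.0, 410, 600),
        ]
        assert detect_fusion(hits, protein_length=620) is None


class TestCheckMotif:
    def test_present_with_wildcards(self):
        assert check_motif("AAADAGELKAAA", "D-GEXK")

    def test_absent_when_region_excludes(self):
        assert not check_motif("AAADAGELKAAA", "D-GEXK", region=(1, 6))

    def test_absent_after_knockout(self):
        assert not check_motif("AAANSAQLTAAA", "D-GEXK")

    def test_malformed_pattern_rejected(self):
        with pytest.raises(InputError):
            check_motif("AAAA", "D-GE*K")

    def test_cohort_fusions_lost_catalytic_motif(self, default_cohort):
        # protease-partner fusion copies carry the knocked-out motif while
        # the standalone seed family retains it
        from gatescan.synthetic_data import HAMA_MOTIF_PATTERN

        c = default_cohort
        ham_rows = c.truth[c.truth["system_label"] == "Hachiman"]
        assert len(ham_rows) == 2
        for _, row in ham_rows.iterrows():
            g = next(g for g in c.genomes if g.genome_id == row["genome"])
            anchor = g.feature_by_gene_id(row["gene_id"])
            feats = g.contigs[anchor.contig]
            idx = next(i for i, f in enumerate(feats) if f.gene_id == anchor.gene_id)
            fusion_prot = c.proteomes[row["genome"]][feats[idx + 1].protein_id]
            assert not check_motif(fusion_prot.sequence, HAMA_MOTIF_PATTERN)
        for rec in c.families["HamA"]:
            assert check_motif(rec.sequence, HAMA_MOTIF_PATTERN)


def _neighborhood(ann, anchor_pid, hits):
    by_protein = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return extract_neighborhood(ann, anchor_pid, hits_by_protein=by_protein), by_protein


class TestClassifyLocus:
    def test_hachiman_architecture(self):
        ann = _genome(5)
        hits = [
            _hit("p1", "nuclease", 500.0, 1, 300),
            _hit("p2", "trypsin", 300.0, 1, 180),
            _hit("p2", "HamA", 350.0, 200, 290),
            _hit("p3", "HamB", 400.0, 1, 250),
        ]
        nb, _ = _neighborhood(ann, "p1", hits)
        call = classify_locus(nb)
        assert call.system_label == "Hachiman"
        assert "trypsin" in call.evidence_families
        assert call.nuclease_upstream is True

    def test_canu_architecture_caspase_upstream(self):
        ann = _genome(5)
        hits = [
            _hit("p1", "caspase", 400.0, 1, 220),
            _hit("p3", "nuclease", 500.0, 1, 300),
        ]
        nb, _ = _neighborhood(ann, "p3", hits)
        call = classify_locus(nb)
        assert call.system_label == "canu"

    def test_caspase_downstream_not_canu(self):
        ann = _genome(5)
        hits = [
            _hit("p1", "nuclease", 500.0, 1, 300),
            _hit("p3", "caspase", 400.0, 1, 220),
        ]
        nb, _ = _neighborhood(ann, "p1", hits)
        assert classify_locus(nb).system_label == "unknown"

    def test_lone_nuclease_unknown(self):
        ann = _genome(5)
        hits = [_hit("p2", "nuclease", 500.0, 1, 300)]
        nb, _ = _neighborhood(ann, "p2", hits)
        call = classify_locus(nb)
        assert call.system_label == "unknown"
        assert call.evidence_families == []

    def test_tie_broken_by_bit_score_and_logged(self):
        ann = _genome(6)
        hits = [
            _hit("p1", "nuclease", 500.0, 1, 300),
            _hit("p2", "trypsin", 300.0, 1, 180),
            _hit("p2", "STAND", 100.0, 200, 290),
            _hit("p3", "trypsin", 300.0, 1, 180),
            _hit("p3", "RT", 350.0, 200, 290),
        ]
        nb, _ = _neighborhood(ann, "p1", hits)
        call = classify_locus(nb)
        assert call.system_label == "DRT"
        assert "AVAST" in call.competing_labels

    def test_strand_flip_invariance(self):
        # reverse-complement the contig: coordinates mirror, strands swap
        fwd = _genome(5, strand="+")
        total = fwd.contigs["c1"][-1].end + 100
        flipped_feats = [
            GeneFeature(f.gene_id, "c1", total - f.end + 1, total - f.start + 1,
                        "-", f.protein_id)
            for f in fwd.contigs["c1"]
        ]
        rev = GenomeAnnotation(genome_id="gr", contigs={"c1": flipped_feats})
        hits = [
            _hit("p1", "caspase", 400.0, 1, 220),
            _hit("p3", "nuclease", 500.0, 1, 300),
        ]
        nb_f, _ = _neighborhood(fwd, "p3", hits)
        nb_r, _ = _neighborhood(rev, "p3", hits)
        assert classify_locus(nb_f).system_label == classify_locus(nb_r).system_label

    def test_decoy_loci_all_unknown_without_markers(self, default_cohort,
                                                    default_report):
        t = default_report.table
        decoy_genes = set(default_cohort.decoys["gene_id"])
        decoy_rows = t[t["anchor_gene"].isin(decoy_genes)]
        assert len(decoy_rows) == len(decoy_genes)
        assert (decoy_rows["system_label"] == "unknown").all()


class TestIslandScore:
    def _locus(self, ann, anchor_pid, hits):
        nb, by_protein = _neighborhood(ann, anchor_pid, hits)
        call = classify_locus(nb)
        call.genome_id = ann.genome_id
        return call, by_protein

    def test_adjacent_transposase_scores(self):
        ann = _genome(5)
        hits = [
            _hit("p2", "nuclease", 500.0, 1, 300),
            _hit("p3", "transposase", 300.0, 1, 200),
        ]
        call, by_protein = self._locus(ann, "p2", hits)
        assert island_score(ann, call, hits_by_protein=by_protein) >= 1

    def test_isolated_locus_scores_zero(self):
        ann = _genome(5)
        hits = [_hit("p2", "nuclease", 500.0, 1, 300)]
        call, by_protein = self._locus(ann, "p2", hits)
        assert island_score(ann, call, hits_by_protein=by_protein) == 0

    def test_monotone_in_window_size(self):
        ann = _genome(12)
        hits = [
            _hit("p5", "nuclease", 500.0, 1, 300),
            _hit("p0", "transposase", 300.0, 1, 200),
            _hit("p11", "RT", 300.0, 1, 200),
        ]
        call, by_protein = self._locus(ann, "p5", hits)
        scores = [
            island_score(ann, call, extended_window_kb=w, hits_by_protein=by_protein)
            for w in (1, 3, 6, 12, 24)
        ]
        assert scores == sorted(scores)
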