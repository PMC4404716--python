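"""Marker filter cascade: context, allele, paralog, organelle, splice,
redundancy and probe-similarity screens, and manifest construction."""

import pytest

from polymine.align_core import revcomp
from polymine.io_formats import SequenceRecord
from polymine.marker_design import (
    FilterParams, assign_snp_ids, build_array,
    chloroplast_screen, classify_and_screen_alleles, cross_set_dedup,
    extract_context, paralog_filter, probe_count, probe_similarity_screen,
    run_cascade, splice_junction_screen,
)
from polymine.snp_mining import SNPCall

from tests.conftest import random_seq


def snp(tid="t1", pos=50, ref="A", alt="G"):
    counts = {b: 0 for b in "ACGT"}
    counts[ref] = 20
    counts[alt] = 10
    return SNPCall(tid, pos, ref, alt, counts,
                   {b: int(b in (ref, alt)) for b in "ACGT"}, True)


def candidate_from(seq, pos, ref=None, alt="G", set_code="K"):
    ref = ref or seq[pos]
    t = SequenceRecord("t1", seq)
    return extract_context(snp("t1", pos, ref, alt), t, [pos], set_code)


class TestExtractContext:
    def test_interior_snp_yields_71mer(self, rng):
        seq = random_seq(rng, 100)
        cand = candidate_from(seq, 40)
        assert cand is not None
        assert len(cand.context) == 71
        assert cand.context == seq[5:76]

    def test_snp_too_close_to_edge_rejected(self, rng):
        assert candidate_from(random_seq(rng, 100), 20) is None

    def test_neighbouring_variant_in_window_rejected(self, rng):
        seq = random_seq(rng, 120)
        t = SequenceRecord("t1", seq)
        out = extract_context(snp("t1", 50), t, [50, 60], "K")
        assert out is None

    def test_ambiguous_base_in_window_rejected(self, rng):
        seq = random_seq(rng, 120)
        seq = seq[:60] + "N" + seq[61:]
        t = SequenceRecord("t1", seq)
        assert extract_context(snp("t1", 50), t, [50], "K") is None


class TestAlleleScreen:
    @pytest.mark.parametrize("ref,alt,kept,klass", [
        ("C", "T", True, "transition"),
        ("A", "G", True, "transition"),
        ("A", "T", False, "strand-ambiguous"),
        ("C", "G", False, "strand-ambiguous"),
        ("A", "C", True, "transversion"),
    ])
    def test_classes(self, rng, ref, alt, kept, klass):
        seq = random_seq(rng, 120)
        seq = seq[:50] + ref + seq[51:]
        cand = candidate_from(seq, 50, ref, alt)
        assert classify_and_screen_alleles(cand) is kept
        assert cand.snp_class == klass


class TestParalogFilter:
    def test_unique_transcript_passes_on_self_hit(self, rng):
        seq = random_seq(rng, 400)
        t = SequenceRecord("t1", seq)
        cand = candidate_from(seq, 50)
        db = [t, SequenceRecord("t2", random_seq(rng, 400))]
        assert paralog_filter(cand, t, db)

    def test_planted_paralog_fails(self, rng):
        seq = random_seq(rng, 400)
        paralog = list(seq)
        for pos in range(0, 390, 13):  # ~92% identity over full length
            paralog[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[paralog[pos]]
        t = SequenceRecord("t1", seq)
        db = [t, SequenceRecord("t1p", "".join(paralog))]
        cand = candidate_from(seq, 50)
        assert not paralog_filter(cand, t, db)

    def test_transcript_absent_from_db_passes(self, rng):
        seq = random_seq(rng, 400)
        t = SequenceRecord("t1", seq)
        cand = candidate_from(seq, 50)
        db = [SequenceRecord("other", random_seq(rng, 400))]
        assert paralog_filter(cand, t, db)


class TestChloroplastScreen:
    def test_context_copied_from_chloroplast_fails(self, rng):
        chloro = SequenceRecord("cp", random_seq(rng, 2000))
        seq = chloro.seq[300:420]
        cand = candidate_from(seq, 60)
        assert not chloroplast_screen(cand, [chloro])

    def test_empty_chloroplast_db_passes(self, rng):
        cand = candidate_from(random_seq(rng, 120), 60)
        assert chloroplast_screen(cand, [])

    def test_unrelated_context_passes(self, rng):
        chloro = SequenceRecord("cp", random_seq(rng, 2000))
        cand = candidate_from(random_seq(rng, 120), 60)
        assert chloroplast_screen(cand, [chloro])


class TestSpliceScreen:
    def test_threshold_is_68_for_35nt_flanks(self):
        assert FilterParams(flank=35).splice_min_match == 68
        # recomputed when the flank changes
        assert FilterParams(flank=40).splice_min_match == 77

    def test_context_inside_one_exon_passes(self, rng):
        genome = SequenceRecord("chr", random_seq(rng, 3000))
        seq = genome.seq[1000:1300]
        cand = candidate_from(seq, 100)
        assert splice_junction_screen(cand, [genome])

    def test_context_spanning_junction_fails(self, rng):
        exon1 = random_seq(rng, 500)
        exon2 = random_seq(rng, 500)
        intron = random_seq(rng, 300)
        genome = SequenceRecord("chr", exon1 + intron + exon2)
        transcript = exon1 + exon2
        # SNP 5 bp left of the junction: 40/31 split of the 71-mer
        cand = candidate_from(transcript, 495)
        assert not splice_junction_screen(cand, [genome])

    def test_no_genomic_hit_passes(self, rng):
        genome = SequenceRecord("chr", random_seq(rng, 3000))
        cand = candidate_from(random_seq(rng, 200), 100)
        assert splice_junction_screen(cand, [genome])


class TestCrossSetDedup:
    def test_same_marker_in_two_sets_keeps_priority_set(self, rng):
        seq = random_seq(rng, 120)
        c_g = candidate_from(seq, 50, set_code="G")
        c_k = candidate_from(seq, 50, set_code="K")
        kept, dropped = cross_set_dedup([c_g, c_k])
        assert [c.set_code for c in kept] == ["K"]
        assert [c.set_code for c in dropped] == ["G"]

    def test_reverse_complement_duplicate_detected(self, rng):
        seq = random_seq(rng, 120)
        c_k = candidate_from(seq, 50)
        rc_seq = revcomp(seq)
        rc_pos = len(seq) - 1 - 50
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        t = SequenceRecord("t1", rc_seq)
        c_g = extract_context(
            snp("t1", rc_pos, comp[seq[50]], comp["G"]), t, [rc_pos], "G"
        )
        kept, dropped = cross_set_dedup([c_k, c_g])
        assert len(kept) == 1 and kept[0].set_code == "K"

    def test_disjoint_markers_all_kept(self, rng):
        cands = [candidate_from(random_seq(rng, 120), 50, set_code=c)
                 for c in "KGMD"]
        kept, dropped = cross_set_dedup(cands)
        assert len(kept) == 4 and not dropped


class TestProbeSimilarity:
    def test_near_identical_pair_drops_one(self, rng):
        seq = random_seq(rng, 120)
        c1 = candidate_from(seq, 50, set_code="K")
        seq2 = seq[:20] + ("A" if seq[20] != "A" else "C") + seq[21:]
        c2 = candidate_from(seq2, 50, set_code="G")
        assign_snp_ids([c1, c2])
        kept, dropped = probe_similarity_screen([c1, c2])
        assert [c.set_code for c in kept] == ["K"]
        assert [c.set_code for c in dropped] == ["G"]

    def test_random_contexts_all_kept(self, rng):
        cands = [candidate_from(random_seq(rng, 120), 50) for _ in range(6)]
        assign_snp_ids(cands)
        kept, dropped = probe_similarity_screen(cands)
        assert len(kept) == 6 and not dropped


class TestBuildArray:
    def _markers(self, rng, n, set_code="K"):
        out = []
        for _ in range(n):
            c = candidate_from(random_seq(rng, 120), 50, set_code=set_code)
            classify_and_screen_alleles(c)
            out.append(c)
        return out

    def test_two_probes_per_snp(self, rng):
        manifest = build_array(self._markers(rng, 3))
        assert probe_count(manifest) == 6
        for row in manifest:
            assert row.probe_id_fwd != row.probe_id_rev

    def test_id_scheme_set_transcript_snp(self, rng):
        seq = random_seq(rng, 200)
        t = SequenceRecord("t17", seq)
        c1 = extract_context(snp("t17", 60), t, [60], "K")
        c2 = extract_context(snp("t17", 130), t, [130], "K")
        assign_snp_ids([c1, c2])
        assert c1.snp_id == "K_1_1"
        assert c2.snp_id == "K_1_2"  # second SNP on the same transcript
        import re
        assert re.match(r"^[KGMD]_\d+_\d+$", c1.snp_id)

    def test_empty_marker_set_gives_empty_manifest(self):
        assert build_array([]) == []


class TestCascade:
    def test_every_input_in_manifest_or_rejections(self, rng):
        seq = random_seq(rng, 300)
        ref = SequenceRecord("t1", seq)
        calls = [
            snp("t1", 80, seq[80], "G" if seq[80] != "G" else "A"),
            snp("t1", 90, seq[90], "C" if seq[90] != "C" else "T"),   # crowded pair
            snp("t1", 200, seq[200], "A" if seq[200] != "A" else "T"),
        ]
        result = run_cascade(
            snp_calls_by_set={"K": calls},
            transcripts_by_set={"K": {"t1": ref}},
            reference_by_set={"K": [ref]},
            chloro_genome=[],
            genome_db=[],
        )
        n_out = len(result.manifest) + len(result.rejections)
        assert n_out == len(calls)
        # crowded pair rejected at the context stage
        stages = {(r.pos, r.stage) for r in result.rejections}
        assert (80, "context") in stages and (90, "context") in stages

    def test_manifest_never_contains_strand_ambiguous(self, rng):
        seq = random_seq(rng, 300)
        ref = SequenceRecord("t1", seq)
        calls = [snp("t1", 100, "A", "T"), snp("t1", 200, "C", "G")]
        result = run_cascade({"K": calls}, {"K": {"t1": ref}}, {"K": [ref]},
                             [], [])
        assert result.manifest == []
        assert all(r.stage == "allele_class" for r in result.rejections)
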