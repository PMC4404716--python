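"""Alignment/assembly kernels vs exhaustive oracles and planted truths."""

import pytest
from hypothesis import given, settings, strategies as st

from polymine.align_core import (
    AlignParams, BatchReadMapper, OverlapAsmParams, local_align, map_read,
    mapq_from_scores, overlap_assemble, revcomp, search, six_frame_translations,
    translated_search,
)
from polymine.io_formats import SequenceRecord
from polymine.synthetic_data import _CODON_TABLE

from tests.conftest import random_seq


def sw_score_oracle(a, b, match=2, mismatch=-3, go=-5, ge=-2):
    """Exhaustive affine-gap local-alignment score, no seeding or pruning."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def back_translate(protein):
    return "".join(_CODON_TABLE[aa][0] for aa in protein)


class TestLocalAlign:
    def test_identical_sequences_full_identity(self):
        aln = local_align("ACGTACGTAC", "ACGTACGTAC")
        assert aln.identity == 1.0
        assert (aln.query_start, aln.query_end) == (0, 10)
        assert (aln.subject_start, aln.subject_end) == (0, 10)

    def test_disjoint_alphabets_score_zero(self):
        aln = local_align("AAAA", "CCCC", AlignParams(match=1, mismatch=-2))
        assert aln.score == 0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_score_matches_exhaustive_dp_oracle(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=50))
        b = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=50))
        aln = local_align(a, b)
        assert aln.score == sw_score_oracle(a, b)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_cigar_rescored_equals_reported_score(self, data):
        a = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        b = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=40))
        aln = local_align(a, b)
        if aln.score == 0:
            return
        import re
        score = 0
        for n, op in re.findall(r"(\d+)([=XID])", aln.cigar):
            n = int(n)
            if op == "=":
                score += 2 * n
            elif op == "X":
                score -= 3 * n
            else:
                score -= 5 + 2 * (n - 1)
        assert score == aln.score


class TestSearch:
    def test_exact_copy_is_top_hit(self, rng, make_records):
        db = make_records([random_seq(rng, 100) for _ in range(10)])
        hits = search(db[3].seq, db)
        assert hits[0].subject_id == db[3].id
        assert hits[0].identity == 1.0

    def test_reverse_complement_found_on_minus_strand(self, rng, make_records):
        (rec,) = make_records([random_seq(rng, 80)])
        hits = search(revcomp(rec.seq), [rec])
        assert hits and hits[0].strand == "-"

    def test_deterministic_hit_lists(self, rng, make_records):
        db = make_records([random_seq(rng, 120) for _ in range(15)])
        q = db[5].seq[10:70]
        assert search(q, db) == search(q, db)

    def test_planted_90pct_subject_always_top(self, rng, make_records):
        wins = 0
        for _ in range(100):
            query = random_seq(rng, 60)
            mutated = list(query)
            for pos in rng.choice(60, size=6, replace=False):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            planted = random_seq(rng, 10) + "".join(mutated) + random_seq(rng, 10)
            db = make_records([random_seq(rng, 80) for _ in range(8)], prefix="d")
            db.append(SequenceRecord("planted", planted))
            hits = search(query, db)
            wins += bool(hits) and hits[0].subject_id == "planted"
        assert wins == 100

    def test_empty_db_empty_result(self):
        assert search("ACGTACGTACGT", []) == []


class TestTranslatedSearch:
    def test_backtranslation_top_hit_frame_plus1(self, rng):
        prot = "M" + "".join("ARNDCEQGHILKFPSTWYV"[i] for i in rng.integers(0, 19, 40))
        db = [SequenceRecord("p1", prot), SequenceRecord("p2", "W" * 40)]
        hits = translated_search(back_translate(prot), db)
        assert hits[0].subject_id == "p1"
        assert hits[0].frame == 1

    def test_frameshift_detected_as_frame_plus2(self, rng):
        prot = "M" + "".join("ARNDCEQGHILKFPSTWYV"[i] for i in rng.integers(0, 19, 40))
        db = [SequenceRecord("p1", prot)]
        hits = translated_search("G" + back_translate(prot), db)
        assert hits[0].subject_id == "p1"
        assert hits[0].frame == 2

    def test_six_frames_cover_both_strands(self):
        frames = [f for f, _ in six_frame_translations("ATGAAACCCGGGTTTTAA")]
        assert sorted(frames) == [-3, -2, -1, 1, 2, 3]

    @given(st.data())
    @settings(max_examples=15, deadline=None)
    def test_scores_match_per_frame_oracle(self, data):
        q = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=45))
        prot = data.draw(st.text(alphabet="ARNDCEQGHILK", min_size=15, max_size=25))
        db = [SequenceRecord("p", prot)]
        params = AlignParams.protein(min_hit_score=1, min_shared_kmers=1)
        hits = translated_search(q, db, params)
        # oracle: best protein-level local alignment over all stop-free
        # segments of all six translations
        best = 0
        for _, tr in six_frame_translations(q):
            for seg in tr.split("*"):
                if len(seg) >= params.k:
                    best = max(best, local_align(seg, prot, params).score)
        if best >= 1:
            assert hits and hits[0].score == best
        else:
            assert not hits


class TestMapRead:
    def test_unique_exact_hit_gets_cap_mapq(self, rng, make_records):
        db = make_records([random_seq(rng, 200) for _ in range(5)])
        aln = map_read(db[2].seq[50:125], db)
        assert aln.subject_id == db[2].id and aln.mapq == 60

    def test_identical_references_give_mapq_zero(self, rng):
        s = random_seq(rng, 200)
        db = [SequenceRecord("a", s), SequenceRecord("b", s)]
        aln = map_read(s[60:135], db)
        assert aln.mapq == 0

    def test_read_with_diagnostic_bases_clears_filter(self, rng):
        ref = random_seq(rng, 300)
        paralog = list(ref)
        for pos in range(3, 300, 7):  # ~85% identity, evenly spread
            paralog[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[paralog[pos]]
        db = [SequenceRecord("gene", ref), SequenceRecord("paralog", "".join(paralog))]
        aln = map_read(ref[100:175], db)
        assert aln.subject_id == "gene"
        assert aln.mapq > 25

    def test_mapq_surrogate_endpoints(self):
        assert mapq_from_scores(150, None) == 60
        assert mapq_from_scores(150, 150) == 0
        assert mapq_from_scores(150, 140) == 30


class TestBatchReadMapper:
    def test_placement_agrees_with_edlib(self, rng, make_records):
        edlib = pytest.importorskip("edlib")
        refs = make_records([random_seq(rng, 500) for _ in range(4)])
        mapper = BatchReadMapper(refs)
        for _ in range(20):
            ridx = int(rng.integers(0, 4))
            start = int(rng.integers(0, 425))
            read = refs[ridx].seq[start : start + 75]
            m = mapper.map(read)
            assert m is not None and m.ref_id == refs[ridx].id
            res = edlib.align(read, refs[ridx].seq, mode="HW", task="locations")
            starts = {loc[0] for loc in res["locations"]}
            assert m.start in starts

    def test_reverse_strand_reads_are_oriented(self, rng, make_records):
        refs = make_records([random_seq(rng, 300)])
        mapper = BatchReadMapper(refs)
        m = mapper.map(revcomp(refs[0].seq[100:175]))
        assert m.strand == "-" and m.start == 100
        assert m.seq == refs[0].seq[100:175]


class TestOverlapAssemble:
    def test_two_reads_with_exact_overlap_reconstruct_source(self, rng):
        src = random_seq(rng, 250)
        reads = [SequenceRecord("a", src[:150]), SequenceRecord("b", src[100:])]
        contigs, members = overlap_assemble(reads)
        assert len(contigs) == 1
        assert contigs[0].seq == src
        assert {m for m, _ in members[contigs[0].id]} == {"a", "b"}

    def test_unrelated_sequences_stay_apart(self, rng):
        a, b = random_seq(rng, 200), random_seq(rng, 200)
        contigs, _ = overlap_assemble(
            [SequenceRecord("a", a), SequenceRecord("b", b)]
        )
        assert sorted(c.seq for c in contigs) == sorted([a, b])

    def test_tiling_fragments_recover_gene(self, rng):
        gene = random_seq(rng, 1000)
        frags = []
        for i, start in enumerate(range(0, 900, 50)):
            frags.append(SequenceRecord(f"f{i}", gene[start : start + 150]))
        contigs, _ = overlap_assemble(frags)
        assert len(contigs) == 1
        aln = local_align(contigs[0].seq, gene)
        assert aln.identity >= 0.999

    def test_reverse_complement_member_joined(self, rng):
        src = random_seq(rng, 250)
        reads = [SequenceRecord("a", src[:150]), SequenceRecord("b", revcomp(src[100:]))]
        contigs, members = overlap_assemble(reads)
        assert len(contigs) == 1 and len(contigs[0].seq) == 250

    def test_low_identity_overlap_not_merged(self, rng):
        src = random_seq(rng, 200)
        a = src[:120]
        b = list(src[80:])
        for pos in range(0, 40, 4):  # 10% divergence in the overlap
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        contigs, _ = overlap_assemble(
            [SequenceRecord("a", a), SequenceRecord("b", "".join(b))],
            OverlapAsmParams(min_overlap_len=40, min_overlap_identity=0.97),
        )
        assert len(contigs) == 2

    def test_contig_never_shorter_than_longest_member(self, rng):
        src = random_seq(rng, 300)
        pieces = [SequenceRecord(f"p{i}", src[s : s + 160])
                  for i, s in enumerate((0, 70, 140))]
        contigs, members = overlap_assemble(pieces)
        by_id = {p.id: len(p.seq) for p in pieces}
        for c in contigs:
            longest = max(by_id[m] for m, _ in members[c.id])
            assert len(c.seq) >= longest
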