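"""Orthology-guided assembly: grouping, reciprocity, ORFs, full-length."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polymine.align_core import revcomp
from polymine.io_formats import IntegrityError, SequenceRecord
from polymine.ortholog_assembly import (
    ORF, annotate, assemble_group, assemble_orthologs,
    call_full_length, group_by_guide, longest_orf, reciprocal_check,
    reassemble_trimmed, trim_to_orf,
)
from polymine.synthetic_data import _CODON_TABLE

from tests.conftest import random_seq

AA19 = "ARNDCEQGHILKFPSTWYV"  # no Met: appended starts stay unique


def back_translate(protein, stop="TAA"):
    return "".join(_CODON_TABLE[aa][0] for aa in protein) + stop


def orf_oracle(seq):
    """Exhaustive enumeration of all ATG..stop spans in six frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, len(s) - 2, 3):
                codon = s[j : j + 3]
                if codon in stops:
                    length = j + 3 - i
                    if best is None or length > best[0]:
                        best = (length, strand, i, j + 3)
                    break
    return best


class TestLongestOrf:
    def test_whole_sequence_orf(self):
        orf = longest_orf("ATGAAATAG")
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")
        assert orf.protein == "MK"

    def test_utrs_trimmed(self):
        orf = longest_orf("CCCATGAAATAGCCC")
        assert (orf.start, orf.end) == (3, 12)
        contig = SequenceRecord("c", "CCCATGAAATAGCCC")
        assert trim_to_orf(contig, orf).seq == "ATGAAATAG"

    def test_no_orf_returns_none(self):
        assert longest_orf("CCCCCCCC") is None

    def test_reverse_strand_orf_found(self):
        fwd = "ATGAAACCCGGGTAG"
        orf = longest_orf(revcomp(fwd))
        assert orf.strand == "-"
        assert orf.protein == "MKPG"

    @given(st.text(alphabet="ACGT", min_size=6, max_size=200))
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_enumeration(self, seq):
        got = longest_orf(seq)
        expected = orf_oracle(seq)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert len(got) == expected[0]
            assert (got.end - got.start) % 3 == 0
            assert "*" not in got.protein


class TestGroupByGuide:
    def test_backtranslated_transcript_assigned_to_its_protein(self, rng):
        prots = []
        for i in range(5):
            p = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 60))
            prots.append(SequenceRecord(f"P{i}", p))
        t = SequenceRecord("t1", back_translate(prots[2].seq))
        groups, unassigned = group_by_guide([t], prots)
        assert list(groups) == ["P2"]
        assert not unassigned

    def test_random_transcript_unassigned(self, rng):
        prots = [SequenceRecord("P0", "M" + "".join(
            AA19[j] for j in rng.integers(0, 19, 60)))]
        t = SequenceRecord("t1", random_seq(rng, 200))
        groups, unassigned = group_by_guide([t], prots)
        assert unassigned == ["t1"]

    def test_overlapping_fragments_share_one_group(self, rng):
        prot = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 200))
        cds = back_translate(prot)
        prots = [SequenceRecord("P0", prot)]
        frags = [SequenceRecord(f"f{i}", cds[s : s + 240])
                 for i, s in enumerate(range(0, len(cds) - 240, 120))]
        groups, unassigned = group_by_guide(frags, prots)
        assert not unassigned
        assert len(groups["P0"]) == len(frags)


class TestAssembleGroup:
    def test_exactly_overlapping_fragments_merge(self, rng):
        src = random_seq(rng, 300)
        contigs, _ = assemble_group(
            [SequenceRecord("a", src[:180]), SequenceRecord("b", src[120:])]
        )
        assert len(contigs) == 1 and contigs[0].seq == src

    def test_disjoint_fragments_stay_apart(self, rng):
        contigs, _ = assemble_group(
            [SequenceRecord("a", random_seq(rng, 150)),
             SequenceRecord("b", random_seq(rng, 150))]
        )
        assert len(contigs) == 2


class TestReciprocalCheck:
    def _protein(self, rng, n=120):
        return "M" + "".join(AA19[j] for j in rng.integers(0, 19, n - 1))

    def test_ortholog_with_distant_decoy_kept(self, rng):
        p = self._protein(rng)
        decoy = list(p)
        for i in range(1, len(decoy), 3):  # ~2/3 identity decoy
            decoy[i] = AA19[(AA19.index(decoy[i]) + 5) % 19] if decoy[i] in AA19 else "A"
        proteome = [SequenceRecord("P", p), SequenceRecord("Pdecoy", "".join(decoy))]
        contig = SequenceRecord("c", back_translate(p))
        assert reciprocal_check(contig, proteome, "P")

    def test_contig_closer_to_other_protein_dropped(self, rng):
        p = self._protein(rng)
        other = self._protein(rng)
        proteome = [SequenceRecord("P", p), SequenceRecord("Q", other)]
        contig = SequenceRecord("c", back_translate(other))
        assert not reciprocal_check(contig, proteome, "P")

    def test_single_protein_proteome_trivially_keeps(self, rng):
        p = self._protein(rng)
        contig = SequenceRecord("c", back_translate(p))
        assert reciprocal_check(contig, [SequenceRecord("P", p)], "P")


class TestFullLength:
    def test_exact_backtranslation_is_full_length(self, rng):
        prot = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 80))
        final = SequenceRecord("P.m1", back_translate(prot))
        assert call_full_length(final, SequenceRecord("P", prot))

    def test_missing_start_codon_not_full_length(self, rng):
        prot = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 80))
        cds = back_translate(prot)
        final = SequenceRecord("P.m1", cds[3:])
        assert not call_full_length(final, SequenceRecord("P", prot))

    def test_short_coverage_not_full_length(self, rng):
        prot = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 80))
        # an ORF covering only ~60% of the guide
        sub = "M" + prot[33:]
        final = SequenceRecord("P.m1", back_translate(sub))
        assert not call_full_length(final, SequenceRecord("P", prot))


class TestReassembleAndNaming:
    def test_single_orf_passes_through_named_m1(self, rng):
        s = SequenceRecord("a_cds", "ATG" + random_seq(rng, 150) + "TAA")
        finals, members = reassemble_trimmed([s], "FV00001")
        assert [f.id for f in finals] == ["FV00001.m1"]
        assert finals[0].seq == s.seq

    def test_identical_trimmed_orfs_collapse(self, rng):
        seq = "ATG" + random_seq(rng, 150) + "TAA"
        finals, _ = reassemble_trimmed(
            [SequenceRecord("a_cds", seq), SequenceRecord("b_cds", seq)],
            "FV00002",
        )
        assert len(finals) == 1 and finals[0].seq == seq

    def test_m_numbers_by_descending_length(self, rng):
        finals, _ = reassemble_trimmed(
            [SequenceRecord("a_cds", "ATG" + random_seq(rng, 90) + "TAA"),
             SequenceRecord("b_cds", "ATG" + random_seq(rng, 300) + "TAA")],
            "FV00003",
        )
        assert [f.id for f in finals] == ["FV00003.m1", "FV00003.m2"]
        assert len(finals[0].seq) > len(finals[1].seq)


class TestAnnotate:
    def _table(self):
        return pd.DataFrame({
            "protein_id": ["P1", "P2"],
            "annotation": ["kinase", "transporter"],
        })

    def test_present_key_copied(self):
        seqs = [SequenceRecord("P1.m1", "ATG")]
        out = annotate(seqs, {"P1.m1": "P1"}, self._table())
        assert out.loc[0, "annotation"] == "kinase"

    def test_absent_key_empty(self):
        seqs = [SequenceRecord("P9.m1", "ATG")]
        out = annotate(seqs, {"P9.m1": "P9"}, self._table())
        assert out.loc[0, "annotation"] == ""

    def test_duplicate_keys_rejected(self):
        bad = pd.DataFrame({"protein_id": ["P1", "P1"],
                            "annotation": ["x", "y"]})
        with pytest.raises(IntegrityError, match="duplicate"):
            annotate([SequenceRecord("P1.m1", "ATG")], {"P1.m1": "P1"}, bad)


class TestEndToEnd:
    def test_singleton_groups_discarded(self, rng):
        prot = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 100))
        proteome = [SequenceRecord("P", prot)]
        t = SequenceRecord("t1", back_translate(prot))
        res = assemble_orthologs([t], proteome)
        assert res.final_sequences == []
        assert res.singletons_discarded == ["t1"]

    def test_reciprocal_invariant_holds_for_all_outputs(self, rng):
        prots, transcripts = [], []
        for i in range(4):
            p = "M" + "".join(AA19[j] for j in rng.integers(0, 19, 100))
            prots.append(SequenceRecord(f"P{i}", p))
            cds = back_translate(p)
            transcripts.append(SequenceRecord(f"t{i}a", "GG" + cds[:240]))
            transcripts.append(SequenceRecord(f"t{i}b", cds[120:] + "CC"))
        res = assemble_orthologs(transcripts, prots)
        assert res.final_sequences
        for s in res.final_sequences:
            gid = res.guide_of_sequence[s.id]
            assert reciprocal_check(s, prots, gid)
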