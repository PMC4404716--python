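"""Haplotype-aware SNP calling: thresholds, clustering, ploidy ceiling."""

import numpy as np
import pytest

from polymine.align_core import MappedRead
from polymine.io_formats import SequenceRecord
from polymine.snp_mining import (
    PloidyModel, Pileup, SnpMiningParams, build_pileups, build_reference,
    call_candidates, call_reliable, cluster_haplotypes, filter_by_ploidy,
    mine_transcript, snp_stats,
)

from tests.conftest import random_seq


def pileup_from_reads(ref, reads, start_of, params=None):
    """Build a pileup from gapless read placements on one reference."""
    mapped = [
        MappedRead(
            read_id=rid, ref_idx=0, ref_id=ref.id, start=start_of[rid],
            strand="+", seq=seq, query_offset=0, aligned_len=len(seq),
            cigar=f"{len(seq)}M", score=2 * len(seq), identity=1.0, mapq=60,
            multi_refs=(0,),
        )
        for rid, seq in reads
    ]
    return build_pileups(mapped, [ref], params)[ref.id]


def reads_from_haplotypes(haps, read_len=40, step=10, n_copies=3):
    """Error-free tiling reads from each haplotype."""
    reads, start_of = [], {}
    i = 0
    for h, hap in enumerate(haps):
        for rep in range(n_copies):
            for s in range(0, len(hap) - read_len + 1, step):
                rid = f"h{h}_c{rep}_s{s}"
                reads.append((rid, hap[s : s + read_len]))
                start_of[rid] = s
                i += 1
    return reads, start_of


class TestCallCandidates:
    def _pileup(self, counts_by_pos, length=100):
        p = Pileup.empty("t", length)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos, counts in counts_by_pos.items():
            for base, n in counts.items():
                if base in idx:
                    p.counts[pos, idx[base]] = n
        return p

    def test_five_vs_five_is_candidate(self):
        p = self._pileup({10: {"A": 5, "G": 5}})
        assert call_candidates(p, 5) == [10]

    def test_four_reads_below_floor(self):
        p = self._pileup({10: {"A": 100, "G": 4}})
        assert call_candidates(p, 5) == []

    def test_ambiguous_bases_ignored(self):
        # N observations never count toward an allele
        p = self._pileup({10: {"A": 5, "G": 5, "N": 3}})
        assert call_candidates(p, 5) == [10]
        calls = call_reliable(
            p, cluster_haplotypes(p, [10], SnpMiningParams(min_cluster_reads=2))
        )
        assert {calls[0].ref, calls[0].alt} == {"A", "G"}


class TestClusterHaplotypes:
    def test_two_planted_haplotypes_recovered(self, rng):
        base = random_seq(rng, 200)
        hap1 = list(base)
        hap2 = list(base)
        for pos in (50, 80, 110, 140):
            hap1[pos] = "A" if base[pos] != "A" else "C"
            hap2[pos] = "G" if base[pos] != "G" else "T"
        ref = SequenceRecord("t", base)
        reads, start_of = reads_from_haplotypes(["".join(hap1), "".join(hap2)],
                                                read_len=60, step=10, n_copies=3)
        pile = pileup_from_reads(ref, reads, start_of)
        table = cluster_haplotypes(pile)
        assert table.n_haplotypes == 2
        consensi = {tuple(sorted(c.consensus.items())) for c in table.clusters}
        assert len(consensi) == 2

    def test_identical_reads_single_cluster(self, rng):
        base = random_seq(rng, 100)
        ref = SequenceRecord("t", base)
        # all fragments carry the same allele vector -> one cluster; the
        # position is polymorphic through a (virtual) second allele set
        reads = [(f"r{i}", base[20:80]) for i in range(10)]
        start_of = {f"r{i}": 20 for i in range(10)}
        pile = pileup_from_reads(ref, reads, start_of)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        other = (idx[base[40]] + 2) % 4
        pile.counts[40, other] = 5  # second allele set, observed by no read here
        table = cluster_haplotypes(pile, [40])
        assert len(table.clusters) == 1

    def test_exact_similarity_isolates_erroneous_read(self, rng):
        # two linked SNPs; one read from haplotype A carries an error that
        # turns the second site into haplotype G's allele: under sim_min=1.0
        # the chimeric read conflicts with both clusters and is discarded
        base = random_seq(rng, 100)
        hapA = base[:35] + "C" + base[36:50] + "A" + base[51:]
        hapG = base[:35] + "T" + base[36:50] + "G" + base[51:]
        reads, start_of = reads_from_haplotypes([hapA, hapG], read_len=60,
                                                step=20, n_copies=3)
        err = hapA[20:80]
        err = err[:30] + "G" + err[31:]  # site 50 flips to the other allele
        reads.append(("err", err))
        start_of["err"] = 20
        ref = SequenceRecord("t", base)
        pile = pileup_from_reads(ref, reads, start_of)
        params = SnpMiningParams(sim_min=1.0)
        table = cluster_haplotypes(pile, [35, 50], params)
        assert "err" not in {f for c in table.clusters for f in c.fragment_keys}


class TestPloidyCeiling:
    def _table_with(self, n_clusters):
        from polymine.snp_mining import HaplotypeCluster, HaplotypeTable
        clusters = [HaplotypeCluster(0, {0: "A"}, 3) for _ in range(n_clusters)]
        return HaplotypeTable("t", [0], clusters, n_clusters)

    @pytest.mark.parametrize("n,ploidy,inds,keep", [
        (9, 4, 2, False),   # over the 8-haplotype ceiling
        (8, 4, 2, True),    # boundary: exactly at the ceiling
        (3, 2, 1, False),   # diploid single individual
        (2, 2, 1, True),
    ])
    def test_ceiling(self, n, ploidy, inds, keep):
        model = PloidyModel(ploidy=ploidy, n_individuals=inds)
        assert filter_by_ploidy(self._table_with(n), model) is keep

    def test_two_tetraploid_parents_expect_eight(self):
        assert PloidyModel(4, 2).max_haplotypes == 8

    def test_paralog_collapse_discards_transcript(self, rng):
        # two genes at ~85% identity forced into one reference; pooled
        # tetraploid parents -> far more apparent haplotypes than 8
        base = random_seq(rng, 300)
        other = list(base)
        for pos in range(2, 300, 7):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        haps = []
        for h in range(8):
            hap = list(base)
            for pos in range(5, 300, 23 + h):
                hap[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[hap[pos]]
            haps.append("".join(hap))
        haps.append("".join(other))
        reads, start_of = reads_from_haplotypes(haps, read_len=75, step=5,
                                                n_copies=2)
        ref = SequenceRecord("t", base)
        pile = pileup_from_reads(ref, reads, start_of)
        calls, table, kept = mine_transcript(pile, PloidyModel(4, 2))
        assert not kept and calls == []
        assert table.n_haplotypes > 8


class TestCallReliable:
    def test_error_singleton_allele_not_reliable(self, rng):
        base = random_seq(rng, 120)
        hapA = base[:60] + "A" + base[61:]
        hapG = base[:60] + "G" + base[61:]
        reads, start_of = reads_from_haplotypes([hapA, hapG], read_len=50,
                                                step=10, n_copies=3)
        ref = SequenceRecord("t", base)
        pile = pileup_from_reads(ref, reads, start_of)
        # fake a third allele just under the floor
        pile.counts[90, :] = 0
        pile.counts[90, 0] = 30
        pile.counts[90, 1] = 4
        calls, _, kept = mine_transcript(pile, PloidyModel(4, 2))
        assert kept
        by_pos = {c.pos: c for c in calls}
        assert by_pos[60].reliable
        assert 90 not in by_pos or not by_pos[90].reliable

    def test_no_reliable_call_violates_read_floor(self, rng):
        base = random_seq(rng, 200)
        haps = []
        for h in range(4):
            hap = list(base)
            for pos in range(15 + h, 200, 31):
                hap[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[hap[pos]]
            haps.append("".join(hap))
        reads, start_of = reads_from_haplotypes(haps, read_len=60, step=7,
                                                n_copies=2)
        ref = SequenceRecord("t", base)
        pile = pileup_from_reads(ref, reads, start_of)
        calls, _, _ = mine_transcript(pile, PloidyModel(4, 1))
        for c in calls:
            if c.reliable:
                assert c.counts[c.ref] >= 5 and c.counts[c.alt] >= 5
                assert c.hap_support[c.ref] >= 1 and c.hap_support[c.alt] >= 1

    def test_deterministic_clustering(self, rng):
        base = random_seq(rng, 150)
        hapA = base[:70] + "A" + base[71:]
        hapC = base[:70] + "C" + base[71:]
        reads, start_of = reads_from_haplotypes([hapA, hapC], read_len=50,
                                                step=9, n_copies=3)
        ref = SequenceRecord("t", base)
        pile = pileup_from_reads(ref, reads, start_of)
        t1 = cluster_haplotypes(pile)
        t2 = cluster_haplotypes(pile)
        assert [c.consensus for c in t1.clusters] == [c.consensus for c in t2.clusters]


class TestBuildReference:
    def test_identical_transcripts_collapse(self, rng):
        s = random_seq(rng, 400)
        ref, members = build_reference(
            [[SequenceRecord("a_t1", s)], [SequenceRecord("b_t1", s)]]
        )
        assert len(ref) == 1
        assert {m for m, _ in members[ref[0].id]} == {"a_t1", "b_t1"}

    def test_divergent_transcripts_stay_apart(self, rng):
        s = random_seq(rng, 400)
        other = list(s)
        for pos in range(0, 400, 10):  # 10% divergence, below -p 97
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        ref, _ = build_reference(
            [[SequenceRecord("a_t1", s)], [SequenceRecord("b_t1", "".join(other))]]
        )
        assert len(ref) == 2


class TestSnpStats:
    def test_density_and_transition_classification(self, rng):
        from polymine.snp_mining import SNPCall
        t = SequenceRecord("t1", random_seq(rng, 1000))
        calls = [
            SNPCall("t1", 100 * i, "C", "T", {"C": 10, "T": 10, "A": 0, "G": 0},
                    {"C": 1, "T": 1, "A": 0, "G": 0}, True)
            for i in range(5)
        ]
        stats = snp_stats(calls, [t])
        row = stats["per_transcript"].iloc[0]
        assert row["density_per_100bp"] == pytest.approx(0.5)
        assert stats["transition_fraction"] == 1.0
        assert calls[0].is_transition
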