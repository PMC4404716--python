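"""Haplotype-aware reliable-SNP detection per sample set.

The mining contract follows the QualitySNPng-style settings: base counts come
only from alignments passing the mapping-quality filter (mapq > 25); a
position is a candidate when two distinct unambiguous bases each have >= 5
supporting reads; reads (paired mates are pooled into fragments) are
clustered into haplotypes by agreement over candidate sites at a minimum
similarity of 0.8; transcripts showing more haplotypes than the ploidy model
allows (8 for two pooled tetraploid individuals) are discarded wholesale; a
candidate is a *reliable* SNP when each of its two major alleles is the
consensus of at least one surviving haplotype cluster.

Haplotype counting note: with short reads, candidate sites fall into linkage
components (sites co-covered by at least one fragment).  Clusters are formed
within components, and the per-transcript haplotype count is the maximum
surviving-cluster count over its components — unlinked site groups cannot be
phased against each other and therefore must not be summed when comparing
against the biological ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align_core import MappedRead, OverlapAsmParams, overlap_assemble
from .io_formats import SequenceRecord

TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass
class PloidyModel:
    """Expected haplotype ceiling for a pooled panel of individuals."""

    ploidy: int = 4
    n_individuals: int = 2

    @property
    def max_haplotypes(self) -> int:
        return self.ploidy * self.n_individuals

    def __post_init__(self) -> None:
        if self.ploidy < 1 or self.n_individuals < 1:
            raise ValueError("ploidy and n_individuals must be >= 1")


@dataclass
class SnpMiningParams:
    mapq_min: int = 25            # strictly-greater filter
    min_reads_per_allele: int = 5
    sim_min: float = 0.8          # similarityAllPolymorphicSites
    min_shared_sites: int = 1     # sites two fragments must co-cover to compare
    min_cluster_reads: int = 2
    # significance for the single-haplotype dose test: a reliable allele's
    # read count must be consistent with >= 1 haplotype of the pool
    # (Binomial(N, 1/max_haplotypes) lower tail >= alpha)
    min_allele_dose_alpha: float = 1e-3


@dataclass
class Pileup:
    """Per-transcript base counts and per-fragment placements."""

    transcript_id: str
    length: int
    counts: np.ndarray                  # (length, 4) A,C,G,T from passing reads
    fragments: dict[str, list[MappedRead]]
    n_passing_reads: int = 0

    @classmethod
    def empty(cls, transcript_id: str, length: int) -> "Pileup":
        return cls(transcript_id, length, np.zeros((length, 4), dtype=np.int32), {})


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


def build_reference(
    per_sample_transcripts: list[list[SequenceRecord]],
    asm_params: OverlapAsmParams | None = None,
    contig_prefix: str = "ref",
) -> tuple[list[SequenceRecord], dict[str, list[tuple[str, str]]]]:
    """Assemble the retained transcripts of all samples of one set into a
    reference transcriptome (overlap consensus at 97% identity)."""
    pool: list[SequenceRecord] = []
    for sample in per_sample_transcripts:
        pool.extend(sample)
    if not pool:
        raise ValueError("no transcripts to assemble")
    params = asm_params or OverlapAsmParams(min_overlap_len=40, min_overlap_identity=0.97)
    return overlap_assemble(pool, params, contig_prefix=contig_prefix)


def build_pileups(
    mapped: list[MappedRead],
    references: list[SequenceRecord],
    params: SnpMiningParams | None = None,
) -> dict[str, Pileup]:
    """Accumulate base counts and fragment placements from passing alignments.

    Paired mates share a read id and are pooled into one fragment.
    """
    from .align_core import encode_nt
    from .io_formats import _cigar_ops

    params = params or SnpMiningParams()
    pile = {r.id: Pileup.empty(r.id, len(r.seq)) for r in references}
    for m in mapped:
        if m.mapq <= params.mapq_min:
            continue
        p = pile[m.ref_id]
        p.n_passing_reads += 1
        enc = encode_nt(m.seq)
        q = m.query_offset
        s = m.start
        for n, op in _cigar_ops(m.cigar):
            if op in "M=X":
                block = enc[q : q + n]
                valid = block < 4
                np.add.at(
                    p.counts,
                    (np.arange(s, s + n)[valid], block[valid].astype(np.intp)),
                    1,
                )
                q += n
                s += n
            elif op == "I":
                q += n
            elif op == "D":
                s += n
        p.fragments.setdefault(m.read_id, []).append(m)
    return pile


def call_candidates(pileup: Pileup, min_reads_per_allele: int = 5) -> list[int]:
    """Positions with >= 2 distinct unambiguous bases at >= the read floor."""
    strong = pileup.counts >= min_reads_per_allele
    return [int(i) for i in np.flatnonzero(strong.sum(axis=1) >= 2)]


@dataclass
class HaplotypeCluster:
    component: int
    consensus: dict[int, str]     # candidate position -> allele
    n_reads: int
    fragment_keys: list[str] = field(default_factory=list)


@dataclass
class HaplotypeTable:
    transcript_id: str
    positions: list[int]
    clusters: list[HaplotypeCluster]
    # the haplotype count compared against the ploidy ceiling: the maximum,
    # over candidate sites, of the number of surviving clusters covering the
    # site.  Counting whole clusters per component instead would overstate
    # haplotypes whenever window-limited fragments chain into clusters that
    # never co-cover a site.
    n_haplotypes: int


def _fragment_vectors(
    pileup: Pileup, positions: list[int],
    min_reads_per_allele: int = 5,
) -> dict[str, dict[int, str]]:
    """Allele observations of each fragment over the candidate positions.

    Only bases belonging to a position's allele set (>= the per-allele read
    floor) count as observations — a base below the floor is sequencing
    noise, not an allele.  Mates disagreeing at a position (error on one of
    them) drop that position from the fragment's vector.
    """
    allowed: dict[int, set[str]] = {
        p: {
            _IDX_BASE[b]
            for b in range(4)
            if pileup.counts[p, b] >= min_reads_per_allele
        }
        for p in positions
    }
    out: dict[str, dict[int, str]] = {}
    for frag_id, reads in pileup.fragments.items():
        vec: dict[int, str] = {}
        bad: set[int] = set()
        for m in reads:
            lo, hi = m.start, m.start + m.aligned_len
            for p in positions:
                if lo <= p < hi:
                    b = m.base_at(p)
                    if b is None or b not in allowed[p]:
                        continue
                    if p in vec and vec[p] != b:
                        bad.add(p)
                    else:
                        vec[p] = b
        for p in bad:
            vec.pop(p, None)
        if vec:
            out[frag_id] = vec
    return out


def _similarity(a: dict[int, str], b: dict[int, str], min_shared: int) -> float | None:
    shared = [p for p in a if p in b]
    if len(shared) < min_shared:
        return None
    agree = sum(1 for p in shared if a[p] == b[p])
    return agree / len(shared)


def cluster_haplotypes(
    pileup: Pileup,
    positions: list[int] | None = None,
    params: SnpMiningParams | None = None,
) -> HaplotypeTable:
    """Agglomerative clustering of fragments over candidate sites.

    Within each linkage component, collapsed identical allele vectors are
    merged while the best pairwise consensus similarity is >= ``sim_min``
    (ties broken toward the smaller cluster index).  Clusters with fewer than
    ``min_cluster_reads`` fragments are discarded as noise.
    """
    params = params or SnpMiningParams()
    if positions is None:
        positions = call_candidates(pileup, params.min_reads_per_allele)
    vectors = _fragment_vectors(pileup, positions, params.min_reads_per_allele)

    # linkage components over candidate positions
    parent = {p: p for p in positions}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for vec in vectors.values():
        ps = sorted(vec)
        for a, b in zip(ps, ps[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comp_of = {p: find(p) for p in positions}
    comp_ids = sorted(set(comp_of.values()))
    comp_index = {c: i for i, c in enumerate(comp_ids)}

    clusters: list[HaplotypeCluster] = []
    for comp in comp_ids:
        comp_pos = {p for p in positions if comp_of[p] == comp}
        # collapse identical restricted vectors
        collapsed: dict[tuple, list[str]] = {}
        for frag_id, vec in vectors.items():
            restricted = tuple(sorted((p, vec[p]) for p in vec if p in comp_pos))
            if restricted:
                collapsed.setdefault(restricted, []).append(frag_id)
        units: dict[int, dict] = {}
        for uid, key in enumerate(sorted(collapsed)):
            members = collapsed[key]
            units[uid] = {
                "alleles": {p: {b: len(members)} for p, b in key},
                "n": len(members), "frags": sorted(members),
            }

        def unit_consensus(u) -> dict[int, str]:
            cons = {}
            for p, bc in u["alleles"].items():
                best = max(bc.values())
                cons[p] = sorted(b for b, c in bc.items() if c == best)[0]
            return cons

        cons: dict[int, dict[int, str]] = {
            uid: unit_consensus(u) for uid, u in units.items()
        }
        sites: dict[int, set[int]] = {
            uid: set(c) for uid, c in cons.items()
        }

        # complete-linkage agglomeration: cluster-pair similarity is the
        # minimum defined pairwise similarity between their member vectors
        # (Lance-Williams update), so two clusters merge only when no member
        # pair conflicts — partial windows that merely look compatible on a
        # few shared sites cannot chain distinct haplotypes together.
        # Highest similarity merges first; among equals, pairs sharing more
        # sites and more reads win, then the smaller cluster index.
        import heapq

        sims: dict[tuple[int, int], float] = {}
        heap: list[tuple] = []

        def key_of(i: int, j: int) -> tuple[int, int]:
            return (i, j) if i < j else (j, i)

        def push(i: int, j: int) -> None:
            sim = sims.get(key_of(i, j))
            if sim is None:
                return
            n_shared = len(sites[i] & sites[j])
            size = units[i]["n"] + units[j]["n"]
            heapq.heappush(heap, (-sim, -n_shared, -size) + key_of(i, j))

        uids = sorted(units)
        for a_i in range(len(uids)):
            for a_j in range(a_i + 1, len(uids)):
                i, j = uids[a_i], uids[a_j]
                sim = _similarity(cons[i], cons[j], params.min_shared_sites)
                if sim is not None:
                    sims[key_of(i, j)] = sim
                    push(i, j)
        next_uid = len(uids)
        while heap:
            neg_sim, _, _, i, j = heapq.heappop(heap)
            if i not in units or j not in units:
                continue
            if -neg_sim < params.sim_min:
                break
            merged = {"alleles": {}, "n": units[i]["n"] + units[j]["n"],
                      "frags": sorted(units[i]["frags"] + units[j]["frags"])}
            for u in (units[i], units[j]):
                for p, bc in u["alleles"].items():
                    dst = merged["alleles"].setdefault(p, {})
                    for b, c in bc.items():
                        dst[b] = dst.get(b, 0) + c
            del units[i], units[j], cons[i], cons[j]
            units[next_uid] = merged
            cons[next_uid] = unit_consensus(merged)
            sites[next_uid] = sites.pop(i) | sites.pop(j)
            for other in list(units):
                if other == next_uid:
                    continue
                vals = [
                    v for v in (sims.pop(key_of(i, other), None),
                                sims.pop(key_of(j, other), None))
                    if v is not None
                ]
                if vals:
                    sims[key_of(other, next_uid)] = min(vals)
                    push(other, next_uid)
            sims.pop(key_of(i, j), None)
            next_uid += 1
        for uid in sorted(units):
            u = units[uid]
            clusters.append(HaplotypeCluster(
                component=comp_index[comp], consensus=cons[uid],
                n_reads=u["n"], fragment_keys=u["frags"],
            ))

    surviving = [c for c in clusters if c.n_reads >= params.min_cluster_reads]
    surviving = _consolidate(surviving)
    per_site: dict[int, int] = {}
    for c in surviving:
        for p in c.consensus:
            per_site[p] = per_site.get(p, 0) + 1
    n_hap = max(per_site.values()) if per_site else 0
    return HaplotypeTable(
        transcript_id=pileup.transcript_id, positions=list(positions),
        clusters=surviving, n_haplotypes=n_hap,
    )


def _consolidate(clusters: list[HaplotypeCluster]) -> list[HaplotypeCluster]:
    """Merge clusters that are indistinguishable as haplotypes.

    Two clusters in the same component whose consensus vectors agree on
    every co-covered site (at least one) cannot be proven to be different
    haplotypes and must not count separately against the ploidy ceiling.
    Pairs sharing the most sites (then the most reads) merge first; a merge
    unions the site sets, so conflicting clusters can never be chained
    together through an intermediate.
    """
    clusters = list(clusters)
    while True:
        best = None
        for i in range(len(clusters)):
            ci = clusters[i]
            for j in range(i + 1, len(clusters)):
                cj = clusters[j]
                if ci.component != cj.component:
                    continue
                shared = [p for p in ci.consensus if p in cj.consensus]
                if not shared:
                    continue
                if any(ci.consensus[p] != cj.consensus[p] for p in shared):
                    continue
                key = (len(shared), ci.n_reads + cj.n_reads, -i, -j)
                if best is None or key > best[0]:
                    best = (key, i, j)
        if best is None:
            return clusters
        _, i, j = best
        ci, cj = clusters[i], clusters[j]
        # weighted union: the larger cluster's allele wins where only one
        # covers a site; shared sites agree by construction
        merged_cons = dict(cj.consensus)
        merged_cons.update(ci.consensus)
        merged = HaplotypeCluster(
            component=ci.component, consensus=merged_cons,
            n_reads=ci.n_reads + cj.n_reads,
            fragment_keys=sorted(ci.fragment_keys + cj.fragment_keys),
        )
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(merged)


def filter_by_ploidy(table: HaplotypeTable, model: PloidyModel) -> bool:
    """True = keep the transcript; False when the observed haplotype count
    exceeds the theoretical ceiling (paralog-collapse signature)."""
    return table.n_haplotypes <= model.max_haplotypes


@dataclass
class SNPCall:
    transcript_id: str
    pos: int                       # 0-based on the reference transcript
    ref: str                       # majority allele
    alt: str
    counts: dict[str, int]
    hap_support: dict[str, int]
    reliable: bool

    @property
    def is_transition(self) -> bool:
        return {self.ref, self.alt} in TRANSITIONS


def call_reliable(
    pileup: Pileup,
    table: HaplotypeTable,
    params: SnpMiningParams | None = None,
    ploidy_model: PloidyModel | None = None,
) -> list[SNPCall]:
    """Score every candidate position; ``reliable`` requires both major
    alleles to reach the read floor AND be a surviving cluster's consensus.

    When a ploidy model is supplied, each allele must additionally be
    dose-consistent with at least one haplotype of the pool: with N passing
    reads at the site, an allele carried by >= 1 of the ``max_haplotypes``
    haplotypes draws ~Binomial(N, 1/max_haplotypes) reads, and counts in
    the extreme lower tail (coincident sequencing errors at high depth)
    are rejected.
    """
    from scipy import stats

    params = params or SnpMiningParams()
    calls = []
    for pos in table.positions:
        row = pileup.counts[pos]
        order = sorted(range(4), key=lambda b: (-row[b], b))
        a1, a2 = order[0], order[1]
        ref, alt = _IDX_BASE[a1], _IDX_BASE[a2]
        counts = {_IDX_BASE[b]: int(row[b]) for b in range(4)}
        hap_support = {b: 0 for b in "ACGT"}
        for c in table.clusters:
            allele = c.consensus.get(pos)
            if allele is not None:
                hap_support[allele] += 1
        reliable = (
            row[a1] >= params.min_reads_per_allele
            and row[a2] >= params.min_reads_per_allele
            and hap_support[ref] >= 1
            and hap_support[alt] >= 1
        )
        if reliable and ploidy_model is not None:
            n_total = int(row.sum())
            p_hap = 1.0 / ploidy_model.max_haplotypes
            for allele_count in (int(row[a1]), int(row[a2])):
                if stats.binom.cdf(allele_count, n_total, p_hap) < params.min_allele_dose_alpha:
                    reliable = False
                    break
        calls.append(SNPCall(
            transcript_id=pileup.transcript_id, pos=pos, ref=ref, alt=alt,
            counts=counts, hap_support=hap_support, reliable=reliable,
        ))
    return calls


def mine_transcript(
    pileup: Pileup,
    ploidy_model: PloidyModel,
    params: SnpMiningParams | None = None,
) -> tuple[list[SNPCall], HaplotypeTable, bool]:
    """Candidates -> haplotype table -> ploidy ceiling -> reliable calls.

    Returns (calls, table, kept).  A transcript over its haplotype ceiling
    returns an empty call list with kept=False.
    """
    params = params or SnpMiningParams()
    positions = call_candidates(pileup, params.min_reads_per_allele)
    table = cluster_haplotypes(pileup, positions, params)
    if not filter_by_ploidy(table, ploidy_model):
        return [], table, False
    return call_reliable(pileup, table, params, ploidy_model), table, True


def read_snp_calls(path) -> list[SNPCall]:
    """Load SNP calls back from the VCF-like table written by
    :func:`polymine.io_formats.write_snp_table`."""
    from .io_formats import read_snp_table

    calls = []
    for row in read_snp_table(path).itertuples():
        info = dict(kv.split("=", 1) for kv in row.INFO.split(";"))
        rc = [int(x) for x in info.get("RC", "0,0").split(",")]
        hap = [int(x) for x in info.get("HAP", "0,0").split(",")]
        counts = {b: 0 for b in "ACGT"}
        support = {b: 0 for b in "ACGT"}
        counts[row.REF], counts[row.ALT] = rc[0], rc[1]
        support[row.REF], support[row.ALT] = hap[0], hap[1]
        calls.append(SNPCall(
            transcript_id=row.CHROM, pos=int(row.POS) - 1,
            ref=row.REF, alt=row.ALT, counts=counts, hap_support=support,
            reliable=bool(int(info.get("RELIABLE", "0"))),
        ))
    return calls


def snp_stats(
    calls: list[SNPCall], transcripts: list[SequenceRecord],
    pileups: dict[str, Pileup] | None = None,
) -> dict:
    """Per-transcript density/coverage summary and overall transition stats.

    Only transcripts with at least one reliable SNP enter the summary, in
    line with how such surveys are tabulated.
    """
    lengths = {t.id: len(t.seq) for t in transcripts}
    reliable = [c for c in calls if c.reliable]
    per_t: dict[str, int] = {}
    for c in reliable:
        per_t[c.transcript_id] = per_t.get(c.transcript_id, 0) + 1
    rows = []
    for tid, n in sorted(per_t.items()):
        length = lengths[tid]
        coverage = np.nan
        if pileups and tid in pileups and length:
            coverage = float(pileups[tid].counts.sum() / length)
        rows.append({
            "transcript_id": tid, "length": length, "n_snps": n,
            "density_per_100bp": 100.0 * n / length, "coverage": coverage,
        })
    df = pd.DataFrame(rows, columns=[
        "transcript_id", "length", "n_snps", "density_per_100bp", "coverage",
    ])
    n_transitions = sum(1 for c in reliable if c.is_transition)
    hist = df["n_snps"].value_counts().sort_index() if len(df) else pd.Series(dtype=int)
    return {
        "per_transcript": df,
        "n_reliable": len(reliable),
        "n_transcripts": len(df),
        "transition_fraction": n_transitions / len(reliable) if reliable else np.nan,
        "mean_density_per_100bp": float(df["density_per_100bp"].mean()) if len(df) else np.nan,
        "sd_density_per_100bp": float(df["density_per_100bp"].std()) if len(df) else np.nan,
        "mean_length": float(df["length"].mean()) if len(df) else np.nan,
        "snps_per_transcript_hist": hist,
    }
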