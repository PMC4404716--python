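"""The filter cascade turning reliable SNPs into array-ready markers.

Cascade order (fixed, every candidate leaves a trace): context extraction ->
allele class screen -> paralog filter -> chloroplast screen -> splice-
junction screen -> cross-set redundancy removal -> probe-similarity screen
-> array construction.  Every input SNP ends up either in the manifest or in
the rejection log with the stage that removed it.

Key constants: 35-nt clean flanks (the 71-mer context must contain no other
variant and no ambiguous base), strand-ambiguous A/T and C/G alleles are
dropped (they would need twice the probes), a marker's source transcript may
hit its own reference set only once (self-hit), and a context whose best
genomic hit matches fewer than ceil(0.95 * 71) = 68 contiguous bases is
taken to span a splice junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .align_core import (AlignParams, KmerIndex, PRESETS, local_align,
                         meets_preset, revcomp, search)
from .io_formats import MarkerManifestRow, SequenceRecord
from .snp_mining import SNPCall, TRANSITIONS

_COMP = str.maketrans("ACGT", "TGCA")

SET_PRIORITY = "KGMD"  # dedup keeps the copy from the earliest-listed set


@dataclass
class FilterParams:
    flank: int = 35
    paralog_preset: str = "strict"
    chloro_preset: str = "loose"
    probe_preset: str = "probe"
    splice_match_fraction: float = 0.95
    paralog_count_self: bool = True   # "two or more hits" includes the self-hit
    splice_sum_hsps: bool = False     # matched bp = best contiguous block if False

    @property
    def context_len(self) -> int:
        return 2 * self.flank + 1

    @property
    def splice_min_match(self) -> int:
        """Matched-length threshold below which a genomic hit implies a
        splice junction inside the context window."""
        return math.ceil(self.splice_match_fraction * self.context_len)


CASCADE_STAGES = [
    "context", "allele_class", "paralog", "chloroplast", "splice",
    "cross_set_dedup", "probe_similarity",
]


@dataclass
class MarkerCandidate:
    snp: SNPCall
    set_code: str
    context: str                   # plain 71-mer with the majority allele at center
    snp_class: str = ""            # transition | transversion | strand-ambiguous
    filter_trace: dict[str, str] = field(default_factory=dict)
    snp_id: str = ""

    @property
    def alleles(self) -> str:
        return f"{self.snp.ref}/{self.snp.alt}"

    @property
    def bracket_context(self) -> str:
        f = (len(self.context) - 1) // 2
        return (
            f"{self.context[:f]}[{self.snp.ref}/{self.snp.alt}]{self.context[f + 1:]}"
        )

    def mark(self, stage: str, verdict: str) -> None:
        self.filter_trace[stage] = verdict


@dataclass
class Rejection:
    set_code: str
    transcript_id: str
    pos: int
    stage: str
    reason: str


def extract_context(
    snp: SNPCall,
    transcript: SequenceRecord,
    all_variant_positions: list[int],
    set_code: str = "K",
    flank: int = 35,
) -> MarkerCandidate | None:
    """71-mer context of a SNP, rejected when too close to a transcript end,
    when any other variant (candidate SNP or indel) falls inside the window,
    or when the window holds an ambiguous base."""
    pos = snp.pos
    seq = transcript.seq
    if pos < flank or pos + flank >= len(seq):
        return None
    lo, hi = pos - flank, pos + flank + 1
    for q in all_variant_positions:
        if q != pos and lo <= q < hi:
            return None
    window = seq[lo:hi]
    if any(c not in "ACGT" for c in window):
        return None
    cand = MarkerCandidate(snp=snp, set_code=set_code, context=window)
    cand.mark("context", "pass")
    return cand


def classify_and_screen_alleles(candidate: MarkerCandidate) -> bool:
    """Transitions and most transversions pass; A/T and C/G pairs are
    strand-ambiguous on a two-probe array design and are rejected."""
    pair = {candidate.snp.ref, candidate.snp.alt}
    if pair in TRANSITIONS:
        candidate.snp_class = "transition"
    elif pair in ({"A", "T"}, {"C", "G"}):
        candidate.snp_class = "strand-ambiguous"
        candidate.mark("allele_class", "fail")
        return False
    else:
        candidate.snp_class = "transversion"
    candidate.mark("allele_class", "pass")
    return True


def paralog_filter(
    candidate: MarkerCandidate,
    source_transcript: SequenceRecord,
    own_reference_db: list[SequenceRecord],
    params: FilterParams | None = None,
    align_params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> bool:
    """Search the marker's source transcript against its own set's reference
    transcriptome; any second hit at the strict preset (the first being the
    self-hit) marks a likely multi-copy gene and fails the marker."""
    params = params or FilterParams()
    align_params = align_params or AlignParams(min_hit_score=40)
    preset = PRESETS[params.paralog_preset]
    hits = search(source_transcript.seq, own_reference_db, align_params,
                  query_id=source_transcript.id, index=index)
    good = [h for h in hits if meets_preset(h, preset)]
    if params.paralog_count_self:
        # "two or more hits" counting the expected self-hit: any extra hit fails
        ok = len(good) < 2
    else:
        ok = len([h for h in good if h.subject_id != source_transcript.id]) < 2
    candidate.mark("paralog", "pass" if ok else "fail")
    return ok


def chloroplast_screen(
    candidate: MarkerCandidate,
    chloro_genome: list[SequenceRecord],
    params: FilterParams | None = None,
    align_params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> bool:
    """Fail when the context hits the chloroplast genome at the loose preset."""
    params = params or FilterParams()
    if not chloro_genome:
        candidate.mark("chloroplast", "pass")
        return True
    align_params = align_params or AlignParams(min_hit_score=40)
    hits = search(candidate.context, chloro_genome, align_params, index=index)
    bad = any(meets_preset(h, PRESETS[params.chloro_preset]) for h in hits)
    candidate.mark("chloroplast", "fail" if bad else "pass")
    return not bad


def splice_junction_screen(
    candidate: MarkerCandidate,
    genome_db: list[SequenceRecord],
    params: FilterParams | None = None,
    align_params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> bool:
    """Fail when the best genomic hit matches fewer than the 95% threshold
    (68 bp for 35-nt flanks) of contiguous context bases — the signature of
    an exon junction inside the window.  No genomic hit at all passes."""
    params = params or FilterParams()
    if not genome_db:
        candidate.mark("splice", "pass")
        return True
    align_params = align_params or AlignParams(min_hit_score=30)
    hits = search(candidate.context, genome_db, align_params, index=index)
    if not hits:
        candidate.mark("splice", "pass")
        return True
    best = hits[0]
    if params.splice_sum_hsps:
        matched = best.aligned_columns
    else:
        matched = best.matched_length
    ok = matched >= params.splice_min_match
    candidate.mark("splice", "pass" if ok else "fail")
    return ok


def _context_key(context: str, ref: str, alt: str) -> tuple:
    """Strand-normalised identity key: a context and its reverse complement
    (with complemented alleles) map to the same key."""
    fwd = (context, frozenset((ref, alt)))
    rc = (revcomp(context), frozenset((ref.translate(_COMP), alt.translate(_COMP))))
    return min(fwd, rc)


def _priority(candidate: MarkerCandidate) -> tuple:
    code = candidate.set_code
    rank = SET_PRIORITY.index(code) if code in SET_PRIORITY else len(SET_PRIORITY)
    return (rank, candidate.snp_id or f"{candidate.snp.transcript_id}:{candidate.snp.pos}")


def cross_set_dedup(candidates: list[MarkerCandidate]) -> tuple[list[MarkerCandidate], list[MarkerCandidate]]:
    """Remove markers whose context (either strand) and alleles coincide
    across sets; the copy from the highest-priority set (K > G > M > D, then
    lexicographic id) survives."""
    groups: dict[tuple, list[MarkerCandidate]] = {}
    for cand in candidates:
        key = _context_key(cand.context, cand.snp.ref, cand.snp.alt)
        groups.setdefault(key, []).append(cand)
    kept, dropped = [], []
    for key in groups:
        members = sorted(groups[key], key=_priority)
        members[0].mark("cross_set_dedup", "pass")
        kept.append(members[0])
        for m in members[1:]:
            m.mark("cross_set_dedup", "fail")
            dropped.append(m)
    kept.sort(key=_priority)
    return kept, dropped


def probe_similarity_screen(
    markers: list[MarkerCandidate],
    params: FilterParams | None = None,
    align_params: AlignParams | None = None,
) -> tuple[list[MarkerCandidate], list[MarkerCandidate]]:
    """Drop the lower-priority member of any pair of near-identical (but not
    identical — those were deduplicated earlier) contexts, which would
    cross-hybridise on the array."""
    params = params or FilterParams()
    align_params = align_params or AlignParams(min_hit_score=40)
    preset = PRESETS[params.probe_preset]
    ordered = sorted(markers, key=_priority)
    kept: list[MarkerCandidate] = []
    dropped: list[MarkerCandidate] = []
    # incremental k-mer prefilter: only already-kept contexts sharing an
    # exact word with the incoming one are aligned
    k = align_params.k
    word_to_kept: dict[str, set[int]] = {}
    for cand in ordered:
        cand_words = set()
        for strand_seq in (cand.context, revcomp(cand.context)):
            for i in range(len(strand_seq) - k + 1):
                cand_words.add(strand_seq[i : i + k])
        near: set[int] = set()
        for w in cand_words:
            near.update(word_to_kept.get(w, ()))
        similar = False
        for kept_idx in sorted(near):
            other = kept[kept_idx].context
            for strand_seq in (cand.context, revcomp(cand.context)):
                aln = local_align(strand_seq, other, align_params)
                if meets_preset(aln, preset):
                    similar = True
                    break
            if similar:
                break
        if similar:
            cand.mark("probe_similarity", "fail")
            dropped.append(cand)
        else:
            cand.mark("probe_similarity", "pass")
            idx = len(kept)
            kept.append(cand)
            for i in range(len(cand.context) - k + 1):
                word_to_kept.setdefault(cand.context[i : i + k], set()).add(idx)
    return kept, dropped


def assign_snp_ids(candidates: list[MarkerCandidate]) -> None:
    """Ids of the form {set}_{transcript#}_{snp#}; transcript numbers are
    assigned per set in first-appearance order, SNP numbers per transcript
    in position order."""
    per_set_tnum: dict[tuple[str, str], int] = {}
    per_t_snum: dict[tuple[str, str], int] = {}
    next_tnum: dict[str, int] = {}
    for cand in sorted(candidates, key=lambda c: (c.set_code, c.snp.transcript_id, c.snp.pos)):
        key = (cand.set_code, cand.snp.transcript_id)
        if key not in per_set_tnum:
            next_tnum[cand.set_code] = next_tnum.get(cand.set_code, 0) + 1
            per_set_tnum[key] = next_tnum[cand.set_code]
        per_t_snum[key] = per_t_snum.get(key, 0) + 1
        cand.snp_id = f"{cand.set_code}_{per_set_tnum[key]}_{per_t_snum[key]}"


def build_array(
    markers: list[MarkerCandidate],
    rhfv_of_transcript: dict[str, str] | None = None,
    protein_of_transcript: dict[str, str] | None = None,
    annotation_of_protein: dict[str, str] | None = None,
) -> list[MarkerManifestRow]:
    """Two probes per SNP (one per strand) and the manifest rows."""
    rhfv_of_transcript = rhfv_of_transcript or {}
    protein_of_transcript = protein_of_transcript or {}
    annotation_of_protein = annotation_of_protein or {}
    if any(not m.snp_id for m in markers):
        assign_snp_ids(markers)
    rows = []
    for m in markers:
        tid = m.snp.transcript_id
        protein = protein_of_transcript.get(tid, "")
        rows.append(MarkerManifestRow(
            snp_id=m.snp_id,
            probe_id_fwd=f"AX_{m.snp_id}_F",
            probe_id_rev=f"AX_{m.snp_id}_R",
            context=m.bracket_context,
            alleles=m.alleles,
            source_transcript=tid,
            rhfv_ortholog=rhfv_of_transcript.get(tid, ""),
            guide_protein=protein,
            annotation=annotation_of_protein.get(protein, ""),
        ))
    return rows


# each SNP is interrogated by one probe per strand
PROBES_PER_SNP = 2


def probe_count(manifest: list[MarkerManifestRow]) -> int:
    """Total probes on the array: one per strand for every SNP."""
    return PROBES_PER_SNP * len(manifest)


@dataclass
class CascadeResult:
    manifest: list[MarkerManifestRow]
    markers: list[MarkerCandidate]
    rejections: list[Rejection]

    def rejection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "set": r.set_code, "transcript": r.transcript_id, "pos": r.pos,
                "stage": r.stage, "reason": r.reason,
            } for r in self.rejections],
            columns=["set", "transcript", "pos", "stage", "reason"],
        )

    def stage_counts(self) -> pd.DataFrame:
        counts: dict[str, int] = {s: 0 for s in CASCADE_STAGES}
        for r in self.rejections:
            counts[r.stage] = counts.get(r.stage, 0) + 1
        rows = [{"stage": s, "rejected": counts[s]} for s in counts]
        rows.append({"stage": "manifest", "rejected": len(self.manifest)})
        return pd.DataFrame(rows)


def run_cascade(
    snp_calls_by_set: dict[str, list[SNPCall]],
    transcripts_by_set: dict[str, dict[str, SequenceRecord]],
    reference_by_set: dict[str, list[SequenceRecord]],
    chloro_genome: list[SequenceRecord],
    genome_db: list[SequenceRecord],
    params: FilterParams | None = None,
    rhfv_of_transcript: dict[str, str] | None = None,
    protein_of_transcript: dict[str, str] | None = None,
    annotation_of_protein: dict[str, str] | None = None,
) -> CascadeResult:
    """Run the full cascade over reliable SNPs of all sample sets."""
    params = params or FilterParams()
    rejections: list[Rejection] = []
    survivors: list[MarkerCandidate] = []
    chloro_params = AlignParams(min_hit_score=40)
    genome_params = AlignParams(min_hit_score=30)
    paralog_params = AlignParams(min_hit_score=40)
    chloro_index = (KmerIndex(chloro_genome, chloro_params.k) if chloro_genome else None)
    genome_index = (KmerIndex(genome_db, genome_params.k) if genome_db else None)
    ref_indices = {
        code: KmerIndex(refs, paralog_params.k)
        for code, refs in reference_by_set.items()
    }
    paralog_verdict: dict[tuple[str, str], bool] = {}  # per source transcript

    for set_code in sorted(snp_calls_by_set):
        calls = [c for c in snp_calls_by_set[set_code] if c.reliable]
        by_transcript: dict[str, list[SNPCall]] = {}
        for c in snp_calls_by_set[set_code]:
            by_transcript.setdefault(c.transcript_id, []).append(c)
        for call in calls:
            transcript = transcripts_by_set[set_code][call.transcript_id]
            variant_positions = [c.pos for c in by_transcript[call.transcript_id]]
            cand = extract_context(call, transcript, variant_positions,
                                   set_code, params.flank)
            if cand is None:
                rejections.append(Rejection(set_code, call.transcript_id, call.pos,
                                            "context", "edge/other-variant/ambiguous"))
                continue
            if not classify_and_screen_alleles(cand):
                rejections.append(Rejection(set_code, call.transcript_id, call.pos,
                                            "allele_class", "strand-ambiguous alleles"))
                continue
            pkey = (set_code, call.transcript_id)
            if pkey not in paralog_verdict:
                paralog_verdict[pkey] = paralog_filter(
                    cand, transcript, reference_by_set[set_code], params,
                    paralog_params, ref_indices[set_code],
                )
            else:
                cand.mark("paralog", "pass" if paralog_verdict[pkey] else "fail")
            if not paralog_verdict[pkey]:
                rejections.append(Rejection(set_code, call.transcript_id, call.pos,
                                            "paralog", "multiple reference hits"))
                continue
            if not chloroplast_screen(cand, chloro_genome, params,
                                      chloro_params, chloro_index):
                rejections.append(Rejection(set_code, call.transcript_id, call.pos,
                                            "chloroplast", "chloroplast hit"))
                continue
            if not splice_junction_screen(cand, genome_db, params,
                                          genome_params, genome_index):
                rejections.append(Rejection(set_code, call.transcript_id, call.pos,
                                            "splice", "context spans junction"))
                continue
            survivors.append(cand)

    kept, dup_dropped = cross_set_dedup(survivors)
    for m in dup_dropped:
        rejections.append(Rejection(m.set_code, m.snp.transcript_id, m.snp.pos,
                                    "cross_set_dedup", "redundant across sets"))
    assign_snp_ids(kept)
    kept, sim_dropped = probe_similarity_screen(kept, params)
    for m in sim_dropped:
        rejections.append(Rejection(m.set_code, m.snp.transcript_id, m.snp.pos,
                                    "probe_similarity", "near-identical context"))
    manifest = build_array(kept, rhfv_of_transcript, protein_of_transcript,
                           annotation_of_protein)
    return CascadeResult(manifest=manifest, markers=kept, rejections=rejections)
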