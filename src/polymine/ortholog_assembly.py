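"""Orthology-guided assembly of a non-redundant transcriptome.

Transcripts are grouped by their best translated hit against a guide
proteome (a related, fully sequenced genome's non-redundant protein set),
assembled within groups by overlap consensus, checked reciprocally (the
contig's top protein hit must return the guide originally used), trimmed to
their longest ORF, reassembled, and finally named after the guide gene
({guide}.m{k}).  Groups backed by a single transcript are discarded as
unverifiable.  A final sequence is called full-length when it starts with
ATG, ends with a stop codon, and its translation covers at least 90% of the
guide protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .align_core import (AlignParams, KmerIndex, OverlapAsmParams, PRESETS,
                         meets_preset, overlap_assemble, revcomp,
                         translated_search)
from .io_formats import IntegrityError, SequenceRecord

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ORF:
    """An open reading frame: ATG..stop on one strand of a contig.

    ``start``/``end`` are 0-based half-open on the *oriented* sequence (the
    contig itself for strand '+', its reverse complement for '-'); ``end``
    includes the stop codon.
    """

    start: int
    end: int
    strand: str
    frame: int
    protein: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OrthologGroup:
    guide_protein_id: str
    member_transcript_ids: list[str]
    contigs: list[SequenceRecord] = field(default_factory=list)
    contig_members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    reciprocal_ok: dict[str, bool] = field(default_factory=dict)
    orfs: dict[str, ORF] = field(default_factory=dict)
    final_sequences: list[SequenceRecord] = field(default_factory=list)
    final_members: dict[str, list[str]] = field(default_factory=dict)
    full_length: dict[str, bool] = field(default_factory=dict)


@dataclass
class OrthologAsmParams:
    grouping_preset: str = "loose"       # transcript -> guide assignment
    reciprocal_preset: str = "standard"  # contig -> proteome check
    flcov: float = 0.90                  # guide coverage for full-length calls
    require_atg: bool = True             # ORFs must start at ATG
    min_group_size: int = 2


def group_by_guide(
    transcripts: list[SequenceRecord],
    guide_proteome: list[SequenceRecord],
    params: OrthologAsmParams | None = None,
    align_params: AlignParams | None = None,
) -> tuple[dict[str, list[SequenceRecord]], list[str]]:
    """Assign each transcript to its best-scoring guide protein.

    Returns ({guide_id: transcripts}, unassigned transcript ids).  Score ties
    break toward the lexicographically smaller protein id (already the hit
    ordering of translated_search).
    """
    if not guide_proteome:
        raise ValueError("guide proteome is empty")
    params = params or OrthologAsmParams()
    align_params = align_params or AlignParams.protein(min_hit_score=30)
    index = KmerIndex(guide_proteome, align_params.k)
    preset = PRESETS[params.grouping_preset]
    groups: dict[str, list[SequenceRecord]] = {}
    unassigned: list[str] = []
    for t in transcripts:
        hits = translated_search(t, guide_proteome, align_params, index=index)
        hit = next((h for h in hits if meets_preset(h.alignment, preset)), None)
        if hit is None:
            unassigned.append(t.id)
        else:
            groups.setdefault(hit.subject_id, []).append(t)
    return groups, unassigned


def assemble_group(
    group: list[SequenceRecord],
    asm_params: OverlapAsmParams | None = None,
    contig_prefix: str = "ctg",
) -> tuple[list[SequenceRecord], dict[str, list[tuple[str, str]]]]:
    """Overlap-consensus assembly within one ortholog group."""
    return overlap_assemble(group, asm_params or OverlapAsmParams(),
                            contig_prefix=contig_prefix)


def reciprocal_check(
    contig: SequenceRecord,
    guide_proteome: list[SequenceRecord],
    original_guide: str,
    params: OrthologAsmParams | None = None,
    align_params: AlignParams | None = None,
    index: KmerIndex | None = None,
) -> bool:
    """Keep the contig only when its top proteome hit is the original guide;
    a score tie between the guide and another protein is ambiguous -> drop."""
    params = params or OrthologAsmParams()
    align_params = align_params or AlignParams.protein(min_hit_score=30)
    hits = translated_search(contig, guide_proteome, align_params, index=index)
    hits = [h for h in hits if meets_preset(h.alignment, PRESETS[params.reciprocal_preset])]
    if not hits:
        return False
    top = hits[0]
    if top.subject_id != original_guide:
        return False
    if len(hits) > 1 and hits[1].score == top.score:
        return False
    return True


def longest_orf(seq: str, require_atg: bool = True) -> ORF | None:
    """Longest ATG..stop span over all six frames.

    With ``require_atg=False`` the spans run stop-to-stop (the region after
    the previous stop).  Ties break toward '+' strand, then lower frame,
    then smaller start.
    """
    best: ORF | None = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            open_start = None  # position of first usable start since last stop
            region_start = frame
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if require_atg and open_start is None and codon == "ATG":
                    open_start = i
                if codon in _STOPS:
                    start = open_start if require_atg else region_start
                    if start is not None:
                        cand = (i + 3) - start
                        if best is None or cand > len(best):
                            prot = str(Seq(s[start : i + 3]).translate())[:-1]
                            best = ORF(start=start, end=i + 3, strand=strand,
                                       frame=frame + 1, protein=prot)
                    open_start = None
                    region_start = i + 3
                i += 3
    return best


def trim_to_orf(contig: SequenceRecord, orf: ORF) -> SequenceRecord:
    """UTR-trimmed coding sequence, oriented to the ORF strand."""
    s = contig.seq if orf.strand == "+" else revcomp(contig.seq)
    return SequenceRecord(contig.id + "_cds", s[orf.start : orf.end],
                          meta=contig.meta)


def reassemble_trimmed(
    orf_sequences: list[SequenceRecord],
    guide_id: str,
    asm_params: OverlapAsmParams | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[tuple[str, str]]]]:
    """Reassemble UTR-trimmed coding sequences; final contigs are named
    {guide}.m{k} with k assigned by descending length."""
    contigs, members = overlap_assemble(
        orf_sequences, asm_params or OverlapAsmParams(), contig_prefix="tmp"
    )
    order = sorted(contigs, key=lambda c: (-len(c.seq), c.id))
    finals = []
    final_members: dict[str, list[tuple[str, str]]] = {}
    for k, c in enumerate(order, 1):
        name = f"{guide_id}.m{k}"
        finals.append(SequenceRecord(name, c.seq, meta=c.meta))
        final_members[name] = members[c.id]
    return finals, final_members


def call_full_length(
    final_seq: SequenceRecord,
    guide_protein: SequenceRecord,
    params: OrthologAsmParams | None = None,
    align_params: AlignParams | None = None,
) -> bool:
    """Full-length = starts with ATG, ends with a stop codon, and the
    translation aligns over >= flcov of the guide protein's length."""
    params = params or OrthologAsmParams()
    align_params = align_params or AlignParams.protein(min_hit_score=20)
    s = final_seq.seq
    if len(s) < 6 or len(s) % 3 != 0:
        return False
    if not s.startswith("ATG") or s[-3:] not in _STOPS:
        return False
    prot = str(Seq(s).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot or not prot:
        return False
    from .align_core import local_align

    aln = local_align(prot, guide_protein.seq, align_params)
    covered = aln.subject_end - aln.subject_start
    return covered >= params.flcov * len(guide_protein.seq)


def annotate(
    final_seqs: list[SequenceRecord],
    guide_of_seq: dict[str, str],
    annotation_table: pd.DataFrame,
) -> pd.DataFrame:
    """Left-join guide protein ids to annotation text (missing -> empty)."""
    if annotation_table["protein_id"].duplicated().any():
        dups = annotation_table["protein_id"][annotation_table["protein_id"].duplicated()]
        raise IntegrityError(f"duplicate annotation keys: {sorted(set(dups))}")
    base = pd.DataFrame({
        "sequence_id": [s.id for s in final_seqs],
        "protein_id": [guide_of_seq.get(s.id, "") for s in final_seqs],
    })
    out = base.merge(annotation_table, on="protein_id", how="left")
    out["annotation"] = out["annotation"].fillna("")
    return out


@dataclass
class OrthologAssemblyResult:
    groups: dict[str, OrthologGroup]
    final_sequences: list[SequenceRecord]
    guide_of_sequence: dict[str, str]
    full_length: dict[str, bool]
    unassigned: list[str]
    singletons_discarded: list[str]

    @property
    def n_full_length(self) -> int:
        return sum(1 for v in self.full_length.values() if v)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.groups):
            g = self.groups[gid]
            for s in g.final_sequences:
                rows.append({
                    "sequence_id": s.id, "guide_protein": gid,
                    "n_members": len(g.member_transcript_ids),
                    "length": len(s.seq),
                    "full_length": self.full_length.get(s.id, False),
                })
        return pd.DataFrame(rows, columns=[
            "sequence_id", "guide_protein", "n_members", "length", "full_length",
        ])


def assemble_orthologs(
    transcripts: list[SequenceRecord],
    guide_proteome: list[SequenceRecord],
    params: OrthologAsmParams | None = None,
    asm_params: OverlapAsmParams | None = None,
) -> OrthologAssemblyResult:
    """The full orthology-guided procedure over a transcript pool."""
    params = params or OrthologAsmParams()
    align_params = AlignParams.protein(min_hit_score=30)
    proteome_index = KmerIndex(guide_proteome, align_params.k)
    guide_by_id = {p.id: p for p in guide_proteome}
    grouped, unassigned = group_by_guide(transcripts, guide_proteome, params,
                                         align_params)
    groups: dict[str, OrthologGroup] = {}
    final_sequences: list[SequenceRecord] = []
    guide_of_sequence: dict[str, str] = {}
    full_length: dict[str, bool] = {}
    singletons: list[str] = []
    for gid in sorted(grouped):
        members = grouped[gid]
        if len(members) < params.min_group_size:
            singletons.extend(m.id for m in members)
            continue
        group = OrthologGroup(
            guide_protein_id=gid,
            member_transcript_ids=[m.id for m in members],
        )
        contigs, membership = assemble_group(members, asm_params,
                                             contig_prefix=f"{gid}_ctg")
        group.contigs = contigs
        group.contig_members = membership
        trimmed: list[SequenceRecord] = []
        transcript_of_cds: dict[str, list[str]] = {}
        for contig in contigs:
            ok = reciprocal_check(contig, guide_proteome, gid, params,
                                  align_params, proteome_index)
            group.reciprocal_ok[contig.id] = ok
            if not ok:
                continue
            orf = longest_orf(contig.seq, params.require_atg)
            if orf is None:
                continue
            group.orfs[contig.id] = orf
            cds = trim_to_orf(contig, orf)
            transcript_of_cds[cds.id] = [m for m, _ in membership[contig.id]]
            trimmed.append(cds)
        if not trimmed:
            groups[gid] = group
            continue
        finals, fmembers = reassemble_trimmed(trimmed, gid, asm_params)
        group.final_sequences = finals
        for name, mems in fmembers.items():
            tids: list[str] = []
            for cds_id, _ in mems:
                tids.extend(transcript_of_cds.get(cds_id, []))
            group.final_members[name] = sorted(set(tids))
        for s in finals:
            fl = call_full_length(s, guide_by_id[gid], params)
            group.full_length[s.id] = fl
            full_length[s.id] = fl
            guide_of_sequence[s.id] = gid
            final_sequences.append(s)
        groups[gid] = group
    return OrthologAssemblyResult(
        groups=groups, final_sequences=final_sequences,
        guide_of_sequence=guide_of_sequence, full_length=full_length,
        unassigned=unassigned, singletons_discarded=singletons,
    )
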