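"""Selection of biologically relevant transcripts per sample.

Isoform filtering mirrors abundance-based selection on read-sharing
components: transcripts connected by multi-mapping reads form a component;
within a component, transcripts drawing less than 1% of the component's
reads (IsoPct) are discarded, and of the rest only the most abundant
transcript survives.  Multi-mapped reads are split equally across their
targets.  A translated screen against contaminant (fungal) proteins removes
foreign transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import (AlignParams, BatchReadMapper, KmerIndex, MappedRead,
                         meets_preset, translated_search)
from .io_formats import SequenceRecord


@dataclass
class ComponentAbundance:
    component_id: int
    transcript_ids: list[str]
    counts: dict[str, float]          # fractional read counts

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def iso_pct(self, tid: str) -> float:
        total = self.total
        if total == 0:
            return 0.0
        return 100.0 * self.counts[tid] / total


def build_components(
    transcripts: list[SequenceRecord],
    read_alignments: list[MappedRead],
) -> list[ComponentAbundance]:
    """Group transcripts sharing multi-mapped reads into components.

    ``read_alignments`` are best placements carrying ``multi_refs`` (the
    near-best reference set of each read); each read contributes 1/k counts
    to each of its k targets.  Transcripts without reads form singleton
    components with zero counts.
    """
    idx_of = {t.id: i for i, t in enumerate(transcripts)}
    parent = list(range(len(transcripts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    counts = {t.id: 0.0 for t in transcripts}
    for m in read_alignments:
        targets = list(m.multi_refs)
        w = 1.0 / len(targets)
        for r in targets:
            counts[transcripts[r].id] += w
        for a, b in zip(targets, targets[1:]):
            union(a, b)
    groups: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for cid, (root, members) in enumerate(sorted(groups.items())):
        tids = [transcripts[i].id for i in members]
        out.append(ComponentAbundance(
            component_id=cid, transcript_ids=tids,
            counts={tid: counts[tid] for tid in tids},
        ))
    return out


def isopct_filter(
    components: list[ComponentAbundance],
    transcripts: list[SequenceRecord],
    iso_pct_min: float = 1.0,
    keep_top_only: bool = True,
) -> list[SequenceRecord]:
    """Drop transcripts with IsoPct strictly below ``iso_pct_min``; then keep
    only the most abundant survivor per component (ties: longer transcript,
    then lexicographically smaller id)."""
    by_id = {t.id: t for t in transcripts}
    keep: list[str] = []
    for comp in components:
        if not comp.transcript_ids:
            continue
        survivors = [
            tid for tid in comp.transcript_ids
            if comp.iso_pct(tid) >= iso_pct_min or comp.total == 0
        ]
        if not survivors:
            continue
        if keep_top_only:
            best = sorted(
                survivors,
                key=lambda tid: (-comp.counts[tid], -len(by_id[tid].seq), tid),
            )[0]
            keep.append(best)
        else:
            keep.extend(survivors)
    keep_set = set(keep)
    return [t for t in transcripts if t.id in keep_set]


@dataclass
class ContaminantReport:
    flagged_ids: list[str]
    mean_identity: float


def contaminant_screen(
    transcripts: list[SequenceRecord],
    contaminant_proteins: list[SequenceRecord],
    preset: str = "standard",
    params: AlignParams | None = None,
) -> tuple[list[SequenceRecord], ContaminantReport]:
    """Remove transcripts whose best translated hit against the contaminant
    protein set meets the preset; returns (clean, report)."""
    if not contaminant_proteins:
        return list(transcripts), ContaminantReport([], float("nan"))
    params = params or AlignParams.protein(min_hit_score=30)
    index = KmerIndex(contaminant_proteins, params.k)
    clean: list[SequenceRecord] = []
    flagged: list[str] = []
    identities: list[float] = []
    for t in transcripts:
        hits = translated_search(t, contaminant_proteins, params, index=index)
        hit = next((h for h in hits if meets_preset(h.alignment, preset)), None)
        if hit is not None:
            flagged.append(t.id)
            identities.append(hit.identity)
        else:
            clean.append(t)
    mean_id = sum(identities) / len(identities) if identities else float("nan")
    return clean, ContaminantReport(flagged_ids=flagged, mean_identity=mean_id)


def select_transcripts(
    transcripts: list[SequenceRecord],
    reads: list[SequenceRecord],
    contaminant_proteins: list[SequenceRecord] | None = None,
    iso_pct_min: float = 1.0,
    keep_top_only: bool = True,
    mapper: BatchReadMapper | None = None,
) -> tuple[list[SequenceRecord], dict]:
    """Full per-sample selection: map reads, isoform-filter, decontaminate."""
    mapper = mapper or BatchReadMapper(transcripts)
    mapped = mapper.map_all(reads)
    components = build_components(transcripts, mapped)
    retained = isopct_filter(components, transcripts, iso_pct_min, keep_top_only)
    report = {
        "transcripts_in": len(transcripts),
        "after_isopct": len(retained),
        "components": len(components),
    }
    if contaminant_proteins:
        retained, contam = contaminant_screen(retained, contaminant_proteins)
        report["contaminants_flagged"] = len(contam.flagged_ids)
        report["contaminant_mean_identity"] = contam.mean_identity
        report["contaminant_ids"] = contam.flagged_ids
    report["retained"] = len(retained)
    return retained, report
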