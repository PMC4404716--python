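"""Scoring of pipeline output against a synthetic truth set.

Assembled reference contigs are located on their originating gene (via the
assembly membership map and a coordinate-lifting alignment), called SNPs are
lifted to truth coordinates, and precision/recall, marker-filter leakage,
ortholog recovery and full-length flag accuracy are computed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align_core import AlignParams, local_align, revcomp
from .io_formats import SequenceRecord, _cigar_ops
from .marker_design import CascadeResult
from .ortholog_assembly import OrthologAssemblyResult
from .snp_mining import SNPCall
from .synthetic_data import TruthSet

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class ContigPlacement:
    contig_id: str
    gene_id: str
    strand: str
    # contig position -> gene expressed-coordinate position (aligned columns)
    pos_map: dict[int, int]


def _transcript_gene_lookup(truth: TruthSet, set_code: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for ind in truth.sets[set_code].individuals:
        out.update(ind.transcript_gene)
    return out


def place_contigs(
    contigs: list[SequenceRecord],
    membership: dict[str, list[tuple[str, str]]],
    truth: TruthSet,
    set_code: str,
) -> dict[str, ContigPlacement]:
    """Locate each reference contig on the gene its members came from."""
    t2g = _transcript_gene_lookup(truth, set_code)
    params = AlignParams(min_hit_score=20)
    out: dict[str, ContigPlacement] = {}
    for contig in contigs:
        genes = {t2g[m] for m, _ in membership.get(contig.id, []) if m in t2g}
        if len(genes) != 1:
            continue  # mixed or unknown origin: skip (counts against precision)
        gene = truth.gene(next(iter(genes)))
        target = gene.expressed
        best = None
        for strand, seq in (("+", contig.seq), ("-", revcomp(contig.seq))):
            aln = local_align(seq, target, params)
            if best is None or aln.score > best[1].score:
                best = (strand, aln, seq)
        strand, aln, seq = best
        pos_map: dict[int, int] = {}
        q, s = aln.query_start, aln.subject_start
        for n, op in _cigar_ops(aln.cigar):
            if op in "=XM":
                for t in range(n):
                    pos_map[q + t] = s + t
                q += n
                s += n
            elif op == "I":
                q += n
            elif op == "D":
                s += n
        if strand == "-":
            L = len(contig.seq)
            pos_map = {L - 1 - k: v for k, v in pos_map.items()}
        out[contig.id] = ContigPlacement(contig.id, gene.gene_id, strand, pos_map)
    return out


def _lift_call(call: SNPCall, placements: dict[str, ContigPlacement]
               ) -> tuple[str, int, frozenset] | None:
    pl = placements.get(call.transcript_id)
    if pl is None:
        return None
    gpos = pl.pos_map.get(call.pos)
    if gpos is None:
        return None
    alleles = {call.ref, call.alt}
    if pl.strand == "-":
        alleles = {a.translate(_COMP) for a in alleles}
    return (pl.gene_id, gpos, frozenset(alleles))


@dataclass
class SnpScores:
    n_calls: int
    n_truth: int
    true_positives: int
    precision: float
    recall: float


def score_snp_calls(
    calls: list[SNPCall],
    placements: dict[str, ContigPlacement],
    truth: TruthSet,
    set_code: str,
) -> SnpScores:
    """Precision/recall of reliable calls against the planted SNP table."""
    truth_rows = truth.snps[truth.snps["set"] == set_code]
    truth_keys = {
        (r.gene_id, int(r.pos), frozenset((r.ref, r.alt)))
        for r in truth_rows.itertuples()
    }
    reliable = [c for c in calls if c.reliable]
    tp = 0
    for c in reliable:
        key = _lift_call(c, placements)
        if key is not None and key in truth_keys:
            tp += 1
    n_calls = len(reliable)
    n_truth = len(truth_keys)
    return SnpScores(
        n_calls=n_calls, n_truth=n_truth, true_positives=tp,
        precision=tp / n_calls if n_calls else float("nan"),
        recall=tp / n_truth if n_truth else float("nan"),
    )


@dataclass
class MarkerScores:
    n_manifest: int
    leaked_chloroplast: int
    leaked_paralog: int
    leaked_junction: int
    clean_truth_total: int
    clean_truth_in_manifest: int

    @property
    def clean_survival(self) -> float:
        if not self.clean_truth_total:
            return float("nan")
        return self.clean_truth_in_manifest / self.clean_truth_total


def score_markers(
    cascade: CascadeResult,
    placements_by_set: dict[str, dict[str, ContigPlacement]],
    truth: TruthSet,
) -> MarkerScores:
    """Leakage of planted decoy classes into the manifest, and survival of
    clean planted SNPs (those the cascade should retain)."""
    truth_idx = {}
    for r in truth.snps.itertuples():
        truth_idx[(r.set, r.gene_id, int(r.pos), frozenset((r.ref, r.alt)))] = r
    leaked_chl = leaked_par = leaked_jun = 0
    manifest_truth_keys = set()
    for m in cascade.markers:
        placements = placements_by_set.get(m.set_code, {})
        key = _lift_call(m.snp, placements)
        if key is None:
            continue
        gene_id, gpos, alleles = key
        row = truth_idx.get((m.set_code, gene_id, gpos, alleles))
        if row is None:
            continue
        manifest_truth_keys.add((row.set, row.gene_id, int(row.pos)))
        if row.chloro:
            leaked_chl += 1
        if row.paralog_gene:
            leaked_par += 1
        if row.near_junction:
            leaked_jun += 1
    clean = truth.snps[truth.snps["clean"]]
    clean_total = len(clean)
    clean_hit = sum(
        1 for r in clean.itertuples()
        if (r.set, r.gene_id, int(r.pos)) in manifest_truth_keys
    )
    return MarkerScores(
        n_manifest=len(cascade.manifest),
        leaked_chloroplast=leaked_chl, leaked_paralog=leaked_par,
        leaked_junction=leaked_jun,
        clean_truth_total=clean_total, clean_truth_in_manifest=clean_hit,
    )


@dataclass
class OrthologScores:
    eligible_genes: int
    recovered_genes: int
    flagged_full_length: int
    flagged_correct: int
    truth_full_length_genes: int
    recovered_flagged_full_length_genes: int

    @property
    def recovery(self) -> float:
        return (self.recovered_genes / self.eligible_genes
                if self.eligible_genes else float("nan"))

    @property
    def full_length_flag_accuracy(self) -> float:
        return (self.flagged_correct / self.flagged_full_length
                if self.flagged_full_length else float("nan"))


def score_orthologs(
    result: OrthologAssemblyResult,
    truth: TruthSet,
    set_codes: list[str] | None = None,
) -> OrthologScores:
    """Gene-level recovery and full-length flag accuracy.

    Eligible genes are nuclear genes represented by at least two transcripts
    in the pipeline input (always true with >= 2 individuals per set).
    """
    set_codes = set_codes or list(truth.sets)
    t2g: dict[str, str] = {}
    for code in set_codes:
        t2g.update(_transcript_gene_lookup(truth, code))
    eligible = [g for g in truth.genes if g.kind == "nuclear"]
    recovered: set[str] = set()
    gene_flagged: dict[str, bool] = {}
    flagged_total = flagged_correct = 0
    for gid, group in result.groups.items():
        for s in group.final_sequences:
            member_genes = [
                t2g[t] for t in group.final_members.get(s.id, []) if t in t2g
            ]
            if not member_genes:
                continue
            majority = max(sorted(set(member_genes)), key=member_genes.count)
            recovered.add(majority)
            flagged = result.full_length.get(s.id, False)
            gene_flagged[majority] = gene_flagged.get(majority, False) or flagged
            if flagged:
                flagged_total += 1
                if truth.gene(majority).full_length_expected:
                    flagged_correct += 1
    truth_fl = [g.gene_id for g in eligible if g.full_length_expected]
    rec_flagged_fl = sum(
        1 for g in truth_fl if g in recovered and gene_flagged.get(g, False)
    )
    return OrthologScores(
        eligible_genes=len(eligible),
        recovered_genes=len([g for g in eligible if g.gene_id in recovered]),
        flagged_full_length=flagged_total,
        flagged_correct=flagged_correct,
        truth_full_length_genes=len(truth_fl),
        recovered_flagged_full_length_genes=rec_flagged_fl,
    )


def transition_fraction(snps: pd.DataFrame) -> float:
    if not len(snps):
        return float("nan")
    return float(snps["is_transition"].mean())
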