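"""End-to-end orchestration: simulate -> prep -> select -> reference ->
SNP mining -> ortholog assembly -> marker design, with summary tables.

Every stage's inputs are conserved: a record either flows to the next stage
or lands in a rejection/summary table, and the run is byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (align_core, io_formats, marker_design, ortholog_assembly,
               read_prep, snp_mining, synthetic_data, transcript_select)
from .align_core import BatchReadMapper, OverlapAsmParams
from .evaluate import (place_contigs, score_markers, score_orthologs,
                       score_snp_calls)
from .io_formats import SequenceRecord, write_fasta, write_marker_manifest, write_snp_table
from .marker_design import FilterParams, run_cascade
from .ortholog_assembly import OrthologAsmParams, assemble_orthologs
from .read_prep import PrepParams, prep_paired, prep_single
from .snp_mining import (PloidyModel, SnpMiningParams, build_pileups,
                         build_reference, mine_transcript, snp_stats)
from .synthetic_data import SimulationParams, make_truth, simulate_reads, write_truth
from .transcript_select import select_transcripts

log = logging.getLogger("polymine")


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, serializable to/from YAML."""

    sim: SimulationParams = field(default_factory=SimulationParams)
    prep: PrepParams = field(default_factory=PrepParams)
    snp: SnpMiningParams = field(default_factory=SnpMiningParams)
    filters: FilterParams = field(default_factory=FilterParams)
    ortho: OrthologAsmParams = field(default_factory=OrthologAsmParams)
    asm_overlap_len: int = 40
    asm_overlap_identity: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        codes = self.sim.set_codes
        if not codes:
            raise ValueError("at least one sample set is required")
        if len(set(codes)) != len(codes) or any(
            len(c) != 1 or not c.isupper() for c in codes
        ):
            raise ValueError("set codes must be unique single uppercase letters")
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.get("sim", {}))
        for key in ("set_codes", "intron_len_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        kwargs = {
            "sim": SimulationParams(**sim),
            "prep": PrepParams(**d.get("prep", {})),
            "snp": SnpMiningParams(**d.get("snp", {})),
            "filters": FilterParams(**d.get("filters", {})),
            "ortho": OrthologAsmParams(**d.get("ortho", {})),
        }
        for key in ("asm_overlap_len", "asm_overlap_identity", "seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SetResult:
    code: str
    reference: list[SequenceRecord]
    membership: dict[str, list[tuple[str, str]]]
    calls: list
    pileups: dict
    stats: dict
    prep_counts: dict[str, dict]
    select_reports: dict[str, dict]
    discarded_over_ceiling: list[str]


@dataclass
class RunResult:
    config: RunConfig
    truth: synthetic_data.TruthSet
    sets: dict[str, SetResult]
    ortho: ortholog_assembly.OrthologAssemblyResult
    cascade: marker_design.CascadeResult
    summary: dict
    outdir: Path | None = None


def _mine_set(
    code: str,
    truth: synthetic_data.TruthSet,
    reads_by_ind: dict[str, synthetic_data.ReadSimulation],
    config: RunConfig,
) -> SetResult:
    sset = truth.sets[code]
    prep_counts: dict[str, dict] = {}
    select_reports: dict[str, dict] = {}
    retained_per_ind: list[list[SequenceRecord]] = []
    prepped_reads_per_ind: dict[str, list[SequenceRecord]] = {}
    for ind in sset.individuals:
        sim = reads_by_ind[ind.ind_id]
        if config.sim.regime == "illumina":
            prep = prep_paired(sim.r1, sim.r2, config.prep)
            mappable = prep.single_end_reads + prep.paired_r1 + prep.paired_r2
        else:
            prep = prep_single(sim.r1, config.prep, long_regime=True)
            mappable = prep.singles
        prep_counts[ind.ind_id] = prep.counts
        prepped_reads_per_ind[ind.ind_id] = mappable
        log.info("set %s %s: %d reads after prep", code, ind.ind_id, len(mappable))
        retained, report = select_transcripts(
            ind.transcripts, mappable, truth.contaminant_proteins,
        )
        select_reports[ind.ind_id] = report
        retained_per_ind.append(retained)
        log.info("set %s %s: %d/%d transcripts retained", code, ind.ind_id,
                 report["retained"], report["transcripts_in"])

    asm = OverlapAsmParams(min_overlap_len=config.asm_overlap_len,
                           min_overlap_identity=config.asm_overlap_identity)
    reference, membership = build_reference(
        retained_per_ind, asm, contig_prefix=f"{code}_ref")
    log.info("set %s: reference of %d contigs", code, len(reference))

    mapper = BatchReadMapper(reference)
    mapped = []
    for ind in sset.individuals:
        mapped.extend(mapper.map_all(prepped_reads_per_ind[ind.ind_id]))
    pileups = build_pileups(mapped, reference, config.snp)
    ploidy_model = PloidyModel(ploidy=config.sim.ploidy,
                               n_individuals=config.sim.n_individuals)
    calls = []
    discarded = []
    for ref in reference:
        t_calls, table, kept = mine_transcript(pileups[ref.id], ploidy_model,
                                               config.snp)
        if not kept:
            discarded.append(ref.id)
        calls.extend(t_calls)
    stats = snp_stats(calls, reference, pileups)
    log.info("set %s: %d reliable SNPs on %d transcripts", code,
             stats["n_reliable"], stats["n_transcripts"])
    return SetResult(
        code=code, reference=reference, membership=membership, calls=calls,
        pileups=pileups, stats=stats, prep_counts=prep_counts,
        select_reports=select_reports, discarded_over_ceiling=discarded,
    )


def run_all(config: RunConfig, outdir=None) -> RunResult:
    """Execute the whole pipeline on synthetic data; optionally write all
    artifacts (truth, references, SNP tables, manifest, summaries)."""
    truth = make_truth(config.sim)
    reads = simulate_reads(truth, config.sim)
    set_results: dict[str, SetResult] = {}
    for code in config.sim.set_codes:
        try:
            set_results[code] = _mine_set(code, truth, reads, config)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage 'snp-mining' failed for set {code}: {exc}") from exc

    # ortholog assembly over the retained transcripts of all individuals
    all_transcripts: list[SequenceRecord] = []
    retained_ids: set[str] = set()
    for code in config.sim.set_codes:
        for ind in truth.sets[code].individuals:
            sres = set_results[code]
            # recover the retained transcript objects from membership of the
            # reference assembly (its members are exactly the retained set)
            member_ids = {m for mem in sres.membership.values() for m, _ in mem}
            for t in ind.transcripts:
                if t.id in member_ids and t.id not in retained_ids:
                    retained_ids.add(t.id)
                    all_transcripts.append(t)
    ortho = assemble_orthologs(all_transcripts, truth.guide_proteins,
                               config.ortho)
    log.info("orthology-guided assembly: %d final sequences, %d full-length",
             len(ortho.final_sequences), ortho.n_full_length)

    # transcript (reference contig) -> Rh-Fv name / guide protein
    t2g: dict[str, str] = {}
    for code in config.sim.set_codes:
        for ind in truth.sets[code].individuals:
            t2g.update(ind.transcript_gene)
    guide_of_gene = {g.gene_id: g.guide_protein_id for g in truth.genes}
    rhfv_of_guide: dict[str, str] = {}
    for s in ortho.final_sequences:
        gid = ortho.guide_of_sequence[s.id]
        rhfv_of_guide.setdefault(gid, s.id)
    rhfv_of_transcript: dict[str, str] = {}
    protein_of_transcript: dict[str, str] = {}
    for code, sres in set_results.items():
        for contig_id, members in sres.membership.items():
            genes = sorted({t2g[m] for m, _ in members if m in t2g})
            if len(genes) != 1:
                continue
            guide = guide_of_gene.get(genes[0])
            if guide:
                protein_of_transcript[contig_id] = guide
                if guide in rhfv_of_guide:
                    rhfv_of_transcript[contig_id] = rhfv_of_guide[guide]
    annotation_of_protein = dict(
        zip(truth.annotation["protein_id"], truth.annotation["annotation"])
    )

    cascade = run_cascade(
        snp_calls_by_set={c: r.calls for c, r in set_results.items()},
        transcripts_by_set={
            c: {t.id: t for t in r.reference} for c, r in set_results.items()
        },
        reference_by_set={c: r.reference for c, r in set_results.items()},
        chloro_genome=[truth.chloro_genome],
        genome_db=truth.genome,
        params=config.filters,
        rhfv_of_transcript=rhfv_of_transcript,
        protein_of_transcript=protein_of_transcript,
        annotation_of_protein=annotation_of_protein,
    )
    log.info("marker cascade: %d markers on the array (%d probes)",
             len(cascade.manifest), marker_design.probe_count(cascade.manifest))

    summary = summarize(config, truth, set_results, ortho, cascade)
    result = RunResult(config=config, truth=truth, sets=set_results,
                       ortho=ortho, cascade=cascade, summary=summary)
    if outdir is not None:
        result.outdir = Path(outdir)
        _write_artifacts(result, reads)
    return result


def summarize(config, truth, set_results, ortho, cascade) -> dict:
    """Per-set sequencing/SNP summaries and the marker count roll-up."""
    seq_rows = []
    snp_rows = []
    markers_per_set: dict[str, int] = {c: 0 for c in set_results}
    for m in cascade.markers:
        markers_per_set[m.set_code] = markers_per_set.get(m.set_code, 0) + 1
    for code, sres in set_results.items():
        reads_in = sum(c.get("reads_in", 0) for c in sres.prep_counts.values())
        reads_out = sum(c.get("reads_out", 0) for c in sres.prep_counts.values())
        retained = sum(r.get("retained", 0) for r in sres.select_reports.values())
        seq_rows.append({
            "set": code, "reads_in": reads_in, "reads_out": reads_out,
            "pct_reads_kept": 100.0 * reads_out / reads_in if reads_in else 0.0,
            "transcripts_retained": retained,
            "reference_contigs": len(sres.reference),
        })
        st = sres.stats
        hist = st["snps_per_transcript_hist"]
        snp_rows.append({
            "set": code,
            "transcripts_with_snp": st["n_transcripts"],
            "mean_length": st["mean_length"],
            "n_reliable_snps": st["n_reliable"],
            "snp_range": (f"{hist.index.min()}-{hist.index.max()}"
                          if len(hist) else "0-0"),
            "density_mean": st["mean_density_per_100bp"],
            "density_sd": st["sd_density_per_100bp"],
            "transition_fraction": st["transition_fraction"],
            "markers_on_array": markers_per_set.get(code, 0),
        })
    total_markers = sum(markers_per_set.values())
    assert total_markers == len(cascade.manifest)
    return {
        "sequencing": pd.DataFrame(seq_rows),
        "snps": pd.DataFrame(snp_rows),
        "markers_per_set": markers_per_set,
        "total_markers": total_markers,
        "total_probes": marker_design.probe_count(cascade.manifest),
        "orthologs": len({ortho.guide_of_sequence[s.id]
                          for s in ortho.final_sequences}),
        "full_length": ortho.n_full_length,
    }


def summarize_counts(markers_per_set: dict[str, int]) -> dict:
    """Roll up per-set marker counts; the total must equal the sum."""
    total = sum(markers_per_set.values())
    return {"per_set": dict(sorted(markers_per_set.items())), "total": total}


def evaluate_run(result: RunResult) -> dict:
    """Truth-based scores of a finished run (used by recovery tests)."""
    placements_by_set = {}
    snp_scores = {}
    for code, sres in result.sets.items():
        placements = place_contigs(sres.reference, sres.membership,
                                   result.truth, code)
        placements_by_set[code] = placements
        snp_scores[code] = score_snp_calls(sres.calls, placements,
                                           result.truth, code)
    marker_scores = score_markers(result.cascade, placements_by_set, result.truth)
    ortho_scores = score_orthologs(result.ortho, result.truth,
                                   list(result.config.sim.set_codes))
    return {
        "snp": snp_scores,
        "markers": marker_scores,
        "orthologs": ortho_scores,
    }


def _write_artifacts(result: RunResult, reads) -> None:
    outdir = result.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    write_truth(result.truth, outdir / "truth", reads)
    for code, sres in result.sets.items():
        write_fasta(sres.reference, outdir / f"{code}_reference.fa")
        write_snp_table(sres.calls, outdir / f"{code}_snps.tsv")
        sres.stats["per_transcript"].to_csv(
            outdir / f"{code}_snp_stats.tsv", sep="\t", index=False)
        hist = sres.stats["snps_per_transcript_hist"]
        hist.rename_axis("n_snps").rename("n_transcripts").to_frame().to_csv(
            outdir / f"{code}_snp_histogram.tsv", sep="\t")
    write_fasta(result.ortho.final_sequences, outdir / "rhfv_transcripts.fa")
    result.ortho.report_frame().to_csv(outdir / "ogasm_report.tsv", sep="\t",
                                       index=False)
    write_marker_manifest(result.cascade.manifest, outdir / "manifest.tsv")
    result.cascade.rejection_frame().to_csv(outdir / "rejections.tsv", sep="\t",
                                            index=False)
    result.cascade.stage_counts().to_csv(outdir / "stage_counts.tsv", sep="\t",
                                         index=False)
    result.summary["sequencing"].to_csv(outdir / "summary_sequencing.tsv",
                                        sep="\t", index=False)
    result.summary["snps"].to_csv(outdir / "summary_snps.tsv", sep="\t",
                                  index=False)
    pd.Series({
        "total_markers": result.summary["total_markers"],
        "total_probes": result.summary["total_probes"],
        "orthologs": result.summary["orthologs"],
        "full_length": result.summary["full_length"],
    }).rename_axis("quantity").rename("value").to_frame().to_csv(
        outdir / "summary_counts.tsv", sep="\t")
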