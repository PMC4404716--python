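"""Fully labelled synthetic inputs with the statistical structure the
pipeline assumes, plus truth tables for recovery tests.

The generator emulates a pooled-cultivar EST study in a highly heterozygous
autotetraploid: a panel of sample sets (default one, two tetraploid
individuals, i.e. the parents of a mapping population), genes carrying up to
``ploidy`` haplotypes per individual with planted biallelic SNPs at a target
density of ~0.5/100 bp and ~60% transitions, paralog pairs at a declared
identity, exon-skipping splice variants, chloroplast-derived and fungal
contaminant decoys, and uniform-coverage reads with a configurable error
rate.  Every planted feature is written to truth tables so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align_core import revcomp
from .io_formats import SequenceRecord, write_fasta, write_fastq

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons by amino acid for back-translation (stop codons excluded)
_CODON_TABLE = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass
class SimulationParams:
    """Study-design parameters of the synthetic truth.

    Defaults are the desk-scale study conditions: 100 tetraploid genes,
    one sample set of two individuals (a mapping-population parent pair),
    SNP density 0.5/100 bp with 60% transitions, 30x per-haplotype coverage
    and a 0.5% sequencing error rate.
    """

    n_genes: int = 100
    gene_len_mean: float = 1000.0
    gene_len_sd: float = 200.0
    ploidy: int = 4
    n_individuals: int = 2
    set_codes: tuple[str, ...] = ("K",)
    snp_density: float = 0.005            # per bp
    transition_fraction: float = 0.60
    paralog_fraction: float = 0.05
    paralog_identity: float = 0.92
    splice_variant_fraction: float = 0.20
    fragmented_fraction: float = 0.50     # genes supplied as 2 overlapping fragments
    truncated_fraction: float = 0.30      # genes expressed without the CDS start
    fragment_overlap: int = 60
    n_chloroplast_decoys: int = 5
    n_contaminant_decoys: int = 8
    chloro_len: int = 12000
    intron_len_range: tuple[int, int] = (90, 250)
    read_len: int = 75
    insert_mean: float = 260.0
    insert_sd: float = 30.0
    read_error_rate: float = 0.005
    coverage: float = 30.0
    variant_read_weight: float = 0.10
    regime: str = "illumina"              # or "454"
    long_read_len_mean: float = 350.0
    long_read_len_sd: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_density", "transition_fraction", "paralog_fraction",
                     "paralog_identity", "splice_variant_fraction",
                     "fragmented_fraction", "truncated_fraction",
                     "read_error_rate", "variant_read_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.regime not in ("illumina", "454"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class GeneModel:
    """One synthetic gene: mRNA with exon structure, CDS and expression form."""

    gene_id: str
    kind: str                        # nuclear | chloro | contaminant
    mrna: str
    cds: tuple[int, int] | None      # on mRNA, 0-based half-open, incl. stop
    exon_bounds: list[int]           # cumulative exon end positions on mRNA
    expressed_start: int
    expressed_end: int
    guide_protein_id: str | None = None
    paralog_of: str | None = None
    truncated: bool = False
    fragmented: bool = False
    has_variant: bool = False
    variant_skip: tuple[int, int] | None = None  # skipped interval, expressed coords

    @property
    def expressed(self) -> str:
        return self.mrna[self.expressed_start : self.expressed_end]

    @property
    def junctions_expressed(self) -> list[int]:
        """Exon-junction coordinates in expressed-sequence space."""
        out = []
        for b in self.exon_bounds[:-1]:
            j = b - self.expressed_start
            if 0 < j < self.expressed_end - self.expressed_start:
                out.append(j)
        return out

    @property
    def full_length_expected(self) -> bool:
        return self.kind == "nuclear" and not self.truncated


@dataclass
class Individual:
    ind_id: str
    # gene_id -> list of haplotype sequences (expressed-form coordinates)
    haplotypes: dict[str, list[str]]
    transcripts: list[SequenceRecord] = field(default_factory=list)
    transcript_gene: dict[str, str] = field(default_factory=dict)


@dataclass
class SampleSet:
    code: str
    individuals: list[Individual]


@dataclass
class TruthSet:
    params: SimulationParams
    genes: list[GeneModel]
    guide_proteins: list[SequenceRecord]
    contaminant_proteins: list[SequenceRecord]
    chloro_genome: SequenceRecord
    genome: list[SequenceRecord]
    sets: dict[str, SampleSet]
    snps: pd.DataFrame
    annotation: pd.DataFrame

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    aas = "".join(_AA20[i] for i in rng.integers(0, 20, size=max(1, n_codons - 2)))
    body = "".join(
        _CODON_TABLE[aa][rng.integers(0, len(_CODON_TABLE[aa]))] for aa in aas
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


def _translate_cds(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            break
        prot.append(_AA_OF.get(codon, "X"))
    return "".join(prot)


_AA_OF = {c: aa for aa, codons in _CODON_TABLE.items() for c in codons}


def _mutate_no_stop(rng: np.random.Generator, mrna: str, cds: tuple[int, int],
                    rate: float) -> str:
    """Substitute bases at ``rate``, evenly spaced with jitter, avoiding stop
    creation inside the CDS.

    Even spacing guarantees every read-length window carries diagnostic
    differences, as it would between genuinely diverged gene-family copies;
    purely Bernoulli placement occasionally leaves long identical stretches
    whose reads are unresolvable in principle.
    """
    seq = list(mrna)
    cs, ce = cds
    step = max(2, int(round(1.0 / max(rate, 1e-6))))
    jitter = rng.integers(-(step // 3), step // 3 + 1,
                          size=len(seq) // step + 1)
    positions = [
        int(np.clip(i * step + step // 2 + jitter[i], 0, len(seq) - 1))
        for i in range(len(seq) // step)
    ]
    for pos in sorted(set(positions)):
        ref = seq[pos]
        choices = [b for b in _BASES if b != ref]
        rng.shuffle(choices)
        for alt in choices:
            if _creates_stop(seq, pos, alt, cs, ce):
                continue
            seq[pos] = alt
            break
    return "".join(seq)


def _creates_stop(seq: list[str] | str, pos: int, alt: str, cs: int, ce: int) -> bool:
    if not (cs <= pos < ce - 3):  # the genuine stop codon may stay a stop
        return False
    ci = (pos - cs) // 3
    start = cs + 3 * ci
    codon = list(seq[start : start + 3])
    codon[pos - start] = alt
    return "".join(codon) in _STOPS


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def make_truth(params: SimulationParams) -> TruthSet:
    """Generate the full labelled truth set, deterministic under the seed."""
    rng = np.random.default_rng(params.seed)
    genes: list[GeneModel] = []
    guide_proteins: list[SequenceRecord] = []

    n_digits = max(3, len(str(params.n_genes)))
    for gi in range(params.n_genes):
        gene_id = f"g{gi:0{n_digits}d}"
        length = int(np.clip(rng.normal(params.gene_len_mean, params.gene_len_sd),
                             400, 4 * params.gene_len_mean))
        utr5 = int(rng.integers(40, 81))
        utr3 = int(rng.integers(60, 121))
        n_codons = max(60, (length - utr5 - utr3) // 3)
        cds = _rand_cds(rng, n_codons)
        mrna = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
        cds_iv = (utr5, utr5 + len(cds))
        # exon structure: 1-4 exons, each at least 80 bp
        max_exons = min(4, len(mrna) // 80)
        n_exons = int(rng.integers(1, max_exons + 1))
        bounds = sorted(rng.choice(np.arange(80, len(mrna) - 80), size=n_exons - 1,
                                   replace=False).tolist()) if n_exons > 1 else []
        exon_bounds = [int(b) for b in bounds] + [len(mrna)]
        truncated = rng.random() < params.truncated_fraction
        fragmented = rng.random() < params.fragmented_fraction
        # splice variants only on whole (unfragmented) genes: a variant shares
        # full exons with both fragments and would bridge them into one
        # abundance component, distorting what the isoform filter is probing
        has_variant = n_exons >= 3 and not truncated and not fragmented and (
            rng.random() < params.splice_variant_fraction
        )
        expressed_start = 0
        if truncated:
            cut = int(len(cds) * rng.uniform(0.25, 0.40))
            expressed_start = cds_iv[0] + cut
        variant_skip = None
        if has_variant:
            # skip one internal exon (expressed coordinates)
            k = int(rng.integers(1, n_exons - 1))
            lo = exon_bounds[k - 1]
            hi = exon_bounds[k]
            variant_skip = (lo - expressed_start, hi - expressed_start)
        prot_id = f"FV{gi:05d}"
        genes.append(GeneModel(
            gene_id=gene_id, kind="nuclear", mrna=mrna, cds=cds_iv,
            exon_bounds=exon_bounds, expressed_start=expressed_start,
            expressed_end=len(mrna), guide_protein_id=prot_id,
            truncated=truncated, fragmented=fragmented,
            has_variant=has_variant, variant_skip=variant_skip,
        ))
        guide_proteins.append(SequenceRecord(prot_id, _translate_cds(cds)))

    # paralog partners of a fraction of nuclear genes
    nuclear = [g for g in genes if g.kind == "nuclear"]
    n_paralogs = int(round(params.paralog_fraction * len(nuclear)))
    paralog_sources = list(rng.choice(len(nuclear), size=n_paralogs, replace=False))
    paralog_pairs: list[tuple[str, str, float]] = []
    for src_idx in paralog_sources:
        src = nuclear[int(src_idx)]
        pid = f"{src.gene_id}p"
        mut = _mutate_no_stop(rng, src.mrna, src.cds, 1.0 - params.paralog_identity)
        genes.append(GeneModel(
            gene_id=pid, kind="nuclear", mrna=mut, cds=src.cds,
            exon_bounds=list(src.exon_bounds), expressed_start=0,
            expressed_end=len(mut), guide_protein_id=src.guide_protein_id,
            paralog_of=src.gene_id,
        ))
        paralog_pairs.append((src.gene_id, pid, params.paralog_identity))

    # chloroplast genome and decoy "transcripts" carved from it
    chloro_seq = _rand_seq(rng, params.chloro_len)
    chloro_genome = SequenceRecord("chloroplast", chloro_seq)
    n_cp = params.n_chloroplast_decoys
    cp_spacing = params.chloro_len // max(1, n_cp)
    for ci in range(n_cp):
        # non-overlapping slices: overlapping decoys would share reads and
        # shadow each other during isoform selection
        dlen = int(rng.integers(600, min(901, cp_spacing)))
        start = ci * cp_spacing + int(rng.integers(0, max(1, cp_spacing - dlen)))
        genes.append(GeneModel(
            gene_id=f"cp{ci:02d}", kind="chloro",
            mrna=chloro_seq[start : start + dlen], cds=None,
            exon_bounds=[dlen], expressed_start=0, expressed_end=dlen,
        ))

    # fungal contaminant proteins and their transcripts
    contaminant_proteins: list[SequenceRecord] = []
    for fi in range(params.n_contaminant_decoys):
        plen = int(rng.integers(150, 301))
        prot = "M" + "".join(_AA20[i] for i in rng.integers(0, 20, size=plen - 1))
        contaminant_proteins.append(SequenceRecord(f"FUNGI{fi:03d}", prot))
        cds = "".join(
            _CODON_TABLE[aa][rng.integers(0, len(_CODON_TABLE[aa]))] for aa in prot
        ) + "TAA"
        mrna = _rand_seq(rng, 30) + cds + _rand_seq(rng, 30)
        genes.append(GeneModel(
            gene_id=f"fg{fi:02d}", kind="contaminant", mrna=mrna,
            cds=(30, 30 + len(cds)), exon_bounds=[len(mrna)],
            expressed_start=0, expressed_end=len(mrna),
        ))

    # toy nuclear genome: loci (mRNA with introns) joined by spacers
    genome_parts: list[str] = []
    locus_of_gene: dict[str, str] = {}
    for g in genes:
        if g.kind != "nuclear":
            continue
        locus = []
        prev = 0
        for i, b in enumerate(g.exon_bounds):
            locus.append(g.mrna[prev:b])
            prev = b
            if i < len(g.exon_bounds) - 1:
                ilen = int(rng.integers(*params.intron_len_range))
                intron = "GT" + _rand_seq(rng, ilen - 4) + "AG"
                locus.append(intron)
        locus_of_gene[g.gene_id] = "".join(locus)
        genome_parts.append(locus_of_gene[g.gene_id])
        genome_parts.append(_rand_seq(rng, 150))
    genome = [SequenceRecord("chr1", "".join(genome_parts))]

    # plant SNPs per sample set and build individual haplotypes
    n_hap = params.ploidy * params.n_individuals
    snp_rows: list[dict] = []
    sets: dict[str, SampleSet] = {}
    for code in params.set_codes:
        individuals = [
            Individual(ind_id=f"{code}{i + 1}", haplotypes={})
            for i in range(params.n_individuals)
        ]
        # pass 1: draw positions and work out which substitution classes are
        # feasible (stop codons must stay intact) so the realised transition
        # fraction can be calibrated against stop-codon fallbacks
        pending: dict[str, list[dict]] = {}
        n_both = n_only_transition = 0
        for g in genes:
            if g.kind == "contaminant":
                continue
            expressed = g.expressed
            L = len(expressed)
            entries: list[dict] = []
            for pos in np.flatnonzero(rng.random(L) < params.snp_density):
                pos = int(pos)
                ref = expressed[pos]
                mrna_pos = pos + g.expressed_start
                # keep start and stop codons intact
                if g.cds is not None and (
                    g.cds[0] <= mrna_pos < g.cds[0] + 3
                    or g.cds[1] - 3 <= mrna_pos < g.cds[1]
                ):
                    continue

                def feasible(base: str) -> bool:
                    return g.cds is None or not _creates_stop(
                        g.mrna, mrna_pos, base, g.cds[0], g.cds[1]
                    )

                t_ok = feasible(_TRANSITION[ref])
                tv = [b for b in _TRANSVERSIONS[ref] if feasible(b)]
                if not t_ok and not tv:
                    continue
                if t_ok and tv:
                    n_both += 1
                elif t_ok:
                    n_only_transition += 1
                entries.append({"pos": pos, "ref": ref, "t_ok": t_ok, "tv": tv})
            pending[g.gene_id] = entries
        total = sum(len(v) for v in pending.values())
        # transition probability for the free positions such that the overall
        # expectation hits the target despite forced-class positions
        p_both = 0.0
        if n_both:
            p_both = float(np.clip(
                (params.transition_fraction * total - n_only_transition) / n_both,
                0.0, 1.0,
            ))

        for g in genes:
            if g.kind == "contaminant":
                for ind in individuals:
                    ind.haplotypes[g.gene_id] = [g.expressed]
                continue
            expressed = g.expressed
            L = len(expressed)
            hap_alleles: list[dict[int, str]] = [dict() for _ in range(n_hap)]
            gene_positions: list[dict] = []
            for entry in pending[g.gene_id]:
                pos, ref = entry["pos"], entry["ref"]
                t_ok, tv = entry["t_ok"], entry["tv"]
                if t_ok and tv:
                    use_transition = rng.random() < p_both
                elif t_ok:
                    use_transition = True
                else:
                    use_transition = False
                if use_transition:
                    alt = _TRANSITION[ref]
                else:
                    alt = tv[rng.integers(0, len(tv))]
                k = int(rng.integers(1, n_hap))
                carriers = sorted(rng.choice(n_hap, size=k, replace=False).tolist())
                for h in carriers:
                    hap_alleles[h][pos] = alt
                gene_positions.append(
                    {"pos": pos, "ref": ref, "alt": alt, "carriers": carriers}
                )
            junctions = g.junctions_expressed
            planted = [d["pos"] for d in gene_positions]
            locus = locus_of_gene.get(g.gene_id)
            for d in gene_positions:
                pos, ref, alt = d["pos"], d["ref"], d["alt"]
                near_end = pos < 35 or pos >= L - 35
                # a context is junction-spanning when its best contiguous
                # genomic match (coincidental run-on into the intron counts)
                # falls below the 68-bp screen threshold
                near_junction = False
                if not near_end and locus is not None and any(
                    pos - 35 < j < pos + 36 for j in junctions
                ):
                    from .align_core import local_align as _la

                    ctx = expressed[pos - 35 : pos + 36]
                    near_junction = _la(ctx, locus).matched_length < 68
                strand_ambiguous = {ref, alt} in ({"A", "T"}, {"C", "G"})
                crowded = any(0 < abs(pos - q) <= 35 for q in planted)
                in_variant_skip = (
                    g.variant_skip is not None
                    and g.variant_skip[0] <= pos < g.variant_skip[1]
                )
                is_paralog_gene = g.paralog_of is not None or any(
                    p[0] == g.gene_id for p in paralog_pairs
                )
                clean = not (
                    near_end or near_junction or strand_ambiguous or crowded
                    or is_paralog_gene or g.kind == "chloro"
                )
                snp_rows.append({
                    "set": code, "gene_id": g.gene_id, "pos": pos,
                    "mrna_pos": pos + g.expressed_start, "ref": ref, "alt": alt,
                    "alt_haps": ",".join(map(str, d["carriers"])),
                    "n_alt_haps": len(d["carriers"]),
                    "is_transition": alt == _TRANSITION[ref],
                    "strand_ambiguous": strand_ambiguous,
                    "near_end": near_end, "near_junction": near_junction,
                    "crowded": crowded, "paralog_gene": is_paralog_gene,
                    "chloro": g.kind == "chloro",
                    "in_variant_skip": in_variant_skip,
                    "clean": clean,
                })
            for ii, ind in enumerate(individuals):
                haps = []
                for h in range(ii * params.ploidy, (ii + 1) * params.ploidy):
                    seq = list(expressed)
                    for pos, alt in hap_alleles[h].items():
                        seq[pos] = alt
                    haps.append("".join(seq))
                ind.haplotypes[g.gene_id] = haps
        for ind in individuals:
            _build_transcripts(ind, genes, params)
        sets[code] = SampleSet(code=code, individuals=individuals)

    snps = pd.DataFrame(snp_rows)
    annotation = pd.DataFrame({
        "protein_id": [p.id for p in guide_proteins],
        "annotation": [f"synthetic guide protein {p.id}" for p in guide_proteins],
    })
    return TruthSet(
        params=params, genes=genes, guide_proteins=guide_proteins,
        contaminant_proteins=contaminant_proteins, chloro_genome=chloro_genome,
        genome=genome, sets=sets, snps=snps, annotation=annotation,
    )


def consensus_of(haps: list[str]) -> str:
    """Per-column majority of equal-length sequences, ties to the smaller base."""
    if len(haps) == 1:
        return haps[0]
    arr = np.array([list(h) for h in haps])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append(sorted(vals[counts == counts.max()])[0])
    return "".join(out)


def _build_transcripts(ind: Individual, genes: list[GeneModel],
                       params: SimulationParams) -> None:
    """Per-individual transcript set: consensus (or two overlapping fragments)
    of the individual's haplotypes, plus splice-variant and decoy entries."""
    for g in genes:
        cons = consensus_of(ind.haplotypes[g.gene_id])
        base = f"{ind.ind_id}_{g.gene_id}"
        if g.kind == "nuclear" and g.fragmented and len(cons) >= 3 * params.fragment_overlap:
            mid = len(cons) // 2
            half = params.fragment_overlap // 2
            parts = [
                (f"{base}_f1", cons[: mid + half]),
                (f"{base}_f2", cons[mid - half :]),
            ]
        else:
            parts = [(f"{base}_t1", cons)]
        if g.has_variant and g.variant_skip is not None:
            lo, hi = g.variant_skip
            parts.append((f"{base}_v1", cons[:lo] + cons[hi:]))
        for tid, seq in parts:
            ind.transcripts.append(SequenceRecord(tid, seq, meta=f"gene={g.gene_id}"))
            ind.transcript_gene[tid] = g.gene_id


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimulation:
    """Reads of one individual plus the per-read origin table."""

    r1: list[SequenceRecord]
    r2: list[SequenceRecord]          # empty in the long single-end regime
    origin: pd.DataFrame


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution errors at ``rate`` with a linear 3' increase (mean = rate)."""
    if rate <= 0:
        return seq
    L = len(seq)
    profile = rate * (0.5 + np.arange(L) / max(1, L - 1))
    hits = np.flatnonzero(rng.random(L) < profile)
    if len(hits) == 0:
        return seq
    out = list(seq)
    for pos in hits:
        pos = int(pos)
        alts = [b for b in _BASES if b != out[pos]]
        out[pos] = alts[rng.integers(0, 3)]
    return "".join(out)


def _apply_indel_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Long-read error model: substitutions plus indel-biased errors."""
    out = []
    for c in seq:
        r = rng.random()
        if r < rate * 0.5:
            out.append(_BASES[rng.integers(0, 4)])       # substitution
        elif r < rate * 0.75:
            out.append(c)
            out.append(_BASES[rng.integers(0, 4)])       # insertion
        elif r < rate:
            continue                                      # deletion
        else:
            out.append(c)
    return "".join(out) or "N"


def _qualities(rng: np.random.Generator, n: int) -> list[int]:
    # high-quality profile with mild 3' decay; never below the trim threshold
    return [38 - int(4 * i / max(1, n - 1)) for i in range(n)]


def simulate_reads(truth: TruthSet, params: SimulationParams | None = None,
                   individual: Individual | None = None,
                   rng: np.random.Generator | None = None) -> dict[str, ReadSimulation]:
    """Simulate reads per individual (all sets, or one individual if given).

    Illumina regime: paired-end reads with configured insert; substitution
    errors.  454 regime: long single-end reads with indel-biased errors.
    Expected pair count per source sequence is coverage*len/(2*read_len);
    read starts are uniform over the source.
    """
    params = params or truth.params
    rng = rng or np.random.default_rng(params.seed + 1)
    out: dict[str, ReadSimulation] = {}
    individuals = (
        [individual] if individual is not None
        else [ind for s in truth.sets.values() for ind in s.individuals]
    )
    for ind in individuals:
        sources: list[tuple[str, str, float, str]] = []  # (gene, hap_label, weight, seq)
        for g in truth.genes:
            for hi, hap in enumerate(ind.haplotypes[g.gene_id]):
                sources.append((g.gene_id, f"h{hi}", 1.0, hap))
            if g.has_variant and g.variant_skip is not None:
                cons = consensus_of(ind.haplotypes[g.gene_id])
                lo, hi_ = g.variant_skip
                sources.append(
                    (g.gene_id, "variant", params.variant_read_weight,
                     cons[:lo] + cons[hi_:])
                )
        r1: list[SequenceRecord] = []
        r2: list[SequenceRecord] = []
        origin_rows: list[dict] = []
        counter = 0
        for gene_id, hap_label, weight, seq in sources:
            L = len(seq)
            if params.regime == "illumina":
                rl = params.read_len
                if L < rl:
                    continue
                n_pairs = rng.poisson(weight * params.coverage * L / (2 * rl))
                for _ in range(n_pairs):
                    frag = int(np.clip(rng.normal(params.insert_mean, params.insert_sd),
                                       rl, L))
                    start = int(rng.integers(0, L - frag + 1))
                    fwd = rng.random() < 0.5
                    from_head = seq[start : start + rl]
                    from_tail = revcomp(seq[start + frag - rl : start + frag])
                    f1, f2 = (from_head, from_tail) if fwd else (from_tail, from_head)
                    rid = f"{ind.ind_id}_r{counter:07d}"
                    counter += 1
                    e1 = _apply_errors(rng, f1, params.read_error_rate)
                    e2 = _apply_errors(rng, f2, params.read_error_rate)
                    r1.append(SequenceRecord(rid, e1, qual=_qualities(rng, len(e1))))
                    r2.append(SequenceRecord(rid, e2, qual=_qualities(rng, len(e2))))
                    origin_rows.append({
                        "read_id": rid, "gene_id": gene_id, "haplotype": hap_label,
                        "strand": "+" if fwd else "-", "start": start, "frag_len": frag,
                    })
            else:  # 454-like long single-end
                mean_rl = params.long_read_len_mean
                n_reads = rng.poisson(weight * params.coverage * L / mean_rl)
                for _ in range(n_reads):
                    rl = int(np.clip(rng.normal(mean_rl, params.long_read_len_sd),
                                     100, L))
                    start = int(rng.integers(0, L - rl + 1))
                    frag = seq[start : start + rl]
                    if rng.random() < 0.5:
                        frag = revcomp(frag)
                        strand = "-"
                    else:
                        strand = "+"
                    err = _apply_indel_errors(rng, frag, params.read_error_rate)
                    rid = f"{ind.ind_id}_r{counter:07d}"
                    counter += 1
                    r1.append(SequenceRecord(rid, err, qual=_qualities(rng, len(err))))
                    origin_rows.append({
                        "read_id": rid, "gene_id": gene_id, "haplotype": hap_label,
                        "strand": strand, "start": start, "frag_len": rl,
                    })
        out[ind.ind_id] = ReadSimulation(
            r1=r1, r2=r2,
            origin=pd.DataFrame(
                origin_rows,
                columns=["read_id", "gene_id", "haplotype", "strand", "start", "frag_len"],
            ),
        )
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, outdir, reads: dict[str, ReadSimulation] | None = None) -> None:
    """Serialize the truth set (FASTA/FASTQ/TSV) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.guide_proteins, outdir / "guide_proteome.faa")
    write_fasta(truth.contaminant_proteins, outdir / "contaminants.faa")
    write_fasta([truth.chloro_genome], outdir / "chloroplast.fa")
    write_fasta(truth.genome, outdir / "genome.fa")
    truth.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
    truth.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    gene_rows = []
    for g in truth.genes:
        gene_rows.append({
            "gene_id": g.gene_id, "kind": g.kind, "length": len(g.mrna),
            "cds_start": g.cds[0] if g.cds else -1,
            "cds_end": g.cds[1] if g.cds else -1,
            "exon_bounds": ",".join(map(str, g.exon_bounds)),
            "expressed_start": g.expressed_start, "expressed_end": g.expressed_end,
            "guide_protein": g.guide_protein_id or "",
            "paralog_of": g.paralog_of or "", "truncated": g.truncated,
            "fragmented": g.fragmented, "has_variant": g.has_variant,
            "full_length_expected": g.full_length_expected,
        })
    pd.DataFrame(gene_rows).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    for code, sset in truth.sets.items():
        for ind in sset.individuals:
            write_fasta(ind.transcripts, outdir / f"{ind.ind_id}_transcripts.fa")
    if reads:
        for ind_id, sim in reads.items():
            write_fastq(sim.r1, outdir / f"{ind_id}_R1.fastq")
            if sim.r2:
                write_fastq(sim.r2, outdir / f"{ind_id}_R2.fastq")
            sim.origin.to_csv(outdir / f"{ind_id}_origin.tsv", sep="\t", index=False)
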