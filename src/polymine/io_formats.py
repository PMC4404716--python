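"""Readers and writers for every external representation the pipeline touches.

Sequence containers are thin dataclasses; parsing of FASTA/FASTQ is delegated
to Biopython's SeqIO, with the integrity checks (unique ids, seq/qual length
agreement) layered on top.  Alignments travel in a SAM-lite dialect: a strict
subset of SAM (``@SQ`` header lines, columns 1-9, plus ``ZI``/``ZS``/``ZE``
tags for identity and query interval) of which this package is both producer
and consumer.  Marker manifests and SNP tables are plain TSV / VCF-like text.

Coordinates are 0-based half-open everywhere in memory; 1-based only where a
serialization format demands it (SAM POS, VCF POS).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord


class ParseError(ValueError):
    """Malformed file content (names the offending record/line where known)."""


class IntegrityError(ValueError):
    """Structurally valid input that violates a cross-record invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence with optional per-base phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise IntegrityError(f"record {self.id!r}: empty sequence")
        if re.search(r"\s", self.id):
            raise IntegrityError(f"record id {self.id!r} contains whitespace")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: qual length {len(self.qual)} != "
                f"seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """A local alignment between a query and a subject sequence.

    Intervals are 0-based half-open on the forward strand of each sequence;
    for minus-strand alignments the query interval refers to the
    reverse-complemented query.  ``cigar`` uses M/X/=/I/D operations with
    I = insertion in the query relative to the subject.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # '+' or '-'
    cigar: str
    score: int
    identity: float
    mapq: int = 255

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise IntegrityError(f"bad strand {self.strand!r}")
        qlen, slen = _cigar_spans(self.cigar)
        if qlen != self.query_end - self.query_start:
            raise IntegrityError(
                f"{self.query_id}->{self.subject_id}: cigar query span {qlen} "
                f"!= interval {self.query_end - self.query_start}"
            )
        if slen != self.subject_end - self.subject_start:
            raise IntegrityError(
                f"{self.query_id}->{self.subject_id}: cigar subject span {slen}"
                f" != interval {self.subject_end - self.subject_start}"
            )

    @property
    def aligned_columns(self) -> int:
        return sum(n for n, op in _cigar_ops(self.cigar))

    @property
    def matched_length(self) -> int:
        """Longest gap-free run of alignment columns (M/X/= ops)."""
        best = run = 0
        for n, op in _cigar_ops(self.cigar):
            if op in "MX=":
                run += n
                best = max(best, run)
            else:
                run = 0
        return best


_SNP_ID_RE = re.compile(r"^[A-Z]_.+_.+$")


@dataclass
class MarkerManifestRow:
    """One array marker: SNP id, probe ids, 71-mer context with [X/Y] center."""

    snp_id: str
    probe_id_fwd: str
    probe_id_rev: str
    context: str  # e.g. 35-mer + "[A/G]" + 35-mer
    alleles: str  # "A/G"
    source_transcript: str
    rhfv_ortholog: str = ""
    guide_protein: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if not _SNP_ID_RE.match(self.snp_id):
            raise IntegrityError(f"snp_id {self.snp_id!r} not of form X_t_s")
        m = re.match(r"^([ACGT]*)\[([ACGT])/([ACGT])\]([ACGT]*)$", self.context)
        if not m:
            raise IntegrityError(f"{self.snp_id}: malformed context")
        left, a, b, right = m.groups()
        if len(left) != len(right):
            raise IntegrityError(f"{self.snp_id}: unequal flanks")
        if self.alleles != f"{a}/{b}":
            raise IntegrityError(f"{self.snp_id}: alleles disagree with context")


MANIFEST_COLUMNS = [
    "snp_id", "probe_id_fwd", "probe_id_rev", "context", "alleles",
    "transcript", "rhfv", "protein", "annotation",
]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _check_unique_ids(records: list[SequenceRecord], path) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise IntegrityError(f"{path}: duplicate record id {r.id!r}")
        seen.add(r.id)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file (wrapped or unwrapped) into SequenceRecords."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}: line 1: FASTA must start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), meta=desc))
    _check_unique_ids(records, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    records = list(records)
    _check_unique_ids(records, path)
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.meta}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Read 4-line phred+33 FASTQ; qualities are decoded to integer lists."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = rec.letter_annotations["phred_quality"]
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, str(rec.seq).upper(), qual=list(qual), meta=desc)
            )
    except ValueError as exc:  # SeqIO raises on seq/qual length mismatch
        raise ParseError(f"{path}: {exc}") from exc
    _check_unique_ids(records, path)
    return records


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    records = list(records)
    _check_unique_ids(records, path)
    with open(path, "w") as fh:
        for r in records:
            if r.qual is None:
                raise IntegrityError(f"record {r.id!r} has no qualities")
            qstr = "".join(chr(q + 33) for q in r.qual)
            header = f"@{r.id} {r.meta}".rstrip()
            fh.write(f"{header}\n{r.seq}\n+\n{qstr}\n")


def to_biopython(record: SequenceRecord) -> _BioRecord:
    out = _BioRecord(Seq(record.seq), id=record.id, description=record.meta)
    if record.qual is not None:
        out.letter_annotations["phred_quality"] = list(record.qual)
    return out


# ---------------------------------------------------------------------------
# SAM-lite
# ---------------------------------------------------------------------------

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_ops(cigar: str):
    ops = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ParseError(f"bad cigar {cigar!r}")
    return ops


def _cigar_spans(cigar: str) -> tuple[int, int]:
    q = s = 0
    for n, op in _cigar_ops(cigar):
        if op in "MX=":
            q += n
            s += n
        elif op == "I":
            q += n
        elif op in "DN":
            s += n
    return q, s


def write_sam_lite(
    alignments: Sequence[AlignmentRecord],
    path,
    subject_lengths: dict[str, int],
) -> None:
    """Write alignments as a SAM subset (header + columns 1-9 + ZI/ZS/ZE tags)."""
    for aln in alignments:
        if aln.subject_id not in subject_lengths:
            raise IntegrityError(f"alignment references unknown subject {aln.subject_id!r}")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in subject_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            fh.write(
                "\t".join(
                    [
                        aln.query_id,
                        str(flag),
                        aln.subject_id,
                        str(aln.subject_start + 1),  # SAM POS is 1-based
                        str(aln.mapq),
                        aln.cigar,
                        "*",
                        "0",
                        "0",
                        "*",
                        "*",
                        f"AS:i:{aln.score}",
                        f"ZI:f:{aln.identity:.6f}",
                        f"ZS:i:{aln.query_start}",
                        f"ZE:i:{aln.query_end}",
                    ]
                )
                + "\n"
            )


def read_sam_lite(path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    subject_lengths: dict[str, int] = {}
    alignments: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    subject_lengths[fields["SN"]] = int(fields["LN"])
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ParseError(f"{path}: line {lineno}: fewer than 11 columns")
            tags = dict()
            for tag in cols[11:]:
                name, typ, val = tag.split(":", 2)
                tags[name] = float(val) if typ == "f" else (int(val) if typ == "i" else val)
            if cols[2] not in subject_lengths:
                raise IntegrityError(f"{path}: line {lineno}: unknown subject {cols[2]!r}")
            sstart = int(cols[3]) - 1
            _, sspan = _cigar_spans(cols[5])
            alignments.append(
                AlignmentRecord(
                    query_id=cols[0],
                    subject_id=cols[2],
                    query_start=int(tags.get("ZS", 0)),
                    query_end=int(tags.get("ZE", 0)),
                    subject_start=sstart,
                    subject_end=sstart + sspan,
                    strand="-" if int(cols[1]) & 16 else "+",
                    cigar=cols[5],
                    score=int(tags.get("AS", 0)),
                    identity=float(tags.get("ZI", 0.0)),
                    mapq=int(cols[4]),
                )
            )
    return alignments, subject_lengths


# ---------------------------------------------------------------------------
# marker manifest (TSV) and SNP table (VCF-like)
# ---------------------------------------------------------------------------

def write_marker_manifest(rows: Iterable[MarkerManifestRow], path) -> None:
    """Write the array manifest as TSV, one row per SNP, sorted by snp_id."""
    rows = sorted(rows, key=lambda r: r.snp_id)
    seen: set[str] = set()
    for r in rows:
        if r.snp_id in seen:
            raise IntegrityError(f"duplicate snp_id {r.snp_id!r} in manifest")
        seen.add(r.snp_id)
    df = pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "probe_id_fwd": r.probe_id_fwd,
                "probe_id_rev": r.probe_id_rev,
                "context": r.context,
                "alleles": r.alleles,
                "transcript": r.source_transcript,
                "rhfv": r.rhfv_ortholog,
                "protein": r.guide_protein,
                "annotation": r.annotation,
            }
            for r in rows
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_manifest(path) -> list[MarkerManifestRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ParseError(f"{path}: unexpected manifest columns {list(df.columns)}")
    return [
        MarkerManifestRow(
            snp_id=row.snp_id,
            probe_id_fwd=row.probe_id_fwd,
            probe_id_rev=row.probe_id_rev,
            context=row.context,
            alleles=row.alleles,
            source_transcript=row.transcript,
            rhfv_ortholog=row.rhfv,
            guide_protein=row.protein,
            annotation=row.annotation,
        )
        for row in df.itertuples()
    ]


SNP_TABLE_COLUMNS = ["CHROM", "POS", "ID", "REF", "ALT", "INFO"]


def write_snp_table(calls, path) -> None:
    """VCF-like SNP table: CHROM=transcript, POS 1-based, INFO carries counts.

    ``calls`` are snp_mining.SNPCall objects (duck-typed here to avoid a
    circular import).
    """
    recs = []
    for c in calls:
        info = (
            f"RC={c.counts[c.ref]},{c.counts[c.alt]};"
            f"HAP={c.hap_support[c.ref]},{c.hap_support[c.alt]};"
            f"RELIABLE={int(c.reliable)}"
        )
        recs.append(
            {
                "CHROM": c.transcript_id,
                "POS": c.pos + 1,
                "ID": ".",
                "REF": c.ref,
                "ALT": c.alt,
                "INFO": info,
            }
        )
    pd.DataFrame(recs, columns=SNP_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    if list(df.columns) != SNP_TABLE_COLUMNS:
        raise ParseError(f"{path}: unexpected SNP table columns")
    return df
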