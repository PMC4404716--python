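"""Read pre-processing: quality/poly-A/complexity filters and pair merging.

The canonical order of operations is head trim -> quality trim -> poly-A/T
trim -> DUST low-complexity filter -> length & ambiguity filter -> duplicate
removal -> pair merging.  All filters except the fixed head trim are
idempotent.  Merged pairs and orphaned mates go on as single-end reads;
unmerged pairs stay paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align_core import revcomp
from .io_formats import SequenceRecord


@dataclass
class PrepParams:
    phred_min: int = 25
    head_trim: int = 10
    min_len_short: int = 50      # Illumina-regime minimum read length
    min_len_long: int = 100      # 454-regime minimum read length
    max_ambiguous: int = 1       # reads with MORE than this many N are dropped
    dust_threshold: float = 7.0
    polyat_min_run: int = 5
    merge_min_overlap: int = 10
    merge_max_mismatch_rate: float = 0.1
    quality_trim_mode: str = "ends"  # "ends" or "three_prime"

    def __post_init__(self) -> None:
        for name in ("phred_min", "head_trim", "min_len_short", "min_len_long",
                     "max_ambiguous", "polyat_min_run", "merge_min_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# SequenceRecord forbids empty sequences; pre-processing can legitimately eat a
# whole read, so an emptied read is built without running validation.
def _empty(read: SequenceRecord) -> SequenceRecord:
    out = object.__new__(SequenceRecord)
    out.id, out.seq, out.qual, out.meta = read.id, "", ([] if read.qual is not None else None), read.meta
    return out


def _cut(read: SequenceRecord, start: int, end: int) -> SequenceRecord:
    if end <= start:
        return _empty(read)
    qual = read.qual[start:end] if read.qual is not None else None
    return SequenceRecord(read.id, read.seq[start:end], qual=qual, meta=read.meta)


def quality_trim(read: SequenceRecord, phred_min: int = 25, mode: str = "ends") -> SequenceRecord:
    """Trim terminal bases with phred < ``phred_min``.

    ``ends`` mode removes the maximal low-quality prefix and suffix (the
    retained interval is the widest one whose boundary bases pass); interior
    low-quality bases are never touched.  ``three_prime`` trims the suffix
    only.
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    start, end = 0, len(read.seq)
    while end > start and read.qual[end - 1] < phred_min:
        end -= 1
    if mode == "ends":
        while start < end and read.qual[start] < phred_min:
            start += 1
    return _cut(read, start, end)


def head_trim(read: SequenceRecord, n: int = 10) -> SequenceRecord:
    """Remove the first min(n, len) bases (random-priming bias trim)."""
    return _cut(read, min(n, len(read.seq)), len(read.seq))


def polyat_trim(read: SequenceRecord, min_run: int = 5) -> SequenceRecord:
    """Strip a terminal poly-A run from the 3' end and poly-T from the 5' end,
    when the run is at least ``min_run`` long."""
    seq = read.seq
    end = len(seq)
    n_a = 0
    while n_a < end and seq[end - 1 - n_a] == "A":
        n_a += 1
    if n_a >= min_run:
        end -= n_a
    start = 0
    n_t = 0
    while n_t < end and seq[start + n_t] == "T":
        n_t += 1
    if n_t >= min_run:
        start += n_t
    return _cut(read, start, end)


def dedupe(reads: list[SequenceRecord]) -> list[SequenceRecord]:
    """Keep the first read (input order) of every exact-sequence duplicate set.

    Reverse complements are NOT considered duplicates.
    """
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def dust_score(seq: str) -> float:
    """DUST triplet score scaled to [0, 100].

    Sum over triplet counts c of c(c-1)/2, divided by the value a homopolymer
    of the same length would reach (k(k-1)/2 for k triplet windows): 100 for
    a homopolymer, ~1.6 for uniform random sequence.
    """
    k = len(seq) - 2
    if k < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(k):
        t = seq[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    raw = sum(c * (c - 1) / 2 for c in counts.values())
    return 100.0 * raw / (k * (k - 1) / 2)


def dust_filter(read: SequenceRecord, threshold: float = 7.0) -> bool:
    """True = keep; drop low-complexity reads with DUST score > threshold."""
    if len(read.seq) < 3:
        return True
    return dust_score(read.seq) <= threshold


def length_ambiguity_filter(
    read: SequenceRecord, min_len: int = 50, max_ambiguous: int = 1
) -> bool:
    """True = keep; drop reads shorter than ``min_len`` or with more than
    ``max_ambiguous`` ambiguous (non-ACGT) bases."""
    if len(read.seq) < min_len:
        return False
    n_ambig = sum(1 for c in read.seq if c not in "ACGT")
    return n_ambig <= max_ambiguous


def merge_pairs(
    r1: SequenceRecord, r2: SequenceRecord, params: PrepParams | None = None
) -> SequenceRecord | None:
    """Merge an overlapping read pair into a single fragment-length read.

    ``r2`` is given in sequencing orientation and is reverse-complemented
    internally.  The best 3' overlap of length >= ``merge_min_overlap`` with a
    mismatch rate <= ``merge_max_mismatch_rate`` wins; conflicting bases take
    the call with the higher quality.  Returns the merged read, or None when
    no acceptable overlap exists (the pair then stays paired).
    """
    params = params or PrepParams()
    s1 = r1.seq
    s2 = revcomp(r2.seq)
    q1 = r1.qual if r1.qual is not None else [30] * len(s1)
    q2 = list(reversed(r2.qual)) if r2.qual is not None else [30] * len(s2)
    from .align_core import encode_nt

    e1 = encode_nt(s1)
    e2 = encode_nt(s2)
    overlap = None
    for ov in range(min(len(s1), len(s2)), params.merge_min_overlap - 1, -1):
        mismatches = int(np.count_nonzero(e1[len(s1) - ov :] != e2[:ov]))
        if mismatches / ov <= params.merge_max_mismatch_rate:
            overlap = ov
            break  # prefer the longest acceptable overlap
    if overlap is None:
        return None
    off = len(s1) - overlap
    merged_seq = []
    merged_qual = []
    for i in range(off):
        merged_seq.append(s1[i])
        merged_qual.append(q1[i])
    for j in range(overlap):
        i = off + j
        if s1[i] == s2[j]:
            merged_seq.append(s1[i])
            merged_qual.append(max(q1[i], q2[j]))
        elif q1[i] >= q2[j]:
            merged_seq.append(s1[i])
            merged_qual.append(q1[i])
        else:
            merged_seq.append(s2[j])
            merged_qual.append(q2[j])
    for j in range(overlap, len(s2)):
        merged_seq.append(s2[j])
        merged_qual.append(q2[j])
    return SequenceRecord(r1.id, "".join(merged_seq), qual=merged_qual, meta="merged")


@dataclass
class PrepResult:
    merged: list[SequenceRecord] = field(default_factory=list)
    singles: list[SequenceRecord] = field(default_factory=list)
    paired_r1: list[SequenceRecord] = field(default_factory=list)
    paired_r2: list[SequenceRecord] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def single_end_reads(self) -> list[SequenceRecord]:
        return self.merged + self.singles


def _prep_one(read: SequenceRecord, params: PrepParams, min_len: int,
              apply_head: bool = True) -> SequenceRecord | None:
    """One read through the filter chain; None when any filter drops it."""
    r = head_trim(read, params.head_trim) if apply_head else read
    if r.qual is not None:
        r = quality_trim(r, params.phred_min, params.quality_trim_mode)
    r = polyat_trim(r, params.polyat_min_run)
    if not r.seq:
        return None
    if not dust_filter(r, params.dust_threshold):
        return None
    if not length_ambiguity_filter(r, min_len, params.max_ambiguous):
        return None
    return r


def prep_paired(
    reads1: list[SequenceRecord],
    reads2: list[SequenceRecord],
    params: PrepParams | None = None,
) -> PrepResult:
    """Full short-read pre-processing of a paired-end library."""
    params = params or PrepParams()
    if len(reads1) != len(reads2):
        raise ValueError("R1/R2 files have different read counts")
    res = PrepResult()
    n_in = len(reads1) * 2
    kept_pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    orphans: list[SequenceRecord] = []
    for r1, r2 in zip(reads1, reads2):
        p1 = _prep_one(r1, params, params.min_len_short)
        p2 = _prep_one(r2, params, params.min_len_short)
        if p1 is not None and p2 is not None:
            kept_pairs.append((p1, p2))
        elif p1 is not None:
            orphans.append(p1)
        elif p2 is not None:
            orphans.append(p2)
    # duplicate removal on the fragment level: key = (seq1, seq2)
    seen: set[tuple[str, str]] = set()
    uniq_pairs = []
    for p1, p2 in kept_pairs:
        key = (p1.seq, p2.seq)
        if key not in seen:
            seen.add(key)
            uniq_pairs.append((p1, p2))
    orphans = dedupe(orphans)
    for p1, p2 in uniq_pairs:
        merged = merge_pairs(p1, p2, params)
        if merged is not None:
            res.merged.append(merged)
        else:
            res.paired_r1.append(p1)
            res.paired_r2.append(p2)
    res.singles = orphans
    res.counts = {
        "reads_in": n_in,
        "pairs_in": len(reads1),
        "pairs_kept": len(uniq_pairs),
        "pairs_dropped_dup": len(kept_pairs) - len(uniq_pairs),
        "orphans": len(orphans),
        "merged": len(res.merged),
        "paired_out": len(res.paired_r1) * 2,
        "reads_out": len(res.merged) + len(orphans) + 2 * len(res.paired_r1),
    }
    return res


def prep_single(
    reads: list[SequenceRecord], params: PrepParams | None = None,
    long_regime: bool = False,
) -> PrepResult:
    """Pre-processing of a single-end library.

    ``long_regime`` applies the long-read minimum length (454-style libraries)
    instead of the short-read one.
    """
    params = params or PrepParams()
    min_len = params.min_len_long if long_regime else params.min_len_short
    res = PrepResult()
    kept = []
    for r in reads:
        p = _prep_one(r, params, min_len)
        if p is not None:
            kept.append(p)
    res.singles = dedupe(kept)
    res.counts = {
        "reads_in": len(reads),
        "reads_kept": len(kept),
        "dropped_dup": len(kept) - len(res.singles),
        "reads_out": len(res.singles),
    }
    return res
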