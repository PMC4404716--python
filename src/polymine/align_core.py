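"""Self-contained alignment and assembly kernels used by all downstream stages.

Everything here is deterministic: seeded candidate finding only prunes the
search space, the reported alignments always come from an affine-gap
Smith-Waterman dynamic program (numba-compiled).  Hit lists are sorted by
score with lexicographic subject-id tie-breaks.

E-value style significance cut-offs are replaced by named presets on
(identity, matched length); see ``PRESETS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import AlignmentRecord, SequenceRecord

# ---------------------------------------------------------------------------
# alphabets and scoring
# ---------------------------------------------------------------------------

NT_ALPHABET = "ACGTN"
_NT_IDX = {c: i for i, c in enumerate(NT_ALPHABET)}

_B62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = "".join(_B62.alphabet)
_AA_IDX = {c: i for i, c in enumerate(AA_ALPHABET)}


from functools import lru_cache


@lru_cache(maxsize=32)
def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = 0  # N scores 0 against everything
    m[:, 4] = 0
    return m


def _aa_matrix() -> np.ndarray:
    n = len(AA_ALPHABET)
    m = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            m[i, j] = int(_B62[a][b])
    return m


_AA_MATRIX = _aa_matrix()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_NT_LUT = np.full(256, 4, dtype=np.uint8)
for _c, _i in _NT_IDX.items():
    _NT_LUT[ord(_c)] = _i

_AA_LUT = np.full(256, _AA_IDX.get("X", 0), dtype=np.uint8)
for _c, _i in _AA_IDX.items():
    _AA_LUT[ord(_c)] = _i


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Preset:
    """Significance preset replacing a BLAST e-value cut-off."""

    min_identity: float
    min_matched_len: int


PRESETS = {
    "loose": Preset(0.80, 50),      # stands in for e-value 1e-5
    "standard": Preset(0.85, 60),   # stands in for e-value 1e-10
    "strict": Preset(0.90, 100),    # stands in for e-value 1e-30
    "probe": Preset(0.95, 60),      # near-identical probe contexts
}


@dataclass
class AlignParams:
    """Scoring and seeding parameters for the alignment kernels."""

    mode: str = "nucleotide"  # or "protein"
    k: int = 12
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_identity: float = 0.0
    min_hit_score: int = 20
    max_hits: int = 250
    # seeded search is used once query*db exceeds this many DP cells
    exhaustive_cell_limit: int = 2_000_000
    min_shared_kmers: int = 1

    def __post_init__(self) -> None:
        if self.mode == "nucleotide" and self.k < 8:
            raise ValueError("nucleotide seeding requires k >= 8")
        if self.mode == "protein" and self.k < 4:
            raise ValueError("protein seeding requires k >= 4")

    @classmethod
    def protein(cls, **kw) -> "AlignParams":
        kw.setdefault("mode", "protein")
        kw.setdefault("k", 4)
        kw.setdefault("gap_open", -11)
        kw.setdefault("gap_extend", -1)
        kw.setdefault("min_shared_kmers", 3)
        return cls(**kw)

    def matrix(self) -> np.ndarray:
        if self.mode == "protein":
            return _AA_MATRIX
        return _nt_matrix(self.match, self.mismatch)

    def encode(self, seq: str) -> np.ndarray:
        return encode_aa(seq) if self.mode == "protein" else encode_nt(seq)


# ---------------------------------------------------------------------------
# affine-gap local DP (numba)
# ---------------------------------------------------------------------------

# traceback pointer codes
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


@njit(cache=True)
def _sw_affine(a, b, matrix, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            h = 0
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if E[i, j] > h:
                h = E[i, j]
                p = _FROM_E
            if F[i, j] > h:
                h = F[i, j]
                p = _FROM_F
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback: ops 0 '=', 1 'X', 2 'I' (query only), 3 'D' (subject only)
    ops = np.empty(n + m + 2, dtype=np.uint8)
    nops = 0
    i, j = bi, bj
    state = 0  # 0 = in H
    while True:
        if state == 0:
            p = ptr[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                ops[nops] = 0 if a[i - 1] == b[j - 1] else 1
                nops += 1
                i -= 1
                j -= 1
            elif p == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:  # in E: gap consuming subject (D)
            ops[nops] = 3
            nops += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:  # in F: gap consuming query (I)
            ops[nops] = 2
            nops += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return best, i, bi, j, bj, ops[:nops][::-1].copy()


_OP_CHARS = "=XID"


def _ops_to_cigar(ops: np.ndarray) -> tuple[str, int, int]:
    """Collapse op codes into a cigar string; return (cigar, matches, columns)."""
    parts = []
    matches = 0
    prev = -1
    run = 0
    for o in ops:
        if o == 0:
            matches += 1
        if o == prev:
            run += 1
        else:
            if run:
                parts.append(f"{run}{_OP_CHARS[prev]}")
            prev = int(o)
            run = 1
    if run:
        parts.append(f"{run}{_OP_CHARS[prev]}")
    return "".join(parts), matches, len(ops)


def local_align(
    a: str,
    b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    strand: str = "+",
    a_enc: np.ndarray | None = None,
    b_enc: np.ndarray | None = None,
) -> AlignmentRecord:
    """Optimal affine-gap local alignment of ``a`` (query) against ``b``.

    Returns a zero-score empty alignment when nothing scores positively.
    Pre-encoded arrays may be supplied to skip re-encoding in hot loops.
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    score, qs, qe, ss, se, ops = _sw_affine(
        params.encode(a) if a_enc is None else a_enc,
        params.encode(b) if b_enc is None else b_enc,
        params.matrix(),
        params.gap_open,
        params.gap_extend,
    )
    if score <= 0:
        return AlignmentRecord(query_id, subject_id, 0, 0, 0, 0, strand, "", 0, 0.0)
    cigar, matches, columns = _ops_to_cigar(ops)
    return AlignmentRecord(
        query_id=query_id,
        subject_id=subject_id,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        strand=strand,
        cigar=cigar,
        score=int(score),
        identity=matches / columns if columns else 0.0,
    )


def meets_preset(aln: AlignmentRecord, preset: Preset | str) -> bool:
    if isinstance(preset, str):
        preset = PRESETS[preset]
    return (
        aln.score > 0
        and aln.identity >= preset.min_identity
        and aln.matched_length >= preset.min_matched_len
    )


# ---------------------------------------------------------------------------
# k-mer index and database search
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over a sequence database (strings, one alphabet)."""

    def __init__(self, records: list[SequenceRecord], k: int):
        self.records = records
        self.k = k
        self.enc_cache: dict[int, np.ndarray] = {}  # filled lazily by search
        self.kmer_to_hits: dict[str, list[tuple[int, int]]] = {}
        for idx, rec in enumerate(records):
            s = rec.seq
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                self.kmer_to_hits.setdefault(kmer, []).append((idx, i))

    def candidates(self, query: str, min_shared: int = 1) -> list[int]:
        counts: dict[int, int] = {}
        k = self.k
        seen: set[str] = set()
        for i in range(len(query) - k + 1):
            kmer = query[i : i + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for idx, _ in self.kmer_to_hits.get(kmer, ()):
                counts[idx] = counts.get(idx, 0) + 1
        return sorted(idx for idx, c in counts.items() if c >= min_shared)

    def diagonals(self, query: str, subject_idx: int) -> list[int]:
        """Seed diagonals (subject_pos - query_pos) of the query on one subject."""
        k = self.k
        out = []
        for i in range(len(query) - k + 1):
            for idx, pos in self.kmer_to_hits.get(query[i : i + k], ()):
                if idx == subject_idx:
                    out.append(pos - i)
        return sorted(set(out))


def search(
    query: str | SequenceRecord,
    subject_db: list[SequenceRecord],
    params: AlignParams | None = None,
    query_id: str | None = None,
    index: KmerIndex | None = None,
) -> list[AlignmentRecord]:
    """Score the query against a database; sorted hits, at most ``max_hits``.

    Nucleotide mode searches both strands (minus-strand hits align the
    reverse-complemented query).  Small databases are scanned exhaustively;
    larger ones are pruned by shared k-mer counting, which can only remove
    subjects that share no (few) exact words with the query.
    """
    params = params or AlignParams()
    if isinstance(query, SequenceRecord):
        query_id = query_id or query.id
        query = query.seq
    query_id = query_id or "query"
    if not subject_db:
        return []
    total_cells = len(query) * sum(len(r.seq) for r in subject_db)
    queries = [("+", query)]
    if params.mode == "nucleotide":
        queries.append(("-", revcomp(query)))
    if index is None and total_cells <= params.exhaustive_cell_limit:
        cand = list(range(len(subject_db)))
    else:
        index = index or KmerIndex(subject_db, params.k)
        cand_set: set[int] = set()
        for _, q in queries:
            cand_set.update(index.candidates(q, params.min_shared_kmers))
        cand = sorted(cand_set)
    enc_cache = index.enc_cache if index is not None else {}
    queries = [(strand, q, params.encode(q)) for strand, q in queries]
    hits: list[AlignmentRecord] = []
    for idx in cand:
        rec = subject_db[idx]
        b_enc = enc_cache.get(idx)
        if b_enc is None:
            b_enc = params.encode(rec.seq)
            enc_cache[idx] = b_enc
        best: AlignmentRecord | None = None
        for strand, q, q_enc in queries:
            aln = _align_to_subject(q, rec, idx, params, query_id, strand,
                                    index, q_enc, b_enc)
            if aln is None:
                continue
            if best is None or aln.score > best.score:
                best = aln
        if (
            best is not None
            and best.score >= params.min_hit_score
            and best.identity >= params.min_identity
        ):
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits[: params.max_hits]


def _align_to_subject(
    q: str,
    rec: SequenceRecord,
    idx: int,
    params: AlignParams,
    query_id: str,
    strand: str,
    index: KmerIndex | None,
    q_enc: np.ndarray | None = None,
    b_enc: np.ndarray | None = None,
) -> AlignmentRecord | None:
    """Full DP against the subject, or DP restricted to seed-diagonal windows
    when the subject is long and an index with positions is available."""
    if index is None or len(rec.seq) <= 4 * len(q) + 400:
        return local_align(q, rec.seq, params, query_id, rec.id, strand,
                           a_enc=q_enc, b_enc=b_enc)
    diagonals = index.diagonals(q, idx)
    if not diagonals:
        return None
    pad = 50
    windows: list[tuple[int, int]] = []
    ws = we = None
    for d in diagonals:
        lo = max(0, d - pad)
        hi = min(len(rec.seq), d + len(q) + pad)
        if ws is None:
            ws, we = lo, hi
        elif lo <= we:
            we = max(we, hi)
        else:
            windows.append((ws, we))
            ws, we = lo, hi
    windows.append((ws, we))
    best: AlignmentRecord | None = None
    for lo, hi in windows:
        aln = local_align(q, rec.seq[lo:hi], params, query_id, rec.id, strand,
                          a_enc=q_enc,
                          b_enc=b_enc[lo:hi] if b_enc is not None else None)
        if aln.score <= 0:
            continue
        aln = replace(aln, subject_start=aln.subject_start + lo,
                      subject_end=aln.subject_end + lo)
        if best is None or aln.score > best.score:
            best = aln
    return best


# ---------------------------------------------------------------------------
# translated (six-frame) search
# ---------------------------------------------------------------------------

@dataclass
class TranslatedHit:
    """Best protein-level hit of a nucleotide query in one of six frames."""

    subject_id: str
    frame: int  # +1..+3, -1..-3
    score: int
    identity: float
    matched_length: int
    alignment: AlignmentRecord


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """All six translations, stop codons rendered as ``*``."""
    out = []
    rc = revcomp(seq)
    for off in range(3):
        for sgn, s in ((1, seq), (-1, rc)):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) >= 3:
                out.append((sgn * (off + 1), str(Seq(sub).translate())))
    out.sort(key=lambda t: (t[0] < 0, abs(t[0])))
    return out


def translated_search(
    nucl_query: str | SequenceRecord,
    protein_db: list[SequenceRecord],
    params: AlignParams | None = None,
    query_id: str | None = None,
    index: KmerIndex | None = None,
) -> list[TranslatedHit]:
    """Search a nucleotide query against proteins in all six reading frames.

    Translations are split at stop codons; each segment of length >= k is
    searched in protein mode and the best frame per subject is reported.
    Hits are sorted by score with (subject_id, frame) tie-breaks.
    """
    params = params or AlignParams.protein()
    if isinstance(nucl_query, SequenceRecord):
        query_id = query_id or nucl_query.id
        nucl_query = nucl_query.seq
    query_id = query_id or "query"
    if len(nucl_query) < 3 * params.k:
        return []
    best_per_subject: dict[str, TranslatedHit] = {}
    for frame, prot in six_frame_translations(nucl_query):
        for segment in prot.split("*"):
            if len(segment) < params.k:
                continue
            for aln in search(segment, protein_db, params, query_id, index=index):
                hit = TranslatedHit(
                    subject_id=aln.subject_id,
                    frame=frame,
                    score=aln.score,
                    identity=aln.identity,
                    matched_length=aln.matched_length,
                    alignment=aln,
                )
                prev = best_per_subject.get(aln.subject_id)
                if prev is None or hit.score > prev.score:
                    best_per_subject[aln.subject_id] = hit
    hits = sorted(best_per_subject.values(), key=lambda h: (-h.score, h.subject_id, h.frame))
    return hits[: params.max_hits]


# ---------------------------------------------------------------------------
# read mapping with a mapping-quality surrogate
# ---------------------------------------------------------------------------

def mapq_from_scores(s1: int, s2: int | None, cap: int = 60) -> int:
    """Phred-scaled ambiguity from best and second-best alignment scores.

    The chance that the best placement is wrong is modelled as halving with
    every score point separating it from the runner-up: p = 2^-(s1-s2),
    mapq = min(cap, round(-10 log10 p)).  No runner-up means an unambiguous
    placement (mapq = cap); an equal-scoring runner-up means mapq 0.
    """
    if s1 <= 0:
        return 0
    if s2 is None or s2 <= 0:
        return cap
    gap = max(0, s1 - s2)
    return min(cap, int(round(10 * math.log10(2) * gap)))


def map_read(
    read: str | SequenceRecord,
    reference_db: list[SequenceRecord],
    params: AlignParams | None = None,
    index: KmerIndex | None = None,
    mapq_min: int = 25,
) -> AlignmentRecord | None:
    """Best local placement of a read with a score-gap mapq.

    Returns None when the read has no positive-scoring hit.  Reads with
    ``mapq <= mapq_min`` are still returned; callers apply the passing filter.
    """
    params = params or AlignParams()
    hits = search(read, reference_db, params, index=index)
    if not hits:
        return None
    s2 = hits[1].score if len(hits) > 1 else None
    best = hits[0]
    return replace(best, mapq=mapq_from_scores(best.score, s2))


# ---------------------------------------------------------------------------
# greedy overlap-layout-consensus assembly
# ---------------------------------------------------------------------------

@dataclass
class OverlapAsmParams:
    """Overlap assembler thresholds (CAP3-like: ``-p 97`` -> identity 0.97)."""

    min_overlap_len: int = 40
    min_overlap_identity: float = 0.97
    end_slack: int = 3  # bp of unaligned overhang tolerated at a dovetail end

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("identity must be in (0, 1]")


class _Profile:
    """A growing contig: per-column base counts over NT_ALPHABET."""

    __slots__ = ("counts", "members")

    def __init__(self, seq: str, member: tuple[str, str]):
        codes = encode_nt(seq)
        self.counts = np.zeros((len(seq), 5), dtype=np.int32)
        self.counts[np.arange(len(seq)), codes] = 1
        self.members: list[tuple[str, str]] = [member]  # (id, strand)

    def consensus(self) -> str:
        # majority per column; ties go to the alphabetically smaller base
        best = np.argmax(self.counts, axis=1)
        return "".join(NT_ALPHABET[i] for i in best)

    def rc(self) -> "_Profile":
        out = object.__new__(_Profile)
        # reverse columns, complement the base axis (A<->T, C<->G, N fixed)
        out.counts = self.counts[::-1][:, [3, 2, 1, 0, 4]].copy()
        out.members = [(m, "-" if s == "+" else "+") for m, s in self.members]
        return out


def _overlap_alignment(
    a: _Profile, b: _Profile, params: AlignParams, asm: OverlapAsmParams
) -> tuple[int, AlignmentRecord, bool] | None:
    """Best dovetail/containment overlap between two profiles, either strand.

    Returns (score, alignment of consA vs consB, b_flipped) or None.
    """
    ca = a.consensus()
    best = None
    for flipped, bb in ((False, b), (True, b.rc())):
        cb = bb.consensus()
        aln = local_align(ca, cb, params)
        if aln.score <= 0:
            continue
        if aln.identity < asm.min_overlap_identity:
            continue
        if aln.aligned_columns < asm.min_overlap_len:
            continue
        e = asm.end_slack
        la, lb = len(ca), len(cb)
        dovetail_ab = aln.query_end >= la - e and aln.subject_start <= e
        dovetail_ba = aln.subject_end >= lb - e and aln.query_start <= e
        contain_b = aln.subject_start <= e and aln.subject_end >= lb - e
        contain_a = aln.query_start <= e and aln.query_end >= la - e
        if not (dovetail_ab or dovetail_ba or contain_a or contain_b):
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, aln, flipped)
    return best


def _merge_profiles(a: _Profile, b: _Profile, aln: AlignmentRecord) -> _Profile:
    """Merge b into a along a pairwise alignment of their consensuses.

    Insertions private to one sequence inside the overlap are resolved in
    favour of the profile that already carries more reads (columns of the
    thinner profile are dropped); at equal depth the existing contig wins.
    """
    la = a.counts.shape[0]
    lb = b.counts.shape[0]
    cols: list[np.ndarray] = []

    def acol(i):
        return a.counts[i]

    def bcol(j):
        return b.counts[j]

    # region before the aligned block: whichever profile extends further left
    # contributes its head; unaligned slack columns of the other are dropped
    for i in range(aln.query_start):
        cols.append(acol(i).copy())
    lead_b = aln.subject_start
    if aln.query_start < lead_b:
        head = [bcol(j).copy() for j in range(lead_b - aln.query_start)]
        cols = head + cols
    i, j = aln.query_start, aln.subject_start
    from .io_formats import _cigar_ops  # local import to avoid cycle at module load

    for n, op in _cigar_ops(aln.cigar):
        if op in "=XM":
            for _ in range(n):
                cols.append(acol(i) + bcol(j))
                i += 1
                j += 1
        elif op == "D":  # column only in b
            for _ in range(n):
                cols.append(bcol(j).copy())
                j += 1
        elif op == "I":  # column only in a
            for _ in range(n):
                cols.append(acol(i).copy())
                i += 1
    # right tails: a's tail always kept; b's tail only when a is exhausted
    for ii in range(i, la):
        cols.append(acol(ii).copy())
    if j < lb and i >= la:
        for jj in range(j, lb):
            cols.append(bcol(jj).copy())
    out = object.__new__(_Profile)
    out.counts = np.vstack(cols) if cols else np.zeros((0, 5), dtype=np.int32)
    out.members = a.members + b.members
    return out


def overlap_assemble(
    seqs: list[SequenceRecord],
    params: OverlapAsmParams | None = None,
    align_params: AlignParams | None = None,
    contig_prefix: str = "contig",
) -> tuple[list[SequenceRecord], dict[str, list[tuple[str, str]]]]:
    """Greedy overlap-layout-consensus assembly.

    Sequences sharing sufficient suffix-prefix (or containment) overlap at
    ``min_overlap_identity`` over ``min_overlap_len`` columns are merged
    best-overlap-first; the consensus takes the per-column majority with ties
    to the alphabetically smaller base.  Returns contigs (longest first) and
    a contig -> [(member_id, strand)] map.
    """
    if not seqs:
        raise ValueError("overlap_assemble requires at least one sequence")
    params = params or OverlapAsmParams()
    align_params = align_params or AlignParams(min_hit_score=1)

    # partition into k-mer-sharing components so greedy all-pairs stays cheap
    k = 16
    kmer_owner: dict[str, int] = {}
    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for idx, rec in enumerate(seqs):
        for s in (rec.seq, revcomp(rec.seq)):
            for i in range(0, max(1, len(s) - k + 1)):
                kmer = s[i : i + k]
                if len(kmer) < k or "N" in kmer:
                    continue
                if kmer in kmer_owner:
                    union(idx, kmer_owner[kmer])
                else:
                    kmer_owner[kmer] = idx
    groups: dict[int, list[int]] = {}
    for idx in range(len(seqs)):
        groups.setdefault(find(idx), []).append(idx)

    contigs: list[_Profile] = []
    for root in sorted(groups):
        units = [_Profile(seqs[i].seq, (seqs[i].id, "+")) for i in groups[root]]
        while len(units) > 1:
            best = None  # (score, ia, ib, aln, flipped)
            for ia in range(len(units)):
                for ib in range(ia + 1, len(units)):
                    ov = _overlap_alignment(units[ia], units[ib], align_params, params)
                    if ov and (best is None or ov[0] > best[0]):
                        best = (ov[0], ia, ib, ov[1], ov[2])
            if best is None:
                break
            _, ia, ib, aln, flipped = best
            b = units[ib].rc() if flipped else units[ib]
            merged = _merge_profiles(units[ia], b, aln)
            units = [u for t, u in enumerate(units) if t not in (ia, ib)] + [merged]
        contigs.extend(units)

    order = sorted(
        range(len(contigs)),
        key=lambda i: (-contigs[i].counts.shape[0], contigs[i].members[0][0]),
    )
    out_records: list[SequenceRecord] = []
    membership: dict[str, list[tuple[str, str]]] = {}
    for rank, i in enumerate(order, 1):
        name = f"{contig_prefix}_{rank}"
        out_records.append(SequenceRecord(name, contigs[i].consensus()))
        membership[name] = list(contigs[i].members)
    return out_records, membership


# ---------------------------------------------------------------------------
# batch read mapping (seed + ungapped extension, DP fallback)
# ---------------------------------------------------------------------------

@dataclass
class MappedRead:
    """A read placement on one reference, oriented to the reference strand."""

    read_id: str
    ref_idx: int
    ref_id: str
    start: int            # reference start of the aligned block
    strand: str
    seq: str              # read in reference orientation
    query_offset: int     # first read base of the aligned block
    aligned_len: int
    cigar: str
    score: int
    identity: float
    mapq: int
    multi_refs: tuple[int, ...]  # references with near-best placements

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to ``ref_pos`` (gapless fast path via cigar)."""
        q = self.query_offset
        s = self.start
        for n, op in _cigar_iter(self.cigar):
            if op in "M=X":
                if s <= ref_pos < s + n:
                    return self.seq[q + (ref_pos - s)]
                q += n
                s += n
            elif op == "I":
                q += n
            elif op == "D":
                if s <= ref_pos < s + n:
                    return None
                s += n
        return None


def _cigar_iter(cigar: str):
    from .io_formats import _cigar_ops

    return _cigar_ops(cigar)


class BatchReadMapper:
    """Maps many short reads against a transcript reference set.

    Exact-k-mer seeding locates candidate (reference, diagonal) placements;
    each candidate is scored by gapless comparison; when the best gapless
    placement falls below ``dp_identity`` an affine-gap DP around the seed
    rescues indel-containing reads.  The mapping quality is the score-gap
    surrogate of :func:`mapq_from_scores`.
    """

    def __init__(
        self,
        refs: list[SequenceRecord],
        k: int = 15,
        match: int = 2,
        mismatch: int = -3,
        min_identity: float = 0.90,
        dp_identity: float = 0.90,
        multi_delta: int = 0,
        min_aligned: int = 30,
        seeds_per_read: int = 4,
    ) -> None:
        self.refs = refs
        self.k = k
        self.match = match
        self.mismatch = mismatch
        self.min_identity = min_identity
        self.dp_identity = dp_identity
        self.multi_delta = multi_delta
        self.min_aligned = min_aligned
        self.seeds_per_read = seeds_per_read
        self._enc = [encode_nt(r.seq) for r in refs]
        self._index: dict[int, list[tuple[int, int]]] = {}
        for ridx, arr in enumerate(self._enc):
            for pos in range(len(arr) - k + 1):
                key = self._pack(arr, pos)
                if key >= 0:
                    self._index.setdefault(key, []).append((ridx, pos))

    def _pack(self, arr: np.ndarray, pos: int) -> int:
        key = 0
        for i in range(pos, pos + self.k):
            c = arr[i]
            if c > 3:
                return -1
            key = (key << 2) | int(c)
        return key

    def _candidates(self, enc: np.ndarray) -> set[tuple[int, int]]:
        L = len(enc)
        k = self.k
        if L < k:
            return set()
        n_seeds = self.seeds_per_read
        if n_seeds == 1 or L == k:
            offsets = [0]
        else:
            offsets = sorted({int(round(i * (L - k) / (n_seeds - 1))) for i in range(n_seeds)})
        out: set[tuple[int, int]] = set()
        for off in offsets:
            key = self._pack(enc, off)
            if key < 0:
                continue
            for ridx, pos in self._index.get(key, ()):
                out.add((ridx, pos - off))
        return out

    def map(self, seq: str, read_id: str = "read") -> MappedRead | None:
        best = None  # (score, matches, ridx, rs, strand, oriented_seq, qoff, alen)
        second_score = None
        scores_by_ref: dict[int, int] = {}
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            enc = encode_nt(oriented)
            L = len(enc)
            for ridx, diag in sorted(self._candidates(enc)):
                ref = self._enc[ridx]
                rs = max(0, diag)
                re_ = min(len(ref), diag + L)
                alen = re_ - rs
                if alen < self.min_aligned:
                    continue
                qoff = rs - diag
                matches = int(np.count_nonzero(enc[qoff : qoff + alen] == ref[rs:re_]))
                score = self.match * matches + self.mismatch * (alen - matches)
                if score <= 0:
                    continue
                prev = scores_by_ref.get(ridx)
                if prev is None or score > prev:
                    scores_by_ref[ridx] = score
                key = (score, -ridx, -rs, strand)
                if best is None or key > (best[0], -best[2], -best[3], best[4]):
                    if best is not None and (
                        best[2] != ridx or abs((best[3] - best[6]) - diag) > 5
                        or best[4] != strand
                    ):
                        cand2 = best[0]
                        if second_score is None or cand2 > second_score:
                            second_score = cand2
                    best = (score, matches, ridx, rs, strand, oriented, qoff, alen)
                else:
                    if best[2] != ridx or abs((best[3] - best[6]) - diag) > 5 or best[4] != strand:
                        if second_score is None or score > second_score:
                            second_score = score
        if best is None:
            return None
        score, matches, ridx, rs, strand, oriented, qoff, alen = best
        identity = matches / alen
        cigar = self._gapless_cigar(qoff, alen, len(oriented))
        if identity < self.dp_identity:
            rescued = self._dp_rescue(oriented, ridx, rs - qoff, len(oriented))
            if rescued is None:
                return None
            score, identity, rs, qoff, alen, cigar = rescued
            if identity < self.min_identity:
                return None
        elif identity < self.min_identity:
            return None
        mapq = mapq_from_scores(score, second_score)
        multi = tuple(sorted(
            r for r, s in scores_by_ref.items() if s >= score - self.multi_delta
        ))
        return MappedRead(
            read_id=read_id, ref_idx=ridx, ref_id=self.refs[ridx].id, start=rs,
            strand=strand, seq=oriented, query_offset=qoff, aligned_len=alen,
            cigar=cigar, score=score, identity=identity, mapq=mapq,
            multi_refs=multi or (ridx,),
        )

    @staticmethod
    def _gapless_cigar(qoff: int, alen: int, read_len: int) -> str:
        parts = []
        if qoff:
            parts.append(f"{qoff}S")
        parts.append(f"{alen}M")
        tail = read_len - qoff - alen
        if tail:
            parts.append(f"{tail}S")
        return "".join(parts)

    def _dp_rescue(self, oriented: str, ridx: int, diag: int, read_len: int):
        """Full local DP of the read against a window around the seed diagonal."""
        pad = 30
        ref = self.refs[ridx].seq
        ws = max(0, diag - pad)
        we = min(len(ref), diag + read_len + pad)
        if we - ws < self.min_aligned:
            return None
        aln = local_align(oriented, ref[ws:we], AlignParams(
            match=self.match, mismatch=self.mismatch))
        if aln.score <= 0 or aln.aligned_columns < self.min_aligned:
            return None
        cigar = aln.cigar
        parts = []
        if aln.query_start:
            parts.append(f"{aln.query_start}S")
        parts.append(cigar)
        tail = read_len - aln.query_end
        if tail:
            parts.append(f"{tail}S")
        return (
            aln.score, aln.identity, ws + aln.subject_start, aln.query_start,
            aln.query_end - aln.query_start, "".join(parts),
        )

    def map_all(self, reads: list[SequenceRecord]) -> list[MappedRead]:
        out = []
        for r in reads:
            m = self.map(r.seq, r.id)
            if m is not None:
                out.append(m)
        return out
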