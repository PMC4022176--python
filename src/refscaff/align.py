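"""Seed-and-extend alignment onto a target genome.

Two tracks mirror the pipeline's needs: long queries (contigs, genome
pieces) are aligned by exact-seed chaining with affine-gap dynamic
programming filling the inter-seed segments (full-window DP on small
instances, so scores there equal unbanded DP); short reads go through a
batched mapper that verifies the best seed diagonal by direct mismatch
counting and falls back to gapped DP only when that fails.

Scoring is affine: ``match`` per identity, ``-mismatch`` per substitution
and ``-(gap_open + gap_extend * L)`` per gap of length ``L``.  ``N`` on
either side is score-neutral (neither match nor mismatch) so that drafts
with gap characters can serve as targets.  The DP kernel is
Bio.Align.PairwiseAligner in query-global / target-local mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import seqcodec
from .errors import IntegrityError, ParameterError
from .genome import Genome
from .reads import ReadBatch

# mapping-confidence tiers
UNIQUE, AMBIGUOUS, UNMAPPED = "unique", "ambiguous", "unmapped"


@dataclass
class AlignParams:
    """Scoring and seeding knobs for one alignment track."""

    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    seed_length: int = 13
    min_score: int = 30
    min_score_frac: float = 0.3      # score floor as a fraction of query length
    max_edit_fraction: Optional[float] = None
    ambiguity_margin: int = 30       # 2nd placement within this score -> ambiguous
    max_hits_per_seed: int = 16
    max_diag_shift: int = 400        # indel drift tolerated within one chain
    dp_cell_cap: int = 2_000_000     # full-window DP when m*n is below this

    def __post_init__(self):
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ParameterError("penalties must be >= 0")
        if self.seed_length < 11:
            raise ParameterError("seed_length must be >= 11")


def contig_preset() -> AlignParams:
    """Long-query preset: cheap gap extension, tolerant of long indels."""
    return AlignParams(match=1, mismatch=3, gap_open=5, gap_extend=1,
                       seed_length=15, min_score=50, min_score_frac=0.4,
                       max_edit_fraction=None, ambiguity_margin=30)


def read_preset() -> AlignParams:
    """Short-read preset: bounded edit distance, standard affine gaps."""
    return AlignParams(match=1, mismatch=3, gap_open=8, gap_extend=2,
                       seed_length=13, min_score=20, min_score_frac=0.3,
                       max_edit_fraction=0.1, ambiguity_margin=8)


def piece_preset() -> AlignParams:
    """Comparator-piece preset: near-free gaps for cross-species pieces."""
    # a piece whose best placement scores below -0.5/base (far worse than
    # the ~0/base of a 25%-divergent but genuine placement) is rejected
    return AlignParams(match=1, mismatch=3, gap_open=1, gap_extend=1,
                       seed_length=15, min_score=50, min_score_frac=-0.5,
                       max_edit_fraction=None, ambiguity_margin=50)


@dataclass
class AlignmentRecord:
    """Placement of one query on one target scaffold."""

    query_id: str
    target_id: str
    target_start: int              # 0-based
    strand: str                    # '+' | '-'
    cigar: List[Tuple[str, int]]   # ops in M/I/D/S, query-order
    score: int
    mapq_proxy: str = UNIQUE
    pair_state: str = "unpaired"
    nm: int = 0
    query_length: int = 0
    query_sequence: Optional[str] = None  # original query orientation

    @property
    def target_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def target_end(self) -> int:
        return self.target_start + self.target_consumed

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")


@dataclass
class PileupColumn:
    """Per-position base-count summary (A, C, G, T, N, deletion)."""

    target_id: str
    position: int
    base_counts: np.ndarray  # length 6

    @property
    def depth(self) -> int:
        return int(self.base_counts.sum())


# ---------------------------------------------------------------------------
# DP kernels (Bio.Align)
# ---------------------------------------------------------------------------

def _substitution_matrix(params: AlignParams):
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = params.match if a == b else -params.mismatch
    for x in "ACGTN":
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    return mat


class _Aligners:
    """Cached PairwiseAligner instances for one parameter set.

    "glocal" charges the full query but skips target ends for free;
    "global" anchors both ends (used between seed anchors); "free_left" /
    "free_right" skip target bases for free on one side only (chain edges).
    """

    def __init__(self, params: AlignParams):
        from Bio import Align

        self.params = params
        mat = _substitution_matrix(params)

        def make(free_left: bool, free_right: bool):
            al = Align.PairwiseAligner()
            al.mode = "global"
            al.substitution_matrix = mat
            al.open_gap_score = -(params.gap_open + params.gap_extend)
            al.extend_gap_score = -params.gap_extend
            if free_left:
                al.left_deletion_score = 0.0
            if free_right:
                al.right_deletion_score = 0.0
            return al

        self.glocal = make(True, True)
        self.global_ = make(False, False)
        self.free_left = make(True, False)
        self.free_right = make(False, True)


_ALIGNER_CACHE: Dict[tuple, _Aligners] = {}


def _aligners(params: AlignParams) -> _Aligners:
    key = (params.match, params.mismatch, params.gap_open, params.gap_extend)
    if key not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[key] = _Aligners(params)
    return _ALIGNER_CACHE[key]


def _cigar_from_alignment(aln, qlen: int) -> Tuple[int, int, List[Tuple[str, int]], int]:
    """(target_start, target_end, cigar, aligned_pairs_nm_base) from a Bio alignment.

    The cigar covers the query (leading/trailing unaligned query as S);
    target positions outside [target_start, target_end) are not consumed.
    """
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0, 0, [("S", qlen)] if qlen else [], 0
    cigar: List[Tuple[str, int]] = []
    t_start = int(t_blocks[0][0])
    if int(q_blocks[0][0]) > 0:
        cigar.append(("S", int(q_blocks[0][0])))
    prev_t, prev_q = t_start, int(q_blocks[0][0])
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ts, te, qs, qe = int(ts), int(te), int(qs), int(qe)
        if qs > prev_q:
            cigar.append(("I", qs - prev_q))
        if ts > prev_t:
            cigar.append(("D", ts - prev_t))
        cigar.append(("M", qe - qs))
        prev_t, prev_q = te, qe
    if qlen > prev_q:
        cigar.append(("S", qlen - prev_q))
    return t_start, prev_t, _merge_cigar(cigar), 0


def _merge_cigar(cigar: List[Tuple[str, int]]) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    for op, n in cigar:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _count_mismatches(qcodes: np.ndarray, tcodes: np.ndarray,
                      cigar: Sequence[Tuple[str, int]], t_start: int) -> int:
    """Edit count (mismatches in M runs + inserted + deleted bases); N neutral."""
    nm = 0
    q = t = 0
    t += t_start
    for op, n in cigar:
        if op == "M":
            qs, ts = qcodes[q:q + n], tcodes[t:t + n]
            both = (qs != seqcodec.N) & (ts != seqcodec.N)
            nm += int(np.sum(both & (qs != ts)))
            q += n
            t += n
        elif op == "I":
            nm += n
            q += n
        elif op == "D":
            nm += n
            t += n
        elif op == "S":
            q += n
    return nm


def glocal_align(qcodes: np.ndarray, tcodes: np.ndarray, params: AlignParams
                 ) -> Tuple[int, int, List[Tuple[str, int]]]:
    """Exact query-global/target-local affine DP.

    Returns ``(score, target_start, cigar)``; this is the unbanded optimum
    over placements of the full query inside the target.
    """
    aligner = _aligners(params).glocal
    aln = aligner.align(seqcodec.decode(tcodes), seqcodec.decode(qcodes))[0]
    t_start, _t_end, cigar, _ = _cigar_from_alignment(aln, qcodes.size)
    return int(round(aln.score)), t_start, cigar


def _ungapped_stats(qseg: np.ndarray, tseg: np.ndarray, params: AlignParams
                    ) -> Tuple[int, int]:
    """(score, mismatches) of an equal-length ungapped comparison; N neutral."""
    both = (qseg != seqcodec.N) & (tseg != seqcodec.N)
    mism = int(np.sum(both & (qseg != tseg)))
    matches = int(np.sum(both)) - mism
    return params.match * matches - params.mismatch * mism, mism


# ---------------------------------------------------------------------------
# target index
# ---------------------------------------------------------------------------

class SeqIndex:
    """Sorted-array exact k-mer index over a genome (forward strand).

    Windows containing N are not indexed.  Positions are kept in a single
    global coordinate frame with sentinel-separated scaffolds.
    """

    def __init__(self, genome: Genome, k: int = 13):
        if not (11 <= k <= 31):
            raise ParameterError("index k must be in [11, 31]")
        self.genome = genome
        self.k = k
        self.names = genome.names
        parts, offsets = [], []
        cursor = 0
        for name in self.names:
            codes = genome.codes(name)
            offsets.append(cursor)
            parts.append(codes)
            parts.append(np.array([5], dtype=np.uint8))  # sentinel
            cursor += codes.size + 1
        self.offsets = np.array(offsets, dtype=np.int64)
        self.scaffold_lengths = np.array(
            [genome.lengths[name] for name in self.names], dtype=np.int64)
        self.concat = np.concatenate(parts) if parts else np.zeros(0, np.uint8)

        from .assemble import _window_limbs

        _hi, lo, valid = _window_limbs(self.concat, k)
        pos = np.flatnonzero(valid)
        codes = lo[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order].astype(np.int64)

    def lookup_ranges(self, codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi

    def scaffold_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def to_local(self, gpos):
        si = self.scaffold_of(np.asarray(gpos))
        return si, np.asarray(gpos) - self.offsets[si]

    def scaffold_codes(self, scaffold_index: int) -> np.ndarray:
        return self.genome.codes(self.names[scaffold_index])


def _query_seed_codes(qcodes: np.ndarray, k: int, step: int = 1):
    """(offsets, codes) of valid k-mer seeds of a single query."""
    from .assemble import _window_limbs

    _hi, lo, valid = _window_limbs(qcodes, k)
    offs = np.arange(lo.size)[valid]
    if step > 1:
        offs = offs[::step]
    return offs, lo[offs] if offs.size else lo[:0]


# ---------------------------------------------------------------------------
# long-query alignment (contigs, genome pieces)
# ---------------------------------------------------------------------------

def _collect_hits(index: SeqIndex, offs, codes, cap: int):
    """Expand index ranges into (query_offset, global_pos) hit arrays."""
    lo, hi = index.lookup_ranges(codes)
    counts = np.minimum(hi - lo, cap)
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    qoffs = np.repeat(offs, counts)
    tpos = np.empty(total, dtype=np.int64)
    cursor = 0
    for i in range(offs.size):
        c = counts[i]
        if c:
            tpos[cursor:cursor + c] = index.sorted_pos[lo[i]:lo[i] + c]
            cursor += c
    return qoffs, tpos


def _diag_clusters(qoffs, tpos, bin_width: int, n_clusters: int = 3):
    """Top diagonal bins by hit count -> list of hit-index arrays."""
    diag = tpos - qoffs
    bins = diag // bin_width
    uniq, inv, counts = np.unique(bins, return_inverse=True, return_counts=True)
    merged = {}
    for bi, b in enumerate(uniq):
        # join adjacent bins so chains straddling a bin edge stay together
        key = None
        for cand in (b - 1, b, b + 1):
            if cand in merged:
                key = cand
                break
        merged.setdefault(key if key is not None else b, []).append(bi)
    scored = []
    for key, members in merged.items():
        mask = np.isin(inv, members)
        scored.append((int(mask.sum()), key, np.flatnonzero(mask)))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return [idx for _cnt, _key, idx in scored[:n_clusters]]


def _chain_blocks(qoffs, tpos, k: int, max_shift: int):
    """Greedy colinear chain of seed hits merged into exact anchor blocks."""
    if qoffs.size == 0:
        return []
    diag = tpos - qoffs
    center = np.int64(np.median(diag))
    keep = np.abs(diag - center) <= max_shift
    qoffs, tpos = qoffs[keep], tpos[keep]
    order = np.lexsort((tpos, qoffs))
    qoffs, tpos = qoffs[order], tpos[order]
    blocks = []  # [qs, qe, ts]
    last_q_end = last_t_end = -1
    for q, t in zip(qoffs, tpos):
        q, t = int(q), int(t)
        if blocks and t - q == blocks[-1][2] - blocks[-1][0] and q <= last_q_end:
            ext = q + k - last_q_end
            if ext > 0:
                blocks[-1][1] += ext
                last_q_end += ext
                last_t_end += ext
            continue
        if q >= last_q_end and t >= last_t_end:
            blocks.append([q, q + k, t])
            last_q_end, last_t_end = q + k, t + k
    return [(qs, qe, ts) for qs, qe, ts in blocks]


def _align_chained(qcodes: np.ndarray, tcodes: np.ndarray, blocks,
                   params: AlignParams) -> Optional[Tuple[int, int, List[Tuple[str, int]]]]:
    """Stitch an alignment through exact anchor blocks.

    Returns ``(score, target_start, cigar)`` or None when a segment is too
    irregular to stitch (caller then falls back or rejects).
    """
    al = _aligners(params)
    m = qcodes.size
    score = 0
    cigar: List[Tuple[str, int]] = []

    qs0, _qe0, ts0 = blocks[0]
    if qs0 > 0:
        pad = qs0 + params.gap_open + 50
        wstart = max(0, ts0 - pad)
        window = tcodes[wstart:ts0]
        if window.size == 0 or qs0 * window.size > params.dp_cell_cap:
            # nothing to align against, or an implausibly long overhang
            # (single-anchor noise chain): clip instead of paying for DP
            cigar.append(("S", qs0))
            t_start = ts0
        else:
            aln = al.free_left.align(seqcodec.decode(window),
                                     seqcodec.decode(qcodes[:qs0]))[0]
            sub_start, _sub_end, sub_cigar, _ = _cigar_from_alignment(aln, qs0)
            score += int(round(aln.score))
            cigar.extend(sub_cigar)
            t_start = wstart + sub_start
            # deletions up to the first anchor are in the DP score already,
            # but _cigar_from_alignment drops them from the cigar
            consumed = sum(n for op, n in sub_cigar if op in "MD")
            gap = window.size - (sub_start + consumed)
            if gap > 0:
                cigar.append(("D", gap))
    else:
        t_start = ts0

    prev_qe, prev_te = qs0, ts0
    for qs, qe, ts in blocks:
        qgap = qs - prev_qe
        tgap = ts - prev_te
        if qgap < 0 or tgap < 0:
            return None
        if qgap or tgap:
            if qgap == tgap:
                s, _mism = _ungapped_stats(qcodes[prev_qe:qs],
                                           tcodes[prev_te:ts], params)
                score += s
                cigar.append(("M", qgap))
            elif qgap == 0:
                score -= params.gap_open + params.gap_extend * tgap
                cigar.append(("D", tgap))
            elif tgap == 0:
                score -= params.gap_open + params.gap_extend * qgap
                cigar.append(("I", qgap))
            elif qgap * tgap > params.dp_cell_cap:
                # oversized inter-anchor segment: stitch approximately as a
                # diagonal run plus one trailing gap (scores stay a lower
                # bound; exactness is only claimed for small instances)
                run = min(qgap, tgap)
                s, _mism = _ungapped_stats(qcodes[prev_qe:prev_qe + run],
                                           tcodes[prev_te:prev_te + run],
                                           params)
                score += s
                cigar.append(("M", run))
                extra = abs(qgap - tgap)
                score -= params.gap_open + params.gap_extend * extra
                cigar.append(("D" if tgap > qgap else "I", extra))
            else:
                aln = al.global_.align(seqcodec.decode(tcodes[prev_te:ts]),
                                       seqcodec.decode(qcodes[prev_qe:qs]))[0]
                sub_start, sub_end, sub_cigar, _ = _cigar_from_alignment(aln, qgap)
                sub_cigar = [("I" if op == "S" else op, n) for op, n in sub_cigar]
                score += int(round(aln.score))
                # end gaps are charged in the DP score but dropped from the
                # extracted cigar; restore them as deletions
                if sub_start > 0:
                    cigar.append(("D", sub_start))
                cigar.extend(sub_cigar)
                if tgap - sub_end > 0:
                    cigar.append(("D", tgap - sub_end))
        blen = qe - qs
        score += params.match * blen
        cigar.append(("M", blen))
        prev_qe, prev_te = qe, ts + blen

    if prev_qe < m:
        tail = m - prev_qe
        pad = tail + params.gap_open + 50
        window = tcodes[prev_te:prev_te + pad]
        if window.size == 0 or tail * window.size > params.dp_cell_cap:
            cigar.append(("S", tail))
        else:
            aln = al.free_right.align(seqcodec.decode(window),
                                      seqcodec.decode(qcodes[prev_qe:]))[0]
            sub_start, _sub_end, sub_cigar, _ = _cigar_from_alignment(aln, tail)
            if sub_start > 0:
                cigar.append(("D", sub_start))  # charged by the DP already
            score += int(round(aln.score))
            cigar.extend(sub_cigar)
    return score, t_start, _merge_cigar(cigar)


def align_long(query, target, params: Optional[AlignParams] = None,
               query_id: Optional[str] = None,
               min_query_length: int = 0) -> List[AlignmentRecord]:
    """Align a long query (contig / piece) to a genome, both strands.

    ``query`` may be a Contig, a string or a code array; ``target`` a
    :class:`Genome` or a prebuilt :class:`SeqIndex`.  Returns candidate
    placements sorted by score (best first); a second placement within the
    ambiguity margin marks the best record ``"ambiguous"``.  No placement
    above the score floor -> empty list.
    """
    params = params or contig_preset()
    if hasattr(query, "sequence") and hasattr(query, "id"):
        query_id = query_id or query.id
        qcodes = seqcodec.encode(query.sequence)
    elif isinstance(query, str):
        qcodes = seqcodec.encode(query)
    else:
        qcodes = np.asarray(query, dtype=np.uint8)
    query_id = query_id or "query"
    if qcodes.size < min_query_length:
        return []
    index = target if isinstance(target, SeqIndex) else SeqIndex(target, params.seed_length)
    if index.k != params.seed_length:
        # index wins; seeding length is a property of the index
        pass

    m = qcodes.size
    step = max(1, (m - index.k) // 400) if m > index.k else 1
    # a negative fraction sets an absolute sub-zero floor (divergent pieces)
    if params.min_score_frac < 0:
        min_score = int(params.min_score_frac * m)
    else:
        min_score = max(params.min_score, int(params.min_score_frac * m))
    candidates: List[AlignmentRecord] = []

    for strand in "+-":
        q = qcodes if strand == "+" else seqcodec.revcomp(qcodes)
        offs, codes = _query_seed_codes(q, index.k, step)
        if offs.size == 0:
            continue
        qoffs, tpos = _collect_hits(index, offs, codes, params.max_hits_per_seed)
        if qoffs.size == 0:
            continue
        bin_width = max(64, params.max_diag_shift)
        for hit_idx in _diag_clusters(qoffs, tpos, bin_width):
            if hit_idx.size < 2 and m > 10 * index.k:
                continue  # a lone chance hit on a long query is noise
            hq, ht = qoffs[hit_idx], tpos[hit_idx]
            si = index.scaffold_of(ht)
            # restrict the cluster to its dominant scaffold
            si_mode = np.bincount(si).argmax()
            inside = si == si_mode
            hq, ht = hq[inside], ht[inside]
            if hq.size == 0:
                continue
            scaffold = int(si_mode)
            local_t = ht - index.offsets[scaffold]
            tcodes = index.scaffold_codes(scaffold)
            est_start = int(np.median(local_t - hq))
            pad = max(50, int(0.15 * m)) + params.max_diag_shift
            wstart = max(0, est_start - pad)
            wend = min(tcodes.size, est_start + m + pad)
            result = None
            if m * (wend - wstart) <= params.dp_cell_cap:
                s, t0, cig = glocal_align(q, tcodes[wstart:wend], params)
                result = (s, wstart + t0, cig)
            else:
                blocks = _chain_blocks(hq, local_t, index.k, params.max_diag_shift)
                if blocks:
                    result = _align_chained(q, tcodes, blocks, params)
                if result is None and step > 1:
                    # highly divergent query: sparse seeding left the chain
                    # too thin; retry with every seed, restricted to this
                    # cluster's diagonal neighbourhood
                    offs_d, codes_d = _query_seed_codes(q, index.k, 1)
                    dq, dt = _collect_hits(index, offs_d, codes_d,
                                           params.max_hits_per_seed)
                    if dq.size:
                        si_d = index.scaffold_of(dt)
                        lt = dt - index.offsets[scaffold]
                        keep = ((si_d == scaffold)
                                & (np.abs((lt - dq) - est_start)
                                   <= 2 * params.max_diag_shift))
                        blocks = _chain_blocks(dq[keep], lt[keep], index.k,
                                               params.max_diag_shift)
                        if blocks:
                            result = _align_chained(q, tcodes, blocks, params)
            if result is None:
                continue
            score, t_start, cigar = result
            if score < min_score:
                continue
            nm = _count_mismatches(q, tcodes, cigar, t_start)
            if (params.max_edit_fraction is not None
                    and nm > params.max_edit_fraction * m):
                continue
            candidates.append(AlignmentRecord(
                query_id=query_id, target_id=index.names[scaffold],
                target_start=t_start, strand=strand, cigar=cigar,
                score=score, nm=nm, query_length=m))

    candidates.sort(key=lambda r: (-r.score, r.target_id, r.target_start))
    # drop duplicate placements (same locus found through several clusters)
    deduped: List[AlignmentRecord] = []
    for rec in candidates:
        dup = any(r.target_id == rec.target_id and r.strand == rec.strand
                  and min(r.target_end, rec.target_end)
                  - max(r.target_start, rec.target_start) > 0
                  for r in deduped)
        if not dup:
            deduped.append(rec)
    if len(deduped) >= 2 and deduped[1].score >= deduped[0].score - params.ambiguity_margin:
        for rec in deduped:
            rec.mapq_proxy = AMBIGUOUS
    return deduped


# ---------------------------------------------------------------------------
# batched short-read mapping
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignments:
    """Struct-of-arrays result of mapping one ReadBatch.

    ``scaffold`` is -1 for unmapped reads; ``pos`` is the 0-based leftmost
    target position; ``strand`` +1/-1; ``tier`` 0 unique / 1 ambiguous /
    2 unmapped.  Reads needing gapped alignment carry a cigar in
    ``cigars`` (query-order, computed on the aligned orientation).
    """

    index: SeqIndex
    batch: ReadBatch
    scaffold: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    score: np.ndarray
    nm: np.ndarray
    tier: np.ndarray
    cigars: Dict[int, List[Tuple[str, int]]] = field(default_factory=dict)
    pair_state: Optional[np.ndarray] = None

    @property
    def n_mapped(self) -> int:
        return int(np.sum(self.scaffold >= 0))

    def aligned_codes(self, i: int) -> np.ndarray:
        L = int(self.batch.lengths[i])
        codes = self.batch.codes[i, :L]
        return codes if self.strand[i] > 0 else seqcodec.revcomp(codes)

    def to_records(self) -> List[AlignmentRecord]:
        out = []
        pair_names = {0: "unpaired", 1: "proper", 2: "discordant"}
        for i in range(self.batch.n):
            if self.scaffold[i] < 0:
                continue
            L = int(self.batch.lengths[i])
            cigar = self.cigars.get(i, [("M", L)])
            out.append(AlignmentRecord(
                query_id=self.batch.read_name(i),
                target_id=self.index.names[int(self.scaffold[i])],
                target_start=int(self.pos[i]),
                strand="+" if self.strand[i] > 0 else "-",
                cigar=cigar, score=int(self.score[i]),
                mapq_proxy=AMBIGUOUS if self.tier[i] == 1 else UNIQUE,
                pair_state=pair_names[int(self.pair_state[i])] if self.pair_state is not None else "unpaired",
                nm=int(self.nm[i]), query_length=L,
                query_sequence=seqcodec.decode(self.batch.codes[i, :L])))
        return out


def _revcomp_batch(codes: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse-complement every row in place-respecting its length."""
    out = np.full_like(codes, seqcodec.N)
    for L in np.unique(lengths):
        rows = lengths == L
        out[rows, :L] = seqcodec._COMPLEMENT[codes[rows, :L][:, ::-1]]
    return out


def _seed_codes_matrix(codes: np.ndarray, lengths: np.ndarray, k: int,
                       offsets_frac=(0.0, 0.45, 1.0)):
    """Seed codes at relative offsets within each read.

    Returns (n, s) arrays of query offsets, codes and validity.
    """
    n = codes.shape[0]
    offs = np.stack([np.clip(((lengths - k) * f).astype(np.int64), 0, None)
                     for f in offsets_frac], axis=1)
    s = offs.shape[1]
    code = np.zeros((n, s), dtype=np.uint64)
    invalid = np.zeros((n, s), dtype=bool)
    rows = np.arange(n)[:, None]
    for j in range(k):
        col = offs + j
        base = codes[rows, col]
        invalid |= base >= 4
        code = (code << np.uint64(2)) | (base & 3).astype(np.uint64)
    invalid |= lengths[:, None] < k
    return offs, code, invalid


def map_reads(batch: ReadBatch, index: SeqIndex,
              params: Optional[AlignParams] = None,
              chunk_size: int = 200_000) -> ReadAlignments:
    """Map a read batch to the indexed genome.

    Seeds at three positions per read and strand vote for a diagonal; the
    winning ungapped placement is verified by direct mismatch counting and
    kept when the edit fraction allows.  Reads failing that but having
    seeds are re-aligned with gapped DP in a small window.  A second
    placement scoring within the ambiguity margin marks the read ambiguous.
    """
    params = params or read_preset()
    k = index.k
    n = batch.n
    r_scaffold = np.full(n, -1, dtype=np.int64)
    r_pos = np.zeros(n, dtype=np.int64)
    r_strand = np.zeros(n, dtype=np.int8)
    r_score = np.full(n, -(2 ** 30), dtype=np.int64)
    r_score2 = np.full(n, -(2 ** 30), dtype=np.int64)
    r_nm = np.zeros(n, dtype=np.int32)
    r_tier = np.full(n, 2, dtype=np.int8)
    cigars: Dict[int, list] = {}
    # read index -> candidate (sgn, diag) placements to retry with gaps;
    # an empty list means no usable diagonal was found at all
    fallback: Dict[int, list] = {}

    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        rows = np.arange(start, stop)
        sub_codes = batch.codes[start:stop]
        sub_len = batch.lengths[start:stop].astype(np.int64)
        rc_codes = _revcomp_batch(sub_codes, sub_len)
        m = rows.size

        cand: Dict[int, list] = {}
        for sgn, mat in ((1, sub_codes), (-1, rc_codes)):
            offs, codes, invalid = _seed_codes_matrix(mat, sub_len, k)
            flat_codes = codes.ravel()
            lo, hi = index.lookup_ranges(flat_codes)
            cnt = np.minimum(hi - lo, params.max_hits_per_seed)
            cnt[invalid.ravel()] = 0
            total = int(cnt.sum())
            if total == 0:
                continue
            seed_row = np.repeat(np.arange(flat_codes.size) // offs.shape[1], cnt)
            seed_off = np.repeat(offs.ravel(), cnt)
            tpos = np.empty(total, dtype=np.int64)
            cursor = 0
            nz = np.flatnonzero(cnt)
            for i in nz:
                c = cnt[i]
                tpos[cursor:cursor + c] = index.sorted_pos[lo[i]:lo[i] + c]
                cursor += c
            diag = tpos - seed_off
            order = np.lexsort((diag, seed_row))
            seed_row, diag = seed_row[order], diag[order]
            # vote per read: run-lengths of equal (row, diag)
            boundary = np.empty(seed_row.size, dtype=bool)
            boundary[0] = True
            boundary[1:] = (seed_row[1:] != seed_row[:-1]) | (diag[1:] != diag[:-1])
            starts = np.flatnonzero(boundary)
            votes = np.diff(np.append(starts, seed_row.size))
            for s_i, v in zip(starts, votes):
                cand.setdefault(int(seed_row[s_i]), []).append(
                    (int(v), sgn, int(diag[s_i])))

        # verify top candidates per read
        for local_row, options in cand.items():
            options.sort(key=lambda o: (-o[0], o[2], o[1]))
            L = int(sub_len[local_row])
            max_edit = (int(params.max_edit_fraction * L)
                        if params.max_edit_fraction is not None else L)
            placements = []
            seen = set()
            for _votes, sgn, diag in options[:4]:
                if any(abs(diag - d) <= 5 and sgn == s for s, d in seen):
                    continue
                seen.add((sgn, diag))
                if diag < 0 or diag + L > index.concat.size:
                    continue
                tseg = index.concat[diag:diag + L]
                if np.any(tseg == 5):  # crosses a scaffold boundary
                    continue
                qseg = (sub_codes[local_row, :L] if sgn > 0
                        else rc_codes[local_row, :L])
                score, mism = _ungapped_stats(qseg, tseg, params)
                placements.append((score, mism, sgn, diag))
            if not placements:
                fallback[start + local_row] = []
                continue
            placements.sort(key=lambda p: -p[0])
            score, mism, sgn, diag = placements[0]
            gi = start + local_row
            if mism > max_edit:
                fallback[gi] = [(p[2], p[3]) for p in placements[:2]]
                continue
            # mismatches piled up at a read end are the signature of an
            # unmodelled indel: re-align those reads with gaps instead of
            # letting shifted tails masquerade as substitutions
            if mism >= 3:
                qseg = (sub_codes[local_row, :L] if sgn > 0
                        else rc_codes[local_row, :L])
                tseg = index.concat[diag:diag + L]
                diffs = np.flatnonzero((qseg != tseg)
                                       & (qseg != seqcodec.N)
                                       & (tseg != seqcodec.N))
                edge = 8
                if (np.sum(diffs < edge) >= 3) or (np.sum(diffs >= L - edge) >= 3):
                    fallback[gi] = [(p[2], p[3]) for p in placements[:2]]
                    continue
            si, local = index.to_local(diag)
            r_scaffold[gi] = si
            r_pos[gi] = local
            r_strand[gi] = sgn
            r_score[gi] = score
            r_nm[gi] = mism
            r_tier[gi] = 0
            if len(placements) > 1:
                r_score2[gi] = placements[1][0]
                if placements[1][0] >= score - params.ambiguity_margin:
                    r_tier[gi] = 1

    # gapped fallback: small-window glocal DP at the candidate diagonal
    # (full align_long only when no diagonal was found at all)
    pad = 16
    for gi, cand_diags in fallback.items():
        L = int(batch.lengths[gi])
        max_edit = (int(params.max_edit_fraction * L)
                    if params.max_edit_fraction is not None else L)
        min_score = max(params.min_score, int(params.min_score_frac * L))
        best = None
        if cand_diags:
            for sgn, diag in cand_diags:
                si = int(index.scaffold_of(np.array([diag]))[0])
                local = diag - int(index.offsets[si])
                tcodes = index.scaffold_codes(si)
                wstart = max(0, local - pad)
                wend = min(tcodes.size, local + L + pad)
                if wend - wstart < L:
                    continue
                q = (batch.codes[gi, :L] if sgn > 0
                     else seqcodec.revcomp(batch.codes[gi, :L]))
                score, t0, cigar = glocal_align(q, tcodes[wstart:wend], params)
                nm = _count_mismatches(q, tcodes, cigar, wstart + t0)
                if best is None or score > best[0]:
                    best = (score, nm, sgn, si, wstart + t0, cigar)
            if best is not None:
                score, nm, sgn, si, t_start, cigar = best
                if nm <= max_edit and score >= min_score:
                    r_scaffold[gi] = si
                    r_pos[gi] = t_start
                    r_strand[gi] = sgn
                    r_score[gi] = score
                    r_nm[gi] = nm
                    r_tier[gi] = 0
                    cigars[gi] = cigar
            continue
        q = batch.codes[gi, :L]
        recs = align_long(q, index, params=params, query_id="r")
        if not recs:
            continue
        rec = recs[0]
        if rec.nm > max_edit or rec.score < min_score:
            continue
        r_scaffold[gi] = index.names.index(rec.target_id)
        r_pos[gi] = rec.target_start
        r_strand[gi] = 1 if rec.strand == "+" else -1
        r_score[gi] = rec.score
        r_nm[gi] = rec.nm
        r_tier[gi] = 1 if rec.mapq_proxy == AMBIGUOUS else 0
        cigars[gi] = rec.cigar

    return ReadAlignments(index=index, batch=batch, scaffold=r_scaffold,
                          pos=r_pos, strand=r_strand, score=r_score,
                          nm=r_nm, tier=r_tier, cigars=cigars)


# ---------------------------------------------------------------------------
# pair resolution
# ---------------------------------------------------------------------------

@dataclass
class InsertEstimate:
    mean: float
    sd: float
    n_used: int
    from_spec: bool = False  # True when too few pairs forced the library values


def align_pairs(pair_batches: Tuple[ReadBatch, ReadBatch], index: SeqIndex,
                params: Optional[AlignParams] = None,
                k_sd: float = 4.0, min_pairs_for_estimate: int = 100
                ) -> Tuple[ReadAlignments, ReadAlignments, InsertEstimate]:
    """Map both mates and classify pairs as proper / discordant.

    The insert-size distribution is estimated from uniquely-both-mapped,
    correctly oriented pairs; a pair is proper iff the mates land on one
    scaffold, in the library's FR orientation, with an outer separation
    within ``mean +/- k_sd * sd``.  Falls back to the LibrarySpec insert
    values when fewer than ``min_pairs_for_estimate`` pairs are usable.
    """
    import warnings

    mate1, mate2 = pair_batches
    if mate1.n != mate2.n:
        raise IntegrityError("mate batches are not synchronized")
    library = mate1.library
    aln1 = map_reads(mate1, index, params)
    aln2 = map_reads(mate2, index, params)

    both = (aln1.tier == 0) & (aln2.tier == 0)
    same = both & (aln1.scaffold == aln2.scaffold) & (aln1.scaffold >= 0)
    opposite = same & (aln1.strand != aln2.strand)
    L1 = mate1.lengths.astype(np.int64)
    L2 = mate2.lengths.astype(np.int64)
    fwd_pos = np.where(aln1.strand > 0, aln1.pos, aln2.pos)
    rev_pos = np.where(aln1.strand > 0, aln2.pos, aln1.pos)
    rev_len = np.where(aln1.strand > 0, L2, L1)
    oriented = opposite & (fwd_pos <= rev_pos)      # FR: forward mate upstream
    sep = rev_pos + rev_len - fwd_pos               # outer fragment length

    usable = oriented.copy()
    if library is not None and library.insert_mean:
        usable &= sep <= 10 * library.insert_mean
    vals = sep[usable].astype(np.float64)
    if vals.size >= min_pairs_for_estimate:
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        inlier = vals[np.abs(vals - med) <= 5 * max(mad, 1.0)]
        est = InsertEstimate(float(inlier.mean()), float(max(inlier.std(), 1.0)),
                             int(inlier.size))
    else:
        if library is None or not library.insert_mean:
            raise ParameterError("too few pairs and no library insert to fall back on")
        warnings.warn("too few uniquely mapped pairs; using library insert values")
        est = InsertEstimate(float(library.insert_mean), float(library.insert_sd),
                             int(vals.size), from_spec=True)

    proper = oriented & (np.abs(sep - est.mean) <= k_sd * est.sd)
    state = np.zeros(mate1.n, dtype=np.int8)
    mapped_both = (aln1.scaffold >= 0) & (aln2.scaffold >= 0)
    state[mapped_both] = 2
    state[proper] = 1
    aln1.pair_state = state
    aln2.pair_state = state
    return aln1, aln2, est


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

DEL_CODE = 5  # row index of the deletion count in a pileup matrix
INS_CODE = 6  # insertion evidence (recorded at the position it precedes)


def new_pileup(genome: Genome) -> Dict[str, np.ndarray]:
    """Empty per-scaffold (7, L) count matrices: A,C,G,T,N,del,ins.

    The first six rows are the pileup proper (depth = their sum); the
    seventh counts insertion events so gap-adjacent artifact columns can
    be recognised downstream.
    """
    return {name: np.zeros((7, genome.lengths[name]), dtype=np.uint32)
            for name in genome.names}


def add_read_alignments(counts: Dict[str, np.ndarray], aln: ReadAlignments,
                        rows_mask: Optional[np.ndarray] = None,
                        unique_only: bool = True) -> int:
    """Accumulate mapped reads into pileup matrices; returns bases added."""
    batch, index = aln.batch, aln.index
    sel = aln.scaffold >= 0
    if unique_only:
        sel &= aln.tier == 0
    if rows_mask is not None:
        sel &= rows_mask
    gapped = np.zeros(batch.n, dtype=bool)
    if aln.cigars:
        gapped[list(aln.cigars.keys())] = True
    total = 0

    plain = np.flatnonzero(sel & ~gapped)
    lengths = batch.lengths
    for si, name in enumerate(index.names):
        L_t = counts[name].shape[1]
        rows = plain[aln.scaffold[plain] == si]
        if rows.size == 0:
            continue
        for L in np.unique(lengths[rows]):
            sub = rows[lengths[rows] == L]
            qmat = batch.codes[sub, :L].copy()
            minus = aln.strand[sub] < 0
            if minus.any():
                qmat[minus] = seqcodec._COMPLEMENT[qmat[minus][:, ::-1]]
            positions = aln.pos[sub][:, None] + np.arange(L)[None, :]
            if positions.max() >= L_t or positions.min() < 0:
                raise IntegrityError("read alignment overruns its target")
            flat = positions.ravel() * np.int64(7) + qmat.ravel()
            counts[name] += np.bincount(flat, minlength=7 * L_t
                                        ).reshape(L_t, 7).T.astype(np.uint32)
            total += int(sub.size * L)

    for gi in np.flatnonzero(sel & gapped):
        name = index.names[int(aln.scaffold[gi])]
        total += _add_cigar_observation(
            counts[name], aln.aligned_codes(gi), int(aln.pos[gi]),
            aln.cigars[gi])
    return total


def _add_cigar_observation(mat: np.ndarray, qcodes: np.ndarray, t_start: int,
                           cigar: Sequence[Tuple[str, int]]) -> int:
    """Add one gapped query observation to a (6, L) pileup matrix."""
    L_t = mat.shape[1]
    q = 0
    t = t_start
    added = 0
    for op, n in cigar:
        if op == "M":
            if t < 0 or t + n > L_t:
                raise IntegrityError("alignment overruns its target")
            np.add.at(mat, (qcodes[q:q + n], np.arange(t, t + n)), 1)
            q += n
            t += n
            added += n
        elif op == "I":
            if 0 <= t < L_t:
                mat[INS_CODE, t] += 1
            q += n
        elif op == "D":
            if t + n > L_t:
                raise IntegrityError("alignment overruns its target")
            mat[DEL_CODE, t:t + n] += 1
            t += n
        elif op == "S":
            q += n
    return added


def add_records(counts: Dict[str, np.ndarray], records, queries=None) -> int:
    """Accumulate long-query AlignmentRecords into pileup matrices.

    ``queries`` maps query_id -> sequence/codes (forward orientation);
    records carrying their own ``query_sequence`` need no entry.
    """
    total = 0
    for rec in records:
        q = (queries or {}).get(rec.query_id, rec.query_sequence)
        if q is None:
            raise IntegrityError(f"no sequence available for query {rec.query_id!r}")
        qcodes = seqcodec.encode(q) if isinstance(q, str) else (
            seqcodec.encode(q.sequence) if hasattr(q, "sequence") else np.asarray(q))
        if rec.strand == "-":
            qcodes = seqcodec.revcomp(qcodes)
        total += _add_cigar_observation(counts[rec.target_id], qcodes,
                                        rec.target_start, rec.cigar)
    return total


def pileup_from_alignments(records, target: Genome, queries=None,
                           skip_empty: bool = True):
    """Stream :class:`PileupColumn` objects from alignment records.

    Every aligned base contributes once, deletions add to the deletion
    count, clipped bases contribute nothing.  ``queries`` supplies
    sequences for records that do not carry their own.
    """
    counts = new_pileup(target)
    add_records(counts, records, queries)
    for name in target.names:
        yield from iter_pileup_columns(counts, name, skip_empty=skip_empty)


def iter_pileup_columns(counts: Dict[str, np.ndarray], target_id: str,
                        skip_empty: bool = True):
    """Yield :class:`PileupColumn` objects for one scaffold."""
    mat = counts[target_id][:6]
    positions = np.flatnonzero(mat.sum(axis=0)) if skip_empty else np.arange(mat.shape[1])
    for p in positions:
        yield PileupColumn(target_id, int(p), mat[:, p].copy())


def coverage_filter(counts: Dict[str, np.ndarray], low_factor: float = 0.5,
                    high_factor: float = 2.0
                    ) -> Tuple[Dict[str, np.ndarray], float]:
    """Mask over-low/high covered sites relative to the mean depth.

    The mean is taken over covered (depth > 0) sites across all scaffolds;
    the returned per-scaffold boolean masks are True where a site is kept
    (``low_factor * mean <= depth <= high_factor * mean``).  All-zero input
    yields all-False masks and a warning.
    """
    import warnings

    depths = {name: mat[:6].sum(axis=0) for name, mat in counts.items()}
    covered = np.concatenate([d[d > 0] for d in depths.values()]) if depths else np.array([])
    if covered.size == 0:
        warnings.warn("no covered sites; coverage filter is empty")
        return {name: np.zeros_like(d, dtype=bool) for name, d in depths.items()}, float("nan")
    mean_depth = float(covered.mean())
    masks = {
        name: (d >= low_factor * mean_depth) & (d <= high_factor * mean_depth) & (d > 0)
        for name, d in depths.items()
    }
    return masks, mean_depth


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

_CIGAR_SAM = {"M": 0, "I": 1, "D": 2, "S": 4}
_CIGAR_FROM_SAM = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M", 3: "D"}


def write_sam(path, genome: Genome, records: Sequence[AlignmentRecord]) -> None:
    """Write alignment records as SAM (tier in the XT tag, NM filled)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": genome.lengths[name]} for name in genome.names],
    }
    name_to_tid = {name: i for i, name in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.query_id
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if rec.pair_state == "proper":
                flag |= 1 | 2
            seg.flag = flag
            seg.reference_id = name_to_tid[rec.target_id]
            seg.reference_start = rec.target_start
            seg.mapping_quality = 60 if rec.mapq_proxy == UNIQUE else 0
            seg.cigartuples = [(_CIGAR_SAM[op], n) for op, n in rec.cigar]
            if rec.query_sequence is not None:
                seq = rec.query_sequence
                if rec.strand == "-":  # SAM stores the aligned orientation
                    seq = seqcodec.decode(seqcodec.revcomp(seqcodec.encode(seq)))
                seg.query_sequence = seq
            seg.set_tag("NM", int(rec.nm))
            seg.set_tag("XT", rec.mapq_proxy)
            seg.set_tag("AS", int(rec.score))
            out.write(seg)


def read_sam(path) -> List[AlignmentRecord]:
    """Read a SAM file (any mapper) into AlignmentRecords."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = _merge_cigar([(_CIGAR_FROM_SAM.get(op, "M"), n)
                                  for op, n in seg.cigartuples or []
                                  if op in _CIGAR_FROM_SAM or op == 5])
            out.append(AlignmentRecord(
                query_id=seg.query_name,
                target_id=seg.reference_name,
                target_start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                cigar=cigar,
                score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                mapq_proxy=(seg.get_tag("XT") if seg.has_tag("XT")
                            else (UNIQUE if seg.mapping_quality > 0 else AMBIGUOUS)),
                pair_state="proper" if seg.is_proper_pair else "unpaired",
                nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                query_length=seg.query_length or 0,
                query_sequence=(
                    None if seg.query_sequence is None else (
                        seg.query_sequence if not seg.is_reverse else
                        seqcodec.decode(seqcodec.revcomp(
                            seqcodec.encode(seg.query_sequence)))))))
    return out
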