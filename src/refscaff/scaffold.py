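"""Reference-projected backbone scaffolds, gap filling and the draft genome.

The backbone is a per-position majority consensus over merged evidence
(contig placements + properly paired read placements) projected onto the
reference coordinate frame: every consensus scaffold has exactly the
length of the reference scaffold it mirrors, with N wherever evidence is
absent, masked, or deletion-dominated.  Gap filling then maps the full
contig set (and, literally, 10 kb fragments of the backbone itself) back
onto the backbone and fills N positions only — bases already called are
never overwritten, so the non-N count can only grow.  Contigs that map
nowhere are screened against a decoy/contamination database and the
survivors join the draft as unplaced sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import align as al
from . import seqcodec
from .align import AlignmentRecord, AlignParams, ReadAlignments, SeqIndex
from .assemble import Contig
from .errors import FormatError, IntegrityError
from .genome import Genome


@dataclass
class ConsensusScaffold:
    """A reference-frame consensus sequence over {A,C,G,T,N}."""

    name: str
    sequence: str
    source_reference: str
    stage: str  # "backbone" | "final"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return seqcodec.encode(self.sequence)

    def non_n(self) -> int:
        return int(np.sum(self.codes != seqcodec.N))


@dataclass
class DraftGenome:
    scaffolds: List[ConsensusScaffold]
    unplaced_contigs: List[Contig] = field(default_factory=list)
    manifest: Dict = field(default_factory=dict)
    chrom_class_map: Dict[str, str] = field(default_factory=dict)

    def to_genome(self) -> Genome:
        """Scaffolds only, as a Genome (reference coordinate frame)."""
        return Genome([(s.name, s.sequence) for s in self.scaffolds],
                      dict(self.chrom_class_map))

    def write_fasta(self, path) -> None:
        records = [(s.name, s.sequence, f"stage={s.stage} source={s.source_reference}")
                   for s in self.scaffolds]
        records += [(c.id, c.sequence, "unplaced") for c in self.unplaced_contigs]
        seqcodec.write_fasta(path, records)


# ---------------------------------------------------------------------------
# evidence merging and consensus
# ---------------------------------------------------------------------------

def merge_evidence(contig_records: Sequence[AlignmentRecord],
                   contig_queries: Dict,
                   pair_alignments: Sequence[ReadAlignments],
                   target: Genome,
                   proper_only: bool = True) -> Dict[str, np.ndarray]:
    """Flat merge of contig and read placements into one pileup.

    Every contig base and every read base is one observation.  Ambiguous
    placements are excluded; read pairs contribute only when proper (unless
    ``proper_only`` is False).  Raises :class:`IntegrityError` when an
    alignment set references a different target dictionary.
    """
    counts = al.new_pileup(target)
    for rec in contig_records:
        if rec.target_id not in counts:
            raise IntegrityError(f"alignment targets unknown scaffold {rec.target_id!r}")
    unique_contigs = [r for r in contig_records if r.mapq_proxy == al.UNIQUE]
    al.add_records(counts, unique_contigs, contig_queries)
    for aln in pair_alignments:
        if list(aln.index.names) != list(target.names):
            raise IntegrityError("read alignments reference a different target dictionary")
        mask = None
        if proper_only and aln.pair_state is not None:
            mask = aln.pair_state == 1
        al.add_read_alignments(counts, aln, rows_mask=mask)
    return counts


def consensus(evidence: Dict[str, np.ndarray], reference: Genome,
              min_depth: int = 1,
              coverage_mask: Optional[Dict[str, np.ndarray]] = None
              ) -> List[ConsensusScaffold]:
    """Majority-vote backbone consensus on the reference frame.

    A position is called iff its base support (A+C+G+T observations)
    reaches ``min_depth``, it is not excluded by ``coverage_mask`` and the
    deletion count does not exceed the winning base count; otherwise N.
    Ties go to the reference base when it is among the tied maxima, else to
    the alphabetically smallest tied base — deliberately mirroring the
    reference bias such a projection approach carries.
    """
    out = []
    for name in reference.names:
        mat = evidence[name]
        ref_codes = reference.codes(name)
        L = ref_codes.size
        base_counts = mat[:4]
        maxc = base_counts.max(axis=0)
        winner = base_counts.argmax(axis=0).astype(np.uint8)  # ties -> smallest base
        ref_is_max = np.take_along_axis(
            base_counts, ref_codes.clip(max=3)[None, :].astype(np.int64), axis=0
        )[0] == maxc
        ref_is_max &= ref_codes < 4
        called = np.where(ref_is_max, ref_codes, winner).astype(np.uint8)
        support = base_counts.sum(axis=0)
        uncalled = (support < min_depth) | (maxc == 0) | (mat[al.DEL_CODE] > maxc)
        if coverage_mask is not None:
            uncalled |= ~coverage_mask[name]
        called[uncalled] = seqcodec.N
        out.append(ConsensusScaffold(
            name=name, sequence=seqcodec.decode(called),
            source_reference=name, stage="backbone"))
    return out


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

@dataclass
class GapFillResult:
    scaffolds: List[ConsensusScaffold]
    mapped_contig_ids: Set[str]
    filled_positions: Dict[str, int]


def _fragment(codes: np.ndarray, size: int):
    return [(start, codes[start:start + size])
            for start in range(0, codes.size, size)]


def gap_fill(backbone: Sequence[ConsensusScaffold], contigs: Sequence[Contig],
             params: Optional[AlignParams] = None,
             min_contig_length: int = 100,
             self_fragment_size: int = 10_000,
             mode: str = "literal") -> GapFillResult:
    """Close N gaps in the backbone with secondary contig placements.

    All contigs of at least ``min_contig_length`` are aligned to the
    backbone; in ``"literal"`` mode the backbone is additionally split into
    ``self_fragment_size`` pieces and mapped back onto itself, in
    ``"direct"`` mode the backbone contributes its own bases without the
    round trip.  Already-called (non-N) backbone bases always dominate and
    are never changed; N positions take the majority of the new evidence.
    """
    params = params or al.contig_preset()
    backbone_genome = Genome([(s.name, s.sequence) for s in backbone])
    index = SeqIndex(backbone_genome, params.seed_length)
    counts = al.new_pileup(backbone_genome)

    mapped: Set[str] = set()
    queries: Dict[str, Contig] = {}
    records: List[AlignmentRecord] = []
    for contig in contigs:
        if len(contig) < min_contig_length:
            continue
        recs = al.align_long(contig, index, params)
        if recs:
            mapped.add(contig.id)
            if recs[0].mapq_proxy == al.UNIQUE:
                records.append(recs[0])
                queries[contig.id] = contig
    al.add_records(counts, records, queries)

    if mode == "literal":
        frag_records, frag_queries = [], {}
        for scaf in backbone:
            codes = scaf.codes
            for start, piece in _fragment(codes, self_fragment_size):
                if np.all(piece == seqcodec.N):
                    continue
                pid = f"{scaf.name}:{start}"
                recs = al.align_long(piece, index, params, query_id=pid)
                if recs and recs[0].mapq_proxy == al.UNIQUE:
                    frag_records.append(recs[0])
                    frag_queries[pid] = piece
        al.add_records(counts, frag_records, frag_queries)
    else:
        for scaf in backbone:
            codes = scaf.codes
            mat = counts[scaf.name]
            non_n = codes != seqcodec.N
            np.add.at(mat, (codes[non_n], np.flatnonzero(non_n)), 1)

    final = []
    filled: Dict[str, int] = {}
    for scaf in backbone:
        codes = scaf.codes.copy()
        gaps = codes == seqcodec.N
        mat = counts[scaf.name]
        base_counts = mat[:4][:, gaps]
        maxc = base_counts.max(axis=0)
        winner = base_counts.argmax(axis=0).astype(np.uint8)
        ok = (maxc > 0) & (mat[al.DEL_CODE][gaps] <= maxc)
        fill = np.where(ok, winner, seqcodec.N).astype(np.uint8)
        codes[gaps] = fill
        filled[scaf.name] = int(ok.sum())
        final.append(ConsensusScaffold(
            name=scaf.name, sequence=seqcodec.decode(codes),
            source_reference=scaf.source_reference, stage="final"))
    return GapFillResult(scaffolds=final, mapped_contig_ids=mapped,
                         filled_positions=filled)


# ---------------------------------------------------------------------------
# contamination screen for unplaced contigs
# ---------------------------------------------------------------------------

def screen_unplaced(unmapped_contigs: Sequence[Contig],
                    decoy_db: Optional[Genome],
                    min_length: int = 200,
                    identity_threshold: float = 0.9,
                    params: Optional[AlignParams] = None
                    ) -> Tuple[List[Contig], List[Contig]]:
    """Length-filter unplaced contigs and discard likely contamination.

    A contig is discarded when it aligns to a decoy sequence with identity
    at or above ``identity_threshold`` over at least half of its length.
    An empty (or None) decoy database keeps every contig of sufficient
    length.
    """
    params = params or al.contig_preset()
    survivors = [c for c in unmapped_contigs if len(c) >= min_length]
    if decoy_db is None or decoy_db.total_length == 0:
        return survivors, []
    index = SeqIndex(decoy_db, params.seed_length)
    kept, discarded = [], []
    for contig in survivors:
        recs = al.align_long(contig, index, params)
        is_contaminant = False
        for rec in recs[:1]:
            m_bases = sum(n for op, n in rec.cigar if op == "M")
            if m_bases < 0.5 * len(contig):
                continue
            mism = _mismatches_in_m(rec, contig, decoy_db)
            identity = (m_bases - mism) / m_bases if m_bases else 0.0
            if identity >= identity_threshold:
                is_contaminant = True
        (discarded if is_contaminant else kept).append(contig)
    return kept, discarded


def _mismatches_in_m(rec: AlignmentRecord, contig: Contig, db: Genome) -> int:
    qcodes = contig.codes
    if rec.strand == "-":
        qcodes = seqcodec.revcomp(qcodes)
    tcodes = db.codes(rec.target_id)
    q = 0
    t = rec.target_start
    mism = 0
    for op, n in rec.cigar:
        if op == "M":
            qs, ts = qcodes[q:q + n], tcodes[t:t + n]
            both = (qs != seqcodec.N) & (ts != seqcodec.N)
            mism += int(np.sum(both & (qs != ts)))
            q += n
            t += n
        elif op in "IS":
            q += n
        elif op == "D":
            t += n
    return mism


# ---------------------------------------------------------------------------
# draft profiling
# ---------------------------------------------------------------------------

@dataclass
class BlockProfile:
    """Lengths of maximal sequenced (non-N) runs and N runs in a draft."""

    sequenced_block_lengths: np.ndarray
    n_block_lengths: np.ndarray
    sequenced_total: int
    n_total: int


def _runs(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.zeros(0, dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return (edges[1::2] - edges[0::2]).astype(np.int64)


def assembly_profile(draft: DraftGenome, window: int = 100_000
                     ) -> Tuple[BlockProfile, pd.DataFrame, pd.DataFrame]:
    """Block-length profile, per-scaffold coverage and windowed fractions.

    Returns ``(profile, per_scaffold, windows)`` where ``per_scaffold`` has
    columns scaffold/length/sequenced/fraction and ``windows`` gives the
    sequenced fraction in fixed tiles (BED-style half-open coordinates).
    """
    seq_blocks, n_blocks = [], []
    rows, win_rows = [], []
    for scaf in draft.scaffolds:
        codes = scaf.codes
        non_n = codes != seqcodec.N
        seq_blocks.append(_runs(non_n))
        n_blocks.append(_runs(~non_n))
        rows.append({
            "scaffold": scaf.name, "length": codes.size,
            "sequenced": int(non_n.sum()),
            "fraction": float(non_n.mean()),
        })
        for start in range(0, codes.size, window):
            end = min(start + window, codes.size)
            win_rows.append({
                "scaffold": scaf.name, "start": start, "end": end,
                "fraction": float(non_n[start:end].mean()),
            })
    seq_lengths = np.concatenate(seq_blocks) if seq_blocks else np.zeros(0, np.int64)
    n_lengths = np.concatenate(n_blocks) if n_blocks else np.zeros(0, np.int64)
    profile = BlockProfile(
        sequenced_block_lengths=seq_lengths,
        n_block_lengths=n_lengths,
        sequenced_total=int(seq_lengths.sum()),
        n_total=int(n_lengths.sum()),
    )
    return profile, pd.DataFrame(rows), pd.DataFrame(win_rows)


def write_window_bed(path, windows: pd.DataFrame) -> None:
    """Windowed sequenced fractions as BED with a 0-1000 score column."""
    with open(path, "w") as fh:
        for _, row in windows.iterrows():
            score = int(round(row["fraction"] * 1000))
            fh.write(f"{row['scaffold']}\t{row['start']}\t{row['end']}\t"
                     f"sequenced\t{score}\n")
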