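"""Comparative layer: piecewise nucleotide divergence, divergent-region
screens, chromosome-class contrasts (faster-Z) and homology annotation.

Comparator genomes are split into fixed-size pieces (10 kb by default)
which are aligned to the draft with near-free gap penalties; draft
positions covered by more than one piece are excluded entirely (the
duplicated-mapping guard), and at singly-covered positions a variable
site is recorded wherever the piece base differs from the draft base.
Divergence is then summarised in fixed tiles (50 kb by default) as
variable / aligned sites, regions above a cutoff are merged and
annotated with overlapping genes, and per-class means contrast the
Z-classed scaffold against the autosomes.

Homology runs through reciprocal best hits of a pluggable similarity
search (any engine producing query/subject/e-value/score tables; the
built-in seed-and-extend aligner provides a desk-scale default with a
nominal Karlin-Altschul e-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import align as al
from . import seqcodec
from .align import AlignParams, SeqIndex
from .errors import FormatError, ParameterError
from .genome import Genome, Z
from .variants import ChromosomeClass


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

@dataclass
class GenomePiece:
    id: str
    scaffold: str
    start: int       # origin coordinates, half-open
    end: int
    codes: np.ndarray

    @classmethod
    def parse_id(cls, piece_id: str) -> Tuple[str, int, int]:
        scaffold, _, span = piece_id.rpartition(":")
        start, end = span.split("-")
        return scaffold, int(start), int(end)


def fragment_genome(genome: Genome, piece: int = 10_000) -> List[GenomePiece]:
    """Split a genome into consecutive non-overlapping pieces.

    The last piece of each scaffold may be shorter; piece ids encode the
    origin scaffold and half-open coordinates and round-trip via
    :meth:`GenomePiece.parse_id`.
    """
    if piece <= 0:
        raise ParameterError("piece size must be positive")
    out = []
    for name in genome.names:
        codes = genome.codes(name)
        for start in range(0, codes.size, piece):
            end = min(start + piece, codes.size)
            out.append(GenomePiece(
                id=f"{name}:{start}-{end}", scaffold=name,
                start=start, end=end, codes=codes[start:end]))
    return out


# ---------------------------------------------------------------------------
# per-site divergence calls
# ---------------------------------------------------------------------------

@dataclass
class SiteCalls:
    """Per-draft-position comparison state for one comparator.

    ``aligned`` marks positions usable for divergence (singly covered,
    non-N on both sides, not adjacent to an indel); ``variable`` marks the
    aligned positions where comparator and draft disagree.
    """

    comparator: str
    aligned: Dict[str, np.ndarray]
    variable: Dict[str, np.ndarray]
    n_pieces: int = 0
    n_pieces_mapped: int = 0

    def divergence(self) -> float:
        a = sum(int(m.sum()) for m in self.aligned.values())
        v = sum(int(m.sum()) for m in self.variable.values())
        return v / a if a else float("nan")


def piecewise_divergence(pieces: Sequence[GenomePiece], draft: Genome,
                         params: Optional[AlignParams] = None,
                         comparator: str = "comparator",
                         index: Optional[SeqIndex] = None) -> SiteCalls:
    """Align comparator pieces to the draft and record per-site calls.

    Pieces map with the near-free-gap preset; only unique placements are
    used.  Draft positions covered by more than one piece are excluded,
    indel columns are excluded from both counts, and N on either side
    makes a position unusable.
    """
    params = params or al.piece_preset()
    if index is None:
        index = SeqIndex(draft, params.seed_length)
    cov = {name: np.zeros(draft.lengths[name], dtype=np.int16)
           for name in draft.names}
    variable = {name: np.zeros(draft.lengths[name], dtype=bool)
                for name in draft.names}
    indel_excl = {name: np.zeros(draft.lengths[name], dtype=bool)
                  for name in draft.names}
    n_mapped = 0
    for piece in pieces:
        recs = al.align_long(piece.codes, index, params, query_id=piece.id)
        if not recs or recs[0].mapq_proxy != al.UNIQUE:
            continue
        n_mapped += 1
        rec = recs[0]
        qcodes = piece.codes if rec.strand == "+" else seqcodec.revcomp(piece.codes)
        tcodes = draft.codes(rec.target_id)
        q = 0
        t = rec.target_start
        for op, n in rec.cigar:
            if op == "M":
                cov[rec.target_id][t:t + n] += 1
                qs, ts = qcodes[q:q + n], tcodes[t:t + n]
                both = (qs != seqcodec.N) & (ts != seqcodec.N)
                variable[rec.target_id][t:t + n] |= both & (qs != ts)
                q += n
                t += n
            elif op in "IS":
                q += n
            elif op == "D":
                indel_excl[rec.target_id][t:t + n] = True
                t += n
    aligned = {}
    for name in draft.names:
        non_n = draft.codes(name) != seqcodec.N
        aligned[name] = (cov[name] == 1) & ~indel_excl[name] & non_n
        variable[name] &= aligned[name]
    return SiteCalls(comparator=comparator, aligned=aligned, variable=variable,
                     n_pieces=len(pieces), n_pieces_mapped=n_mapped)


# ---------------------------------------------------------------------------
# windows, regions, class contrast
# ---------------------------------------------------------------------------

def window_divergence(calls: SiteCalls, window: int = 50_000,
                      min_aligned_fraction: float = 0.1) -> pd.DataFrame:
    """Tile the draft into fixed windows and summarise divergence.

    Windows are non-overlapping tiles (step = width).  A window with fewer
    aligned sites than ``min_aligned_fraction`` of its span is marked
    undefined (``divergence`` NaN) and excluded from downstream means.
    """
    if window <= 0:
        raise ParameterError("window size must be positive")
    rows = []
    for name, aligned in calls.aligned.items():
        L = aligned.size
        starts = np.arange(0, L, window)
        bounds = np.append(starts, L)
        a = np.add.reduceat(aligned.astype(np.int64), starts)
        v = np.add.reduceat(calls.variable[name].astype(np.int64), starts)
        for i, start in enumerate(starts):
            end = int(bounds[i + 1])
            span = end - start
            defined = a[i] >= min_aligned_fraction * span and a[i] > 0
            rows.append({
                "scaffold": name, "start": int(start), "end": end,
                "aligned_sites": int(a[i]), "variable_sites": int(v[i]),
                "divergence": (v[i] / a[i]) if defined else float("nan"),
                "comparator": calls.comparator,
            })
    return pd.DataFrame(rows)


@dataclass
class DivergentRegion:
    scaffold: str
    start: int
    end: int
    divergence: Dict[str, float]          # per comparator, max over windows
    genes_overlapping: List[str] = field(default_factory=list)


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    cds_intervals: List[Tuple[int, int]]  # 0-based half-open, sorted

    def __post_init__(self):
        self.cds_intervals = sorted(self.cds_intervals)
        for (s1, e1), (s2, _) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 < e1:
                raise ParameterError(f"gene {self.gene_id}: overlapping CDS intervals")
        if any(s >= e for s, e in self.cds_intervals):
            raise ParameterError(f"gene {self.gene_id}: empty CDS interval")

    @property
    def span(self) -> Tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


def flag_divergent(windows: pd.DataFrame, cutoff: float = 0.2,
                   gene_models: Sequence[GeneModel] = ()) -> List[DivergentRegion]:
    """Merge windows above the divergence cutoff into regions.

    A window is flagged when its divergence exceeds ``cutoff`` in at least
    one comparator; adjacent flagged windows on one scaffold merge.  Genes
    whose CDS span intersects a region are attached.
    """
    flagged = windows[windows["divergence"] > cutoff]
    regions: List[DivergentRegion] = []
    for (scaffold,), group in flagged.groupby(["scaffold"], sort=True):
        group = group.sort_values("start")
        current: Optional[DivergentRegion] = None
        for _, row in group.iterrows():
            comp = row.get("comparator", "comparator")
            if current is not None and row["start"] <= current.end:
                current.end = max(current.end, int(row["end"]))
                current.divergence[comp] = max(
                    current.divergence.get(comp, 0.0), float(row["divergence"]))
            else:
                current = DivergentRegion(
                    scaffold=scaffold, start=int(row["start"]),
                    end=int(row["end"]),
                    divergence={comp: float(row["divergence"])})
                regions.append(current)
    for region in regions:
        for gene in gene_models:
            if gene.scaffold != region.scaffold:
                continue
            gs, ge = gene.span
            if gs < region.end and region.start < ge:
                region.genes_overlapping.append(gene.gene_id)
    return regions


def class_divergence(windows: pd.DataFrame,
                     classes: Sequence[ChromosomeClass]
                     ) -> Tuple[pd.DataFrame, float]:
    """Mean/sd of window divergence per chromosome class, plus faster-Z.

    Undefined windows are excluded.  The returned ratio is the Z-class
    mean over the pooled autosomal (non-Z classes) mean; NaN when either
    side has no defined windows.  Classes with no defined windows are
    omitted with a warning.
    """
    import warnings

    scaffold_to_class = {m: c.label for c in classes for m in c.members}
    defined = windows.dropna(subset=["divergence"]).copy()
    defined["class"] = defined["scaffold"].map(scaffold_to_class)
    defined = defined.dropna(subset=["class"])
    rows = []
    for cls in classes:
        sub = defined[defined["class"] == cls.label]
        if sub.empty:
            warnings.warn(f"class {cls.label} has no defined windows; omitted")
            continue
        rows.append({
            "class": cls.label,
            "mean_divergence": float(sub["divergence"].mean()),
            "sd_divergence": float(sub["divergence"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "n_windows": int(len(sub)),
        })
    table = pd.DataFrame(rows)
    z_windows = defined[defined["class"] == Z]["divergence"]
    auto_windows = defined[defined["class"] != Z]["divergence"]
    ratio = (float(z_windows.mean() / auto_windows.mean())
             if len(z_windows) and len(auto_windows) and auto_windows.mean() > 0
             else float("nan"))
    return table, ratio


# ---------------------------------------------------------------------------
# homology: similarity search, reciprocal best hits, CDS coverage
# ---------------------------------------------------------------------------

# nominal ungapped Karlin-Altschul parameters for the +1/-3 scheme at
# uniform base composition; e-values are comparative, not calibrated
_KA_LAMBDA = 1.374
_KA_K = 0.1


def evalue(score: float, query_length: int, database_length: int) -> float:
    if score <= 0:
        return float("inf")
    exponent = max(-_KA_LAMBDA * score, -700.0)
    return float(_KA_K * query_length * database_length * np.exp(exponent))


def search_hits(queries: Dict[str, str], target: Genome,
                params: Optional[AlignParams] = None,
                index: Optional[SeqIndex] = None,
                max_hits: int = 3) -> pd.DataFrame:
    """Similarity search of sequences against a genome (built-in engine).

    Returns the standard hit-table columns query / subject / evalue /
    score / target coordinates; ``subject`` is ``scaffold:start-end`` so
    hits can double as region identifiers in the reciprocal search.
    """
    params = params or al.contig_preset()
    if index is None:
        index = SeqIndex(target, params.seed_length)
    db_len = target.total_length
    rows = []
    for qid, seq in queries.items():
        recs = al.align_long(seq, index, params)
        for rec in recs[:max_hits]:
            rows.append({
                "query": qid,
                "subject": f"{rec.target_id}:{rec.target_start}-{rec.target_end}",
                "scaffold": rec.target_id,
                "start": rec.target_start, "end": rec.target_end,
                "evalue": evalue(rec.score, len(seq), db_len),
                "score": rec.score,
            })
    return pd.DataFrame(rows, columns=["query", "subject", "scaffold",
                                       "start", "end", "evalue", "score"])


@dataclass
class RBHPair:
    gene_id: str
    draft_region: str
    forward_evalue: float
    reverse_evalue: float


def _best_hits(hits: pd.DataFrame) -> Dict[str, Tuple[str, float]]:
    """Best subject per query: min e-value, ties to higher score then id."""
    required = {"query", "subject", "evalue"}
    if not required.issubset(hits.columns):
        raise FormatError(f"hit table must contain columns {sorted(required)}")
    best: Dict[str, Tuple[str, float]] = {}
    table = hits.copy()
    if "score" not in table.columns:
        table["score"] = 0.0
    table = table.sort_values(["query", "evalue", "score", "subject"],
                              ascending=[True, True, False, True])
    for _, row in table.drop_duplicates("query", keep="first").iterrows():
        best[row["query"]] = (row["subject"], float(row["evalue"]))
    return best


def reciprocal_best_hits(forward_hits: pd.DataFrame, reverse_hits: pd.DataFrame,
                         evalue_cutoff: float = 1e-10) -> List[RBHPair]:
    """Mutual-best pairing of genes and draft regions.

    Gene g pairs with region r iff r is g's best forward hit, g is r's
    best reverse hit and both e-values pass the cutoff.
    """
    fwd = _best_hits(forward_hits)
    rev = _best_hits(reverse_hits)
    pairs = []
    for gene, (region, fe) in sorted(fwd.items()):
        if fe > evalue_cutoff:
            continue
        back = rev.get(region)
        if back is None:
            continue
        partner, re_ = back
        if partner == gene and re_ <= evalue_cutoff:
            pairs.append(RBHPair(gene, region, fe, re_))
    return pairs


def cds_coverage(gene_models: Sequence[GeneModel], draft: Genome
                 ) -> Tuple[pd.DataFrame, np.ndarray, int]:
    """Fraction of each gene's CDS covered by called (non-N) draft bases.

    Gene models live on the reference frame, which the draft scaffolds
    mirror coordinate-for-coordinate.  Returns the per-gene table, a
    histogram over 10% bins and the count of genes above 90% coverage.
    Genes on scaffolds absent from the draft get fraction 0 and a flag.
    """
    non_n_cum: Dict[str, np.ndarray] = {}
    for name in draft.names:
        non_n = (draft.codes(name) != seqcodec.N).astype(np.int64)
        non_n_cum[name] = np.concatenate([[0], np.cumsum(non_n)])
    rows = []
    for gene in gene_models:
        cum = non_n_cum.get(gene.scaffold)
        if cum is None:
            rows.append({"gene_id": gene.gene_id, "cds_length": gene.cds_length,
                         "covered": 0, "fraction": 0.0, "missing_scaffold": True})
            continue
        covered = sum(int(cum[min(e, cum.size - 1)] - cum[min(s, cum.size - 1)])
                      for s, e in gene.cds_intervals)
        rows.append({"gene_id": gene.gene_id, "cds_length": gene.cds_length,
                     "covered": covered,
                     "fraction": covered / gene.cds_length,
                     "missing_scaffold": False})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, np.zeros(10, dtype=np.int64), 0
    hist, _ = np.histogram(table["fraction"], bins=np.linspace(0, 1, 11))
    over_90 = int((table["fraction"] > 0.9).sum())
    return table, hist.astype(np.int64), over_90


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(gff3_path) -> List[GeneModel]:
    """Load gene models (CDS features grouped by gene) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="merge",
                            keep_order=True)
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        intervals = [(cds.start - 1, cds.end)
                     for cds in db.children(gene, featuretype="CDS")]
        if not intervals:
            continue
        genes.append(GeneModel(gene_id=gene.id, scaffold=gene.seqid,
                               strand=gene.strand or "+",
                               cds_intervals=intervals))
    return genes


def write_gene_models(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            gs, ge = gene.span
            fh.write(f"{gene.scaffold}\trefscaff\tgene\t{gs + 1}\t{ge}\t.\t"
                     f"{gene.strand}\t.\tID={gene.gene_id}\n")
            for i, (s, e) in enumerate(gene.cds_intervals, 1):
                fh.write(f"{gene.scaffold}\trefscaff\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{gene.strand}\t0\tID={gene.gene_id}.cds{i};"
                         f"Parent={gene.gene_id}\n")


def write_regions_bed(path, regions: Sequence[DivergentRegion]) -> None:
    """Divergent regions as BED; score = max divergence x 1000."""
    with open(path, "w") as fh:
        for region in regions:
            score = int(round(max(region.divergence.values()) * 1000))
            genes = ",".join(region.genes_overlapping) or "."
            fh.write(f"{region.scaffold}\t{region.start}\t{region.end}\t"
                     f"{genes}\t{score}\n")


def write_windows_bed(path, windows: pd.DataFrame) -> None:
    """Divergence windows as BED; score = divergence x 1000 (-1 undefined)."""
    with open(path, "w") as fh:
        for _, row in windows.iterrows():
            d = row["divergence"]
            score = -1 if pd.isna(d) else int(round(d * 1000))
            fh.write(f"{row['scaffold']}\t{row['start']}\t{row['end']}\t"
                     f"{row['comparator']}\t{score}\n")
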