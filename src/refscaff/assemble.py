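"""Minimal de Bruijn contig assembly.

Reads are decomposed into canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement); k-mers below a count threshold are
pruned as likely sequencing errors, and contigs are the maximal
non-branching paths (unitigs) of the remaining graph.  No mate-pair
scaffolding happens here — long-range structure comes from the
reference-guided stage.  The k-mer size can be chosen by an exhaustive
sweep that keeps the assembly with the longest N50.

k-mer counting is vectorised: windows are encoded as base-4 integers
(one uint64 for k <= 31, a two-limb pair above that, so any odd k up to
62 is supported) and counted with a sort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import seqcodec
from .errors import ParameterError, PipelineError
from .reads import ReadBatch

_SENTINEL = 5  # separates reads in the concatenated base stream


@dataclass
class Contig:
    """A de novo assembled sequence with its mean k-mer depth."""

    id: str
    sequence: str
    mean_depth: float
    k_used: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return seqcodec.encode(self.sequence)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    max_length: int
    mean_length: float
    depth_min: float
    depth_max: float
    depth_mean: float

    @classmethod
    def from_contigs(cls, contigs: Sequence[Contig]) -> "AssemblyStats":
        if not contigs:
            return cls(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)
        lengths = [len(c) for c in contigs]
        depths = [c.mean_depth for c in contigs]
        return cls(
            n_contigs=len(contigs),
            total_length=int(sum(lengths)),
            n50=n50(lengths),
            max_length=int(max(lengths)),
            mean_length=float(np.mean(lengths)),
            depth_min=float(min(depths)),
            depth_max=float(max(depths)),
            depth_mean=float(np.mean(depths)),
        )


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L hold half the assembly."""
    if len(lengths) == 0:
        raise ParameterError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if np.any(arr <= 0):
        raise ParameterError("contig lengths must be positive")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


# ---------------------------------------------------------------------------
# k-mer counting
# ---------------------------------------------------------------------------

def _concat_bases(batches: Iterable[ReadBatch]) -> np.ndarray:
    """Concatenate read bases with sentinels between reads."""
    parts = []
    for batch in batches:
        n, width = batch.codes.shape
        if n == 0:
            continue
        arr = np.full((n, width + 1), _SENTINEL, dtype=np.uint8)
        arr[:, :width] = batch.codes
        cols = np.arange(width + 1)
        arr[cols[None, :] >= batch.lengths[:, None]] = _SENTINEL
        parts.append(arr.ravel())
    if not parts:
        return np.zeros(0, dtype=np.uint8)
    return np.concatenate(parts)


def _poly_codes(clean: np.ndarray, start: int, length: int, width: int) -> np.ndarray:
    """Base-4 codes of ``length``-wide windows at offsets ``start..start+width``."""
    code = np.zeros(width, dtype=np.uint64)
    for j in range(length):
        code = (code << np.uint64(2)) | clean[start + j:start + j + width].astype(np.uint64)
    return code


def _window_limbs(bases: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hi, lo, valid) for all k-windows of a base stream.

    ``hi`` covers the first ``max(k - 31, 0)`` bases, ``lo`` the rest;
    for k <= 31 ``hi`` is all zeros.  ``valid`` is False for windows
    containing non-ACGT codes.
    """
    W = bases.size - k + 1
    if W <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z, np.zeros(0, dtype=bool)
    clean = (bases & 3).astype(np.uint8)
    bad = (bases >= 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    if k <= 31:
        hi = np.zeros(W, dtype=np.uint64)
        lo = _poly_codes(clean, 0, k, W)
    else:
        hi = _poly_codes(clean, 0, k - 31, W)
        lo = _poly_codes(clean, k - 31, 31, W)
    return hi, lo, valid


def _canonical_limbs(bases: np.ndarray, k: int):
    """Canonical (hi, lo, valid) limbs for all k-windows, both strands merged."""
    hi, lo, valid = _window_limbs(bases, k)
    comp = np.where(bases < 4, 3 - bases, bases).astype(np.uint8)
    rhi_rev, rlo_rev, _ = _window_limbs(comp[::-1], k)
    rhi, rlo = rhi_rev[::-1], rlo_rev[::-1]
    less = (hi < rhi) | ((hi == rhi) & (lo <= rlo))
    chi = np.where(less, hi, rhi)
    clo = np.where(less, lo, rlo)
    return chi, clo, valid


def count_kmers(batches: Iterable[ReadBatch], k: int,
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Count canonical k-mers across read batches.

    Returns ``(hi, lo, counts)`` sorted lexicographically by (hi, lo).
    """
    if k < 15 or k % 2 == 0:
        raise ParameterError("k must be odd and >= 15")
    if k > 62:
        raise ParameterError("k must be <= 62")
    bases = _concat_bases(batches)
    chi, clo, valid = _canonical_limbs(bases, k)
    chi, clo = chi[valid], clo[valid]
    if chi.size == 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z, np.zeros(0, dtype=np.int64)
    if k <= 31:
        uniq, counts = np.unique(clo, return_counts=True)
        return np.zeros_like(uniq), uniq, counts
    order = np.lexsort((clo, chi))
    chi, clo = chi[order], clo[order]
    new = np.empty(chi.size, dtype=bool)
    new[0] = True
    new[1:] = (chi[1:] != chi[:-1]) | (clo[1:] != clo[:-1])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, chi.size))
    return chi[starts], clo[starts], counts


def _combine(hi: np.ndarray, lo: np.ndarray) -> List[int]:
    """Merge limb arrays into python ints (lexicographic order preserved)."""
    if not hi.any():
        return [int(x) for x in lo]
    return [(int(h) << 62) | int(x) for h, x in zip(hi, lo)]


# ---------------------------------------------------------------------------
# unitig extraction
# ---------------------------------------------------------------------------

def _decode_kmer(code: int, k: int) -> np.ndarray:
    out = np.empty(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        out[i] = code & 3
        code >>= 2
    return out


class _KmerGraph:
    """Canonical k-mer set with O(1) oriented-extension queries."""

    def __init__(self, solid: Dict[int, int], k: int):
        self.solid = solid
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.top = 2 * (k - 1)

    def canon(self, f: int, r: int) -> int:
        return f if f <= r else r

    def rc(self, f: int) -> int:
        r = 0
        k = self.k
        for _ in range(k):
            r = (r << 2) | (3 - (f & 3))
            f >>= 2
        return r

    def forward_exts(self, f: int, r: int):
        """Oriented successors present in the solid set."""
        out = []
        for b in range(4):
            nf = ((f << 2) | b) & self.mask
            nr = (r >> 2) | ((3 - b) << self.top)
            if self.canon(nf, nr) in self.solid:
                out.append((b, nf, nr))
        return out

    def backward_exts(self, f: int, r: int):
        out = []
        for b in range(4):
            pf = (f >> 2) | (b << self.top)
            pr = ((r << 2) | (3 - b)) & self.mask
            if self.canon(pf, pr) in self.solid:
                out.append((b, pf, pr))
        return out


def build_contigs(batches, k: int, min_contig_length: int = 100,
                  min_kmer_count: int = 2) -> List[Contig]:
    """Assemble unitigs from read batches.

    Contigs are maximal non-branching paths of the canonical k-mer graph
    after pruning k-mers seen fewer than ``min_kmer_count`` times; contigs
    shorter than ``min_contig_length`` are dropped.  An empty result is a
    warning condition, not an error.
    """
    if isinstance(batches, ReadBatch):
        batches = [batches]
    hi, lo, counts = count_kmers(batches, k)
    keep = counts >= min_kmer_count
    keys = _combine(hi[keep], lo[keep])
    solid = dict(zip(keys, counts[keep].tolist()))
    if not solid:
        return []
    graph = _KmerGraph(solid, k)

    visited = set()
    contigs: List[Contig] = []
    n_solid = len(solid)

    for seed in keys:
        if seed in visited:
            continue
        f, r = seed, graph.rc(seed)
        # walk backward to the unitig start
        steps = 0
        while steps <= n_solid:
            back = graph.backward_exts(f, r)
            if len(back) != 1:
                break
            _, pf, pr = back[0]
            pc = graph.canon(pf, pr)
            if pc in visited or pc == seed:
                break
            fwd_of_prev = graph.forward_exts(pf, pr)
            if len(fwd_of_prev) != 1:
                break
            f, r = pf, pr
            steps += 1
        # walk forward collecting bases
        start_canon = graph.canon(f, r)
        bases = list(_decode_kmer(f, k))
        depth_sum = solid[start_canon]
        n_kmers = 1
        visited.add(start_canon)
        steps = 0
        while steps <= n_solid:
            fwd = graph.forward_exts(f, r)
            if len(fwd) != 1:
                break
            b, nf, nr = fwd[0]
            nc = graph.canon(nf, nr)
            if nc in visited:
                break
            if len(graph.backward_exts(nf, nr)) != 1:
                break
            bases.append(b)
            depth_sum += solid[nc]
            n_kmers += 1
            visited.add(nc)
            f, r = nf, nr
            steps += 1
        if len(bases) >= min_contig_length:
            seq = seqcodec.decode(np.array(bases, dtype=np.uint8))
            contigs.append(Contig(
                id=f"contig_{len(contigs) + 1}",
                sequence=seq,
                mean_depth=depth_sum / n_kmers,
                k_used=k,
            ))
    return contigs


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------

@dataclass
class SelectKResult:
    best_k: int
    contigs: List[Contig]
    stats: pd.DataFrame  # one row per k scanned


def select_k(batches, k_min: int = 15, k_max: int = 55, k_step: int = 2,
             min_contig_length: int = 100, min_kmer_count: int = 2,
             subsample_fraction: Optional[float] = None,
             seed: int = 0) -> SelectKResult:
    """Exhaustive k sweep keeping the assembly with the longest N50.

    Ties resolve toward the larger k.  With ``subsample_fraction`` the sweep
    runs on a random subset of reads and the winning k is then re-assembled
    from the full input (keeps deep inputs tractable without changing the
    selection contract).
    """
    if isinstance(batches, ReadBatch):
        batches = [batches]
    if k_min > k_max or k_min % 2 == 0 or k_step % 2 != 0:
        raise ParameterError("k range must be odd-aligned with an even step")
    sweep_batches = batches
    if subsample_fraction is not None and 0 < subsample_fraction < 1:
        rng = np.random.default_rng(seed)
        sweep_batches = []
        for batch in batches:
            mask = rng.random(batch.n) < subsample_fraction
            sweep_batches.append(batch.subset(mask))

    rows = []
    best_k, best_n50, best_contigs = None, -1, None
    for k in range(k_min, k_max + 1, k_step):
        contigs = build_contigs(sweep_batches, k,
                                min_contig_length=min_contig_length,
                                min_kmer_count=min_kmer_count)
        stats = AssemblyStats.from_contigs(contigs)
        rows.append({"k": k, **stats.__dict__})
        if stats.n_contigs and stats.n50 >= best_n50:
            best_k, best_n50, best_contigs = k, stats.n50, contigs

    if best_k is None:
        raise PipelineError("every k in the sweep produced an empty assembly")
    if sweep_batches is not batches:
        best_contigs = build_contigs(batches, best_k,
                                     min_contig_length=min_contig_length,
                                     min_kmer_count=min_kmer_count)
    return SelectKResult(best_k=best_k, contigs=best_contigs,
                         stats=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_contigs_fasta(path, contigs: Sequence[Contig]) -> None:
    seqcodec.write_fasta(
        path,
        [(c.id, c.sequence, f"depth={c.mean_depth:.2f} k={c.k_used}")
         for c in contigs],
    )


def read_contigs_fasta(path) -> List[Contig]:
    """Load externally assembled contigs; depth/k parsed when present."""
    contigs = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        depth, k = 1.0, 0
        for token in rec.description.split():
            if token.startswith("depth="):
                depth = float(token[6:])
            elif token.startswith("k="):
                k = int(token[2:])
        contigs.append(Contig(rec.id, str(rec.seq).upper(), depth, k))
    return contigs
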