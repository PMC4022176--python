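"""Synthetic genomes, diploid individuals and sequencing libraries.

The generator emulates the statistical structure a reference-guided
assembly pipeline has to cope with: a focal genome diverged from an
ancestral reference by substitutions (with a transition bias), small
indels and optionally inversions; locally elevated divergence segments
(MHC-like islands); an elevated substitution rate on a designated Z-like
scaffold (faster-Z); intra-individual heterozygosity; and error-bearing
single-end and mate-pair read libraries with known read origins.

Every operation is a pure function of its inputs and a seed, and every
planted event is recorded in a :class:`SimulationTruth` so downstream
estimates can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import seqcodec
from .errors import ParameterError
from .genome import Genome, Z
from .reads import LibrarySpec, ReadBatch

# Transition partner of each base: A<->G, C<->T.
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# The two transversion partners of each base.
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass
class IndelEvent:
    scaffold: str
    position: int          # reference coordinate (0-based; insertions occur before it)
    length: int
    kind: str              # "ins" | "del"
    inserted: str = ""     # inserted bases for "ins"


@dataclass
class InversionEvent:
    scaffold: str
    start: int
    end: int               # reference coordinates, half-open


@dataclass
class SimulationTruth:
    """Complete record of the differences planted between genomes.

    Coordinates: substitution/indel/inversion events and ``ref_to_focal``
    are on the reference frame; ``het_sites`` and ``focal_to_ref`` are on
    the focal frame.  The coordinate maps hold ``-1`` where a position has
    no counterpart (deleted from / inserted into the focal genome).
    """

    substitutions: Dict[str, pd.DataFrame] = field(default_factory=dict)
    indel_events: List[IndelEvent] = field(default_factory=list)
    inversion_events: List[InversionEvent] = field(default_factory=list)
    het_sites: Dict[str, pd.DataFrame] = field(default_factory=dict)
    ref_to_focal: Dict[str, np.ndarray] = field(default_factory=dict)
    focal_to_ref: Dict[str, np.ndarray] = field(default_factory=dict)
    divergent_segments: List[Tuple[str, int, int, float]] = field(default_factory=list)

    def het_positions(self, scaffold: str) -> np.ndarray:
        df = self.het_sites.get(scaffold)
        return df["position"].to_numpy() if df is not None else np.array([], dtype=int)

    def het_sites_on_reference(self, scaffold: str) -> np.ndarray:
        """Planted heterozygous positions projected onto the reference frame."""
        pos = self.het_positions(scaffold)
        if pos.size == 0 or scaffold not in self.focal_to_ref:
            return pos
        mapped = self.focal_to_ref[scaffold][pos]
        return mapped[mapped >= 0]

    def write_tables(self, directory) -> None:
        """Dump all truth channels as tab-separated files."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        subs = [df.assign(scaffold=name) for name, df in self.substitutions.items()]
        (pd.concat(subs, ignore_index=True) if subs else
         pd.DataFrame(columns=["position", "ancestral", "derived", "scaffold"])
         ).to_csv(directory / "substitutions.tsv", sep="\t", index=False)
        hets = [df.assign(scaffold=name) for name, df in self.het_sites.items()]
        (pd.concat(hets, ignore_index=True) if hets else
         pd.DataFrame(columns=["position", "allele1", "allele2", "scaffold"])
         ).to_csv(directory / "het_sites.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(e.scaffold, e.position, e.length, e.kind, e.inserted)
             for e in self.indel_events],
            columns=["scaffold", "position", "length", "kind", "inserted"],
        ).to_csv(directory / "indels.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.divergent_segments,
            columns=["scaffold", "start", "end", "rate"],
        ).to_csv(directory / "divergent_segments.tsv", sep="\t", index=False)
        for name, arr in self.ref_to_focal.items():
            np.savetxt(directory / f"ref_to_focal.{name}.tsv", arr, fmt="%d")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def generate_reference(n_scaffolds: int,
                       lengths: Sequence[int],
                       gc: float,
                       seed: int,
                       names: Optional[Sequence[str]] = None,
                       chrom_classes: Optional[Sequence[str]] = None) -> Genome:
    """Generate a random ancestral reference genome.

    Bases are i.i.d. with the requested GC fraction.  ``chrom_classes``
    optionally labels each scaffold (macro / intermediate / micro / Z);
    one scaffold may be classed ``"Z"`` to act as the sex chromosome.
    """
    if n_scaffolds <= 0 or len(lengths) != n_scaffolds:
        raise ParameterError("lengths must supply one entry per scaffold")
    if any(L <= 0 for L in lengths):
        raise ParameterError("scaffold lengths must be positive")
    if not (0 < gc < 1):
        raise ParameterError("gc must be in (0, 1)")
    if names is None:
        names = [f"scaffold_{i + 1}" for i in range(n_scaffolds)]
    if chrom_classes is not None and len(chrom_classes) != n_scaffolds:
        raise ParameterError("chrom_classes must supply one label per scaffold")

    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    coded = [(name, rng.choice(4, size=L, p=probs).astype(np.uint8))
             for name, L in zip(names, lengths)]
    class_map = dict(zip(names, chrom_classes)) if chrom_classes else {}
    return Genome.from_codes(coded, class_map)


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _mutate_bases(bases: np.ndarray, rng, ts_bias: float) -> np.ndarray:
    """Substitute each base, transitions favoured ``ts_bias`` : 1 overall."""
    p_ts = ts_bias / (ts_bias + 1.0)
    is_ts = rng.random(bases.size) < p_ts
    tv_pick = rng.integers(0, 2, size=bases.size)
    out = np.where(is_ts, _TRANSITION[bases],
                   _TRANSVERSIONS[bases, tv_pick])
    return out.astype(np.uint8)


def evolve_genome(ref: Genome,
                  sub_rate: float,
                  indel_rate: float,
                  divergent_segments: Sequence[Tuple[str, int, int, float]] = (),
                  z_multiplier: float = 1.0,
                  seed: int = 0,
                  ts_bias: float = 2.0,
                  indel_mean_length: float = 3.0,
                  max_indel_length: int = 50,
                  inversions: Sequence[Tuple[str, int, int]] = ()) -> Tuple[Genome, SimulationTruth]:
    """Derive a focal genome from ``ref`` and record every planted event.

    Substitutions occur at ``sub_rate`` per site (``sub_rate * z_multiplier``
    on the scaffold classed ``"Z"``); each ``(scaffold, start, end, rate)``
    divergent segment substitutes at its own rate instead.  Indels occur at
    ``indel_rate`` per site with geometric lengths.  Explicit ``inversions``
    reverse-complement their segment; they may not overlap indels or
    divergent segments.
    """
    for rate in (sub_rate, indel_rate):
        if not (0 <= rate < 0.5):
            raise ParameterError("rates must be in [0, 0.5)")
    if z_multiplier < 0:
        raise ParameterError("z_multiplier must be >= 0")
    seg_by_scaffold: Dict[str, list] = {}
    for scaf, start, end, rate in divergent_segments:
        if scaf not in ref.names:
            raise ParameterError(f"divergent segment on unknown scaffold {scaf!r}")
        L = ref.lengths[scaf]
        if not (0 <= start < end <= L):
            raise ParameterError("divergent segment outside scaffold bounds")
        if not (0 <= rate < 0.5):
            raise ParameterError("segment rate must be in [0, 0.5)")
        seg_by_scaffold.setdefault(scaf, []).append((start, end, rate))
    for scaf, segs in seg_by_scaffold.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ParameterError("divergent segments overlap")
    inv_by_scaffold: Dict[str, list] = {}
    for scaf, start, end in inversions:
        if not (0 <= start < end <= ref.lengths[scaf]):
            raise ParameterError("inversion outside scaffold bounds")
        inv_by_scaffold.setdefault(scaf, []).append((start, end))

    rng = np.random.default_rng(seed)
    truth = SimulationTruth(divergent_segments=list(divergent_segments))
    focal_coded = []

    for name, _ in ref.scaffolds:
        codes = ref.codes(name).copy()
        L = codes.size

        rate = np.full(L, sub_rate, dtype=np.float64)
        if ref.chrom_class_map.get(name) == Z:
            rate *= z_multiplier
        for start, end, seg_rate in seg_by_scaffold.get(name, []):
            rate[start:end] = seg_rate

        sub_mask = rng.random(L) < rate
        sub_pos = np.flatnonzero(sub_mask)
        ancestral = codes[sub_pos].copy()
        derived = _mutate_bases(ancestral, rng, ts_bias)
        codes[sub_pos] = derived

        # indels: sampled positions, geometric lengths, overlaps dropped
        events: List[IndelEvent] = []
        if indel_rate > 0:
            ipos = np.flatnonzero(rng.random(L) < indel_rate)
            kinds = rng.integers(0, 2, size=ipos.size)  # 0 = del, 1 = ins
            lens = np.minimum(rng.geometric(1.0 / indel_mean_length, size=ipos.size),
                              max_indel_length)
            cursor = -1
            for p, kind, g in zip(ipos, kinds, lens):
                p, g = int(p), int(g)
                if p <= cursor:
                    continue
                if kind == 0:
                    if p + g > L:
                        continue
                    events.append(IndelEvent(name, p, g, "del"))
                    cursor = p + g - 1
                else:
                    ins = seqcodec.decode(rng.integers(0, 4, size=g).astype(np.uint8))
                    events.append(IndelEvent(name, p, g, "ins", ins))
                    cursor = p
        for start, end in inv_by_scaffold.get(name, []):
            for ev in events:
                if ev.position < end and ev.position + (ev.length if ev.kind == "del" else 0) >= start:
                    raise ParameterError("inversion overlaps an indel event")
            for s, e, _r in seg_by_scaffold.get(name, []):
                if s < end and start < e:
                    raise ParameterError("inversion overlaps a divergent segment")

        # splice indels, building the reference->focal coordinate map
        ref2focal = np.empty(L, dtype=np.int64)
        pieces: List[np.ndarray] = []
        focal_cursor = 0
        ref_cursor = 0
        for ev in events:
            if ev.position > ref_cursor:
                seg = codes[ref_cursor:ev.position]
                ref2focal[ref_cursor:ev.position] = (
                    np.arange(seg.size, dtype=np.int64) + focal_cursor)
                pieces.append(seg)
                focal_cursor += seg.size
                ref_cursor = ev.position
            if ev.kind == "del":
                ref2focal[ref_cursor:ref_cursor + ev.length] = -1
                ref_cursor += ev.length
            else:
                pieces.append(seqcodec.encode(ev.inserted))
                focal_cursor += ev.length
        if ref_cursor < L:
            seg = codes[ref_cursor:]
            ref2focal[ref_cursor:] = np.arange(seg.size, dtype=np.int64) + focal_cursor
            pieces.append(seg)
            focal_cursor += seg.size
        focal = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.uint8)

        # inversions (reference coordinates; indel-free by construction)
        for start, end in inv_by_scaffold.get(name, []):
            fs, fe = ref2focal[start], ref2focal[end - 1] + 1
            focal[fs:fe] = seqcodec.revcomp(focal[fs:fe])
            ref2focal[start:end] = ref2focal[start:end][::-1]
            truth.inversion_events.append(InversionEvent(name, int(start), int(end)))

        focal2ref = np.full(focal.size, -1, dtype=np.int64)
        mapped = ref2focal >= 0
        focal2ref[ref2focal[mapped]] = np.flatnonzero(mapped)

        # substitutions falling inside deleted segments create no difference
        kept = ref2focal[sub_pos] >= 0
        truth.substitutions[name] = pd.DataFrame({
            "position": sub_pos[kept].astype(np.int64),
            "ancestral": [seqcodec.decode(np.array([b])) for b in ancestral[kept]],
            "derived": [seqcodec.decode(np.array([b])) for b in derived[kept]],
        })
        truth.indel_events.extend(events)
        truth.ref_to_focal[name] = ref2focal
        truth.focal_to_ref[name] = focal2ref
        focal_coded.append((name, focal))

    focal_genome = Genome.from_codes(focal_coded, dict(ref.chrom_class_map))
    return focal_genome, truth


def verify_truth(ref: Genome, focal: Genome, truth: SimulationTruth) -> None:
    """Reconcile the genomes against the truth channel.

    Every mapped-position mismatch must be a recorded substitution (or lie
    inside a recorded inversion), and every unmapped position must belong to
    a recorded indel.  Raises ``AssertionError`` on any unexplained
    difference; intended for instances of at most ~100 kb.
    """
    for name in ref.names:
        rcodes, fcodes = ref.codes(name), focal.codes(name)
        r2f = truth.ref_to_focal[name]
        subs = set(truth.substitutions[name]["position"].tolist())
        inverted = np.zeros(rcodes.size, dtype=bool)
        for ev in truth.inversion_events:
            if ev.scaffold == name:
                inverted[ev.start:ev.end] = True
        mapped = np.flatnonzero(r2f >= 0)
        diff = mapped[rcodes[mapped] != fcodes[r2f[mapped]]]
        unexplained = [p for p in diff if p not in subs and not inverted[p]]
        assert not unexplained, f"unexplained differences on {name}: {unexplained[:5]}"
        # recorded substitutions must actually differ
        for p in subs:
            assert rcodes[p] != fcodes[r2f[p]] or inverted[p]
        # unmapped reference positions must be explained by deletions
        deleted = np.zeros(rcodes.size, dtype=bool)
        for ev in truth.indel_events:
            if ev.scaffold == name and ev.kind == "del":
                deleted[ev.position:ev.position + ev.length] = True
        assert np.array_equal(r2f < 0, deleted)


# ---------------------------------------------------------------------------
# diploid individual
# ---------------------------------------------------------------------------

def make_diploid(focal: Genome, het_rate: float, seed: int,
                 ts_bias: float = 2.0) -> Tuple[Tuple[Genome, Genome], Dict[str, pd.DataFrame]]:
    """Plant heterozygous sites onto ``focal``, returning the two haplotypes.

    At each planted site one haplotype keeps the focal base and the other
    receives a different base (transition-biased); which haplotype carries
    which allele is random.  Returns ``((hap1, hap2), het_truth)`` with the
    truth keyed by scaffold, positions on the focal frame.
    """
    if not (0 <= het_rate < 0.1):
        raise ParameterError("het_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    hap1_coded, hap2_coded = [], []
    het_truth: Dict[str, pd.DataFrame] = {}
    for name, _ in focal.scaffolds:
        codes = focal.codes(name)
        pos = np.flatnonzero(rng.random(codes.size) < het_rate)
        alt = _mutate_bases(codes[pos], rng, ts_bias)
        onto_hap1 = rng.integers(0, 2, size=pos.size).astype(bool)
        h1, h2 = codes.copy(), codes.copy()
        h1[pos[onto_hap1]] = alt[onto_hap1]
        h2[pos[~onto_hap1]] = alt[~onto_hap1]
        het_truth[name] = pd.DataFrame({
            "position": pos.astype(np.int64),
            "allele1": [seqcodec.decode(h1[p:p + 1]) for p in pos],
            "allele2": [seqcodec.decode(h2[p:p + 1]) for p in pos],
        })
        hap1_coded.append((name, h1))
        hap2_coded.append((name, h2))
    haps = (Genome.from_codes(hap1_coded, dict(focal.chrom_class_map)),
            Genome.from_codes(hap2_coded, dict(focal.chrom_class_map)))
    return haps, het_truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Reads plus their origin truth.

    ``batches`` holds one :class:`ReadBatch` for a single-end library and
    two (mate1, mate2, synchronized order) for a mate-pair library.  The
    ``truth`` frame has one row per read: read index, mate, haplotype,
    scaffold, 0-based leftmost position on that haplotype, and strand.
    """

    library: LibrarySpec
    batches: List[ReadBatch]
    truth: pd.DataFrame

    def write_fastq(self, prefix) -> List[str]:
        paths = []
        if self.library.kind == "single_end":
            path = f"{prefix}.fastq"
            self.batches[0].write_fastq(path)
            paths.append(path)
        else:
            for tag, batch in zip((1, 2), self.batches):
                path = f"{prefix}_{tag}.fastq"
                batch.write_fastq(path)
                paths.append(path)
        return paths

    def manifest(self) -> dict:
        return {
            "library": self.library.name,
            "kind": self.library.kind,
            "read_length": self.library.read_length,
            "coverage": self.library.coverage,
            "error_rate": self.library.error_rate,
            "insert_mean": self.library.insert_mean,
            "insert_sd": self.library.insert_sd,
            "orientation": self.library.orientation,
            "n_reads": int(sum(b.n for b in self.batches)),
        }


def random_gene_models(genome: Genome, n_genes: int, seed: int,
                       exons_per_gene: Tuple[int, int] = (2, 6),
                       exon_length: Tuple[int, int] = (100, 400),
                       intron_length: Tuple[int, int] = (100, 1000)):
    """Plant non-overlapping multi-exon gene models on a genome.

    Returns :class:`~refscaff.compare.GeneModel` objects on the genome's
    coordinate frame (synthetic stand-ins for downloaded gene annotation).
    """
    from .compare import GeneModel

    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    genes = []
    cursor = {n: 200 for n in names}
    for i in range(n_genes):
        name = names[rng.integers(0, len(names))]
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        start = cursor[name] + int(rng.integers(200, 2000))
        intervals = []
        pos = start
        for _ in range(n_ex):
            ex = int(rng.integers(exon_length[0], exon_length[1] + 1))
            intervals.append((pos, pos + ex))
            pos += ex + int(rng.integers(intron_length[0], intron_length[1] + 1))
        if pos >= genome.lengths[name] - 200:
            continue
        cursor[name] = pos
        strand = "+" if rng.integers(0, 2) else "-"
        genes.append(GeneModel(gene_id=f"gene_{i + 1}", scaffold=name,
                               strand=strand, cds_intervals=intervals))
    return genes


def _extract_segments(genome_codes: Dict[str, np.ndarray], scaf_idx, pos,
                      length, names) -> np.ndarray:
    """Gather ``length``-base segments at (scaffold, pos) into a matrix."""
    out = np.empty((pos.size, length), dtype=np.uint8)
    offs = np.arange(length)
    for si, name in enumerate(names):
        rows = np.flatnonzero(scaf_idx == si)
        if rows.size:
            out[rows] = genome_codes[name][pos[rows][:, None] + offs]
    return out


def _apply_errors(codes: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    return np.where(mask & (codes < 4), (codes + shift) % 4, codes).astype(np.uint8)


def _revcomp_rows(codes: np.ndarray, rows: np.ndarray) -> None:
    codes[rows] = seqcodec._COMPLEMENT[codes[rows][:, ::-1]]


def simulate_reads(haplotypes, spec: LibrarySpec, seed: int) -> SimulatedReads:
    """Simulate a sequencing library from a haploid or diploid genome.

    ``haplotypes`` is a single :class:`Genome` or a pair; fragments are drawn
    from either haplotype with equal probability, from scaffolds in
    proportion to length, on either strand.  The read count is
    ``round(coverage * haploid_length / bases_per_fragment)``.  Mate pairs
    follow the library's declared "FR" orientation.
    """
    if isinstance(haplotypes, Genome):
        haplotypes = (haplotypes,)
    else:
        haplotypes = tuple(haplotypes)
    names = haplotypes[0].names
    lengths = np.array([haplotypes[0].lengths[n] for n in names], dtype=np.int64)
    rl = spec.read_length
    min_scaffold = int(lengths.min())
    if spec.kind == "single_end":
        if rl > min_scaffold:
            raise ParameterError("read_length exceeds a scaffold length")
    else:
        if spec.insert_mean > min_scaffold:
            raise ParameterError("insert_mean exceeds a scaffold length")

    genome_len = int(np.mean([g.total_length for g in haplotypes]))
    n = int(round(spec.coverage * genome_len / spec.bases_per_fragment))
    rng = np.random.default_rng(seed)

    hap = (rng.integers(0, len(haplotypes), size=n)
           if len(haplotypes) > 1 else np.zeros(n, dtype=np.int64))
    scaf = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    codes_by_hap = [{name: g.codes(name) for name in names} for g in haplotypes]

    if spec.kind == "single_end":
        span = np.full(n, rl, dtype=np.int64)
    else:
        ins = np.round(rng.normal(spec.insert_mean, spec.insert_sd, size=n)).astype(np.int64)
        span = np.clip(ins, 2 * rl, lengths[scaf])
    pos = np.floor(rng.random(n) * (lengths[scaf] - span + 1)).astype(np.int64)
    flip = rng.integers(0, 2, size=n).astype(bool)

    def gather(offset_pos, length):
        segs = np.empty((n, length), dtype=np.uint8)
        for h in range(len(haplotypes)):
            hrows = hap == h
            segs[hrows] = _extract_segments(
                codes_by_hap[h], scaf[hrows], offset_pos[hrows], length, names)
        return segs

    pair_ids = np.arange(n, dtype=np.int64)
    if spec.kind == "single_end":
        segs = gather(pos, rl)
        _revcomp_rows(segs, np.flatnonzero(flip))
        segs = _apply_errors(segs, spec.error_rate, rng)
        quals = np.tile(spec.quality_profile(rl), (n, 1))
        batch = ReadBatch(codes=segs, quals=quals,
                          lengths=np.full(n, rl, dtype=np.int32),
                          pair_ids=pair_ids, library=spec,
                          name_prefix=spec.name)
        truth = pd.DataFrame({
            "read_index": pair_ids, "mate": 0, "haplotype": hap,
            "scaffold": [names[s] for s in scaf], "position": pos,
            "strand": np.where(flip, "-", "+"),
        })
        return SimulatedReads(spec, [batch], truth)

    # mate pair, FR: upstream mate forward, downstream mate reverse-complement;
    # `flip` samples the fragment from the opposite strand (mate roles swap ends)
    left = gather(pos, rl)
    right = gather(pos + span - rl, rl)
    m1 = np.where(flip[:, None], right, left).astype(np.uint8)
    m2 = np.where(flip[:, None], left, right).astype(np.uint8)
    _revcomp_rows(m1, np.flatnonzero(flip))    # mate1 on '-' when flipped
    _revcomp_rows(m2, np.flatnonzero(~flip))   # mate2 on '-' otherwise
    m1 = _apply_errors(m1, spec.error_rate, rng)
    m2 = _apply_errors(m2, spec.error_rate, rng)
    quals = np.tile(spec.quality_profile(rl), (n, 1))
    batches = [
        ReadBatch(codes=m1, quals=quals.copy(), lengths=np.full(n, rl, np.int32),
                  pair_ids=pair_ids, mate_tag=1, library=spec, name_prefix=spec.name),
        ReadBatch(codes=m2, quals=quals.copy(), lengths=np.full(n, rl, np.int32),
                  pair_ids=pair_ids, mate_tag=2, library=spec, name_prefix=spec.name),
    ]
    pos1 = np.where(flip, pos + span - rl, pos)
    pos2 = np.where(flip, pos, pos + span - rl)
    truth = pd.concat([
        pd.DataFrame({"read_index": pair_ids, "mate": 1, "haplotype": hap,
                      "scaffold": [names[s] for s in scaf], "position": pos1,
                      "strand": np.where(flip, "-", "+")}),
        pd.DataFrame({"read_index": pair_ids, "mate": 2, "haplotype": hap,
                      "scaffold": [names[s] for s in scaf], "position": pos2,
                      "strand": np.where(flip, "+", "-")}),
    ], ignore_index=True)
    return SimulatedReads(spec, batches, truth)
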