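"""Heterozygous SNP calling on the draft genome and summary statistics.

The caller is an explicit diallelic genotype-likelihood model: at each
pileup column within the coverage window, the two candidate alleles are
the draft base and the most frequent non-draft base; reads are treated as
independent draws with per-base error ``e`` (a wrong base is any of the
three alternatives with probability ``e/3``; a heterozygote emits either
allele with probability 1/2).  The maximum-a-posteriori genotype under a
flat prior is reported when it differs from homozygous-reference and its
phred-scaled confidence passes the threshold.

The coverage window is given as absolute 50-100X cutoffs or as
mean-relative factors for scaled-down runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import seqcodec
from .errors import ParameterError
from .genome import Genome, MACRO, INTERMEDIATE, MICRO, Z

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

HOM_REF, HET, HOM_ALT = "hom_ref", "het", "hom_alt"


@dataclass
class SNPRecord:
    scaffold: str
    position: int        # 1-based (output frame)
    ref_allele: str
    alt_allele: str
    genotype: str        # het | hom_alt
    depth: int
    quality: float       # phred-scaled genotype confidence

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ParameterError("ref and alt alleles must differ")


@dataclass
class ChromosomeClass:
    label: str
    members: List[str]


def default_classes(genome: Genome) -> List[ChromosomeClass]:
    """Build chromosome classes from a genome's class map."""
    by_label: Dict[str, List[str]] = {}
    for name, label in genome.chrom_class_map.items():
        by_label.setdefault(label, []).append(name)
    return [ChromosomeClass(label, sorted(members))
            for label, members in sorted(by_label.items())]


@dataclass
class CallingConfig:
    """Coverage window and error model for the SNP caller.

    ``cov_min``/``cov_max`` are absolute depths when ``mean_relative`` is
    False; otherwise they are factors applied to the observed mean depth
    (the scaled-down analogue of fixed 50-100X cutoffs at ~57X mean depth).
    """

    cov_min: float = 50
    cov_max: float = 100
    base_error: float = 0.01
    min_genotype_quality: float = 20.0
    mean_relative: bool = False
    ploidy: int = 2
    gap_exclusion_window: int = 10  # skip calls this close to indel evidence

    def __post_init__(self):
        if not (0 < self.cov_min <= self.cov_max):
            raise ParameterError("need 0 < cov_min <= cov_max")
        if not (0 < self.base_error < 0.5):
            raise ParameterError("base_error must be in (0, 0.5)")
        if self.ploidy != 2:
            raise ParameterError("only diploid calling is supported")

    def window(self, mean_depth: float) -> Tuple[float, float]:
        if self.mean_relative:
            return self.cov_min * mean_depth, self.cov_max * mean_depth
        return self.cov_min, self.cov_max


@dataclass
class CallResult:
    snps: List[SNPRecord]
    mean_depth: float
    counters: Dict[str, int] = field(default_factory=dict)


def genotype_loglikelihoods(n_ref: np.ndarray, n_alt: np.ndarray,
                            n_other: np.ndarray, e: float) -> np.ndarray:
    """Log-likelihoods of (hom_ref, het, hom_alt) for diallelic columns.

    Emission per read: the true allele with probability ``1 - e``, each
    wrong base ``e/3``; a het emits either allele with probability 1/2.
    Returns an (n, 3) array.
    """
    log_true = np.log(1 - e)
    log_err = np.log(e / 3)
    log_het_allele = np.log(0.5 * (1 - e) + 0.5 * (e / 3))
    ll = np.empty((np.size(n_ref), 3), dtype=np.float64)
    ll[:, 0] = n_ref * log_true + (n_alt + n_other) * log_err
    ll[:, 1] = (n_ref + n_alt) * log_het_allele + n_other * log_err
    ll[:, 2] = n_alt * log_true + (n_ref + n_other) * log_err
    return ll


def call_snps(counts: Dict[str, np.ndarray], draft: Genome,
              config: CallingConfig) -> CallResult:
    """Call heterozygous/homozygous-alternative SNPs from pileup matrices.

    ``counts`` maps scaffold -> (6, L) base-count matrices (A,C,G,T,N,del)
    from mapping all filtered reads back onto the draft.  Columns outside
    the coverage window, on N draft bases, or dominated by deletions are
    skipped (counted).  Only the draft base and the single most frequent
    other base are modelled; tri-allelic columns are reduced (counted).
    """
    from scipy.special import logsumexp

    depths_all = np.concatenate([mat[:4].sum(axis=0) for mat in counts.values()])
    covered = depths_all[depths_all > 0]
    mean_depth = float(covered.mean()) if covered.size else 0.0
    lo, hi = config.window(mean_depth)

    counters = {"columns_tested": 0, "n_reference_skipped": 0,
                "out_of_window": 0, "deletion_dominant": 0,
                "triallelic_reduced": 0, "low_quality": 0, "near_gap": 0}
    snps: List[SNPRecord] = []

    for name, mat in counts.items():
        ref_codes = draft.codes(name)
        base = mat[:4].astype(np.int64)
        depth = base.sum(axis=0)
        # candidate columns: at least one non-reference base observation
        ref_safe = ref_codes.clip(max=3).astype(np.int64)
        ref_counts = np.take_along_axis(base, ref_safe[None, :], axis=0)[0]
        ref_counts[ref_codes >= 4] = 0
        has_alt = (depth - ref_counts) > 0
        cand = np.flatnonzero(has_alt & (depth > 0))
        if cand.size == 0:
            continue

        is_n = ref_codes[cand] >= 4
        counters["n_reference_skipped"] += int(is_n.sum())
        cand = cand[~is_n]
        in_window = (depth[cand] >= lo) & (depth[cand] <= hi)
        counters["out_of_window"] += int((~in_window).sum())
        cand = cand[in_window]
        if cand.size == 0:
            continue

        # sites adjacent to indel evidence are alignment-artifact prone
        # (the varFilter-style gap exclusion); insertion evidence is in the
        # pileup's seventh row when present
        w = config.gap_exclusion_window
        if w > 0:
            support = np.maximum(2, 0.05 * depth)
            gap_ev = mat[5] >= support
            if mat.shape[0] > 6:
                gap_ev |= mat[6] >= support
            if gap_ev.any():
                from scipy.ndimage import binary_dilation

                near = binary_dilation(gap_ev, np.ones(2 * w + 1, dtype=bool))
                hit = near[cand]
                counters["near_gap"] += int(hit.sum())
                cand = cand[~hit]
                if cand.size == 0:
                    continue

        sub = base[:, cand]
        refc = ref_safe[cand]
        n_ref = sub[refc, np.arange(cand.size)]
        masked = sub.copy()
        masked[refc, np.arange(cand.size)] = -1
        altc = masked.argmax(axis=0)
        n_alt = sub[altc, np.arange(cand.size)]
        n_other = depth[cand] - n_ref - n_alt
        counters["triallelic_reduced"] += int((n_other > 0).sum())

        del_dom = mat[5, cand] > np.maximum(n_ref, n_alt)
        counters["deletion_dominant"] += int(del_dom.sum())
        keep = ~del_dom
        cand, refc, altc = cand[keep], refc[keep], altc[keep]
        n_ref, n_alt, n_other = n_ref[keep], n_alt[keep], n_other[keep]
        if cand.size == 0:
            continue
        counters["columns_tested"] += int(cand.size)

        ll = genotype_loglikelihoods(n_ref, n_alt, n_other, config.base_error)
        best = ll.argmax(axis=1)
        total = logsumexp(ll, axis=1)
        p_best = ll[np.arange(ll.shape[0]), best] - total
        with np.errstate(divide="ignore"):
            quality = -10.0 / np.log(10.0) * np.log1p(-np.exp(np.minimum(p_best, -1e-12)))
        quality = np.minimum(quality, 99.0)

        emit = best > 0
        pass_q = quality >= config.min_genotype_quality
        counters["low_quality"] += int((emit & ~pass_q).sum())
        emit &= pass_q
        for i in np.flatnonzero(emit):
            snps.append(SNPRecord(
                scaffold=name,
                position=int(cand[i]) + 1,
                ref_allele=seqcodec.decode(np.array([refc[i]], dtype=np.uint8)),
                alt_allele=seqcodec.decode(np.array([altc[i]], dtype=np.uint8)),
                genotype=HET if best[i] == 1 else HOM_ALT,
                depth=int(n_ref[i] + n_alt[i] + n_other[i]),
                quality=float(quality[i]),
            ))
    return CallResult(snps=snps, mean_depth=mean_depth, counters=counters)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class TsTvResult:
    transitions: int
    transversions: int
    ratio: float                     # nan when no transversions
    type_counts: Dict[str, int]      # unordered pair label -> count

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ratio)


def tstv(snps: Sequence[SNPRecord]) -> TsTvResult:
    """Transition/transversion ratio with per-type counts.

    Transitions are A<->G and C<->T; the four other unordered allele pairs
    are transversions.  With zero transversions the ratio is reported as
    NaN (undefined marker) with the counts intact.
    """
    type_counts: Dict[str, int] = {}
    ts = tv = 0
    for snp in snps:
        pair = "/".join(sorted((snp.ref_allele, snp.alt_allele)))
        type_counts[pair] = type_counts.get(pair, 0) + 1
        if (snp.ref_allele, snp.alt_allele) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    ratio = ts / tv if tv else float("nan")
    return TsTvResult(ts, tv, ratio, type_counts)


def snp_density(snps: Sequence[SNPRecord], draft: Genome,
                classes: Sequence[ChromosomeClass]) -> pd.DataFrame:
    """Per-chromosome-class SNP counts and densities.

    Density is SNPs per sequenced (non-N) draft site, in percent.  A
    genome-wide row is always included; SNPs on scaffolds missing from all
    classes count only there (with a warning).
    """
    import warnings

    scaffold_to_class: Dict[str, str] = {}
    for cls in classes:
        for member in cls.members:
            scaffold_to_class[member] = cls.label

    by_class: Dict[str, List[SNPRecord]] = {cls.label: [] for cls in classes}
    unclassed = 0
    for snp in snps:
        label = scaffold_to_class.get(snp.scaffold)
        if label is None:
            unclassed += 1
        else:
            by_class[label].append(snp)
    if unclassed:
        warnings.warn(f"{unclassed} SNPs on scaffolds outside every class")

    non_n = {name: draft.non_n_count(name) for name in draft.names}
    rows = []
    order = [MACRO, INTERMEDIATE, MICRO, Z]
    labels = sorted(by_class, key=lambda x: (order.index(x) if x in order else 99, x))
    for label in labels:
        cls_members = next(c.members for c in classes if c.label == label)
        denom = sum(non_n.get(m, 0) for m in cls_members)
        cls_snps = by_class[label]
        tt = tstv(cls_snps)
        rows.append({
            "class": label, "n_snps": len(cls_snps),
            "non_n_sites": denom,
            "density_pct": 100.0 * len(cls_snps) / denom if denom else 0.0,
            "zero_denominator": denom == 0,
            "transitions": tt.transitions, "transversions": tt.transversions,
            "tstv": tt.ratio,
        })
    tt = tstv(list(snps))
    total_non_n = sum(non_n.values())
    rows.append({
        "class": "genome", "n_snps": len(list(snps)),
        "non_n_sites": total_non_n,
        "density_pct": 100.0 * len(list(snps)) / total_non_n if total_non_n else 0.0,
        "zero_denominator": total_non_n == 0,
        "transitions": tt.transitions, "transversions": tt.transversions,
        "tstv": tt.ratio,
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF output (minimal v4.2)
# ---------------------------------------------------------------------------

def write_vcf(path, snps: Sequence[SNPRecord], draft: Genome,
              sample: str = "individual") -> None:
    """Minimal single-sample VCF: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name in draft.names:
            fh.write(f"##contig=<ID={name},length={draft.lengths[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        ordered = sorted(snps, key=lambda s: (draft.names.index(s.scaffold), s.position))
        for snp in ordered:
            gt = "0/1" if snp.genotype == HET else "1/1"
            fh.write(f"{snp.scaffold}\t{snp.position}\t.\t{snp.ref_allele}\t"
                     f"{snp.alt_allele}\t{snp.quality:.0f}\tPASS\t"
                     f"DP={snp.depth}\tGT\t{gt}\n")
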