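"""Pipeline configuration: one document holding every numeric knob.

Defaults are the tuning this kind of short-read reference-guided
workflow is run with: FASTQ quality threshold 30 with minimum
trimmed lengths of 60 bp (single-end) / 50 bp (mate-pair); k-mer sweep
15-55 stepped by 2; contigs of at least 1 kb mapped to the reference and
of at least 100 bp used for gap filling; unplaced contigs kept from
200 bp; SNP-calling coverage window 50-100X (or mean-relative factors
0.874-1.748, the same window expressed against a ~57X mean depth);
10 kb comparator pieces, 50 kb divergence windows, 0.2 region cutoff and
1e-10 reciprocal-best-hit e-value cutoff.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from .errors import ParameterError


@dataclass
class SimulationConfig:
    """The synthetic fixture: 3 scaffolds (2 autosomes + 1 Z-classed),
    2% background divergence with a 1.5x faster Z, one 50 kb island at
    rate 0.25, heterozygosity 1e-3, and libraries mirroring the 75 bp
    single-end + 60x60 bp mate-pair (2 kb and 5 kb inserts) design."""

    scaffold_lengths: List[int] = field(default_factory=lambda: [900_000, 700_000, 400_000])
    scaffold_names: List[str] = field(default_factory=lambda: ["chr1", "chr2", "chrZ"])
    chrom_classes: List[str] = field(default_factory=lambda: ["macro", "micro", "Z"])
    gc: float = 0.42
    sub_rate: float = 0.02
    indel_rate: float = 0.0002
    z_multiplier: float = 1.5
    divergent_segment_scaffold: str = "chr1"
    divergent_segment_start: int = 500_000
    divergent_segment_length: int = 50_000
    divergent_segment_rate: float = 0.25
    het_rate: float = 0.001
    ts_bias: float = 2.0
    se_read_length: int = 75
    se_coverage: float = 20.0
    mp_read_length: int = 60
    mp_coverages: List[float] = field(default_factory=lambda: [20.0, 20.0])
    mp_insert_means: List[int] = field(default_factory=lambda: [2000, 5000])
    mp_insert_sds: List[float] = field(default_factory=lambda: [200.0, 500.0])
    error_rate: float = 0.001  # post-filter error rate of the emulated platform
    n_genes: int = 40
    decoy_scaffolds: int = 2
    decoy_length: int = 20_000


@dataclass
class PipelineConfig:
    # preprocess
    quality_threshold: int = 30
    min_read_length_se: int = 60
    min_read_length_mp: int = 50
    # assemble
    k_min: int = 15
    k_max: int = 55
    k_step: int = 2
    k_fixed: Optional[int] = None          # skip the sweep when set
    sweep_subsample: Optional[float] = 0.1 # sweep on this read fraction
    min_contig_length: int = 100
    min_kmer_count: int = 2
    # align
    min_contig_for_reference_mapping: int = 1000
    min_contig_for_gapfill: int = 100
    min_unplaced_contig: int = 200
    coverage_low_factor: float = 0.5
    coverage_high_factor: float = 2.0
    pair_k_sd: float = 4.0
    # variants
    cov_min: float = 50
    cov_max: float = 100
    cov_mean_relative: bool = False
    base_error: float = 0.01
    min_genotype_quality: float = 20.0
    # compare
    piece_size: int = 10_000
    window_size: int = 50_000
    min_aligned_fraction: float = 0.1
    divergence_cutoff: float = 0.2
    evalue_cutoff: float = 1e-10
    # scaffold
    consensus_min_depth: int = 1
    self_fragment_size: int = 10_000
    gapfill_mode: str = "literal"
    # seeds
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.k_min % 2 == 0 or self.k_step % 2 != 0:
            raise ParameterError("k range must be odd-aligned with an even step")
        if not (0 < self.cov_min <= self.cov_max):
            raise ParameterError("need 0 < cov_min <= cov_max")
        for value in (self.quality_threshold, self.min_read_length_se,
                      self.min_read_length_mp, self.min_contig_length,
                      self.piece_size, self.window_size):
            if value <= 0:
                raise ParameterError("thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})
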