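"""Genome container shared by the simulator, aligner and scaffolder."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import seqcodec
from .errors import ParameterError

# chromosome-class labels used for density / divergence contrasts
MACRO, INTERMEDIATE, MICRO, Z = "macro", "intermediate", "micro", "Z"


@dataclass
class Genome:
    """An ordered set of named scaffolds over {A,C,G,T,N}.

    ``chrom_class_map`` optionally assigns each scaffold a chromosome-size
    class (macro / intermediate / micro / Z) used by the SNP-density and
    divergence summaries.
    """

    scaffolds: List[Tuple[str, str]]
    chrom_class_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = [name for name, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ParameterError("scaffold names must be unique")
        for name, seq in self.scaffolds:
            if len(seq) == 0:
                raise ParameterError(f"scaffold {name!r} is empty")
        self._codes: Dict[str, np.ndarray] = {}

    @property
    def names(self) -> List[str]:
        return [name for name, _ in self.scaffolds]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.scaffolds)

    def sequence(self, name: str) -> str:
        for n, seq in self.scaffolds:
            if n == name:
                return seq
        raise KeyError(name)

    def codes(self, name: str) -> np.ndarray:
        """uint8 code array for one scaffold (cached)."""
        if name not in self._codes:
            self._codes[name] = seqcodec.encode(self.sequence(name))
        return self._codes[name]

    def replace_sequences(self, new: Dict[str, str]) -> "Genome":
        scaffolds = [(name, new.get(name, seq)) for name, seq in self.scaffolds]
        return Genome(scaffolds, dict(self.chrom_class_map))

    def write_fasta(self, path) -> None:
        seqcodec.write_fasta(path, self.scaffolds)

    @classmethod
    def from_fasta(cls, path, chrom_class_map: Optional[Dict[str, str]] = None) -> "Genome":
        return cls(seqcodec.read_fasta(path), chrom_class_map or {})

    @classmethod
    def from_codes(cls, coded: List[Tuple[str, np.ndarray]],
                   chrom_class_map: Optional[Dict[str, str]] = None) -> "Genome":
        genome = cls([(name, seqcodec.decode(codes)) for name, codes in coded],
                     chrom_class_map or {})
        for name, codes in coded:
            genome._codes[name] = np.asarray(codes, dtype=np.uint8)
        return genome

    def non_n_count(self, name: str) -> int:
        return int(np.sum(self.codes(name) != seqcodec.N))
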