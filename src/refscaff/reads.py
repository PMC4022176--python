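"""In-memory read containers.

Reads are carried through the pipeline as dense batches (one uint8 matrix
for bases, one for qualities, plus a per-read length vector) rather than
as per-read objects; the object view :class:`SequencingRead` is generated
on demand at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import seqcodec
from .errors import FormatError, ParameterError


@dataclass
class LibrarySpec:
    """Description of a sequencing library.

    ``kind`` is ``"single_end"`` or ``"mate_pair"``.  For mate pairs the
    insert is the outer fragment length spanned by the two reads, and
    ``orientation`` declares the simulated/expected relative orientation
    ("FR": the upstream mate on the forward strand, the downstream mate
    reverse-complemented).
    """

    kind: str
    read_length: int
    coverage: float
    error_rate: float = 0.0
    insert_mean: Optional[int] = None
    insert_sd: Optional[float] = None
    quality_model: str = "constant"  # "constant" | "decay"
    quality_value: int = 40
    quality_floor: int = 10
    name: str = "lib"
    orientation: str = "FR"

    def __post_init__(self):
        if self.kind not in ("single_end", "mate_pair"):
            raise ParameterError(f"unknown library kind {self.kind!r}")
        if self.read_length <= 0:
            raise ParameterError("read_length must be positive")
        if self.coverage <= 0:
            raise ParameterError("coverage must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ParameterError("error_rate must be in [0, 0.5)")
        if self.kind == "mate_pair":
            if self.insert_mean is None or self.insert_sd is None:
                raise ParameterError("mate_pair libraries need insert_mean and insert_sd")
            if self.insert_mean <= 2 * self.read_length:
                raise ParameterError("insert_mean must exceed 2 * read_length")

    @property
    def bases_per_fragment(self) -> int:
        return self.read_length * (2 if self.kind == "mate_pair" else 1)

    def quality_profile(self, length: int) -> np.ndarray:
        """Per-position Phred profile for a read of ``length`` bases."""
        if self.quality_model == "constant":
            return np.full(length, self.quality_value, dtype=np.uint8)
        if self.quality_model == "decay":
            q = np.linspace(self.quality_value, self.quality_floor, length)
            return np.round(q).astype(np.uint8)
        raise ParameterError(f"unknown quality model {self.quality_model!r}")


@dataclass
class SequencingRead:
    """Object view of a single read (API boundary type)."""

    id: str
    sequence: str
    qualities: np.ndarray
    mate_tag: Optional[int] = None  # None | 1 | 2
    library: Optional[LibrarySpec] = None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


@dataclass
class ReadBatch:
    """Dense batch of reads of bounded length.

    ``codes``/``quals`` are ``(n, max_len)`` uint8 matrices; only the first
    ``lengths[i]`` entries of row ``i`` are meaningful.  ``pair_ids`` holds a
    shared integer fragment identifier for mate batches.
    """

    codes: np.ndarray
    quals: np.ndarray
    lengths: np.ndarray
    names: Optional[list] = None
    pair_ids: Optional[np.ndarray] = None
    mate_tag: Optional[int] = None
    library: Optional[LibrarySpec] = None
    name_prefix: str = "read"

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def read_name(self, i: int) -> str:
        if self.names is not None:
            return self.names[i]
        base = (
            f"{self.name_prefix}:{self.pair_ids[i]}"
            if self.pair_ids is not None
            else f"{self.name_prefix}:{i}"
        )
        return f"{base}/{self.mate_tag}" if self.mate_tag else base

    def subset(self, index: np.ndarray) -> "ReadBatch":
        return ReadBatch(
            codes=self.codes[index],
            quals=self.quals[index],
            lengths=self.lengths[index],
            names=[self.names[i] for i in np.flatnonzero(index)] if isinstance(self.names, list) and index.dtype == bool else (
                [self.names[i] for i in index] if self.names is not None else None),
            pair_ids=self.pair_ids[index] if self.pair_ids is not None else None,
            mate_tag=self.mate_tag,
            library=self.library,
            name_prefix=self.name_prefix,
        )

    def iter_records(self) -> Iterable[SequencingRead]:
        for i in range(self.n):
            L = int(self.lengths[i])
            yield SequencingRead(
                id=self.read_name(i),
                sequence=seqcodec.decode(self.codes[i, :L]),
                qualities=self.quals[i, :L].astype(np.int16),
                mate_tag=self.mate_tag,
                library=self.library,
            )

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(self.n):
                L = int(self.lengths[i])
                seq = seqcodec.decode(self.codes[i, :L])
                qual = seqcodec.phred_to_ascii(self.quals[i, :L])
                fh.write(f"@{self.read_name(i)}\n{seq}\n+\n{qual}\n")


def batch_from_records(records: Iterable[SequencingRead],
                       library: Optional[LibrarySpec] = None,
                       mate_tag: Optional[int] = None) -> ReadBatch:
    """Pack an iterable of :class:`SequencingRead` into a :class:`ReadBatch`."""
    records = list(records)
    if not records:
        return ReadBatch(
            codes=np.zeros((0, 1), dtype=np.uint8),
            quals=np.zeros((0, 1), dtype=np.uint8),
            lengths=np.zeros(0, dtype=np.int32),
            names=[],
            mate_tag=mate_tag,
            library=library,
        )
    max_len = max(len(r.sequence) for r in records)
    n = len(records)
    codes = np.full((n, max_len), seqcodec.N, dtype=np.uint8)
    quals = np.zeros((n, max_len), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int32)
    names = []
    for i, rec in enumerate(records):
        L = len(rec.sequence)
        codes[i, :L] = seqcodec.encode(rec.sequence)
        quals[i, :L] = np.asarray(rec.qualities, dtype=np.uint8)
        lengths[i] = L
        names.append(rec.id)
    return ReadBatch(codes=codes, quals=quals, lengths=lengths, names=names,
                     mate_tag=mate_tag, library=library)


def batch_from_fastq(path, library: Optional[LibrarySpec] = None,
                     mate_tag: Optional[int] = None) -> ReadBatch:
    """Load a FASTQ file into a :class:`ReadBatch`."""
    names, seqs, quals = [], [], []
    for name, seq, qual in seqcodec.iter_fastq(path):
        names.append(name)
        seqs.append(seq)
        quals.append(qual)
    if not seqs:
        return batch_from_records([], library=library, mate_tag=mate_tag)
    max_len = max(len(s) for s in seqs)
    n = len(seqs)
    codes = np.full((n, max_len), seqcodec.N, dtype=np.uint8)
    qmat = np.zeros((n, max_len), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int32)
    for i, (s, q) in enumerate(zip(seqs, quals)):
        L = len(s)
        codes[i, :L] = seqcodec.encode(s)
        qmat[i, :L] = seqcodec.ascii_to_phred(q).astype(np.uint8)
        lengths[i] = L
    return ReadBatch(codes=codes, quals=qmat, lengths=lengths, names=names,
                     mate_tag=mate_tag, library=library)
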