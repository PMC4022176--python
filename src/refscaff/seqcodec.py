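"""Numeric sequence codec and small-format I/O helpers.

Sequences are held internally as ``uint8`` arrays with the coding
A=0, C=1, G=2, T=3, N=4 (anything else also maps to N).  The first four
codes are chosen so that ``3 - code`` is the Watson-Crick complement and
so that ``argmax`` ties resolve to the lexicographically smallest base.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an upper-case string."""
    return _DECODE[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (N maps to N)."""
    return _COMPLEMENT[codes[::-1]]


def phred_to_ascii(quals: np.ndarray) -> str:
    """Sanger Phred+33 encoding of a quality array."""
    return (quals.astype(np.uint8) + 33).tobytes().decode("ascii")


def ascii_to_phred(qual_str: str) -> np.ndarray:
    arr = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8)
    return (arr - 33).astype(np.int16)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(name, sequence), ...]`` (upper-cased)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records, width: int = 70) -> None:
    """Write ``(name, sequence)`` or ``(name, sequence, description)`` records."""
    seq_records = []
    for rec in records:
        name, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        seq_records.append(SeqRecord(Seq(seq), id=name, description=desc))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# FASTQ (Sanger Phred+33)
# ---------------------------------------------------------------------------

def iter_fastq(path):
    """Yield ``(name, sequence, quality_string)`` tuples from a FASTQ file.

    Raises :class:`FormatError` naming the record when sequence and quality
    lengths disagree.
    """
    import pysam

    last = None
    with pysam.FastxFile(str(path)) as fh:
        while True:
            try:
                entry = next(fh)
            except StopIteration:
                return
            except ValueError as exc:
                after = f" (after record {last!r})" if last else ""
                raise FormatError(f"malformed FASTQ in {path}{after}: {exc}") from exc
            if entry.quality is None or len(entry.sequence) != len(entry.quality):
                raise FormatError(
                    f"FASTQ record {entry.name!r}: sequence and quality lengths differ"
                )
            last = entry.name
            yield entry.name, entry.sequence, entry.quality


def write_fastq(path, reads) -> None:
    """Write ``(name, sequence, quality_string)`` tuples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
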