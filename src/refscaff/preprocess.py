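"""Quality/length filtering of raw reads and mate re-pairing.

Filtering trims each read at the 3' end so that every remaining base has
quality at or above the threshold (the longest such truncation), then
discards reads shorter than the library's minimum length.  Mates filtered
independently are paired again afterwards; survivors whose mate was lost
become singletons and are carried into assembly and SNP mapping but not
into pair-anchored backbone mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .reads import ReadBatch


@dataclass
class FilterReport:
    """Per-library tally of the filtering outcome."""

    library: str
    input: int
    retained: int
    discarded: int
    full_length: int

    def as_row(self) -> dict:
        return {
            "library": self.library, "input": self.input,
            "retained": self.retained, "discarded": self.discarded,
            "full_length": self.full_length,
        }


@dataclass
class FilterResult:
    retained: ReadBatch
    report: FilterReport
    kept_mask: np.ndarray


def filter_reads(batch: ReadBatch, quality_threshold: int, min_length: int,
                 mode: str = "tail") -> FilterResult:
    """Trim and length-filter a read batch.

    ``mode="tail"`` (default) truncates at the first sub-threshold base so
    the retained prefix is entirely at or above the threshold;
    ``mode="mean"`` keeps untrimmed reads whose mean quality passes instead.
    Retained + discarded always equals the input count.
    """
    if quality_threshold < 0:
        raise ParameterError("quality_threshold must be >= 0")
    if min_length < 1:
        raise ParameterError("min_length must be >= 1")
    if mode not in ("tail", "mean"):
        raise ParameterError(f"unknown filter mode {mode!r}")

    n, width = batch.codes.shape
    if n == 0:
        report = FilterReport(batch.library.name if batch.library else "lib", 0, 0, 0, 0)
        return FilterResult(batch, report, np.zeros(0, dtype=bool))

    cols = np.arange(width)
    in_read = cols[None, :] < batch.lengths[:, None]
    if mode == "tail":
        bad = (batch.quals < quality_threshold) & in_read
        first_bad = np.where(bad.any(axis=1), bad.argmax(axis=1), batch.lengths)
        new_lengths = first_bad.astype(np.int32)
    else:
        sums = np.where(in_read, batch.quals, 0).sum(axis=1)
        means = sums / np.maximum(batch.lengths, 1)
        new_lengths = np.where(means >= quality_threshold, batch.lengths, 0).astype(np.int32)

    keep = new_lengths >= min_length
    retained = batch.subset(keep)
    retained.lengths = new_lengths[keep]
    report = FilterReport(
        library=batch.library.name if batch.library else "lib",
        input=int(n),
        retained=int(keep.sum()),
        discarded=int(n - keep.sum()),
        full_length=int(((new_lengths == batch.lengths) & keep).sum()),
    )
    return FilterResult(retained, report, keep)


def repair_pairs(mate1: ReadBatch, mate2: ReadBatch
                 ) -> Tuple[Tuple[ReadBatch, ReadBatch], ReadBatch]:
    """Re-pair independently filtered mate batches.

    Returns ``((pairs1, pairs2), singletons)``: a pair survives iff both
    mates did; lone survivors are concatenated into the singleton batch.
    ``2 * n_pairs + n_singletons`` equals the total surviving reads.
    """
    for side in (mate1, mate2):
        if side.pair_ids is None:
            raise FormatError("mate batches must carry pair identifiers")
        ids = side.pair_ids
        if np.unique(ids).size != ids.size:
            raise FormatError("duplicate pair identifier on one side")

    common, idx1, idx2 = np.intersect1d(mate1.pair_ids, mate2.pair_ids,
                                        return_indices=True)
    pairs = (mate1.subset(idx1), mate2.subset(idx2))
    lone1 = mate1.subset(np.setdiff1d(np.arange(mate1.n), idx1))
    lone2 = mate2.subset(np.setdiff1d(np.arange(mate2.n), idx2))
    singles = _concat_batches(lone1, lone2)
    return pairs, singles


def _concat_batches(a: ReadBatch, b: ReadBatch) -> ReadBatch:
    import numpy as np

    width = max(a.codes.shape[1], b.codes.shape[1], 1)

    def pad(batch):
        if batch.codes.shape[1] == width:
            return batch.codes, batch.quals
        codes = np.full((batch.n, width), 4, dtype=np.uint8)
        quals = np.zeros((batch.n, width), dtype=np.uint8)
        codes[:, :batch.codes.shape[1]] = batch.codes
        quals[:, :batch.quals.shape[1]] = batch.quals
        return codes, quals

    ca, qa = pad(a)
    cb, qb = pad(b)
    names = None
    if a.names is not None or b.names is not None:
        names = ([a.read_name(i) for i in range(a.n)]
                 + [b.read_name(i) for i in range(b.n)])
    return ReadBatch(
        codes=np.concatenate([ca, cb]),
        quals=np.concatenate([qa, qb]),
        lengths=np.concatenate([a.lengths, b.lengths]),
        names=names,
        pair_ids=None,
        library=a.library or b.library,
        name_prefix=a.name_prefix,
    )


def filtering_report_frame(reports) -> pd.DataFrame:
    """Assemble per-library :class:`FilterReport` rows into one table."""
    return pd.DataFrame([r.as_row() for r in reports])
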