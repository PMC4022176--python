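"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (explicit loops, no shared code
with the package's fast paths) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

NEG = -(10 ** 9)


def glocal_dp_score(query: str, target: str, match=1, mismatch=3,
                    gap_open=5, gap_extend=2) -> int:
    """Unbanded affine-gap DP: full query against any target substring.

    Three-state Gotoh over (m+1)x(n+1); leading/trailing target bases are
    free, query gaps (insertions) are charged everywhere, N is neutral.
    """
    m, n = len(query), len(target)
    go = gap_open + gap_extend
    ge = gap_extend

    def s(a, b):
        if a == "N" or b == "N":
            return 0
        return match if a == b else -mismatch

    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (query consumed)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (target consumed)
    for j in range(n + 1):
        M[0][j] = 0  # free leading target
    for i in range(1, m + 1):
        Ix[i][0] = max(M[i - 1][0] - go, Ix[i - 1][0] - ge)
        for j in range(1, n + 1):
            sc = s(query[i - 1], target[j - 1])
            M[i][j] = sc + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - go, Ix[i - 1][j] - ge, Iy[i - 1][j] - go)
            Iy[i][j] = max(M[i][j - 1] - go, Ix[i][j - 1] - go, Iy[i][j - 1] - ge)
    return max(max(M[m][j], Ix[m][j]) for j in range(n + 1))  # free trailing target


def brute_pileup(length: int, observations) -> np.ndarray:
    """(6, length) base counts from (start, codes, cigar) observations.

    ``codes`` is the query in aligned orientation; cigar ops M/I/D/S.
    """
    mat = np.zeros((6, length), dtype=np.int64)
    for start, codes, cigar in observations:
        q, t = 0, start
        for op, n in cigar:
            if op == "M":
                for i in range(n):
                    mat[codes[q + i], t + i] += 1
                q += n
                t += n
            elif op == "I" or op == "S":
                q += n
            elif op == "D":
                for i in range(n):
                    mat[5, t + i] += 1
                t += n
    return mat


def majority_consensus(column_counts: np.ndarray, ref_base: int,
                       min_depth: int = 1, masked: bool = False) -> int:
    """Expected consensus code for one column (6 counts); 4 means N."""
    bases = column_counts[:4]
    best = int(max(bases))
    if masked or best == 0 or int(sum(bases)) < min_depth:
        return 4
    if column_counts[5] > best:
        return 4
    winners = [b for b in range(4) if bases[b] == best]
    if ref_base in winners:
        return ref_base
    return winners[0]


def n50_recount(lengths) -> int:
    """N50 by explicit scan."""
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable for non-empty input")


def window_recount(aligned: np.ndarray, variable: np.ndarray, window: int):
    """Per-window (aligned, variable) counts by explicit slicing."""
    out = []
    for start in range(0, aligned.size, window):
        a = int(aligned[start:start + window].sum())
        v = int(variable[start:start + window].sum())
        out.append((a, v))
    return out


def count_kmers_dict(seqs, k: int) -> dict:
    """Canonical k-mer counts via plain string handling."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if set(kmer) - set("ACGT"):
                continue
            rc = kmer.translate(comp)[::-1]
            canon = min(kmer, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts
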