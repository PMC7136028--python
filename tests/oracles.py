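"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most direct method available
(position-by-position scans, memoised recursion over all alignments, pooled
ECDF enumeration) and deliberately shares no code with the implementation.
"""

from functools import lru_cache

import numpy as np


def naive_cpg_counts(sequence: str) -> tuple[int, int, int, int]:
    """Position-by-position dinucleotide scan: (n_cpg, n_c, n_g, length)."""
    seq = sequence.upper()
    n_cpg = sum(
        1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
    )
    n_c = sum(1 for b in seq if b == "C")
    n_g = sum(1 for b in seq if b == "G")
    length = sum(1 for b in seq if b != "N")
    return n_cpg, n_c, n_g, length


def naive_cpg_ratio(sequence: str) -> float:
    n_cpg, n_c, n_g, length = naive_cpg_counts(sequence)
    return n_cpg * length / (n_c * n_g) if n_c * n_g else 0.0


def brute_force_alignment_score(
    ref: str,
    read: str,
    snp_offset: int | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Optimal global alignment score by recursion over all three moves.

    Bisulfite-asymmetric substitution: ref C vs read T is a match; at the
    SNP offset read A/C/T all count as match.
    """

    def sub(i: int, j: int) -> float:
        a, b = ref[i], read[j]
        if snp_offset is not None and i == snp_offset and b in "ACT":
            return match  # A/C/T never penalized at the SNP; G falls through
        if a == b or (a == "C" and b == "T"):
            return match
        return mismatch

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(ref) and j == len(read):
            return 0.0
        options = []
        if i < len(ref) and j < len(read):
            options.append(sub(i, j) + best(i + 1, j + 1))
        if i < len(ref):
            options.append(gap + best(i + 1, j))
        if j < len(read):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def brute_force_ks_d(x, y) -> float:
    """sup |ECDF_x - ECDF_y| over all pooled breakpoints."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def rank_based_quartiles(values) -> list[str]:
    """Sort-and-split quartile assignment honouring tie-to-lower-quartile."""
    values = np.asarray(values, dtype=float)
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    labels = []
    for v in values:
        if v <= q25:
            labels.append("Q1")
        elif v <= q50:
            labels.append("Q2")
        elif v <= q75:
            labels.append("Q3")
        else:
            labels.append("Q4")
    return labels
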