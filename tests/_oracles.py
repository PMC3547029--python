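"""Independent oracles used by the test suite.

These deliberately avoid the package's scanning/indexing code paths:
the array oracle enumerates (start, period) pairs exhaustively with
plain string operations; the flank oracle rasterizes qualifying window
starts into a boolean mask; the read-truncation oracle is a closed form
under uniform read placement.
"""

from __future__ import annotations

import numpy as np

_ACGT = set("ACGT")


def _span_smallest_period(s: str) -> int:
    n = len(s)
    for p in range(1, n):
        if all(s[i] == s[i + p] for i in range(n - p)):
            return p
    return n


def brute_force_arrays(
    seq: str, k_min: int = 1, k_max: int = 3, min_len_bp: int | None = None
) -> list[tuple[int, int, int, str, str]]:
    """Exhaustive enumeration of maximal perfect arrays.

    Returns sorted (start, end, period, start_kmer, end_kmer) tuples for
    every maximal run of exact period-k repetition whose smallest period
    equals k and whose length passes the minimum (default 3k).
    """
    s = seq.upper()
    n = len(s)
    found: set[tuple[int, int, int]] = set()
    out = []
    for k in range(k_min, k_max + 1):
        mlen = 3 * k if min_len_bp is None else max(min_len_bp, k + 1)
        mlen = max(mlen, k + 1)
        for i in range(n - k):
            if any(c not in _ACGT for c in s[i : i + k]):
                continue
            # left-maximality
            if i > 0 and s[i - 1] in _ACGT and s[i - 1] == s[i - 1 + k]:
                continue
            j = i + k
            while j < n and s[j] in _ACGT and s[j] == s[j - k]:
                j += 1
            if j - i < mlen:
                continue
            if _span_smallest_period(s[i:j]) != k:
                continue
            if (i, j, k) not in found:
                found.add((i, j, k))
                out.append((i, j, k, s[i : i + k], s[j - k : j]))
    out.sort()
    return out


def brute_force_background_proportion(
    genome_seq: str,
    te_lengths: list[int],
    min_bp: int = 10,
    window: int = 50,
    arrays: list[tuple[int, int]] | None = None,
) -> float:
    """Probability a uniformly placed TE has >= min_bp of one array in a
    flank window, by exhaustive counting over interior placements.

    ``arrays`` is a list of (start, end) spans of qualifying arrays; if
    None they are enumerated with :func:`brute_force_arrays` (periods
    1-3, length >= min_bp).
    """
    n = len(genome_seq)
    if arrays is None:
        arrays = [
            (a, b)
            for a, b, _, _, _ in brute_force_arrays(genome_seq, 1, 3, min_bp)
            if b - a >= min_bp
        ]
    mask = np.zeros(n, dtype=bool)
    for a, b in arrays:
        lo = max(0, a - (window - min_bp))
        hi = min(n - window, b - min_bp)
        if hi >= lo:
            mask[lo : hi + 1] = True
    props = []
    for L in te_lengths:
        starts = np.arange(window, n - L - window)
        qual = mask[starts - window] | mask[starts + L]
        props.append(float(qual.mean()))
    return float(np.mean(props))


def expected_truncated_fraction(
    array_len: int, read_lengths: np.ndarray
) -> float:
    """Closed-form expected fraction of array-overlapping reads that
    truncate the array, under uniform read placement far from edges.

    For read length R there are L + R - 1 start positions overlapping an
    array of length L and max(R - L - 1, 0) positions containing it with
    both flanking bases; the rest truncate it.
    """
    R = np.asarray(read_lengths, dtype=float)
    L = float(array_len)
    overlapping = L + R - 1
    internal = np.maximum(R - L - 1, 0.0)
    return float((overlapping - internal).sum() / overlapping.sum())
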