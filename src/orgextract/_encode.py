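"""Vectorised 2-bit DNA encoding and canonical k-mer extraction.

A k-mer of length k <= 64 is represented by two unsigned 64-bit limbs
(hi, lo): ``lo`` holds the last min(k, 32) bases and ``hi`` the preceding
bases, each base packed big-endian as 2 bits (A=0, C=1, G=2, T=3).
Comparing (hi, lo) tuples numerically is equivalent to comparing the
k-mer strings lexicographically, which is what canonicalisation needs.

Any character outside ACGT (upper or lower case) gets code 4 and
invalidates every window that contains it.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

MAX_K = 64

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_BATCH = 1 << 18


def seq_to_codes(seq: str) -> np.ndarray:
    """Map a DNA string to a uint8 code array (4 = invalid base)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _weights(nbases: int) -> np.ndarray:
    # big-endian base-4 digit weights, highest first
    shifts = 2 * np.arange(nbases - 1, -1, -1, dtype=np.uint64)
    return np.left_shift(np.uint64(1), shifts)


def canonical_kmer_limbs(codes: np.ndarray, k: int):
    """Canonical (hi, lo) limbs for every length-k window of ``codes``.

    Returns ``(hi, lo, valid)`` arrays of length ``len(codes) - k + 1``;
    ``valid`` is False for windows containing a non-ACGT code. Values at
    invalid positions are unspecified.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty.copy(), np.empty(0, dtype=bool)

    bad = np.concatenate(([0], np.cumsum(codes >= 4, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0

    m = min(k, 32)
    hi_len = k - m
    w_lo = _weights(m)
    w_hi = _weights(hi_len) if hi_len else None

    hi = np.zeros(n, dtype=np.uint64)
    lo = np.empty(n, dtype=np.uint64)
    windows = sliding_window_view(codes, k)
    for s in range(0, n, _BATCH):
        e = min(n, s + _BATCH)
        w = windows[s:e].astype(np.uint64)
        f_lo = (w[:, hi_len:] * w_lo).sum(axis=1)
        f_hi = (w[:, :hi_len] * w_hi).sum(axis=1) if hi_len else np.zeros(e - s, dtype=np.uint64)
        # reverse complement: complement codes (3 - c) read right-to-left
        rw = (np.uint64(3) - w)[:, ::-1]
        r_lo = (rw[:, hi_len:] * w_lo).sum(axis=1)
        r_hi = (rw[:, :hi_len] * w_hi).sum(axis=1) if hi_len else np.zeros(e - s, dtype=np.uint64)
        take_r = (r_hi < f_hi) | ((r_hi == f_hi) & (r_lo < f_lo))
        hi[s:e] = np.where(take_r, r_hi, f_hi)
        lo[s:e] = np.where(take_r, r_lo, f_lo)
    return hi, lo, valid


def pooled_canonical_kmers(seqs, k: int, with_seq_index: bool = False):
    """Canonical k-mer limbs over a pool of sequences.

    Sequences are concatenated with a separator code so windows never
    straddle two sequences. Returns ``(hi, lo)`` restricted to valid
    windows; with ``with_seq_index`` also returns the index of the source
    sequence for every emitted k-mer.
    """
    parts = []
    starts = []
    pos = 0
    sep = np.array([4], dtype=np.uint8)
    for s in seqs:
        c = seq_to_codes(s)
        starts.append(pos)
        parts.append(c)
        parts.append(sep)
        pos += len(c) + 1
    if not parts:
        empty = np.empty(0, dtype=np.uint64)
        if with_seq_index:
            return empty, empty.copy(), np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    codes = np.concatenate(parts)
    hi, lo, valid = canonical_kmer_limbs(codes, k)
    idx = np.nonzero(valid)[0]
    if with_seq_index:
        seq_idx = np.searchsorted(np.asarray(starts), idx, side="right") - 1
        return hi[idx], lo[idx], seq_idx
    return hi[idx], lo[idx]


def count_limbs(hi: np.ndarray, lo: np.ndarray, weights: np.ndarray | None = None):
    """Aggregate duplicate (hi, lo) pairs.

    Returns ``(uhi, ulo, counts)`` with unique pairs in sorted order and
    their summed weights (1 per occurrence when ``weights`` is None).
    """
    if hi.size == 0:
        return hi, lo, np.empty(0, dtype=np.int64)
    order = np.lexsort((lo, hi))
    h, l = hi[order], lo[order]
    new = np.empty(h.size, dtype=bool)
    new[0] = True
    new[1:] = (h[1:] != h[:-1]) | (l[1:] != l[:-1])
    starts = np.nonzero(new)[0]
    if weights is None:
        counts = np.diff(np.append(starts, h.size))
    else:
        w = np.asarray(weights, dtype=np.int64)[order]
        cw = np.concatenate(([0], np.cumsum(w)))
        ends = np.append(starts[1:], h.size)
        counts = cw[ends] - cw[starts]
    return h[starts], l[starts], counts


def decode_limbs(hi: np.ndarray, lo: np.ndarray, k: int) -> list[str]:
    """Decode limb pairs back to k-mer strings."""
    n = len(hi)
    m = min(k, 32)
    digits = np.empty((n, k), dtype=np.uint8)
    for j in range(m):
        digits[:, k - 1 - j] = (lo >> np.uint64(2 * j)) & np.uint64(3)
    for j in range(k - m):
        digits[:, k - m - 1 - j] = (hi >> np.uint64(2 * j)) & np.uint64(3)
    raw = _BASE_BYTES[digits].tobytes()
    return [raw[i * k:(i + 1) * k].decode("ascii") for i in range(n)]


def encode_kmer(kmer: str) -> tuple[int, int]:
    """Encode one k-mer string (no canonicalisation) to (hi, lo) ints."""
    codes = seq_to_codes(kmer)
    if (codes >= 4).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    k = len(codes)
    m = min(k, 32)
    lo = 0
    for c in codes[k - m:]:
        lo = (lo << 2) | int(c)
    hi = 0
    for c in codes[:k - m]:
        hi = (hi << 2) | int(c)
    return hi, lo
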