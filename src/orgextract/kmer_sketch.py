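"""Canonical k-mer counting in a Count-Min Sketch.

The sketch stores approximate multiplicities of canonical k-mers with
one-sided error: an estimate can exceed the true count (hash collisions)
but can never fall below it. That property is what guarantees the
read-binning stage downstream cannot lose a genuinely high-frequency
read.

:class:`ExactKmerTable` is a deliberately independent, string-based exact
counter used as a test oracle; it shares no code path with the sketch.
"""

from __future__ import annotations

import struct
import warnings
from collections import Counter
from typing import Iterable, Union

import numpy as np

from . import _encode
from .io_preprocess import ReadRecord

DEFAULT_K = 31
DEFAULT_WIDTH = 1 << 26
DEFAULT_DEPTH = 3

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")
_MAGIC = b"CMSK\x01"


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    if not kmer:
        raise ValueError("empty k-mer")
    for ch in kmer:
        if ch not in "ACGT":
            raise ValueError(f"k-mer contains invalid character {ch!r}: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _mix64(z: np.ndarray) -> np.ndarray:
    # murmur3 finalizer; uint64 wraparound is intentional
    z = z ^ (z >> np.uint64(33))
    z = z * np.uint64(0xFF51AFD7ED558CCD)
    z = z ^ (z >> np.uint64(33))
    z = z * np.uint64(0xC4CEB9FE1A85EC53)
    return z ^ (z >> np.uint64(33))


class KmerSketch:
    """Count-Min Sketch over canonical k-mers (k <= 64).

    ``depth`` independent hash rows of ``width`` counters; the row hash
    functions are derived deterministically from ``seed``.
    """

    def __init__(self, k: int = DEFAULT_K, width: int = DEFAULT_WIDTH,
                 depth: int = DEFAULT_DEPTH, seed: int = 0):
        if k < 1 or k > _encode.MAX_K:
            raise ValueError(f"k must be in [1, {_encode.MAX_K}]")
        if width < 1 or depth < 1:
            raise ValueError("width and depth must be >= 1")
        self.k = int(k)
        self.width = int(width)
        self.depth = int(depth)
        self.seed = int(seed)
        self.counters = np.zeros((depth, width), dtype=np.uint32)
        self.total_kmers_inserted = 0
        rng = np.random.default_rng(seed)
        self._row_keys = rng.integers(0, 2**63, size=depth, dtype=np.uint64) * np.uint64(2) + np.uint64(1)

    # -- encoded-array interface (fast path) --------------------------------

    def _row_index(self, row: int, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        h = _mix64(lo ^ _mix64(hi ^ self._row_keys[row]))
        return (h % np.uint64(self.width)).astype(np.int64)

    def insert_encoded(self, hi: np.ndarray, lo: np.ndarray) -> None:
        for r in range(self.depth):
            np.add.at(self.counters[r], self._row_index(r, hi, lo), 1)
        self.total_kmers_inserted += int(hi.size)

    def estimate_encoded(self, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        est = self.counters[0][self._row_index(0, hi, lo)].astype(np.int64)
        for r in range(1, self.depth):
            np.minimum(est, self.counters[r][self._row_index(r, hi, lo)], out=est)
        return est

    # -- string interface ----------------------------------------------------

    def add_read(self, seq: str) -> int:
        """Insert every valid canonical k-mer window of ``seq``; returns count."""
        hi, lo = _encode.pooled_canonical_kmers([seq], self.k)
        if hi.size:
            self.insert_encoded(hi, lo)
        return int(hi.size)

    def estimate(self, kmer: str) -> int:
        """Upper-bound estimate of the canonical count of ``kmer``."""
        if len(kmer) != self.k:
            raise ValueError(f"expected k-mer of length {self.k}, got {len(kmer)}")
        canonical(kmer)  # validates alphabet
        ehi, elo = _encode.encode_kmer(kmer)
        rhi, rlo = _encode.encode_kmer(reverse_complement(kmer))
        if (rhi, rlo) < (ehi, elo):
            ehi, elo = rhi, rlo
        hi = np.array([ehi], dtype=np.uint64)
        lo = np.array([elo], dtype=np.uint64)
        return int(self.estimate_encoded(hi, lo)[0])

    def max_kmer_count(self, read: Union[ReadRecord, str]) -> int:
        """Max estimate over all N-free k-mer windows of a read (0 if none)."""
        seq = read.bases if isinstance(read, ReadRecord) else read
        hi, lo = _encode.pooled_canonical_kmers([seq], self.k)
        if hi.size == 0:
            return 0
        return int(self.estimate_encoded(hi, lo).max())

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        header = struct.pack(
            "<5sQQQQQ", _MAGIC, self.k, self.width, self.depth,
            self.seed % 2**64, self.total_kmers_inserted,
        )
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(self.counters.tobytes())

    @classmethod
    def load(cls, path) -> "KmerSketch":
        with open(path, "rb") as fh:
            header = fh.read(struct.calcsize("<5sQQQQQ"))
            magic, k, width, depth, seed, total = struct.unpack("<5sQQQQQ", header)
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a k-mer sketch file")
            sk = cls(k=k, width=width, depth=depth, seed=seed)
            data = np.frombuffer(fh.read(), dtype=np.uint32)
            sk.counters = data.reshape(depth, width).copy()
            sk.total_kmers_inserted = total
        return sk


def build_sketch(reads: Iterable[Union[ReadRecord, str]], k: int = DEFAULT_K,
                 width: int = DEFAULT_WIDTH, depth: int = DEFAULT_DEPTH,
                 seed: int = 0, batch_reads: int = 20000) -> KmerSketch:
    """Count every valid canonical k-mer window of every read into a sketch."""
    sketch = KmerSketch(k=k, width=width, depth=depth, seed=seed)
    batch: list[str] = []
    any_reads = False

    def flush():
        if not batch:
            return
        hi, lo = _encode.pooled_canonical_kmers(batch, k)
        if hi.size:
            sketch.insert_encoded(hi, lo)
        batch.clear()

    for read in reads:
        any_reads = True
        batch.append(read.bases if isinstance(read, ReadRecord) else read)
        if len(batch) >= batch_reads:
            flush()
    flush()
    if any_reads and sketch.total_kmers_inserted == 0:
        warnings.warn(f"no k-mers inserted: every read is shorter than k={k} "
                      "or contains only ambiguous bases")
    return sketch


class ExactKmerTable:
    """Exact canonical k-mer counts; a desk-scale oracle for the sketch."""

    def __init__(self, k: int):
        self.k = k
        self.counts: Counter[str] = Counter()

    @classmethod
    def from_reads(cls, reads: Iterable[Union[ReadRecord, str]], k: int) -> "ExactKmerTable":
        table = cls(k)
        for read in reads:
            table.add_read(read.bases if isinstance(read, ReadRecord) else read)
        return table

    def add_read(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            rc = reverse_complement(w)
            self.counts[w if w <= rc else rc] += 1

    def count(self, kmer: str) -> int:
        return self.counts[canonical(kmer)]

    def max_count_in_read(self, seq: str) -> int:
        k = self.k
        best = 0
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            rc = reverse_complement(w)
            best = max(best, self.counts[w if w <= rc else rc])
        return best
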