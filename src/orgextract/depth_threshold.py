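"""Nuclear-depth threshold estimation and depth/k-mer-count conversion.

The threshold is derived from per-position read depths over an anchor
contig assumed to be nuclear: sort the non-zero depths, take the slice
from the 25th to the 75th percentile, and multiply the slice mean by a
factor (default 5). Genome depth N and k-mer depth M are related by
N = M * L / (L - k + 1) for read length L, which converts the threshold
into k-mer-count units for binning.

Percentile convention: with m sorted non-zero depths the slice is indices
floor(0.25*(m-1)) .. floor(0.75*(m-1)) inclusive, so an all-non-zero
profile uses about half of its positions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

from .io_preprocess import ReadPair, ReadRecord
from .kmer_sketch import reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import Contig

MAX_ANCHOR_BP = 100_000
DEFAULT_FACTOR = 5.0
SEED_K = 21


@dataclass
class DepthProfile:
    """Per-position read depth over (a truncated prefix of) a contig."""

    contig_id: str
    depths: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)

    def mean_depth(self) -> float:
        return float(self.depths.mean()) if len(self.depths) else 0.0


@dataclass
class NDThreshold:
    """factor x trimmed mean of non-zero depths, plus its k-mer-unit form."""

    value: float
    trimmed_mean: float
    factor: float
    n_used: int
    kmer_threshold: Optional[float] = None


class _AnchorIndex:
    """Exact seed index over an anchor sequence for crude ungapped placement."""

    def __init__(self, ref: str, seed_k: int = SEED_K):
        self.ref = ref
        self.seed_k = seed_k
        self.index: dict[str, int] = {}
        for i in range(len(ref) - seed_k + 1):
            km = ref[i:i + seed_k]
            if "N" not in km:
                self.index.setdefault(km, i)

    def place(self, seq: str, tries: int = 5) -> Optional[int]:
        """Best ungapped start for a read (may be negative); None if unseeded.

        Seeds at a few spread offsets on both strands vote for an implied
        start; the modal start wins. The strand does not matter for the
        coverage span, so only the span start is returned.
        """
        k = self.seed_k
        span = len(seq) - k
        if span < 0:
            return None
        if span == 0:
            offsets = [0]
        else:
            n = min(tries, span + 1)
            offsets = sorted({round(j * span / (n - 1)) for j in range(n)}) if n > 1 else [0]
        votes: Counter[int] = Counter()
        for strand_seq, flip in ((seq, False), (reverse_complement(seq), True)):
            for o in offsets:
                pos = self.index.get(strand_seq[o:o + k])
                if pos is not None:
                    votes[pos - o] += 1
        if not votes:
            return None
        # modal start; deterministic tie-break on the smaller coordinate
        best = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return best[0]


def depth_profile(pairs: Iterable[ReadPair], anchor: "Contig", *,
                  max_positions: int = MAX_ANCHOR_BP, seed_k: int = SEED_K,
                  seed_tries: int = 5) -> DepthProfile:
    """Per-position depth of reads over the anchor's first ``max_positions`` bp.

    Placement uses exact seed k-mer matching with a single best ungapped
    position per read; unplaceable reads contribute nothing.
    """
    if not anchor.bases:
        raise ValueError("anchor contig is empty")
    ref = anchor.bases[:max_positions].upper()
    idx = _AnchorIndex(ref, seed_k)
    diff = np.zeros(len(ref) + 1, dtype=np.int64)
    n_reads = 0
    for pair in pairs:
        for read in pair:
            n_reads += 1
            start = idx.place(read.bases, tries=seed_tries)
            if start is None:
                continue
            a = max(0, start)
            b = min(len(ref), start + len(read.bases))
            if b > a:
                diff[a] += 1
                diff[b] -= 1
    if n_reads == 0:
        warnings.warn("depth_profile: empty read stream, profile is all zeros")
    return DepthProfile(anchor.contig_id, np.cumsum(diff[:-1]))


def nd_threshold(profile: DepthProfile, factor: float = DEFAULT_FACTOR) -> NDThreshold:
    """Trimmed-mean depth threshold from a profile's non-zero depths."""
    nz = np.sort(profile.depths[profile.depths > 0])
    m = nz.size
    if m == 0:
        raise ValueError(
            "depth profile has no non-zero positions; supply the threshold "
            "manually (--nd-threshold)"
        )
    lo = int(0.25 * (m - 1))
    hi = int(0.75 * (m - 1))
    slc = nz[lo:hi + 1]
    tm = float(slc.mean())
    return NDThreshold(value=factor * tm, trimmed_mean=tm, factor=factor,
                       n_used=int(slc.size))


def genome_depth_from_kmer_depth(M: float, L: int, k: int) -> float:
    """N = M * L / (L - k + 1); requires k <= L."""
    if k > L:
        raise ValueError(f"k-mer size k={k} must not exceed read length L={L}")
    return M * L / (L - k + 1)


def kmer_depth_from_genome_depth(N: float, L: int, k: int) -> float:
    """Inverse conversion: M = N * (L - k + 1) / L."""
    if k > L:
        raise ValueError(f"k-mer size k={k} must not exceed read length L={L}")
    return N * (L - k + 1) / L


def kmer_threshold_from_nd(nd: NDThreshold, L: int, k: int) -> float:
    """Convert a depth threshold into k-mer-count units; stored on ``nd``."""
    nd.kmer_threshold = kmer_depth_from_genome_depth(nd.value, L, k)
    return nd.kmer_threshold


def effective_read_length(reads: Iterable[ReadRecord], sample_limit: int = 100_000) -> int:
    """Modal read length over a bounded sample; ties break to the smaller."""
    lengths: Counter[int] = Counter()
    for i, read in enumerate(reads):
        if i >= sample_limit:
            break
        lengths[len(read.bases)] += 1
    if not lengths:
        raise ValueError("cannot determine read length from an empty sample")
    return min(lengths.items(), key=lambda kv: (-kv[1], kv[0]))[0]
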