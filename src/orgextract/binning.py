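"""High-copy-number read binning by sketch k-mer frequency.

A read qualifies when its maximum canonical k-mer estimate strictly
exceeds the threshold. Because sketch estimates never undercount, no
read whose true maximum k-mer frequency exceeds the threshold can be
lost; collisions can only add (nuclear) false positives, which are
harmless downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .io_preprocess import ReadPair
from .kmer_sketch import KmerSketch


@dataclass
class BinSummary:
    reads_in: int = 0
    reads_qualified: int = 0
    reads_retained: int = 0
    retained_by_mate: int = 0
    pairs_out: int = 0
    singletons_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_qualifies(sketch: KmerSketch, read, threshold: float) -> bool:
    """True when some k-mer of the read has estimate > threshold (strict)."""
    return sketch.max_kmer_count(read) > threshold


def bin_reads(pairs: Iterable[ReadPair], sketch: KmerSketch, threshold: float,
              keep_pairs: bool = True,
              summary: Optional[BinSummary] = None) -> Iterator[ReadPair]:
    """Yield the pairs/reads that carry at least one high-frequency k-mer.

    With ``keep_pairs`` (default) a pair is kept whole when either mate
    qualifies; otherwise only qualifying mates are emitted (a lone
    qualifying mate becomes a singleton).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if summary is None:
        summary = BinSummary()
    for pair in pairs:
        summary.reads_in += pair.n_reads()
        q1 = read_qualifies(sketch, pair.r1, threshold)
        q2 = read_qualifies(sketch, pair.r2, threshold) if pair.r2 is not None else False
        summary.reads_qualified += int(q1) + int(q2)
        if keep_pairs:
            if not (q1 or q2):
                continue
            summary.reads_retained += pair.n_reads()
            if pair.r2 is not None and q1 != q2:
                summary.retained_by_mate += 1
            if pair.r2 is not None:
                summary.pairs_out += 1
            else:
                summary.singletons_out += 1
            yield pair
        else:
            if q1 and q2:
                summary.reads_retained += 2
                summary.pairs_out += 1
                yield pair
            elif q1:
                summary.reads_retained += 1
                summary.singletons_out += 1
                yield ReadPair(pair.r1)
            elif q2:
                summary.reads_retained += 1
                summary.singletons_out += 1
                yield ReadPair(pair.r2)
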