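"""FASTQ/FASTA I/O, read pairing, and adapter/quality trimming.

FASTQ is assumed 4-line, Phred+33. Gzip compression is autodetected from
the magic bytes on input; output is gzipped when the target path ends in
``.gz``.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import Contig

FASTA_WRAP = 70
_VALID_RE = re.compile(r"^[ACGTN]*$")
_MATE_SUFFIX_RE = re.compile(r"/[12]$")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records."""


class PairingError(ValueError):
    """Raised when two FASTQ files cannot be paired record-for-record."""


@dataclass
class ReadRecord:
    """A sequencing read: identifier, bases over {A,C,G,T,N}, Phred+33 quals."""

    read_id: str
    bases: str
    quals: str
    mate_index: int = 0  # 0 unpaired, 1/2 for paired mates

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise FastqParseError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and quals "
                f"({len(self.quals)}) differ in length"
            )
        if not _VALID_RE.match(self.bases):
            upper = self.bases.upper()
            if not _VALID_RE.match(upper):
                warnings.warn(
                    f"read {self.read_id!r}: non-ACGTN characters replaced with N"
                )
                upper = "".join(ch if ch in "ACGTN" else "N" for ch in upper)
            self.bases = upper

    def __len__(self) -> int:
        return len(self.bases)

    def qual_scores(self) -> list[int]:
        return [ord(c) - 33 for c in self.quals]


@dataclass
class ReadPair:
    """One fragment's reads: r1 always present, r2 for paired-end data."""

    r1: ReadRecord
    r2: Optional[ReadRecord] = None

    def __iter__(self) -> Iterator[ReadRecord]:
        yield self.r1
        if self.r2 is not None:
            yield self.r2

    @property
    def is_paired(self) -> bool:
        return self.r2 is not None

    def n_reads(self) -> int:
        return 2 if self.r2 is not None else 1


@dataclass
class TrimConfig:
    adapter_sequences: tuple[str, ...] = ()
    min_length: int = 30
    quality_cutoff: int = 2
    min_adapter_overlap: int = 8

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        self.adapter_sequences = tuple(a.upper() for a in self.adapter_sequences)


@dataclass
class PreprocessSummary:
    reads_in: int = 0
    reads_out: int = 0
    reads_discarded: int = 0
    pairs_out: int = 0
    singletons_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing /1 or /2 or a whitespace-delimited tag from an id."""
    base = read_id.split()[0] if read_id else read_id
    return _MATE_SUFFIX_RE.sub("", base)


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def open_output(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _iter_fastq_records(path, mate_index: int) -> Iterator[ReadRecord]:
    with _open_text(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"{path}: record {i}: sequence and quality lengths differ"
                    )
                yield ReadRecord(title, seq.upper(), qual, mate_index)
        except ValueError as exc:
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(f"{path}: malformed FASTQ ({exc})") from exc


def parse_fastq(path, paired_path=None) -> Iterator[ReadPair]:
    """Stream ReadPairs from one (single-end) or two (paired-end) FASTQ files.

    Paired files are matched record-for-record by position; unequal record
    counts raise :class:`PairingError`.
    """
    if paired_path is None:
        for rec in _iter_fastq_records(path, 0):
            yield ReadPair(rec)
        return
    it1 = _iter_fastq_records(path, 1)
    it2 = _iter_fastq_records(paired_path, 2)
    sentinel = object()
    for i, (r1, r2) in enumerate(zip_longest(it1, it2, fillvalue=sentinel)):
        if r1 is sentinel or r2 is sentinel:
            raise PairingError(
                f"{path} and {paired_path} have unequal record counts "
                f"(mismatch at record {i})"
            )
        yield ReadPair(r1, r2)


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    """Write reads as 4-line FASTQ; returns the number written."""
    n = 0
    with open_output(path) as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")
            n += 1
    return n


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path, singles_path):
    """Split pairs/singletons across three FASTQ files; returns counts."""
    counts = {"pairs": 0, "singletons": 0}
    with open_output(r1_path) as f1, open_output(r2_path) as f2, \
            open_output(singles_path) as fs:
        for pair in pairs:
            if pair.r2 is not None:
                f1.write(f"@{pair.r1.read_id}\n{pair.r1.bases}\n+\n{pair.r1.quals}\n")
                f2.write(f"@{pair.r2.read_id}\n{pair.r2.bases}\n+\n{pair.r2.quals}\n")
                counts["pairs"] += 1
            else:
                r = pair.r1
                fs.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")
                counts["singletons"] += 1
    return counts


def write_fasta(contigs: Iterable["Contig"], path) -> int:
    """Write contigs as wrapped FASTA in input order; returns count written."""
    n = 0
    with open_output(path) as fh:
        for c in contigs:
            if not c.bases:
                raise ValueError(f"contig {c.contig_id!r} has an empty sequence")
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.bases), FASTA_WRAP):
                fh.write(c.bases[i:i + FASTA_WRAP] + "\n")
            n += 1
    return n


def parse_fasta(path) -> list["Contig"]:
    """Parse a FASTA file into Contig records (source marked external)."""
    from .assembly import Contig

    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append(Contig(rec.id, str(rec.seq).upper(), source="external"))
    return out


def trim_read(read: ReadRecord, cfg: TrimConfig) -> Optional[ReadRecord]:
    """Adapter-trim then quality-trim one read; None means discarded.

    Adapter rule: the longest exact match of an adapter prefix at the 3'
    end of the read, requiring at least ``cfg.min_adapter_overlap`` bases,
    is removed. Quality rule: 3' bases with Phred < quality_cutoff are
    stripped. Reads ending shorter than ``cfg.min_length`` are discarded.
    """
    bases, quals = read.bases, read.quals
    for adapter in cfg.adapter_sequences:
        hi = min(len(bases), len(adapter))
        for ov in range(hi, cfg.min_adapter_overlap - 1, -1):
            if bases.endswith(adapter[:ov]):
                bases, quals = bases[:-ov], quals[:-ov]
                break
    cut = ord("!") + cfg.quality_cutoff
    end = len(quals)
    while end > 0 and ord(quals[end - 1]) < cut:
        end -= 1
    bases, quals = bases[:end], quals[:end]
    if len(bases) < cfg.min_length:
        return None
    return ReadRecord(read.read_id, bases, quals, read.mate_index)


def preprocess(pairs: Iterable[ReadPair], cfg: TrimConfig | None = None,
               summary: PreprocessSummary | None = None) -> Iterator[ReadPair]:
    """Trim every mate; orphan a pair when exactly one mate is discarded.

    ``summary`` (if given) is filled in as the stream is consumed.
    """
    cfg = cfg or TrimConfig()
    if summary is None:
        summary = PreprocessSummary()
    for pair in pairs:
        summary.reads_in += pair.n_reads()
        t1 = trim_read(pair.r1, cfg)
        t2 = trim_read(pair.r2, cfg) if pair.r2 is not None else None
        n_in = pair.n_reads()
        survivors = [t for t in (t1, t2) if t is not None]
        summary.reads_discarded += n_in - len(survivors)
        summary.reads_out += len(survivors)
        if not survivors:
            continue
        if len(survivors) == 2:
            summary.pairs_out += 1
            yield ReadPair(t1, t2)
        else:
            summary.singletons_out += 1
            yield ReadPair(survivors[0])
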