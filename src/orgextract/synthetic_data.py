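"""Synthetic WGS datasets: nuclear genome + high-copy circular organelle.

Generates uniform-composition random genomes, optionally plants organelle
fragments into the nuclear sequence (NUMT-like insertions at 100%
identity, the worst case for contamination), samples paired-end reads
uniformly — treating the organelle as circular so fragments may wrap the
origin — applies i.i.d. substitution errors, and records per-read origin
labels for downstream scoring.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import Contig
from .io_preprocess import ReadPair, ReadRecord, open_output
from .kmer_sketch import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_QUAL_CHAR = chr(35 + 33)  # Phred 35


@dataclass
class SyntheticDatasetSpec:
    nuclear_length: int = 50_000
    organelle_length: int = 16_000
    copy_ratio: float = 20.0
    nuclear_depth: float = 10.0
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    error_rate: float = 0.005
    numt_count: int = 0
    numt_length: int = 500
    low_quality_tail: int = 0  # bases at the 3' end demoted to Phred 2
    seed: int = 0

    def __post_init__(self):
        if self.copy_ratio <= 1:
            raise ValueError("copy_ratio must be > 1")
        if min(self.nuclear_length, self.organelle_length, self.read_length) <= 0:
            raise ValueError("all lengths must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.insert_mean > min(self.nuclear_length, self.organelle_length):
            raise ValueError(
                "insert_mean exceeds a genome length; the spec is infeasible"
            )
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")


@dataclass
class SyntheticTruth:
    nuclear_seq: str
    organelle_seq: str
    numt_positions: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    read_origins: dict[str, str] = field(default_factory=dict)  # id -> label
    read_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def label_counts(self) -> Counter:
        return Counter(self.read_origins.values())


@dataclass
class SimulatedDataset:
    spec: SyntheticDatasetSpec
    pairs: list[ReadPair]
    truth: SyntheticTruth
    r1_path: Optional[str] = None
    r2_path: Optional[str] = None
    truth_fasta: Optional[str] = None
    truth_table: Optional[str] = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hit.size == 0:
        return seq
    # substitute with one of the three other bases
    codes = np.searchsorted(_BASES, arr[hit])
    new_codes = (codes + rng.integers(1, 4, size=hit.size)) % 4
    arr[hit] = _BASES[new_codes]
    return arr.tobytes().decode("ascii")


def simulate(spec: SyntheticDatasetSpec,
             out_dir: Optional[str] = None,
             gzip_output: bool = True) -> SimulatedDataset:
    """Generate a fully labelled paired-end dataset from ``spec``.

    Fragment counts are proportional to genome length x depth with the
    organelle at ``copy_ratio`` times the nuclear depth. Deterministic for
    a fixed seed, including the emitted FASTQ bytes.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length

    nuclear = _random_seq(rng, spec.nuclear_length)
    organelle = _random_seq(rng, spec.organelle_length)

    numt_positions: list[tuple[int, tuple[int, int]]] = []
    if spec.numt_count > 0:
        nuc = list(nuclear)
        taken: list[tuple[int, int]] = []
        for _ in range(spec.numt_count):
            src = int(rng.integers(0, spec.organelle_length - spec.numt_length))
            for _attempt in range(1000):
                dst = int(rng.integers(0, spec.nuclear_length - spec.numt_length))
                if all(dst + spec.numt_length <= a or dst >= b
                       for a, b in taken):
                    break
            else:
                raise ValueError("cannot place non-overlapping NUMT insertions; "
                                 "reduce numt_count or numt_length")
            taken.append((dst, dst + spec.numt_length))
            nuc[dst:dst + spec.numt_length] = organelle[src:src + spec.numt_length]
            numt_positions.append((dst, (src, src + spec.numt_length)))
        nuclear = "".join(nuc)

    truth = SyntheticTruth(nuclear, organelle, numt_positions)
    organelle2 = organelle + organelle  # wrap-around sampling

    n_nuc = int(round(spec.nuclear_depth * spec.nuclear_length / (2 * L)))
    n_org = int(round(spec.copy_ratio * spec.nuclear_depth
                      * spec.organelle_length / (2 * L)))

    def numt_label(start: int, end: int) -> str:
        for dst, _src in numt_positions:
            if start < dst + spec.numt_length and end > dst:
                return "numt"
        return "nuclear"

    pairs: list[ReadPair] = []
    quals = DEFAULT_QUAL_CHAR * L
    if spec.low_quality_tail > 0:
        tail = min(spec.low_quality_tail, L)
        quals = DEFAULT_QUAL_CHAR * (L - tail) + chr(2 + 33) * tail

    jobs = [("nuc", n_nuc, nuclear, spec.nuclear_length, False),
            ("org", n_org, organelle2, spec.organelle_length, True)]
    for tag, count, template, glen, circular in jobs:
        for i in range(count):
            flen = int(np.clip(round(rng.normal(spec.insert_mean, spec.insert_sd)),
                               L, glen))
            if circular:
                start = int(rng.integers(0, glen))
            else:
                start = int(rng.integers(0, glen - flen + 1))
            frag = template[start:start + flen]
            r1 = _mutate(rng, frag[:L], spec.error_rate)
            r2 = _mutate(rng, reverse_complement(frag[-L:]), spec.error_rate)
            rid = f"sim_{tag}_{i:07d}"
            label = "organelle" if tag == "org" else numt_label(start, start + flen)
            truth.read_origins[rid] = label
            truth.read_coords[rid] = (start, start + flen)
            pairs.append(ReadPair(
                ReadRecord(rid, r1, quals, mate_index=1),
                ReadRecord(rid, r2, quals, mate_index=2),
            ))

    ds = SimulatedDataset(spec, pairs, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        ext = ".fastq.gz" if gzip_output else ".fastq"
        ds.r1_path = os.path.join(out_dir, "reads_R1" + ext)
        ds.r2_path = os.path.join(out_dir, "reads_R2" + ext)
        with open_output(ds.r1_path) as f1, open_output(ds.r2_path) as f2:
            for p in pairs:
                f1.write(f"@{p.r1.read_id}/1\n{p.r1.bases}\n+\n{p.r1.quals}\n")
                f2.write(f"@{p.r2.read_id}/2\n{p.r2.bases}\n+\n{p.r2.quals}\n")
        ds.truth_fasta = os.path.join(out_dir, "truth.fasta")
        with open(ds.truth_fasta, "w") as fh:
            fh.write(f">nuclear\n{nuclear}\n>organelle\n{organelle}\n")
        ds.truth_table = os.path.join(out_dir, "truth_reads.tsv")
        with open(ds.truth_table, "w") as fh:
            fh.write("read_id\torigin\tstart\tend\n")
            for rid, label in truth.read_origins.items():
                s, e = truth.read_coords[rid]
                fh.write(f"{rid}\t{label}\t{s}\t{e}\n")
    return ds


def score_recovery(candidate: Optional[Contig], truth: SyntheticTruth,
                   anchor_k: int = 31) -> tuple[float, float]:
    """(identity, coverage) of a candidate against the true organelle.

    The candidate is anchored to the doubled organelle sequence (both
    strands) by exact k-mer votes and compared ungapped, which handles
    arbitrary rotation and strand of a circular assembly. Substitution
    differences lower identity; with no anchor at all both scores are 0.
    Fractions in [0, 1].
    """
    if candidate is None or not candidate.bases:
        return 0.0, 0.0
    ref2 = truth.organelle_seq * 2
    glen = len(truth.organelle_seq)
    index: dict[str, int] = {}
    for i in range(len(ref2) - anchor_k + 1):
        index.setdefault(ref2[i:i + anchor_k], i)

    best = None  # (votes, seq, offset)
    for seq in (candidate.bases, reverse_complement(candidate.bases)):
        votes: Counter[int] = Counter()
        step = max(1, (len(seq) - anchor_k) // 64 or 1)
        for o in range(0, max(1, len(seq) - anchor_k + 1), step):
            pos = index.get(seq[o:o + anchor_k])
            if pos is not None:
                votes[pos - o] += 1
        if votes:
            off, n = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0], max(votes.values())
            if best is None or n > best[0]:
                best = (n, seq, off)
    if best is None:
        return 0.0, 0.0
    _, seq, off = best
    off %= glen  # the doubled reference repeats with period glen
    a = max(0, off)
    b = min(len(ref2), off + len(seq))
    if b <= a:
        return 0.0, 0.0
    cand_slice = seq[a - off:b - off]
    ref_slice = ref2[a:b]
    arr_c = np.frombuffer(cand_slice.encode("ascii"), dtype=np.uint8)
    arr_r = np.frombuffer(ref_slice.encode("ascii"), dtype=np.uint8)
    matches = int(np.count_nonzero(arr_c == arr_r))
    identity = matches / len(ref_slice)
    coverage = min(1.0, len(ref_slice) / glen)
    return identity, coverage
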