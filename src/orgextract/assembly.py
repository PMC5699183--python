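"""Minimal iterative-k de Bruijn unitig assembler plus external adapters.

The built-in assembler targets the small, high-depth read subsets this
pipeline produces: for each k in an increasing odd k list it builds a
canonical de Bruijn graph from k-mers passing a count filter, pops short
tips and simple bubbles, collapses unbranched paths into unitigs, and
carries the unitigs forward as pseudo-reads for the next k. A closed
cycle is emitted with its first k-1 bases repeated at the end so that
the downstream circularity check can detect and trim the junction.

An optional single-substitution read corrector (on by default) repairs
isolated sequencing errors before graph construction; it marks a base as
suspect when every k-mer window covering it is rare and accepts the one
substitution that makes all of those windows solid.

Production deployments can substitute any external assembler through
:func:`run_external_assembler`.
"""

from __future__ import annotations

import glob
import os
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import _encode
from .io_preprocess import ReadPair, ReadRecord, parse_fasta
from .kmer_sketch import reverse_complement

# k ranges used by the external assemblers this tool was designed around
INITIAL_ASSEMBLY_K = (21, 49, 77, 105)
HIGH_FREQ_ASSEMBLY_K = (20, 40, 60, 80, 100)


class AssemblyError(RuntimeError):
    """Raised when an external assembler fails."""


@dataclass
class Contig:
    contig_id: str
    bases: str
    mean_depth: float = float("nan")
    source: str = "built_in"
    circular: bool = False

    def __post_init__(self):
        if not self.bases:
            raise ValueError("contig sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AssemblyConfig:
    k_list: tuple[int, ...] = (21, 41, 61)
    min_kmer_count: int = 2
    first_k_min_count: Optional[int] = None  # override for k_list[0] only
    min_contig_length: int = 200
    correct_errors: bool = True
    solid_count: int = 2
    cleanup_rounds: int = 4

    def __post_init__(self):
        ks = tuple(self.k_list)
        if any(k % 2 == 0 for k in ks):
            raise ValueError(f"k values must be odd, got {ks}")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"k_list must be strictly increasing, got {ks}")
        if any(k > _encode.MAX_K for k in ks):
            raise ValueError(f"built-in assembler supports k <= {_encode.MAX_K}")
        self.k_list = ks


def _reads_to_seqs(reads: Iterable[Union[ReadPair, ReadRecord, str]]) -> list[str]:
    seqs: list[str] = []
    for item in reads:
        if isinstance(item, ReadPair):
            for r in item:
                seqs.append(r.bases)
        elif isinstance(item, ReadRecord):
            seqs.append(item.bases)
        else:
            seqs.append(item)
    return seqs


# ---------------------------------------------------------------------------
# read error correction

def _canonical_key(w: str) -> str:
    rc = reverse_complement(w)
    return w if w <= rc else rc


def correct_reads(seqs: Sequence[str], k: int, solid: int = 2,
                  rel_cutoff: float = 0.25) -> list[str]:
    """Repair isolated substitution errors using the pool's k-mer spectrum.

    A window is suspect when its count falls below both ``solid`` and
    ``rel_cutoff`` times the read's mean window count, so high-depth reads
    still get recurring errors flagged while low-depth reads keep a
    permissive absolute floor.
    """
    if k > 32:
        raise ValueError("read correction supports k <= 32")
    _, lo, seq_idx = _encode.pooled_canonical_kmers(seqs, k, with_seq_index=True)
    if lo.size == 0:
        return list(seqs)
    _, ulo, counts = _encode.count_limbs(np.zeros_like(lo), lo)  # sorted by lo
    win_counts = counts[np.searchsorted(ulo, lo)]
    table = dict(zip(ulo.tolist(), counts.tolist()))

    n_seqs = len(seqs)
    occ = np.bincount(seq_idx, minlength=n_seqs)
    tot = np.bincount(seq_idx, weights=win_counts, minlength=n_seqs)
    mean_cnt = np.divide(tot, occ, out=np.zeros(n_seqs), where=occ > 0)
    thresholds = np.maximum(solid, rel_cutoff * mean_cnt)
    weak_seqs = np.unique(seq_idx[win_counts < thresholds[seq_idx]])
    out = list(seqs)
    for si in weak_seqs.tolist():
        out[si] = _repair_seq(out[si], k, thresholds[si], table)
    return out


def _window_count(s: str, i: int, k: int, table: dict) -> int:
    w = s[i:i + k]
    if "N" in w:
        return 0
    _, l = _encode.encode_kmer(_canonical_key(w))
    return table.get(l, 0)


def _repair_seq(seq: str, k: int, solid: float, table: dict) -> str:
    n = len(seq)
    nwin = n - k + 1
    if nwin <= 0:
        return seq
    weak_idx = [i for i in range(nwin) if _window_count(seq, i, k, table) < solid]
    if not weak_idx:
        return seq
    # group into maximal runs; each run is attributed to one suspect base
    runs = []
    start = prev = weak_idx[0]
    for i in weak_idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))

    s = list(seq)
    for run_start, run_end in runs[:4]:
        candidates = {min(run_start + k - 1, n - 1), run_end}
        fixed = False
        for p in sorted(candidates):
            orig = s[p]
            for b in "ACGT":
                if b == orig:
                    continue
                s[p] = b
                trial = "".join(s)
                ok = all(
                    _window_count(trial, i, k, table) >= solid
                    for i in range(run_start, run_end + 1)
                )
                if ok:
                    fixed = True
                    break
                s[p] = orig
            if fixed:
                break
    return "".join(s)


# ---------------------------------------------------------------------------
# de Bruijn graph / unitigs

@dataclass
class _Unitig:
    seq: str
    kmers: set  # canonical k-mer strings
    circular: bool
    mean_count: float


class _Graph:
    """Canonical k-mer set with oriented adjacency queries."""

    def __init__(self, counts: dict[str, float], k: int):
        self.k = k
        self.counts = counts
        self.oriented: dict[str, float] = {}
        for km, c in counts.items():
            self.oriented[km] = c
            self.oriented[reverse_complement(km)] = c

    def canon(self, x: str) -> str:
        rc = reverse_complement(x)
        return x if x <= rc else rc

    def fwd(self, x: str) -> list[str]:
        base = x[1:]
        return [base + b for b in "ACGT" if base + b in self.oriented]

    def bwd(self, x: str) -> list[str]:
        base = x[:-1]
        return [b + base for b in "ACGT" if b + base in self.oriented]

    def remove(self, kmers: Iterable[str]) -> None:
        for km in kmers:
            if km in self.counts:
                del self.counts[km]
                self.oriented.pop(km, None)
                self.oriented.pop(reverse_complement(km), None)


def _walk(g: _Graph, start: str, visited: set) -> _Unitig:
    path = [start]
    in_path = {start}
    circular = False
    x = start
    while True:  # extend right
        nxt = g.fwd(x)
        if len(nxt) != 1:
            break
        y = nxt[0]
        if len(g.bwd(y)) != 1:
            break
        if y == start:
            circular = True
            break
        cy = g.canon(y)
        if cy in in_path or cy in visited:
            break
        path.append(y)
        in_path.add(cy)
        x = y
    if not circular:
        x = start
        left: list[str] = []
        while True:  # extend left
            prv = g.bwd(x)
            if len(prv) != 1:
                break
            y = prv[0]
            if len(g.fwd(y)) != 1:
                break
            cy = g.canon(y)
            if cy in in_path or cy in visited:
                break
            left.append(y)
            in_path.add(cy)
            x = y
        left.reverse()
        path = left + path
    # a closed cycle's path string already ends with its first k-1 bases,
    # i.e. the duplicated junction the circularity check will trim
    seq = path[0] + "".join(p[-1] for p in path[1:])
    if not circular:
        rc = reverse_complement(seq)
        if rc < seq:
            seq = rc
    visited |= in_path
    mean_count = sum(g.counts[c] for c in in_path) / len(in_path)
    return _Unitig(seq, in_path, circular, mean_count)


def _build_unitigs(g: _Graph) -> list[_Unitig]:
    visited: set = set()
    out = []
    for ck in sorted(g.counts):
        if ck in visited:
            continue
        out.append(_walk(g, ck, visited))
    return out


def _cleanup(g: _Graph, rounds: int) -> list[_Unitig]:
    """Iteratively pop tips and dominated branch arms, then rebuild unitigs.

    Tips are dead-end unitigs shorter than 2k. At every branch point the
    competing short arms (1-in/1-out, <= 3k) are compared by mean k-mer
    count: arms weaker than the strongest sibling are spurious paths from
    sequencing errors and are dropped; exact ties keep only the
    lexicographically smallest arm. Arm removal is branch-local, so
    interleaved bubbles that share no common endpoints still resolve.
    """
    k = g.k
    unis = _build_unitigs(g)
    for _ in range(rounds):
        owner: dict[str, int] = {}
        for ui, u in enumerate(unis):
            for km in u.kmers:
                owner[km] = ui

        def flank_degrees(u: _Unitig) -> tuple[int, int]:
            return len(g.bwd(u.seq[:k])), len(g.fwd(u.seq[-k:]))

        degrees = [flank_degrees(u) if not u.circular else (0, 0) for u in unis]
        removable = [
            not u.circular and len(u.seq) <= 3 * k and dl <= 1 and dr <= 1
            for u, (dl, dr) in zip(unis, degrees)
        ]

        doomed: set[int] = set()
        for ui, u in enumerate(unis):
            if u.circular:
                continue
            dl, dr = degrees[ui]
            if (dl == 0) != (dr == 0) and len(u.seq) < 2 * k:
                doomed.add(ui)  # tip
                continue
            for arms in (g.fwd(u.seq[-k:]) if dr >= 2 else (),
                         g.bwd(u.seq[:k]) if dl >= 2 else ()):
                arm_units = []
                for a in arms:
                    vi = owner.get(g.canon(a))
                    if vi is not None and vi != ui:
                        arm_units.append(unis[vi])
                if len(arm_units) < 2:
                    continue
                best = max(v.mean_count for v in arm_units)
                tied = sorted((v.seq for v in arm_units if v.mean_count == best))
                for v in arm_units:
                    vi = owner[next(iter(v.kmers))]
                    if not removable[vi]:
                        continue
                    if v.mean_count < best or (v.mean_count == best
                                               and len(tied) > 1
                                               and v.seq != tied[0]):
                        doomed.add(vi)

        if not doomed:
            break
        to_remove: set = set()
        for ui in doomed:
            to_remove |= unis[ui].kmers
        g.remove(to_remove)
        unis = _build_unitigs(g)
    return unis


def _kmer_counts(seqs: Sequence[str], pseudo: Sequence[str], k: int,
                 min_count: int, pseudo_weight: int) -> dict[str, float]:
    """Counts of canonical k-mers from reads plus weighted pseudo-reads."""
    hi_r, lo_r = _encode.pooled_canonical_kmers(seqs, k)
    parts_hi = [hi_r]
    parts_lo = [lo_r]
    parts_w = [np.ones(hi_r.size, dtype=np.int64)]
    if pseudo:
        hi_p, lo_p = _encode.pooled_canonical_kmers(pseudo, k)
        parts_hi.append(hi_p)
        parts_lo.append(lo_p)
        parts_w.append(np.full(hi_p.size, pseudo_weight, dtype=np.int64))
    hi = np.concatenate(parts_hi)
    lo = np.concatenate(parts_lo)
    wt = np.concatenate(parts_w)
    if hi.size == 0:
        return {}
    uhi, ulo, counts = _encode.count_limbs(hi, lo, weights=wt)
    keep = counts >= min_count
    kmers = _encode.decode_limbs(uhi[keep], ulo[keep], k)
    return dict(zip(kmers, counts[keep].astype(float).tolist()))


def assemble(reads: Iterable[Union[ReadPair, ReadRecord, str]],
             cfg: Optional[AssemblyConfig] = None) -> list[Contig]:
    """Assemble a read pool into contigs with the built-in unitig assembler."""
    cfg = cfg or AssemblyConfig()
    seqs = _reads_to_seqs(reads)
    if not seqs:
        return []
    if cfg.correct_errors:
        seqs = correct_reads(seqs, k=cfg.k_list[0], solid=cfg.solid_count)
    pseudo_weight = max(cfg.min_kmer_count, 1)
    unitigs: list[_Unitig] = []
    pseudo: list[str] = []
    for ki, k in enumerate(cfg.k_list):
        min_count = cfg.min_kmer_count
        if ki == 0 and cfg.first_k_min_count is not None:
            min_count = cfg.first_k_min_count
        counts = _kmer_counts(seqs, pseudo, k, min_count, pseudo_weight)
        if not counts:
            continue
        g = _Graph(counts, k)
        unitigs = _cleanup(g, cfg.cleanup_rounds)
        pseudo = [u.seq for u in unitigs]
    contigs = [
        Contig("", u.seq, mean_depth=u.mean_count, circular=u.circular)
        for u in unitigs if len(u.seq) >= cfg.min_contig_length
    ]
    contigs.sort(key=lambda c: (-len(c.bases), c.bases))
    for i, c in enumerate(contigs, start=1):
        c.contig_id = f"contig_{i}"
    return contigs


# ---------------------------------------------------------------------------
# external assembler adapter

def run_external_assembler(read_paths: dict[str, str], tool_spec: str,
                           workdir: Optional[str] = None) -> list[Contig]:
    """Run an external assembler command template and parse its contigs.

    ``tool_spec`` may use the placeholders ``{r1}``, ``{r2}``, ``{reads}``,
    ``{outdir}`` and ``{out_fasta}``. If ``{out_fasta}`` is absent, the
    first FASTA file found in ``{outdir}`` is used.
    """
    tmp = workdir or tempfile.mkdtemp(prefix="orgextract_asm_")
    outdir = os.path.join(tmp, "asm_out")
    os.makedirs(outdir, exist_ok=True)
    subs = dict(read_paths)
    subs.setdefault("outdir", outdir)
    subs.setdefault("out_fasta", os.path.join(outdir, "contigs.fasta"))
    cmd = tool_spec.format(**subs)
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AssemblyError(
            f"external assembler failed (exit {proc.returncode}): {cmd}\n"
            f"stderr: {proc.stderr.strip()}"
        )
    out_fasta = subs["out_fasta"]
    if not os.path.exists(out_fasta):
        hits = sorted(
            glob.glob(os.path.join(subs["outdir"], "*.fa"))
            + glob.glob(os.path.join(subs["outdir"], "*.fasta"))
        )
        if not hits:
            raise AssemblyError(
                f"external assembler produced no FASTA output in {subs['outdir']}"
            )
        out_fasta = hits[0]
    contigs = parse_fasta(out_fasta)
    if not contigs:
        warnings.warn(f"external assembler output {out_fasta} contains no contigs")
    for c in contigs:
        c.source = "external"
    return contigs
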