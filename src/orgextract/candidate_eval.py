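"""Candidate organelle contig selection, circularity trimming, validation.

A contig assembled from a circular molecule carries a duplicated stretch:
its start reappears at its end. The circularity check scans overlap
lengths from long to short for a prefix/suffix match within a small
mismatch budget and cuts the duplicated suffix once. Validation maps the
read pool back to the candidate and to an equally long window of the
nuclear anchor and compares mean depths; an elevated ratio supports an
organelle origin.
"""

from __future__ import annotations

import csv
import os
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assembly import Contig
from .depth_threshold import DepthProfile, depth_profile
from .io_preprocess import ReadPair, write_fasta

MIN_OVERLAP = 50
MAX_MISMATCH_FRAC = 0.02
MAX_SCAN = 2000
SUPPORT_RATIO = 5.0


@dataclass
class CircularityResult:
    is_circular: bool
    overlap_length: int
    trimmed: Contig


@dataclass
class AnnotationHit:
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bit_score: float


@dataclass
class ValidationReport:
    candidate_mean_depth: float
    nuclear_mean_depth: float
    depth_ratio: float
    candidate_profile: DepthProfile
    nuclear_profile: DepthProfile
    verdict: str  # "supported" | "unsupported"
    notes: list[str] = field(default_factory=list)


def select_candidate(contigs: Sequence[Contig], mode: str = "longest",
                     hits: Optional[dict] = None) -> Contig:
    """Pick the organelle candidate: longest contig, or longest annotated one.

    Ties on length break to the lexicographically smaller sequence. In
    ``annotated`` mode, contigs without an annotation hit are ignored;
    when no hits exist at all the choice falls back to longest.
    """
    if not contigs:
        raise ValueError("cannot select a candidate from an empty contig list")
    if mode not in ("longest", "annotated"):
        raise ValueError(f"unknown selection mode {mode!r}")
    pool = list(contigs)
    if mode == "annotated":
        flagged = [c for c in pool if hits and hits.get(c.contig_id)]
        if flagged:
            pool = flagged
        else:
            warnings.warn(
                "annotated selection requested but no annotation hits are "
                "available; falling back to longest contig"
            )
    return min(pool, key=lambda c: (-len(c.bases), c.bases))


def check_circularity(contig: Contig, min_overlap: int = MIN_OVERLAP,
                      max_mismatch_frac: float = MAX_MISMATCH_FRAC,
                      max_scan: int = MAX_SCAN) -> CircularityResult:
    """Find and trim the longest duplicated terminal overlap of a contig."""
    n = len(contig.bases)
    if n <= 2 * min_overlap:
        warnings.warn(
            f"contig {contig.contig_id!r} is too short ({n} bp) for a "
            f"circularity check at min_overlap={min_overlap}"
        )
        return CircularityResult(False, 0, contig)
    arr = np.frombuffer(contig.bases.encode("ascii"), dtype=np.uint8)
    hi = min(n // 2, max_scan)
    for ov in range(hi, min_overlap - 1, -1):
        mismatches = int(np.count_nonzero(arr[:ov] != arr[-ov:]))
        if mismatches <= max_mismatch_frac * ov:
            trimmed = Contig(contig.contig_id, contig.bases[:n - ov],
                             mean_depth=contig.mean_depth, source=contig.source,
                             circular=True)
            return CircularityResult(True, ov, trimmed)
    return CircularityResult(False, 0, contig)


def validate_candidate(pairs: Sequence[ReadPair], candidate: Contig,
                       nuclear_anchor: Contig,
                       support_ratio: float = SUPPORT_RATIO) -> ValidationReport:
    """Depth comparison of the candidate against a same-length nuclear window."""
    if not candidate.bases or not nuclear_anchor.bases:
        raise ValueError("candidate and nuclear anchor must be non-empty")
    span = len(candidate.bases)
    cand_profile = depth_profile(pairs, candidate, max_positions=span)
    nuc_window = Contig(nuclear_anchor.contig_id, nuclear_anchor.bases[:span],
                        source=nuclear_anchor.source)
    nuc_profile = depth_profile(pairs, nuc_window, max_positions=span)

    cand_mean = cand_profile.mean_depth()
    nuc_mean = nuc_profile.mean_depth()
    notes: list[str] = []
    if nuc_mean > 0:
        ratio = cand_mean / nuc_mean
        verdict = "supported" if ratio >= support_ratio else "unsupported"
    else:
        ratio = float("nan")
        verdict = "unsupported"
        notes.append(
            "no reads mapped to the nuclear anchor window; the depth "
            "comparison is uninformative"
        )
    if len(nuclear_anchor.bases) < span:
        notes.append(
            f"nuclear anchor ({len(nuclear_anchor.bases)} bp) is shorter than "
            f"the candidate ({span} bp); compared over the anchor length only"
        )
    return ValidationReport(cand_mean, nuc_mean, ratio, cand_profile,
                            nuc_profile, verdict, notes)


def write_depth_comparison(report: ValidationReport, path) -> None:
    """Tabular depth comparison (position, candidate depth, nuclear depth)."""
    cd = report.candidate_profile.depths
    nd = report.nuclear_profile.depths
    span = max(len(cd), len(nd))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["position", "candidate_depth", "nuclear_depth"])
        for i in range(span):
            w.writerow([i, int(cd[i]) if i < len(cd) else "",
                        int(nd[i]) if i < len(nd) else ""])


def plot_depth_comparison(report: ValidationReport, path) -> None:
    """Optional rendering of the depth comparison as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(report.candidate_profile.depths, label="candidate", lw=0.8)
    ax.plot(report.nuclear_profile.depths, label="nuclear window", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("read depth")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def annotation_hook(contigs: Sequence[Contig], hook_spec: str,
                    workdir: Optional[str] = None,
                    max_hits: int = 10) -> dict[str, list[AnnotationHit]]:
    """Run a user-supplied annotation command and collect its top hits.

    ``hook_spec`` is a shell template with ``{query_fasta}`` and
    ``{out_tsv}`` placeholders; the output must be 6-column tabular
    (query id, subject id, percent identity, alignment length, e-value,
    bit score). Failures degrade to a warning and an empty mapping:
    annotation is optional by design.
    """
    tmp = workdir or tempfile.mkdtemp(prefix="orgextract_annot_")
    query = os.path.join(tmp, "query.fasta")
    out_tsv = os.path.join(tmp, "hits.tsv")
    write_fasta(contigs, query)
    cmd = hook_spec.format(query_fasta=query, out_tsv=out_tsv)
    try:
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"exit {proc.returncode}: {proc.stderr.strip()}")
        hits: dict[str, list[tuple]] = {}
        with open(out_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                qid, sid, pident, alen, evalue, bits = line.split("\t")[:6]
                hits.setdefault(qid, []).append(AnnotationHit(
                    sid, float(pident), int(float(alen)), float(evalue),
                    float(bits)))
    except (OSError, RuntimeError, ValueError) as exc:
        warnings.warn(f"annotation hook failed, continuing without hits: {exc}")
        return {}
    out: dict[str, list[AnnotationHit]] = {}
    for qid, lst in hits.items():
        lst.sort(key=lambda h: (-h.bit_score, h.subject_id))
        out[qid] = lst[:max_hits]
    return out
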