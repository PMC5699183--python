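"""End-to-end orchestration: trim, anchor, threshold, sketch, bin,
assemble, circularise, validate — with a structured JSON run report.

Every stage records its parameters and counts; intermediate files are
kept in the output directory so a failed run can be inspected. Supplying
a nuclear anchor FASTA or an explicit depth threshold skips the initial
whole-pool assembly, which is by far the slowest stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass
from typing import Optional

from . import __version__
from .assembly import AssemblyConfig, Contig, assemble, run_external_assembler
from .binning import BinSummary, bin_reads
from .candidate_eval import (annotation_hook, check_circularity,
                             plot_depth_comparison, select_candidate,
                             validate_candidate, write_depth_comparison)
from .depth_threshold import (MAX_ANCHOR_BP, NDThreshold, depth_profile,
                              effective_read_length, kmer_threshold_from_nd,
                              nd_threshold)
from .io_preprocess import (PreprocessSummary, TrimConfig, parse_fasta,
                            parse_fastq, preprocess, write_fasta,
                            write_fastq_pairs)
from .kmer_sketch import build_sketch

logger = logging.getLogger("orgextract")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot continue; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    r1: str = ""
    r2: Optional[str] = None
    out_dir: str = "orgextract_out"
    anchor_fasta: Optional[str] = None
    nd_threshold: Optional[float] = None
    factor: float = 5.0
    k: int = 31
    min_length: int = 30
    quality_cutoff: int = 2
    adapters: tuple[str, ...] = ()
    sketch_width: int = 1 << 26
    sketch_depth: int = 3
    seed: int = 0
    keep_pairs: bool = True
    depth_conversion: bool = True
    mode: str = "longest"
    assembler: str = "builtin"  # or an external command template
    annotation_hook_spec: Optional[str] = None
    support_ratio: float = 5.0
    min_contig_length: int = 200
    anchor_truncate: int = MAX_ANCHOR_BP
    make_plot: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(report: dict, name: str, status: str, t0: float, **details):
    entry = {"stage": name, "status": status,
             "elapsed_s": round(time.monotonic() - t0, 3), **details}
    report["stages"].append(entry)
    logger.info("stage %-18s %s (%.2fs)", name, status, entry["elapsed_s"])
    return entry


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full extraction workflow; returns the run report dict."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {
        "tool": "orgextract",
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": [],
        "results": {},
    }
    report_path = os.path.join(cfg.out_dir, "report.json")

    def fail(stage: str, msg: str):
        _stage(report, stage, "failed", time.monotonic(), error=msg)
        _write_report(report, report_path)
        raise PipelineError(stage, msg)

    # 1. preprocess -----------------------------------------------------------
    t0 = time.monotonic()
    trim_cfg = TrimConfig(adapter_sequences=cfg.adapters,
                          min_length=cfg.min_length,
                          quality_cutoff=cfg.quality_cutoff)
    summary = PreprocessSummary()
    try:
        raw_pairs = parse_fastq(cfg.r1, cfg.r2)
        pairs = list(preprocess(raw_pairs, trim_cfg, summary))
    except (OSError, ValueError) as exc:
        fail("preprocess", str(exc))
    _stage(report, "preprocess", "done", t0, **summary.as_dict())
    if not pairs:
        fail("preprocess", "no reads survived trimming")

    reads_flat = [r for p in pairs for r in p]
    L = effective_read_length(reads_flat)
    report["results"]["effective_read_length"] = L

    # 2. anchor ---------------------------------------------------------------
    t0 = time.monotonic()
    anchor: Optional[Contig] = None
    if cfg.anchor_fasta:
        anchor_contigs = parse_fasta(cfg.anchor_fasta)
        if not anchor_contigs:
            fail("anchor", f"no sequences in {cfg.anchor_fasta}")
        anchor = min(anchor_contigs, key=lambda c: (-len(c.bases), c.bases))
        _stage(report, "anchor_assembly", "skipped", t0,
               reason="anchor supplied", anchor_id=anchor.contig_id,
               anchor_length=len(anchor.bases))
    elif cfg.nd_threshold is not None:
        _stage(report, "anchor_assembly", "skipped", t0,
               reason="nd_threshold supplied")
    else:
        # permissive first k so low-depth nuclear regions survive, strict at
        # later ks where carried-forward unitigs protect true k-mers
        asm_cfg = AssemblyConfig(first_k_min_count=1,
                                 min_contig_length=cfg.min_contig_length)
        if cfg.assembler == "builtin":
            contigs = assemble(pairs, asm_cfg)
        else:
            contigs = run_external_assembler(
                {"r1": cfg.r1, "r2": cfg.r2 or ""}, cfg.assembler,
                workdir=os.path.join(cfg.out_dir, "anchor_asm"))
        if not contigs:
            fail("anchor_assembly", "initial assembly produced no contigs")
        write_fasta(contigs, os.path.join(cfg.out_dir, "initial_assembly.fasta"))
        # longest contig is assumed nuclear; contigs that closed into a
        # circle are organelle candidates, not nuclear, so skip them here
        linear = [c for c in contigs if not c.circular] or contigs
        anchor = min(linear, key=lambda c: (-len(c.bases), c.bases))
        _stage(report, "anchor_assembly", "done", t0, n_contigs=len(contigs),
               anchor_id=anchor.contig_id, anchor_length=len(anchor.bases))

    # 3. depth threshold ------------------------------------------------------
    t0 = time.monotonic()
    if cfg.nd_threshold is not None:
        nd = NDThreshold(value=float(cfg.nd_threshold),
                         trimmed_mean=float("nan"), factor=cfg.factor, n_used=0)
        status, extra = "skipped", {"reason": "nd_threshold supplied"}
    else:
        profile = depth_profile(pairs, anchor, max_positions=cfg.anchor_truncate)
        try:
            nd = nd_threshold(profile, factor=cfg.factor)
        except ValueError as exc:
            fail("depth_threshold", str(exc))
        status, extra = "done", {"profile_length": len(profile)}
    kmer_threshold_from_nd(nd, L, cfg.k)
    bin_threshold = nd.kmer_threshold if cfg.depth_conversion else nd.value
    _stage(report, "depth_threshold", status, t0,
           nd_threshold=nd.value, trimmed_mean=nd.trimmed_mean,
           n_used=nd.n_used, kmer_threshold=nd.kmer_threshold,
           bin_threshold=bin_threshold, factor=nd.factor, L=L, k=cfg.k, **extra)
    with open(os.path.join(cfg.out_dir, "threshold.json"), "w") as fh:
        json.dump({"nd_threshold": nd.value, "trimmed_mean": nd.trimmed_mean,
                   "factor": nd.factor, "n_used": nd.n_used,
                   "kmer_threshold": nd.kmer_threshold, "L": L, "k": cfg.k},
                  fh, indent=2)

    # 4. sketch + binning -----------------------------------------------------
    t0 = time.monotonic()
    sketch = build_sketch(reads_flat, k=cfg.k, width=cfg.sketch_width,
                          depth=cfg.sketch_depth, seed=cfg.seed)
    _stage(report, "kmer_sketch", "done", t0, k=cfg.k, width=cfg.sketch_width,
           depth=cfg.sketch_depth, seed=cfg.seed,
           kmers_inserted=sketch.total_kmers_inserted)

    t0 = time.monotonic()
    bin_summary = BinSummary()
    binned = list(bin_reads(pairs, sketch, bin_threshold,
                            keep_pairs=cfg.keep_pairs, summary=bin_summary))
    write_fastq_pairs(binned,
                      os.path.join(cfg.out_dir, "binned_R1.fastq"),
                      os.path.join(cfg.out_dir, "binned_R2.fastq"),
                      os.path.join(cfg.out_dir, "binned_singletons.fastq"))
    _stage(report, "binning", "done", t0, threshold=bin_threshold,
           **bin_summary.as_dict())
    if not binned:
        fail("binning", "no reads carry a k-mer above the threshold; "
                        "consider lowering --nd-threshold or --factor")

    # 5. second assembly ------------------------------------------------------
    t0 = time.monotonic()
    asm_cfg = AssemblyConfig(min_contig_length=cfg.min_contig_length)
    if cfg.assembler == "builtin":
        contigs = assemble(binned, asm_cfg)
    else:
        contigs = run_external_assembler(
            {"r1": os.path.join(cfg.out_dir, "binned_R1.fastq"),
             "r2": os.path.join(cfg.out_dir, "binned_R2.fastq")},
            cfg.assembler, workdir=os.path.join(cfg.out_dir, "highfreq_asm"))
    if not contigs:
        fail("assembly", "assembly of the binned reads produced no contigs; "
                         "the threshold may be too high")
    write_fasta(contigs, os.path.join(cfg.out_dir, "highfreq_assembly.fasta"))
    _stage(report, "assembly", "done", t0, n_contigs=len(contigs),
           longest=len(contigs[0].bases))

    # 6. candidate selection + circularity -----------------------------------
    t0 = time.monotonic()
    hits = None
    if cfg.annotation_hook_spec:
        hits = annotation_hook(contigs, cfg.annotation_hook_spec,
                               workdir=os.path.join(cfg.out_dir, "annotation"))
        report["results"]["annotation_hits"] = {
            cid: [asdict(h) for h in lst] for cid, lst in hits.items()}
    candidate = select_candidate(contigs, mode=cfg.mode, hits=hits)
    circ = check_circularity(candidate)
    candidate = circ.trimmed
    write_fasta([candidate], os.path.join(cfg.out_dir, "candidate.fasta"))
    with open(os.path.join(cfg.out_dir, "circularity.json"), "w") as fh:
        json.dump({"is_circular": circ.is_circular,
                   "overlap_length": circ.overlap_length,
                   "trimmed_length": len(candidate.bases)}, fh, indent=2)
    _stage(report, "candidate", "done", t0, candidate_id=candidate.contig_id,
           length=len(candidate.bases), is_circular=circ.is_circular,
           overlap_length=circ.overlap_length)

    # 7. validation -----------------------------------------------------------
    t0 = time.monotonic()
    if anchor is None:
        _stage(report, "validation", "skipped", t0,
               reason="no nuclear anchor available")
        validation = None
    else:
        validation = validate_candidate(pairs, candidate, anchor,
                                        support_ratio=cfg.support_ratio)
        write_depth_comparison(validation,
                               os.path.join(cfg.out_dir, "depth_comparison.tsv"))
        if cfg.make_plot:
            plot_depth_comparison(validation,
                                  os.path.join(cfg.out_dir, "depth_comparison.png"))
        candidate.mean_depth = validation.candidate_mean_depth
        _stage(report, "validation", "done", t0,
               candidate_mean_depth=validation.candidate_mean_depth,
               nuclear_mean_depth=validation.nuclear_mean_depth,
               depth_ratio=validation.depth_ratio, verdict=validation.verdict,
               notes=validation.notes)

    report["results"].update({
        "nd_threshold": nd.value,
        "kmer_threshold": nd.kmer_threshold,
        "candidate": {
            "id": candidate.contig_id,
            "length": len(candidate.bases),
            "is_circular": circ.is_circular,
            "overlap_length": circ.overlap_length,
            "mean_depth": candidate.mean_depth,
        },
        "depth_ratio": validation.depth_ratio if validation else None,
        "verdict": validation.verdict if validation else None,
    })
    _write_report(report, report_path)
    return report


def _write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
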