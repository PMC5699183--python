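# orgextract

Reference-free extraction and de novo assembly of organelle (mitochondrial /
plastid) genomes from whole-genome shotgun short reads.

Organelle genomes are present at 10–100 copies per nuclear genome, so their
reads carry k-mers that occur far more often in the read pool than nuclear
k-mers. `orgextract` exploits this without any reference or seed sequence:

1. **Preprocess** — adapter/quality trimming with a minimum-length filter
   (default 30 bp).
2. **Anchor** — an initial whole-pool assembly; the longest (non-circular)
   contig is assumed nuclear. Skipped when you supply an anchor FASTA or an
   explicit threshold.
3. **Depth threshold** — reads are mapped back to the first 100,000 bp of the
   anchor; the nuclear-depth (ND) threshold is 5× the mean of the non-zero
   per-base depths between the 25th and 75th percentiles. It is converted to
   k-mer-count units via `N = M·L/(L−k+1)`.
4. **Count & bin** — canonical 31-mers are counted in a Count-Min Sketch
   (one-sided error: estimates never undercount, so no high-depth read can be
   lost); reads with at least one k-mer strictly above the threshold are
   retained, with optional mate rescue.
5. **Assemble, circularise, validate** — the binned reads are assembled
   (built-in iterative-k de Bruijn unitig assembler, or any external assembler
   via a command template); the longest contig is checked for a duplicated
   terminal overlap, trimmed once if circular, and validated by comparing its
   read depth against an equally long nuclear window.

## CLI

```bash
# full pipeline
orgextract run --in R1.fastq.gz --in2 R2.fastq.gz --out-dir run1 \
    [--anchor nuclear.fasta | --nd-threshold 50] [--factor 5] [--k 31] \
    [--assembler builtin] [--mode longest|annotated] [--plot]

# individual stages
orgextract preprocess --in R1.fq --in2 R2.fq --min-length 30 --out-prefix trimmed
orgextract count      --reads trimmed_R1.fastq --k 31 --sketch pool.cms
orgextract threshold  --reads trimmed_R1.fastq --anchor nuclear.fasta
orgextract bin        --reads trimmed_R1.fastq --sketch pool.cms --threshold 35
orgextract assemble   --reads binned_R1.fastq --out contigs.fasta

# labelled synthetic data (nuclear + high-copy circular organelle)
orgextract simulate --spec spec.yaml --out-dir fixtures/
```

`run` writes `report.json` (stage-by-stage parameters and counts),
`threshold.json`, `candidate.fasta`, `circularity.json`,
`depth_comparison.tsv` (and `.png` with `--plot`), plus both intermediate
assemblies and the binned FASTQ files.

External assemblers plug in as templates, e.g.
`--assembler "megahit -1 {r1} -2 {r2} -o {outdir}"`. Annotation (e.g. BLAST
against organelle references) is an optional hook:
`--annotation-hook "blastn -query {query_fasta} -db mito -outfmt 6 -out {out_tsv}"`;
the top 10 hits per contig by bit-score are reported and can drive
`--mode annotated` candidate selection.

### Fragmented assemblies / plastids

For plant samples the high-frequency assembly typically contains fragmented
chloroplast and mitochondrial contigs. Use the saved
`highfreq_assembly.fasta` (e.g. its longest contigs, or the ones flagged by
the annotation hook) as seed sequences for a seed-based extender such as
NOVOPlasty or MITObim, then validate the result by circularity and depth.

## Library use

```python
from orgextract import (SyntheticDatasetSpec, simulate, PipelineConfig,
                        run_pipeline, score_recovery)

ds = simulate(SyntheticDatasetSpec(seed=1), out_dir="sim")
report = run_pipeline(PipelineConfig(r1=ds.r1_path, r2=ds.r2_path,
                                     out_dir="run", seed=1))
```

`score_recovery` compares a candidate against the simulated truth by
anchored ungapped alignment on the doubled organelle sequence (handles any
rotation and strand); it is exact for the substitution-only error model the
simulator uses and is not a general-purpose aligner.

## Notes & limitations

- The built-in assembler is a deliberately small unitig assembler (iterative
  k = 21/41/61, single-substitution read correction, tip and dominated-arm
  popping). It is meant for the small high-depth read subsets this pipeline
  produces and for deterministic testing; use an external assembler for real
  deployments.
- The built-in mapper does exact-seed ungapped placement and produces depth
  profiles only (no SAM/BAM).
- Count-Min Sketch estimates are one-sided: collisions can only add nuclear
  false positives, which end up as short contigs and never displace the
  organelle candidate.
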