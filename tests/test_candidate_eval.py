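import os
import stat

import numpy as np
import pytest

from orgextract.assembly import Contig
from orgextract.candidate_eval import (AnnotationHit, annotation_hook,
                                       check_circularity, select_candidate,
                                       validate_candidate,
                                       write_depth_comparison)
from orgextract.io_preprocess import ReadPair
from .conftest import make_read, random_seq, tile_reads


def _pairs(seqs):
    return [ReadPair(make_read(s, f"r{i}")) for i, s in enumerate(seqs)]


class TestSelectCandidate:
    def test_longest_wins(self, rng):
        contigs = [Contig("a", random_seq(rng, 16000)),
                   Contig("b", random_seq(rng, 3000)),
                   Contig("c", random_seq(rng, 900))]
        assert select_candidate(contigs).contig_id == "a"

    def test_tie_breaks_lexicographically(self):
        contigs = [Contig("x", "TTTTT" * 50), Contig("y", "AAAAA" * 50)]
        assert select_candidate(contigs).contig_id == "y"

    def test_annotated_mode_prefers_hit(self, rng):
        contigs = [Contig("big", random_seq(rng, 3000)),
                   Contig("hit", random_seq(rng, 1000))]
        hits = {"hit": [AnnotationHit("s", 99.0, 500, 1e-50, 900.0)]}
        assert select_candidate(contigs, mode="annotated", hits=hits).contig_id == "hit"

    def test_annotated_mode_falls_back_with_warning(self, rng):
        contigs = [Contig("big", random_seq(rng, 3000)),
                   Contig("small", random_seq(rng, 1000))]
        with pytest.warns(UserWarning):
            chosen = select_candidate(contigs, mode="annotated", hits={})
        assert chosen.contig_id == "big"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_candidate([])

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            select_candidate([Contig("a", "ACGT")], mode="shortest")


class TestCheckCircularity:
    def test_engineered_overlap_trimmed_exactly(self, rng):
        s = random_seq(rng, 5000)
        contig = Contig("c", s + s[:80])
        res = check_circularity(contig, min_overlap=50)
        assert res.is_circular
        assert res.overlap_length == 80
        assert res.trimmed.bases == s
        assert res.trimmed.circular

    def test_no_overlap_not_circular(self, rng):
        contig = Contig("c", random_seq(rng, 5000))
        res = check_circularity(contig)
        assert not res.is_circular
        assert res.overlap_length == 0
        assert res.trimmed.bases == contig.bases

    def test_overlap_below_min_ignored(self, rng):
        s = random_seq(rng, 5000)
        res = check_circularity(Contig("c", s + s[:30]), min_overlap=50)
        assert not res.is_circular

    def test_mismatch_tolerance(self, rng):
        s = random_seq(rng, 4000)
        overlap = list(s[:200])
        overlap[100] = "A" if overlap[100] != "A" else "C"  # 1 mismatch in 200
        res = check_circularity(Contig("c", s + "".join(overlap)))
        assert res.is_circular
        assert res.overlap_length == 200

    def test_trim_idempotent(self, rng):
        s = random_seq(rng, 5000)
        res = check_circularity(Contig("c", s + s[:123]))
        again = check_circularity(res.trimmed)
        assert not again.is_circular
        assert again.trimmed.bases == s

    def test_short_contig_warns(self):
        with pytest.warns(UserWarning):
            res = check_circularity(Contig("c", "ACGT" * 20), min_overlap=50)
        assert not res.is_circular


class TestValidateCandidate:
    def test_copy_ratio_recovered(self, rng):
        nuclear = random_seq(rng, 3000)
        organelle = random_seq(rng, 1500)
        reads = tile_reads(nuclear, 100, 20)          # 5x
        reads += tile_reads(organelle, 100, 1)        # 100x -> ratio 20
        report = validate_candidate(_pairs(reads), Contig("cand", organelle),
                                    Contig("nuc", nuclear))
        assert 14 <= report.depth_ratio <= 26
        assert report.verdict == "supported"

    def test_self_comparison_unsupported(self, rng):
        nuclear = random_seq(rng, 3000)
        reads = tile_reads(nuclear, 100, 10)
        candidate = Contig("cand", nuclear[:1000])
        report = validate_candidate(_pairs(reads), candidate, Contig("nuc", nuclear))
        assert report.depth_ratio == pytest.approx(1.0, abs=0.35)
        assert report.verdict == "unsupported"

    def test_no_nuclear_coverage_is_diagnosed(self, rng):
        organelle = random_seq(rng, 1000)
        reads = tile_reads(organelle, 100, 2)
        report = validate_candidate(_pairs(reads), Contig("cand", organelle),
                                    Contig("nuc", random_seq(rng, 1500)))
        assert report.verdict == "unsupported"
        assert report.notes
        assert np.isnan(report.depth_ratio)

    def test_depth_comparison_table(self, rng, tmp_path):
        nuclear = random_seq(rng, 800)
        reads = tile_reads(nuclear, 100, 10)
        report = validate_candidate(_pairs(reads), Contig("c", nuclear[:500]),
                                    Contig("n", nuclear))
        out = tmp_path / "cmp.tsv"
        write_depth_comparison(report, out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "position\tcandidate_depth\tnuclear_depth"
        assert len(lines) == 501


class TestAnnotationHook:
    def _hook_script(self, tmp_path, rows):
        script = tmp_path / "fake_blast.sh"
        body = "\n".join(f'printf \'%s\\n\' "{r}" >> "$2"' for r in rows)
        script.write_text(f"#!/bin/sh\n: > \"$2\"\n{body}\n")
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        return f"{script} {{query_fasta}} {{out_tsv}}"

    def test_top_ten_by_bitscore(self, tmp_path, rng):
        rows = [f"c1\tsubj{i:02d}\t99.0\t500\t1e-10\t{100 + i}" for i in range(12)]
        spec = self._hook_script(tmp_path, rows)
        hits = annotation_hook([Contig("c1", random_seq(rng, 300))], spec,
                               workdir=str(tmp_path))
        assert len(hits["c1"]) == 10
        scores = [h.bit_score for h in hits["c1"]]
        assert scores == sorted(scores, reverse=True)
        assert hits["c1"][0].subject_id == "subj11"

    def test_bitscore_ties_stable_by_subject(self, tmp_path, rng):
        rows = [f"c1\tzzz\t99.0\t500\t1e-10\t200",
                f"c1\taaa\t99.0\t500\t1e-10\t200"]
        spec = self._hook_script(tmp_path, rows)
        hits = annotation_hook([Contig("c1", random_seq(rng, 300))], spec,
                               workdir=str(tmp_path))
        assert [h.subject_id for h in hits["c1"]] == ["aaa", "zzz"]

    def test_failing_tool_degrades_to_empty(self, tmp_path, rng):
        with pytest.warns(UserWarning):
            hits = annotation_hook([Contig("c1", "ACGTACGT")],
                                   "false", workdir=str(tmp_path))
        assert hits == {}
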