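import numpy as np
import pytest

from orgextract.assembly import Contig
from orgextract.kmer_sketch import reverse_complement
from orgextract.synthetic_data import (SyntheticDatasetSpec, score_recovery,
                                       simulate)

SMALL = dict(nuclear_length=20_000, organelle_length=6_000, copy_ratio=20.0,
             nuclear_depth=10.0, read_length=100, insert_mean=300,
             insert_sd=30, error_rate=0.0)


class TestSpecValidation:
    def test_copy_ratio_must_exceed_one(self):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(copy_ratio=1.0)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(error_rate=0.2)

    def test_infeasible_insert(self):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(organelle_length=200, insert_mean=300)


class TestSimulate:
    def test_read_count_ratio_matches_copy_ratio(self):
        spec = SyntheticDatasetSpec(**SMALL, seed=5)
        ds = simulate(spec)
        counts = ds.truth.label_counts()
        n_org = 2 * counts["organelle"]
        n_nuc = 2 * (counts["nuclear"] + counts.get("numt", 0))
        expected = 20 * 6000 / 20000
        # binomial-ish tolerance: 3 SD around the expected ratio
        assert n_org / n_nuc == pytest.approx(expected, rel=0.1)

    def test_deterministic_fastq_bytes(self, tmp_path):
        spec = SyntheticDatasetSpec(**SMALL, seed=7)
        a = simulate(spec, out_dir=tmp_path / "a", gzip_output=False)
        b = simulate(spec, out_dir=tmp_path / "b", gzip_output=False)
        assert open(a.r1_path, "rb").read() == open(b.r1_path, "rb").read()
        assert open(a.r2_path, "rb").read() == open(b.r2_path, "rb").read()

    def test_different_seed_differs(self):
        a = simulate(SyntheticDatasetSpec(**SMALL, seed=1))
        b = simulate(SyntheticDatasetSpec(**SMALL, seed=2))
        assert a.truth.organelle_seq != b.truth.organelle_seq

    def test_wraparound_fragments_exist(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=3))
        wraps = [rid for rid, (s, e) in ds.truth.read_coords.items()
                 if rid.startswith("sim_org") and e > 6000]
        assert wraps  # circular sampling guarantees junction-spanning pairs

    def test_labels_partition_reads(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=4))
        assert set(ds.truth.read_origins) == {p.r1.read_id for p in ds.pairs}
        assert sum(ds.truth.label_counts().values()) == len(ds.pairs)

    def test_empirical_depth_ratio(self):
        spec = SyntheticDatasetSpec(**SMALL, seed=9)
        ds = simulate(spec)
        org_bases = sum(e - s for rid, (s, e) in ds.truth.read_coords.items()
                        if ds.truth.read_origins[rid] == "organelle")
        nuc_bases = sum(e - s for rid, (s, e) in ds.truth.read_coords.items()
                        if ds.truth.read_origins[rid] != "organelle")
        ratio = (org_bases / 6000) / (nuc_bases / 20000)
        assert ratio == pytest.approx(20.0, rel=0.1)

    def test_error_rate_applied(self):
        spec_err = dict(SMALL)
        spec_err["error_rate"] = 0.01
        noisy = simulate(SyntheticDatasetSpec(**spec_err, seed=6))
        org2 = noisy.truth.organelle_seq * 2
        diffs = total = 0
        for p in noisy.pairs[:500]:
            rid = p.r1.read_id
            s, e = noisy.truth.read_coords[rid]
            template = org2 if noisy.truth.read_origins[rid] == "organelle" \
                else noisy.truth.nuclear_seq
            true_r1 = template[s:s + len(p.r1.bases)]
            diffs += sum(a != b for a, b in zip(p.r1.bases, true_r1))
            total += len(true_r1)
        assert diffs / total == pytest.approx(0.01, rel=0.3)

    def test_numt_insertions_labelled(self):
        spec = SyntheticDatasetSpec(**SMALL, numt_count=3, numt_length=400,
                                    seed=8)
        ds = simulate(spec)
        assert len(ds.truth.numt_positions) == 3
        assert ds.truth.label_counts()["numt"] > 0
        for dst, (src_a, src_b) in ds.truth.numt_positions:
            assert ds.truth.nuclear_seq[dst:dst + 400] == \
                ds.truth.organelle_seq[src_a:src_b]

    def test_low_quality_tail(self):
        spec = SyntheticDatasetSpec(**SMALL, low_quality_tail=10, seed=2)
        ds = simulate(spec)
        quals = ds.pairs[0].r1.qual_scores()
        assert all(q == 2 for q in quals[-10:])
        assert all(q == 35 for q in quals[:-10])

    def test_truth_files_written(self, tmp_path):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=1),
                      out_dir=tmp_path, gzip_output=True)
        assert ds.r1_path.endswith(".gz")
        from orgextract.io_preprocess import parse_fastq
        pairs = list(parse_fastq(ds.r1_path, ds.r2_path))
        assert len(pairs) == len(ds.pairs)
        lines = open(ds.truth_table).read().strip().split("\n")
        assert len(lines) == len(ds.pairs) + 1


class TestScoreRecovery:
    def test_rotation_scores_perfectly(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        org = ds.truth.organelle_seq
        rotated = org[1000:] + org[:1000]
        identity, coverage = score_recovery(Contig("c", rotated), ds.truth)
        assert identity == 1.0
        assert coverage == 1.0

    def test_reverse_complement_scores_perfectly(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        rc = reverse_complement(ds.truth.organelle_seq)
        identity, coverage = score_recovery(Contig("c", rc), ds.truth)
        assert identity == 1.0
        assert coverage == 1.0

    def test_rotated_reverse_complement(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        org = ds.truth.organelle_seq
        rc = reverse_complement(org[4321:] + org[:4321])
        identity, coverage = score_recovery(Contig("c", rc), ds.truth)
        assert identity == 1.0
        assert coverage == 1.0

    def test_nuclear_fragment_scores_zero(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        frag = ds.truth.nuclear_seq[2000:4000]
        identity, coverage = score_recovery(Contig("c", frag), ds.truth)
        assert coverage == 0.0

    def test_empty_candidate(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        assert score_recovery(None, ds.truth) == (0.0, 0.0)

    def test_partial_coverage(self):
        ds = simulate(SyntheticDatasetSpec(**SMALL, seed=10))
        half = ds.truth.organelle_seq[:3000]
        identity, coverage = score_recovery(Contig("c", half), ds.truth)
        assert identity == 1.0
        assert coverage == pytest.approx(0.5, abs=0.01)
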