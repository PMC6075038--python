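import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausepier.core import (
    GenomeAnnotation,
    Interval,
    SignalTrack,
    Transcript,
    merge_intervals,
    region_rpkm,
    rpm_normalize,
    smooth_track,
)
from pausepier.io import read_annotation, read_bedgraph, read_intervals, write_bedgraph

from conftest import make_track

SIZES = {"chrI": 100}


def write(tmp_path, text, name="in.bedgraph"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestBedgraphIO:
    def test_record_expands_to_dense_vector(self, tmp_path):
        p = write(tmp_path, "chrI\t10\t13\t5.0\n")
        t = read_bedgraph(p, SIZES, strand="+")
        v = t.values("chrI", "+")
        assert list(v[10:13]) == [5.0, 5.0, 5.0]
        assert v.sum() == 15.0

    def test_empty_file_gives_zero_track(self, tmp_path):
        t = read_bedgraph(write(tmp_path, ""), SIZES, strand="+")
        assert t.total_reads == 0

    @pytest.mark.parametrize(
        "text,match",
        [
            ("chrI\t0\t5\t1\nchrI\t3\t8\t1\n", "overlap"),
            ("chrZ\t0\t5\t1\n", "chrZ"),
            ("chrI\t0\t5\t-2\n", "negative"),
            ("chrI\t90\t200\t1\n", "bad interval"),
        ],
    )
    def test_malformed_inputs_error(self, tmp_path, text, match):
        with pytest.raises(ValueError, match=match):
            read_bedgraph(write(tmp_path, text), SIZES, strand="+")

    def test_single_position_written_as_one_record(self, tmp_path):
        t = make_track(np.zeros(20), chrom="chr")
        t.values("chr", "+")[7] = 3
        p = tmp_path / "out.bedgraph"
        write_bedgraph(t, p, strand="+")
        assert p.read_text().strip() == "chr\t7\t8\t3"

    def test_all_zero_track_writes_empty_data_section(self, tmp_path):
        p = tmp_path / "out.bedgraph"
        write_bedgraph(make_track(np.zeros(50)), p, strand="+")
        assert p.read_text() == ""

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=60))
    def test_roundtrip_identity_for_integer_tracks(self, values):
        import tempfile, os

        t = make_track(np.asarray(values, dtype=float), chrom="c")
        fd, path = tempfile.mkstemp()
        os.close(fd)
        try:
            write_bedgraph(t, path, strand="+")
            back = read_bedgraph(path, {"c": len(values)}, strand="+")
            np.testing.assert_array_equal(back.values("c", "+"), t.values("c", "+"))
        finally:
            os.unlink(path)


class TestAnnotationIO:
    def test_gff3_converts_to_zero_based_half_open(self, tmp_path):
        p = write(tmp_path, "chrI\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1;biotype=ncRNA\n", "a.gff3")
        ann = read_annotation(p, SIZES, dialect="gff3")
        t = ann.transcripts[0]
        assert (t.start, t.end, t.cls, t.essential) == (0, 10, "ncRNA", False)

    def test_bed6_native_coordinates(self, tmp_path):
        p = write(tmp_path, "chrI\t0\t10\tgeneA\t0\t+\n", "a.bed")
        ann = read_annotation(p, SIZES, dialect="bed6")
        t = ann.transcripts[0]
        assert (t.start, t.end, t.strand, t.id) == (0, 10, "+", "geneA")

    def test_feature_beyond_chromosome_end_errors(self, tmp_path):
        p = write(tmp_path, "chrI\tsrc\tgene\t1\t500\t.\t+\t.\tID=g1\n", "a.gff3")
        with pytest.raises(ValueError, match="outside"):
            read_annotation(p, SIZES, dialect="gff3")

    def test_bed_intervals_reader(self, tmp_path):
        p = write(tmp_path, "chrI\t5\t25\tsite1\t0\t-\n", "s.bed")
        ivs = read_intervals(p, SIZES)
        assert ivs[0] == Interval("chrI", 5, 25, "-", "site1")


class TestSmoothing:
    def test_uniform_track_is_invariant(self):
        t = make_track(np.full(500, 7.0))
        for w in (1, 10, 101, 500):
            np.testing.assert_allclose(
                smooth_track(t, w).values("chrI", "+"), 7.0, rtol=1e-12
            )

    def test_delta_matches_direct_convolution_oracle(self):
        v = np.zeros(5000)
        v[2500] = 1000.0
        t = make_track(v)
        w = 1000
        got = smooth_track(t, w).values("chrI", "+")
        # direct window-sum oracle (even windows take the extra position
        # downstream; ends truncated and renormalized)
        lo, hi = (w - 1) // 2, w // 2
        expected = np.array(
            [v[max(i - lo, 0) : min(i + hi + 1, v.size)].mean() for i in range(v.size)]
        )
        np.testing.assert_allclose(got, expected, atol=1e-9)
        assert got[2500] == pytest.approx(1.0)

    def test_window_one_is_identity(self, rng):
        v = rng.poisson(3, 200).astype(float)
        t = make_track(v)
        np.testing.assert_array_equal(smooth_track(t, 1).values("chrI", "+"), v)

    def test_linearity(self, rng):
        a, b = 2.5, -1.0
        v1, v2 = rng.random(300), rng.random(300)
        left = smooth_track(make_track(a * v1 + b * v2), 50).values("chrI", "+")
        right = a * smooth_track(make_track(v1), 50).values("chrI", "+") + b * smooth_track(
            make_track(v2), 50
        ).values("chrI", "+")
        np.testing.assert_allclose(left, right, rtol=1e-9)

    def test_window_below_one_errors(self):
        with pytest.raises(ValueError):
            smooth_track(make_track([1.0, 2.0]), 0)


class TestNormalization:
    def test_rpm_scales_to_one_million(self, rng):
        t = make_track(rng.poisson(5, 1000).astype(float))
        out = rpm_normalize(t)
        assert out.total_reads == pytest.approx(1e6, rel=1e-9)
        scale = 1e6 / t.total_reads
        np.testing.assert_allclose(
            out.values("chrI", "+"), t.values("chrI", "+") * scale
        )

    def test_rpm_idempotent_up_to_scale(self, rng):
        t = make_track(rng.poisson(5, 100).astype(float) + 1)
        once = rpm_normalize(t)
        twice = rpm_normalize(once)
        np.testing.assert_allclose(
            once.values("chrI", "+"), twice.values("chrI", "+"), rtol=1e-12
        )

    def test_rpm_zero_track_errors(self):
        with pytest.raises(ValueError):
            rpm_normalize(make_track(np.zeros(10)))

    def test_rpkm_definitional(self):
        v = np.zeros(10_000)
        v[:1000] = 0.1  # 100 reads in the 1-kb interval of interest
        v[2000] = 1e6 - 100  # pad the library to exactly 1e6 total reads
        t = make_track(v)
        assert region_rpkm(t, Interval("chrI", 0, 1000, "+")) == pytest.approx(100.0)

    def test_rpkm_halves_when_interval_doubles(self, rng):
        v = np.zeros(4000)
        v[:500] = 2.0
        t = make_track(v)
        r1 = region_rpkm(t, Interval("chrI", 0, 1000, "+"))
        r2 = region_rpkm(t, Interval("chrI", 0, 2000, "+"))
        assert r2 == pytest.approx(r1 / 2)

    def test_rpkm_matches_naive_loop_oracle(self, rng):
        v = rng.poisson(2, 5000).astype(float)
        t = make_track(v)
        iv = Interval("chrI", 1234, 3456, "+")
        reads = sum(float(v[i]) for i in range(iv.start, iv.end))
        expected = (reads / (iv.length / 1000)) / (t.total_reads / 1e6)
        assert region_rpkm(t, iv) == pytest.approx(expected, rel=1e-12)

    def test_rpkm_partition_reconstructs_total_density(self, rng):
        v = rng.poisson(4, 6000).astype(float)
        t = make_track(v)
        cuts = [0, 700, 2100, 4000, 6000]
        parts = [Interval("chrI", a, b, "+") for a, b in zip(cuts, cuts[1:])]
        weighted = sum(region_rpkm(t, iv) * iv.length for iv in parts) / 6000
        total_density = region_rpkm(t, Interval("chrI", 0, 6000, "+"))
        assert weighted == pytest.approx(total_density, rel=1e-9)


class TestDomainTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            Interval("chrI", 5, 5)
        with pytest.raises(ValueError):
            Interval("chrI", -1, 4)

    def test_transcript_length_consistency(self):
        t = Transcript("g", "chrI", "+", 10, 30)
        assert t.length == 20

    def test_annotation_rejects_out_of_bounds_transcript(self):
        with pytest.raises(ValueError, match="outside"):
            GenomeAnnotation(
                chrom_sizes={"chrI": 50},
                transcripts=[Transcript("g", "chrI", "+", 10, 80)],
            )

    def test_interval_distance_boundary_to_boundary(self):
        a = Interval("chrI", 0, 10)
        assert a.distance(Interval("chrI", 5, 20)) == 0
        assert a.distance(Interval("chrI", 25, 30)) == 15

    def test_merge_intervals_gap_rule(self):
        merged = merge_intervals(
            [Interval("c", 0, 10), Interval("c", 14, 20), Interval("c", 40, 45)], gap=5
        )
        assert [(m.start, m.end) for m in merged] == [(0, 20), (40, 45)]
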