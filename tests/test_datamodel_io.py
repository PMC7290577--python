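import numpy as np
import pytest

from retrofunc import io as rio
from retrofunc.datamodel import (
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    SampleMeta,
    TranscriptModel,
    ValidationError,
)


class TestGenomicInterval:
    def test_valid(self):
        iv = GenomicInterval("chr1", 10, 20, "+")
        assert len(iv) == 10

    @pytest.mark.parametrize(
        "start,end,strand",
        [(-1, 5, "+"), (10, 10, "+"), (10, 5, "-"), (0, 5, "x")],
    )
    def test_invalid(self, start, end, strand):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end, strand)

    def test_overlap_length(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        assert a.overlap_length(b) == 50
        assert a.overlap_length(GenomicInterval("chr2", 50, 150)) == 0


class TestTranscriptModel:
    def test_single_exon_plus(self):
        t = TranscriptModel(
            "t1", "g1", "other",
            (GenomicInterval("chr1", 100, 400, "+"),),
        )
        assert t.tss == 100
        assert t.tes == 399

    def test_minus_strand_tss(self):
        t = TranscriptModel(
            "t1", "g1", "other",
            (
                GenomicInterval("chr1", 100, 200, "-"),
                GenomicInterval("chr1", 300, 400, "-"),
            ),
        )
        assert t.tss == 399
        assert t.tes == 100

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t1", "g1", "other",
                (
                    GenomicInterval("chr1", 100, 250, "+"),
                    GenomicInterval("chr1", 200, 300, "+"),
                ),
            )

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t1", "g1", "protein_coding",
                (GenomicInterval("chr1", 100, 200, "+"),),
                cds_span=GenomicInterval("chr1", 300, 400, "+"),
            )

    def test_utr_cds_split(self):
        t = TranscriptModel(
            "t1", "g1", "protein_coding",
            (
                GenomicInterval("chr1", 0, 100, "+"),
                GenomicInterval("chr1", 200, 300, "+"),
            ),
            cds_span=GenomicInterval("chr1", 50, 250, "+"),
        )
        regions = t.utr_cds_regions()
        assert [(iv.start, iv.end) for iv in regions["utr5"]] == [(0, 50)]
        assert [(iv.start, iv.end) for iv in regions["cds"]] == [
            (50, 100), (200, 250),
        ]
        assert [(iv.start, iv.end) for iv in regions["utr3"]] == [(250, 300)]


class TestAnnotationReader:
    def test_bed12_single_exon(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t100\t400\tt1|g1|protein_coding\t0\t+\t100\t100\t0\t1\t300\t0\n"
        )
        genes = rio.read_annotation(p)
        (t,) = genes["g1"]
        assert t.tss == 100 and t.tes == 399 and t.cds_span is None

    def test_bed12_three_blocks_union_length(self, tmp_path, rng):
        # brute-force oracle: per-base union count
        sizes, starts = [50, 60, 70], [0, 100, 300]
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t1000\t1370\tt1|g1|lncRNA\t0\t-\t1000\t1000\t0\t3\t"
            + ",".join(map(str, sizes)) + "\t" + ",".join(map(str, starts))
            + "\n"
        )
        (t,) = rio.read_annotation(p)["g1"]
        assert len(t.exons) == 3
        covered = set()
        for s, size in zip(starts, sizes):
            covered.update(range(1000 + s, 1000 + s + size))
        assert t.transcribed_length == len(covered) == sum(sizes)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\tnope\tt1\t0\t+\t0\t0\t0\t1\t10\t0\n")
        with pytest.raises(rio.ParseError, match=":1"):
            rio.read_annotation(p)

    def test_gtf_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t400\t.\t+\t.\tgene_id "g1"; '
            'transcript_id "t1"; transcript_biotype "protein_coding";\n'
            'chr1\tsrc\tCDS\t151\t350\t.\t+\t.\tgene_id "g1"; '
            'transcript_id "t1";\n'
        )
        (t,) = rio.read_annotation(p)["g1"]
        assert t.exons[0].start == 100 and t.exons[0].end == 400
        assert t.cds_span.start == 150 and t.cds_span.end == 350
        assert t.biotype == "protein_coding"

    def test_bed12_round_trip(self, tmp_path, sim_world):
        _, annotation, _, _ = sim_world
        transcripts = [t for g in annotation for t in annotation[g]]
        p = tmp_path / "rt.bed"
        rio.write_bed12(transcripts, p)
        back = rio.read_annotation(p)
        flat = {t.transcript_id: t for g in back for t in back[g]}
        for t in transcripts:
            assert flat[t.transcript_id] == t


def _write_catalog(path, counts):
    lines = ["\t".join(rio.CATALOG_COLUMNS)]
    i = 0
    for status, n in counts.items():
        for _ in range(n):
            i += 1
            lines.append(
                f"r{i}\tchr1\t{i * 10}\t{i * 10 + 5}\t+\t{status}\tG1"
            )
    path.write_text("\n".join(lines) + "\n")


class TestCatalogReader:
    def test_tally_sums_grch37(self, tmp_path):
        p = tmp_path / "cat.tsv"
        _write_catalog(
            p,
            {"known_protein_coding": 106, "known_pseudogene": 4384,
             "novel": 121},
        )
        records, tally = rio.read_retrocopy_catalog(p)
        assert sum(tally.values()) == len(records) == 4611

    def test_tally_sums_grch38(self, tmp_path):
        p = tmp_path / "cat.tsv"
        _write_catalog(
            p,
            {"known_pseudogene": 4351, "known_protein_coding": 111,
             "novel": 77, "other": 15},
        )
        records, tally = rio.read_retrocopy_catalog(p)
        assert sum(tally.values()) == len(records) == 4554

    def test_empty_catalog(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("\t".join(rio.CATALOG_COLUMNS) + "\n")
        records, tally = rio.read_retrocopy_catalog(p)
        assert records == [] and sum(tally.values()) == 0

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text(
            "\t".join(rio.CATALOG_COLUMNS) + "\n"
            "r1\tchr1\t0\t5\t+\tnovel\tG1\n"
            "r1\tchr1\t10\t15\t+\tnovel\tG1\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            rio.read_retrocopy_catalog(p)

    def test_unknown_status_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text(
            "\t".join(rio.CATALOG_COLUMNS) + "\n"
            "r1\tchr1\t0\t5\t+\tbogus\tG1\n"
        )
        with pytest.raises(ValidationError, match="status"):
            rio.read_retrocopy_catalog(p)


class TestExpressionMatrixIO:
    def _toy(self):
        samples = [
            SampleMeta("s1", "liver"),
            SampleMeta("s2", "", is_cancer_line=True),
        ]
        return ExpressionMatrix(
            ["t1", "t2", "t3"], samples, np.arange(6).reshape(3, 2) * 1.5
        )

    def test_toy_round_trip(self, tmp_path):
        m = self._toy()
        rio.write_expression_matrix(
            m, tmp_path / "m.tsv", tmp_path / "s.tsv"
        )
        back = rio.read_expression_matrix(
            tmp_path / "m.tsv", tmp_path / "s.tsv"
        )
        assert back.transcript_ids == m.transcript_ids
        assert back.samples == m.samples
        np.testing.assert_array_equal(back.tpm, m.tpm)

    def test_negative_tpm_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "transcript_id\ts1\nt1\t-2.0\n"
        )
        (tmp_path / "s.tsv").write_text(
            "sample_id\ttissue_label\tis_cancer_line\tis_control\n"
            "s1\tliver\t0\t1\n"
        )
        with pytest.raises(ValidationError, match="negative"):
            rio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_sample_missing_from_metadata(self, tmp_path):
        (tmp_path / "m.tsv").write_text("transcript_id\ts1\nt1\t2.0\n")
        (tmp_path / "s.tsv").write_text(
            "sample_id\ttissue_label\tis_cancer_line\tis_control\n"
            "s9\tliver\t0\t1\n"
        )
        with pytest.raises(ValidationError, match="missing"):
            rio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv")


class TestBedgraph:
    def test_abutting_records_accepted(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t5\nchr1\t100\t200\t7\n")
        track = rio.read_bedgraph(p, "lib1", "rna")
        assert len(track.records) == 2

    def test_overlapping_records_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t5\nchr1\t50\t150\t7\n")
        with pytest.raises(ValidationError, match="overlap"):
            rio.read_bedgraph(p, "lib1", "rna")

    def test_non_numeric_depth_rejected(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\thigh\n")
        with pytest.raises(rio.ParseError):
            rio.read_bedgraph(p, "lib1", "rna")

    def test_round_trip_per_base_oracle(self, tmp_path, rng):
        # random non-overlapping fixture vs naive per-base expansion
        pos = 0
        records = []
        for _ in range(60):
            pos += int(rng.integers(0, 30))
            length = int(rng.integers(1, 40))
            records.append(
                (GenomicInterval("chr1", pos, pos + length),
                 float(rng.integers(0, 50)))
            )
            pos += length
        track = CoverageTrack("lib1", "ribo", records)
        p = tmp_path / "rt.bedgraph"
        rio.write_bedgraph(track, p)
        back = rio.read_bedgraph(p, "lib1", "ribo")

        expanded = np.zeros(pos + 10)
        for iv, depth in records:
            expanded[iv.start : iv.end] = depth
        for start in range(0, pos, 97):
            end = min(start + 97, pos + 10)
            assert back.total_depth("chr1", start, end) == pytest.approx(
                expanded[start:end].sum()
            )
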