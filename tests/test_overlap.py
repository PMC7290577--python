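import numpy as np
import pytest

from retrofunc.datamodel import GenomicInterval, RetrocopyRecord, TranscriptModel
from retrofunc.expression import CorrelationResult
from retrofunc.overlap import (
    classify_cis_nat,
    classify_exon_contribution,
    detect_transcriptional_interference,
    find_gene_overlaps,
    gene_span,
    identify_trans_nat,
)


def _retro(rid, start, end, strand="+", parent="GP", chrom="chr1"):
    return RetrocopyRecord(
        rid, GenomicInterval(chrom, start, end, strand), "known_pseudogene",
        parent,
    )


def _tx(tid, gid, exon_coords, strand="+", biotype="protein_coding",
        cds=None, chrom="chr1"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    cds_span = (
        GenomicInterval(chrom, cds[0], cds[1], strand) if cds else None
    )
    return TranscriptModel(tid, gid, biotype, exons, cds_span)


def _corr(a, b, rho, p=1e-6):
    return {(a, b): CorrelationResult(a, b, rho, p, 100, "all")}


class TestFindGeneOverlaps:
    def test_intronic_opposite(self):
        ann = {"g1": [_tx("t1", "g1", [(0, 100), (1000, 1100)], "+")]}
        retro = _retro("r1", 300, 700, "-")
        (ov,) = find_gene_overlaps([retro], ann)
        assert ov.relative_strand == "opposite"
        assert ov.context == "intronic"
        assert ov.overlap_bases == 400

    def test_disjoint_no_record(self):
        ann = {"g1": [_tx("t1", "g1", [(0, 100)], "+")]}
        assert find_gene_overlaps([_retro("r1", 500, 700)], ann) == []

    def test_exonic_and_mixed(self):
        ann = {"g1": [_tx("t1", "g1", [(0, 100), (1000, 1100)], "+")]}
        (exonic,) = find_gene_overlaps([_retro("r1", 10, 90)], ann)
        assert exonic.context == "exonic"
        (mixed,) = find_gene_overlaps([_retro("r2", 50, 500)], ann)
        assert mixed.context == "mixed"

    def test_quadratic_oracle(self, rng):
        genes = {}
        for i in range(200):
            start = int(rng.integers(0, 50_000))
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], start
            for _ in range(n_ex):
                length = int(rng.integers(50, 300))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(50, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            genes[f"g{i}"] = [_tx(f"t{i}", f"g{i}", exons, strand)]
        retros = [
            _retro(
                f"r{j}", s := int(rng.integers(0, 50_000)),
                s + int(rng.integers(50, 800)),
                "+" if rng.random() < 0.5 else "-",
            )
            for j in range(500)
        ]
        got = {
            (o.retro_id, o.gene_id) for o in find_gene_overlaps(retros, genes)
        }
        expected = set()
        for r in retros:
            for gid, ts in genes.items():
                if r.interval.overlap_length(gene_span(ts)) >= 1:
                    expected.add((r.retro_id, gid))
        assert got == expected


class TestCisNat:
    def _setup(self):
        ann = {"g1": [_tx("t1", "g1", [(0, 100), (1000, 1100)], "+")]}
        retro = _retro("r1", 300, 700, "-")
        overlaps = find_gene_overlaps([retro], ann)
        return ann, overlaps

    def test_correlated_called(self):
        ann, overlaps = self._setup()
        (call,) = classify_cis_nat(overlaps, ann, _corr("r1", "t1", 0.89))
        assert call.stats["called"] and call.stats["rho"] == 0.89

    def test_same_strand_not_candidate(self):
        ann = {"g1": [_tx("t1", "g1", [(0, 100), (1000, 1100)], "+")]}
        overlaps = find_gene_overlaps([_retro("r1", 300, 700, "+")], ann)
        assert classify_cis_nat(overlaps, ann, {}) == []

    def test_uncorrelated_candidate_not_called(self):
        ann, overlaps = self._setup()
        (call,) = classify_cis_nat(overlaps, ann, {})
        assert not call.stats["called"]

    def test_calls_subset_of_opposite_overlaps(self, pipeline_result):
        opposite = {
            (o.retro_id, o.gene_id)
            for o in pipeline_result.overlaps
            if o.relative_strand == "opposite"
        }
        for c in pipeline_result.cis_nat_calls:
            assert (c.retro_id, c.partner_id) in opposite


class TestTransNat:
    def _parents(self):
        return {"GP": ["GP-t1"]}

    def test_route_a_lncrna(self):
        retro = _retro("r1", 500, 1000, "+")
        ann = {"L1": [_tx("lt1", "L1", [(400, 1100)], "-", biotype="lncRNA")]}
        corr = {
            ("lt1", "GP-t1"): CorrelationResult(
                "lt1", "GP-t1", 0.7, 1e-8, 50, "coexpressed"
            )
        }
        (call,) = identify_trans_nat([retro], ann, [], corr, self._parents())
        assert call.stats["routes"] == "a" and call.stats["called"]

    def test_route_c_tss(self):
        retro = _retro("r1", 500, 1000, "+")
        tss = [("chr1", 1199, "-")]
        (call,) = identify_trans_nat([retro], {}, tss, {}, self._parents())
        assert call.stats["routes"] == "c" and not call.stats["called"]

    def test_same_strand_tss_no_candidate(self):
        retro = _retro("r1", 500, 1000, "+")
        tss = [("chr1", 1100, "+")]
        assert identify_trans_nat([retro], {}, tss, {}, self._parents()) == []

    def test_tss_window_monotone(self):
        retro = _retro("r1", 500, 1000, "+")
        tss = [("chr1", 1399, "-")]
        wide = identify_trans_nat(
            [retro], {}, tss, {}, self._parents(), tss_window=500
        )
        narrow = identify_trans_nat(
            [retro], {}, tss, {}, self._parents(), tss_window=100
        )
        assert len(wide) == 1 and narrow == []

    def test_planted_routes_recovered(self, pipeline_result, ground_truth):
        calls = {c.retro_id: c for c in pipeline_result.trans_nat_calls}
        for rid in ground_truth.planted("trans_nat"):
            expected_routes = ground_truth.params(rid, "trans_nat")["routes"]
            assert rid in calls, rid
            got = set(calls[rid].stats["routes"].split(","))
            assert set(expected_routes) <= got
            assert calls[rid].stats["called"]


class TestExonContribution:
    def test_utr3_exon(self):
        # retro-derived second exon entirely past the CDS end
        ann = {
            "h1": [
                _tx("ht1", "h1", [(0, 400), (600, 800)], "+",
                    cds=(60, 360))
            ]
        }
        retro = _retro("r1", 550, 850, "-")
        (ec,) = classify_exon_contribution([retro], ann)
        assert ec.region_classes == frozenset({"utr3"})
        assert ec.orientation == "opposite" and ec.cds_complete

    def test_utr5_plus_cds_first_exon(self):
        # retro contributes the first exon holding the 5'UTR plus the
        # first codons of the CDS
        ann = {
            "h1": [
                _tx("ht1", "h1", [(0, 200), (400, 800)], "+",
                    cds=(140, 700))
            ]
        }
        retro = _retro("r1", 0, 210, "+")
        (ec,) = classify_exon_contribution([retro], ann)
        assert ec.region_classes == frozenset({"utr5", "cds"})

    def test_no_cds_flagged_incomplete(self):
        ann = {"h1": [_tx("ht1", "h1", [(0, 400)], "+", biotype="lncRNA")]}
        (ec,) = classify_exon_contribution([_retro("r1", 100, 300)], ann)
        assert not ec.cds_complete and ec.region_classes == frozenset()

    def test_planted_exonization_recovered(self, pipeline_result, ground_truth):
        by_retro = {}
        for ec in pipeline_result.exon_contributions:
            by_retro.setdefault(ec.retro_id, []).append(ec)
        for rid in ground_truth.planted("exonization"):
            p = ground_truth.params(rid, "exonization")
            matches = [
                ec for ec in by_retro.get(rid, [])
                if ec.transcript_id == p["host_transcript"]
            ]
            assert matches, rid
            assert matches[0].region_classes == frozenset(p["region_classes"])
            assert matches[0].orientation == p["orientation"]


def _interference_world(retro_start, retro_end, strand="-"):
    shared = (0, 200)
    short2 = (350, 550)
    long2 = (5000, 5300)
    ann = {
        "h1": [
            _tx("short", "h1", [shared, short2], "+"),
            _tx("long", "h1", [shared, long2], "+"),
        ]
    }
    retro = _retro("r1", retro_start, retro_end, strand)
    return ann, retro


class TestInterference:
    def test_candidate_called(self):
        ann, retro = _interference_world(1350, 2000)
        corr = {
            ("r1", "short"): CorrelationResult("r1", "short", 0.6, 1e-7, 100,
                                               "all"),
            ("r1", "long"): CorrelationResult("r1", "long", 0.05, 0.8, 100,
                                              "all"),
        }
        (cand,) = detect_transcriptional_interference([retro], ann, corr)
        assert cand.called
        assert cand.downstream_distance == 800
        assert cand.short_isoform_ids == ["short"]

    def test_beyond_1000_not_candidate(self):
        ann, retro = _interference_world(1750, 2400)  # 1200 downstream
        assert detect_transcriptional_interference([retro], ann, {}) == []

    def test_overlapping_long_exon_not_candidate(self):
        ann, retro = _interference_world(900, 5100)  # crosses long exon2
        assert detect_transcriptional_interference([retro], ann, {}) == []

    def test_long_correlation_blocks_call(self):
        ann, retro = _interference_world(1350, 2000)
        corr = {
            ("r1", "short"): CorrelationResult("r1", "short", 0.6, 1e-7, 100,
                                               "all"),
            ("r1", "long"): CorrelationResult("r1", "long", 0.5, 1e-7, 100,
                                              "all"),
        }
        (cand,) = detect_transcriptional_interference([retro], ann, corr)
        assert not cand.called

    def test_negative_rho_blocks_call(self):
        ann, retro = _interference_world(1350, 2000)
        corr = {
            ("r1", "short"): CorrelationResult("r1", "short", -0.6, 1e-7, 100,
                                               "all"),
        }
        (cand,) = detect_transcriptional_interference([retro], ann, corr)
        assert not cand.called

    def test_max_downstream_monotone(self):
        ann, retro = _interference_world(1350, 2000)
        assert detect_transcriptional_interference(
            [retro], ann, {}, max_downstream=700
        ) == []

    def test_planted_geometry_recovered(self, pipeline_result, ground_truth):
        planted = ground_truth.planted("interference")
        candidates = {c.retro_id: c for c in pipeline_result.interference}
        assert planted == set(candidates)
        for rid in planted:
            p = ground_truth.params(rid, "interference")
            c = candidates[rid]
            assert c.host_gene_id == p["host_gene"]
            assert c.downstream_distance == p["distance"]
            assert c.called

    def test_candidates_never_overlap_long_exons(self, pipeline_result,
                                                 fixture_dir):
        from retrofunc import io as rio

        ann = rio.read_annotation(fixture_dir / "annotation.bed")
        cat, _ = rio.read_retrocopy_catalog(fixture_dir / "catalog.tsv")
        by_id = {r.retro_id: r for r in cat}
        flat = {t.transcript_id: t for g in ann for t in ann[g]}
        for c in pipeline_result.interference:
            iv = by_id[c.retro_id].interval
            for tid in c.long_isoform_ids:
                for exon in flat[tid].exons:
                    assert not exon.overlaps(iv)
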