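import numpy as np
import pytest

from retrofunc.datamodel import CoverageTrack, GenomicInterval
from retrofunc.ribosome import (
    DensityFeature,
    DensityRecord,
    calibrate_and_call,
    calibrate_library,
    compute_density,
    mean_coverage,
    zscore_trim,
)


def _track(records, assay="rna", lib="lib1"):
    return CoverageTrack(lib, assay, records)


class TestMeanCoverage:
    def test_uniform_depth(self):
        t = _track([(GenomicInterval("chr1", 0, 1000), 10.0)])
        assert mean_coverage(t, GenomicInterval("chr1", 100, 200)) == 10.0

    def test_half_covered(self):
        t = _track([(GenomicInterval("chr1", 0, 50), 10.0)])
        assert mean_coverage(t, GenomicInterval("chr1", 0, 100)) == 5.0

    def test_brute_force_oracle(self, rng):
        pos, records = 0, []
        for _ in range(50):
            pos += int(rng.integers(0, 20))
            length = int(rng.integers(1, 30))
            records.append(
                (GenomicInterval("chr1", pos, pos + length),
                 float(rng.integers(0, 40)))
            )
            pos += length
        t = _track(records)
        expanded = np.zeros(pos + 100)
        for iv, d in records:
            expanded[iv.start : iv.end] = d
        for _ in range(30):
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(1, 200))
            feature = GenomicInterval("chr1", s, e)
            assert mean_coverage(t, feature) == pytest.approx(
                expanded[s : min(e, len(expanded))].sum() / (e - s), abs=1e-9
            )


class TestComputeDensity:
    def _tracks(self, ribo_depth, rna_depth):
        iv = GenomicInterval("chr1", 0, 100)
        return (
            _track([(iv, ribo_depth)], "ribo"),
            _track([(iv, rna_depth)], "rna"),
        )

    def _feature(self):
        return [DensityFeature("f1", "retro", (GenomicInterval("chr1", 0, 100),))]

    def test_direct_arithmetic(self):
        ribo, rna = self._tracks(20.0, 10.0)
        (rec,) = compute_density(ribo, rna, self._feature())
        assert rec.density == pytest.approx(2.0) and rec.included

    def test_low_rna_excluded(self):
        ribo, rna = self._tracks(20.0, 9.5)
        (rec,) = compute_density(ribo, rna, self._feature())
        assert not rec.included and rec.density is None

    def test_zero_ribo_included(self):
        ribo, rna = self._tracks(0.0, 50.0)
        (rec,) = compute_density(ribo, rna, self._feature())
        assert rec.density == 0.0 and rec.included

    def test_scale_invariance(self, rng):
        iv = GenomicInterval("chr1", 0, 200)
        ribo = _track([(iv, 33.0)], "ribo")
        rna = _track([(iv, 44.0)], "rna")
        feats = [DensityFeature("f1", "retro", (iv,))]
        (base,) = compute_density(ribo, rna, feats)
        c = 7.5
        (scaled,) = compute_density(
            _track([(iv, 33.0 * c)], "ribo"),
            _track([(iv, 44.0 * c)], "rna"),
            feats,
        )
        assert scaled.density == pytest.approx(base.density)

    def test_raising_min_rna_never_includes(self):
        ribo, rna = self._tracks(20.0, 15.0)
        (lo,) = compute_density(ribo, rna, self._feature(), 10.0)
        (hi,) = compute_density(ribo, rna, self._feature(), 20.0)
        assert lo.included and not hi.included


class TestZscoreTrim:
    def test_normal_retains_about_ninety_percent(self):
        rng = np.random.default_rng(123)
        values = rng.standard_normal(100_000)
        kept = zscore_trim(values)
        frac = len(kept) / len(values)
        assert 0.895 <= frac <= 0.905

    def test_small_symmetric_set_all_retained(self):
        assert list(zscore_trim([-1.0, 0.0, 1.0])) == [-1.0, 0.0, 1.0]

    def test_single_extreme_outlier_removed(self):
        values = [0.0, 1.0, -1.0, 0.5, -0.5, 1000.0]
        kept = zscore_trim(values)
        # hand-computed: only the 1000 has |Z| > 1.64
        assert 1000.0 not in kept and len(kept) == 5

    def test_zero_spread_warns_and_keeps_all(self):
        with pytest.warns(UserWarning):
            kept = zscore_trim([2.0, 2.0, 2.0])
        assert len(kept) == 3


def _density_records(lib, utr3_values, retro_values, cds_values=()):
    records = []
    for i, v in enumerate(utr3_values):
        records.append(DensityRecord(f"u{i}", "utr3", lib, 50, v * 50, v, True))
    for i, v in enumerate(cds_values):
        records.append(DensityRecord(f"c{i}", "cds", lib, 50, v * 50, v, True))
    for i, v in enumerate(retro_values):
        records.append(DensityRecord(f"r{i}", "retro", lib, 50, v * 50, v, True))
    return records


class TestCalibrateAndCall:
    def test_cutoff_formula(self, rng):
        utr3 = list(rng.normal(0.2, 0.02, size=50))
        cal = calibrate_library(_density_records("lib1", utr3, []))
        trimmed = zscore_trim(utr3)
        assert cal.cutoff == pytest.approx(
            np.mean(trimmed) + 1.64 * np.std(trimmed, ddof=1)
        )

    def test_exactly_at_cutoff_is_negative(self, rng):
        utr3 = list(rng.normal(0.2, 0.02, size=50))
        cal = calibrate_library(_density_records("lib1", utr3, []))
        records = {
            "lib1": _density_records("lib1", utr3, [cal.cutoff, cal.cutoff + 0.01])
        }
        _, calls = calibrate_and_call(records)
        by_id = {c.retro_id: c.stats["n_positive_libraries"] for c in calls}
        assert by_id["r0"] == 0  # strict >
        assert by_id["r1"] == 1

    def test_too_few_utr3_skips_library(self):
        records = {"lib1": _density_records("lib1", [0.2] * 5, [9.9])}
        cals, calls = calibrate_and_call(records)
        assert cals == []
        assert calls[0].stats["n_positive_libraries"] == 0

    def test_cutoff_multiplier_monotone(self, rng):
        utr3 = list(rng.normal(0.2, 0.05, size=60))
        retro = list(rng.normal(0.4, 0.2, size=40))
        records = {"lib1": _density_records("lib1", utr3, retro)}
        sizes = []
        for z in (1.0, 1.64, 2.5, 4.0):
            _, calls = calibrate_and_call(records, z_abs_max=z)
            sizes.append(
                sum(1 for c in calls if c.stats["n_positive_libraries"] > 0)
            )
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_positive_recovery(self, pipeline_result, ground_truth):
        planted_pos = {
            rid
            for rid in ground_truth.planted("ribosome")
            if ground_truth.params(rid, "ribosome").get("group") == "positive"
            and not ground_truth.params(rid, "ribosome").get("low_rna")
        }
        calls = {
            c.retro_id: c.stats["n_positive_libraries"]
            for c in pipeline_result.ribo_calls
        }
        n_lib = len(pipeline_result.calibrations)
        for rid in planted_pos:
            assert calls[rid] >= 0.8 * n_lib, rid

    def test_planted_negative_below_cutoff(self, pipeline_result, ground_truth):
        planted_neg = {
            rid
            for rid in ground_truth.planted("ribosome")
            if ground_truth.params(rid, "ribosome").get("group") == "negative"
        }
        n_lib = len(pipeline_result.calibrations)
        for c in pipeline_result.ribo_calls:
            if c.retro_id in planted_neg:
                assert c.stats["n_positive_libraries"] <= 0.2 * n_lib

    def test_cds_rate_exceeds_utr3_rate(self, fixture_dir, pipeline_result):
        # positive/negative-control sanity: CDS group densities sit above
        # the 3'UTR-calibrated cutoff far more often than 3'UTR densities
        from retrofunc import io as rio
        from retrofunc.ribosome import compute_density, density_features

        cat, _ = rio.read_retrocopy_catalog(fixture_dir / "catalog.tsv")
        ann = rio.read_annotation(fixture_dir / "annotation.bed")
        feats = density_features(ann, cat)
        cals = {c.library_id: c for c in pipeline_result.calibrations}
        for lib, cal in cals.items():
            ribo = rio.read_bedgraph(
                fixture_dir / "tracks" / f"{lib}.ribo.bedgraph", lib, "ribo"
            )
            rna = rio.read_bedgraph(
                fixture_dir / "tracks" / f"{lib}.rna.bedgraph", lib, "rna"
            )
            recs = compute_density(ribo, rna, feats)
            rates = {}
            for group in ("cds", "utr3"):
                vals = [
                    r.density
                    for r in recs
                    if r.group == group and r.included and r.density is not None
                ]
                rates[group] = np.mean([v > cal.cutoff for v in vals])
            assert rates["cds"] > rates["utr3"]
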