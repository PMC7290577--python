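"""Ribosome-density calling calibrated against 3'UTR negative controls.

Density for a feature is mean Ribo-seq coverage divided by mean RNA-seq
coverage. Per library, the 3'UTR density distribution is trimmed at
|Z| <= 1.64 in a single pass and the positive-call cutoff is set at
Z = +1.64 of the trimmed distribution; CDS features act as positive
controls and retrocopies are called against the cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from retrofunc.datamodel import CoverageTrack, EvidenceCall, GenomicInterval

log = logging.getLogger(__name__)

Z_ABS_MAX = 1.64
MIN_RNA_COVERAGE = 10.0
MIN_UTR3_RECORDS = 20


@dataclass(frozen=True)
class DensityFeature:
    """A genomic feature entering density computation.

    ``intervals`` may hold several genomic pieces (spliced CDS/UTR);
    mean coverage is taken over their union length.
    """

    feature_id: str
    group: str  # cds | utr3 | retro
    intervals: tuple[GenomicInterval, ...]

    @property
    def length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class DensityRecord:
    feature_id: str
    group: str
    library_id: str
    rna_ratio: float
    ribo_ratio: float
    density: Optional[float]
    included: bool


@dataclass
class CalibrationResult:
    library_id: str
    utr3_mean: float
    utr3_sd: float
    cutoff: float
    n_trimmed_per_group: dict


def density_features(
    annotation: dict,
    retrocopies: Sequence,
    exclude_protein_coding_retros: bool = True,
) -> list[DensityFeature]:
    """Assemble the three control/target feature groups.

    CDS and 3'UTR regions come from the representative transcript of
    each protein-coding gene (longest CDS, ties by transcript id);
    retrocopy spans form the target group. Retrocopies annotated as
    known protein-coding are excluded by default.
    """
    out = []
    for gid, transcripts in annotation.items():
        coding = [t for t in transcripts if t.cds_span is not None]
        if not coding:
            continue
        rep = max(coding, key=lambda t: (len(t.cds_span), t.transcript_id))
        regions = rep.utr_cds_regions()
        if regions["cds"]:
            out.append(
                DensityFeature(f"{gid}:cds", "cds", tuple(regions["cds"]))
            )
        if regions["utr3"]:
            out.append(
                DensityFeature(f"{gid}:utr3", "utr3", tuple(regions["utr3"]))
            )
    for r in retrocopies:
        if exclude_protein_coding_retros and r.status == "known_protein_coding":
            continue
        out.append(DensityFeature(r.retro_id, "retro", (r.interval,)))
    return out


def mean_coverage(track: CoverageTrack, feature: GenomicInterval) -> float:
    """Mean per-base depth over a feature; absent bases count 0."""
    if len(feature) <= 0:
        raise ValueError("feature length must be positive")
    return track.total_depth(feature.chrom, feature.start, feature.end) / len(
        feature
    )


def mean_coverage_multi(
    track: CoverageTrack, intervals: Sequence[GenomicInterval]
) -> float:
    total = sum(
        track.total_depth(iv.chrom, iv.start, iv.end) for iv in intervals
    )
    length = sum(len(iv) for iv in intervals)
    if length <= 0:
        raise ValueError("feature length must be positive")
    return total / length


def compute_density(
    ribo: CoverageTrack,
    rna: CoverageTrack,
    features: Sequence[DensityFeature],
    min_rna_coverage: float = MIN_RNA_COVERAGE,
) -> list[DensityRecord]:
    """Per-feature ribosome density = ribo_ratio / rna_ratio.

    Features with mean RNA coverage below ``min_rna_coverage`` (or zero)
    are retained in the output with ``included=False`` and no density.
    """
    out = []
    for f in features:
        rna_ratio = mean_coverage_multi(rna, f.intervals)
        ribo_ratio = mean_coverage_multi(ribo, f.intervals)
        included = rna_ratio >= min_rna_coverage
        density = ribo_ratio / rna_ratio if rna_ratio > 0 and included else None
        out.append(
            DensityRecord(
                f.feature_id, f.group, ribo.library_id,
                rna_ratio, ribo_ratio, density, included and density is not None,
            )
        )
    return out


def zscore_trim(
    values: Sequence[float], z_abs_max: float = Z_ABS_MAX
) -> np.ndarray:
    """Single-pass outlier removal: keep v with |(v - mean)/sd| <= z_abs_max.

    Mean and SD come from the untrimmed input (no iteration). With the
    default bound on normal data this retains ~90%.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        warnings.warn("zero spread; retaining all values", stacklevel=2)
        return arr
    z = (arr - arr.mean()) / sd
    return arr[np.abs(z) <= z_abs_max]


def calibrate_library(
    records: Sequence[DensityRecord],
    z_abs_max: float = Z_ABS_MAX,
    trim_utr3_before_cutoff: bool = True,
) -> Optional[CalibrationResult]:
    """3'UTR-calibrated cutoff for one library.

    Returns None (library skipped) when fewer than ``MIN_UTR3_RECORDS``
    included 3'UTR records are present or their spread is degenerate.
    ``trim_utr3_before_cutoff=False`` computes the cutoff from the
    untrimmed 3'UTR distribution instead.
    """
    by_group: dict[str, list[float]] = {"cds": [], "utr3": [], "retro": []}
    library_id = records[0].library_id if records else ""
    for r in records:
        if r.included and r.density is not None:
            by_group.setdefault(r.group, []).append(r.density)
    utr3 = by_group["utr3"]
    if len(utr3) < MIN_UTR3_RECORDS:
        log.warning(
            "library %s skipped: only %d included utr3 records",
            library_id, len(utr3),
        )
        return None
    n_trimmed = {}
    trimmed: dict[str, np.ndarray] = {}
    for group, vals in by_group.items():
        if len(vals) >= 3 and np.std(vals, ddof=1) > 0:
            kept = zscore_trim(vals, z_abs_max)
        else:
            kept = np.asarray(vals, dtype=float)
        trimmed[group] = kept
        n_trimmed[group] = len(vals) - len(kept)
    base = trimmed["utr3"] if trim_utr3_before_cutoff else np.asarray(utr3)
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        log.warning("library %s skipped: degenerate utr3 distribution",
                    library_id)
        return None
    mean = float(np.mean(base))
    return CalibrationResult(
        library_id=library_id,
        utr3_mean=mean,
        utr3_sd=sd,
        cutoff=mean + z_abs_max * sd,
        n_trimmed_per_group=n_trimmed,
    )


def calibrate_and_call(
    records_per_library: dict[str, list[DensityRecord]],
    z_abs_max: float = Z_ABS_MAX,
    trim_utr3_before_cutoff: bool = True,
) -> tuple[list[CalibrationResult], list[EvidenceCall]]:
    """Calibrate every library and call ribosome-associated retrocopies.

    A retrocopy is positive in a library iff it is included there and
    its density strictly exceeds that library's cutoff. The returned
    calls summarize per-retrocopy positive-library counts.
    """
    calibrations = []
    positives: dict[str, list[str]] = {}
    seen_retros: set[str] = set()
    for library_id, records in records_per_library.items():
        for r in records:
            if r.group == "retro":
                seen_retros.add(r.feature_id)
        cal = calibrate_library(records, z_abs_max, trim_utr3_before_cutoff)
        if cal is None:
            continue
        calibrations.append(cal)
        for r in records:
            if (
                r.group == "retro"
                and r.included
                and r.density is not None
                and r.density > cal.cutoff
            ):
                positives.setdefault(r.feature_id, []).append(library_id)
    calls = []
    for rid in sorted(seen_retros):
        libs = positives.get(rid, [])
        calls.append(
            EvidenceCall(
                retro_id=rid,
                evidence_class="ribosome",
                stats={
                    "n_positive_libraries": len(libs),
                    "libraries": ",".join(libs),
                },
            )
        )
    return calibrations, calls
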