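"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open on the forward genomic strand.
GTF input (1-based inclusive) is converted on read; BED is consumed
natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_STRANDS = frozenset({"+", "-", "."})
RETRO_STATUSES = frozenset(
    {"known_pseudogene", "known_protein_coding", "novel", "other"}
)
BIOTYPES = frozenset({"protein_coding", "lncRNA", "other"})
EVIDENCE_CLASSES = frozenset(
    {
        "expressed",
        "pattern",
        "ribosome",
        "peptide",
        "sponge",
        "cis_nat",
        "trans_nat",
        "interference",
        "exonization",
        "fusion",
    }
)


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RetrocopyRecord:
    """One catalog entry: a retrocopy and its parental-gene link."""

    retro_id: str
    interval: GenomicInterval
    status: str
    parental_gene_id: str
    parental_transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in RETRO_STATUSES:
            raise ValidationError(
                f"{self.retro_id}: unknown status {self.status!r}"
            )
        if not self.parental_gene_id:
            raise ValidationError(f"{self.retro_id}: empty parental_gene_id")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-structured transcript with optional CDS span.

    ``tss``/``tes`` are the 5'-most and 3'-most transcribed bases in the
    transcript's reading direction (both inclusive positions).
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: tuple[GenomicInterval, ...]
    cds_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: invalid biotype {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1 or "." in strands:
            raise ValidationError(
                f"{self.transcript_id}: exons must share one stranded strand"
            )
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chromosomes"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e.end
        if self.cds_span is not None:
            covered = sum(
                self.cds_span.overlap_length(e) for e in self.exons
            )
            inside = (
                self.exons[0].start <= self.cds_span.start
                and self.cds_span.end <= self.exons[-1].end
            )
            if not inside or covered == 0:
                raise ValidationError(
                    f"{self.transcript_id}: cds_span outside exon span"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def tes(self) -> int:
        if self.strand == "+":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def transcribed_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return out

    def utr_cds_regions(self) -> dict[str, list[GenomicInterval]]:
        """Split exons into genomic utr5/cds/utr3 pieces.

        Empty when the transcript has no CDS.
        """
        if self.cds_span is None:
            return {"utr5": [], "cds": [], "utr3": []}
        left, right, inner = [], [], []
        cs, ce = self.cds_span.start, self.cds_span.end
        for e in self.exons:
            if e.end <= cs:
                left.append(e)
            elif e.start >= ce:
                right.append(e)
            else:
                if e.start < cs:
                    left.append(
                        GenomicInterval(e.chrom, e.start, cs, e.strand)
                    )
                if e.end > ce:
                    right.append(GenomicInterval(e.chrom, ce, e.end, e.strand))
                inner.append(
                    GenomicInterval(
                        e.chrom, max(e.start, cs), min(e.end, ce), e.strand
                    )
                )
        if self.strand == "+":
            return {"utr5": left, "cds": inner, "utr3": right}
        return {"utr5": right, "cds": inner, "utr3": left}


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue_label: str
    is_cancer_line: bool = False
    is_control: bool = True

    def __post_init__(self) -> None:
        if not self.is_cancer_line and not self.tissue_label:
            raise ValidationError(
                f"{self.sample_id}: tissue_label required for normal samples"
            )


class ExpressionMatrix:
    """Transcripts x samples TPM matrix with per-sample metadata."""

    def __init__(
        self,
        transcript_ids: list[str],
        samples: list[SampleMeta],
        tpm: np.ndarray,
    ) -> None:
        tpm = np.asarray(tpm, dtype=float)
        if tpm.shape != (len(transcript_ids), len(samples)):
            raise ValidationError(
                f"matrix shape {tpm.shape} does not match "
                f"{len(transcript_ids)} transcripts x {len(samples)} samples"
            )
        if np.any(tpm < 0):
            raise ValidationError("negative TPM values are not allowed")
        if len(set(transcript_ids)) != len(transcript_ids):
            raise ValidationError("duplicate transcript ids")
        if len({s.sample_id for s in samples}) != len(samples):
            raise ValidationError("duplicate sample ids")
        self.transcript_ids = list(transcript_ids)
        self.samples = list(samples)
        self.tpm = tpm
        self._row_index = {t: i for i, t in enumerate(transcript_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._row_index

    def row(self, transcript_id: str) -> np.ndarray:
        try:
            return self.tpm[self._row_index[transcript_id]]
        except KeyError:
            raise KeyError(f"unknown transcript id {transcript_id!r}") from None


class CoverageTrack:
    """Per-base read depth for one library, stored as sorted runs."""

    def __init__(
        self,
        library_id: str,
        assay: str,
        records: list[tuple[GenomicInterval, float]],
    ) -> None:
        if assay not in {"ribo", "rna"}:
            raise ValidationError(f"invalid assay {assay!r}")
        recs = sorted(records, key=lambda r: (r[0].chrom, r[0].start))
        prev: dict[str, int] = {}
        for iv, depth in recs:
            if depth < 0:
                raise ValidationError(
                    f"negative depth {depth} at {iv.chrom}:{iv.start}"
                )
            if iv.chrom in prev and iv.start < prev[iv.chrom]:
                raise ValidationError(
                    f"overlapping records at {iv.chrom}:{iv.start}"
                )
            prev[iv.chrom] = iv.end
        self.library_id = library_id
        self.assay = assay
        self.records = recs
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for iv, depth in recs:
            self._by_chrom.setdefault(iv.chrom, ([], [], []))  # type: ignore
        tmp: dict[str, list[list[float]]] = {}
        for iv, depth in recs:
            tmp.setdefault(iv.chrom, [[], [], []])
            tmp[iv.chrom][0].append(iv.start)
            tmp[iv.chrom][1].append(iv.end)
            tmp[iv.chrom][2].append(depth)
        self._by_chrom = {
            c: (np.array(v[0]), np.array(v[1]), np.array(v[2], dtype=float))
            for c, v in tmp.items()
        }

    def total_depth(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over ``[start, end)``; absent bases are 0."""
        if chrom not in self._by_chrom:
            return 0.0
        starts, ends, depths = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * depths[lo:hi]))


@dataclass(frozen=True)
class FusionRecord:
    fusion_id: str
    gene5_id: str
    gene3_id: str
    breakpoint5: tuple[str, int]
    breakpoint3: tuple[str, int]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.gene5_id or not self.gene3_id:
            raise ValidationError(f"{self.fusion_id}: empty gene id")
        if self.breakpoint5[1] < 0 or self.breakpoint3[1] < 0:
            raise ValidationError(f"{self.fusion_id}: negative breakpoint")


@dataclass
class EvidenceCall:
    """A typed per-retrocopy finding with its supporting statistics."""

    retro_id: str
    evidence_class: str
    partner_id: Optional[str] = None
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValidationError(
                f"invalid evidence class {self.evidence_class!r}"
            )
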