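"""Strand-aware overlap detection and its downstream classifiers.

Four classifiers build on retrocopy-vs-gene geometry: cis-NAT
candidates (opposite-strand overlap), trans-NAT candidates (three
routes: antisense lncRNA exons, antisense exonized protein-coding
transcripts, opposite-strand TSS near the retrocopy 3' end),
exon-contribution (which transcript regions a retrocopy-derived exon
lands in), and transcriptional-interference geometry (retrocopy close
downstream of a short isoform and inside an intron of a long isoform
of the same gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from retrofunc.datamodel import (
    EvidenceCall,
    GenomicInterval,
    RetrocopyRecord,
    TranscriptModel,
)
from retrofunc.expression import CorrelationResult, passes_correlation_filter

TSS_WINDOW = 500
MAX_DOWNSTREAM = 1000


@dataclass(frozen=True)
class OverlapRecord:
    retro_id: str
    gene_id: str
    relative_strand: str  # same | opposite
    context: str  # exonic | intronic | mixed
    overlap_bases: int


@dataclass
class InterferenceCandidate:
    retro_id: str
    host_gene_id: str
    short_isoform_ids: list[str]
    long_isoform_ids: list[str]
    downstream_distance: int
    relative_strand: str
    called: bool = False
    correlated_short: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ExonContribution:
    retro_id: str
    transcript_id: str
    region_classes: frozenset[str]  # subset of {utr5, cds, utr3}
    orientation: str  # same | opposite
    cds_complete: bool


Annotation = dict[str, list[TranscriptModel]]
CorrMap = dict[tuple[str, str], CorrelationResult]


def _lookup(corrs: CorrMap, a: str, b: str) -> Optional[CorrelationResult]:
    return corrs.get((a, b)) or corrs.get((b, a))


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def gene_span(transcripts: Sequence[TranscriptModel]) -> GenomicInterval:
    """Transcribed span of a gene: union envelope of all isoforms."""
    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    return GenomicInterval(
        chrom,
        min(t.span.start for t in transcripts),
        max(t.span.end for t in transcripts),
        strand,
    )


def find_gene_overlaps(
    retrocopies: Sequence[RetrocopyRecord], annotation: Annotation
) -> list[OverlapRecord]:
    """One record per (retrocopy, gene) pair with >= 1 overlapping base.

    The gene side is its transcribed span (exons + introns, all
    isoforms). Context is exonic when the overlap falls entirely in
    exons of some isoform union, intronic when entirely outside every
    exon, mixed otherwise.
    """
    out = []
    for retro in retrocopies:
        ri = retro.interval
        for gid, transcripts in annotation.items():
            span = gene_span(transcripts)
            ov = ri.overlap_length(span)
            if ov < 1:
                continue
            exon_pieces = [
                (max(e.start, ri.start), min(e.end, ri.end))
                for t in transcripts
                for e in t.exons
                if e.overlaps(ri)
            ]
            exonic_bases = _union_length(exon_pieces)
            if exonic_bases == 0:
                context = "intronic"
            elif exonic_bases >= ov:
                context = "exonic"
            else:
                context = "mixed"
            relative = (
                "same" if span.strand == ri.strand else "opposite"
            )
            out.append(OverlapRecord(retro.retro_id, gid, relative, context, ov))
    return out


def classify_cis_nat(
    overlaps: Sequence[OverlapRecord],
    annotation: Annotation,
    correlations_all_mode: CorrMap,
) -> list[EvidenceCall]:
    """cis-NAT candidates: opposite-strand overlaps.

    A candidate becomes a call when >= 1 transcript of the overlapped
    gene passes the correlation filter (all-samples mode) against the
    retrocopy.
    """
    calls = []
    for ov in overlaps:
        if ov.relative_strand != "opposite":
            continue
        best: Optional[CorrelationResult] = None
        partner = ""
        for t in annotation.get(ov.gene_id, []):
            corr = _lookup(correlations_all_mode, ov.retro_id, t.transcript_id)
            if corr is not None and passes_correlation_filter(corr):
                if best is None or abs(corr.rho) > abs(best.rho):
                    best, partner = corr, t.transcript_id
        calls.append(
            EvidenceCall(
                retro_id=ov.retro_id,
                evidence_class="cis_nat",
                partner_id=ov.gene_id,
                stats={
                    "context": ov.context,
                    "overlap_bases": ov.overlap_bases,
                    "called": best is not None,
                    "best_transcript": partner,
                    "rho": best.rho if best else float("nan"),
                    "p": best.p if best else float("nan"),
                },
            )
        )
    return calls


def _retro_three_prime(retro: RetrocopyRecord) -> int:
    iv = retro.interval
    return iv.end - 1 if iv.strand == "+" else iv.start


def identify_trans_nat(
    retrocopies: Sequence[RetrocopyRecord],
    annotation: Annotation,
    tss_table: Sequence[tuple[str, int, str]],
    correlations_coexpressed: CorrMap,
    parental_transcripts: dict[str, list[str]],
    tss_window: int = TSS_WINDOW,
) -> list[EvidenceCall]:
    """Trans-NAT candidates via three routes, each tagged on the call.

    (a) lncRNA with exons overlapping the retrocopy on the opposite
    strand; (b) protein-coding transcript carrying a retrocopy-derived
    exon in antisense orientation; (c) TSS on the opposite strand
    within ``tss_window`` of the retrocopy 3' end. A call requires the
    candidate transcript (routes a/b) or the retrocopy itself (route c)
    to pass the correlation filter against >= 1 parental-gene
    transcript (coexpressed mode).
    """
    calls = []
    for retro in retrocopies:
        ri = retro.interval
        parent_tids = parental_transcripts.get(retro.parental_gene_id, [])
        candidates: list[tuple[str, str]] = []  # (route, candidate id)
        for gid, transcripts in annotation.items():
            for t in transcripts:
                if t.strand == ri.strand:
                    continue
                if not any(e.overlaps(ri) for e in t.exons):
                    continue
                if t.biotype == "lncRNA":
                    candidates.append(("a", t.transcript_id))
                elif t.biotype == "protein_coding":
                    candidates.append(("b", t.transcript_id))
        tp = _retro_three_prime(retro)
        for chrom, pos, strand in tss_table:
            if chrom != ri.chrom or strand == ri.strand or strand == ".":
                continue
            if abs(pos - tp) <= tss_window:
                candidates.append(("c", retro.retro_id))
                break
        if not candidates:
            continue
        routes = sorted({r for r, _ in candidates})
        called = False
        best_rho, best_partner = float("nan"), ""
        for route, cand in candidates:
            for ptid in parent_tids:
                corr = _lookup(correlations_coexpressed, cand, ptid)
                if corr is not None and passes_correlation_filter(corr):
                    called = True
                    if best_partner == "" or abs(corr.rho) > abs(best_rho):
                        best_rho, best_partner = corr.rho, ptid
        calls.append(
            EvidenceCall(
                retro_id=retro.retro_id,
                evidence_class="trans_nat",
                partner_id=retro.parental_gene_id,
                stats={
                    "routes": ",".join(routes),
                    "candidates": ",".join(sorted({c for _, c in candidates})),
                    "called": called,
                    "rho": best_rho,
                    "best_parent_transcript": best_partner,
                },
            )
        )
    return calls


def classify_exon_contribution(
    retrocopies: Sequence[RetrocopyRecord], annotation: Annotation
) -> list[ExonContribution]:
    """Which transcript regions a retrocopy-derived exon portion lands in.

    Transcripts without a complete CDS are reported with
    ``cds_complete=False`` and must be excluded from CDS-impact tallies
    by consumers.
    """
    out = []
    for retro in retrocopies:
        ri = retro.interval
        for gid, transcripts in annotation.items():
            for t in transcripts:
                pieces = [
                    GenomicInterval(
                        ri.chrom, max(e.start, ri.start), min(e.end, ri.end),
                        t.strand,
                    )
                    for e in t.exons
                    if e.overlaps(ri)
                ]
                if not pieces:
                    continue
                orientation = "same" if t.strand == ri.strand else "opposite"
                if t.cds_span is None:
                    # no CDS: region split undefined; excluded from
                    # CDS-impact tallies downstream
                    out.append(
                        ExonContribution(
                            retro.retro_id, t.transcript_id,
                            frozenset(), orientation, False,
                        )
                    )
                    continue
                regions = t.utr_cds_regions()
                classes = set()
                for label, ivs in regions.items():
                    for piece in pieces:
                        if any(piece.overlap_length(iv) > 0 for iv in ivs):
                            classes.add(label)
                if classes:
                    out.append(
                        ExonContribution(
                            retro.retro_id, t.transcript_id,
                            frozenset(classes), orientation, True,
                        )
                    )
    return out


def _downstream_distance(t: TranscriptModel, retro_iv: GenomicInterval) -> int:
    """Strand-aware distance from a transcript 3' end to the nearest
    retrocopy boundary; negative when the retrocopy is not downstream."""
    if t.strand == "+":
        return retro_iv.start - (t.tes + 1)
    return t.tes - retro_iv.end


def detect_transcriptional_interference(
    retrocopies: Sequence[RetrocopyRecord],
    annotation: Annotation,
    correlations_all_mode: CorrMap,
    max_downstream: int = MAX_DOWNSTREAM,
) -> list[InterferenceCandidate]:
    """Interference geometry: retrocopy <= max_downstream past the 3'
    end of one isoform and wholly inside an intron of another isoform
    of the same gene.

    The candidate is called when the retrocopy passes the correlation
    filter (all mode, positive rho) against >= 1 short isoform and
    against no long isoform.
    """
    out = []
    for retro in retrocopies:
        ri = retro.interval
        for gid, transcripts in annotation.items():
            if len(transcripts) < 2:
                continue
            if transcripts[0].chrom != ri.chrom:
                continue
            shorts = []
            for t in transcripts:
                d = _downstream_distance(t, ri)
                if 0 <= d <= max_downstream:
                    shorts.append((t, d))
            longs = [
                t
                for t in transcripts
                if any(intron.contains(ri) for intron in t.introns())
            ]
            if not shorts or not longs:
                continue
            long_ids = {t.transcript_id for t in longs}
            shorts = [(t, d) for t, d in shorts
                      if t.transcript_id not in long_ids]
            if not shorts:
                continue
            correlated_short = []
            for t, _ in shorts:
                corr = _lookup(correlations_all_mode, retro.retro_id,
                               t.transcript_id)
                if (
                    corr is not None
                    and passes_correlation_filter(corr)
                    and corr.rho > 0
                ):
                    correlated_short.append(t.transcript_id)
            long_correlated = any(
                (c := _lookup(correlations_all_mode, retro.retro_id,
                              t.transcript_id)) is not None
                and passes_correlation_filter(c)
                for t in longs
            )
            cand = InterferenceCandidate(
                retro_id=retro.retro_id,
                host_gene_id=gid,
                short_isoform_ids=[t.transcript_id for t, _ in shorts],
                long_isoform_ids=sorted(long_ids),
                downstream_distance=min(d for _, d in shorts),
                relative_strand=(
                    "same" if transcripts[0].strand == ri.strand else "opposite"
                ),
                called=bool(correlated_short) and not long_correlated,
                correlated_short=correlated_short,
            )
            out.append(cand)
    return out
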