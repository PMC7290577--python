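"""Fusion-transcript categorization and breakpoint classification.

Fusions are related to retrocopies through host relationships (a
retrocopy fully inside a gene's transcribed span) and parental links.
Breakpoints are classified against individual retrocopy spans:
in-body, downstream-near (strand-aware, within ``near_max``), distant
(same chromosome; upstream-near reported as distant with a flag), or
unrelated (different chromosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from retrofunc.datamodel import (
    FusionRecord,
    RetrocopyRecord,
    TranscriptModel,
)
from retrofunc.overlap import gene_span

log = logging.getLogger(__name__)

NEAR_MAX = 1000


@dataclass(frozen=True)
class FusionParams:
    near_max: int = NEAR_MAX

    def __post_init__(self) -> None:
        if self.near_max <= 0:
            raise ValueError("near_max must be positive")


@dataclass(frozen=True)
class BreakpointClass:
    label: str  # in_body | downstream_near | distant | unrelated
    distance: int = 0
    upstream: bool = False


@dataclass
class FusionClassification:
    fusion_id: str
    category: str  # parental_x_host | retro_x_parental | host_x_host | other
    retro_ids: list[str] = field(default_factory=list)
    breakpoint_classes: dict = field(default_factory=dict)


def host_map(
    retrocopies: Sequence[RetrocopyRecord],
    annotation: dict[str, list[TranscriptModel]],
) -> dict[str, set[str]]:
    """retro_id -> gene ids whose transcribed span fully contains it.

    Partial overlaps are logged as marginal and excluded.
    """
    hosts: dict[str, set[str]] = {r.retro_id: set() for r in retrocopies}
    for gid, transcripts in annotation.items():
        span = gene_span(transcripts)
        for r in retrocopies:
            if span.contains(r.interval):
                hosts[r.retro_id].add(gid)
            elif span.overlaps(r.interval):
                log.debug(
                    "marginal host overlap %s vs %s excluded", r.retro_id, gid
                )
    return hosts


def classify_fusion_category(
    fusion: FusionRecord,
    retrocopies: Sequence[RetrocopyRecord],
    hosts: dict[str, set[str]],
) -> FusionClassification:
    """Assign one of the retrocopy-related fusion categories.

    parental_x_host: one partner is the parental gene of a retrocopy
    hosted by the other partner. retro_x_parental: one partner is a
    retrocopy, the other its parent. host_x_host: the partners host
    distinct retrocopies of one common parental gene.
    """
    by_id = {r.retro_id: r for r in retrocopies}
    g5, g3 = fusion.gene5_id, fusion.gene3_id
    implicated: list[str] = []
    category = "other"

    for r in retrocopies:
        if {r.retro_id} & {g5, g3}:
            other = g3 if r.retro_id == g5 else g5
            if other == r.parental_gene_id:
                category = "retro_x_parental"
                implicated.append(r.retro_id)
    if category == "other":
        for r in retrocopies:
            for parent_side, host_side in ((g5, g3), (g3, g5)):
                if (
                    r.parental_gene_id == parent_side
                    and host_side in hosts.get(r.retro_id, set())
                ):
                    category = "parental_x_host"
                    implicated.append(r.retro_id)
    if category == "other":
        hosted5 = {
            rid for rid, hs in hosts.items() if g5 in hs and rid in by_id
        }
        hosted3 = {
            rid for rid, hs in hosts.items() if g3 in hs and rid in by_id
        }
        for r5 in hosted5:
            for r3 in hosted3:
                if (
                    r5 != r3
                    and by_id[r5].parental_gene_id
                    == by_id[r3].parental_gene_id
                ):
                    category = "host_x_host"
                    implicated.extend([r5, r3])
    return FusionClassification(
        fusion_id=fusion.fusion_id,
        category=category,
        retro_ids=sorted(set(implicated)),
    )


def classify_breakpoint(
    breakpoint: tuple[str, int],
    retro: RetrocopyRecord,
    params: FusionParams = FusionParams(),
) -> BreakpointClass:
    """Classify one breakpoint against one retrocopy span.

    in_body: position within [start, end). downstream_near: outside
    the span, strand-aware downstream distance <= near_max. distant:
    same chromosome otherwise (distance to nearest boundary reported;
    upstream-near positions are flagged). unrelated: other chromosome.
    """
    chrom, pos = breakpoint
    iv = retro.interval
    if chrom != iv.chrom:
        return BreakpointClass("unrelated")
    if iv.start <= pos < iv.end:
        return BreakpointClass("in_body")
    if iv.strand == "-":
        downstream = pos < iv.start
        dist = iv.start - pos if downstream else pos - (iv.end - 1)
    else:
        downstream = pos >= iv.end
        dist = pos - (iv.end - 1) if downstream else iv.start - pos
    if downstream and dist <= params.near_max:
        return BreakpointClass("downstream_near", distance=dist)
    return BreakpointClass("distant", distance=dist, upstream=not downstream)


def classify_fusions(
    fusions: Sequence[FusionRecord],
    retrocopies: Sequence[RetrocopyRecord],
    annotation: dict[str, list[TranscriptModel]],
    params: FusionParams = FusionParams(),
) -> list[FusionClassification]:
    """Full per-fusion classification: category plus per-breakpoint
    classes against every implicated retrocopy."""
    hosts = host_map(retrocopies, annotation)
    by_id = {r.retro_id: r for r in retrocopies}
    out = []
    for fusion in fusions:
        cls = classify_fusion_category(fusion, retrocopies, hosts)
        for rid in cls.retro_ids:
            retro = by_id[rid]
            cls.breakpoint_classes[(rid, "5")] = classify_breakpoint(
                fusion.breakpoint5, retro, params
            )
            cls.breakpoint_classes[(rid, "3")] = classify_breakpoint(
                fusion.breakpoint3, retro, params
            )
        out.append(cls)
    return out
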