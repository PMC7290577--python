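"""Readers and writers for the external formats the pipeline touches.

Supported inputs: GTF or BED12 annotation, TSV retrocopy catalog, TSV
expression matrix + sample metadata, 4-column bedGraph coverage, TSV
fusion tables, FASTA sequence files.  All writers emit tab-separated
text with a commented header naming the producing module.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from retrofunc.datamodel import (
    CoverageTrack,
    ExpressionMatrix,
    FusionRecord,
    GenomicInterval,
    RetrocopyRecord,
    SampleMeta,
    TranscriptModel,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on a malformed input line; names the offending line."""


# ---------------------------------------------------------------------------
# annotation


def _biotype_of(raw: str) -> str:
    if raw in {"protein_coding", "lncRNA"}:
        return raw
    if raw in {"lincRNA", "antisense", "processed_transcript"}:
        return "lncRNA"
    return "other"


def read_annotation(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Read a GTF or BED12 annotation into transcripts grouped by gene.

    Dialect is chosen by file extension (.gtf / .gff vs .bed). GTF
    coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED12 is consumed natively.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        transcripts = _read_bed12(path)
    else:
        transcripts = _read_gtf(path)
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return genes


def _read_bed12(path: Path) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{ln}: expected 12 BED columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(
                    f"{path}:{ln}: blockCount disagrees with block lists"
                )
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(starts, sizes)
            )
            if exons[-1].end != end:
                raise ParseError(f"{path}:{ln}: blocks do not reach chromEnd")
            # name encodes transcript|gene|biotype; plain names become
            # their own single-transcript gene.
            parts = name.split("|")
            tid = parts[0]
            gid = parts[1] if len(parts) > 1 else tid
            biotype = _biotype_of(parts[2]) if len(parts) > 2 else "other"
            cds = None
            if thick_end > thick_start:
                cds = GenomicInterval(chrom, thick_start, thick_end, strand)
            out.append(TranscriptModel(tid, gid, biotype, exons, cds))
    return out


def _read_gtf(path: Path) -> list[TranscriptModel]:
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in {"exon", "CDS"}:
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, ValidationError) as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
            tags = {}
            for item in attrs.strip().rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                tags[key] = val.strip().strip('"')
            tid = tags.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{ln}: missing transcript_id")
            meta.setdefault(
                tid,
                (
                    tags.get("gene_id", tid),
                    _biotype_of(
                        tags.get("transcript_biotype", tags.get("gene_biotype", ""))
                    ),
                ),
            )
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    out = []
    for tid, ivs in exons.items():
        gid, biotype = meta[tid]
        ivs = sorted(ivs, key=lambda i: i.start)
        cds_span = None
        if tid in cds:
            cs = min(i.start for i in cds[tid])
            ce = max(i.end for i in cds[tid])
            cds_span = GenomicInterval(ivs[0].chrom, cs, ce, ivs[0].strand)
        out.append(TranscriptModel(tid, gid, biotype, tuple(ivs), cds_span))
    return out


def write_bed12(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            span = t.span
            thick = (
                (t.cds_span.start, t.cds_span.end)
                if t.cds_span
                else (span.start, span.start)
            )
            sizes = ",".join(str(len(e)) for e in t.exons)
            offs = ",".join(str(e.start - span.start) for e in t.exons)
            name = f"{t.transcript_id}|{t.gene_id}|{t.biotype}"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        span.chrom, span.start, span.end, name, 0, t.strand,
                        thick[0], thick[1], 0, len(t.exons), sizes, offs,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# retrocopy catalog

CATALOG_COLUMNS = [
    "retro_id", "chrom", "start", "end", "strand", "status",
    "parental_gene_id",
]


def read_retrocopy_catalog(
    path: str | Path,
) -> tuple[list[RetrocopyRecord], Counter]:
    """Read a catalog TSV; returns records plus a per-status tally.

    The tally's sum always equals the record count (consistency check
    asserted here on every read).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.retro_id in seen:
            raise ValidationError(f"duplicate retro_id {row.retro_id}")
        seen.add(row.retro_id)
        ptid = getattr(row, "parental_transcript_id", None)
        if ptid is not None and (pd.isna(ptid) or ptid == ""):
            ptid = None
        records.append(
            RetrocopyRecord(
                retro_id=row.retro_id,
                interval=GenomicInterval(
                    row.chrom, int(row.start), int(row.end), row.strand
                ),
                status=row.status,
                parental_gene_id=row.parental_gene_id,
                parental_transcript_id=ptid,
            )
        )
    tally = Counter(r.status for r in records)
    assert sum(tally.values()) == len(records)
    return records, tally


def write_retrocopy_catalog(
    records: Iterable[RetrocopyRecord], path: str | Path
) -> None:
    rows = [
        {
            "retro_id": r.retro_id,
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "strand": r.interval.strand,
            "status": r.status,
            "parental_gene_id": r.parental_gene_id,
            "parental_transcript_id": r.parental_transcript_id or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(
    path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    meta_by_id = {}
    for row in meta.itertuples(index=False):
        meta_by_id[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            tissue_label=row.tissue_label if pd.notna(row.tissue_label) else "",
            is_cancer_line=str(row.is_cancer_line).lower() in {"1", "true"},
            is_control=str(row.is_control).lower() in {"1", "true"},
        )
    samples = []
    for sid in df.columns:
        if sid not in meta_by_id:
            raise ValidationError(f"sample {sid!r} missing from metadata")
        samples.append(meta_by_id[sid])
    return ExpressionMatrix(
        transcript_ids=[str(i) for i in df.index],
        samples=samples,
        tpm=df.to_numpy(dtype=float),
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path
) -> None:
    df = pd.DataFrame(
        matrix.tpm, index=matrix.transcript_ids, columns=matrix.sample_ids
    )
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "tissue_label": s.tissue_label,
                "is_cancer_line": int(s.is_cancer_line),
                "is_control": int(s.is_control),
            }
            for s in matrix.samples
        ]
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, library_id: str, assay: str) -> CoverageTrack:
    """Read a 4-column bedGraph; overlapping records are an input error."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
                depth = float(f[3])
            except (ValueError, ValidationError) as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
            records.append((iv, depth))
    return CoverageTrack(library_id, assay, records)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, depth in track.records:
            d = int(depth) if float(depth).is_integer() else depth
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d}\n")


# ---------------------------------------------------------------------------
# fusions, FASTA, TSV helpers


def read_fusion_table(path: str | Path) -> list[FusionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            FusionRecord(
                fusion_id=row.fusion_id,
                gene5_id=row.gene5_id,
                gene3_id=row.gene3_id,
                breakpoint5=(row.chrom5, int(row.pos5)),
                breakpoint3=(row.chrom3, int(row.pos3)),
                source_label=getattr(row, "source_label", "") or "",
            )
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def config_hash(params: dict) -> str:
    blob = repr(sorted(params.items())).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    module: str,
    params: Optional[dict] = None,
) -> None:
    """Write an output table with a commented provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# module={module} config={config_hash(params or {})}\n")
        df.to_csv(fh, sep="\t", index=False)
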