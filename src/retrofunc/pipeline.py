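"""End-to-end orchestration over a directory of input files.

Stages run in dependency order: expression -> correlations -> {ribosome
density, peptides, sponges, overlap/NAT/interference, fusions} ->
summary. Every stage writes a TSV into the output directory and the
run finishes with a JSON log of parameters and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from retrofunc import io as rio
from retrofunc import expression as ex
from retrofunc import fusion as fu
from retrofunc import overlap as ov
from retrofunc import peptides as pep
from retrofunc import ribosome as rb
from retrofunc import sponge as sp
from retrofunc.synth import transcript_sequence

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    min_tpm: float = 1.0
    min_sample_fraction: float = 0.01
    p_max: float = 0.001
    rho_abs_min: float = 0.25
    min_pair_samples: int = 10
    min_rna_coverage: float = 10.0
    z_abs_max: float = 1.64
    trim_utr3_before_cutoff: bool = True
    min_orf_overlap: int = 60
    extension: int = 500
    min_peptide_len: int = 10
    alpha: float = 0.05
    tss_window: int = 500
    max_downstream: int = 1000
    near_max: int = 1000
    seed: int = 0
    stages: tuple = (
        "expression", "ribo", "peptides", "sponges", "overlap", "fusion",
    )

    def __post_init__(self) -> None:
        valid = {"expression", "ribo", "peptides", "sponges", "overlap",
                 "fusion"}
        unknown = set(self.stages) - valid
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class PipelineResult:
    expressed_retros: set = field(default_factory=set)
    patterns: list = field(default_factory=list)
    correlations_all: dict = field(default_factory=dict)
    correlations_coexpressed: dict = field(default_factory=dict)
    calibrations: list = field(default_factory=list)
    ribo_calls: list = field(default_factory=list)
    peptide_hits: list = field(default_factory=list)
    peptide_support: dict = field(default_factory=dict)
    sponge_tests: list = field(default_factory=list)
    overlaps: list = field(default_factory=list)
    cis_nat_calls: list = field(default_factory=list)
    trans_nat_calls: list = field(default_factory=list)
    exon_contributions: list = field(default_factory=list)
    interference: list = field(default_factory=list)
    fusion_classes: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def _read_tss_bed(path: Path) -> list[tuple[str, int, str]]:
    out = []
    if not path.exists():
        return out
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 6:
                out.append((f[0], int(f[1]), f[5]))
    return out


def _read_peptides(path: Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [(r.peptide_id, r.sequence) for r in df.itertuples(index=False)]


def _read_sites(path: Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        (r.sequence_id, r.mirna_family) for r in df.itertuples(index=False)
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        k: v for k, v in asdict(config).items()
        if k not in {"input_dir", "output_dir"}
    }
    res = PipelineResult()

    required = {
        "expression": ["expression.tsv", "samples.tsv", "catalog.tsv"],
        "ribo": ["tracks", "annotation.bed", "catalog.tsv"],
        "peptides": ["peptides.tsv", "genome.fa", "catalog.tsv"],
        "sponges": ["mirna_sites.tsv"],
        "overlap": ["annotation.bed", "catalog.tsv"],
        "fusion": ["fusions.tsv", "annotation.bed", "catalog.tsv"],
    }
    for stage in config.stages:
        for name in required[stage]:
            if not (indir / name).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires missing input {indir / name}"
                )

    if not config.stages:
        (outdir / "run_log.json").write_text(
            json.dumps({"params": params, "counts": {}}, indent=2)
        )
        return res

    catalog, tally = rio.read_retrocopy_catalog(indir / "catalog.tsv")
    annotation = rio.read_annotation(indir / "annotation.bed")
    retro_ids = [r.retro_id for r in catalog]
    parent_transcripts = {
        gid: [t.transcript_id for t in ts] for gid, ts in annotation.items()
    }

    matrix = None
    if {"expression", "sponges", "overlap"} & set(config.stages):
        matrix = rio.read_expression_matrix(
            indir / "expression.tsv", indir / "samples.tsv"
        )

    # ---- expression -----------------------------------------------------
    if "expression" in config.stages:
        fparams = ex.ExpressionFilterParams(
            config.min_tpm, config.min_sample_fraction
        )
        expressed = ex.filter_expressed(matrix, fparams)
        res.expressed_retros = expressed & set(retro_ids)
        res.patterns = ex.classify_pattern(matrix, retro_ids, config.min_tpm)
        rio.write_tsv(
            pd.DataFrame({"id": sorted(res.expressed_retros)}),
            outdir / "expressed_ids.tsv", "expression", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": p.retro_id, "pattern": p.pattern,
                     "tissue": p.tissue}
                    for p in res.patterns
                ]
            ),
            outdir / "patterns.tsv", "expression", params,
        )

    # ---- correlations (shared by sponge / overlap stages) ---------------
    overlaps = ov.find_gene_overlaps(catalog, annotation)
    res.overlaps = overlaps
    if matrix is not None:
        all_pairs = set()
        for o in overlaps:
            for t in annotation[o.gene_id]:
                all_pairs.add((o.retro_id, t.transcript_id))
        co_pairs = set()
        for r in catalog:
            for ptid in parent_transcripts.get(r.parental_gene_id, []):
                co_pairs.add((r.retro_id, ptid))
            for o in overlaps:
                if o.retro_id != r.retro_id or o.relative_strand != "opposite":
                    continue
                for t in annotation[o.gene_id]:
                    for ptid in parent_transcripts.get(r.parental_gene_id, []):
                        co_pairs.add((t.transcript_id, ptid))
        site_rows = (
            _read_sites(indir / "mirna_sites.tsv")
            if (indir / "mirna_sites.tsv").exists()
            else []
        )
        site_map = sp.load_site_table(site_rows) if site_rows else None
        if site_map is not None:
            tids = [
                t.transcript_id
                for g in annotation
                for t in annotation[g]
            ]
            for rid in retro_ids:
                rsites = site_map.sites.get(rid, set())
                if not rsites:
                    continue
                for tid in tids:
                    if rsites & site_map.sites.get(tid, set()):
                        co_pairs.add((rid, tid))
        valid_all = [
            p for p in sorted(all_pairs) if p[0] in matrix and p[1] in matrix
        ]
        valid_co = [
            p for p in sorted(co_pairs) if p[0] in matrix and p[1] in matrix
        ]
        res.correlations_all = {
            (c.id_a, c.id_b): c
            for c in ex.correlate_pairs(
                matrix, valid_all, "all", config.min_pair_samples
            )
        }
        res.correlations_coexpressed = {
            (c.id_a, c.id_b): c
            for c in ex.correlate_pairs(
                matrix, valid_co, "coexpressed", config.min_pair_samples
            )
        }
        rows = [
            {
                "id_a": c.id_a, "id_b": c.id_b, "mode": c.mode,
                "n_used": c.n_used, "rho": c.rho, "p": c.p,
                "kept": ex.passes_correlation_filter(
                    c, config.p_max, config.rho_abs_min
                ),
            }
            for c in list(res.correlations_all.values())
            + list(res.correlations_coexpressed.values())
        ]
        rio.write_tsv(
            pd.DataFrame(rows), outdir / "correlations.tsv", "expression",
            params,
        )

    # ---- ribosome density ----------------------------------------------
    if "ribo" in config.stages:
        features = rb.density_features(annotation, catalog)
        tracks_dir = indir / "tracks"
        per_library = {}
        for ribo_path in sorted(tracks_dir.glob("*.ribo.bedgraph")):
            library_id = ribo_path.name.replace(".ribo.bedgraph", "")
            rna_path = tracks_dir / f"{library_id}.rna.bedgraph"
            ribo = rio.read_bedgraph(ribo_path, library_id, "ribo")
            rna = rio.read_bedgraph(rna_path, library_id, "rna")
            per_library[library_id] = rb.compute_density(
                ribo, rna, features, config.min_rna_coverage
            )
        res.calibrations, res.ribo_calls = rb.calibrate_and_call(
            per_library, config.z_abs_max, config.trim_utr3_before_cutoff
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "feature_id": d.feature_id, "group": d.group,
                        "library": d.library_id, "rna_ratio": d.rna_ratio,
                        "ribo_ratio": d.ribo_ratio,
                        "density": d.density if d.density is not None else "",
                        "included": d.included,
                    }
                    for recs in per_library.values()
                    for d in recs
                ]
            ),
            outdir / "density.tsv", "ribo", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": c.retro_id,
                     "n_positive_libraries": c.stats["n_positive_libraries"],
                     "libraries": c.stats["libraries"]}
                    for c in res.ribo_calls
                ]
            ),
            outdir / "ribo_calls.tsv", "ribo", params,
        )

    # ---- peptides -------------------------------------------------------
    if "peptides" in config.stages:
        genome = rio.read_fasta(indir / "genome.fa")
        peptide_list = _read_peptides(indir / "peptides.tsv")
        decoys = {
            t.transcript_id: transcript_sequence(genome, t)
            for g in annotation
            for t in annotation[g]
        }
        orfs = []
        for r in catalog:
            iv = r.interval
            lo = max(0, iv.start - config.extension)
            hi = min(len(genome[iv.chrom]), iv.end + config.extension)
            orfs.extend(
                pep.six_frame_orfs(
                    genome[iv.chrom][lo:hi],
                    (iv.start - lo, iv.end - lo),
                    retro_strand=iv.strand,
                    min_overlap=config.min_orf_overlap,
                    retro_id=r.retro_id,
                )
            )
        hits, n_short = pep.match_peptides(
            peptide_list, orfs, decoys, config.min_peptide_len
        )
        res.peptide_hits = hits
        for h in hits:
            res.peptide_support[h.retro_id] = (
                res.peptide_support.get(h.retro_id, 0) + 1
            )
        log.info("rejected %d peptides shorter than %d aa",
                 n_short, config.min_peptide_len)
        rio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "peptide_id": h.peptide_id, "retro_id": h.retro_id,
                        "frame": h.orf.frame, "orientation": h.orf.orientation,
                        "unique": h.unique,
                    }
                    for h in hits
                ]
            ),
            outdir / "peptide_hits.tsv", "peptides", params,
        )

    # ---- sponges --------------------------------------------------------
    if "sponges" in config.stages and matrix is not None:
        site_rows = _read_sites(indir / "mirna_sites.tsv")
        site_map = sp.load_site_table(site_rows)
        tids = [
            t.transcript_id for g in annotation for t in annotation[g]
        ]
        res.sponge_tests = sp.call_sponges(
            site_map, retro_ids, tids, res.correlations_coexpressed,
            config.alpha,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "retro_id": t.retro_id,
                        "transcript_id": t.transcript_id,
                        "M": t.M, "K": t.K, "n": t.n, "k": t.k,
                        "p": t.p, "q": t.q, "rho": t.rho,
                        "corr_p": t.corr_p, "called": t.called,
                        "corr_sign": t.corr_sign,
                    }
                    for t in res.sponge_tests
                ]
            ),
            outdir / "sponge_calls.tsv", "sponges", params,
        )

    # ---- overlap / NAT / interference / exonization ---------------------
    if "overlap" in config.stages:
        res.cis_nat_calls = ov.classify_cis_nat(
            overlaps, annotation, res.correlations_all
        )
        tss = _read_tss_bed(indir / "tss.bed")
        res.trans_nat_calls = ov.identify_trans_nat(
            catalog, annotation, tss, res.correlations_coexpressed,
            parent_transcripts, config.tss_window,
        )
        res.exon_contributions = ov.classify_exon_contribution(
            catalog, annotation
        )
        res.interference = ov.detect_transcriptional_interference(
            catalog, annotation, res.correlations_all, config.max_downstream
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": o.retro_id, "gene_id": o.gene_id,
                     "relative_strand": o.relative_strand,
                     "context": o.context, "overlap_bases": o.overlap_bases}
                    for o in overlaps
                ]
            ),
            outdir / "overlaps.tsv", "overlap", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": c.retro_id, "gene_id": c.partner_id,
                     **c.stats}
                    for c in res.cis_nat_calls
                ]
            ),
            outdir / "cis_nat_calls.tsv", "overlap", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": c.retro_id, "parent": c.partner_id,
                     **c.stats}
                    for c in res.trans_nat_calls
                ]
            ),
            outdir / "trans_nat_calls.tsv", "overlap", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": e.retro_id, "transcript_id": e.transcript_id,
                     "region_classes": ",".join(sorted(e.region_classes)),
                     "orientation": e.orientation,
                     "cds_complete": e.cds_complete}
                    for e in res.exon_contributions
                ]
            ),
            outdir / "exon_contributions.tsv", "overlap", params,
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {"retro_id": c.retro_id, "host_gene": c.host_gene_id,
                     "short_isoforms": ",".join(c.short_isoform_ids),
                     "long_isoforms": ",".join(c.long_isoform_ids),
                     "downstream_distance": c.downstream_distance,
                     "relative_strand": c.relative_strand,
                     "called": c.called}
                    for c in res.interference
                ]
            ),
            outdir / "interference_calls.tsv", "overlap", params,
        )

    # ---- fusions --------------------------------------------------------
    if "fusion" in config.stages:
        fusions = rio.read_fusion_table(indir / "fusions.tsv")
        res.fusion_classes = fu.classify_fusions(
            fusions, catalog, annotation, fu.FusionParams(config.near_max)
        )
        rio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "fusion_id": c.fusion_id, "category": c.category,
                        "retro_ids": ",".join(c.retro_ids),
                        "breakpoint_classes": ";".join(
                            f"{rid}:{side}:{bc.label}"
                            for (rid, side), bc in
                            sorted(c.breakpoint_classes.items())
                        ),
                    }
                    for c in res.fusion_classes
                ]
            ),
            outdir / "fusion_classes.tsv", "fusion", params,
        )

    res.counts = summarize_counts(res)
    (outdir / "run_log.json").write_text(
        json.dumps({"params": params, "counts": res.counts}, indent=2,
                   default=str)
    )
    return res


def summarize_counts(res: PipelineResult) -> dict:
    return {
        "expressed": len(res.expressed_retros),
        "ribo_positive": sum(
            1 for c in res.ribo_calls
            if c.stats["n_positive_libraries"] >= 1
        ),
        "peptide_supported": len(res.peptide_support),
        "sponge_called": sum(1 for t in res.sponge_tests if t.called),
        "cis_nat_called": sum(
            1 for c in res.cis_nat_calls if c.stats["called"]
        ),
        "trans_nat_called": sum(
            1 for c in res.trans_nat_calls if c.stats["called"]
        ),
        "interference_called": sum(1 for c in res.interference if c.called),
        "fusions_retro_related": sum(
            1 for c in res.fusion_classes if c.category != "other"
        ),
    }


def summarize_evidence(res: PipelineResult) -> pd.DataFrame:
    """Per-retrocopy evidence matrix plus mechanism-tagged network edges.

    Returns a DataFrame indexed by retro_id with one boolean column per
    evidence class and a ``dual_function`` flag for retrocopies called
    by more than one regulatory mechanism.
    """
    rows: dict[str, dict] = {}

    def mark(rid: str, cls: str) -> None:
        rows.setdefault(rid, {})[cls] = True

    for rid in res.expressed_retros:
        mark(rid, "expressed")
    for c in res.ribo_calls:
        if c.stats["n_positive_libraries"] >= 1:
            mark(c.retro_id, "ribosome")
    for rid in res.peptide_support:
        mark(rid, "peptide")
    for t in res.sponge_tests:
        if t.called:
            mark(t.retro_id, "sponge")
    for c in res.cis_nat_calls:
        if c.stats["called"]:
            mark(c.retro_id, "cis_nat")
    for c in res.trans_nat_calls:
        if c.stats["called"]:
            mark(c.retro_id, "trans_nat")
    for c in res.interference:
        if c.called:
            mark(c.retro_id, "interference")
    for c in res.fusion_classes:
        for rid in c.retro_ids:
            mark(rid, "fusion")
    classes = [
        "expressed", "ribosome", "peptide", "sponge", "cis_nat",
        "trans_nat", "interference", "fusion",
    ]
    df = pd.DataFrame(
        [
            {"retro_id": rid, **{c: flags.get(c, False) for c in classes}}
            for rid, flags in sorted(rows.items())
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["retro_id", *classes, "dual_function"])
    mech = ["sponge", "cis_nat", "trans_nat", "interference"]
    df["dual_function"] = df[mech].sum(axis=1) > 1
    return df.set_index("retro_id")


def network_edges(res: PipelineResult) -> list[tuple[str, str, str, str]]:
    """(retro, regulated id, mechanism, correlation sign) edge list."""
    edges = []
    for t in res.sponge_tests:
        if t.called:
            edges.append(
                (t.retro_id, t.transcript_id, "sponge", t.corr_sign or "+")
            )
    for c in res.cis_nat_calls:
        if c.stats["called"]:
            sign = "+" if c.stats["rho"] >= 0 else "-"
            edges.append((c.retro_id, c.partner_id, "cis_nat", sign))
    for c in res.trans_nat_calls:
        if c.stats["called"]:
            sign = "+" if c.stats["rho"] >= 0 else "-"
            edges.append((c.retro_id, c.partner_id, "trans_nat", sign))
    for c in res.interference:
        if c.called:
            edges.append((c.retro_id, c.host_gene_id, "interference", "+"))
    return edges
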