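"""Synthetic fixture generation with planted, machine-readable truth.

Every downstream stage gets a signal class planted here: expressed /
patterned retrocopies, Spearman-correlated pairs (Gaussian copula),
group-specific ribosome densities, peptides sampled from real six-frame
ORFs, shared miRNA target sites for sponges, antisense TSSs, and fusion
breakpoints in/near/far from retrocopy spans. Parental genes live on
chr1; retrocopies and their host genes on chr2, so cross-chromosome
fusion breakpoints exercise the "unrelated" class.

One RNG stream per generator op, seeded from ``(seed, op offset)``, so
regenerating a single fixture is reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from retrofunc.datamodel import (
    CoverageTrack,
    ExpressionMatrix,
    FusionRecord,
    GenomicInterval,
    RetrocopyRecord,
    SampleMeta,
    TranscriptModel,
)
from retrofunc.peptides import six_frame_orfs, _translate
from retrofunc.ribosome import density_features

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# op offsets for per-stage RNG streams
_OP_GENOME = 1
_OP_EXPRESSION = 2
_OP_COVERAGE = 3
_OP_PEPTIDES = 4
_OP_SITES = 5


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 24
    n_retrocopies: int = 40
    # (tissue_label, n_samples, is_cancer_line)
    tissue_plan: tuple = (
        ("spleen", 8, False),
        ("liver", 8, False),
        ("lung", 8, False),
        ("skin", 8, False),
        ("brain", 8, False),
        ("K562", 4, True),
        ("HepG2", 4, True),
    )
    planted_fractions: dict = field(
        default_factory=lambda: {
            "interference": 0.10,
            "cis_nat": 0.10,
            "exonization": 0.05,
            "trans_nat_a": 0.075,
            "trans_nat_c": 0.075,
            "sponge": 0.15,
            "peptide": 0.20,
            "ribosome": 0.40,
            "expressed": 0.75,
            "ubiquitous": 0.10,
            "tissue_specific": 0.10,
            "cancer_only": 0.05,
            "low_rna": 0.05,
        }
    )
    correlation_targets: tuple = ()  # extra (id_a, id_b, rho)
    density_means: dict = field(
        default_factory=lambda: {
            "cds": 1.0,
            "utr3": 0.2,
            "retro_positive": 1.0,
            "retro_negative": 0.1,
        }
    )
    mutation_rate: float = 0.03
    n_libraries: int = 6
    nb_dispersion: float = 10.0
    mirna_universe: int = 200
    sponge_sites: int = 15
    sponge_shared: int = 8
    background_site_rate: float = 2.0
    # 2-edge correlation stars stay positive-semidefinite only while
    # 2*sin(pi*rho/6)*sqrt(2) < 1, i.e. rho < ~0.66
    planted_rho: float = 0.65

    @property
    def n_samples(self) -> int:
        return sum(n for _, n, _ in self.tissue_plan)

    def __post_init__(self) -> None:
        for k, v in self.planted_fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")
        for k, v in self.density_means.items():
            if v <= 0:
                raise ValueError(f"density mean {k}={v} must be positive")
        for _, _, rho in self.correlation_targets:
            if not -1 <= rho <= 1:
                raise ValueError(f"target rho {rho} outside [-1, 1]")
        if self.sponge_shared > self.sponge_sites:
            raise ValueError("sponge_shared exceeds sites per sequence")
        geom = sum(
            self.planted_fractions.get(k, 0)
            for k in ("interference", "cis_nat", "exonization",
                      "trans_nat_a", "trans_nat_c")
        )
        if geom > 1:
            raise ValueError("geometry fractions sum beyond placeable loci")

    def rng(self, op_offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, op_offset])


class GroundTruth:
    """Per-retrocopy map of planted evidence classes and parameters."""

    def __init__(self) -> None:
        self.classes: dict[str, dict[str, dict]] = {}

    def add(self, retro_id: str, evidence_class: str, **params) -> None:
        self.classes.setdefault(retro_id, {})[evidence_class] = params

    def planted(self, evidence_class: str) -> set[str]:
        return {
            rid
            for rid, cls in self.classes.items()
            if evidence_class in cls
        }

    def params(self, retro_id: str, evidence_class: str) -> dict:
        return self.classes[retro_id][evidence_class]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("retro_id\tevidence_class\tparams\n")
            for rid in sorted(self.classes):
                for cls in sorted(self.classes[rid]):
                    fh.write(
                        f"{rid}\t{cls}\t"
                        f"{json.dumps(self.classes[rid][cls], sort_keys=True)}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        gt = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                rid, ec, params = line.rstrip("\n").split("\t")
                gt.add(rid, ec, **json.loads(params))
        return gt


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _designed_mrna(rng: np.random.Generator, total: int = 650) -> str:
    """mRNA with a 150-codon stop-free core so long ORFs always exist."""
    head = _random_seq(rng, 99)
    core = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(len(_NONSTOP_CODONS), size=150)
    )
    tail = _random_seq(rng, total - 99 - 450)
    return head + core + tail


class _ChromBuilder:
    def __init__(self, name: str) -> None:
        self.name = name
        self.chunks: list[str] = []
        self.cursor = 0

    def add(self, seq: str) -> int:
        start = self.cursor
        self.chunks.append(seq)
        self.cursor += len(seq)
        return start

    def add_random(self, rng: np.random.Generator, n: int) -> int:
        return self.add(_random_seq(rng, n))

    def sequence(self) -> str:
        return "".join(self.chunks)


def transcript_sequence(genome: dict[str, str], t: TranscriptModel) -> str:
    """Spliced transcript sequence in reading orientation."""
    s = "".join(genome[e.chrom][e.start:e.end] for e in t.exons)
    return s if t.strand == "+" else _revcomp(s)


def _allocate_classes(config: SimConfig) -> dict[int, str]:
    """Assign a geometry class to each retrocopy index."""
    n = config.n_retrocopies
    f = config.planted_fractions
    classes = {}
    idx = 0
    for cls in ("interference", "cis_nat", "exonization",
                "trans_nat_a", "trans_nat_c"):
        count = round(f.get(cls, 0) * n)
        for _ in range(count):
            if idx < n:
                classes[idx] = cls
                idx += 1
    while idx < n:
        classes[idx] = "intergenic"
        idx += 1
    return classes


def generate_genome_and_catalog(
    config: SimConfig,
) -> tuple[
    dict[str, str],
    dict[str, list[TranscriptModel]],
    list[RetrocopyRecord],
    GroundTruth,
]:
    rng = config.rng(_OP_GENOME)
    truth = GroundTruth()
    annotation: dict[str, list[TranscriptModel]] = {}
    catalog: list[RetrocopyRecord] = []

    # --- chr1: parental genes -------------------------------------------
    chr1 = _ChromBuilder("chr1")
    mrnas: dict[str, str] = {}
    parent_tid: dict[str, str] = {}
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    exon_lens = (220, 210, 220)
    for gid in gene_ids:
        chr1.add_random(rng, 300)
        mrna = _designed_mrna(rng, sum(exon_lens))
        exons = []
        offset = 0
        for j, elen in enumerate(exon_lens):
            if j > 0:
                chr1.add_random(rng, 160)
            start = chr1.add(mrna[offset : offset + elen])
            exons.append(GenomicInterval("chr1", start, start + elen, "+"))
            offset += elen
        cds = GenomicInterval(
            "chr1", exons[0].start + 60, exons[-1].end - 120, "+"
        )
        tid = f"{gid}-t1"
        annotation[gid] = [
            TranscriptModel(tid, gid, "protein_coding", tuple(exons), cds)
        ]
        mrnas[gid] = mrna
        parent_tid[gid] = tid
    chr1.add_random(rng, 500)

    # --- chr2: retrocopies and host genes -------------------------------
    chr2 = _ChromBuilder("chr2")
    classes = _allocate_classes(config)
    host_n = 0
    lnc_n = 0
    host_x_host_retros: list[int] = []
    for i in range(config.n_retrocopies):
        cls = classes[i]
        rid = f"retro_syn_{i + 1:04d}"
        parent = gene_ids[i % len(gene_ids)]
        # force a shared parent for the two host_x_host intronic retros
        if cls == "cis_nat" and len(host_x_host_retros) < 2:
            parent = gene_ids[0]
            host_x_host_retros.append(i)
        retro_seq = _mutate(rng, mrnas[parent], config.mutation_rate)
        retro_strand = "+" if i % 2 == 0 else "-"
        placed = retro_seq if retro_strand == "+" else _revcomp(retro_seq)
        chr2.add_random(rng, 400)

        if cls in ("intergenic", "trans_nat_a", "trans_nat_c"):
            chr2.add_random(rng, 600)
            rstart = chr2.add(placed)
            rend = rstart + len(placed)
            chr2.add_random(rng, 600)
            if cls == "trans_nat_a":
                lnc_n += 1
                lnc_gid = f"LNC{lnc_n:04d}"
                anti = "-" if retro_strand == "+" else "+"
                exon = GenomicInterval(
                    "chr2", max(0, rstart - 40), rend + 40, anti
                )
                annotation[lnc_gid] = [
                    TranscriptModel(
                        f"{lnc_gid}-t1", lnc_gid, "lncRNA", (exon,)
                    )
                ]
                truth.add(rid, "trans_nat", routes=["a"], parent=parent,
                          candidate=f"{lnc_gid}-t1")
            elif cls == "trans_nat_c":
                tp = rend - 1 if retro_strand == "+" else rstart
                anti = "-" if retro_strand == "+" else "+"
                tss_pos = tp + 200 if retro_strand == "+" else max(0, tp - 200)
                truth.add(rid, "trans_nat", routes=["c"], parent=parent,
                          tss=["chr2", int(tss_pos), anti])
        elif cls in ("cis_nat",):
            host_n += 1
            hgid = f"HOST{host_n:04d}"
            e1 = GenomicInterval(
                "chr2", chr2.add_random(rng, 200), chr2.cursor, "+"
            )
            chr2.add_random(rng, 300)
            anti = "-"  # host is '+'; cis-NAT retro goes antisense
            placed_anti = retro_seq if anti == "+" else _revcomp(retro_seq)
            rstart = chr2.add(placed_anti)
            rend = rstart + len(placed_anti)
            retro_strand = anti
            chr2.add_random(rng, 300)
            e2 = GenomicInterval(
                "chr2", chr2.add_random(rng, 200), chr2.cursor, "+"
            )
            annotation[hgid] = [
                TranscriptModel(
                    f"{hgid}-t1", hgid, "protein_coding", (e1, e2)
                )
            ]
            truth.add(rid, "cis_nat", host_gene=hgid,
                      host_transcript=f"{hgid}-t1")
        elif cls == "interference":
            host_n += 1
            hgid = f"HOST{host_n:04d}"
            shared = GenomicInterval(
                "chr2", chr2.add_random(rng, 200), chr2.cursor, "+"
            )
            chr2.add_random(rng, 150)
            short2 = GenomicInterval(
                "chr2", chr2.add_random(rng, 200), chr2.cursor, "+"
            )
            gap = int(rng.integers(100, 800))
            chr2.add_random(rng, gap)
            rstart = chr2.add(placed)
            rend = rstart + len(placed)
            chr2.add_random(rng, 1500)
            long2 = GenomicInterval(
                "chr2", chr2.add_random(rng, 250), chr2.cursor, "+"
            )
            short_t = TranscriptModel(
                f"{hgid}-short", hgid, "protein_coding", (shared, short2)
            )
            long_t = TranscriptModel(
                f"{hgid}-long", hgid, "protein_coding", (shared, long2)
            )
            annotation[hgid] = [short_t, long_t]
            truth.add(
                rid, "interference",
                host_gene=hgid,
                short_ids=[short_t.transcript_id],
                long_ids=[long_t.transcript_id],
                distance=rstart - short2.end,
            )
            if retro_strand == "-":
                # antisense nested retro correlated with a host isoform
                # also satisfies the cis-NAT call definition
                truth.add(rid, "cis_nat", host_gene=hgid,
                          host_transcript=short_t.transcript_id,
                          via="interference")
        elif cls == "exonization":
            host_n += 1
            hgid = f"HOST{host_n:04d}"
            e1_start = chr2.add_random(rng, 400)
            e1 = GenomicInterval("chr2", e1_start, e1_start + 400, "+")
            cds = GenomicInterval("chr2", e1_start + 60, e1_start + 360, "+")
            chr2.add_random(rng, 200)
            rstart = chr2.add(placed)
            rend = rstart + len(placed)
            e2 = GenomicInterval("chr2", rstart + 50, rstart + 250, "+")
            chr2.add_random(rng, 400)
            annotation[hgid] = [
                TranscriptModel(
                    f"{hgid}-t1", hgid, "protein_coding", (e1, e2), cds
                )
            ]
            truth.add(rid, "exonization", host_transcript=f"{hgid}-t1",
                      region_classes=["utr3"],
                      orientation="same" if retro_strand == "+" else "opposite")
        else:  # pragma: no cover
            raise AssertionError(cls)

        status = "known_pseudogene"
        if i % 17 == 3:
            status = "novel"
        elif i % 17 == 7:
            status = "other"
        catalog.append(
            RetrocopyRecord(
                retro_id=rid,
                interval=GenomicInterval("chr2", rstart, rend, retro_strand),
                status=status,
                parental_gene_id=parent,
                parental_transcript_id=parent_tid[parent],
            )
        )
    chr2.add_random(rng, 8000)  # room for distant fusion breakpoints

    # --- overlay (non-geometry) evidence classes ------------------------
    f = config.planted_fractions
    n = config.n_retrocopies
    all_ids = [r.retro_id for r in catalog]
    geometry_correlated = truth.planted("cis_nat") | truth.planted(
        "interference"
    ) | {
        rid
        for rid in truth.planted("trans_nat")
        if "c" in truth.params(rid, "trans_nat")["routes"]
    }

    n_sponge = round(f.get("sponge", 0) * n)
    # keep sponge retros off the geometry-correlated ones so no node
    # accumulates several strong copula edges (PSD clipping would
    # shrink the planted rho)
    sponge_pool = [rid for rid in all_ids if rid not in geometry_correlated]
    sponge_ids = sponge_pool[: n_sponge]
    other_gene_ids = gene_ids[1:] + gene_ids[:1]
    for j, rid in enumerate(sponge_ids):
        partner_gene = other_gene_ids[(j * 5 + 3) % len(other_gene_ids)]
        truth.add(rid, "sponge", partner=parent_tid[partner_gene])

    n_pep = round(f.get("peptide", 0) * n)
    for rid in all_ids[:n_pep]:
        truth.add(rid, "peptide")

    n_ribo = round(f.get("ribosome", 0) * n)
    n_low = round(f.get("low_rna", 0) * n)
    for rid in all_ids[:n_ribo]:
        truth.add(rid, "ribosome", group="positive")
    for rid in all_ids[n_ribo:]:
        truth.add(rid, "ribosome", group="negative")
    for rid in all_ids[n - n_low:]:
        truth.classes[rid]["ribosome"]["low_rna"] = True

    # expression patterns: correlated retros must be ubiquitous so the
    # copula transform (range (1, 100]) matches the planted label
    correlated = geometry_correlated | set(sponge_ids)
    n_ubiq = max(round(f.get("ubiquitous", 0) * n), 0)
    remaining = [rid for rid in all_ids if rid not in correlated]
    ubiq = set(list(correlated) + remaining[:n_ubiq])
    remaining = [rid for rid in remaining if rid not in ubiq]
    tissues = [t for t, cnt, c in config.tissue_plan if not c and cnt >= 2]
    n_tis = round(f.get("tissue_specific", 0) * n)
    tissue_specific = {
        rid: tissues[j % len(tissues)]
        for j, rid in enumerate(remaining[:n_tis])
    }
    remaining = remaining[n_tis:]
    n_can = round(f.get("cancer_only", 0) * n)
    cancer_only = set(remaining[:n_can])
    remaining = remaining[n_can:]
    n_expr = round(f.get("expressed", 0) * n)
    n_other = max(
        0, n_expr - len(ubiq) - len(tissue_specific) - len(cancer_only)
    )
    other_expr = set(remaining[:n_other])
    not_expr = set(remaining[n_other:])

    for rid in all_ids:
        if rid in ubiq:
            pattern, tissue = "ubiquitous", ""
        elif rid in tissue_specific:
            pattern, tissue = "tissue_specific", tissue_specific[rid]
        elif rid in cancer_only:
            pattern, tissue = "cancer_only", ""
        elif rid in other_expr:
            pattern, tissue = "other", ""
        else:
            pattern, tissue = "not_expressed", ""
        truth.add(rid, "pattern", pattern=pattern, tissue=tissue)
        if pattern != "not_expressed":
            truth.add(rid, "expressed")

    genome = {"chr1": chr1.sequence(), "chr2": chr2.sequence()}
    return genome, annotation, catalog, truth


# ---------------------------------------------------------------------------
# expression


def _correlation_pairs(
    config: SimConfig,
    catalog: list[RetrocopyRecord],
    truth: GroundTruth,
) -> list[tuple[str, str, float]]:
    by_id = {r.retro_id: r for r in catalog}
    pairs = []
    rho = config.planted_rho
    for rid in sorted(truth.planted("cis_nat")):
        pairs.append((rid, truth.params(rid, "cis_nat")["host_transcript"], rho))
    for rid in sorted(truth.planted("interference")):
        for tid in truth.params(rid, "interference")["short_ids"]:
            pairs.append((rid, tid, rho))
    for rid in sorted(truth.planted("trans_nat")):
        p = truth.params(rid, "trans_nat")
        parent_tid = f"{by_id[rid].parental_gene_id}-t1"
        if "a" in p["routes"]:
            pairs.append((p["candidate"], parent_tid, rho))
        if "c" in p["routes"]:
            pairs.append((rid, parent_tid, rho))
    for rid in sorted(truth.planted("sponge")):
        pairs.append((rid, truth.params(rid, "sponge")["partner"], rho))
    pairs.extend(config.correlation_targets)
    return pairs


def generate_expression_matrix(
    config: SimConfig,
    catalog: list[RetrocopyRecord],
    annotation: dict[str, list[TranscriptModel]],
    truth: GroundTruth,
) -> ExpressionMatrix:
    """TPM matrix realizing the planted patterns and correlations.

    Correlated groups are drawn from a Gaussian copula whose Pearson
    parameter is 2*sin(pi*rho_s/6), so the population Spearman equals
    the target; the monotone map z -> 1 + 99*Phi(z) keeps ranks intact
    and every correlated row above 1 TPM (ubiquitous).
    """
    rng = config.rng(_OP_EXPRESSION)
    samples = []
    k = 0
    for tissue, count, is_cancer in config.tissue_plan:
        for _ in range(count):
            k += 1
            samples.append(
                SampleMeta(
                    sample_id=f"S{k:04d}",
                    tissue_label="" if is_cancer else tissue,
                    is_cancer_line=is_cancer,
                    is_control=True,
                )
            )
    ns = len(samples)

    row_ids = [
        t.transcript_id
        for gid in annotation
        for t in annotation[gid]
    ] + [r.retro_id for r in catalog]
    tpm = np.zeros((len(row_ids), ns))
    row_index = {rid: i for i, rid in enumerate(row_ids)}

    # correlated components via Gaussian copula
    pairs = _correlation_pairs(config, catalog, truth)
    adj: dict[str, dict[str, float]] = {}
    for a, b, rho in pairs:
        adj.setdefault(a, {})[b] = rho
        adj.setdefault(b, {})[a] = rho
    visited: set[str] = set()
    z_by_row: dict[str, np.ndarray] = {}
    for start in sorted(adj):
        if start in visited:
            continue
        comp = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node in visited:
                continue
            visited.add(node)
            comp.append(node)
            stack.extend(adj[node])
        comp.sort()
        m = len(comp)
        cov = np.eye(m)
        for i, a in enumerate(comp):
            for j, b in enumerate(comp):
                if b in adj.get(a, {}):
                    cov[i, j] = 2 * math.sin(math.pi * adj[a][b] / 6)
        # eigen-based factor tolerates singular fills (|rho| = 1) and
        # clips slightly indefinite pairwise matrices to PSD
        w, v = np.linalg.eigh(cov)
        factor = v * np.sqrt(np.clip(w, 0.0, None))
        z = factor @ rng.standard_normal((m, ns))
        for i, node in enumerate(comp):
            z_by_row[node] = z[i]

    def ubiquitous_row(node: str) -> np.ndarray:
        z = z_by_row.get(node)
        if z is None:
            z = rng.standard_normal(ns)
        return 1.0 + 99.0 * norm.cdf(z)

    normal_idx = {
        t: [i for i, s in enumerate(samples)
            if not s.is_cancer_line and s.tissue_label == t]
        for t, _, c in config.tissue_plan if not c
    }
    cancer_idx = [i for i, s in enumerate(samples) if s.is_cancer_line]
    all_normal = [i for i, s in enumerate(samples) if not s.is_cancer_line]

    # non-retro transcripts: ubiquitous baseline
    for gid in annotation:
        for t in annotation[gid]:
            tpm[row_index[t.transcript_id]] = ubiquitous_row(t.transcript_id)

    for r in catalog:
        rid = r.retro_id
        i = row_index[rid]
        p = truth.params(rid, "pattern")
        pattern = p["pattern"]
        if pattern == "ubiquitous":
            tpm[i] = ubiquitous_row(rid)
        elif pattern == "tissue_specific":
            idx = normal_idx[p["tissue"]]
            tpm[i, idx] = rng.uniform(2.0, 20.0, size=len(idx))
        elif pattern == "cancer_only":
            tpm[i, cancer_idx] = rng.uniform(2.0, 20.0, size=len(cancer_idx))
        elif pattern == "other":
            # spread over >= 2 normal tissues but not everywhere
            n_on = max(4, ns // 3)
            chosen = list(rng.choice(ns, size=n_on, replace=False))
            chosen.append(normal_idx[sorted(normal_idx)[0]][0])
            chosen.append(normal_idx[sorted(normal_idx)[1]][0])
            off = [j for j in all_normal if j not in chosen]
            if not off:  # keep it non-ubiquitous
                chosen = chosen[:-1]
            tpm[i, sorted(set(chosen))] = rng.uniform(
                1.5, 15.0, size=len(set(chosen))
            )
        else:  # not_expressed: sub-threshold noise in one sample
            j = int(rng.integers(ns))
            tpm[i, j] = float(rng.uniform(0.0, 0.5))
    return ExpressionMatrix(row_ids, samples, tpm)


# ---------------------------------------------------------------------------
# coverage


def _nb_counts(
    rng: np.random.Generator, mean: float, size: int, dispersion: float
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def _rle_records(
    chrom: str, start: int, depths: np.ndarray
) -> list[tuple[GenomicInterval, float]]:
    out = []
    i = 0
    n = len(depths)
    while i < n:
        j = i
        while j < n and depths[j] == depths[i]:
            j += 1
        if depths[i] > 0:
            out.append(
                (GenomicInterval(chrom, start + i, start + j), float(depths[i]))
            )
        i = j
    return out


def generate_coverage_tracks(
    config: SimConfig,
    annotation: dict[str, list[TranscriptModel]],
    catalog: list[RetrocopyRecord],
    truth: GroundTruth,
) -> list[tuple[CoverageTrack, CoverageTrack]]:
    """Per-library (ribo, rna) track pairs with group-specific densities.

    RNA coverage is >= 10 by construction except for the planted
    low-coverage subset; Ribo coverage is RNA mean scaled by the
    feature group's density mean, with negative-binomial noise.
    """
    rng = config.rng(_OP_COVERAGE)
    # exonization-host CDS/UTR features overlap retro spans on chr2;
    # generate coverage only for disjoint features (chr1 genes + retros)
    features = [
        f
        for f in density_features(annotation, catalog)
        if f.group == "retro" or f.intervals[0].chrom == "chr1"
    ]
    dm = config.density_means
    out = []
    for lib in range(config.n_libraries):
        library_id = f"lib{lib + 1:02d}"
        rna_records: list[tuple[GenomicInterval, float]] = []
        ribo_records: list[tuple[GenomicInterval, float]] = []
        for feat in features:
            if feat.group == "retro":
                info = truth.classes.get(feat.feature_id, {}).get(
                    "ribosome", {"group": "negative"}
                )
                density = (
                    dm["retro_positive"]
                    if info.get("group") == "positive"
                    else dm["retro_negative"]
                )
                rna_mean = 3.0 if info.get("low_rna") else rng.uniform(25, 55)
            else:
                density = dm[feat.group]
                rna_mean = rng.uniform(25, 55)
            for iv in feat.intervals:
                rna_depth = np.maximum(
                    _nb_counts(rng, rna_mean, len(iv), config.nb_dispersion),
                    0.0,
                )
                ribo_depth = _nb_counts(
                    rng, rna_mean * density, len(iv), config.nb_dispersion
                )
                rna_records.extend(_rle_records(iv.chrom, iv.start, rna_depth))
                ribo_records.extend(
                    _rle_records(iv.chrom, iv.start, ribo_depth)
                )
        out.append(
            (
                CoverageTrack(library_id, "ribo", ribo_records),
                CoverageTrack(library_id, "rna", rna_records),
            )
        )
    return out


# ---------------------------------------------------------------------------
# peptides


def generate_peptides(
    config: SimConfig,
    catalog: list[RetrocopyRecord],
    genome: dict[str, str],
    annotation: dict[str, list[TranscriptModel]],
    truth: GroundTruth,
) -> list[tuple[str, str]]:
    """Peptide list with planted true hits, decoys and short rejects.

    True peptides (10-25 aa) are substrings of a real six-frame ORF of
    their retrocopy locus, checked for absence from every transcript
    translation (uniqueness holds by construction). Decoys are sampled
    from parental transcripts; a planted fraction is shorter than
    10 aa.
    """
    rng = config.rng(_OP_PEPTIDES)
    decoy_aa: list[str] = []
    for gid in annotation:
        for t in annotation[gid]:
            seq = transcript_sequence(genome, t)
            rc = _revcomp(seq)
            for s in (seq, rc):
                for frame in range(3):
                    decoy_aa.append(_translate(s[frame:]))

    peptides: list[tuple[str, str]] = []
    pid = 0
    for r in catalog:
        if "peptide" not in truth.classes.get(r.retro_id, {}):
            continue
        iv = r.interval
        lo = max(0, iv.start - 500)
        hi = min(len(genome[iv.chrom]), iv.end + 500)
        locus = genome[iv.chrom][lo:hi]
        orfs = six_frame_orfs(
            locus, (iv.start - lo, iv.end - lo),
            retro_strand=iv.strand, retro_id=r.retro_id,
        )
        orfs = [o for o in orfs if o.orientation == "sense"]
        if not orfs:
            truth.classes[r.retro_id].pop("peptide")
            continue
        orf = max(orfs, key=lambda o: len(o.aa_sequence))
        planted: list[str] = []
        for _ in range(60):
            if len(planted) >= 2:
                break
            plen = int(rng.integers(10, 26))
            if len(orf.aa_sequence) <= plen:
                continue
            off = int(rng.integers(0, len(orf.aa_sequence) - plen))
            pep = orf.aa_sequence[off : off + plen]
            if any(pep in d for d in decoy_aa):
                continue
            if pep in planted:
                continue
            pid += 1
            peptides.append((f"pep_{pid:05d}", pep))
            planted.append(pep)
        if planted:
            truth.classes[r.retro_id]["peptide"] = {"peptides": planted}
        else:
            truth.classes[r.retro_id].pop("peptide")

    # decoys: verbatim parental-translation fragments (non-unique)
    for gid in sorted(annotation)[:10]:
        t = annotation[gid][0]
        aa = _translate(transcript_sequence(genome, t))
        clean = max(aa.split("*"), key=len)
        if len(clean) > 15:
            off = int(rng.integers(0, len(clean) - 12))
            pid += 1
            peptides.append((f"pep_{pid:05d}", clean[off : off + 12]))
    # short peptides (must be rejected) and random no-match peptides
    aa_alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(5):
        pid += 1
        peptides.append(
            (f"pep_{pid:05d}",
             "".join(rng.choice(aa_alphabet, size=int(rng.integers(5, 10)))))
        )
    for _ in range(10):
        pid += 1
        peptides.append(
            (f"pep_{pid:05d}",
             "".join(rng.choice(aa_alphabet, size=15)))
        )
    return peptides


# ---------------------------------------------------------------------------
# miRNA sites, TSS, fusions


def generate_sites_tss_fusions(
    config: SimConfig,
    catalog: list[RetrocopyRecord],
    annotation: dict[str, list[TranscriptModel]],
    truth: GroundTruth,
) -> tuple[
    list[tuple[str, str]],
    list[tuple[str, int, str]],
    list[FusionRecord],
]:
    rng = config.rng(_OP_SITES)
    M = config.mirna_universe
    families = [f"fam_{i + 1:04d}" for i in range(M)]
    site_rows: list[tuple[str, str]] = []
    assigned: dict[str, set[str]] = {}

    def assign(seq_id: str, fams: set[str]) -> None:
        prev = assigned.setdefault(seq_id, set())
        for fam in sorted(fams - prev):
            site_rows.append((seq_id, fam))
        prev |= fams

    # background sites for every retro and parental transcript
    seq_ids = [r.retro_id for r in catalog] + [
        t.transcript_id for gid in annotation for t in annotation[gid]
    ]
    for sid in seq_ids:
        n_bg = rng.poisson(config.background_site_rate)
        if n_bg:
            assign(sid, set(rng.choice(families, size=min(n_bg, M),
                                       replace=False)))
    # planted sponge pairs: k shared of n/K sites each
    for rid in sorted(truth.planted("sponge")):
        partner = truth.params(rid, "sponge")["partner"]
        picked = list(
            rng.choice(
                families, size=2 * config.sponge_sites - config.sponge_shared,
                replace=False,
            )
        )
        shared = picked[: config.sponge_shared]
        retro_only = picked[
            config.sponge_shared : config.sponge_sites
        ]
        partner_only = picked[config.sponge_sites :]
        assign(rid, set(shared) | set(retro_only))
        assign(partner, set(shared) | set(partner_only))
        truth.classes[rid]["sponge"].update(
            k_planted=config.sponge_shared, M=M
        )

    # TSS table: planted antisense TSSs plus decoys
    tss_rows: list[tuple[str, int, str]] = []
    for rid in sorted(truth.planted("trans_nat")):
        p = truth.params(rid, "trans_nat")
        if "tss" in p:
            chrom, pos, strand = p["tss"]
            tss_rows.append((chrom, int(pos), strand))
    by_id = {r.retro_id: r for r in catalog}
    for r in catalog[:5]:  # decoys: same strand or far away
        iv = r.interval
        tss_rows.append((iv.chrom, iv.end + 100, iv.strand))
        tss_rows.append((iv.chrom, iv.end + 5000, "-" if iv.strand == "+" else "+"))

    # fusions
    fusions: list[FusionRecord] = []
    fid = 0

    def bp_for(retro: RetrocopyRecord, kind: str) -> tuple[str, int]:
        iv = retro.interval
        if kind == "in_body":
            return (iv.chrom, (iv.start + iv.end) // 2)
        if kind == "downstream_near":
            d = int(rng.integers(20, 211))
            pos = iv.end - 1 + d if iv.strand == "+" else iv.start - d
            return (iv.chrom, max(0, pos))
        d = int(rng.integers(6001, 7001))
        pos = iv.end - 1 + d if iv.strand == "+" else max(0, iv.start - d)
        return (iv.chrom, pos)

    bp_kinds = ["in_body", "in_body", "downstream_near", "distant"]
    cis_retros = sorted(truth.planted("cis_nat"))
    for j, rid in enumerate(cis_retros):
        r = by_id[rid]
        host = truth.params(rid, "cis_nat")["host_gene"]
        kind = bp_kinds[j % len(bp_kinds)]
        fid += 1
        parent_span = annotation[r.parental_gene_id][0].span
        fusions.append(
            FusionRecord(
                fusion_id=f"FUS{fid:03d}",
                gene5_id=r.parental_gene_id,
                gene3_id=host,
                breakpoint5=(parent_span.chrom, parent_span.start + 100),
                breakpoint3=bp_for(r, kind),
                source_label="synthetic",
            )
        )
        truth.add(rid, "fusion", category="parental_x_host",
                  breakpoint_class=kind, fusion_id=f"FUS{fid:03d}")

    # retro x parental fusion for the first intergenic retro
    intergenic = [
        r for r in catalog
        if not (
            truth.classes.get(r.retro_id, {}).keys()
            & {"cis_nat", "interference", "exonization"}
        )
    ]
    if intergenic:
        r = intergenic[0]
        fid += 1
        parent_span = annotation[r.parental_gene_id][0].span
        fusions.append(
            FusionRecord(
                fusion_id=f"FUS{fid:03d}",
                gene5_id=r.retro_id,
                gene3_id=r.parental_gene_id,
                breakpoint5=bp_for(r, "in_body"),
                breakpoint3=(parent_span.chrom, parent_span.end - 50),
                source_label="synthetic",
            )
        )
        truth.add(r.retro_id, "fusion", category="retro_x_parental",
                  breakpoint_class="in_body", fusion_id=f"FUS{fid:03d}")

    # host_x_host: the two intronic retros sharing a parent
    shared_parent: dict[str, list[RetrocopyRecord]] = {}
    for rid in cis_retros:
        shared_parent.setdefault(by_id[rid].parental_gene_id, []).append(
            by_id[rid]
        )
    for parent, rs in sorted(shared_parent.items()):
        if len(rs) >= 2:
            r1, r2 = rs[0], rs[1]
            h1 = truth.params(r1.retro_id, "cis_nat")["host_gene"]
            h2 = truth.params(r2.retro_id, "cis_nat")["host_gene"]
            fid += 1
            fusions.append(
                FusionRecord(
                    fusion_id=f"FUS{fid:03d}",
                    gene5_id=h1,
                    gene3_id=h2,
                    breakpoint5=bp_for(r1, "in_body"),
                    breakpoint3=bp_for(r2, "in_body"),
                    source_label="synthetic",
                )
            )
            # separate key: r1 already carries a parental_x_host record
            truth.add(r1.retro_id, "fusion_hxh", category="host_x_host",
                      breakpoint_class="in_body", fusion_id=f"FUS{fid:03d}")
            break

    # unrelated fusions (category "other")
    gene_ids = sorted(g for g in annotation if g.startswith("GENE"))
    for j in range(min(3, (len(gene_ids) - 2) // 2)):
        g5, g3 = gene_ids[2 * j + 2], gene_ids[2 * j + 3]
        fid += 1
        fusions.append(
            FusionRecord(
                fusion_id=f"FUS{fid:03d}",
                gene5_id=g5,
                gene3_id=g3,
                breakpoint5=("chr1", annotation[g5][0].span.start + 10),
                breakpoint3=("chr1", annotation[g3][0].span.start + 10),
                source_label="synthetic",
            )
        )
    return site_rows, tss_rows, fusions


# ---------------------------------------------------------------------------
# full fixture set


def write_fixtures(config: SimConfig, outdir: str | Path) -> Path:
    """Generate and serialize the complete fixture set for one config."""
    from retrofunc import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, catalog, truth = generate_genome_and_catalog(config)
    matrix = generate_expression_matrix(config, catalog, annotation, truth)
    tracks = generate_coverage_tracks(config, annotation, catalog, truth)
    peptides = generate_peptides(config, catalog, genome, annotation, truth)
    sites, tss, fusions = generate_sites_tss_fusions(
        config, catalog, annotation, truth
    )

    rio.write_fasta(genome, outdir / "genome.fa")
    rio.write_bed12(
        [t for g in annotation for t in annotation[g]],
        outdir / "annotation.bed",
    )
    rio.write_retrocopy_catalog(catalog, outdir / "catalog.tsv")
    rio.write_expression_matrix(
        matrix, outdir / "expression.tsv", outdir / "samples.tsv"
    )
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for ribo, rna in tracks:
        rio.write_bedgraph(ribo, tracks_dir / f"{ribo.library_id}.ribo.bedgraph")
        rio.write_bedgraph(rna, tracks_dir / f"{rna.library_id}.rna.bedgraph")
    with open(outdir / "peptides.tsv", "w") as fh:
        fh.write("peptide_id\tsequence\n")
        for pid, seq in peptides:
            fh.write(f"{pid}\t{seq}\n")
    with open(outdir / "mirna_sites.tsv", "w") as fh:
        fh.write("sequence_id\tmirna_family\n")
        for sid, fam in sites:
            fh.write(f"{sid}\t{fam}\n")
    with open(outdir / "tss.bed", "w") as fh:
        for chrom, pos, strand in tss:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttss\t0\t{strand}\n")
    with open(outdir / "fusions.tsv", "w") as fh:
        fh.write(
            "fusion_id\tgene5_id\tgene3_id\tchrom5\tpos5\tchrom3\tpos3"
            "\tsource_label\n"
        )
        for f in fusions:
            fh.write(
                f"{f.fusion_id}\t{f.gene5_id}\t{f.gene3_id}"
                f"\t{f.breakpoint5[0]}\t{f.breakpoint5[1]}"
                f"\t{f.breakpoint3[0]}\t{f.breakpoint3[1]}"
                f"\t{f.source_label}\n"
            )
    truth.to_tsv(outdir / "ground_truth.tsv")
    return outdir
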