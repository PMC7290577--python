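"""Six-frame ORF discovery on retrocopy loci and exact peptide matching.

The locus handed to :func:`six_frame_orfs` is the retrocopy span
extended by a flank (500 b by default, clipped at chromosome ends).
ORFs are maximal stop-to-stop translations of at least 20 codons; an
ORF is retained only when its nucleotide span intersects the
un-extended retrocopy span by at least 60 bases. Peptides (>= 10 aa)
must match an ORF translation exactly, full length, no gaps; matches
that also occur in any decoy transcript translation, or in ORFs of
more than one retrocopy, are flagged non-unique and excluded from the
final set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

MIN_ORF_OVERLAP = 60
MIN_ORF_AA = 20
MIN_PEPTIDE_LEN = 10
EXTENSION = 500

_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class OrfRecord:
    retro_id: str
    start: int  # locus-relative nt offset (forward coordinates)
    end: int
    frame: int  # 0-2 within its own reading strand
    strand: str  # reading direction in locus coordinates
    orientation: str  # sense/antisense relative to the retrocopy strand
    aa_sequence: str
    overlap_with_retro: int


@dataclass
class PeptideHit:
    peptide_id: str
    aa_sequence: str
    retro_id: str
    orf: OrfRecord
    offset_in_orf: int
    unique: bool = True
    frame_concordance: Optional[str] = None


@dataclass(frozen=True)
class CdsAlignment:
    """Ungapped anchor between locus coordinates and the parental CDS.

    ``locus_offset`` is the locus position that maps to CDS coordinate
    ``cds_offset``; ``parent_forward`` tells whether the parental mRNA
    runs in the locus-forward direction.
    """

    locus_offset: int
    cds_offset: int
    parent_forward: bool = True


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def six_frame_orfs(
    locus_sequence: str,
    retro_span_within_locus: tuple[int, int],
    retro_strand: str = "+",
    min_overlap: int = MIN_ORF_OVERLAP,
    min_aa: int = MIN_ORF_AA,
    retro_id: str = "",
) -> list[OrfRecord]:
    """Enumerate stop-to-stop ORFs in all six frames of a locus.

    Returns only ORFs overlapping the un-extended retrocopy span by
    ``min_overlap`` bases. ORF spans are locus-relative, forward
    coordinates regardless of reading strand.
    """
    seq = locus_sequence.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    rs, re_ = retro_span_within_locus
    L = len(seq)
    out = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            aa = _translate(s[frame:])
            pos = 0
            for segment in aa.split("*"):
                if len(segment) >= min_aa:
                    nt_start = frame + 3 * pos
                    nt_end = frame + 3 * (pos + len(segment))
                    if strand == "+":
                        span = (nt_start, nt_end)
                    else:
                        span = (L - nt_end, L - nt_start)
                    overlap = max(
                        0, min(span[1], re_) - max(span[0], rs)
                    )
                    if overlap >= min_overlap:
                        orientation = (
                            "sense" if strand == retro_strand else "antisense"
                        )
                        out.append(
                            OrfRecord(
                                retro_id=retro_id,
                                start=span[0],
                                end=span[1],
                                frame=frame,
                                strand=strand,
                                orientation=orientation,
                                aa_sequence=segment,
                                overlap_with_retro=overlap,
                            )
                        )
                pos += len(segment) + 1
    return out


def match_peptides(
    peptides: Sequence[tuple[str, str]],
    orfs: Sequence[OrfRecord],
    decoy_sequences: Optional[dict[str, str]] = None,
    min_peptide_len: int = MIN_PEPTIDE_LEN,
) -> tuple[list[PeptideHit], int]:
    """Exact full-length peptide-to-ORF matching with uniqueness filter.

    Returns the final hit list (unique hits only) plus the count of
    peptides rejected for being shorter than ``min_peptide_len``.
    Decoys are nucleotide sequences; they are translated in all six
    frames before substring comparison.
    """
    decoy_aa: list[str] = []
    for seq in (decoy_sequences or {}).values():
        seq = seq.upper().replace("U", "T")
        rc = str(Seq(seq).reverse_complement())
        for s in (seq, rc):
            for frame in range(3):
                decoy_aa.append(_translate(s[frame:]))

    n_short = 0
    all_hits: list[PeptideHit] = []
    for pep_id, pep_seq in peptides:
        pep_seq = pep_seq.upper()
        if len(pep_seq) < min_peptide_len:
            n_short += 1
            continue
        in_decoy = any(pep_seq in d for d in decoy_aa)
        hits_here = []
        for orf in orfs:
            off = orf.aa_sequence.find(pep_seq)
            if off >= 0:
                hits_here.append(
                    PeptideHit(pep_id, pep_seq, orf.retro_id, orf, off)
                )
        matched_retros = {h.retro_id for h in hits_here}
        unique = not in_decoy and len(matched_retros) == 1
        for h in hits_here:
            h.unique = unique
        all_hits.extend(hits_here)
    final = [h for h in all_hits if h.unique]
    return final, n_short


def annotate_frame_concordance(
    hit: PeptideHit, alignment: Optional[CdsAlignment]
) -> str:
    """Classify a hit's reading frame against the parental CDS.

    ``antisense`` when the ORF reads against the parental direction;
    otherwise ``concordant`` iff the peptide's first codon maps to a
    CDS position that is a multiple of three under the ungapped anchor.
    Hits with no alignable region are flagged ``unmapped``.
    """
    if alignment is None:
        hit.frame_concordance = "unmapped"
        return "unmapped"
    orf_forward = hit.orf.strand == "+"
    if orf_forward != alignment.parent_forward:
        hit.frame_concordance = "antisense"
        return "antisense"
    if orf_forward:
        first_base = hit.orf.start + 3 * hit.offset_in_orf
        q = alignment.cds_offset + (first_base - alignment.locus_offset)
    else:
        first_base = hit.orf.end - 1 - 3 * hit.offset_in_orf
        q = alignment.cds_offset + (alignment.locus_offset - first_base)
    label = "concordant" if q % 3 == 0 else "discordant"
    hit.frame_concordance = label
    return label
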