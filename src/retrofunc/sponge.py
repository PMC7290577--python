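"""miRNA-sponge (ceRNA) testing.

Target sites come either from canonical seed matching (7mer-m8 / 8mer)
or from a precomputed site table. Shared-site enrichment between a
retrocopy and a transcript is scored with an upper-tail hypergeometric
test over the screened miRNA-family universe, Benjamini-Hochberg
corrected across all tested pairs; a sponge call additionally requires
the pair's coexpressed-mode correlation to pass the expression filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from retrofunc.expression import CorrelationResult, passes_correlation_filter

ALPHA = 0.05


@dataclass
class TargetSiteMap:
    sites: dict[str, set[str]]  # sequence_id -> miRNA family ids
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty miRNA family universe")
        for sid, fams in self.sites.items():
            extra = fams - self.universe
            if extra:
                raise ValueError(
                    f"{sid}: families outside the universe: {sorted(extra)[:3]}"
                )

    @property
    def universe_size(self) -> int:
        return len(self.universe)


@dataclass
class SpongeTest:
    retro_id: str
    transcript_id: str
    M: int
    K: int
    n: int
    k: int
    p: float
    q: float = float("nan")
    rho: float = float("nan")
    corr_p: float = float("nan")
    called: bool = False
    corr_sign: str = ""


def seed_family(mirna_seq: str) -> str:
    """Collapse a mature miRNA to its seed (positions 2-8)."""
    s = mirna_seq.upper().replace("T", "U")
    if len(s) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    return s[1:8]


def _revcomp_dna(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq.upper()))


def predict_sites(
    sequences: dict[str, str],
    mirnas: dict[str, str],
    collapse_families: bool = True,
) -> TargetSiteMap:
    """Canonical seed-match site caller (7mer-m8 or 8mer).

    A site is reported when the transcript contains the reverse
    complement of miRNA positions 2-8 (7mer-m8); an 8mer is that
    heptamer followed by an A opposite position 1 and matches the same
    family. miRNAs are collapsed to seed families unless disabled.
    """
    families: dict[str, str] = {}
    for mid, mseq in mirnas.items():
        seed = seed_family(mseq)
        fam_id = f"fam_{seed}" if collapse_families else mid
        families[fam_id] = seed
    universe = set(families)
    sites: dict[str, set[str]] = {}
    for sid, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        hits = set()
        for fam_id, seed in families.items():
            if _revcomp_dna(seed) in seq:
                hits.add(fam_id)
        sites[sid] = hits
    return TargetSiteMap(sites=sites, universe=universe)


def load_site_table(rows: Sequence[tuple[str, str]],
                    universe: Optional[set[str]] = None) -> TargetSiteMap:
    """Build a TargetSiteMap from precomputed (sequence_id, family) rows."""
    sites: dict[str, set[str]] = {}
    fams = set()
    for sid, fam in rows:
        sites.setdefault(sid, set()).add(fam)
        fams.add(fam)
    return TargetSiteMap(sites=sites, universe=universe or fams)


def sponge_pvalue(M: int, K: int, n: int, k: int) -> float:
    """Upper-tail inclusive hypergeometric probability P(X >= k).

    Universe of M families, K targeting the transcript, n targeting the
    retrocopy, k shared.
    """
    if not (0 <= k <= min(K, n) and K <= M and n <= M):
        raise ValueError(f"inconsistent parameters M={M} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def bh_correct(
    pvalues: Sequence[float], alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Standard step-up Benjamini-Hochberg; returns (q-values, rejections)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def call_sponges(
    site_map: TargetSiteMap,
    retro_ids: Sequence[str],
    transcript_ids: Sequence[str],
    correlations: dict[tuple[str, str], CorrelationResult],
    alpha: float = ALPHA,
) -> list[SpongeTest]:
    """Test all retrocopy-transcript pairs sharing >= 1 miRNA family.

    BH correction runs across every tested pair. A call requires
    q <= alpha and a coexpressed-mode correlation passing the p/rho
    filter; negative-rho calls are kept with the sign flagged.
    """
    M = site_map.universe_size
    tests: list[SpongeTest] = []
    for rid in retro_ids:
        r_sites = site_map.sites.get(rid, set())
        if not r_sites:
            continue
        for tid in transcript_ids:
            t_sites = site_map.sites.get(tid, set())
            shared = r_sites & t_sites
            if not shared:
                continue
            tests.append(
                SpongeTest(
                    retro_id=rid,
                    transcript_id=tid,
                    M=M,
                    K=len(t_sites),
                    n=len(r_sites),
                    k=len(shared),
                    p=sponge_pvalue(M, len(t_sites), len(r_sites), len(shared)),
                )
            )
    if not tests:
        return []
    q, reject = bh_correct([t.p for t in tests], alpha)
    for t, qi, rej in zip(tests, q, reject):
        t.q = float(qi)
        corr = correlations.get((t.retro_id, t.transcript_id))
        if corr is not None:
            t.rho = corr.rho
            t.corr_p = corr.p
            t.corr_sign = "+" if corr.rho >= 0 else "-"
            t.called = bool(rej) and passes_correlation_filter(corr)
        else:
            t.called = False
    return tests
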