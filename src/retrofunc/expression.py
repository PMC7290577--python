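"""Expression filtering, pattern classification and co-expression.

Defaults follow the study design this pipeline operationalizes: a
transcript counts as expressed at >= 1 TPM in at least 1% of
experiments; correlations are kept at p < 0.001 and |rho| > 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from retrofunc.datamodel import ExpressionMatrix, SampleMeta

#: minimum number of samples entering any correlation; below this the
#: p < 0.001 bar is unreachable and rho is unstable.
MIN_PAIR_SAMPLES = 10


@dataclass(frozen=True)
class ExpressionFilterParams:
    min_tpm: float = 1.0
    min_sample_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_tpm <= 0:
            raise ValueError("min_tpm must be positive")
        if not 0 < self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    id_a: str
    id_b: str
    rho: float
    p: float
    n_used: int
    mode: str


@dataclass(frozen=True)
class PatternCall:
    retro_id: str
    pattern: str  # ubiquitous | tissue_specific | cancer_only | other | not_expressed
    tissue: str = ""
    presence_fractions: dict = field(default_factory=dict, compare=False)


def min_support_samples(n_experiments: int, fraction: float) -> int:
    """Smallest integer n with n / n_experiments >= fraction."""
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    return math.ceil(fraction * n_experiments)


def filter_expressed(
    matrix: ExpressionMatrix,
    params: ExpressionFilterParams = ExpressionFilterParams(),
) -> set[str]:
    """Ids expressed at >= min_tpm in at least the support-sample count."""
    need = min_support_samples(matrix.n_samples, params.min_sample_fraction)
    counts = np.sum(matrix.tpm >= params.min_tpm, axis=1)
    return {
        tid
        for tid, c in zip(matrix.transcript_ids, counts)
        if c >= need
    }


def eligible_tissues(samples: list[SampleMeta]) -> set[str]:
    """Normal tissues represented by at least two samples."""
    counts: dict[str, int] = {}
    for s in samples:
        if not s.is_cancer_line:
            counts[s.tissue_label] = counts.get(s.tissue_label, 0) + 1
    return {t for t, c in counts.items() if c >= 2}


def classify_pattern(
    matrix: ExpressionMatrix,
    retro_ids: list[str],
    min_tpm: float = 1.0,
) -> list[PatternCall]:
    """Assign each retrocopy exactly one expression pattern.

    - ubiquitous: detected (TPM >= min_tpm) in every sample;
    - cancer_only: detected in every cancer-line control sample and in
      zero normal-tissue samples;
    - tissue_specific: detected in >= 1 sample of exactly one eligible
      normal tissue and nowhere else among normal tissues (cancer-line
      samples are ignored for this call);
    - not_expressed: detected nowhere; otherwise other.

    Normal tissues with fewer than two samples are excluded from
    tissue-specific consideration.
    """
    tissues = eligible_tissues(matrix.samples)
    if not tissues:
        raise ValueError("no normal tissue has >= 2 samples")
    normal_idx = [
        i for i, s in enumerate(matrix.samples) if not s.is_cancer_line
    ]
    cancer_ctrl_idx = [
        i
        for i, s in enumerate(matrix.samples)
        if s.is_cancer_line and s.is_control
    ]
    tissue_idx = {
        t: [
            i
            for i, s in enumerate(matrix.samples)
            if not s.is_cancer_line and s.tissue_label == t
        ]
        for t in tissues
    }

    calls = []
    for rid in retro_ids:
        row = matrix.row(rid)
        detected = row >= min_tpm
        fractions = {
            t: float(np.mean(detected[idx])) for t, idx in tissue_idx.items()
        }
        normal_hits = {
            matrix.samples[i].tissue_label
            for i in normal_idx
            if detected[i]
        }
        if bool(np.all(detected)):
            pattern, tissue = "ubiquitous", ""
        elif (
            cancer_ctrl_idx
            and bool(np.all(detected[cancer_ctrl_idx]))
            and not any(detected[i] for i in normal_idx)
        ):
            pattern, tissue = "cancer_only", ""
        elif len(normal_hits) == 1 and normal_hits <= tissues:
            pattern, tissue = "tissue_specific", next(iter(normal_hits))
        elif not np.any(detected):
            pattern, tissue = "not_expressed", ""
        else:
            pattern, tissue = "other", ""
        calls.append(PatternCall(rid, pattern, tissue, fractions))
    return calls


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (mid-rank Pearson) with a two-sided t-approximate p.

    Returns ``(nan, nan)`` when either vector has zero rank variance;
    such results are excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_pairs(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    mode: str,
    min_pair_samples: int = MIN_PAIR_SAMPLES,
) -> list[CorrelationResult]:
    """Spearman correlation for each pair in one of two sample modes.

    ``coexpressed`` uses only samples where both members have TPM > 0;
    ``all`` uses every sample. Pairs with fewer than ``min_pair_samples``
    usable samples, or with a degenerate (constant-rank) vector, return
    no result.
    """
    if mode not in {"coexpressed", "all"}:
        raise ValueError(f"invalid mode {mode!r}")
    out = []
    for id_a, id_b in pairs:
        if id_a not in matrix:
            raise KeyError(f"unknown transcript id {id_a!r}")
        if id_b not in matrix:
            raise KeyError(f"unknown transcript id {id_b!r}")
        xa, xb = matrix.row(id_a), matrix.row(id_b)
        if mode == "coexpressed":
            mask = (xa > 0) & (xb > 0)
            xa, xb = xa[mask], xb[mask]
        if len(xa) < min_pair_samples:
            continue
        rho, p = spearman(xa, xb)
        if math.isnan(rho):
            continue
        out.append(CorrelationResult(id_a, id_b, rho, p, len(xa), mode))
    return out


def filter_correlations(
    results: list[CorrelationResult],
    p_max: float = 0.001,
    rho_abs_min: float = 0.25,
) -> list[CorrelationResult]:
    """Keep results with p strictly below p_max and |rho| strictly above
    rho_abs_min."""
    return [r for r in results if r.p < p_max and abs(r.rho) > rho_abs_min]


def passes_correlation_filter(
    r: CorrelationResult, p_max: float = 0.001, rho_abs_min: float = 0.25
) -> bool:
    return r.p < p_max and abs(r.rho) > rho_abs_min
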