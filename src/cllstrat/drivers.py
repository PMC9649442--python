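"""Coding-driver discovery: FDR voting, p-value combination, recurrent CNA
regions and focality/recurrence integration.

Two discovery routes are implemented. Route 1 works on per-gene p-values
from four (pluggable) mutation-recurrence algorithms: a gene is selected if
at least two of the four per-algorithm BH-FDRs fall below the significance
threshold, or if the FDR of a combined statistic does — the combination
being either a weighted Stouffer Z or a weighted harmonic mean of p-values.
Route 2 starts from copy-number data: minimally affected regions recurrent
in at least four samples are intersected with gene-level focality and
recurrence scores (the MutComFocal construction) and an SNV/indel count,
requiring the gene's mechanism of action (tumor suppressor vs oncogene) to
be concordant with the direction of the copy-number change.

A baseline per-gene binomial recurrence test is provided so the pipeline can
run end-to-end without external algorithm output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_EPS = 1e-15


def _clamp(p: np.ndarray) -> np.ndarray:
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at {0,1} clamped to (eps, 1-eps)", stacklevel=3)
    return np.clip(p, _EPS, 1 - _EPS)


def combine_stouffer_weighted(p: Sequence[float], w: Sequence[float] | None = None) -> float:
    """Weighted Stouffer combination: Z = sum(w_i z_i) / sqrt(sum w_i^2),
    z_i = Phi^{-1}(1 - p_i); returns the upper-tail p of Z."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    w = np.ones_like(p) if w is None else np.asarray(w, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights and p-values differ in length")
    if np.all(w == 0) or np.any(w < 0):
        raise ValueError("weights must be nonnegative and not all zero")
    z = stats.norm.isf(_clamp(p))
    Z = float(w @ z / math.sqrt(float(w @ w)))
    return float(stats.norm.sf(Z))


def combine_hmp_weighted(p: Sequence[float], w: Sequence[float] | None = None) -> float:
    """Normalized weighted harmonic mean of p-values:
    (sum w_i) / (sum w_i / p_i).

    Used as a ranking statistic ahead of BH-FDR; no asymptotic (Landau)
    calibration is applied, which is anti-conservative for small numbers of
    tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    w = np.ones_like(p) if w is None else np.asarray(w, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights and p-values differ in length")
    if np.all(w == 0) or np.any(w < 0):
        raise ValueError("weights must be nonnegative and not all zero")
    p = _clamp(p)
    return float(w.sum() / float((w / p).sum()))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneTestResult:
    gene: str
    p_values: list[float]
    weights: list[float] = field(default_factory=list)
    fdr_per_algorithm: list[float] = field(default_factory=list)
    combined_p_stouffer: Optional[float] = None
    combined_p_hmp: Optional[float] = None
    selected_by: list[str] = field(default_factory=list)


def select_drivers_method1(
    results: Sequence[GeneTestResult], alpha: float = 0.05
) -> set[str]:
    """Route-1 selection over a shared gene universe.

    Per-algorithm BH-FDR is computed column-wise; a gene is selected via the
    2-of-4 vote, or when the BH-FDR of the weighted-Stouffer or the
    weighted-harmonic-mean combined p falls below ``alpha``. Each selected
    gene's ``selected_by`` records which routes fired.
    """
    if not results:
        return set()
    n_alg = len(results[0].p_values)
    if any(len(r.p_values) != n_alg for r in results):
        raise ValueError("all genes must carry the same number of algorithm p-values")

    P = np.array([r.p_values for r in results], dtype=float)
    fdr_alg = np.column_stack([bh_fdr(P[:, j]) for j in range(n_alg)])
    for r, row in zip(results, fdr_alg):
        r.fdr_per_algorithm = list(row)
        w = r.weights or None
        r.combined_p_stouffer = combine_stouffer_weighted(r.p_values, w)
        r.combined_p_hmp = combine_hmp_weighted(r.p_values, w)
    fdr_st = bh_fdr([r.combined_p_stouffer for r in results])
    fdr_hmp = bh_fdr([r.combined_p_hmp for r in results])

    selected: set[str] = set()
    for i, r in enumerate(results):
        routes = []
        if int(np.sum(fdr_alg[i] < alpha)) >= 2:
            routes.append("vote_2of4")
        if fdr_st[i] < alpha:
            routes.append("stouffer")
        if fdr_hmp[i] < alpha:
            routes.append("hmp")
        r.selected_by = routes
        if routes:
            selected.add(r.gene)
    return selected


def binomial_recurrence_test(
    n_mutated: int, n_samples: int, gene_length_bp: int, background_rate: float
) -> float:
    """Baseline per-gene test: upper-tail binomial p for the number of
    mutated samples against a per-bp, per-sample background rate."""
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    p_hit = 1.0 - math.exp(-background_rate * gene_length_bp)
    return float(stats.binom.sf(n_mutated - 1, n_samples, p_hit))


@dataclass
class RecurrentRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    type: str  # gain | loss
    n_samples: int
    member_genes: list[str] = field(default_factory=list)


def minimally_affected_regions(
    segments_by_sample: Mapping[str, Sequence],
    min_samples: int = 4,
) -> list[RecurrentRegion]:
    """Minimal regions recurrently hit by CNAs in >= ``min_samples`` samples.

    Per type (gain/loss) and chromosome, a sweep line over segment endpoints
    finds maximal intervals with sample coverage >= ``min_samples``; within
    each, the reported region is the max-coverage core (the minimally
    overlapped region). Coordinates are 1-based inclusive. A sample
    contributes at most once per position.
    """
    events: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for sample, segs in segments_by_sample.items():
        for seg in segs:
            t = "gain" if seg.type == "gain" else ("loss" if seg.type == "loss" else None)
            if t is None:
                continue
            events.setdefault((t, seg.chrom), []).append((seg.start, seg.end, sample))

    regions: list[RecurrentRegion] = []
    for (cna_type, chrom), items in events.items():
        # sweep over breakpoints; coverage = number of distinct samples
        points: dict[int, list[tuple[int, str]]] = {}
        for start, end, sample in items:
            points.setdefault(start, []).append((+1, sample))
            points.setdefault(end + 1, []).append((-1, sample))
        xs = sorted(points)
        active: dict[str, int] = {}
        # piecewise-constant coverage over [xs[i], xs[i+1]-1]
        pieces: list[tuple[int, int, int]] = []
        for i, x in enumerate(xs[:-1]):
            for delta, sample in points[x]:
                active[sample] = active.get(sample, 0) + delta
                if active[sample] == 0:
                    del active[sample]
            pieces.append((x, xs[i + 1] - 1, len(active)))
        # maximal runs with coverage >= min_samples; core = argmax coverage
        run: list[tuple[int, int, int]] = []
        for piece in pieces + [(0, 0, 0)]:
            if piece[2] >= min_samples:
                run.append(piece)
                continue
            if run:
                peak = max(c for _, _, c in run)
                core = [pc for pc in run if pc[2] == peak]
                regions.append(
                    RecurrentRegion(chrom, core[0][0], core[-1][1], cna_type, peak)
                )
                run = []
    regions.sort(key=lambda r: (r.chrom, r.start, r.type))
    return regions


@dataclass
class Lesion:
    """One copy-number lesion in one sample: the set of genes it spans."""
    sample: str
    genes: frozenset[str]
    type: str = "loss"  # gain | loss

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("lesion spans zero genes")


@dataclass
class FocalityRecurrence:
    gene: str
    recurrence_score: float
    focality_score: float
    combined_score: float
    snv_indel_count: int = 0
    mechanism: str = "unknown"  # TSG | oncogene | unknown
    cna_direction: str = "loss"


def focality_recurrence(
    gene: str,
    lesions: Sequence[Lesion],
    n_cohort: int,
    snv_indel_count: int = 0,
    mechanism: str = "unknown",
) -> FocalityRecurrence:
    """MutComFocal-style scores for one gene.

    Per altered sample, recurrence contributes 1 / (number of lesions in
    that sample) and focality 1 / (number of genes spanned by the lesion
    covering the gene); both sums are normalized by cohort size, and the
    combined score is their product rescaled back onto the per-cohort scale.
    """
    by_sample: dict[str, list[Lesion]] = {}
    for les in lesions:
        by_sample.setdefault(les.sample, []).append(les)
    rec = foc = 0.0
    directions: list[str] = []
    for sample_lesions in by_sample.values():
        hits = [l for l in sample_lesions if gene in l.genes]
        if not hits:
            continue
        rec += 1.0 / len(sample_lesions)
        hit = min(hits, key=lambda l: len(l.genes))  # most focal covering lesion
        foc += 1.0 / len(hit.genes)
        directions.append(hit.type)
    rec /= n_cohort
    foc /= n_cohort
    combined = rec * foc * n_cohort  # product on the per-cohort scale
    direction = (
        max(set(directions), key=directions.count) if directions else "loss"
    )
    return FocalityRecurrence(
        gene, rec, foc, combined, snv_indel_count, mechanism, direction
    )


_CONCORDANT = {("TSG", "loss"), ("oncogene", "gain")}


def select_drivers_method2(
    fr: Sequence[FocalityRecurrence],
    score_threshold: float,
    min_snv: int = 5,
) -> tuple[set[str], set[str]]:
    """Route-2 selection: candidates need >= ``min_snv`` coding SNV/indels,
    both scores above ``score_threshold`` and a mechanism concordant with the
    CNA direction (loss for tumor suppressors, gain for oncogenes). Genes
    passing everything except the SNV count form the permissive set."""
    candidates: set[str] = set()
    permissive: set[str] = set()
    for r in fr:
        base = (
            r.recurrence_score > score_threshold
            and r.focality_score > score_threshold
            and (r.mechanism, r.cna_direction) in _CONCORDANT
        )
        if not base:
            continue
        if r.snv_indel_count >= min_snv:
            candidates.add(r.gene)
        else:
            permissive.add(r.gene)
    return candidates, permissive
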