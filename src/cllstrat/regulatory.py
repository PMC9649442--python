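"""Regulatory-element catalog, enhancer–gene linking, mutation recurrence and
allelic skew.

The catalog intersects open-chromatin (ATAC) peaks with H3K27ac peaks;
resulting regions are annotated with the consensus chromatin state observed
in at least two per-sample segmentations, and flagged when active only in
one IGHV stratum. Enhancers are linked to genes by correlating per-sample
H3K27ac signal with gene expression, testing only pairs inside the same
topologically associated domain and keeping links with Pearson r above a
floor at BH-FDR <= 0.05. Mutation recurrence per element is tested against a
length-adjusted binomial background model (this package's stand-in for a
full covariate-aware background), with single-site hotspot and kataegis
annotation. Allelic skew compares assay (ATAC/RNA) VAF with the WGS VAF.

Intervals are 0-based half-open internally; converters sit at VCF
boundaries (VCF positions are 1-based).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .drivers import bh_fdr


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


_STATE_TO_RE_TYPE = {
    "promoter": "promoter",
    "tss": "promoter",
    "enhancer": "enhancer",
    "utr5": "UTR5",
    "utr3": "UTR3",
}


@dataclass
class RECatalogEntry:
    interval: GenomicInterval
    re_type: Optional[str]  # promoter | enhancer | UTR5 | UTR3 | None
    state_support: int = 0
    ighv_specificity: str = "common"  # common | u-only | m-only
    id: str = ""


def _to_pyranges(intervals: Sequence[GenomicInterval]) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [i.chrom for i in intervals],
                "Start": [i.start for i in intervals],
                "End": [i.end for i in intervals],
            }
        )
    )


def _from_pyranges(ranges: pr.PyRanges) -> list[GenomicInterval]:
    if len(ranges) == 0:
        return []
    df = ranges.df
    return [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in df.itertuples()
    ]


def build_re_catalog(
    atac: Sequence[GenomicInterval],
    h3k27ac: Sequence[GenomicInterval],
    state_tracks: Mapping[str, Sequence[tuple[GenomicInterval, str]]] | None = None,
    u_track: Sequence[GenomicInterval] | None = None,
    m_track: Sequence[GenomicInterval] | None = None,
    min_state_support: int = 2,
) -> list[RECatalogEntry]:
    """Intersect ATAC and H3K27ac peaks and annotate chromatin state.

    ``state_tracks`` maps sample id to a list of (interval, state-label)
    segments. The consensus state of a catalog region is the most frequent
    state among samples whose segmentation overlaps it, and is assigned only
    when seen in at least ``min_state_support`` samples; otherwise the entry
    is emitted with no type. Entries overlapping only the u- or only the
    m-IGHV activity track are flagged stratum-specific.
    """
    if not atac or not h3k27ac:
        return []
    merged = _to_pyranges(atac).merge().intersect(_to_pyranges(h3k27ac).merge()).merge()
    entries: list[RECatalogEntry] = []
    for idx, iv in enumerate(_from_pyranges(merged)):
        state, support = None, 0
        if state_tracks:
            votes: dict[str, set[str]] = {}
            for sample, segs in state_tracks.items():
                for seg_iv, label in segs:
                    if iv.overlaps(seg_iv):
                        votes.setdefault(label.lower(), set()).add(sample)
            if votes:
                label, samples = max(
                    votes.items(), key=lambda kv: (len(kv[1]), kv[0])
                )
                if len(samples) >= min_state_support:
                    state, support = label, len(samples)
        spec = "common"
        if u_track is not None or m_track is not None:
            in_u = any(iv.overlaps(t) for t in (u_track or []))
            in_m = any(iv.overlaps(t) for t in (m_track or []))
            if in_u and not in_m:
                spec = "u-only"
            elif in_m and not in_u:
                spec = "m-only"
        entries.append(
            RECatalogEntry(
                interval=iv,
                re_type=_STATE_TO_RE_TYPE.get(state) if state else None,
                state_support=support,
                ighv_specificity=spec,
                id=f"RE_{iv.chrom}_{iv.start}_{iv.end}",
            )
        )
    return entries


@dataclass
class RETargetLink:
    re_id: str
    gene: str
    pearson_r: float
    p: float
    fdr: float
    tad_id: str


def link_enhancer_targets(
    catalog: Sequence[RECatalogEntry],
    signal: pd.DataFrame,  # RE id x sample
    expr: pd.DataFrame,    # gene x sample
    tads: Sequence[GenomicInterval],
    gene_locations: Mapping[str, GenomicInterval],
    r_min: float = 0.3,
    fdr_max: float = 0.05,
) -> list[RETargetLink]:
    """Correlate RE signal with expression of genes in the same TAD.

    Pearson r with a two-sided t-test p per pair; BH-FDR across all tested
    pairs; links kept at r >= ``r_min`` and FDR <= ``fdr_max``. Pairs with a
    constant signal or expression vector are skipped with a warning.
    """
    samples = [s for s in signal.columns if s in set(expr.columns)]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples to correlate")
    tad_ids = {t: f"TAD_{t.chrom}_{t.start}_{t.end}" for t in tads}

    tested: list[tuple[str, str, float, float, str]] = []
    for entry in catalog:
        if entry.id not in signal.index:
            continue
        tad = next((t for t in tads if entry.interval.overlaps(t)), None)
        if tad is None:
            continue
        x = signal.loc[entry.id, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant signal for {entry.id}; skipped", stacklevel=2)
            continue
        for gene, loc in gene_locations.items():
            if gene not in expr.index or not loc.overlaps(tad):
                continue
            y = expr.loc[gene, samples].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            tested.append((entry.id, gene, float(r), float(p), tad_ids[tad]))
    if not tested:
        return []
    fdr = bh_fdr([t[3] for t in tested])
    return [
        RETargetLink(re_id, gene, r, p, float(q), tad_id)
        for (re_id, gene, r, p, tad_id), q in zip(tested, fdr)
        if r >= r_min and q <= fdr_max
    ]


@dataclass
class REMutationTest:
    re_id: str
    n_mutated_samples: int
    p_recurrence: float
    fdr: float = math.nan
    hotspot_positions: list[int] = field(default_factory=list)
    kataegis_flag: bool = False
    signature_attribution: dict[str, float] = field(
        default_factory=lambda: {"AID": 0.0, "APOBEC": 0.0, "other": 1.0}
    )


def test_re_recurrence(
    re_entry: RECatalogEntry,
    mutations_by_sample: Mapping[str, Sequence[tuple[str, int]]],
    n_samples: int,
    background_rate: float,
    hotspot_min_samples: int = 3,
    kataegis_min: int = 6,
    kataegis_window: int = 1000,
) -> REMutationTest:
    """Binomial recurrence test for one regulatory element.

    The per-sample hit probability is 1 - exp(-background_rate * length);
    p = P(X >= observed mutated samples), X ~ Binom(n_samples, p_hit).
    Mutation positions are 1-based (VCF convention). A hotspot is a single
    position mutated in >= ``hotspot_min_samples`` samples; kataegis is
    flagged when one sample carries >= ``kataegis_min`` mutations inside the
    element within ``kataegis_window`` bp.
    """
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    iv = re_entry.interval
    hits_per_pos: dict[int, set[str]] = {}
    per_sample_positions: dict[str, list[int]] = {}
    for sample, muts in mutations_by_sample.items():
        for chrom, pos1 in muts:
            if iv.contains_point(chrom, pos1 - 1):
                hits_per_pos.setdefault(pos1, set()).add(sample)
                per_sample_positions.setdefault(sample, []).append(pos1)
    n_mut = len(per_sample_positions)
    p_hit = 1.0 - math.exp(-background_rate * iv.length)
    p = float(stats.binom.sf(n_mut - 1, n_samples, p_hit)) if n_mut else 1.0
    hotspots = sorted(
        pos for pos, ss in hits_per_pos.items() if len(ss) >= hotspot_min_samples
    )
    kataegis = False
    for positions in per_sample_positions.values():
        positions = sorted(positions)
        for i in range(len(positions)):
            j = i
            while j + 1 < len(positions) and positions[j + 1] - positions[i] <= kataegis_window:
                j += 1
            if j - i + 1 >= kataegis_min:
                kataegis = True
                break
        if kataegis:
            break
    return REMutationTest(
        re_id=re_entry.id,
        n_mutated_samples=n_mut,
        p_recurrence=p,
        hotspot_positions=hotspots,
        kataegis_flag=kataegis,
    )


def fdr_across_catalog(
    tests: Sequence[REMutationTest], fdr_threshold: float = 0.1
) -> list[REMutationTest]:
    """BH-FDR over the catalog's recurrence p-values; returns the
    significant elements (FDR < threshold) and sets ``fdr`` on every test."""
    if not tests:
        return []
    q = bh_fdr([t.p_recurrence for t in tests])
    for t, qq in zip(tests, q):
        t.fdr = float(qq)
    return [t for t in tests if t.fdr < fdr_threshold]


@dataclass
class AllelicSkewCall:
    variant: tuple[str, int, str, str]
    wgs_vaf: float
    assay_vaf: float
    assay_depth: int
    skew: str  # ref-skewed | alt-skewed | none | insufficient


def call_allelic_skew(
    variant: tuple[str, int, str, str],
    wgs_vaf: float,
    assay_vaf: float,
    assay_depth: int,
    min_depth: int = 10,
    diff_threshold: float = 0.1,
) -> AllelicSkewCall:
    """Allelic skew between an assay (ATAC/RNA) VAF and the WGS VAF.

    Calls are 'insufficient' below ``min_depth``; otherwise skewed toward
    the alternate allele when assay VAF exceeds WGS VAF by more than
    ``diff_threshold``, toward the reference when it falls short by more
    than that, and 'none' inside the band.
    """
    if assay_depth < 0:
        raise ValueError("negative assay depth")
    if assay_depth < min_depth:
        skew = "insufficient"
    else:
        diff = assay_vaf - wgs_vaf
        if diff > diff_threshold:
            skew = "alt-skewed"
        elif diff < -diff_threshold:
            skew = "ref-skewed"
        else:
            skew = "none"
    return AllelicSkewCall(variant, wgs_vaf, assay_vaf, assay_depth, skew)


def expression_contrast(
    tpm_mut: Sequence[float], tpm_wt: Sequence[float]
) -> tuple[float, float]:
    """Expression ratio (mutated over wild-type mean) with a two-sided
    Welch t-test p (Satterthwaite df). p is NaN when either group has fewer
    than two observations; the ratio is NaN when the wild-type mean is 0."""
    mut = np.asarray(tpm_mut, dtype=float)
    wt = np.asarray(tpm_wt, dtype=float)
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both groups must be nonempty")
    wt_mean = wt.mean()
    ratio = float(mut.mean() / wt_mean) if wt_mean != 0 else math.nan
    if mut.size < 2 or wt.size < 2:
        return ratio, math.nan
    _, p = stats.ttest_ind(mut, wt, equal_var=False)
    return ratio, float(p)
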