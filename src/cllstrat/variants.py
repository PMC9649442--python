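"""Somatic lesion records, filter engines, CCF and SV consensus merging.

Implements the tumor-only-against-matched-normal filtering rules used for
whole-genome CLL cohorts: hard thresholds on depth, allele fraction, caller
quality, population allele frequency, cohort recurrence, repeat context and
panel-of-normals evidence for SNVs/indels; quality and minimum-length rules
for copy-number segments (after merging adjacent same-state segments); and a
multi-caller consensus rule for structural variants (a call is reported when
at least two callers agree on type with both break-ends within a tolerance).

Cancer cell fractions are computed by the standard purity / local
copy-number rescaling of the variant allele fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt_reads: int
    normal_depth: int = 0
    filter_flag: str = "PASS"
    quality_score: float = 100.0
    population_af: float = 0.0
    germline_af: Optional[float] = None
    vqsr_score: Optional[float] = None
    recurrence_cohort_af: float = 0.0
    repeat_overlap: bool = False
    indel_proximity_flag: bool = False
    somatic_panel_phred: float = 255.0

    def __post_init__(self) -> None:
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError(f"negative depth at {self.chrom}:{self.pos}")
        if not 0 <= self.tumor_alt_reads <= self.tumor_depth:
            raise ValueError(
                f"alt reads outside [0, depth] at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af outside [0, 1]")

    @property
    def vaf(self) -> float:
        return self.tumor_alt_reads / self.tumor_depth if self.tumor_depth else 0.0


@dataclass
class CNASegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    type: str  # gain | loss | cnLOH
    total_copy_number: int = 2
    quality: float = 100.0
    caller: str = "canvas"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNA segment start must be < end")
        if self.type not in ("gain", "loss", "cnLOH"):
            raise ValueError(f"unknown CNA type {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class BreakEnd(NamedTuple):
    chrom: str
    pos: int
    orientation: str  # '+' or '-'


@dataclass
class SVBreakpointPair:
    type: str  # deletion | duplication | inversion | translocation
    break_end_1: BreakEnd
    break_end_2: BreakEnd
    caller: str
    allele_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction outside [0, 1]")
        if self.type not in ("deletion", "duplication", "inversion", "translocation"):
            raise ValueError(f"unknown SV type {self.type!r}")
        self.break_end_1 = BreakEnd(*self.break_end_1)
        self.break_end_2 = BreakEnd(*self.break_end_2)


@dataclass
class FilterPolicy:
    """Thresholds for the SNV/indel filter engine.

    Depth and caller quality use strict '>' comparisons; allele fraction
    keeps records at or above ``min_af``. Records with a VQSR score below
    ``min_vqsr`` are removed when the score is present; the rule is skipped
    for caller dialects that do not emit one.
    """

    min_depth: int = 10          # strict: depth > 10
    min_af: float = 0.05         # keep VAF >= 0.05
    min_quality: float = 30.0    # strict: quality > 30
    max_population_af: float = 0.05       # catalog AF must be < 0.05
    max_germline_af: float = 0.01         # cohort germline AF must be <= 0.01
    max_cohort_recurrence: float = 0.05   # somatic recurrence must be <= 0.05
    min_vqsr: float = 2.75       # remove vqsr < 2.75 when present
    min_somatic_panel_phred: float = 80.0
    require_pass: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_depth", "min_af", "min_quality", "max_population_af",
            "max_germline_af", "max_cohort_recurrence", "min_vqsr",
            "min_somatic_panel_phred",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# Rules in the order they are stated for the filtering pipeline; the first
# failing rule is the recorded removal reason.
_SNV_RULES = (
    ("min_depth", lambda v, p: v.tumor_depth > p.min_depth),
    ("min_af", lambda v, p: v.vaf >= p.min_af),
    ("filter_flag", lambda v, p: (not p.require_pass) or v.filter_flag == "PASS"),
    ("min_quality", lambda v, p: v.quality_score > p.min_quality),
    ("population_af", lambda v, p: v.population_af < p.max_population_af),
    ("germline_af", lambda v, p: v.germline_af is None or v.germline_af <= p.max_germline_af),
    ("cohort_recurrence", lambda v, p: v.recurrence_cohort_af <= p.max_cohort_recurrence),
    ("repeat_overlap", lambda v, p: not v.repeat_overlap),
    ("indel_proximity", lambda v, p: not v.indel_proximity_flag),
    ("vqsr", lambda v, p: v.vqsr_score is None or v.vqsr_score >= p.min_vqsr),
    ("somatic_panel", lambda v, p: v.somatic_panel_phred >= p.min_somatic_panel_phred),
)


def filter_snv_indels(
    calls: Sequence[VariantCall], policy: FilterPolicy | None = None
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Partition SNV/indel calls into kept and (removed, reason) lists.

    ``kept + [r for r, _ in removed]`` equals the input; each removed record
    carries the first rule it failed, in pipeline order.
    """
    policy = policy or FilterPolicy()
    kept: list[VariantCall] = []
    removed: list[tuple[VariantCall, str]] = []
    for call in calls:
        for reason, rule in _SNV_RULES:
            if not rule(call, policy):
                removed.append((call, reason))
                break
        else:
            kept.append(call)
    return kept, removed


@dataclass
class CCFInput:
    vaf: float
    purity: float
    local_total_cn: int = 2
    multiplicity: Optional[int] = None  # None -> estimate, floor 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf outside [0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.multiplicity is not None and self.multiplicity > self.local_total_cn:
            raise ValueError("multiplicity exceeds local total copy number")


class CCF(NamedTuple):
    ccf: float
    multiplicity: int
    capped: bool  # raw estimate exceeded 1.05 and was truncated to 1


def compute_ccf(x: CCFInput, cap_at: float = 1.05) -> CCF:
    """Cancer cell fraction from VAF, purity and local copy number.

    ccf = vaf * (purity * CN_tumor + (1 - purity) * 2) / (purity * m).
    When multiplicity is not given it is estimated as
    round(vaf * (purity*CN + (1-purity)*2) / purity), floored at 1. Raw
    values above ``cap_at`` are truncated to 1 and flagged.
    """
    denom_cn = x.purity * x.local_total_cn + (1.0 - x.purity) * 2.0
    if x.multiplicity is not None:
        m = x.multiplicity
    else:
        m = max(1, round(x.vaf * denom_cn / x.purity)) if x.vaf > 0 else 1
    ccf = x.vaf * denom_cn / (x.purity * m)
    capped = ccf > cap_at
    return CCF(min(ccf, 1.0) if capped else ccf, m, capped)


def _ends_close(a: SVBreakpointPair, b: SVBreakpointPair, tol: int) -> bool:
    for ea, eb in zip(
        (a.break_end_1, a.break_end_2), (b.break_end_1, b.break_end_2)
    ):
        if ea.chrom != eb.chrom or abs(ea.pos - eb.pos) > tol:
            return False
    return True


def merge_sv_consensus(
    calls_by_caller: Mapping[str, Sequence[SVBreakpointPair]],
    tolerance: int = 100,
) -> list[SVBreakpointPair]:
    """Consensus SVs supported by >= 2 callers.

    Calls of the same type whose two break-ends both lie within ``tolerance``
    bp are clustered (single-linkage across callers); clusters supported by
    at least two distinct callers are reported with median coordinates.
    Break-ends are canonically ordered within a call before comparison.
    """
    if len(calls_by_caller) < 2:
        raise ValueError("SV consensus requires calls from at least two callers")

    flat: list[tuple[str, SVBreakpointPair]] = []
    for caller, calls in calls_by_caller.items():
        for c in calls:
            b1, b2 = sorted([c.break_end_1, c.break_end_2])
            flat.append(
                (caller, SVBreakpointPair(c.type, b1, b2, caller, c.allele_fraction))
            )

    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            ci, cj = flat[i][1], flat[j][1]
            if ci.type == cj.type and _ends_close(ci, cj, tolerance):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[tuple[str, SVBreakpointPair]]] = {}
    for idx, item in enumerate(flat):
        clusters.setdefault(find(idx), []).append(item)

    consensus: list[SVBreakpointPair] = []
    for members in clusters.values():
        callers = {caller for caller, _ in members}
        if len(callers) < 2:
            continue
        calls = [c for _, c in members]
        b1 = BreakEnd(
            calls[0].break_end_1.chrom,
            int(median(c.break_end_1.pos for c in calls)),
            calls[0].break_end_1.orientation,
        )
        b2 = BreakEnd(
            calls[0].break_end_2.chrom,
            int(median(c.break_end_2.pos for c in calls)),
            calls[0].break_end_2.orientation,
        )
        consensus.append(
            SVBreakpointPair(
                calls[0].type, b1, b2,
                caller="+".join(sorted(callers)),
                allele_fraction=float(median(c.allele_fraction for c in calls)),
            )
        )
    consensus.sort(key=lambda c: (c.break_end_1.chrom, c.break_end_1.pos))
    return consensus


def filter_sv_af(calls: Iterable[SVBreakpointPair], min_af: float = 0.05) -> list[SVBreakpointPair]:
    """Drop SV calls with alternative allele fraction below ``min_af``."""
    return [c for c in calls if c.allele_fraction >= min_af]


def _merge_adjacent(segments: list[CNASegment], max_gap: int = 1) -> list[CNASegment]:
    out: list[CNASegment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (
            out
            and out[-1].chrom == seg.chrom
            and out[-1].type == seg.type
            and out[-1].total_copy_number == seg.total_copy_number
            and seg.start <= out[-1].end + max_gap
        ):
            prev = out[-1]
            out[-1] = CNASegment(
                prev.chrom, prev.start, max(prev.end, seg.end), prev.type,
                prev.total_copy_number, min(prev.quality, seg.quality), prev.caller,
            )
        else:
            out.append(seg)
    return out


def filter_cna(
    segments: Sequence[CNASegment],
    min_quality: float = 10.0,
    min_length: int = 100_000,
    exclusion: Optional[Sequence[tuple[str, int, int]]] = None,
) -> list[CNASegment]:
    """Quality, exclusion-region and minimum-length filtering of CNA calls.

    Segments with quality below ``min_quality`` are dropped; segments
    overlapping an exclusion interval (centromeres/telomeres; 1-based
    inclusive tuples) are dropped; adjacent same-state segments are merged;
    merged segments are kept only when strictly longer than ``min_length``.
    """
    if exclusion is None:
        warnings.warn(
            "no centromere/telomere exclusion track supplied; proceeding without",
            stacklevel=2,
        )
        exclusion = []
    passing = [s for s in segments if s.quality >= min_quality]
    passing = [
        s for s in passing
        if not any(
            s.chrom == chrom and s.start <= e and s.end >= b
            for chrom, b, e in exclusion
        )
    ]
    merged = _merge_adjacent(passing)
    return [s for s in merged if s.length > min_length]
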