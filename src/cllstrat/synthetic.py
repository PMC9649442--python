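"""Synthetic CLL cohorts with planted structure.

Every downstream stage of the pipeline is exercised on cohorts generated
here: a binary alteration matrix drawn from per-subgroup feature-prevalence
profiles with symmetric bit-flip noise, IGHV strata of fixed size,
subgroup-dependent exponential event times with independent exponential
censoring tuned to a target censoring fraction, somatic variant tables with
binomial read sampling consistent with purity and local copy number, and
correlated regulatory-element signal / gene-expression pairs inside shared
TADs.

The default cohort mirrors the study design the pipeline targets: 485
patients whose survival subset splits into 243 u-IGHV and 168 m-IGHV
(after exclusions), three planted u-IGHV and two m-IGHV genomic subgroups,
5% feature noise. ``default_cohort_spec`` builds that configuration over the
reference schema; all parameters are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import BinaryFeatureMatrix
from .regulatory import GenomicInterval, RECatalogEntry
from .schema import FeatureSchema, load_reference_schema
from .survival import SurvivalRecord
from .variants import CNASegment, VariantCall


@dataclass
class SubgroupProfile:
    label: str
    ighv_stratum: str                      # 'u' or 'm'
    feature_prevalence: dict[str, float]   # feature id -> P(present)
    hazard_scale: float                    # mean event time, months
    weight: float = 1.0                    # mixing weight within stratum

    def __post_init__(self) -> None:
        if self.ighv_stratum not in ("u", "m"):
            raise ValueError("ighv_stratum must be 'u' or 'm'")
        if self.hazard_scale <= 0:
            raise ValueError("hazard_scale must be positive")
        bad = {k: v for k, v in self.feature_prevalence.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"prevalence outside [0,1]: {list(bad)[:3]}")


@dataclass
class CohortSpec:
    n_patients: int
    subgroup_profiles: list[SubgroupProfile]
    ighv_split: float = 243 / 411          # fraction labelled u-IGHV
    noise_flip_prob: float = 0.05
    censoring_rate: float = 0.3
    seed: int = 0
    schema: FeatureSchema = field(default_factory=load_reference_schema)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.subgroup_profiles:
            raise ValueError("subgroup_profiles must be nonempty")
        for p in (self.ighv_split, self.noise_flip_prob, self.censoring_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        known = set(self.schema.feature_ids)
        for prof in self.subgroup_profiles:
            unknown = set(prof.feature_prevalence) - known
            if unknown:
                raise KeyError(
                    f"profile {prof.label} references unknown features: "
                    f"{sorted(unknown)[:3]}"
                )
        for stratum in ("u", "m"):
            profs = [p for p in self.subgroup_profiles if p.ighv_stratum == stratum]
            if profs:
                total = sum(p.weight for p in profs)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{stratum}-stratum mixing weights sum to {total}, not 1"
                    )


@dataclass
class SyntheticCohort:
    feature_matrix: BinaryFeatureMatrix
    true_labels: pd.Series               # patient -> subgroup label
    covariates: pd.DataFrame             # age, sex, ighv, percent_germline_identity
    survival: list[SurvivalRecord]
    spec: CohortSpec
    variant_tables: Optional[dict[str, list[VariantCall]]] = None

    def stratum_patients(self, stratum: str) -> list[str]:
        return list(self.covariates.index[self.covariates["ighv"] == stratum])


def default_cohort_spec(
    n_patients: int = 411,
    noise_flip_prob: float = 0.05,
    seed: int = 0,
    schema: FeatureSchema | None = None,
    n_defining: int = 12,
    defining_prevalence: float = 0.85,
    background_prevalence: float = 0.05,
) -> CohortSpec:
    """The default study conditions: 3 u-IGHV + 2 m-IGHV subgroups over the
    reference schema, with 243 u / 168 m patients at the default size.

    Each subgroup carries a disjoint block of ``n_defining`` defining
    features at ``defining_prevalence``; every other non-GC feature sits at
    ``background_prevalence``. Hazard scales differ across subgroups so that
    survival association is recoverable.
    """
    schema = schema or load_reference_schema()
    # GC-group columns are assigned downstream, not planted
    plantable = [f.id for f in schema.features if f.category != "gc_group"]
    blocks = [plantable[i * n_defining:(i + 1) * n_defining] for i in range(5)]
    if any(len(b) < n_defining for b in blocks):
        raise ValueError("schema too small for five disjoint defining blocks")
    hazard = {"u-GS1": 18.0, "u-GS2": 36.0, "u-GS3": 60.0, "m-GS1": 48.0, "m-GS2": 96.0}
    labels = ["u-GS1", "u-GS2", "u-GS3", "m-GS1", "m-GS2"]
    strata = ["u", "u", "u", "m", "m"]
    weights = [1 / 3, 1 / 3, 1 / 3, 0.5, 0.5]
    profiles = []
    for label, stratum, w, block in zip(labels, strata, weights, blocks):
        prev = {f: background_prevalence for f in plantable}
        prev.update({f: defining_prevalence for f in block})
        profiles.append(
            SubgroupProfile(label, stratum, prev, hazard[label], weight=w)
        )
    return CohortSpec(
        n_patients=n_patients,
        subgroup_profiles=profiles,
        ighv_split=243 / 411,
        noise_flip_prob=noise_flip_prob,
        seed=seed,
        schema=schema,
    )


def _deterministic_counts(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    raw = [w * total for w in weights]
    base = [int(np.floor(r)) for r in raw]
    rem = total - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for i in range(rem):
        base[order[i]] += 1
    return base


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort: features ~ Bernoulli(profile prevalence) then flipped
    with ``noise_flip_prob``; exponential event times per subgroup with
    independent exponential censoring at the target censoring fraction.
    Deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n_u = int(round(spec.n_patients * spec.ighv_split))
    n_m = spec.n_patients - n_u
    feature_ids = spec.schema.feature_ids
    fid_index = {f: i for i, f in enumerate(feature_ids)}

    rows, labels, strata = [], [], []
    for stratum, n_stratum in (("u", n_u), ("m", n_m)):
        profs = [p for p in spec.subgroup_profiles if p.ighv_stratum == stratum]
        if n_stratum and not profs:
            raise ValueError(f"no profiles for the {stratum}-IGHV stratum")
        if n_stratum == 0:
            continue
        counts = _deterministic_counts(n_stratum, [p.weight for p in profs])
        for prof, count in zip(profs, counts):
            prev = np.zeros(len(feature_ids))
            for f, p in prof.feature_prevalence.items():
                prev[fid_index[f]] = p
            for _ in range(count):
                x = (rng.random(len(feature_ids)) < prev).astype(int)
                if spec.noise_flip_prob > 0:
                    flip = rng.random(len(feature_ids)) < spec.noise_flip_prob
                    x = np.where(flip, 1 - x, x)
                rows.append(x)
                labels.append(prof.label)
                strata.append(stratum)

    patients = [f"P{i:04d}" for i in range(1, len(rows) + 1)]
    values = pd.DataFrame(np.array(rows), index=patients, columns=feature_ids)
    matrix = BinaryFeatureMatrix(values=values, schema=spec.schema)
    true_labels = pd.Series(labels, index=patients, name="subgroup")

    age = np.clip(np.round(rng.normal(65, 10, size=len(patients))), 30, 95).astype(int)
    sex = np.where(rng.random(len(patients)) < 0.7, "M", "F")
    pct = np.where(
        np.array(strata) == "u",
        rng.uniform(98.0, 100.0, size=len(patients)),
        rng.uniform(90.0, 97.9, size=len(patients)),
    )
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "ighv": strata,
         "percent_germline_identity": np.round(pct, 2)},
        index=patients,
    )

    scale_of = {p.label: p.hazard_scale for p in spec.subgroup_profiles}
    survival: list[SurvivalRecord] = []
    c = spec.censoring_rate
    for patient, label in true_labels.items():
        scale = scale_of[label]
        t_event = rng.exponential(scale)
        if c > 0:
            # exponential censoring with P(C < T) = c for exponential T
            t_cens = rng.exponential(scale * (1 - c) / c)
        else:
            t_cens = np.inf
        time = max(min(t_event, t_cens), 1e-3)
        survival.append(
            SurvivalRecord(patient, float(time), int(t_event <= t_cens), "PFS")
        )
    return SyntheticCohort(matrix, true_labels, covariates, survival, spec)


def expected_vaf(purity: float, total_cn: int, multiplicity: int, ccf: float = 1.0) -> float:
    """VAF implied by purity, local copy number, multiplicity and clonality:
    vaf = purity * ccf * m / (purity * CN + (1 - purity) * 2)."""
    return purity * ccf * multiplicity / (purity * total_cn + (1 - purity) * 2)


def generate_variant_table(
    n_variants: int,
    purity: float,
    cn_profile: Sequence[CNASegment] = (),
    seed: int = 0,
    mean_depth: float = 100.0,
    clonal_fraction: float = 0.8,
) -> list[VariantCall]:
    """Variant records with binomially sampled read counts.

    Each variant lands uniformly on a copy-number segment (or a diploid
    background when none covers it), is clonal with probability
    ``clonal_fraction`` (otherwise subclonal with CCF ~ U(0.2, 0.8)), and
    carries depth ~ Poisson(mean_depth) with alt reads ~ Binomial(depth,
    expected VAF). All fields the filter engine inspects are populated with
    passing defaults.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if n_variants < 0:
        raise ValueError("n_variants must be nonnegative")
    rng = np.random.default_rng(seed)
    calls: list[VariantCall] = []
    bases = np.array(list("ACGT"))
    for i in range(n_variants):
        if cn_profile and rng.random() < 0.5:
            seg = cn_profile[rng.integers(len(cn_profile))]
            chrom, pos = seg.chrom, int(rng.integers(seg.start, seg.end + 1))
            total_cn = seg.total_copy_number
        else:
            chrom, pos = "chr1", int(rng.integers(1, 10_000_000))
            total_cn = 2
        mult = 1
        ccf = 1.0 if rng.random() < clonal_fraction else float(rng.uniform(0.2, 0.8))
        vaf = expected_vaf(purity, total_cn, mult, ccf)
        depth = max(1, int(rng.poisson(mean_depth)))
        alt = int(rng.binomial(depth, min(vaf, 1.0)))
        ref, alt_base = rng.choice(bases, size=2, replace=False)
        calls.append(
            VariantCall(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt_base),
                tumor_depth=depth, tumor_alt_reads=alt,
                normal_depth=int(rng.poisson(mean_depth)),
            )
        )
    return calls


@dataclass
class RESignalData:
    signal: pd.DataFrame                   # RE id x sample
    expr: pd.DataFrame                     # gene x sample
    tads: list[GenomicInterval]
    re_entries: list[RECatalogEntry]
    gene_locations: dict[str, GenomicInterval]
    linked_pairs: list[tuple[str, str]]    # (re id, gene)


def generate_re_signal(
    n_samples: int,
    n_res: int,
    n_genes: int,
    linked_pairs: Sequence[tuple[int, int]],
    rho: float,
    seed: int = 0,
    tad_size: int = 1_000_000,
    res_per_tad: int = 5,
) -> RESignalData:
    """Correlated RE-signal / expression fixtures.

    REs and genes are laid out in TADs of ``tad_size`` bp, ``res_per_tad``
    REs (and as many genes) per TAD, so that an RE and the like-indexed
    genes share a TAD. ``linked_pairs`` are (RE index, gene index) pairs
    whose signal/expression share a latent factor giving population
    correlation ``rho``; a configured pair spanning two TADs is an error.
    Unlinked pairs are independent.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]

    tads: list[GenomicInterval] = []
    re_entries: list[RECatalogEntry] = []
    gene_locations: dict[str, GenomicInterval] = {}
    genes: list[str] = []
    n_tads = max((max(n_res, n_genes) + res_per_tad - 1) // res_per_tad, 1)
    for t in range(n_tads):
        tads.append(GenomicInterval("chr1", t * tad_size, (t + 1) * tad_size))
    for i in range(n_res):
        t = i // res_per_tad
        start = t * tad_size + (i % res_per_tad) * 10_000 + 1000
        iv = GenomicInterval("chr1", start, start + 500)
        re_entries.append(
            RECatalogEntry(iv, "enhancer", state_support=2,
                           id=f"RE_{iv.chrom}_{iv.start}_{iv.end}")
        )
    for j in range(n_genes):
        t = j // res_per_tad
        start = t * tad_size + (j % res_per_tad) * 10_000 + 5000
        gene = f"GENE{j:03d}"
        genes.append(gene)
        gene_locations[gene] = GenomicInterval("chr1", start, start + 2000)

    for i, j in linked_pairs:
        if i // res_per_tad != j // res_per_tad:
            raise ValueError(f"linked pair ({i}, {j}) spans two TADs")

    signal = rng.standard_normal((n_res, n_samples))
    expr = rng.standard_normal((n_genes, n_samples))
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    for i, j in linked_pairs:
        z = rng.standard_normal(n_samples)
        signal[i] = a * z + b * rng.standard_normal(n_samples)
        expr[j] = np.sign(rho) * a * z + b * rng.standard_normal(n_samples)

    return RESignalData(
        signal=pd.DataFrame(signal, index=[e.id for e in re_entries], columns=samples),
        expr=pd.DataFrame(expr, index=genes, columns=samples),
        tads=tads,
        re_entries=re_entries,
        gene_locations=gene_locations,
        linked_pairs=[(re_entries[i].id, genes[j]) for i, j in linked_pairs],
    )


# ---------------------------------------------------------------------------
# plain-text writers

def write_feature_matrix(matrix: BinaryFeatureMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="patient")


def write_clinical(cohort: SyntheticCohort, path: str | Path) -> None:
    surv = pd.DataFrame(
        {
            "patient": [r.patient for r in cohort.survival],
            "time": [r.time for r in cohort.survival],
            "event": [r.event for r in cohort.survival],
            "endpoint": [r.endpoint for r in cohort.survival],
        }
    ).set_index("patient")
    cohort.covariates.join(surv).to_csv(path, sep="\t", index_label="patient")


def write_truth_sidecar(cohort: SyntheticCohort, path: str | Path) -> None:
    payload = {
        "seed": cohort.spec.seed,
        "n_patients": cohort.spec.n_patients,
        "noise_flip_prob": cohort.spec.noise_flip_prob,
        "true_labels": cohort.true_labels.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Minimal VCF v4.2 (1-based) for variant fixtures."""
    lines = [_VCF_HEADER]
    for c in sorted(calls, key=lambda v: (v.chrom, v.pos)):
        ref_reads = c.tumor_depth - c.tumor_alt_reads
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.quality_score:.0f}\t"
            f"{c.filter_flag}\t.\tDP:AD\t{c.tumor_depth}:{ref_reads},{c.tumor_alt_reads}\n"
        )
    Path(path).write_text("".join(lines))


def write_seg(segments: Sequence[CNASegment], path: str | Path) -> None:
    """SEG-style TSV (1-based inclusive)."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "type": [s.type for s in segments],
            "total_copy_number": [s.total_copy_number for s in segments],
            "quality": [s.quality for s in segments],
            "caller": [s.caller for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
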