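"""Assembly rules for the binary genomic alteration matrix.

Continuous measures are binarized at the cohort median (>= median -> 1);
gene-level SNV/indel and CNA presence are combined by union; recurrent CNA
features on the same chromosome that strongly co-occur (phi, the mean-square
contingency coefficient, above 0.3) are union-merged transitively; and only
alterations with at least five occurrences across the cohort are retained,
with noncoding drivers additionally required to be mutated in more than 5%
of samples. Per-patient driver counts and pathway burdens follow the three
count definitions and four pathway gene-set modes described alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import FeatureSchema


@dataclass
class BinaryFeatureMatrix:
    """Patients x features matrix in {0,1} with its schema."""

    values: pd.DataFrame  # index = patient ids, columns = feature ids
    schema: FeatureSchema

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("feature matrix must be binary")
        unknown = [c for c in self.values.columns if c not in self.schema]
        if unknown:
            raise ValueError(f"features absent from schema: {unknown[:5]}")

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    def category_counts(self) -> dict[str, int]:
        by_id = {f.id: f.category for f in self.schema.features}
        counts: dict[str, int] = {}
        for c in self.values.columns:
            counts[by_id[c]] = counts.get(by_id[c], 0) + 1
        return counts


def binarize_continuous(values: Sequence[float]) -> np.ndarray:
    """Median split: 1 where value >= cohort median (over non-missing),
    0 below; missing values stay missing (NaN)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("all values missing; median undefined")
    med = float(np.median(finite))
    out = np.where(arr >= med, 1.0, 0.0)
    out[~np.isfinite(arr)] = np.nan
    return out


def combine_gene_feature(snv_present: Sequence[int], cna_present: Sequence[int]) -> np.ndarray:
    """Union (element-wise OR) of SNV/indel presence and CNA presence."""
    a = np.asarray(snv_present, dtype=int)
    b = np.asarray(cna_present, dtype=int)
    if a.shape != b.shape:
        raise ValueError("presence vectors differ in length")
    return (a | b).astype(int)


def phi_coefficient(x: Sequence[int], y: Sequence[int]) -> float:
    """Mean-square contingency (phi) of two binary vectors:
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)). NaN when a margin is zero."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return (a * d - b * c) / math.sqrt(denom)


def merge_cooccurring_cnas(
    cna_features: pd.DataFrame,
    chrom_of: Mapping[str, str],
    phi_min: float = 0.3,
) -> pd.DataFrame:
    """Union-merge same-chromosome CNA features that co-occur (phi > phi_min).

    Merging is transitive within a chromosome: clusters are connected
    components of the phi > phi_min graph. Degenerate (constant) features
    never pair. Merged columns are named by joining members with '+'.
    """
    cols = list(cna_features.columns)
    parent = {c: c for c in cols}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            if chrom_of[ci] != chrom_of[cj]:
                continue
            phi = phi_coefficient(cna_features[ci], cna_features[cj])
            if math.isnan(phi):
                continue
            if phi > phi_min:
                ri, rj = find(ci), find(cj)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[str, list[str]] = {}
    for c in cols:
        clusters.setdefault(find(c), []).append(c)
    out = {}
    for members in clusters.values():
        chroms = {chrom_of[m] for m in members}
        assert len(chroms) == 1, "merged cluster spans chromosomes"
        name = "+".join(members) if len(members) > 1 else members[0]
        out[name] = (cna_features[members].sum(axis=1) > 0).astype(int)
    return pd.DataFrame(out, index=cna_features.index)


def prevalence_filter(
    matrix: pd.DataFrame,
    min_occurrences: int = 5,
    noncoding_features: Iterable[str] = (),
    noncoding_min_fraction: float = 0.05,
) -> pd.DataFrame:
    """Drop features with fewer than ``min_occurrences`` positives; noncoding
    drivers must additionally be present in more than
    ``noncoding_min_fraction`` of samples."""
    if matrix.empty:
        return matrix
    noncoding = set(noncoding_features)
    n = len(matrix)
    keep = []
    for col in matrix.columns:
        s = int(matrix[col].sum())
        if s < min_occurrences:
            continue
        if col in noncoding and s / n <= noncoding_min_fraction:
            continue
        keep.append(col)
    return matrix[keep]


#: Exonic consequences counted as functional in the total-burden definition.
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "transcript_amplification",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "protein_altering_variant",
        "incomplete_terminal_codon_variant",
    }
)

#: High-impact subset used by the exome pathway mode.
HIGH_IMPACT_CONSEQUENCES = frozenset(
    {
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
    }
)


def _norm_consequence(term: str) -> str:
    return term.strip().lower().replace(" ", "_").replace("-", "_").replace("in_frame", "inframe")


@dataclass
class PatientLesions:
    """Annotated lesions of one patient used for counting.

    ``snv_indels`` holds (gene, consequence) pairs; ``cna_driver_genes`` and
    ``noncoding_drivers`` hold feature identifiers already matched to the
    schema's driver lists.
    """

    snv_indels: list[tuple[str, str]]
    cna_driver_genes: set[str]
    noncoding_drivers: set[str]


def count_drivers(
    lesions: PatientLesions, coding_driver_genes: Iterable[str]
) -> tuple[int, int, int]:
    """Per-patient driver counts under the three definitions:
    (1) functional variants (consequence in the functional list);
    (2) SNV/indel-mutated coding drivers;
    (3) coding drivers altered by SNV/indel or CNA, plus noncoding drivers.
    """
    drivers = set(coding_driver_genes)
    n_functional = 0
    snv_driver_genes: set[str] = set()
    for gene, consequence in lesions.snv_indels:
        term = _norm_consequence(consequence)
        if term not in FUNCTIONAL_CONSEQUENCES:
            if term not in _KNOWN_NONFUNCTIONAL:
                warnings.warn(f"unknown consequence {consequence!r}; counted as non-functional",
                              stacklevel=2)
            continue
        n_functional += 1
        if gene in drivers:
            snv_driver_genes.add(gene)
    n_coding_driver = len(snv_driver_genes)
    n_all = len(
        snv_driver_genes
        | (lesions.cna_driver_genes & drivers)
        | lesions.noncoding_drivers
    )
    return n_functional, n_coding_driver, n_all


_KNOWN_NONFUNCTIONAL = frozenset(
    {
        "synonymous_variant", "intron_variant", "intergenic_variant",
        "upstream_gene_variant", "downstream_gene_variant",
        "5_prime_utr_variant", "3_prime_utr_variant",
        "non_coding_transcript_exon_variant", "regulatory_region_variant",
    }
)


def merge_pathway_lists(
    primary: Sequence[str], secondary: Sequence[str]
) -> list[str]:
    """Merge two pathway name lists, preferring the primary catalog for
    names present in both (order: primary first, then novel secondary)."""
    primary_set = set(primary)
    merged = list(primary)
    merged.extend(p for p in secondary if p not in primary_set)
    return merged


def pathway_burden(
    patient_lesions: Mapping[str, PatientLesions],
    pathway_defs: Mapping[str, set[str]],
    mode: str = "driver_panel",
    coding_driver_genes: Iterable[str] = (),
    noncoding_target_genes: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Number of patients with a qualifying lesion in each pathway.

    Modes: ``driver_panel`` counts SNV/indels in the coding-driver panel;
    ``exome_high_impact`` adds any high-impact exonic mutation;
    ``driver_plus_noncoding`` adds noncoding drivers (mapped to target genes
    via ``noncoding_target_genes``); ``all`` combines everything. A gene in
    several pathways increments each of them.
    """
    if not pathway_defs:
        raise ValueError("pathway_defs must be nonempty")
    if mode not in ("driver_panel", "exome_high_impact", "driver_plus_noncoding", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    drivers = set(coding_driver_genes)
    nc_map = noncoding_target_genes or {}
    counts = {p: 0 for p in pathway_defs}
    for lesions in patient_lesions.values():
        hit_genes: set[str] = set()
        for gene, consequence in lesions.snv_indels:
            term = _norm_consequence(consequence)
            if gene in drivers and term in FUNCTIONAL_CONSEQUENCES:
                if mode in ("driver_panel", "exome_high_impact",
                            "driver_plus_noncoding", "all"):
                    hit_genes.add(gene)
            elif term in HIGH_IMPACT_CONSEQUENCES and mode in ("exome_high_impact", "all"):
                hit_genes.add(gene)
        if mode in ("driver_plus_noncoding", "all"):
            hit_genes |= {
                nc_map.get(nc, nc) for nc in lesions.noncoding_drivers
            }
        for pathway, members in pathway_defs.items():
            if hit_genes & members:
                counts[pathway] += 1
    return counts
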