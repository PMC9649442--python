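"""Feature schema for the binary genomic alteration matrix.

The integrated matrix holds one binary column per recurrent genomic
alteration, grouped into six categories: coding drivers (gene-level
SNV/indel or CNA, combined by union), recurrent CNA regions (same-chromosome
co-occurring regions merged by union), noncoding drivers (mutated regulatory
elements), pathway burdens, global genome features (mutational-signature
exposures, telomere metrics and similar continuous measures binarized at the
cohort median), and the eight genomic-complexity groups.

The reference schema shipped with the package
(``data/reference_schema_synthetic.yaml``) reproduces the published category
counts (58 + 36 + 44 + 12 + 28 + 8 = 186). It is a synthetic reconstruction:
feature identifiers use the gene, region and regulatory-element names printed
in the main text where available, and placeholder identifiers elsewhere.
All category-count invariants are driven by the schema object, never
hard-coded, so a user schema with different counts is equally valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

CATEGORIES = (
    "coding_driver",
    "recurrent_cna",
    "noncoding_driver",
    "pathway",
    "global",
    "gc_group",
)

#: Category counts of the reference schema (total 186).
REFERENCE_CATEGORY_COUNTS = {
    "coding_driver": 58,
    "recurrent_cna": 36,
    "noncoding_driver": 44,
    "pathway": 12,
    "global": 28,
    "gc_group": 8,
}

#: Binarization rules a feature may declare.
BINARIZATION_RULES = ("presence", "median")


@dataclass(frozen=True)
class Feature:
    id: str
    category: str
    binarization: str = "presence"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category: {self.category!r}")
        if self.binarization not in BINARIZATION_RULES:
            raise ValueError(f"unknown binarization rule: {self.binarization!r}")


@dataclass
class FeatureSchema:
    """Ordered feature list with category bookkeeping."""

    features: list[Feature] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in schema")

    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for f in self.features:
            counts[f.category] += 1
        return counts

    @property
    def n_features(self) -> int:
        return len(self.features)

    def ids_in_category(self, category: str) -> list[str]:
        return [f.id for f in self.features if f.category == category]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in set(self.feature_ids)

    def to_yaml(self, path) -> None:
        payload = {
            "version": self.version,
            "features": [
                {"id": f.id, "category": f.category, "binarization": f.binarization}
                for f in self.features
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "FeatureSchema":
        feats = [
            Feature(d["id"], d["category"], d.get("binarization", "presence"))
            for d in payload["features"]
        ]
        return cls(features=feats, version=str(payload.get("version", "0")))


# Names printed in the main text; the remainder of each category is padded
# with synthetic placeholders up to the published counts.
_CODING_DRIVERS_NAMED = [
    "TP53", "ATM", "SF3B1", "NOTCH1", "BIRC3", "MYD88", "XPO1", "POT1",
    "EGR2", "NFKBIE", "BRAF", "KRAS", "NRAS", "RPS15", "IKZF3", "DDX3X",
    "FBXW7", "CHD2", "MED12", "BAZ2A", "ASXL1", "SETD2", "ZNF292", "IRF4",
    "PTPN11", "CARD11", "IRF2BP2", "PCM1", "SMCHD1", "BACH2", "TRAF3",
    "ZMYM3", "MGA", "NXF1", "RANBP2", "CREBBP",
]
_RECURRENT_CNAS_NAMED = [
    "del13q14.2", "del11q22.3", "del17p13.1", "tri12", "del6q21",
    "gain2p16.1", "gain8q24.21", "del8p", "del1q42.2q42.3",
    "del18p11.32p11.31", "del10q24.32", "del14q24.3", "gain17q21",
    "del15q15.1",
]
_NONCODING_DRIVERS_NAMED = [
    "NOTCH1_3UTR", "IGLL5_5UTR", "BCL2_5UTR", "NFKBIZ_3UTR",
    "BIRC3_promoter", "IKZF3_promoter", "TP53_promoter", "BACH2_promoter",
    "BCL6_enhancer_2", "PAX5_enhancer",
]
_PATHWAYS = [
    "BCR_signaling", "NOTCH_signaling", "DNA_damage_cell_cycle",
    "RNA_ribosome_processing", "NFKB_signaling", "chromatin_remodeling",
    "MAPK_signaling", "apoptosis", "WNT_signaling", "inflammation",
    "cell_adhesion", "JAK_STAT",
]
_GLOBAL_MEDIAN = [
    "telomere_length", "telomere_content", "snv_count", "indel_count",
    "sv_count", "mutation_burden",
]
_GLOBAL_PRESENCE = [
    "SBS1", "SBS5", "SBS8", "SBS9", "SBS13", "SBS18", "SBS40",
    "chromothripsis", "kataegis", "complex_karyotype", "whole_genome_doubling",
    "aneuploidy", "cnLOH_any", "translocation_any", "inversion_any",
    "tandem_duplication_any", "BCR_stereotype_subset2", "IGHV3_21",
    "AID_signature_high", "APOBEC_signature_high", "MBL_phase", "del_burden_high",
]


def _padded(named: list[str], count: int, prefix: str) -> list[str]:
    ids = list(named[:count])
    i = len(ids) + 1
    while len(ids) < count:
        ids.append(f"{prefix}_{i:02d}")
        i += 1
    return ids


def build_reference_schema() -> FeatureSchema:
    """Construct the 186-feature reference schema programmatically.

    Identical to the shipped YAML; regenerating it keeps the two in sync.
    """
    counts = REFERENCE_CATEGORY_COUNTS
    feats: list[Feature] = []
    for fid in _padded(_CODING_DRIVERS_NAMED, counts["coding_driver"], "DRIVER"):
        feats.append(Feature(fid, "coding_driver"))
    for fid in _padded(_RECURRENT_CNAS_NAMED, counts["recurrent_cna"], "CNA_REGION"):
        feats.append(Feature(fid, "recurrent_cna"))
    for fid in _padded(_NONCODING_DRIVERS_NAMED, counts["noncoding_driver"], "RE_DRIVER"):
        feats.append(Feature(fid, "noncoding_driver"))
    for fid in _PATHWAYS[: counts["pathway"]]:
        feats.append(Feature(f"pathway_{fid}", "pathway"))
    glob = [(g, "median") for g in _GLOBAL_MEDIAN] + [(g, "presence") for g in _GLOBAL_PRESENCE]
    for fid, rule in glob[: counts["global"]]:
        feats.append(Feature(fid, "global", rule))
    for i in range(1, counts["gc_group"] + 1):
        feats.append(Feature(f"GC{i}", "gc_group"))
    return FeatureSchema(features=feats, version="1")


def load_reference_schema() -> FeatureSchema:
    """Load the shipped synthetic reference schema (186 features)."""
    ref = resources.files("cllstrat").joinpath("data/reference_schema_synthetic.yaml")
    with ref.open() as fh:
        return FeatureSchema._from_payload(yaml.safe_load(fh))
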