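"""Domain types shared across the pipeline.

The analysis operates over a curated panel of genes involved in xenobiotic
detoxification (DET), or in the permeability/integrity of physiological
barriers: blood-brain barrier (BBB), placenta (PLC) and respiratory cilia
(RC).  Evidence for a gene comes from two sides: rare predicted-damaging
single-nucleotide variants enriched in cases, and copy-number variants whose
carrier proportion is higher in cases than in controls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class ValidationError(ValueError):
    """A record violates a domain invariant (bad category, AC > AN, ...)."""


class FormatError(ValueError):
    """A file cannot be parsed in the declared dialect."""


class ConfigurationError(ValueError):
    """A run configuration is internally inconsistent (missing cohort, ...)."""


class PanelCategory(str, enum.Enum):
    DET = "DET"  # detoxification enzymes (phase I / phase II metabolism)
    BBB = "BBB"  # blood-brain barrier transporters, junctions
    PLC = "PLC"  # placenta hormones, receptors, morphogenesis
    RC = "RC"    # respiratory cilia


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class SiftLabel(str, enum.Enum):
    deleterious = "deleterious"
    deleterious_low_confidence = "deleterious_low_confidence"
    tolerated = "tolerated"
    tolerated_low_confidence = "tolerated_low_confidence"


class PolyphenLabel(str, enum.Enum):
    probably_damaging = "probably_damaging"
    possibly_damaging = "possibly_damaging"
    benign = "benign"
    unknown = "unknown"


class CnvClass(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"


class ConsequenceClass(str, enum.Enum):
    """Outcome of consequence triage.

    MISSENSE_CANDIDATE is the intermediate state before the SIFT/PolyPhen-2
    gate; a candidate that passes the gate becomes DAMAGING_MISSENSE.
    """

    LOF = "LOF"
    MISSENSE_CANDIDATE = "MISSENSE_CANDIDATE"
    DAMAGING_MISSENSE = "DAMAGING_MISSENSE"
    EXCLUDED = "EXCLUDED"


class Stage(str, enum.Enum):
    """How far a variant got through the prioritization cascade."""

    qc_fail = "qc_fail"
    common_fail = "common_fail"
    impact_fail = "impact_fail"
    prediction_fail = "prediction_fail"
    internal_enrichment_fail = "internal_enrichment_fail"
    reference_enrichment_fail = "reference_enrichment_fail"
    prioritized = "PRIORITIZED"


class EnrichmentMode(str, enum.Enum):
    exclusive = "exclusive"  # alternate allele absent from the comparison cohorts
    ratio = "ratio"          # case MAF / control MAF above the enrichment ratio


class Criterion(str, enum.Enum):
    """High-evidence classes: SNV+CNV, >=5 unique damaging SNVs,
    CNV-exclusive, or CNV carrier proportion significantly higher in cases."""

    C1_snv_and_cnv = "C1_snv_and_cnv"
    C2_five_plus_snv = "C2_five_plus_snv"
    C3_cnv_exclusive = "C3_cnv_exclusive"
    C4_cnv_enriched = "C4_cnv_enriched"
    none = "none"


CHEMICAL_GROUPS = (
    "Air Pollutants",
    "Toxic Heavy Metals",
    "Non-Persistent Organic Pollutants",
    "Persistent Organic Pollutants",
    "Pesticides",
    "Clinical Drugs",
    "Nutritional Factors",
)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so joins across files are name-insensitive."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class GenePanelEntry:
    symbol: str
    category: PanelCategory
    subcategory: str = ""
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("panel entry with empty gene symbol")


@dataclass(frozen=True)
class GeneModel:
    """Gene footprint used for CNV-gene overlap; 0-based half-open."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"gene {self.symbol}: empty chromosome")
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.symbol}: start {self.start} >= end {self.end}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class CohortFrequency:
    """Allele counts for one cohort; MAF = AC / AN."""

    label: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if not 0 <= self.ac <= self.an:
            raise ValidationError(
                f"cohort {self.label}: AC={self.ac} outside [0, AN={self.an}]"
            )

    @property
    def maf(self) -> float:
        if self.an == 0:
            raise ValidationError(f"cohort {self.label}: no called alleles (AN=0)")
        return self.ac / self.an


@dataclass(frozen=True)
class AnnotatedVariant:
    """One SNV (one alt allele) with its functional annotations and
    per-cohort allele counts.  Identity key is (chrom, pos, ref, alt)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene_symbol: str
    consequence_terms: tuple[str, ...]
    impact: Impact
    sift: Optional[SiftLabel] = None
    polyphen: Optional[PolyphenLabel] = None
    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None
    cohort_counts: Mapping[str, CohortFrequency] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos} ref == alt ({self.ref})")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    cohort: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    cnv_class: CnvClass
    dataset_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("CNV call with empty sample_id")
        if not self.start < self.end:
            raise ValidationError(
                f"CNV {self.sample_id} {self.chrom}: start {self.start} >= end {self.end}"
            )
        if self.dataset_frequency is not None and not 0 <= self.dataset_frequency <= 1:
            raise ValidationError(
                f"CNV {self.sample_id}: dataset_frequency {self.dataset_frequency} "
                "outside [0, 1]"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass
class TrioRecord:
    """A proband with optional parents.

    ``carried`` maps a person id to the set of qualifying keys that person
    carries: SNV identity keys ("chrom:pos:ref:alt") and, for CNV-driven gene
    carriage, "CNV:<GENE>".  A person present in ``carried`` (even with an
    empty set) has genotype data; an absent person has none.
    """

    proband_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    family_id: str = ""
    carried: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.proband_id:
            raise ValidationError("trio with empty proband_id")


@dataclass(frozen=True)
class InteractionRecord:
    """One curated chemical-gene interaction record (CTD-export shaped)."""

    gene_symbol: str
    chemical_name: str
    chemical_mesh_id: str
    organism: str
    pmids: frozenset[str] = frozenset()
    action: str = ""

    def __post_init__(self) -> None:
        if not self.chemical_mesh_id:
            raise ValidationError(
                f"interaction {self.gene_symbol}/{self.chemical_name}: empty MeSH id"
            )


@dataclass(frozen=True)
class ChemicalEntry:
    name: str
    mesh_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in CHEMICAL_GROUPS:
            raise ValidationError(
                f"chemical {self.name}: unknown group {self.group!r} "
                f"(expected one of {', '.join(CHEMICAL_GROUPS)})"
            )
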