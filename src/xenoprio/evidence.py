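"""Combine SNV and CNV evidence into the high-evidence gene classification.

A panel gene lands in exactly one class:

* C1 — at least one prioritized damaging SNV AND CNV evidence (exclusive to
  cases, or carrier proportion significantly higher in cases);
* C2 — five or more unique prioritized SNVs, no CNV evidence;
* C3 — CNVs exclusively in cases, no prioritized SNV;
* C4 — significantly higher CNV carrier proportion in cases, no prioritized
  SNV;
* none — anything else (including 1-4 prioritized SNVs without CNV support).

CNV evidence from any case cohort suffices; exclusivity takes precedence
over enrichment when a gene shows both (C3 before C4), which keeps the
partition disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .cnv import BurdenReport
from .snv import GeneSnvSummary
from .types import (
    Criterion,
    GenePanelEntry,
    PanelCategory,
    TrioRecord,
    ValidationError,
)

HIGH_EVIDENCE_MIN_SNVS = 5


@dataclass(frozen=True)
class GeneEvidence:
    gene_symbol: str
    category: PanelCategory
    has_prioritized_snv: bool
    unique_snv_count: int
    cnv_exclusive: bool
    cnv_enriched: bool
    previously_reported: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.has_prioritized_snv and self.unique_snv_count < 1:
            raise ValidationError(
                f"{self.gene_symbol}: has_prioritized_snv with zero unique SNVs"
            )


@dataclass
class HighEvidenceSet:
    by_criterion: dict[Criterion, list[str]]
    criterion_of: dict[str, Criterion]

    @property
    def total(self) -> int:
        return sum(len(v) for c, v in self.by_criterion.items()
                   if c is not Criterion.none)

    @property
    def genes(self) -> set[str]:
        return {g for c, gs in self.by_criterion.items()
                if c is not Criterion.none for g in gs}

    def counts(self) -> dict[str, int]:
        return {c.value: len(self.by_criterion.get(c, []))
                for c in Criterion if c is not Criterion.none}


@dataclass
class TransmissionSummary:
    cohort_label: str
    n_maternal: int
    n_assessed: int

    @property
    def fraction(self) -> Optional[float]:
        """Percentage of assessed subjects with a maternally inherited
        qualifying variant; None (flagged) when nobody was assessable."""
        if self.n_assessed == 0:
            return None
        return 100.0 * self.n_maternal / self.n_assessed


def classify_gene(evidence: GeneEvidence) -> Criterion:
    """Assign the single high-evidence criterion for one gene."""
    cnv_any = evidence.cnv_exclusive or evidence.cnv_enriched
    if evidence.has_prioritized_snv and cnv_any:
        return Criterion.C1_snv_and_cnv
    if evidence.unique_snv_count >= HIGH_EVIDENCE_MIN_SNVS:
        return Criterion.C2_five_plus_snv
    if evidence.cnv_exclusive and not evidence.has_prioritized_snv:
        return Criterion.C3_cnv_exclusive
    if evidence.cnv_enriched and not evidence.has_prioritized_snv:
        return Criterion.C4_cnv_enriched
    return Criterion.none


def build_evidence(panel: Sequence[GenePanelEntry],
                   snv_summaries: Mapping[str, GeneSnvSummary],
                   burden: Optional[BurdenReport] = None,
                   previously_reported: Optional[Mapping[str, bool]] = None
                   ) -> dict[str, GeneEvidence]:
    """Assemble per-gene evidence from the SNV and CNV stage outputs."""
    exclusive: set[str] = set()
    enriched: set[str] = set()
    if burden is not None:
        for excl_list in burden.exclusivity.values():
            exclusive |= {e.gene_symbol for e in excl_list}
        for tests in burden.tests.values():
            enriched |= {t.gene_symbol for t in tests if t.significant}
    prev = previously_reported or {}
    out = {}
    for entry in panel:
        s = snv_summaries.get(entry.symbol)
        n_snv = s.unique_prioritized_variants if s else 0
        out[entry.symbol] = GeneEvidence(
            gene_symbol=entry.symbol,
            category=entry.category,
            has_prioritized_snv=n_snv > 0,
            unique_snv_count=n_snv,
            cnv_exclusive=entry.symbol in exclusive,
            cnv_enriched=entry.symbol in enriched,
            previously_reported=prev.get(entry.symbol),
        )
    return out


def high_evidence_set(evidences: Iterable[GeneEvidence]) -> HighEvidenceSet:
    """Partition genes over {C1..C4, none}; disjoint and order-independent."""
    by_criterion: dict[Criterion, list[str]] = {c: [] for c in Criterion}
    criterion_of: dict[str, Criterion] = {}
    for ev in sorted(evidences, key=lambda e: e.gene_symbol):
        if ev.gene_symbol in criterion_of:
            raise ValidationError(f"duplicate evidence for {ev.gene_symbol}")
        c = classify_gene(ev)
        by_criterion[c].append(ev.gene_symbol)
        criterion_of[ev.gene_symbol] = c
    return HighEvidenceSet(by_criterion=by_criterion, criterion_of=criterion_of)


def carrier_rate(n_carriers: int, n_subjects: int) -> float:
    """Carrier percentage, reported to 1 decimal place."""
    if n_subjects <= 0:
        raise ValidationError("carrier_rate: n_subjects must be positive")
    if not 0 <= n_carriers <= n_subjects:
        raise ValidationError("carrier_rate: n_carriers outside [0, n_subjects]")
    return round(100.0 * n_carriers / n_subjects, 1)


def qualifying_variant_keys(prioritized_keys: Iterable[str],
                            variant_gene: Mapping[str, str],
                            panel: Sequence[GenePanelEntry],
                            high_set: HighEvidenceSet,
                            category: PanelCategory = PanelCategory.DET
                            ) -> frozenset[str]:
    """Prioritized variant keys restricted to high-evidence genes of one
    panel category (detoxification enzymes by default)."""
    cat_of = {e.symbol: e.category for e in panel}
    keep = set()
    for key in prioritized_keys:
        gene = variant_gene.get(key)
        if gene is None:
            continue
        if cat_of.get(gene) is category and gene in high_set.genes:
            keep.add(key)
    return frozenset(keep)


def maternal_transmission_fraction(trios: Sequence[TrioRecord],
                                   qualifying_keys: frozenset[str],
                                   cohort_label: str = "") -> TransmissionSummary:
    """Subject-level maternal transmission of qualifying variants.

    A proband is *assessed* iff the mother has genotype data (is present in
    the trio's carried map) and the proband carries at least one qualifying
    key; *maternal* iff the mother carries at least one of those same keys.
    Subjects count once regardless of how many qualifying variants they
    carry.
    """
    n_assessed = n_maternal = 0
    for t in trios:
        proband_keys = t.carried.get(t.proband_id, frozenset()) & qualifying_keys
        if not proband_keys:
            continue
        if t.mother_id is None or t.mother_id not in t.carried:
            continue  # no maternal data: not assessable
        n_assessed += 1
        if proband_keys & t.carried[t.mother_id]:
            n_maternal += 1
    return TransmissionSummary(cohort_label=cohort_label,
                               n_maternal=n_maternal, n_assessed=n_assessed)
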