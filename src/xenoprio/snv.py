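"""Staged prioritization of predicted-damaging SNVs.

The cascade, applied in fixed order to every variant in a panel gene:

1. genotype-level QC (depth, genotype quality, variant missingness) when
   genotype data is supplied; recorded as not-assessed when only AC/AN
   summaries exist,
2. population-frequency ceiling: drop variants common in the reference
   cohort (MAF above ``max_reference_maf``),
3. consequence triage: loss-of-function (frameshift, start/stop loss, stop
   gain, splice donor/acceptor; HIGH impact) or candidate missense
   (MODERATE impact),
4. deleteriousness gate for missense: SIFT deleterious AND PolyPhen-2
   probably/possibly damaging,
5. case enrichment vs the internal control cohort: exclusive to cases, or
   case MAF / control MAF strictly above the enrichment ratio,
6. the same enrichment rule vs the large reference cohort.

A variant passing everything is PRIORITIZED; otherwise it records the first
stage at which it fell out.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import (
    AnnotatedVariant,
    CohortFrequency,
    ConfigurationError,
    ConsequenceClass,
    EnrichmentMode,
    GenePanelEntry,
    Impact,
    PolyphenLabel,
    SiftLabel,
    Stage,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Sequence-Ontology terms counted as loss-of-function (with HIGH impact).
LOF_TERMS = frozenset({
    "frameshift_variant",
    "start_lost",
    "stop_lost",
    "stop_gained",
    "splice_donor_variant",
    "splice_acceptor_variant",
})

#: Terms the triage understands; anything else is excluded with a warning.
KNOWN_TERMS = LOF_TERMS | frozenset({
    "missense_variant", "synonymous_variant", "intron_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant", "upstream_gene_variant",
    "downstream_gene_variant", "intergenic_variant", "splice_region_variant",
    "inframe_insertion", "inframe_deletion", "stop_retained_variant",
    "coding_sequence_variant", "non_coding_transcript_exon_variant",
})


@dataclass(frozen=True)
class QcThresholds:
    """Genotype-level QC.  Genotypes below ``min_depth`` reads or with
    genotype quality below ``min_gq`` (i.e. GQ <= min_gq - 1) are set to
    missing; variants whose missingness then exceeds
    ``max_variant_missingness`` are dropped."""

    min_depth: int = 8
    min_gq: int = 21
    max_variant_missingness: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValidationError("QC thresholds must be non-negative")
        if not 0 <= self.max_variant_missingness <= 1:
            raise ValidationError("max_variant_missingness outside [0, 1]")


@dataclass(frozen=True)
class FrequencyRules:
    """Population-frequency ceiling and case-enrichment ratio."""

    max_reference_maf: float = 0.05
    enrichment_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.max_reference_maf <= 0 or self.enrichment_ratio <= 0:
            raise ValidationError("frequency rules must be strictly positive")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one variant; ``alt_count`` None = missing."""

    sample_id: str
    alt_count: Optional[int]
    dp: int
    gq: int


@dataclass(frozen=True)
class VariantVerdict:
    key: str
    gene_symbol: str
    consequence_class: ConsequenceClass
    stage_reached: Stage
    enrichment_mode: Optional[EnrichmentMode] = None
    qc_assessed: bool = False

    def __post_init__(self) -> None:
        if self.stage_reached is Stage.prioritized:
            assert self.consequence_class is not ConsequenceClass.EXCLUDED
            assert self.enrichment_mode is not None


@dataclass
class GeneSnvSummary:
    gene_symbol: str
    variant_keys: set[str] = field(default_factory=set)
    carrier_subjects: Optional[set[str]] = None
    carrier_estimate: int = 0

    @property
    def unique_prioritized_variants(self) -> int:
        return len(self.variant_keys)


@dataclass
class PrioritizationResult:
    verdicts: list[VariantVerdict]
    summaries: dict[str, GeneSnvSummary]
    stage_counts: Counter
    n_panel_variants: int
    n_off_panel: int

    @property
    def prioritized_keys(self) -> set[str]:
        return {v.key for v in self.verdicts if v.stage_reached is Stage.prioritized}


def classify_consequence(terms: Sequence[str], impact: Impact) -> ConsequenceClass:
    """Triage consequence terms into LOF / MISSENSE_CANDIDATE / EXCLUDED.

    LoF requires a loss-of-function term and HIGH impact; candidate missense
    requires the missense term and MODERATE impact (start-loss is handled on
    the LoF side only, never double-counted).  Unknown terms are logged and
    excluded, never fatal.
    """
    if not terms:
        raise ValidationError("classify_consequence: empty consequence terms")
    unknown = [t for t in terms if t not in KNOWN_TERMS]
    if unknown:
        logger.warning("unknown consequence terms %s; treated as non-qualifying",
                       unknown)
    if impact is Impact.HIGH and any(t in LOF_TERMS for t in terms):
        return ConsequenceClass.LOF
    if impact is Impact.MODERATE and "missense_variant" in terms:
        return ConsequenceClass.MISSENSE_CANDIDATE
    return ConsequenceClass.EXCLUDED


def damaging_missense_filter(sift: Optional[SiftLabel],
                             polyphen: Optional[PolyphenLabel]) -> bool:
    """SIFT deleterious AND PolyPhen-2 probably/possibly damaging.
    A missing or 'unknown' prediction fails (reason: prediction_missing)."""
    if sift is None or polyphen is None or polyphen is PolyphenLabel.unknown:
        return False
    return sift is SiftLabel.deleterious and polyphen in (
        PolyphenLabel.probably_damaging, PolyphenLabel.possibly_damaging
    )


def enrichment_filter(maf_case: CohortFrequency, maf_ctrl: CohortFrequency,
                      rules: FrequencyRules) -> tuple[bool, Optional[EnrichmentMode]]:
    """Case-enrichment rule against one comparison cohort.

    Pass *exclusive* iff the alternate allele is absent from the comparison
    cohort but present in cases; pass *ratio* iff present in both and the
    MAF ratio strictly exceeds ``enrichment_ratio``.  A zero control MAF is
    always routed to the exclusive path (never an infinite ratio).
    """
    if maf_case.an == 0 or maf_ctrl.an == 0:
        raise ValidationError("no_called_alleles: AN = 0 in a compared cohort")
    if maf_ctrl.ac == 0:
        if maf_case.ac > 0:
            return True, EnrichmentMode.exclusive
        return False, None
    if maf_case.maf / maf_ctrl.maf > rules.enrichment_ratio:
        return True, EnrichmentMode.ratio
    return False, None


def apply_genotype_qc(calls: Sequence[GenotypeCall], qc: QcThresholds
                      ) -> tuple[CohortFrequency, float, set[str]]:
    """Mask genotypes failing DP/GQ, then recompute AC/AN, missingness and
    the carrier set from the surviving calls."""
    n = len(calls)
    if n == 0:
        raise ValidationError("genotype QC on empty call set")
    ac = an = missing = 0
    carriers: set[str] = set()
    for c in calls:
        if c.alt_count is None or c.dp < qc.min_depth or c.gq < qc.min_gq:
            missing += 1
            continue
        an += 2
        ac += c.alt_count
        if c.alt_count > 0:
            carriers.add(c.sample_id)
    freq = CohortFrequency("qc", ac, an) if an > 0 else CohortFrequency("qc", 0, 0)
    return freq, missing / n, carriers


def prioritize(variants: Iterable[AnnotatedVariant],
               panel: Sequence[GenePanelEntry],
               qc: QcThresholds | None = None,
               rules: FrequencyRules | None = None,
               case_label: str = "cases",
               internal_label: str = "controls",
               reference_label: str = "reference",
               genotypes: Optional[dict[str, Sequence[GenotypeCall]]] = None,
               reference_rule: str = "same") -> PrioritizationResult:
    """Run the full cascade and aggregate per-gene summaries.

    ``genotypes`` optionally maps variant keys to case-cohort genotype calls;
    when present, QC is applied at genotype level and the case AC/AN are
    recomputed from post-QC genotypes.  ``reference_rule`` is "same"
    (exclusive-or-ratio against the reference cohort, the default) or
    "exclusive_only".
    """
    qc = qc or QcThresholds()
    rules = rules or FrequencyRules()
    if reference_rule not in ("same", "exclusive_only"):
        raise ConfigurationError(f"unknown reference_rule {reference_rule!r}")

    variants = list(variants)
    panel_genes = {e.symbol for e in panel} | {
        a for e in panel for a in e.aliases
    }
    alias_to_symbol = {a: e.symbol for e in panel for a in e.aliases}
    alias_to_symbol.update({e.symbol: e.symbol for e in panel})

    in_panel = [v for v in variants if v.gene_symbol in panel_genes]
    n_off_panel = len(variants) - len(in_panel)
    if in_panel and not any(case_label in v.cohort_counts for v in in_panel):
        raise ConfigurationError(
            f"case cohort label {case_label!r} absent from every variant"
        )
    has_internal = any(internal_label in v.cohort_counts for v in in_panel)
    has_reference = any(reference_label in v.cohort_counts for v in in_panel)

    verdicts: list[VariantVerdict] = []
    summaries: dict[str, GeneSnvSummary] = {}
    for v in in_panel:
        gene = alias_to_symbol[v.gene_symbol]
        verdict = _evaluate(v, gene, qc, rules, case_label, internal_label,
                            reference_label, has_internal, has_reference,
                            genotypes, reference_rule)
        verdicts.append(verdict[0])
        if verdict[0].stage_reached is Stage.prioritized:
            case_freq, carriers = verdict[1], verdict[2]
            s = summaries.setdefault(gene, GeneSnvSummary(gene))
            s.variant_keys.add(verdict[0].key)
            if carriers is not None:
                if s.carrier_subjects is None:
                    s.carrier_subjects = set()
                s.carrier_subjects |= carriers
            # upper-bound carrier estimate from allele counts (het assumption)
            s.carrier_estimate += case_freq.ac

    stage_counts = Counter(v.stage_reached for v in verdicts)
    return PrioritizationResult(
        verdicts=verdicts, summaries=summaries, stage_counts=stage_counts,
        n_panel_variants=len(in_panel), n_off_panel=n_off_panel,
    )


def _evaluate(v: AnnotatedVariant, gene: str, qc: QcThresholds,
              rules: FrequencyRules, case_label: str, internal_label: str,
              reference_label: str, has_internal: bool, has_reference: bool,
              genotypes, reference_rule: str):
    """Evaluate one variant; returns (verdict, case frequency, carriers)."""
    triage = classify_consequence(v.consequence_terms, v.impact)
    gate_ok = (triage is not ConsequenceClass.MISSENSE_CANDIDATE
               or damaging_missense_filter(v.sift, v.polyphen))
    # the verdict reports the *final* class: a missense candidate is only
    # DAMAGING_MISSENSE once the SIFT/PolyPhen-2 gate agrees
    if triage is ConsequenceClass.LOF:
        cls = ConsequenceClass.LOF
    elif triage is ConsequenceClass.MISSENSE_CANDIDATE and gate_ok:
        cls = ConsequenceClass.DAMAGING_MISSENSE
    else:
        cls = ConsequenceClass.EXCLUDED

    case_freq = v.cohort_counts.get(case_label)
    carriers: Optional[set[str]] = None
    qc_assessed = False

    # stage 1: genotype-level QC (recomputes the case AC/AN when available)
    if genotypes is not None and v.key in genotypes:
        qc_assessed = True
        qc_freq, missingness, carriers = apply_genotype_qc(genotypes[v.key], qc)
        if missingness > qc.max_variant_missingness:
            return (VariantVerdict(v.key, gene, cls,
                                   Stage.qc_fail, qc_assessed=True),
                    case_freq, carriers)
        case_freq = qc_freq

    if case_freq is None:
        raise ConfigurationError(
            f"variant {v.key}: no counts for case cohort {case_label!r}"
        )

    def fail(stage: Stage) -> tuple:
        return (VariantVerdict(v.key, gene, cls, stage,
                               qc_assessed=qc_assessed), case_freq, carriers)

    # stage 2: reference-population frequency ceiling
    ref_freq = v.cohort_counts.get(reference_label)
    if ref_freq is not None and ref_freq.an > 0 and \
            ref_freq.maf > rules.max_reference_maf:
        return fail(Stage.common_fail)

    # stage 3: consequence triage
    if triage is ConsequenceClass.EXCLUDED:
        return fail(Stage.impact_fail)

    # stage 4: deleteriousness gate for missense candidates
    if triage is ConsequenceClass.MISSENSE_CANDIDATE and not gate_ok:
        return fail(Stage.prediction_fail)

    modes: list[EnrichmentMode] = []

    # stage 5: enrichment vs internal controls
    int_freq = v.cohort_counts.get(internal_label)
    if int_freq is not None:
        ok, mode = enrichment_filter(case_freq, int_freq, rules)
        if not ok:
            return fail(Stage.internal_enrichment_fail)
        modes.append(mode)

    # stage 6: enrichment vs the reference cohort
    if ref_freq is not None:
        if reference_rule == "exclusive_only":
            if ref_freq.ac > 0:
                return fail(Stage.reference_enrichment_fail)
            modes.append(EnrichmentMode.exclusive)
        else:
            ok, mode = enrichment_filter(case_freq, ref_freq, rules)
            if not ok:
                return fail(Stage.reference_enrichment_fail)
            modes.append(mode)

    # "exclusive to cases" demands absence from every configured comparison
    final_mode = (EnrichmentMode.exclusive
                  if modes and all(m is EnrichmentMode.exclusive for m in modes)
                  else EnrichmentMode.ratio)
    return (VariantVerdict(v.key, gene, cls, Stage.prioritized,
                           enrichment_mode=final_mode, qc_assessed=qc_assessed),
            case_freq, carriers)
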