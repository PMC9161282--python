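"""Gene-level CNV carrier burden in cases vs controls.

A subject is a *carrier* for a gene when at least one of their CNVs (DEL or
DUP, pooled by default) overlaps the gene footprint by >= 1 bp; a subject
counts at most once per gene per cohort.  Genes with carriers in cases but
none in controls are reported on the *exclusivity* path; genes with carriers
on both sides go to a one-tailed two-proportion test (H1: case carrier
proportion higher), with Bonferroni correction over the number of genes
actually tested in that dataset.

The test statistic is the UNPOOLED Wald z,

    z = (p1 - p2) / sqrt( p1 (1-p1) / n1  +  p2 (1-p2) / n2 ),

with the upper-tail standard-normal p-value.  No continuity correction is
applied.  The unpooled variance is deliberate: it is the form consistent
with published per-gene statistics this package reproduces in its tests,
where the pooled form is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree
from scipy.stats import norm

from .types import (
    CnvCall,
    CnvClass,
    ConfigurationError,
    GeneModel,
    GenePanelEntry,
    ValidationError,
)


@dataclass(frozen=True)
class GeneCarrierCount:
    gene_symbol: str
    x_case: int
    n_case: int
    x_ctrl: int
    n_ctrl: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_case <= self.n_case and 0 <= self.x_ctrl <= self.n_ctrl):
            raise ValidationError(
                f"{self.gene_symbol}: carrier count outside [0, cohort size]"
            )

    @property
    def carrier_pct_case(self) -> float:
        return 100.0 * self.x_case / self.n_case

    @property
    def carrier_pct_ctrl(self) -> float:
        return 100.0 * self.x_ctrl / self.n_ctrl


@dataclass
class BurdenTestResult:
    gene_symbol: str
    x_case: int
    n_case: int
    x_ctrl: int
    n_ctrl: int
    z: Optional[float]
    p_raw: Optional[float]
    m: Optional[int] = None
    p_adj: Optional[float] = None
    alpha: float = 0.05
    not_applicable: bool = False

    @property
    def significant(self) -> bool:
        return (not self.not_applicable and self.p_adj is not None
                and self.p_adj < self.alpha)

    @property
    def carrier_pct_case(self) -> float:
        return 100.0 * self.x_case / self.n_case

    @property
    def carrier_pct_ctrl(self) -> float:
        return 100.0 * self.x_ctrl / self.n_ctrl


@dataclass
class ExclusivityResult:
    gene_symbol: str
    #: carrier count and cohort size per case cohort (only cohorts with >= 1)
    case_counts: dict[str, tuple[int, int]]
    n_ctrl: int
    x_ctrl: int = 0


@dataclass
class CohortCnvData:
    """CNV calls plus the subject count of the cohort they came from."""

    label: str
    cnvs: list[CnvCall]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"cohort {self.label}: n_subjects < 1")


@dataclass
class BurdenReport:
    exclusivity: dict[str, list[ExclusivityResult]]  # per case-cohort label
    tests: dict[str, list[BurdenTestResult]]         # per case-cohort label
    m: dict[str, int]                                # genes tested per dataset
    #: genes exclusive in every case cohort / significant in every case cohort
    exclusive_in_all: set[str] = field(default_factory=set)
    significant_in_all: set[str] = field(default_factory=set)


def map_cnvs_to_genes(cnvs: Iterable[CnvCall], genes: Sequence[GeneModel]
                      ) -> dict[str, set[tuple[str, str]]]:
    """Map genes to the (cohort, sample) pairs with >= 1 overlapping CNV.

    Intervals are 0-based half-open; overlap requires >= 1 shared base on the
    same chromosome.  DEL and DUP are not distinguished here — a subject with
    both in one gene is still one carrier.
    """
    dup_check: set[str] = set()
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.symbol in dup_check:
            raise ValidationError(f"duplicate gene model {g.symbol!r}")
        dup_check.add(g.symbol)
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.symbol)

    hits: dict[str, set[tuple[str, str]]] = {}
    for c in cnvs:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(c.start, c.end):
            hits.setdefault(iv.data, set()).add((c.cohort, c.sample_id))
    return hits


def rare_filter(cnvs: Iterable[CnvCall], mode: str = "dataset_freq",
                threshold: float = 0.01, max_common_overlap: float = 0.50,
                common_regions: Optional[Sequence[tuple[str, int, int, float]]] = None
                ) -> list[CnvCall]:
    """Keep rare CNVs.

    ``dataset_freq``: keep calls whose ``dataset_frequency`` is strictly
    below ``threshold`` (missing frequency is an error in this mode).

    ``common_region_overlap``: keep calls whose length-fraction overlapping
    population regions of frequency >= ``threshold`` is <= ``max_common_overlap``;
    ``common_regions`` is a sequence of (chrom, start, end, frequency).
    """
    cnvs = list(cnvs)
    if mode == "dataset_freq":
        for c in cnvs:
            if c.dataset_frequency is None:
                raise ValidationError(
                    f"CNV {c.sample_id} {c.chrom}:{c.start}-{c.end}: "
                    "dataset_frequency required in dataset_freq mode"
                )
        return [c for c in cnvs if c.dataset_frequency < threshold]

    if mode == "common_region_overlap":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, freq in (common_regions or []):
            if freq >= threshold:
                from .types import normalize_chrom
                trees.setdefault(normalize_chrom(chrom), IntervalTree()
                                 ).addi(start, end)
        kept = []
        for c in cnvs:
            tree = trees.get(c.chrom)
            if tree is None:
                kept.append(c)
                continue
            merged = IntervalTree(tree.overlap(c.start, c.end))
            merged.merge_overlaps()
            covered = sum(min(iv.end, c.end) - max(iv.begin, c.start)
                          for iv in merged)
            if covered / (c.end - c.start) <= max_common_overlap:
                kept.append(c)
        return kept

    raise ConfigurationError(f"unknown rarity mode {mode!r}")


def two_proportion_one_tailed(x_case: int, n_case: int, x_ctrl: int, n_ctrl: int
                              ) -> BurdenTestResult:
    """Unpooled one-tailed two-proportion z test (H1: p_case > p_ctrl).

    ``x_case = 0`` yields a not-applicable result rather than a statistic;
    genes with ``x_ctrl = 0`` belong on the exclusivity path and are
    rejected here.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValidationError("two_proportion_one_tailed: empty cohort")
    if x_ctrl < 0 or x_case < 0 or x_case > n_case or x_ctrl > n_ctrl:
        raise ValidationError("two_proportion_one_tailed: counts out of range")
    if x_case == 0:
        return BurdenTestResult("", x_case, n_case, x_ctrl, n_ctrl,
                                z=None, p_raw=None, not_applicable=True)
    if x_ctrl == 0:
        raise ValidationError(
            "x_ctrl = 0: gene belongs on the exclusivity path, not the test"
        )
    p1, p2 = x_case / n_case, x_ctrl / n_ctrl
    se = math.sqrt(p1 * (1 - p1) / n_case + p2 * (1 - p2) / n_ctrl)
    z = (p1 - p2) / se
    return BurdenTestResult("", x_case, n_case, x_ctrl, n_ctrl,
                            z=z, p_raw=float(norm.sf(z)))


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """p_adj = min(1, m * p_raw); m = genes actually tested in the dataset."""
    if m < 1:
        raise ValidationError(f"bonferroni_adjust: m = {m} < 1")
    return min(1.0, m * p_raw)


def run_burden(case_cohorts: Sequence[CohortCnvData], control: CohortCnvData,
               genes: Sequence[GeneModel], panel: Sequence[GenePanelEntry],
               alpha: float = 0.05) -> BurdenReport:
    """Carrier counting, exclusivity detection and burden testing.

    Each case cohort is analyzed separately against the shared control
    cohort; `m` for the Bonferroni correction is the number of genes tested
    in that dataset (carriers in both cases and controls).  Cross-cohort
    intersections (exclusive in all case cohorts, significant in all) are
    reported alongside.
    """
    if not case_cohorts:
        raise ConfigurationError("run_burden: no case cohorts")
    if not control.cnvs and control.n_subjects < 1:
        raise ConfigurationError("run_burden: empty control cohort")
    panel_symbols = {e.symbol for e in panel}
    panel_genes = [g for g in genes if g.symbol in panel_symbols]

    all_cnvs = list(control.cnvs)
    for cc in case_cohorts:
        all_cnvs.extend(cc.cnvs)
    gene_hits = map_cnvs_to_genes(all_cnvs, panel_genes)

    def carriers(gene: str, cohort: str) -> int:
        return sum(1 for (coh, _s) in gene_hits.get(gene, ()) if coh == cohort)

    report = BurdenReport(exclusivity={}, tests={}, m={})
    for cc in case_cohorts:
        excl: list[ExclusivityResult] = []
        tests: list[BurdenTestResult] = []
        for gene in sorted(gene_hits):
            x_case = carriers(gene, cc.label)
            x_ctrl = carriers(gene, control.label)
            if x_case == 0 and x_ctrl == 0:
                continue
            if x_ctrl == 0:
                excl.append(ExclusivityResult(
                    gene_symbol=gene,
                    case_counts={cc.label: (x_case, cc.n_subjects)},
                    n_ctrl=control.n_subjects,
                ))
                continue
            if x_case == 0:
                continue  # control-only gene: neither list for this cohort
            res = two_proportion_one_tailed(x_case, cc.n_subjects,
                                            x_ctrl, control.n_subjects)
            res.gene_symbol = gene
            res.alpha = alpha
            tests.append(res)
        m = len(tests)
        for res in tests:
            res.m = m
            res.p_adj = bonferroni_adjust(res.p_raw, m)
        report.exclusivity[cc.label] = [e for e in excl
                                        if e.case_counts[cc.label][0] >= 1]
        report.tests[cc.label] = tests
        report.m[cc.label] = m

    excl_sets = [
        {e.gene_symbol for e in report.exclusivity[cc.label]} for cc in case_cohorts
    ]
    sig_sets = [
        {t.gene_symbol for t in report.tests[cc.label] if t.significant}
        for cc in case_cohorts
    ]
    report.exclusive_in_all = set.intersection(*excl_sets) if excl_sets else set()
    report.significant_in_all = set.intersection(*sig_sets) if sig_sets else set()
    return report
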