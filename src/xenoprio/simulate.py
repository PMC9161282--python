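"""Seeded generator of complete toy cohort studies with planted truth.

The generator emulates the statistical structure the analysis assumes —
rare variants with binomially drawn allele counts, per-subject Bernoulli
CNV carriage, trio transmission at a set maternal rate, and a curated-style
interaction database with planted gene degrees — at a scale that runs the
full pipeline in seconds.  It makes no attempt at linkage structure,
realistic site-frequency spectra, or genome-scale coordinates.

Every draw comes from one ``numpy`` Generator seeded from the config, so a
given seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as xio
from .cnv import CohortCnvData
from .evidence import HIGH_EVIDENCE_MIN_SNVS
from .snv import GenotypeCall
from .types import (
    AnnotatedVariant,
    ChemicalEntry,
    CnvCall,
    CnvClass,
    CohortFrequency,
    Criterion,
    GeneModel,
    GenePanelEntry,
    Impact,
    InteractionRecord,
    PanelCategory,
    PolyphenLabel,
    SiftLabel,
    TrioRecord,
    ValidationError,
    CHEMICAL_GROUPS,
)


@dataclass(frozen=True)
class PlantedSnvGene:
    """A gene seeded with unique predicted-damaging SNVs at the given case
    and comparison-cohort MAFs (0 for exclusivity)."""

    gene: str
    n_unique: int
    case_maf: float
    control_maf: float = 0.0
    reference_maf: Optional[float] = None  # defaults to control_maf

    @property
    def ref_maf(self) -> float:
        return self.control_maf if self.reference_maf is None else self.reference_maf


@dataclass(frozen=True)
class PlantedCnvGene:
    """A gene seeded with CNV carriers at per-subject Bernoulli rates;
    ``ctrl_prob = 0`` plants case-exclusivity."""

    gene: str
    case_prob: float
    ctrl_prob: float = 0.0


@dataclass
class SimulationConfig:
    seed: int = 0
    # SNV cohort sizes (subjects; allele totals are 2n)
    n_case: int = 500
    n_internal_ctrl: int = 500
    n_reference: int = 5000
    # CNV cohort sizes
    n_cnv_case: int = 500
    n_cnv_ctrl: int = 2000
    # panel: genes per category
    panel_spec: Mapping[str, int] = field(
        default_factory=lambda: {"DET": 8, "BBB": 5, "PLC": 4, "RC": 3})
    # background structure per gene
    baseline_benign_variants: int = 2
    baseline_null_damaging_variants: int = 1
    baseline_maf: float = 0.02
    planted_snv: Sequence[PlantedSnvGene] = ()
    planted_cnv: Sequence[PlantedCnvGene] = ()
    cnv_dataset_freq: float = 0.005
    #: a gene carrying CNVs at equal rates in both cohorts but with a common
    #: dataset frequency, so the rarity filter removes it
    common_cnv_gene: Optional[str] = None
    common_cnv_prob: float = 0.02
    common_cnv_freq: float = 0.05
    # trios
    n_trios: int = 200
    maternal_transmission_prob: float = 0.5
    mother_data_prob: float = 0.9
    # interaction database
    planted_degrees: Mapping[str, int] = field(default_factory=dict)
    n_whitelist_chemicals: int = 14
    decoy_records: int = 10
    # genotype-level output
    emit_genotypes: bool = True
    genotype_missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in self.planted_snv:
            for maf in (p.case_maf, p.control_maf, p.ref_maf):
                if not 0 <= maf <= 0.5:
                    raise ValidationError(
                        f"planted MAF {maf} for {p.gene} outside [0, 0.5]")
        for p in self.planted_cnv:
            if not (0 <= p.case_prob <= 1 and 0 <= p.ctrl_prob <= 1):
                raise ValidationError(f"planted CNV prob for {p.gene} outside [0,1]")
        for n in (self.n_case, self.n_internal_ctrl, self.n_reference,
                  self.n_cnv_case, self.n_cnv_ctrl):
            if n < 1:
                raise ValidationError("cohort sizes must be >= 1")


@dataclass
class PlantedTruth:
    criterion_of: dict[str, Criterion]
    snv_genes: dict[str, int]          # gene -> planted unique damaging SNVs
    cnv_exclusive: set[str]
    cnv_enriched: set[str]
    degrees: dict[str, int]            # planted per-gene chemical degree
    maternal_prob: float


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    panel: list[GenePanelEntry]
    gene_models: list[GeneModel]
    variants: list[AnnotatedVariant]
    genotypes: Optional[dict[str, list[GenotypeCall]]]
    cnv_cases: CohortCnvData
    cnv_controls: CohortCnvData
    trios: list[TrioRecord]
    records: list[InteractionRecord]
    whitelist: list[ChemicalEntry]
    truth: PlantedTruth


def default_config(seed: int = 0) -> SimulationConfig:
    """The default strong-effect design: one gene per evidence route
    (plus a second C2 and C4 gene), planted effects far above threshold.

    Background variants are benign-only so the planted criterion of every
    gene is a deterministic function of the config: an equal-frequency
    *damaging* background variant would cross the case-enrichment rule at
    its inherent false-positive rate (roughly 1% per variant at these
    cohort sizes) and spuriously promote a CNV-only gene to the SNV+CNV
    class.  Designs that want that background noise set
    ``baseline_null_damaging_variants`` explicitly.
    """
    return SimulationConfig(
        seed=seed,
        baseline_null_damaging_variants=0,
        planted_snv=(
            PlantedSnvGene("D01", 2, 0.01, 0.0),   # C1 with the CNV below
            PlantedSnvGene("D02", 6, 0.01, 0.0),   # C2
            PlantedSnvGene("B01", 5, 0.01, 0.0),   # C2
            PlantedSnvGene("D04", 2, 0.01, 0.0),   # below the >=5 rule: none
        ),
        planted_cnv=(
            PlantedCnvGene("D01", 0.02, 0.0),      # exclusive -> C1
            PlantedCnvGene("P01", 0.02, 0.0),      # C3
            PlantedCnvGene("R01", 0.02, 0.0),      # C3
            PlantedCnvGene("D03", 0.10, 0.01),     # C4
            PlantedCnvGene("B02", 0.10, 0.01),     # C4
        ),
        common_cnv_gene="D08",
        planted_degrees={"D01": 5, "D02": 3, "B01": 2, "P01": 1, "D03": 1},
    )


def make_panel(spec: Mapping[str, int]) -> tuple[list[GenePanelEntry], list[GeneModel]]:
    """Deterministic panel and gene models; genes are 50 kb, 100 kb apart,
    round-robined over four chromosomes."""
    subcat = {"DET": "CYPs", "BBB": "SLCs", "PLC": "hormones", "RC": "dyneins"}
    panel, models = [], []
    i = 0
    for cat, n in spec.items():
        for j in range(1, n + 1):
            sym = f"{cat[0]}{j:02d}"
            panel.append(GenePanelEntry(symbol=sym,
                                        category=PanelCategory(cat),
                                        subcategory=subcat[cat]))
            chrom = str(i % 4 + 1)
            start = 100_000 + (i // 4) * 100_000
            models.append(GeneModel(symbol=sym, chrom=chrom,
                                    start=start, end=start + 50_000))
            i += 1
    return panel, models


def expected_truth(config: SimulationConfig) -> PlantedTruth:
    """The criterion each planted gene should reach, derived from the config
    alone (the same classification rules applied to the planted design)."""
    panel, _ = make_panel(config.panel_spec)
    snv_genes = {p.gene: p.n_unique for p in config.planted_snv}
    exclusive = {p.gene for p in config.planted_cnv if p.ctrl_prob == 0}
    enriched = {p.gene for p in config.planted_cnv
                if p.ctrl_prob > 0 and p.case_prob > p.ctrl_prob}
    criterion_of = {}
    for e in panel:
        g = e.symbol
        n_snv = snv_genes.get(g, 0)
        cnv_any = g in exclusive or g in enriched
        if n_snv > 0 and cnv_any:
            c = Criterion.C1_snv_and_cnv
        elif n_snv >= HIGH_EVIDENCE_MIN_SNVS:
            c = Criterion.C2_five_plus_snv
        elif g in exclusive:
            c = Criterion.C3_cnv_exclusive
        elif g in enriched:
            c = Criterion.C4_cnv_enriched
        else:
            c = Criterion.none
        criterion_of[g] = c
    return PlantedTruth(
        criterion_of=criterion_of, snv_genes=snv_genes,
        cnv_exclusive=exclusive, cnv_enriched=enriched,
        degrees=dict(config.planted_degrees),
        maternal_prob=config.maternal_transmission_prob,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    rng = np.random.default_rng(config.seed)
    panel, models = make_panel(config.panel_spec)
    by_symbol = {m.symbol: m for m in models}
    truth = expected_truth(config)

    variants, genotypes, planted_keys = _simulate_variants(
        config, panel, by_symbol, rng)
    cnv_cases, cnv_controls = _simulate_cnvs(config, by_symbol, rng)
    trios = _simulate_trios(config, panel, truth, planted_keys, rng)
    whitelist = _make_whitelist(config.n_whitelist_chemicals)
    records = _simulate_interactions(config, panel, whitelist, rng)

    return SimulatedStudy(
        config=config, panel=panel, gene_models=models, variants=variants,
        genotypes=genotypes if config.emit_genotypes else None,
        cnv_cases=cnv_cases, cnv_controls=cnv_controls, trios=trios,
        records=records, whitelist=whitelist, truth=truth,
    )


def _simulate_variants(config, panel, by_symbol, rng):
    planted = {p.gene: p for p in config.planted_snv}
    variants: list[AnnotatedVariant] = []
    genotypes: dict[str, list[GenotypeCall]] = {}
    planted_keys: dict[str, list[str]] = {}  # gene -> planted damaging keys
    an_case = 2 * config.n_case
    an_ctrl = 2 * config.n_internal_ctrl
    an_ref = 2 * config.n_reference

    def counts(case_maf, ctrl_maf, ref_maf):
        return {
            "cases": CohortFrequency("cases",
                                     int(rng.binomial(an_case, case_maf)), an_case),
            "controls": CohortFrequency("controls",
                                        int(rng.binomial(an_ctrl, ctrl_maf)), an_ctrl),
            "reference": CohortFrequency("reference",
                                         int(rng.binomial(an_ref, ref_maf)), an_ref),
        }

    for e in panel:
        model = by_symbol[e.symbol]
        pos = model.start + 1  # 1-based inside the gene
        # background: benign variants, then equal-frequency damaging variants
        for b in range(config.baseline_benign_variants):
            pos += 97
            variants.append(AnnotatedVariant(
                chrom=model.chrom, pos=pos, ref="C", alt="T",
                gene_symbol=e.symbol,
                consequence_terms=("synonymous_variant",), impact=Impact.LOW,
                cohort_counts=counts(config.baseline_maf, config.baseline_maf,
                                     config.baseline_maf),
            ))
        for b in range(config.baseline_null_damaging_variants):
            pos += 97
            variants.append(AnnotatedVariant(
                chrom=model.chrom, pos=pos, ref="G", alt="A",
                gene_symbol=e.symbol,
                consequence_terms=("missense_variant",), impact=Impact.MODERATE,
                sift=SiftLabel.deleterious, sift_score=0.01,
                polyphen=PolyphenLabel.probably_damaging, polyphen_score=0.97,
                cohort_counts=counts(config.baseline_maf, config.baseline_maf,
                                     config.baseline_maf),
            ))
        # planted damaging variants: alternate missense and LoF annotations
        spec = planted.get(e.symbol)
        if spec is not None:
            for k in range(spec.n_unique):
                pos += 211
                lof = k % 3 == 2
                variants.append(AnnotatedVariant(
                    chrom=model.chrom, pos=pos, ref="A", alt="G",
                    gene_symbol=e.symbol,
                    consequence_terms=("stop_gained",) if lof
                    else ("missense_variant",),
                    impact=Impact.HIGH if lof else Impact.MODERATE,
                    sift=None if lof else SiftLabel.deleterious,
                    sift_score=None if lof else 0.0,
                    polyphen=None if lof else PolyphenLabel.probably_damaging,
                    polyphen_score=None if lof else 0.99,
                    cohort_counts=counts(spec.case_maf, spec.control_maf,
                                         spec.ref_maf),
                ))
                planted_keys.setdefault(e.symbol, []).append(variants[-1].key)

    if config.emit_genotypes:
        samples = [f"S{i:05d}" for i in range(config.n_case)]
        for v in variants:
            ac = v.cohort_counts["cases"].ac
            calls = []
            # distribute alt alleles as heterozygous carriers (hom if ac > n)
            carrier_idx = rng.choice(config.n_case,
                                     size=min(ac, config.n_case), replace=False)
            alt_of = {int(i): 1 for i in carrier_idx}
            for extra in range(max(0, ac - config.n_case)):
                alt_of[int(carrier_idx[extra % len(carrier_idx)])] = 2
            for i, sid in enumerate(samples):
                lowq = rng.random() < config.genotype_missing_rate
                calls.append(GenotypeCall(
                    sample_id=sid, alt_count=alt_of.get(i, 0),
                    dp=int(rng.integers(2, 7)) if lowq else int(rng.integers(20, 60)),
                    gq=int(rng.integers(0, 20)) if lowq else int(rng.integers(40, 99)),
                ))
            genotypes[v.key] = calls
    return variants, genotypes, planted_keys


def _simulate_cnvs(config, by_symbol, rng):
    planted = {p.gene: p for p in config.planted_cnv}

    def draw(cohort_label, n_subjects, prob_of):
        calls = []
        for gene, prob in prob_of.items():
            if prob == 0:
                continue
            model = by_symbol[gene]
            carriers = np.flatnonzero(rng.random(n_subjects) < prob)
            for i in carriers:
                klass = CnvClass.DEL if rng.random() < 0.5 else CnvClass.DUP
                freq = (config.common_cnv_freq
                        if gene == config.common_cnv_gene
                        else config.cnv_dataset_freq)
                calls.append(CnvCall(
                    sample_id=f"{cohort_label}_{i:05d}", cohort=cohort_label,
                    chrom=model.chrom,
                    start=model.start - 1_000, end=model.end + 1_000,
                    cnv_class=klass, dataset_frequency=freq,
                ))
        return calls

    case_probs = {p.gene: p.case_prob for p in planted.values()}
    ctrl_probs = {p.gene: p.ctrl_prob for p in planted.values()}
    if config.common_cnv_gene is not None:
        case_probs[config.common_cnv_gene] = config.common_cnv_prob
        ctrl_probs[config.common_cnv_gene] = config.common_cnv_prob

    cases = CohortCnvData("cnv_cases",
                          draw("cnv_cases", config.n_cnv_case, case_probs),
                          config.n_cnv_case)
    controls = CohortCnvData("cnv_controls",
                             draw("cnv_controls", config.n_cnv_ctrl, ctrl_probs),
                             config.n_cnv_ctrl)
    return cases, controls


def _simulate_trios(config, panel, truth, planted_keys, rng):
    """Trios whose probands carry one qualifying variant (a planted damaging
    SNV in a detoxification-category high-evidence gene); the mother carries
    it with the configured transmission probability."""
    cat_of = {e.symbol: e.category for e in panel}
    qualifying = [
        key for gene, keys in sorted(planted_keys.items())
        if cat_of[gene] is PanelCategory.DET
        and truth.criterion_of[gene] in
        (Criterion.C1_snv_and_cnv, Criterion.C2_five_plus_snv)
        for key in keys
    ]
    trios = []
    for i in range(config.n_trios):
        pid, mid, fid = f"P{i:04d}", f"M{i:04d}", f"F{i:04d}"
        key = qualifying[int(rng.integers(len(qualifying)))] if qualifying else None
        carried = {pid: frozenset([key] if key else [])}
        mother_known = rng.random() < config.mother_data_prob
        if mother_known:
            maternal = key is not None and \
                rng.random() < config.maternal_transmission_prob
            carried[mid] = frozenset([key]) if maternal else frozenset()
        carried[fid] = frozenset()
        trios.append(TrioRecord(
            proband_id=pid, mother_id=mid if mother_known else None,
            father_id=fid, family_id=f"FAM{i:04d}", carried=carried,
        ))
    return trios


def _make_whitelist(n: int) -> list[ChemicalEntry]:
    return [
        ChemicalEntry(name=f"chem{i:02d}", mesh_id=f"M{i:03d}",
                      group=CHEMICAL_GROUPS[i % len(CHEMICAL_GROUPS)])
        for i in range(n)
    ]


def _simulate_interactions(config, panel, whitelist, rng):
    """Curated-style records with planted per-gene degrees, plus decoys in
    the wrong organism or off the whitelist that the filter must drop."""
    records: list[InteractionRecord] = []
    pmid_counter = 10_000_000
    for e in panel:
        degree = config.planted_degrees.get(e.symbol, 0)
        if degree > len(whitelist):
            raise ValidationError(
                f"planted degree {degree} for {e.symbol} exceeds whitelist size")
        chosen = rng.choice(len(whitelist), size=degree, replace=False)
        for ci in sorted(int(c) for c in chosen):
            chem = whitelist[ci]
            for _rep in range(1 + int(rng.poisson(1))):
                n_pmids = 1 + int(rng.poisson(2))
                pmids = frozenset(str(pmid_counter + k) for k in range(n_pmids))
                pmid_counter += n_pmids
                records.append(InteractionRecord(
                    gene_symbol=e.symbol, chemical_name=chem.name,
                    chemical_mesh_id=chem.mesh_id, organism="Homo sapiens",
                    pmids=pmids, action="affects expression",
                ))
    genes = [e.symbol for e in panel]
    for d in range(config.decoy_records):
        gene = genes[int(rng.integers(len(genes)))]
        if d % 2 == 0:  # wrong organism, whitelisted chemical
            chem = whitelist[int(rng.integers(len(whitelist)))]
            records.append(InteractionRecord(
                gene_symbol=gene, chemical_name=chem.name,
                chemical_mesh_id=chem.mesh_id, organism="Mus musculus",
                pmids=frozenset({str(pmid_counter + d)}),
            ))
        else:  # human record, chemical off the whitelist
            records.append(InteractionRecord(
                gene_symbol=gene, chemical_name="offlist",
                chemical_mesh_id=f"X{d:03d}", organism="Homo sapiens",
                pmids=frozenset({str(pmid_counter + d)}),
            ))
    return records


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Materialize the study as the flat-file dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}" for k in (
        "panel.tsv", "gene_models.tsv", "variants.tsv", "variants.vcf",
        "genotypes.tsv", "cnv_cases.tsv", "cnv_controls.tsv", "trios.ped",
        "carriage.tsv", "ctd.tsv", "chemicals.tsv", "truth.json")}
    xio.write_panel(study.panel, paths["panel.tsv"])
    xio.write_gene_models(study.gene_models, paths["gene_models.tsv"])
    xio.write_variant_table(study.variants, paths["variants.tsv"])
    xio.write_variants_vcf(study.variants, paths["variants.vcf"])
    if study.genotypes is not None:
        xio.write_genotypes(study.genotypes, paths["genotypes.tsv"])
    xio.write_cnv_table(study.cnv_cases.cnvs, paths["cnv_cases.tsv"])
    xio.write_cnv_table(study.cnv_controls.cnvs, paths["cnv_controls.tsv"])
    xio.write_ped(study.trios, paths["trios.ped"])
    carriage: dict[str, frozenset[str]] = {}
    for t in study.trios:
        carriage.update(t.carried)
    xio.write_carriage(carriage, paths["carriage.tsv"])
    xio.write_ctd_tsv(study.records, paths["ctd.tsv"])
    xio.write_chemicals(study.whitelist, paths["chemicals.tsv"])
    with open(paths["truth.json"], "w", encoding="utf-8") as fh:
        json.dump({
            "criterion_of": {g: c.value for g, c in study.truth.criterion_of.items()},
            "snv_genes": study.truth.snv_genes,
            "cnv_exclusive": sorted(study.truth.cnv_exclusive),
            "cnv_enriched": sorted(study.truth.cnv_enriched),
            "degrees": study.truth.degrees,
            "maternal_prob": study.truth.maternal_prob,
        }, fh, indent=1, sort_keys=True)
    return paths


@dataclass
class RecoveryReport:
    per_criterion: dict[Criterion, dict[str, int]]  # tp / fn per planted class
    sensitivity: dict[Criterion, Optional[float]]
    specificity: Optional[float]
    false_positives: list[str]

    def min_sensitivity(self) -> Optional[float]:
        vals = [s for s in self.sensitivity.values() if s is not None]
        return min(vals) if vals else None


def evaluate_recovery(predicted: Mapping[str, Criterion],
                      truth: PlantedTruth) -> RecoveryReport:
    """Per-criterion confusion counts of the pipeline against planted truth.

    Sensitivity for a criterion is the fraction of its planted genes
    predicted exactly right (None when nothing was planted for it);
    specificity is computed over planted-null genes and None (flagged) when
    the truth contains no null genes.
    """
    if set(predicted) != set(truth.criterion_of):
        raise ValidationError("truth/prediction gene universes differ")
    per: dict[Criterion, dict[str, int]] = {
        c: {"tp": 0, "fn": 0} for c in Criterion if c is not Criterion.none}
    tn = fp = 0
    false_positives = []
    for gene, c_true in truth.criterion_of.items():
        c_pred = predicted[gene]
        if c_true is Criterion.none:
            if c_pred is Criterion.none:
                tn += 1
            else:
                fp += 1
                false_positives.append(gene)
        else:
            per[c_true]["tp" if c_pred is c_true else "fn"] += 1
    sens = {
        c: (d["tp"] / (d["tp"] + d["fn"]) if d["tp"] + d["fn"] else None)
        for c, d in per.items()
    }
    spec = tn / (tn + fp) if tn + fp else None
    return RecoveryReport(per_criterion=per, sensitivity=sens,
                          specificity=spec, false_positives=sorted(false_positives))
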