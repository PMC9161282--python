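"""Orchestrate the full analysis from files to tables and a run summary.

Stages run in a fixed order — SNV prioritization, CNV burden, evidence
classification, trio transmission, interaction mapping — each a pure
function of its inputs and the configuration.  The JSON run summary records
input file hashes, parameter values and every headline count, so a run can
be reproduced and reconciled record-for-record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as xio
from .cnv import CohortCnvData, rare_filter, run_burden
from .evidence import (
    build_evidence,
    carrier_rate,
    high_evidence_set,
    maternal_transmission_fraction,
    qualifying_variant_keys,
)
from .interactions import (
    build_pairs,
    degree_ordered_axes,
    degrees,
    filter_records,
    group_rollup,
    matrix,
    pct_chemicals_with_pairs,
    write_degrees,
    write_pairs,
)
from .snv import FrequencyRules, QcThresholds, prioritize
from .types import ConfigurationError, Criterion, Stage

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    panel: str
    gene_models: str
    variants: str
    outdir: str
    variant_dialect: str = "flat_tsv"
    genotypes: Optional[str] = None
    cnv_cases: dict[str, str] = field(default_factory=dict)   # label -> path
    cnv_case_sizes: dict[str, int] = field(default_factory=dict)
    cnv_controls: Optional[str] = None
    cnv_control_size: int = 0
    ped: Optional[str] = None
    carriage: Optional[str] = None
    ctd: Optional[str] = None
    chemicals: Optional[str] = None
    case_label: str = "cases"
    internal_label: str = "controls"
    reference_label: str = "reference"
    qc: QcThresholds = field(default_factory=QcThresholds)
    rules: FrequencyRules = field(default_factory=FrequencyRules)
    reference_rule: str = "same"
    rarity_mode: str = "dataset_freq"
    rarity_threshold: float = 0.01
    max_common_overlap: float = 0.50
    alpha: float = 0.05
    organism: str = "Homo sapiens"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcThresholds(**raw.pop("qc", {}))
        rules = FrequencyRules(**raw.pop("rules", {}))
        return cls(qc=qc, rules=rules, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the output tables plus summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "qc": vars(config.qc), "rules": vars(config.rules),
        "reference_rule": config.reference_rule,
        "rarity_mode": config.rarity_mode,
        "rarity_threshold": config.rarity_threshold,
        "alpha": config.alpha, "seed": config.seed,
    }, "input_hashes": {}}
    for name in ("panel", "gene_models", "variants", "genotypes", "cnv_controls",
                 "ped", "carriage", "ctd", "chemicals"):
        p = getattr(config, name)
        if p:
            summary["input_hashes"][name] = _sha256(p)
    for label, p in config.cnv_cases.items():
        summary["input_hashes"][f"cnv_cases:{label}"] = _sha256(p)

    # ------------------------------------------------------------------ SNV
    stage = "snv_prioritizer"
    try:
        panel = xio.read_panel(config.panel)
        models = xio.read_gene_models(config.gene_models)
        variants = xio.read_variant_table(config.variants, config.variant_dialect)
        genotypes = (xio.read_genotypes(config.genotypes)
                     if config.genotypes else None)
        prio = prioritize(
            variants, panel, qc=config.qc, rules=config.rules,
            case_label=config.case_label, internal_label=config.internal_label,
            reference_label=config.reference_label, genotypes=genotypes,
            reference_rule=config.reference_rule,
        )
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    pd.DataFrame(
        [(v.key, v.gene_symbol, v.consequence_class.value,
          v.stage_reached.value,
          v.enrichment_mode.value if v.enrichment_mode else "",
          v.qc_assessed)
         for v in prio.verdicts],
        columns=["variant_key", "gene", "consequence_class", "stage",
                 "enrichment_mode", "qc_assessed"],
    ).to_csv(outdir / "variant_verdicts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, s.unique_prioritized_variants,
          len(s.carrier_subjects) if s.carrier_subjects is not None else "",
          s.carrier_estimate)
         for g, s in sorted(prio.summaries.items())],
        columns=["gene", "unique_prioritized_variants", "carrier_subjects",
                 "carrier_estimate"],
    ).to_csv(outdir / "gene_snv_summary.tsv", sep="\t", index=False)

    summary["snv"] = {
        "n_input_variants": prio.n_panel_variants + prio.n_off_panel,
        "n_panel_variants": prio.n_panel_variants,
        "n_off_panel": prio.n_off_panel,
        "stage_counts": {s.value: prio.stage_counts.get(s, 0) for s in Stage},
        "n_prioritized": len(prio.prioritized_keys),
        "n_genes_with_prioritized_snv": len(prio.summaries),
    }
    # record-count reconciliation is a hard invariant, not just a log line
    assert sum(prio.stage_counts.values()) == prio.n_panel_variants

    # ------------------------------------------------------------------ CNV
    burden = None
    if config.cnv_cases and config.cnv_controls:
        stage = "cnv_burden"
        try:
            case_data = []
            for label, path in config.cnv_cases.items():
                calls = rare_filter(
                    xio.read_cnv_table(path, cohort=label),
                    mode=config.rarity_mode, threshold=config.rarity_threshold,
                    max_common_overlap=config.max_common_overlap)
                n = config.cnv_case_sizes.get(label)
                if not n:
                    raise ConfigurationError(
                        f"cnv_case_sizes missing for cohort {label!r}")
                case_data.append(CohortCnvData(label, calls, n))
            ctrl_calls = rare_filter(
                xio.read_cnv_table(config.cnv_controls, cohort="cnv_controls"),
                mode=config.rarity_mode, threshold=config.rarity_threshold,
                max_common_overlap=config.max_common_overlap)
            control = CohortCnvData("cnv_controls", ctrl_calls,
                                    config.cnv_control_size)
            burden = run_burden(case_data, control, models, panel,
                                alpha=config.alpha)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        excl_rows, test_rows = [], []
        for label, excl in burden.exclusivity.items():
            for e in excl:
                x, n = e.case_counts[label]
                excl_rows.append((label, e.gene_symbol, x, n,
                                  round(100.0 * x / n, 3)))
        for label, tests in burden.tests.items():
            for t in tests:
                test_rows.append((label, t.gene_symbol, t.x_case, t.n_case,
                                  round(t.carrier_pct_case, 3),
                                  round(t.z, 2), t.p_raw, t.p_adj, t.m,
                                  t.significant, t.x_ctrl, t.n_ctrl,
                                  round(t.carrier_pct_ctrl, 3)))
        pd.DataFrame(excl_rows, columns=[
            "cohort", "gene", "n_carriers", "n_subjects", "carrier_pct",
        ]).to_csv(outdir / "cnv_exclusive.tsv", sep="\t", index=False)
        pd.DataFrame(test_rows, columns=[
            "cohort", "gene", "x_case", "n_case", "carrier_pct_case", "z",
            "p_raw", "p_adj", "m", "significant", "x_ctrl", "n_ctrl",
            "carrier_pct_ctrl",
        ]).to_csv(outdir / "cnv_burden.tsv", sep="\t", index=False)
        summary["cnv"] = {
            "m": burden.m,
            "n_exclusive": {k: len(v) for k, v in burden.exclusivity.items()},
            "n_significant": {
                k: sum(t.significant for t in v) for k, v in burden.tests.items()},
            "exclusive_in_all": sorted(burden.exclusive_in_all),
            "significant_in_all": sorted(burden.significant_in_all),
        }

    # ------------------------------------------------------- classification
    stage = "evidence_classifier"
    try:
        evidence = build_evidence(panel, prio.summaries, burden)
        high = high_evidence_set(evidence.values())
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    cat_of = {e.symbol: e.category.value for e in panel}
    pd.DataFrame(
        [(high.criterion_of[g].value, cat_of[g], g)
         for c in Criterion for g in high.by_criterion[c]
         if c is not Criterion.none],
        columns=["criterion", "category", "gene"],
    ).to_csv(outdir / "high_evidence.tsv", sep="\t", index=False)
    summary["evidence"] = {
        "criterion_counts": high.counts(),
        "total_high_evidence": high.total,
        "criterion_of": {g: c.value for g, c in sorted(high.criterion_of.items())},
    }
    case_carriers = set()
    for g in high.genes:
        s = prio.summaries.get(g)
        if s is not None and s.carrier_subjects is not None:
            case_carriers |= s.carrier_subjects
    if genotypes is not None:
        n_case_subjects = max(
            (len(calls) for calls in genotypes.values()), default=0)
        if n_case_subjects:
            summary["evidence"]["snv_carrier_rate_pct"] = carrier_rate(
                len(case_carriers), n_case_subjects)

    # --------------------------------------------------------- transmission
    if config.ped and config.carriage:
        stage = "transmission"
        try:
            trios = xio.attach_carriage(xio.read_ped(config.ped),
                                        xio.read_carriage(config.carriage))
            qual = qualifying_variant_keys(
                prio.prioritized_keys,
                {v.key: v.gene_symbol for v in prio.verdicts}, panel, high)
            tx = maternal_transmission_fraction(trios, qual, config.case_label)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        summary["transmission"] = {
            "n_maternal": tx.n_maternal, "n_assessed": tx.n_assessed,
            "fraction_pct": (round(tx.fraction, 1)
                             if tx.fraction is not None else None),
        }

    # ----------------------------------------------------------- interactions
    if config.ctd and config.chemicals:
        stage = "interaction_mapper"
        try:
            whitelist = xio.read_chemicals(config.chemicals)
            records = xio.read_ctd_tsv(config.ctd)
            kept = filter_records(records, whitelist, organism=config.organism)
            kept = [r for r in kept if r.gene_symbol in high.genes]
            pairs = build_pairs(kept, whitelist)
            gene_axis, chem_axis = degree_ordered_axes(
                pairs, sorted(high.genes), whitelist)
            mat = matrix(pairs, gene_axis, chem_axis)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        write_pairs(pairs, outdir / "interaction_pairs.tsv")
        write_degrees(degrees(pairs), outdir / "interaction_degrees.tsv")
        mat.to_csv(outdir / "interaction_matrix.tsv", sep="\t")
        summary["interactions"] = {
            "n_records": len(records), "n_filtered_records": len(kept),
            "n_pairs": len(pairs),
            "pct_chemicals_with_pairs": pct_chemicals_with_pairs(pairs, whitelist),
            "group_pairs": group_rollup(pairs),
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
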