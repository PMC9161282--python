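"""The SNV prioritization cascade: triage rules, enrichment, invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from xenoprio.snv import (
    FrequencyRules,
    GenotypeCall,
    QcThresholds,
    apply_genotype_qc,
    classify_consequence,
    damaging_missense_filter,
    enrichment_filter,
    prioritize,
)
from xenoprio.types import (
    AnnotatedVariant,
    CohortFrequency,
    ConfigurationError,
    ConsequenceClass,
    EnrichmentMode,
    GenePanelEntry,
    Impact,
    PanelCategory,
    PolyphenLabel,
    SiftLabel,
    Stage,
    ValidationError,
)


@pytest.mark.parametrize("terms,impact,expected", [
    (("stop_gained",), Impact.HIGH, ConsequenceClass.LOF),
    (("frameshift_variant",), Impact.HIGH, ConsequenceClass.LOF),
    (("splice_acceptor_variant", "intron_variant"), Impact.HIGH,
     ConsequenceClass.LOF),
    (("start_lost",), Impact.HIGH, ConsequenceClass.LOF),
    # start-loss is handled on the LoF side only, never as missense
    (("start_lost",), Impact.MODERATE, ConsequenceClass.EXCLUDED),
    (("missense_variant",), Impact.MODERATE, ConsequenceClass.MISSENSE_CANDIDATE),
    # a LoF term without HIGH impact does not qualify
    (("stop_gained",), Impact.MODERATE, ConsequenceClass.EXCLUDED),
    (("missense_variant",), Impact.HIGH, ConsequenceClass.EXCLUDED),
    (("synonymous_variant",), Impact.LOW, ConsequenceClass.EXCLUDED),
    (("intron_variant",), Impact.MODIFIER, ConsequenceClass.EXCLUDED),
])
def test_consequence_triage(terms, impact, expected):
    assert classify_consequence(terms, impact) is expected


def test_unknown_term_warns_but_never_crashes(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="xenoprio.snv"):
        out = classify_consequence(("made_up_term",), Impact.HIGH)
    assert out is ConsequenceClass.EXCLUDED
    assert "made_up_term" in caplog.text


def test_empty_terms_rejected():
    with pytest.raises(ValidationError):
        classify_consequence((), Impact.HIGH)


@pytest.mark.parametrize("sift,poly,expected", [
    (SiftLabel.deleterious, PolyphenLabel.probably_damaging, True),
    (SiftLabel.deleterious, PolyphenLabel.possibly_damaging, True),
    (SiftLabel.tolerated, PolyphenLabel.probably_damaging, False),
    (SiftLabel.deleterious_low_confidence, PolyphenLabel.probably_damaging, False),
    (SiftLabel.deleterious, PolyphenLabel.benign, False),
    (SiftLabel.deleterious, PolyphenLabel.unknown, False),
    (None, PolyphenLabel.probably_damaging, False),
    (SiftLabel.deleterious, None, False),
])
def test_damaging_missense_gate(sift, poly, expected):
    assert damaging_missense_filter(sift, poly) is expected


class TestEnrichmentFilter:
    rules = FrequencyRules()

    def test_exclusive_to_cases(self):
        ok, mode = enrichment_filter(CohortFrequency("cases", 2, 5348),
                                     CohortFrequency("ctrl", 0, 1504), self.rules)
        assert ok and mode is EnrichmentMode.exclusive

    def test_ratio_exactly_at_threshold_fails(self):
        # 0.003 / 0.002 = 1.5, the inequality is strict
        ok, mode = enrichment_filter(CohortFrequency("cases", 3, 1000),
                                     CohortFrequency("ctrl", 2, 1000), self.rules)
        assert not ok and mode is None

    def test_ratio_above_threshold_passes(self):
        ok, mode = enrichment_filter(CohortFrequency("cases", 4, 1000),
                                     CohortFrequency("ctrl", 2, 1000), self.rules)
        assert ok and mode is EnrichmentMode.ratio

    def test_absent_from_both_fails(self):
        ok, _ = enrichment_filter(CohortFrequency("cases", 0, 1000),
                                  CohortFrequency("ctrl", 0, 1000), self.rules)
        assert not ok

    def test_no_called_alleles_is_an_error(self):
        with pytest.raises(ValidationError, match="no_called_alleles"):
            enrichment_filter(CohortFrequency("cases", 0, 0),
                              CohortFrequency("ctrl", 1, 100), self.rules)


def _variant(gene, pos, terms, impact, sift=None, poly=None,
             case=(0, 1000), ctrl=(0, 1000), ref=(0, 10000)):
    return AnnotatedVariant(
        chrom="1", pos=pos, ref="A", alt="G", gene_symbol=gene,
        consequence_terms=terms, impact=impact, sift=sift, polyphen=poly,
        cohort_counts={
            "cases": CohortFrequency("cases", *case),
            "controls": CohortFrequency("controls", *ctrl),
            "reference": CohortFrequency("reference", *ref),
        },
    )


@pytest.fixture
def hand_cascade(small_panel):
    """Ten variants with hand-enumerated cascade outcomes."""
    DEL, PROB = SiftLabel.deleterious, PolyphenLabel.probably_damaging
    variants = [
        # PRIORITIZED, exclusive: absent from controls and reference
        _variant("GENE1", 101, ("missense_variant",), Impact.MODERATE,
                 DEL, PROB, case=(5, 1000)),
        # PRIORITIZED, ratio: 0.004 vs 0.001 (x4) and vs 0.001 (x4)
        _variant("GENE1", 102, ("stop_gained",), Impact.HIGH,
                 case=(4, 1000), ctrl=(1, 1000), ref=(10, 10000)),
        # synonymous: impact_fail
        _variant("GENE1", 103, ("synonymous_variant",), Impact.LOW,
                 case=(5, 1000)),
        # SIFT tolerated: prediction_fail
        _variant("GENE1", 104, ("missense_variant",), Impact.MODERATE,
                 SiftLabel.tolerated, PROB, case=(5, 1000)),
        # PolyPhen unknown counts as missing: prediction_fail
        _variant("GENE1", 105, ("missense_variant",), Impact.MODERATE,
                 DEL, PolyphenLabel.unknown, case=(5, 1000)),
        # equal case/control MAF: internal_enrichment_fail
        _variant("GENE2", 201, ("missense_variant",), Impact.MODERATE,
                 DEL, PolyphenLabel.possibly_damaging,
                 case=(2, 1000), ctrl=(2, 1000)),
        # reference MAF 0.06 > 0.05 ceiling: common_fail
        _variant("GENE2", 202, ("stop_gained",), Impact.HIGH,
                 case=(3, 1000), ctrl=(1, 1000), ref=(600, 10000)),
        # passes internal (x3) but reference ratio exactly 1.5: strict fail
        _variant("GENE2", 203, ("stop_gained",), Impact.HIGH,
                 case=(3, 1000), ctrl=(1, 1000), ref=(20, 10000)),
        # PRIORITIZED, mixed exclusive+ratio reports ratio
        _variant("GENE2", 204, ("missense_variant",), Impact.MODERATE,
                 DEL, PROB, case=(4, 1000), ctrl=(0, 1000), ref=(2, 10000)),
        # off-panel gene: excluded from accounting entirely
        _variant("GENE3", 301, ("stop_gained",), Impact.HIGH, case=(5, 1000)),
    ]
    expected = {
        "1:101:A:G": (Stage.prioritized, EnrichmentMode.exclusive),
        "1:102:A:G": (Stage.prioritized, EnrichmentMode.ratio),
        "1:103:A:G": (Stage.impact_fail, None),
        "1:104:A:G": (Stage.prediction_fail, None),
        "1:105:A:G": (Stage.prediction_fail, None),
        "1:201:A:G": (Stage.internal_enrichment_fail, None),
        "1:202:A:G": (Stage.common_fail, None),
        "1:203:A:G": (Stage.reference_enrichment_fail, None),
        "1:204:A:G": (Stage.prioritized, EnrichmentMode.ratio),
    }
    return variants, expected


class TestCascade:
    def test_hand_enumerated_verdicts(self, hand_cascade, small_panel):
        variants, expected = hand_cascade
        res = prioritize(variants, small_panel)
        assert res.n_off_panel == 1 and res.n_panel_variants == 9
        got = {v.key: (v.stage_reached, v.enrichment_mode) for v in res.verdicts}
        assert got == expected
        assert res.summaries["GENE1"].unique_prioritized_variants == 2
        assert res.summaries["GENE2"].unique_prioritized_variants == 1

    def test_counting_identity(self, hand_cascade, small_panel):
        variants, _ = hand_cascade
        res = prioritize(variants, small_panel)
        assert sum(res.stage_counts.values()) == res.n_panel_variants

    def test_order_insensitivity(self, hand_cascade, small_panel):
        variants, _ = hand_cascade
        base = prioritize(variants, small_panel)
        shuffled = variants[:]
        random.Random(3).shuffle(shuffled)
        perm = prioritize(shuffled, small_panel)
        assert sorted(map(repr, base.verdicts)) == sorted(map(repr, perm.verdicts))

    def test_all_common_variants_fail_common_stage(self, small_panel):
        variants = [
            _variant("GENE1", p, ("missense_variant",), Impact.MODERATE,
                     SiftLabel.deleterious, PolyphenLabel.probably_damaging,
                     case=(5, 1000), ref=(5000, 10000))
            for p in range(100, 110)
        ]
        res = prioritize(variants, small_panel)
        assert not res.prioritized_keys
        assert res.stage_counts[Stage.common_fail] == 10

    def test_missing_case_cohort_is_configuration_error(self, small_panel):
        v = AnnotatedVariant(
            chrom="1", pos=1, ref="A", alt="G", gene_symbol="GENE1",
            consequence_terms=("missense_variant",), impact=Impact.MODERATE,
            cohort_counts={"controls": CohortFrequency("controls", 0, 10)})
        with pytest.raises(ConfigurationError, match="cases"):
            prioritize([v], small_panel)

    def test_monotone_in_reference_ceiling_and_ratio(self, small_panel):
        rng = random.Random(5)
        variants = [
            _variant("GENE1", 1000 + i, ("missense_variant",), Impact.MODERATE,
                     SiftLabel.deleterious, PolyphenLabel.probably_damaging,
                     case=(rng.randint(0, 12), 1000),
                     ctrl=(rng.randint(0, 6), 1000),
                     ref=(rng.randint(0, 800), 10000))
            for i in range(40)
        ]

        def run(maf, ratio):
            return prioritize(
                variants, small_panel,
                rules=FrequencyRules(max_reference_maf=maf,
                                     enrichment_ratio=ratio)).prioritized_keys

        assert run(0.01, 1.5) <= run(0.05, 1.5) <= run(0.10, 1.5)
        assert run(0.05, 3.0) <= run(0.05, 1.5) <= run(0.05, 1.1)

    def test_brute_force_oracle_equivalence(self, small_panel):
        """Re-evaluate every rule independently on random variants and
        compare with the pipeline verdicts."""
        rng = random.Random(17)
        rules = FrequencyRules()
        lof_terms = ["stop_gained", "frameshift_variant", "splice_donor_variant"]
        other = ["missense_variant", "synonymous_variant", "intron_variant"]
        variants = []
        for i in range(50):
            terms = (rng.choice(lof_terms + other),)
            impact = rng.choice(list(Impact))
            variants.append(_variant(
                rng.choice(["GENE1", "GENE2"]), 5000 + i, terms, impact,
                rng.choice([None] + list(SiftLabel)),
                rng.choice([None] + list(PolyphenLabel)),
                case=(rng.randint(0, 10), 1000),
                ctrl=(rng.randint(0, 5), 1000),
                ref=(rng.randint(0, 700), 10000)))

        def oracle(v):
            ref = v.cohort_counts["reference"]
            if ref.ac / ref.an > rules.max_reference_maf:
                return Stage.common_fail
            is_lof = v.impact is Impact.HIGH and any(
                t in ("stop_gained", "frameshift_variant", "splice_donor_variant",
                      "splice_acceptor_variant", "start_lost", "stop_lost")
                for t in v.consequence_terms)
            is_mis = v.impact is Impact.MODERATE and \
                "missense_variant" in v.consequence_terms
            if not (is_lof or is_mis):
                return Stage.impact_fail
            if is_mis and not (
                    v.sift is SiftLabel.deleterious and v.polyphen in
                    (PolyphenLabel.probably_damaging,
                     PolyphenLabel.possibly_damaging)):
                return Stage.prediction_fail
            case, ctrl = v.cohort_counts["cases"], v.cohort_counts["controls"]
            def enriched(a, b):
                if b.ac == 0:
                    return a.ac > 0
                return (a.ac / a.an) / (b.ac / b.an) > rules.enrichment_ratio
            if not enriched(case, ctrl):
                return Stage.internal_enrichment_fail
            if not enriched(case, ref):
                return Stage.reference_enrichment_fail
            return Stage.prioritized

        res = prioritize(variants, small_panel, rules=rules)
        got = {v.key: v.stage_reached for v in res.verdicts}
        want = {v.key: oracle(v) for v in variants}
        assert got == want


class TestGenotypeQc:
    qc = QcThresholds()

    def test_low_quality_genotypes_masked_and_counts_recomputed(self):
        calls = [
            GenotypeCall("S1", 1, dp=30, gq=80),
            GenotypeCall("S2", 1, dp=5, gq=80),    # depth below 8: masked
            GenotypeCall("S3", 0, dp=30, gq=20),   # GQ <= 20: masked
            GenotypeCall("S4", 0, dp=30, gq=21),
            GenotypeCall("S5", None, dp=30, gq=80),  # already missing
        ]
        freq, missingness, carriers = apply_genotype_qc(calls, self.qc)
        assert (freq.ac, freq.an) == (1, 4)
        assert missingness == pytest.approx(3 / 5)
        assert carriers == {"S1"}

    def test_high_missingness_fails_variant(self, small_panel):
        v = _variant("GENE1", 700, ("missense_variant",), Impact.MODERATE,
                     SiftLabel.deleterious, PolyphenLabel.probably_damaging,
                     case=(5, 1000))
        calls = [GenotypeCall(f"S{i}", 1 if i < 3 else 0,
                              dp=5 if i < 20 else 30, gq=80)
                 for i in range(100)]  # 20% missing after depth mask
        res = prioritize([v], small_panel, genotypes={v.key: calls})
        (verdict,) = res.verdicts
        assert verdict.stage_reached is Stage.qc_fail and verdict.qc_assessed

    def test_summary_only_variants_record_qc_not_assessed(self, small_panel):
        v = _variant("GENE1", 701, ("missense_variant",), Impact.MODERATE,
                     SiftLabel.deleterious, PolyphenLabel.probably_damaging,
                     case=(5, 1000))
        (verdict,) = prioritize([v], small_panel).verdicts
        assert not verdict.qc_assessed
        assert verdict.stage_reached is Stage.prioritized


@settings(derandomize=True, max_examples=60)
@given(ac_case=st.integers(0, 50), ac_ctrl=st.integers(0, 50))
def test_enrichment_pass_always_has_a_mode(ac_case, ac_ctrl):
    ok, mode = enrichment_filter(CohortFrequency("c", ac_case, 1000),
                                 CohortFrequency("k", ac_ctrl, 1000),
                                 FrequencyRules())
    assert ok == (mode is not None)
    if ac_ctrl == 0 and ok:
        assert mode is EnrichmentMode.exclusive
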