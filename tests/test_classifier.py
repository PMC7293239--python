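import numpy as np
import pytest

from chipcall.classifier import (FilterThresholds, call_chip, classify_variant,
                                 default_driver_rules, exceeds_contamination,
                                 hotspot_matches, min_alt_reads,
                                 passes_quality, summarize_cohort)
from chipcall.errors import ConfigurationError, ValidationError
from conftest import binom_tail_oracle, ctx, make_variant


class TestMinAltReads:
    def test_floor_binds_at_zero_contamination(self):
        for depth in (10, 100, 978, 5000):
            assert min_alt_reads(depth, 0.0) == 4

    @pytest.mark.parametrize("contamination", [0.01, 0.03, 0.08])
    def test_matches_bruteforce_tail_summation(self, contamination):
        depth, alpha = 978, 0.01
        p = contamination / 3.0
        k_star = next(k for k in range(1, depth + 1)
                      if binom_tail_oracle(k, depth, p) < alpha)
        assert min_alt_reads(depth, contamination) == max(4, k_star)

    def test_monotone_in_contamination(self):
        ks = [min_alt_reads(978, c) for c in np.linspace(0.0, 0.45, 30)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))
        assert min_alt_reads(978, 0.08) >= min_alt_reads(978, 0.01)

    def test_contamination_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            min_alt_reads(978, 0.5)


class TestQualityGate:
    @pytest.mark.parametrize("tlod,ok", [(6.3, True), (6.31, True),
                                         (6.29, False), (0.0, False)])
    def test_snv_tlod_boundary(self, tlod, ok):
        v = make_variant(tlod=tlod)
        passed, reason = passes_quality(v)
        assert passed is ok
        if not ok:
            assert reason == "fails_tlod"

    @pytest.mark.parametrize("qsi,ok", [(30.0, True), (29.0, False)])
    def test_indel_qsi_boundary(self, qsi, ok):
        v = make_variant(ref="AC", alt="-", variant_class="frameshift_del",
                         protein_change="p.V716fs", tlod=None, qsi_nt=qsi)
        passed, reason = passes_quality(v)
        assert passed is ok
        if not ok:
            assert reason == "fails_qsi"

    def test_missing_score_fails_in_strict_mode_only(self):
        v = make_variant(tlod=None)
        assert passes_quality(v)[0] is False
        lax = FilterThresholds(strict_missing_quality=False)
        assert passes_quality(v, lax)[0] is True

    def test_indel_judged_on_qsi_not_tlod(self):
        v = make_variant(ref="AC", alt="-", variant_class="frameshift_del",
                         protein_change="p.V716fs", tlod=2.0, qsi_nt=100.0)
        assert passes_quality(v)[0] is True


class TestDriverRules:
    def test_hotspot_position_vs_exact_match(self):
        assert hotspot_matches("p.R882H", "R882")
        assert hotspot_matches("p.R882C", "R882")
        assert hotspot_matches("p.V617F", "V617F")
        assert not hotspot_matches("p.V617G", "V617F")
        assert not hotspot_matches("p.R88H", "R882")   # position boundary
        assert not hotspot_matches("p.R8821H", "R882")
        assert not hotspot_matches(None, "R882")

    def test_whitelist_semantics(self, rules):
        v = make_variant(gene="KRAS", variant_class="missense",
                         protein_change="p.G12D")
        assert not rules.is_driver(v)

    @pytest.mark.parametrize("gene,vclass,pchange,expected", [
        ("DNMT3A", "missense", "p.R882H", True),
        ("DNMT3A", "missense", "p.S714C", False),   # non-hotspot missense
        ("DNMT3A", "nonsense", "p.W305*", True),
        ("TET2", "frameshift_ins", "p.H1380fs", True),
        ("TET2", "missense", "p.C1135Y", False),    # truncating-only gene
        ("TP53", "missense", "p.R175H", True),
        ("TP53", "synonymous", "p.P36P", False),
        ("JAK2", "missense", "p.V617F", True),
        ("JAK2", "nonsense", "p.Q100*", False),     # hotspots-only gene
        ("SRSF2", "missense", "p.P95H", True),
    ])
    def test_mode_semantics(self, rules, gene, vclass, pchange, expected):
        v = make_variant(gene=gene, variant_class=vclass,
                         protein_change=pchange)
        assert rules.is_driver(v) is expected

    def test_yaml_round_trip(self, rules, tmp_path):
        from chipcall.classifier import DriverRules
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        back = DriverRules.from_yaml(path)
        assert back.to_dict() == rules.to_dict()


class TestClassifyVariant:
    def test_clean_hotspot_call_is_retained(self, rules):
        v = make_variant(alt_count=30, ref_count=170, tlod=50.0)
        call = classify_variant(v, ctx(contamination=0.01), rules)
        assert call.status == "retained_driver"
        assert call.reasons == ()

    def test_contamination_worked_example(self, rules):
        # a 2% clone in a sample with 3% contamination is not callable
        v = make_variant(alt_count=4, ref_count=196, tlod=50.0)
        call = classify_variant(v, ctx(contamination=0.03), rules)
        assert call.status == "filtered"
        assert "within_contamination" in call.reasons
        assert binom_tail_oracle(4, 200, 0.01) >= 0.01  # gate is right to fail

    def test_germline_gate_respects_exemptions(self, rules):
        exempt = make_variant(gene="TET2", variant_class="frameshift_ins",
                              protein_change="p.H1380fs", ref="-", alt="T",
                              alt_count=90, ref_count=110, tlod=None,
                              qsi_nt=100.0)
        call = classify_variant(exempt, ctx(contamination=0.01), rules)
        assert "above_germline_vaf" not in call.reasons
        assert call.status == "retained_driver"
        nonexempt = make_variant(gene="KRAS", variant_class="missense",
                                 protein_change="p.G12D", alt_count=90,
                                 ref_count=110, tlod=50.0)
        call = classify_variant(nonexempt, ctx(contamination=0.01), rules)
        assert "above_germline_vaf" in call.reasons

    def test_reasons_accumulate_without_short_circuit(self, rules):
        # fails VAF floor, quality, alt-read floor, contamination and driver
        v = make_variant(gene="KRAS", variant_class="synonymous",
                         protein_change=None, alt_count=2, ref_count=498,
                         tlod=1.0)
        call = classify_variant(v, ctx(contamination=0.05), rules)
        assert call.reasons == ("below_vaf_min", "fails_tlod",
                                "insufficient_alt_reads",
                                "within_contamination", "not_driver")

    def test_sample_mismatch_is_configuration_error(self, rules):
        v = make_variant(sample_id="A")
        with pytest.raises(ConfigurationError):
            classify_variant(v, ctx(sample_id="B"), rules)

    def test_contamination_gate_matches_bruteforce_enumeration(self,
                                                               thresholds):
        for depth in range(1, 51, 7):
            for c in (0.0, 0.03, 0.08):
                for alt in range(0, depth + 1):
                    expected = (alt >= 1) if c == 0 else \
                        (binom_tail_oracle(alt, depth, c / 3.0) < 0.01)
                    got = exceeds_contamination(alt, depth, c, thresholds)
                    assert got == expected, (depth, c, alt)


def _mini_cohort(rules):
    """10 samples; exactly 3 carry one retained driver."""
    variants, contexts = [], []
    for i in range(10):
        sid = f"S{i}"
        contexts.append(ctx(sample_id=sid, contamination=0.01))
        if i < 3:
            variants.append(make_variant(sample_id=sid, alt_count=30,
                                         ref_count=170, tlod=50.0))
        elif i < 5:  # filtered: synonymous
            variants.append(make_variant(
                sample_id=sid, variant_class="synonymous",
                protein_change=None, alt_count=30, ref_count=170, tlod=50.0))
    return variants, contexts


class TestCallChip:
    def test_no_variants_no_chip(self, rules):
        contexts = [ctx(sample_id="S1"), ctx(sample_id="S2")]
        cs = call_chip([], contexts, rules)
        assert len(cs.per_sample) == 2
        assert cs.per_sample.chip.sum() == 0

    def test_prevalence_on_constructed_fixture(self, rules):
        variants, contexts = _mini_cohort(rules)
        cs = call_chip(variants, contexts, rules)
        s = summarize_cohort(cs)
        assert s.n_chip_patients == 3
        assert s.prevalence == pytest.approx(0.30)

    def test_missing_context_raises(self, rules):
        with pytest.raises(ConfigurationError):
            call_chip([make_variant(sample_id="ghost")],
                      [ctx(sample_id="S1")], rules)

    def test_small_clone_counted_only_under_lower_vaf_floor(self, rules):
        # clone at VAF 0.015: CHIP under vaf_min=0.01, not under 0.02
        v = make_variant(alt_count=15, ref_count=985, tlod=50.0)
        contexts = [ctx(contamination=0.0)]
        loose = call_chip([v], contexts, rules, FilterThresholds(vaf_min=0.01))
        strict = call_chip([v], contexts, rules, FilterThresholds(vaf_min=0.02))
        assert loose.per_sample.chip.iloc[0]
        assert not strict.per_sample.chip.iloc[0]

    def test_raising_thresholds_never_increases_chip_count(self, rules,
                                                           small_cohort):
        variants = small_cohort.variants
        contexts = small_cohort.contexts
        n_01 = call_chip(variants, contexts, rules,
                         FilterThresholds(vaf_min=0.01)).per_sample.chip.sum()
        n_02 = call_chip(variants, contexts, rules,
                         FilterThresholds(vaf_min=0.02)).per_sample.chip.sum()
        assert n_02 <= n_01
        from chipcall.classifier import SampleContext
        worse = [SampleContext(sample_id=c.sample_id,
                               contamination=min(c.contamination + 0.04, 0.49),
                               tumor_fraction=c.tumor_fraction,
                               mean_depth=c.mean_depth) for c in contexts]
        n_hi_c = call_chip(variants, worse, rules).per_sample.chip.sum()
        assert n_hi_c <= n_01

    def test_verdicts_do_not_depend_on_row_order(self, rules, small_cohort):
        variants = list(small_cohort.variants.iter_calls())
        cs1 = call_chip(variants, small_cohort.contexts, rules)
        rng = np.random.default_rng(0)
        shuffled = [variants[i] for i in rng.permutation(len(variants))]
        cs2 = call_chip(shuffled, small_cohort.contexts, rules)
        a = cs1.per_sample.sort_values("sample_id").reset_index(drop=True)
        b = cs2.per_sample.sort_values("sample_id").reset_index(drop=True)
        assert a.equals(b)

    def test_reason_completeness_invariant(self, rules, small_cohort):
        cs = call_chip(small_cohort.variants, small_cohort.contexts, rules)
        for call in cs.calls:
            if call.status == "retained_driver":
                assert call.reasons == ()
            else:
                assert len(call.reasons) >= 1

    def test_tumor_fraction_flag_vs_drop(self, rules):
        v = make_variant(alt_count=30, ref_count=170, tlod=50.0)
        tumor_ctx = [ctx(tumor_fraction=0.04)]
        flagged = call_chip([v], tumor_ctx, rules, tumor_fraction_policy="flag")
        assert flagged.tumor_flagged_samples == ["S1"]
        assert flagged.per_sample.chip.iloc[0]          # flag only
        dropped = call_chip([v], tumor_ctx, rules, tumor_fraction_policy="drop")
        assert len(dropped.per_sample) == 0
        assert dropped.calls[0].status == "filtered"
        assert "tumor_contaminated_sample" in dropped.calls[0].reasons


class TestSummarizeCohort:
    def test_two_mutations_one_gene_counts_one_distinct_gene(self, rules):
        v1 = make_variant(alt_count=30, ref_count=170, tlod=50.0)
        v2 = make_variant(alt_count=50, ref_count=150, tlod=60.0,
                          pos=25457300, protein_change="p.W305*",
                          variant_class="nonsense")
        cs = call_chip([v1, v2], [ctx(contamination=0.01)], rules)
        s = summarize_cohort(cs)
        assert s.genes_per_patient.loc["S1"] == 1
        assert s.gene_patient_counts["DNMT3A"] == 1

    def test_median_vaf_is_middle_order_statistic(self, rules):
        variants = []
        for i, (alt, depth) in enumerate([(10, 1000), (27, 1000), (300, 1000)]):
            variants.append(make_variant(
                sample_id=f"S{i}", alt_count=alt, ref_count=depth - alt,
                tlod=50.0))
        contexts = [ctx(sample_id=f"S{i}", contamination=0.0)
                    for i in range(3)]
        s = summarize_cohort(call_chip(variants, contexts, rules))
        assert s.median_vaf == pytest.approx(0.027)

    def test_comutation_column_sums_equal_gene_counts(self, rules,
                                                      default_cohort):
        cs = call_chip(default_cohort.variants, default_cohort.contexts, rules)
        s = summarize_cohort(cs)
        sums = s.comutation.sum(axis=0)
        for gene, count in s.gene_patient_counts.items():
            assert sums[gene] == count

    def test_dnmt3a_is_modal_gene_in_default_cohort(self, rules,
                                                    default_cohort):
        cs = call_chip(default_cohort.variants, default_cohort.contexts, rules)
        assert summarize_cohort(cs).modal_gene == "DNMT3A"
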