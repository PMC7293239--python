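import numpy as np
import pandas as pd
import pytest

from chipcall.classifier import SampleContext
from chipcall.simulate import SimConfig, simulate_tmn_pair
from chipcall.tracking import (MutationId, clonal_relation_summary,
                               detection_test, force_call, track_mutations)
from conftest import binom_tail_oracle


def pileup_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                       "alt", "alt_count", "depth"])


MUT = MutationId(chrom="17", pos=7577120, ref="C", alt="T", gene="TP53")


def one_call(alt, depth, contamination=0.01, alpha=0.01, base_error=1e-3):
    pile = pileup_frame([("S1", "17", 7577120, "C", "T", alt, depth)])
    ctx = SampleContext(sample_id="S1", contamination=contamination,
                        mean_depth=depth)
    return force_call([MUT], pile, ctx, alpha=alpha,
                      base_error=base_error)[0]


class TestForceCall:
    def test_zero_alt_reads_not_detected(self):
        call = one_call(0, 500)
        assert call.detected is False
        assert call.vaf == 0.0
        assert call.covered

    def test_detection_verdict_matches_binomial_oracle(self):
        # 8 alt reads in 1000 with 1% contamination and 1e-3 base error
        p0 = 1e-3 + 0.01 / 3.0
        oracle_p = binom_tail_oracle(8, 1000, p0)
        call = one_call(8, 1000, contamination=0.01)
        assert call.p_value == pytest.approx(oracle_p, rel=1e-9)
        assert call.detected is (oracle_p < 0.01)

    def test_vaf_reported_even_when_not_detected(self):
        call = one_call(3, 1000)
        assert call.vaf == pytest.approx(0.003)
        assert call.detected is False

    def test_missing_site_and_zero_depth_are_uncovered(self):
        pile = pileup_frame([("S1", "17", 7577120, "C", "T", 0, 0)])
        ctx = SampleContext(sample_id="S1", contamination=0.01,
                            mean_depth=100)
        call = force_call([MUT], pile, ctx)[0]
        assert not call.covered and call.detected is None
        other = MutationId(chrom="1", pos=1, ref="A", alt="G")
        call2 = force_call([other], pile, ctx)[0]
        assert not call2.covered

    def test_detection_monotone_in_alt_and_antimonotone_in_error(self):
        pvals = [one_call(k, 1000).p_value for k in range(1, 30)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))
        p_low = one_call(8, 1000, base_error=1e-4).p_value
        p_high = one_call(8, 1000, base_error=5e-3).p_value
        assert p_low <= p_high

    def test_detects_below_discovery_vaf_threshold_in_deep_pileup(self):
        # VAF 0.005 clone, clean sample, 2000x: detectable despite < 0.01
        call = one_call(10, 2000, contamination=0.002)
        assert call.vaf < 0.01
        assert call.detected is True

    def test_rediscovers_retained_drivers_from_own_counts(self, rules,
                                                          small_cohort):
        # on the discovery sample, with force-calling's error model reduced
        # to the contamination term, every retained driver must re-detect
        from chipcall.classifier import call_chip
        cs = call_chip(small_cohort.variants, small_cohort.contexts, rules)
        ctx_by_id = {c.sample_id: c for c in small_cohort.contexts}
        assert len(cs.retained) > 0
        for call in cs.retained[:40]:
            v = call.variant
            ctx = ctx_by_id[v.sample_id]
            pile = pileup_frame([(v.sample_id, v.chrom, v.pos, v.ref, v.alt,
                                  v.alt_count, v.depth)])
            fc = force_call([MutationId(chrom=v.chrom, pos=v.pos, ref=v.ref,
                                        alt=v.alt, gene=v.gene)], pile, ctx,
                            base_error=0.0)[0]
            assert fc.detected is True


class TestTracking:
    def test_fold_change_ratio(self):
        pile1 = pileup_frame([("A_t1", "17", 7577120, "C", "T", 10, 2000)])
        pile2 = pileup_frame([("A_t2", "17", 7577120, "C", "T", 600, 2000)])
        ctxs = [SampleContext(sample_id="A_t1", contamination=0.002,
                              mean_depth=2000),
                SampleContext(sample_id="A_t2", contamination=0.002,
                              mean_depth=2000)]
        tracked = track_mutations([MUT], [pile1, pile2], ctxs)[0]
        assert tracked.fold_change == pytest.approx(60.0)  # 0.30 / 0.005
        assert tracked.detected_at(0) and tracked.detected_at(1)

    def test_fold_change_undefined_when_absent_earlier(self):
        pile1 = pileup_frame([("A_t1", "17", 7577120, "C", "T", 0, 2000)])
        pile2 = pileup_frame([("A_t2", "17", 7577120, "C", "T", 600, 2000)])
        ctxs = [SampleContext(sample_id="A_t1", contamination=0.002,
                              mean_depth=2000),
                SampleContext(sample_id="A_t2", contamination=0.002,
                              mean_depth=2000)]
        tracked = track_mutations([MUT], [pile1, pile2], ctxs)[0]
        assert tracked.fold_change is None

    def test_patient_without_shared_mutation_not_related(self):
        pile1 = pileup_frame([("P_t1", "17", 7577120, "C", "T", 0, 2000)])
        pile2 = pileup_frame([("P_t2", "17", 7577120, "C", "T", 400, 2000)])
        ctxs = [SampleContext(sample_id="P_t1", contamination=0.002,
                              mean_depth=2000),
                SampleContext(sample_id="P_t2", contamination=0.002,
                              mean_depth=2000)]
        tracked = {"P": track_mutations([MUT], [pile1, pile2], ctxs)}
        summary = clonal_relation_summary(tracked)
        assert summary.per_patient["P"] is False
        assert summary.n_later_only == 1

    def test_all_uncovered_patient_is_indeterminate(self):
        pile1 = pileup_frame([("P_t1", "17", 7577120, "C", "T", 0, 0)])
        pile2 = pileup_frame([("P_t2", "17", 7577120, "C", "T", 400, 2000)])
        ctxs = [SampleContext(sample_id="P_t1", contamination=0.002,
                              mean_depth=2000),
                SampleContext(sample_id="P_t2", contamination=0.002,
                              mean_depth=2000)]
        tracked = {"P": track_mutations([MUT], [pile1, pile2], ctxs)}
        summary = clonal_relation_summary(tracked)
        assert summary.per_patient["P"] is None
        assert summary.n_indeterminate == 1
        assert summary.n_patients == 0

    def test_constructed_eight_of_ten_shared_driver_scenario(self):
        data = simulate_tmn_pair(SimConfig(seed=123))
        tracked = {
            pid: track_mutations(muts, data.pileups,
                                 data.contexts_by_patient[pid])
            for pid, muts in data.mutations_by_patient.items()}
        summary = clonal_relation_summary(tracked)
        assert summary.n_patients == 10
        assert summary.n_clonally_related == 8
        assert summary.n_later_only == 2
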