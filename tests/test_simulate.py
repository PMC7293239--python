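import filecmp
import json

import numpy as np
import pytest

from chipcall import io as cio
from chipcall.classifier import call_chip, default_driver_rules
from chipcall.errors import ConfigurationError
from chipcall.simulate import (SimConfig, calibrate_vaf_lognormal,
                               simulate_cohort, simulate_tmn_pair)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            simulate_cohort(SimConfig(n_patients=80, seed=11)).write(
                tmp_path / d)
        for name in ("clinical.csv", "variants.maf.tsv", "contexts.tsv",
                     "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_cohort(SimConfig(n_patients=80, seed=1))
        b = simulate_cohort(SimConfig(n_patients=80, seed=2))
        assert not a.clinical.df.equals(b.clinical.df)


class TestEmittedTables:
    def test_variant_rows_satisfy_call_invariants(self, default_cohort):
        df = default_cohort.variants.df
        assert (df.alt_count >= 0).all() and (df.ref_count >= 0).all()
        depth = df.alt_count + df.ref_count
        assert (depth >= 1).all()
        assert np.allclose(df.vaf, df.alt_count / depth, atol=1e-9)
        assert set(df.variant_class) <= cio.VARIANT_CLASSES
        for v in default_cohort.variants.iter_calls():
            assert v.is_snv != v.is_indel

    def test_clinical_table_round_trips_without_diagnostics(self,
                                                            default_cohort,
                                                            tmp_path):
        path = tmp_path / "clinical.csv"
        cio.write_clinical(default_cohort.clinical, path)
        back = cio.read_clinical(path)
        assert len(back) == len(default_cohort.clinical)
        assert not back.diagnostics

    def test_tmn_events_precede_death(self, default_cohort):
        df = default_cohort.clinical.df
        tmn = df[df.tmn_event == 1]
        assert (tmn.tmn_time <= tmn.os_time + 1e-9).all()
        assert (df.pfs_time <= df.os_time + 1e-9).all()

    def test_contexts_cover_every_sample(self, default_cohort):
        ids = {c.sample_id for c in default_cohort.contexts}
        assert set(default_cohort.variants.df.sample_id) <= ids
        assert set(default_cohort.clinical.df.patient_id) == ids


class TestCalibration:
    def test_vaf_params_reproduce_frozen_solution(self):
        mu, sigma = calibrate_vaf_lognormal()
        assert sigma == pytest.approx(3.0128, abs=2e-3)
        assert mu == pytest.approx(-9.635, abs=2e-2)

    def test_planted_prevalence_matches_age_bin_calibration(self):
        # expectation sum_b P(bin) * P(CHIP | bin) = 136/629
        reps, target = 20, 136 / 629
        chips = []
        for seed in range(300, 300 + reps):
            truth = simulate_cohort(SimConfig(seed=seed)).truth
            chips.extend(d["chip"] for d in truth["patients"].values())
        est = np.mean(chips)
        band = 3 * np.sqrt(target * (1 - target) / len(chips))
        assert abs(est - target) < band

    def test_age_gradient_in_planted_prevalence(self):
        by_bin = {}
        for seed in range(300, 312):
            co = simulate_cohort(SimConfig(seed=seed))
            df = co.clinical.df
            for b, sub in df.groupby("age_group"):
                by_bin.setdefault(b, []).extend(sub.chip.tolist())
        low = np.mean(by_bin["40-49"])
        high = np.mean(by_bin["70-79"])
        assert high > low
        assert high == pytest.approx(9 / 19, abs=0.12)

    def test_null_hazard_config_recovers_hr_one(self):
        from chipcall.pipeline import fit_formula
        cfg_kwargs = dict(hr_chip_os=1.0, hr_chip_pfs=1.0,
                          hr_chip_maint_pfs=1.0)
        coefs = []
        for seed in range(25):
            co = simulate_cohort(SimConfig(seed=500 + seed, n_patients=400,
                                           **cfg_kwargs))
            fit = fit_formula(co.clinical.df,
                              "os ~ chip strata(age_group, iss, prior_lines)")
            coefs.append(fit.coef[0])
        coefs = np.array(coefs)
        assert abs(coefs.mean()) < 3 * coefs.std() / np.sqrt(len(coefs))


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(chip_by_age=(0.1, 0.2, 0.3, 1.4, 0.2, 0.1))

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(lam_death=0.0)

    def test_pfs_dominance_violation_rejected(self):
        # PFS hazard must dominate OS hazard for the comonotone coupling
        with pytest.raises(ConfigurationError):
            SimConfig(lam_pfs=0.05)


class TestTmnPair:
    def test_truth_matches_construction(self):
        data = simulate_tmn_pair(SimConfig(seed=9))
        truth = data.truth
        assert truth["n_shared"] == 8
        shared = [p for p, d in truth["patients"].items() if d["shared"]]
        assert len(shared) == 8
        for pid, d in truth["patients"].items():
            if d["shared"]:
                assert 0 < d["vaf_asct"] < d["vaf_tmn"]
            else:
                assert d["vaf_asct"] == 0.0

    def test_pileups_are_deterministic_rounding_of_planted_vafs(self):
        data = simulate_tmn_pair(SimConfig(seed=9), pileup_depth=2000)
        p1 = data.pileups[0].set_index("pos")
        for pid, d in data.truth["patients"].items():
            m = data.mutations_by_patient[pid][0]
            assert p1.loc[m.pos, "alt_count"] == round(d["vaf_asct"] * 2000)

    def test_write_layout(self, tmp_path):
        data = simulate_tmn_pair(SimConfig(seed=9))
        data.write(tmp_path)
        assert (tmp_path / "pileup_t1.tsv").exists()
        assert (tmp_path / "pileup_t2.tsv").exists()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["n_patients"] == 10


class TestEndToEndSpectrum:
    def test_caller_sees_dnmt3a_modal_and_plausible_spectrum(self,
                                                             default_cohort):
        from chipcall.classifier import summarize_cohort
        cs = call_chip(default_cohort.variants, default_cohort.contexts,
                       default_driver_rules())
        s = summarize_cohort(cs)
        ranked = list(s.gene_patient_counts.index)
        assert ranked[0] == "DNMT3A"
        assert s.median_vaf == pytest.approx(0.027, abs=0.006)
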