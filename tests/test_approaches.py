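import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nlmetest as nt
from nlmetest import models as M
from nlmetest.approaches import (CandidateSet, akaike_weights, build_null,
                                 h1_weight_fraction, run_clrt, run_ima,
                                 run_mad, run_mapd, run_rclrt, run_sss,
                                 run_stds)
from nlmetest.cohort import GeneratorConfig, generate_natural_history
from nlmetest.engine import CohortData, FitOptions, chi2_critical, fit


@pytest.fixture(scope="module")
def single_offset_candidates():
    return CandidateSet(drugs=(M.drug_model("offset", False),))


class TestAkaikeWeights:
    def test_equal_aics_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two_gives_073_027(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_gap_of_110_drives_weight_to_1e24_scale(self):
        w = akaike_weights([0.0, 110.0])
        assert w[1] < 1e-23
        assert w[1] > 1e-25

    def test_nonfinite_handling(self):
        w = akaike_weights([5.0, np.inf, np.nan])
        assert w[0] == 1.0 and w[1] == 0.0 and w[2] == 0.0
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.nan])

    @given(st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=1,
                    max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_weights_sum_to_one_and_best_model_wins(self, aics):
        w = akaike_weights(aics)
        assert abs(w.sum() - 1.0) < 1e-12
        # the max-weight model has (up to float ties) the minimum AIC
        assert aics[int(np.argmax(w))] <= min(aics) + 1e-9

    def test_h1_fraction_uniform_case(self):
        # 1 H0 and 4 H1 models with equal AIC -> fraction 0.8
        frac = h1_weight_fraction([1.0] * 5, [False, True, True, True, True])
        assert frac == pytest.approx(0.8)


class TestStds:
    def test_strong_effect_rejected(self, effect_data, fast_options):
        res = run_stds(effect_data, CandidateSet.power(),
                       options=fast_options)
        assert res.decision == "reject_h0"
        assert res.dofv < -100
        assert res.effect_estimate == pytest.approx(8.0, abs=1.0)

    def test_single_df2_candidate_uses_599(self, effect_data, fast_options):
        cands = CandidateSet(drugs=(M.drug_model("offset", True),))
        res = run_stds(effect_data, cands, options=fast_options)
        assert res.critical_value == pytest.approx(-5.99, abs=0.005)

    def test_candidate_order_invariance(self, effect_data, fast_options):
        cands = CandidateSet.power()
        rev = CandidateSet(drugs=tuple(reversed(cands.drugs)))
        a = run_stds(effect_data, cands, options=fast_options)
        b = run_stds(effect_data, rev, options=fast_options)
        assert a.decision == b.decision
        assert a.dofv == pytest.approx(b.dofv, abs=0.05)


class TestSss:
    def test_identical_arms_give_null_dofv(self, fast_options):
        # duplicate every subject into both arms: arm-specific estimates
        # cannot beat shared ones by more than optimizer noise
        cfg = GeneratorConfig(n_subjects=30)
        cohort = generate_natural_history(cfg, 41)
        twins = []
        import copy
        for s in cohort.subjects:
            twins.append(s)
            t = copy.deepcopy(s)
            t.id = s.id + 1000
            t.trt = 1
            twins.append(t)
        cohort.subjects = twins
        cohort.meta["allocated"] = True
        data = CohortData.from_cohort(cohort)
        cands = CandidateSet(drugs=(M.drug_model("offset", False),))
        res = run_sss(data, cands, options=fast_options)
        assert res.decision in ("retain_h0", "reject_h0")
        assert abs(res.dofv) < 1.0
        assert abs(res.effect_estimate) < 0.5

    def test_offset_without_iiv_has_df1(self, effect_data, fast_options):
        cands = CandidateSet(drugs=(M.drug_model("offset", False),))
        res = run_sss(effect_data, cands, options=fast_options)
        assert res.critical_value == pytest.approx(chi2_critical(1), abs=1e-9)


class TestBuildNull:
    def test_bookkeeping(self, clean_data, fast_options,
                         single_offset_candidates):
        null = build_null(clean_data, single_offset_candidates,
                          source="permutation", n=20, seed=3,
                          options=fast_options)
        assert len(null.values) == 20
        assert null.n_failed == 0
        assert null.source == "permutation"

    def test_reproducible(self, clean_data, fast_options,
                          single_offset_candidates):
        a = build_null(clean_data, single_offset_candidates, n=10, seed=3,
                       options=fast_options)
        b = build_null(clean_data, single_offset_candidates, n=10, seed=3,
                       options=fast_options)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_source(self, clean_data):
        with pytest.raises(ValueError):
            build_null(clean_data, source="bootstrap")

    def test_cutoff_rules(self):
        null = nt.NullDistribution(values=np.arange(-20.0, 0.0),
                                   source="permutation", n_requested=20)
        q = null.critical_value(0.05, rule="quantile")
        r = null.critical_value(0.05, rule="rank")
        assert q == pytest.approx(np.quantile(null.values, 0.05))
        assert r == -20.0  # floor(0.05 * 21) - 1 = 0 -> smallest value
        with pytest.raises(ValueError):
            null.critical_value(rule="midway")

    def test_h0_simulation_null_matches_chi2_with_one_candidate(
            self, clean_data, single_offset_candidates, fast_options):
        """With a correctly specified placebo and a single df=1 drug
        candidate, the simulated-H0 null of dOFV is -chi2(1); its 5%
        quantile approaches -3.84."""
        null = build_null(clean_data, single_offset_candidates,
                          source="h0_simulation", n=150, seed=4,
                          options=fast_options)
        q = np.quantile(null.values, 0.05)
        assert -6.5 < q < -2.2
        # bulk must look like a chi2(1): median around -0.45
        assert -1.2 < np.median(null.values) < 0.0


class TestClrtRclrt:
    def test_clrt_critical_value_near_chi2(self, clean_data,
                                           single_offset_candidates,
                                           fast_options):
        res = run_clrt(clean_data, single_offset_candidates, n=60, seed=5,
                       options=fast_options)
        assert res.decision in ("reject_h0", "retain_h0")
        assert -8.0 < res.critical_value < -1.0

    def test_rclrt_strong_effect_rejected(self, effect_data, fast_options):
        res = run_rclrt(effect_data, CandidateSet.power(), n=30, seed=6,
                        options=fast_options)
        assert res.decision == "reject_h0"
        assert res.dofv < res.critical_value

    def test_clrt_cutoffs_smaller_in_magnitude_than_rclrt_when_misspecified(
            self, fast_options):
        """The simulated-H0 null cannot see the placebo-model
        misspecification, so its cutoff stays chi-square-sized, while the
        permutation null inherits the real-data misfit and is far more
        negative."""
        cfg = GeneratorConfig(n_subjects=100,
                              misspec=nt.MisspecConfig(enabled=True))
        cohort = nt.randomize_allocation(generate_natural_history(cfg, 81),
                                         82)
        data = CohortData.from_cohort(cohort)
        cands = CandidateSet.type1()
        c = run_clrt(data, cands, n=25, seed=83, options=fast_options)
        r = run_rclrt(data, cands, n=25, seed=83, options=fast_options)
        assert c.critical_value > -12.0          # chi-square magnitude
        assert r.critical_value < 2 * c.critical_value
        assert r.critical_value < -12.0

    def test_rclrt_type1_small_battery(self, fast_options,
                                       single_offset_candidates):
        """Permutation exchangeability: over replicate no-effect trials the
        rejection rate stays inside the exact binomial region."""
        rejections = 0
        n_trials = 30
        for trial in range(n_trials):
            cfg = GeneratorConfig(n_subjects=60)
            cohort = generate_natural_history(cfg, (51, trial))
            cohort = nt.randomize_allocation(cohort, (52, trial))
            res = run_rclrt(CohortData.from_cohort(cohort),
                            single_offset_candidates, n=20,
                            seed=(53, trial), options=fast_options)
            rejections += res.decision == "reject_h0"
        lo, hi = nt.binomial_acceptance(0.05, n_trials)
        assert 100.0 * rejections / n_trials <= hi


class TestModelAveraging:
    def test_mad_strong_effect_puts_weight_on_h1(self, effect_data,
                                                 fast_options):
        res = run_mad(effect_data, CandidateSet.power(),
                      options=fast_options)
        assert res.h1_weight_fraction > 0.99
        assert res.effect_estimate == pytest.approx(8.0, abs=1.5)

    def test_mapd_grid_is_5x5(self, fast_options):
        cfg = GeneratorConfig(n_subjects=24)
        cohort = nt.randomize_allocation(generate_natural_history(cfg, 61),
                                         62)
        res = run_mapd(CohortData.from_cohort(cohort),
                       options=FitOptions(route="fo", ftol=1e-6))
        assert res.details["n_fits"] == 25
        assert res.h1_weight_fraction is not None
        assert 0.0 <= res.h1_weight_fraction <= 1.0

    def test_mapd_requires_multiple_placebos(self, clean_data):
        with pytest.raises(ValueError):
            run_mapd(clean_data, CandidateSet.type1())


class TestIma:
    def test_strong_effect_detected(self, effect_data, fast_options):
        res = run_ima(effect_data, CandidateSet.power(),
                      options=fast_options)
        assert res.decision == "reject_h0"
        assert res.details["th_mix"] > 0.9
        assert res.effect_estimate == pytest.approx(8.0, abs=2.0)

    def test_critical_value_is_1df(self, effect_data, fast_options):
        res = run_ima(effect_data, CandidateSet.power(),
                      options=fast_options)
        assert res.critical_value == pytest.approx(-3.84, abs=0.005)

    def test_nesting_dofv_nonpositive(self, clean_data, fast_options):
        res = run_ima(clean_data,
                      CandidateSet(drugs=(M.drug_model("offset", False),)),
                      options=fast_options)
        assert res.dofv <= 1e-9
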