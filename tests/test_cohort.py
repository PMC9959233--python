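import copy

import numpy as np
import pytest

import nlmetest as nt
from nlmetest.cohort import (EffectScenario, GeneratorConfig, MisspecConfig,
                             generate_natural_history,
                             inject_treatment_effect, permute_allocation,
                             randomize_allocation)


def _noise_free_config(**kw):
    base = dict(n_subjects=5, th_base=10.0, th_bmms=0.0, th_slope=0.1,
                th_slope_bmms=0.0, om2_base=0.0, om2_slope=0.0, sig2=0.0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerate:
    def test_noise_free_degenerate(self):
        cohort = generate_natural_history(_noise_free_config(), seed=1)
        for s in cohort.subjects:
            np.testing.assert_allclose(s.scores, 10.0 + 0.1 * s.times,
                                       rtol=0, atol=1e-12)

    def test_default_dimensions(self):
        cfg = GeneratorConfig(n_subjects=817)
        cohort = generate_natural_history(cfg, seed=2)
        assert cohort.n_subjects == 817
        assert all(len(s.visits) == 6 for s in cohort.subjects)
        assert cohort.n_obs == 4902

    def test_dropout_reduces_observations(self):
        cfg = GeneratorConfig(n_subjects=817, dropout=0.27)
        cohort = generate_natural_history(cfg, seed=2)
        assert cohort.n_obs < 4902
        # baseline visits are never dropped
        assert all(s.times[0] == 0.0 for s in cohort.subjects)
        # 27% thinning of post-baseline visits aims near the 3597 density
        assert 3200 < cohort.n_obs < 4000

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig(n_subjects=20)
        a = generate_natural_history(cfg, seed=7)
        b = generate_natural_history(cfg, seed=7)
        c = generate_natural_history(cfg, seed=8)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.bmms == sb.bmms
            np.testing.assert_array_equal(sa.scores, sb.scores)
        assert any(not np.array_equal(sa.scores, sc.scores)
                   for sa, sc in zip(a.subjects, c.subjects))

    def test_truth_record_present(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=5), 1)
        assert all(s.truth is not None for s in cohort.subjects)
        assert all(s.trt == 0 for s in cohort.subjects)

    def test_errors(self):
        with pytest.raises(ValueError):
            generate_natural_history(GeneratorConfig(n_subjects=1), 1)
        with pytest.raises(ValueError):
            generate_natural_history(GeneratorConfig(om2_base=-1.0), 1)
        with pytest.raises(ValueError):
            generate_natural_history(GeneratorConfig(schedule=()), 1)
        with pytest.raises(ValueError):
            generate_natural_history(GeneratorConfig(n_subjects=5), None)

    def test_baseline_variance_decomposition(self):
        # Var(score at t=0) = th_bmms^2 Var(bmms) + om2_base + sig2
        cfg = GeneratorConfig(n_subjects=10_000)
        cohort = generate_natural_history(cfg, seed=11)
        y0 = np.array([s.scores[0] for s in cohort.subjects])
        expected = cfg.th_bmms**2 * cfg.bmms_sd**2 + cfg.om2_base + cfg.sig2
        assert abs(np.var(y0) - expected) < 0.06 * expected

    def test_clipping_flag(self):
        cfg = GeneratorConfig(n_subjects=200, th_base=75.0, clip=True)
        cohort = generate_natural_history(cfg, seed=3)
        scores = np.concatenate([s.scores for s in cohort.subjects])
        assert scores.max() <= 70.0 and scores.min() >= 0.0

    def test_latent_component_recorded(self):
        cfg = GeneratorConfig(n_subjects=10,
                              misspec=MisspecConfig(enabled=True))
        cohort = generate_natural_history(cfg, seed=4)
        gammas = [s.truth.latent_gamma for s in cohort.subjects]
        assert np.std(gammas) > 0
        s = cohort.subjects[0]
        np.testing.assert_allclose(
            s.truth.latent_values,
            s.truth.latent_gamma * (s.times / 36.0) ** 2)


class TestInjection:
    @pytest.fixture()
    def allocated(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=40), 5)
        return randomize_allocation(cohort, 6)

    def test_offset_high_effect(self, allocated):
        scen = EffectScenario("offset", typical_effect=8.0, iiv_cv=0.0)
        out = inject_treatment_effect(allocated, scen, 7)
        for before, after in zip(allocated.subjects, out.subjects):
            delta = after.scores - before.scores
            if before.trt == 1:
                assert delta[0] == 0.0  # baseline precedes treatment
                np.testing.assert_allclose(delta[1:], 8.0)
            else:
                np.testing.assert_array_equal(delta, 0.0)

    def test_time_linear_evaluates_at_stated_times(self, allocated):
        scen = EffectScenario("time_linear", typical_effect=2.0)
        out = inject_treatment_effect(allocated, scen, 7)
        treated = next(s for s in out.subjects if s.trt == 1)
        before = next(s for s in allocated.subjects if s.id == treated.id)
        delta = dict(zip(treated.times, treated.scores - before.scores))
        assert delta[36.0] == pytest.approx(2.0)
        assert delta[18.0] == pytest.approx(1.0)
        assert delta[0.0] == 0.0

    def test_null_effect_identity(self, allocated):
        scen = EffectScenario("offset", typical_effect=0.0)
        out = inject_treatment_effect(allocated, scen, 7)
        for a, b in zip(allocated.subjects, out.subjects):
            np.testing.assert_array_equal(a.scores, b.scores)

    def test_iiv_draws_differ_across_subjects(self, allocated):
        scen = EffectScenario("offset", typical_effect=8.0, iiv_cv=0.3)
        out = inject_treatment_effect(allocated, scen, 7)
        etas = [s.truth.drug_eta for s in out.subjects if s.trt == 1]
        assert np.std(etas) > 0
        # CV definition: eta ~ N(0, (0.3 * 8)^2)
        assert abs(np.std(etas) - 2.4) < 1.2

    def test_requires_allocation(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=5), 1)
        with pytest.raises(ValueError, match="arm labels"):
            inject_treatment_effect(cohort, EffectScenario("offset", 8.0), 1)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            EffectScenario("offset", typical_effect=-1.0)
        with pytest.raises(ValueError):
            EffectScenario("banana", typical_effect=1.0)

    def test_paper_grid_has_eight_scenarios(self):
        grid = EffectScenario.paper_grid()
        assert len(grid) == 8
        assert len({s.id for s in grid}) == 8


class TestAllocation:
    def test_odd_split_sizes(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=817), 1)
        out = randomize_allocation(cohort, 2)
        assert sorted(out.arm_sizes()) == [408, 409]

    def test_same_seed_same_allocation(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=20), 1)
        a = randomize_allocation(cohort, 9)
        b = randomize_allocation(cohort, 9)
        assert [s.trt for s in a.subjects] == [s.trt for s in b.subjects]

    def test_uniform_over_balanced_allocations(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=4), 1)
        counts = {}
        n_draws = 3000
        for seed in range(n_draws):
            out = randomize_allocation(cohort, seed)
            key = tuple(s.trt for s in out.subjects)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6  # C(4, 2) balanced allocations
        freqs = np.array(list(counts.values())) / n_draws
        assert np.all(np.abs(freqs - 1 / 6) < 0.035)

    def test_requires_two_subjects(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=2), 1)
        cohort.subjects = cohort.subjects[:1]
        with pytest.raises(ValueError):
            randomize_allocation(cohort, 1)


class TestPermutation:
    @pytest.fixture()
    def allocated4(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=4), 1)
        return randomize_allocation(cohort, 2)

    def test_conserves_arm_sizes(self, allocated4):
        before = allocated4.arm_sizes()
        out = permute_allocation(allocated4, 3)
        assert out.arm_sizes() == before

    def test_data_immutable(self, allocated4):
        out = permute_allocation(allocated4, 3)
        for a, b in zip(allocated4.subjects, out.subjects):
            np.testing.assert_array_equal(a.scores, b.scores)
            assert a.bmms == b.bmms

    def test_requires_allocation(self):
        cohort = generate_natural_history(GeneratorConfig(n_subjects=4), 1)
        with pytest.raises(ValueError):
            permute_allocation(cohort, 1)

    def test_double_permutation_same_marginal(self, allocated4):
        """Composing two independent permutations gives the same
        distribution over allocations as a single one (group property),
        checked by enumeration on 4 subjects."""
        def dist(fn, n=4000):
            counts = {}
            for seed in range(n):
                out = fn(seed)
                key = tuple(s.trt for s in out.subjects)
                counts[key] = counts.get(key, 0) + 1
            return {k: v / n for k, v in counts.items()}

        single = dist(lambda s: permute_allocation(allocated4, s))
        double = dist(lambda s: permute_allocation(
            permute_allocation(allocated4, (s, 0)), (s, 1)))
        assert set(single) == set(double)
        for key in single:
            assert abs(single[key] - double[key]) < 0.04
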