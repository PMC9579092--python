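import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from anota import (
    DesignSpec,
    ObserverConfig,
    dprime,
    exact_power,
    hit_fa_probs,
    mc_power,
    mc_power_design,
    observer_from_discordant,
    pattern_probs_from_observer,
    sdt_counts,
    simulate_pattern_counts,
    simulate_responses,
    tabulate_patterns,
)


class TestPatternProbs:
    def test_chance_observer_uniform(self):
        assert pattern_probs_from_observer(0.0, 0.0) == pytest.approx((0.25,) * 4)

    def test_unit_dprime_unbiased(self):
        p = pattern_probs_from_observer(1.0, 0.0)
        phi = stats.norm.cdf(0.5)
        assert p[2] == pytest.approx(phi**2, abs=1e-12)  # both correct
        assert p[2] == pytest.approx(0.47812, abs=1e-5)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-4, 4), st.floats(-2, 2))
    def test_sums_to_one(self, d, c):
        assert sum(pattern_probs_from_observer(d, c)) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-3, 3))
    def test_sign_symmetry(self, d):
        p_pos = pattern_probs_from_observer(d, 0.0)
        p_neg = pattern_probs_from_observer(-d, 0.0)
        assert p_pos[1] == pytest.approx(p_neg[2])  # p_b(d) = p_c(-d)

    def test_hit_fa_recover_parameters(self):
        h, f = hit_fa_probs(1.3, 0.4)
        s = dprime(h, f, k=10)
        assert s.d_prime == pytest.approx(1.3)
        assert s.criterion_c == pytest.approx(0.4)


class TestObserverInverse:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.02, 0.25), st.floats(0.02, 0.25))
    def test_round_trip(self, pb, pc):
        try:
            d, c = observer_from_discordant(pb, pc)
        except ValueError:
            return  # not attainable under conditional independence
        _, got_b, got_c, _ = pattern_probs_from_observer(d, c)
        assert got_b == pytest.approx(pb, abs=1e-9)
        assert got_c == pytest.approx(pc, abs=1e-9)

    def test_high_discordance_unattainable(self):
        with pytest.raises(ValueError):
            observer_from_discordant(0.2, 0.4)


class TestSimulateResponses:
    def test_seeded_runs_identical(self):
        cfg = ObserverConfig(n=20, k=6, d_prime_true=1.0, seed=7)
        rm1 = simulate_responses(cfg)
        rm2 = simulate_responses(cfg)
        assert np.array_equal(rm1.responses, rm2.responses)

    def test_shape_and_pairing(self):
        rm = simulate_responses(ObserverConfig(n=5, k=3, seed=0))
        assert rm.responses.shape == (5, 6)
        assert rm.pair_index == [(0, 3), (1, 4), (2, 5)]
        assert rm.column_names[0].endswith("_A")
        assert rm.column_names[3].endswith("_NotA")

    def test_chance_observer_rates(self):
        cfg = ObserverConfig(n=100, k=100, d_prime_true=0.0, seed=1)
        sc = sdt_counts(simulate_responses(cfg), "pooled")
        se3 = 3 * np.sqrt(0.25 / 10_000)
        assert sc.p_hits == pytest.approx(0.5, abs=se3)
        assert sc.p_fas == pytest.approx(0.5, abs=se3)

    def test_high_dprime_concentrates_on_correct_pattern(self):
        cfg = ObserverConfig(n=50, k=20, d_prime_true=6.0, seed=2)
        pc = tabulate_patterns(simulate_responses(cfg), "pooled")
        assert pc.c / pc.N > 0.98

    def test_parameter_recovery_moderate_size(self):
        cfg = ObserverConfig(n=500, k=20, d_prime_true=1.0,
                             criterion_true=0.0, seed=3)
        sc = sdt_counts(simulate_responses(cfg), "pooled")
        s = dprime(sc.p_hits, sc.p_fas, cfg.k)
        assert s.d_prime == pytest.approx(1.0, abs=0.1)
        assert s.criterion_c == pytest.approx(0.0, abs=0.06)


class TestMultinomialShortcut:
    def test_matches_trial_level_distribution(self):
        # mean pooled counts from the shortcut track the trial-level
        # generator for a heterogeneous population
        cfg = ObserverConfig(n=100, k=6, d_prime_true=1.0,
                             sd_between_dprime=0.5, sd_between_criterion=0.3,
                             seed=11)
        reps = 400
        shortcut = simulate_pattern_counts(cfg, reps).mean(axis=0)
        trial_level = np.zeros(4)
        for i in range(100):
            rm = simulate_responses(ObserverConfig(
                n=100, k=6, d_prime_true=1.0, sd_between_dprime=0.5,
                sd_between_criterion=0.3, seed=1000 + i))
            pc = tabulate_patterns(rm, "pooled")
            trial_level += np.array([pc.a, pc.b, pc.c, pc.d]) / 100
        assert np.allclose(shortcut, trial_level, atol=12)  # ~3 SE of means

    def test_reproducible(self):
        cfg = ObserverConfig(n=30, k=4, seed=9)
        assert np.array_equal(simulate_pattern_counts(cfg, 50),
                              simulate_pattern_counts(cfg, 50))


class TestMCPower:
    def test_type_one_error_controlled(self):
        # conservative exact test: rejection rate at the null stays below alpha
        cfg = ObserverConfig(n=100, k=2, d_prime_true=0.0, seed=0)
        res = mc_power(cfg, alpha=0.05, tails="one", method="exact",
                       reps=2000, seed=5)
        assert res.power <= 0.05 + 3 * max(res.se, 0.005)

    def test_agrees_with_exact_power(self):
        spec = DesignSpec(p_b=0.0333, p_c=0.1667)
        res = mc_power_design(spec, 75, method="exact", reps=4000, seed=21)
        assert res.power == pytest.approx(exact_power(spec, 75),
                                          abs=3 * res.se + 0.005)

    def test_observer_route_matches_design_route(self):
        d, c = observer_from_discordant(0.0333, 0.1667)
        cfg = ObserverConfig(n=75, k=1, d_prime_true=d, criterion_true=c)
        res = mc_power(cfg, alpha=0.05, method="exact", reps=4000, seed=22)
        assert res.power == pytest.approx(exact_power(
            DesignSpec(p_b=0.0333, p_c=0.1667), 75), abs=3 * res.se + 0.005)

    def test_rejects_too_few_reps(self):
        with pytest.raises(ValueError):
            mc_power(ObserverConfig(n=10, k=1), reps=10)
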