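import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from anota import (
    DesignSpec,
    bu_n,
    bu_power,
    exact_n,
    exact_power,
    from_or_pd,
    miettinen_n,
    miettinen_power,
    sample_size_grid,
)


class TestFromOrPd:
    @pytest.mark.parametrize("OR,pD,pb,pc", [
        (5, 0.2, 0.1667, 0.0333),
        (1, 0.4, 0.2, 0.2),
        (2, 0.6, 0.4, 0.2),
    ])
    def test_values(self, OR, pD, pb, pc):
        got_b, got_c = from_or_pd(OR, pD)
        assert got_b == pytest.approx(pb, abs=5e-5)
        assert got_c == pytest.approx(pc, abs=5e-5)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.05, 0.95))
    def test_identities(self, OR, pD):
        pb, pc = from_or_pd(OR, pD)
        assert pb / pc == pytest.approx(OR)
        assert pb + pc == pytest.approx(pD)


class TestMiettinen:
    def test_power_brackets_target_at_minimum_n(self):
        spec = DesignSpec(p_b=0.1667, p_c=0.0333)
        assert miettinen_power(spec, 59) >= 0.8
        assert miettinen_power(spec, 59) == pytest.approx(0.807, abs=5e-4)
        assert miettinen_power(spec, 58) < 0.8

    @pytest.mark.parametrize("pb,pc,expected", [
        (0.1667, 0.0333, 59),
        (0.15, 0.05, 113),
        (0.12, 0.08, 763),
        (0.4, 0.2, 90),
    ])
    def test_minimum_n_anchors(self, pb, pc, expected):
        assert miettinen_n(DesignSpec(p_b=pb, p_c=pc)) == expected

    def test_null_design_power_is_alpha(self):
        spec = DesignSpec(p_b=0.1, p_c=0.1, alpha=0.05)
        assert miettinen_power(spec, 100) == pytest.approx(0.05, abs=1e-9)

    def test_direction_symmetry(self):
        a = miettinen_n(DesignSpec(p_b=0.15, p_c=0.05))
        b = miettinen_n(DesignSpec(p_b=0.05, p_c=0.15))
        assert a == b

    def test_no_effect_rejected(self):
        with pytest.raises(ValueError):
            miettinen_n(DesignSpec(p_b=0.1, p_c=0.1))


class TestBennettUnderwood:
    def test_power_brackets_target_at_minimum_n(self):
        spec = DesignSpec(p_b=0.1667, p_c=0.0333)
        assert bu_power(spec, 70) >= 0.8
        assert bu_power(spec, 70) == pytest.approx(0.8026, abs=5e-4)
        assert bu_power(spec, 69) < 0.8

    @pytest.mark.parametrize("pb,pc,expected", [
        (0.1667, 0.0333, 70),
        (0.15, 0.05, 124),
        (0.12, 0.08, 773),
        (0.4, 0.2, 93),
    ])
    def test_minimum_n_anchors(self, pb, pc, expected):
        assert bu_n(DesignSpec(p_b=pb, p_c=pc)) == expected

    def test_null_noncentrality_gives_double_alpha_tail(self):
        # lambda = 0 reduces to the central chi-square beyond its 1-2a quantile
        spec = DesignSpec(p_b=0.1, p_c=0.1, alpha=0.05)
        assert bu_power(spec, 50) == pytest.approx(0.10, abs=1e-9)

    def test_power_increasing_in_n(self):
        spec = DesignSpec(p_b=0.15, p_c=0.05)
        powers = [bu_power(spec, N) for N in range(10, 200, 10)]
        assert all(p1 < p2 for p1, p2 in zip(powers, powers[1:]))


class TestExact:
    @pytest.mark.parametrize("pb,pc,expected", [
        (0.1667, 0.0333, 75),
        (0.4, 0.2, 99),
    ])
    def test_minimum_n_anchors(self, pb, pc, expected):
        assert exact_n(DesignSpec(p_b=pb, p_c=pc)) == expected

    def test_tiny_design_near_zero_power(self):
        spec = DesignSpec(p_b=0.001, p_c=0.01)
        assert exact_power(spec, 1) < 0.02

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            exact_power(DesignSpec(p_b=0.11, p_c=0.1), 10**6)

    def test_brute_force_oracle_small_n(self):
        # independent enumeration over (n_D, c) using scipy's binomtest
        spec = DesignSpec(p_b=0.1, p_c=0.3, alpha=0.05)
        N = 12
        pD = spec.p_D
        p_dom = max(spec.p_b, spec.p_c) / pD
        expected = 0.0
        for n_d in range(1, N + 1):
            w = stats.binom.pmf(n_d, N, pD)
            for c in range(n_d + 1):
                if stats.binomtest(c, n_d, 0.5, alternative="greater").pvalue <= 0.05:
                    expected += w * stats.binom.pmf(c, n_d, p_dom)
        assert exact_power(spec, N) == pytest.approx(expected, abs=1e-12)


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.15, 0.6), st.floats(0.05, 0.45))
    def test_required_n_decreases_with_imbalance(self, psi, frac):
        # fixed psi, growing |p_c - p_b|
        delta_small = psi * frac / 2
        delta_large = psi * min(frac + 0.3, 0.9) / 2
        n_small = miettinen_n(DesignSpec(p_b=psi / 2 - delta_small,
                                         p_c=psi / 2 + delta_small))
        n_large = miettinen_n(DesignSpec(p_b=psi / 2 - delta_large,
                                         p_c=psi / 2 + delta_large))
        assert n_large <= n_small

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(1.3, 6.0), st.floats(0.15, 0.5))
    def test_required_n_decreases_as_pd_grows(self, OR, pD):
        n1 = miettinen_n(DesignSpec.from_or_pd(OR, pD))
        n2 = miettinen_n(DesignSpec.from_or_pd(OR, min(pD + 0.2, 0.9)))
        assert n2 <= n1

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(1.2, 8.0), st.floats(0.1, 0.7),
           st.floats(0.01, 0.1), st.floats(0.5, 0.95))
    def test_closed_form_inverts_power(self, OR, pD, alpha, target):
        spec = DesignSpec.from_or_pd(OR, pD, alpha=alpha, target_power=target)
        N = miettinen_n(spec)
        assert miettinen_power(spec, N) >= target
        if N > 1:
            assert miettinen_power(spec, N - 1) < target

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.floats(1.5, 6.0), st.floats(0.2, 0.6))
    def test_bu_inversion_consistent(self, OR, pD):
        spec = DesignSpec.from_or_pd(OR, pD)
        N = bu_n(spec)
        assert bu_power(spec, N) >= spec.target_power
        if N > 1:
            assert bu_power(spec, N - 1) < spec.target_power


def test_sample_size_grid_layout():
    df = sample_size_grid(methods=("miettinen",))
    assert len(df) == 25
    row = df[(df.p_D == 0.2) & (df.OR == 5)].iloc[0]
    assert (row.p_b, row.p_c) == (0.1667, 0.0333)
    assert row.N_miettinen == 59
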