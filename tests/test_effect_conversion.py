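"""Conversion of reported statistics to Cohen's d, checked against
independently coded textbook formulas and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from capsmeta.effect_conversion import (
    convert_effect_input,
    d_between,
    d_from_f,
    d_from_p,
    d_from_r,
    d_from_t,
    d_within,
    p_of_d,
    r_of_d,
    select_timepoint,
)
from capsmeta.evidence_model import EffectInput, StatisticKind, ValidationError


def smd_reference(m_e, m_c, sd_e, sd_c, n_e, n_c):
    """Textbook standardized mean difference, coded independently."""
    pooled_var = ((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / (n_e + n_c - 2)
    d = (m_e - m_c) / math.sqrt(pooled_var)
    var = (n_e + n_c) / (n_e * n_c) + d**2 / (2 * (n_e + n_c))
    return d, var


class TestBetween:
    def test_hand_computed_example(self):
        est = d_between(10, 8, 2, 2, 20, 20)
        assert est.d == pytest.approx(1.0, abs=1e-12)
        assert est.var_d == pytest.approx(0.1125, abs=1e-12)

    def test_equal_means_give_zero(self):
        assert d_between(5, 5, 1, 3, 10, 10).d == 0.0

    def test_matches_independent_reference_on_random_inputs(self, rng):
        for _ in range(200):
            m_e, m_c = rng.normal(0, 5, 2)
            sd_e, sd_c = rng.uniform(0.2, 4, 2)
            n_e, n_c = rng.integers(5, 200, 2)
            est = d_between(m_e, m_c, sd_e, sd_c, int(n_e), int(n_c))
            d_ref, v_ref = smd_reference(m_e, m_c, sd_e, sd_c, int(n_e), int(n_c))
            assert est.d == pytest.approx(d_ref, rel=1e-12)
            assert est.var_d == pytest.approx(v_ref, rel=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            d_between(1, 0, 0, 1, 10, 10)

    def test_hedges_flag_shrinks_d(self):
        plain = d_between(10, 8, 2, 2, 10, 10)
        g = d_between(10, 8, 2, 2, 10, 10, hedges_g=True)
        assert 0 < g.d < plain.d
        assert g.d == pytest.approx(plain.d * (1 - 3 / (4 * 18 - 1)), rel=1e-12)


class TestWithin:
    def test_equal_sds_r_half_collapses_to_sd(self):
        # denominator sqrt(2(1-r)) * SD = SD at r = 0.5
        assert d_within(12, 10, 4, 4, 0.5, 30).d == pytest.approx(0.5, abs=1e-12)

    def test_equal_means_give_zero(self):
        assert d_within(7, 7, 2, 3, 0.3, 15).d == 0.0

    def test_strictly_increasing_in_r(self):
        ds = [d_within(1.0, 0.0, 1.5, 1.5, r, 25).d for r in (0.3, 0.5, 0.7)]
        assert ds[0] < ds[1] < ds[2]

    def test_variance_is_paired_design_form(self):
        est = d_within(1, 0, 1, 1, 0.5, 20)
        expected = (1 / 20 + est.d**2 / 40) * 2 * 0.5
        assert est.var_d == pytest.approx(expected, rel=1e-12)


class TestFromTestStatistics:
    def test_t_zero_gives_zero(self):
        assert d_from_t(0, 12, 15).d == 0.0

    def test_t_hand_value(self):
        assert d_from_t(2, 20, 20).d == pytest.approx(2 * math.sqrt(0.1), rel=1e-12)

    def test_t_route_equals_means_route(self, rng):
        """t computed from group summaries reproduces d_between exactly."""
        for _ in range(300):
            m_e, m_c = rng.normal(0, 3, 2)
            sd = rng.uniform(0.3, 3)
            n_e, n_c = (int(x) for x in rng.integers(5, 100, 2))
            d_ref, v_ref = smd_reference(m_e, m_c, sd, sd, n_e, n_c)
            sd_p = math.sqrt(((n_e - 1) + (n_c - 1)) / (n_e + n_c - 2)) * sd
            t = (m_e - m_c) / (sd_p * math.sqrt(1 / n_e + 1 / n_c))
            est = d_from_t(t, n_e, n_c)
            assert est.d == pytest.approx(d_ref, rel=1e-12, abs=1e-12)
            assert est.var_d == pytest.approx(v_ref, rel=1e-12)

    def test_f_is_squared_t(self, rng):
        for _ in range(300):
            t = float(rng.normal(0, 3))
            n_e, n_c = (int(x) for x in rng.integers(5, 100, 2))
            dt = d_from_t(t, n_e, n_c)
            df = d_from_f(t**2, n_e, n_c, "+" if t >= 0 else "-")
            assert abs(df.d) == pytest.approx(abs(dt.d), rel=1e-12, abs=1e-12)
            assert df.d == pytest.approx(dt.d, rel=1e-12, abs=1e-12)

    def test_f_hand_value_with_sign(self):
        assert d_from_f(4, 20, 20, "+").d == pytest.approx(0.6324555, abs=1e-6)
        assert d_from_f(4, 20, 20, "-").d == pytest.approx(-0.6324555, abs=1e-6)

    def test_f_zero_gives_zero(self):
        assert d_from_f(0, 10, 10, "0").d == 0.0

    def test_f_sign_required_when_nonzero(self):
        with pytest.raises(ValidationError):
            d_from_f(3.0, 10, 10, "0")


class TestFromCorrelation:
    def test_r_zero_gives_zero(self):
        assert d_from_r(0.0, 30).d == 0.0

    def test_closed_form(self):
        assert d_from_r(0.6, 100).d == pytest.approx(1.5, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-0.95, 0.95), st.integers(4, 1000))
    def test_round_trip_r_d_r(self, r, n):
        assert r_of_d(d_from_r(r, n).d) == pytest.approx(r, abs=1e-12)


class TestFromP:
    def test_conservative_p_one_is_exact_zero(self):
        assert d_from_p(1.0, 25, 30, "0").d == 0.0

    def test_inversion_recovers_d(self, rng):
        """p computed from a known d via the exact t inverse round-trips."""
        for _ in range(100):
            n_e, n_c = (int(x) for x in rng.integers(5, 80, 2))
            d_true = float(rng.normal(0, 1.2))
            t = d_true / math.sqrt(1 / n_e + 1 / n_c)
            p = 2 * stats.t.sf(abs(t), df=n_e + n_c - 2)
            if p >= 1.0:
                continue
            est = d_from_p(p, n_e, n_c, "+" if d_true >= 0 else "-")
            assert est.d == pytest.approx(d_true, abs=1e-9)

    def test_quantile_lookup(self):
        est = d_from_p(0.05, 30, 30, "+")
        expected = stats.t.ppf(0.975, df=58) * math.sqrt(2 / 30)
        assert est.d == pytest.approx(expected, rel=1e-12)

    def test_direction_zero_with_small_p_rejected(self):
        with pytest.raises(ValidationError, match="unrecoverable"):
            d_from_p(0.01, 20, 20, "0")


class TestPofD:
    def test_null_effect_p_is_one(self):
        from conftest import make_est

        assert p_of_d(make_est(0.0, 0.05)) == pytest.approx(1.0)

    def test_critical_value(self):
        from conftest import make_est

        se = 0.2
        assert p_of_d(make_est(1.959964 * se, se**2)) == pytest.approx(0.05, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 5), st.floats(0.01, 5))
    def test_monotone_decreasing_in_abs_d(self, d, extra):
        from conftest import make_est

        assert p_of_d(make_est(d + extra, 0.04)) <= p_of_d(make_est(d, 0.04))


class TestTimepointSelection:
    def _inp(self, tp):
        return EffectInput(statistic_kind=StatisticKind.T_STAT, t=1.0,
                           n_e=10, n_c=10, timepoint_minutes=tp)

    def test_picks_most_immediate(self):
        cands = [self._inp(120), self._inp(15), self._inp(60)]
        assert select_timepoint(cands).timepoint_minutes == 15

    def test_single_candidate(self):
        c = self._inp(45)
        assert select_timepoint([c]) is c

    def test_tie_breaks_by_input_order(self):
        a, b = self._inp(30), self._inp(30)
        picked = select_timepoint([a, b])
        assert picked is a

    def test_all_missing_raises(self):
        with pytest.raises(ValidationError, match="manual"):
            select_timepoint([self._inp(None), self._inp(None)])


def test_dispatch_covers_every_kind(rng):
    inputs = [
        EffectInput(statistic_kind=StatisticKind.MEANS_BETWEEN, m_e=1, m_c=0,
                    sd_e=1, sd_c=1, n_e=20, n_c=20),
        EffectInput(statistic_kind=StatisticKind.MEANS_WITHIN, m_t1=1, m_t2=0,
                    sd_t1=1, sd_t2=1, n=20),
        EffectInput(statistic_kind=StatisticKind.T_STAT, t=2, n_e=20, n_c=20),
        EffectInput(statistic_kind=StatisticKind.F_STAT, f=4, n_e=20, n_c=20,
                    direction="+"),
        EffectInput(statistic_kind=StatisticKind.CORRELATION, r=0.3, n=40),
        EffectInput(statistic_kind=StatisticKind.REGRESSION, r=0.2, n=40),
        EffectInput(statistic_kind=StatisticKind.P_ONLY, p=1.0, n_e=20, n_c=20,
                    direction="0"),
    ]
    for inp in inputs:
        est = convert_effect_input(inp, sample_id="s", study_id="x")
        assert est.var_d > 0
        assert est.sample_id == "s"
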