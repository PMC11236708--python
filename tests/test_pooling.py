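"""Pooling models: aggregation, random effects, multilevel, heterogeneity."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsmeta.evidence_model import ModelType, ValidationError
from capsmeta.pooling import (
    PoolingSpec,
    Tau2Estimator,
    aggregate_within_sample,
    choose_model,
    fit_multilevel,
    fit_random_effects,
    heterogeneity_stats,
    pool_auto,
)
from conftest import make_est


def fixed_effect_reference(ds, vs):
    """Closed-form inverse-variance combination, coded independently."""
    w = [1 / v for v in vs]
    mu = sum(wi * di for wi, di in zip(w, ds)) / sum(w)
    return mu, 1 / sum(w)


class TestHeterogeneity:
    def test_two_point_hand_example(self, two_symmetric_estimates):
        Q, p_Q, I2 = heterogeneity_stats(two_symmetric_estimates)
        assert Q == pytest.approx(2.0, abs=1e-12)
        assert I2 == pytest.approx(50.0, abs=1e-9)

    def test_homogeneous_inputs(self):
        ests = [make_est(0.4, 0.02, f"s{i}") for i in range(6)]
        Q, p_Q, I2 = heterogeneity_stats(ests)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert I2 == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.001, 2)),
                    min_size=2, max_size=15))
    def test_i2_bounded(self, pairs):
        ests = [make_est(d, v, f"s{i}") for i, (d, v) in enumerate(pairs)]
        _, p_Q, I2 = heterogeneity_stats(ests)
        assert 0.0 <= I2 <= 100.0
        assert 0.0 <= p_Q <= 1.0


class TestRandomEffects:
    def test_dl_two_point_oracle(self, two_symmetric_estimates):
        res = fit_random_effects(two_symmetric_estimates,
                                 PoolingSpec(tau2_estimator="DL"))
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.Q == pytest.approx(2.0, abs=1e-12)
        assert res.tau2 == pytest.approx(0.04, abs=1e-12)
        assert res.I2 == pytest.approx(50.0, abs=1e-9)

    def test_identical_estimates_collapse(self):
        ests = [make_est(0.35, 0.03, f"s{i}") for i in range(4)]
        res = fit_random_effects(ests)
        assert res.estimate == pytest.approx(0.35, abs=1e-10)
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_tau2_zero_equals_fixed_effect(self):
        ests = [make_est(0.4 + 0.001 * i, 0.05 + 0.01 * i, f"s{i}") for i in range(5)]
        res = fit_random_effects(ests)
        mu_fe, _ = fixed_effect_reference([e.d for e in ests], [e.var_d for e in ests])
        # near-homogeneous data: REML tau2 -> 0 and the mean matches FE
        assert res.tau2 < 1e-6
        assert res.estimate == pytest.approx(mu_fe, abs=1e-4)

    def test_min_k_refusal_names_rule(self):
        with pytest.raises(ValidationError, match="at least 2"):
            fit_random_effects([make_est(0.2, 0.04)])

    def test_order_invariance(self, rng):
        ests = [make_est(float(d), float(v), f"s{i}") for i, (d, v) in
                enumerate(zip(rng.normal(0.3, 0.4, 10), rng.uniform(0.01, 0.2, 10)))]
        a = fit_random_effects(ests)
        b = fit_random_effects(list(reversed(ests)))
        # agreement to the REML optimizer's own tolerance
        assert a.estimate == pytest.approx(b.estimate, abs=1e-7)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-7)

    def test_ci_width_shrinks_with_homogeneous_studies(self):
        widths = []
        for k in (3, 6, 12, 24):
            ests = [make_est(0.4, 0.04, f"s{i}") for i in range(k)]
            res = fit_random_effects(ests)
            widths.append(res.ci_high - res.ci_low)
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_dl_and_reml_agree_at_large_k(self, rng):
        theta = rng.normal(0.5, 0.2, 400)
        v = rng.uniform(0.02, 0.08, 400)
        ests = [make_est(float(rng.normal(t, math.sqrt(vi))), float(vi), f"s{i}")
                for i, (t, vi) in enumerate(zip(theta, v))]
        reml = fit_random_effects(ests, PoolingSpec(tau2_estimator="REML"))
        dl = fit_random_effects(ests, PoolingSpec(tau2_estimator="DL"))
        assert reml.tau2 == pytest.approx(dl.tau2, rel=0.15)
        assert reml.estimate == pytest.approx(dl.estimate, abs=0.01)

    def test_parameter_recovery(self, rng):
        mu, tau2 = 0.5, 0.04
        ests = []
        for i in range(500):
            v = float(rng.uniform(0.01, 0.1))
            theta = float(rng.normal(mu, math.sqrt(tau2)))
            ests.append(make_est(float(rng.normal(theta, math.sqrt(v))), v, f"s{i}"))
        res = fit_random_effects(ests)
        assert res.estimate == pytest.approx(mu, abs=0.04)
        assert res.tau2 == pytest.approx(tau2, rel=0.20)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_reml_matches_metafor_cross_check():
    """Independent oracle: the R metafor engine on a fixed heterogeneous set."""
    y = [0.10, 0.55, -0.20, 0.80, 0.35, 0.60, -0.05, 0.45]
    v = [0.04, 0.02, 0.06, 0.03, 0.05, 0.02, 0.07, 0.03]
    script = (
        "suppressMessages(library(metafor));"
        f"y<-c({','.join(map(str, y))}); v<-c({','.join(map(str, v))});"
        "r<-rma(yi=y,vi=v,method='REML');"
        "cat(sprintf('%.10f %.10f', r$beta, r$tau2))"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True).stdout.split()
    mu_ref, tau2_ref = float(out[0]), float(out[1])
    res = fit_random_effects([make_est(d, vi, f"s{i}")
                              for i, (d, vi) in enumerate(zip(y, v))])
    assert res.estimate == pytest.approx(mu_ref, abs=1e-6)
    assert res.tau2 == pytest.approx(tau2_ref, abs=1e-6)


class TestAggregation:
    def test_symmetric_mean(self):
        ests = [make_est(0.4, 0.05, "one"), make_est(0.6, 0.05, "one")]
        assert aggregate_within_sample(ests).d == pytest.approx(0.5, abs=1e-12)

    def test_compound_symmetry_variance(self):
        v = 0.05
        ests = [make_est(0.4, v, "one"), make_est(0.6, v, "one")]
        agg = aggregate_within_sample(ests, rho=0.5)
        assert agg.var_d == pytest.approx(0.75 * v, rel=1e-12)

    def test_rho_zero_reduces_to_independent_combination(self, rng):
        ds = rng.normal(0.3, 0.2, 4)
        vs = rng.uniform(0.02, 0.1, 4)
        ests = [make_est(float(d), float(v), "one") for d, v in zip(ds, vs)]
        agg = aggregate_within_sample(ests, rho=0.0)
        mu_ref, var_ref = fixed_effect_reference(list(ds), list(vs))
        assert agg.d == pytest.approx(mu_ref, rel=1e-12)
        assert agg.var_d == pytest.approx(var_ref, rel=1e-12)

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValidationError, match="single sample"):
            aggregate_within_sample([make_est(0.1, 0.05, "a"),
                                     make_est(0.2, 0.05, "b")])


class TestMultilevel:
    def test_singleton_clusters_delegate_to_random_effects(self, rng):
        ests = [make_est(float(d), float(v), f"s{i}") for i, (d, v) in
                enumerate(zip(rng.normal(0.4, 0.3, 8), rng.uniform(0.02, 0.1, 8)))]
        ml = fit_multilevel(ests)
        re = fit_random_effects(ests)
        assert ml.estimate == pytest.approx(re.estimate, abs=1e-8)
        assert ml.tau2 == pytest.approx(re.tau2, abs=1e-8)

    def test_component_recovery(self, rng):
        """40 clusters x 3 estimates; variance components within MC tolerance."""
        mu, s2b, s2w = 0.3, 0.05, 0.02
        mus, bs, ws = [], [], []
        for rep in range(10):
            ests = []
            for c in range(40):
                b = rng.normal(0, math.sqrt(s2b))
                for j in range(3):
                    w = rng.normal(0, math.sqrt(s2w))
                    n = int(rng.integers(50, 200))
                    v = 4.0 / n
                    ests.append(make_est(float(rng.normal(mu + b + w, math.sqrt(v))),
                                         v, f"c{c}"))
            res = fit_multilevel(ests)
            mus.append(res.estimate)
            bs.append(res.sigma2_between)
            ws.append(res.sigma2_within)
        assert np.mean(mus) == pytest.approx(mu, abs=0.04)
        assert np.mean(bs) == pytest.approx(s2b, abs=0.016)
        assert np.mean(ws) == pytest.approx(s2w, abs=0.007)

    def test_restricted_likelihood_is_maximal_at_fit(self, rng):
        from capsmeta.pooling import _cluster_index, _neg_reml_3level

        ests = []
        for c in range(15):
            b = rng.normal(0, 0.2)
            for j in range(3):
                ests.append(make_est(float(rng.normal(0.3 + b, 0.25)), 0.04, f"c{c}"))
        res = fit_multilevel(ests)
        d = np.array([e.d for e in ests])
        v = np.array([e.var_d for e in ests])
        clusters = _cluster_index(ests)
        at_opt = _neg_reml_3level(np.array([res.sigma2_between, res.sigma2_within]),
                                  d, v, clusters)
        for fb, fw in [(1.2, 1.0), (0.8, 1.0), (1.0, 1.2), (1.0, 0.8)]:
            perturbed = _neg_reml_3level(
                np.array([res.sigma2_between * fb + 1e-6,
                          res.sigma2_within * fw + 1e-6]), d, v, clusters)
            assert perturbed >= at_opt - 1e-9


class TestModelChoice:
    def test_distinct_samples_random_effects(self):
        ests = [make_est(0.1, 0.05, s) for s in ("a", "b", "c")]
        assert choose_model(ests) is ModelType.RANDOM_EFFECTS

    def test_mixture_multilevel(self):
        ests = [make_est(0.1, 0.05, s) for s in ("a", "a", "b", "b")]
        assert choose_model(ests) is ModelType.MULTILEVEL

    def test_single_sample_aggregation(self):
        ests = [make_est(0.1, 0.05, "a"), make_est(0.3, 0.05, "a")]
        assert choose_model(ests) is ModelType.AGGREGATION

    def test_pool_auto_routes_by_layout(self):
        same = [make_est(0.4, 0.05, "a"), make_est(0.6, 0.05, "a")]
        res = pool_auto(same)
        assert res.model_type is ModelType.AGGREGATION
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
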