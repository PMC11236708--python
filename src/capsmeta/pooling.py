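"""Pooling models: within-sample aggregation, random effects, and three-level.

Three model classes cover the dependence structures in the evidence base:

- *aggregation* — several estimates from the same participant sample are
  combined into one, with a compound-symmetry correlation ``rho`` between
  them (default 0.5) inflating the aggregate's variance;
- *random effects* — independent estimates pooled under the normal-normal
  model ``d_i ~ N(mu, v_i + tau^2)``, with tau^2 by REML (default) or
  DerSimonian-Laird;
- *multilevel* — a three-level model for a mixture of independent and
  same-sample estimates, with separate between-cluster and within-cluster
  variance components, both fitted by restricted maximum likelihood.

Heterogeneity is summarized by Cochran's Q, its chi-square p-value, and
I^2 = max(0, (Q - df)/Q) * 100; I^2 above 30 is read as moderate and above
50 as substantial heterogeneity.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .evidence_model import EffectEstimate, MetaResult, ModelType, ValidationError

__all__ = [
    "Tau2Estimator",
    "PoolingSpec",
    "aggregate_within_sample",
    "fit_random_effects",
    "fit_multilevel",
    "heterogeneity_stats",
    "choose_model",
    "pool_auto",
]

logger = logging.getLogger(__name__)


class Tau2Estimator(str, enum.Enum):
    REML = "REML"
    DL = "DL"


@dataclass(frozen=True)
class PoolingSpec:
    """Configuration of a pooling run."""

    model_type: Optional[ModelType] = None  # None = choose from sample layout
    tau2_estimator: Tau2Estimator = Tau2Estimator.REML
    within_sample_rho: float = 0.5
    min_k: int = 2
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.within_sample_rho < 1:
            raise ValidationError("within_sample_rho must lie in [0, 1)")
        if self.min_k < 2:
            raise ValidationError("min_k must be >= 2")
        object.__setattr__(self, "tau2_estimator", Tau2Estimator(self.tau2_estimator))


def _arrays(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([e.d for e in estimates], dtype=float)
    v = np.array([e.var_d for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise ValidationError("all sampling variances must be positive")
    return d, v


def heterogeneity_stats(
    estimates: Sequence[EffectEstimate], pooled: Optional[float] = None
) -> tuple[float, float, float]:
    """Cochran's Q, its p-value against chi-square(k-1), and I^2 in percent.

    Q is computed about the fixed-effect inverse-variance mean regardless of
    the pooling model, matching the conventional definition.
    """
    d, v = _arrays(estimates)
    k = len(d)
    if k < 2:
        raise ValidationError("heterogeneity requires k >= 2")
    w = 1.0 / v
    mu_fe = np.sum(w * d) / np.sum(w)
    Q = float(np.sum(w * (d - mu_fe) ** 2))
    p_Q = float(stats.chi2.sf(Q, df=k - 1))
    I2 = 0.0 if Q <= 0 else max(0.0, (Q - (k - 1)) / Q) * 100.0
    return Q, p_Q, I2


def _tau2_dl(d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu_fe = np.sum(w * d) / np.sum(w)
    Q = np.sum(w * (d - mu_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (Q - (len(d) - 1)) / denom))


def _neg_restricted_ll(tau2: float, d: np.ndarray, v: np.ndarray) -> float:
    wi = 1.0 / (v + tau2)
    mu = np.sum(wi * d) / np.sum(wi)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + np.log(np.sum(wi)) + np.sum(wi * (d - mu) ** 2)
    )


def _tau2_reml(d: np.ndarray, v: np.ndarray) -> float:
    # bounded scalar search; upper bound covers tau^2 well beyond both the
    # largest sampling variance and the raw dispersion of the estimates
    upper = 10.0 * (np.max(v) + (np.var(d, ddof=1) if len(d) > 1 else 0.0)) + 1e-8
    try:
        res = optimize.minimize_scalar(
            _neg_restricted_ll, args=(d, v), bounds=(0.0, upper),
            method="bounded", options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(res.message)
        return float(res.x)
    except Exception as exc:  # pragma: no cover - scipy failure is exotic
        logger.warning("REML optimization failed (%s); falling back to DL", exc)
        return _tau2_dl(d, v)


def fit_random_effects(
    estimates: Sequence[EffectEstimate], spec: PoolingSpec = PoolingSpec()
) -> MetaResult:
    """Random-effects pooling of independent effect estimates.

    tau^2 is estimated by the estimator in ``spec`` (REML default, DL closed
    form), the pooled mean is the inverse-variance weighted average with
    weights ``1/(v_i + tau^2)``, and inference uses Wald normal intervals.
    """
    if len(estimates) < spec.min_k:
        raise ValidationError(
            f"pooling requires at least {spec.min_k} estimates, got {len(estimates)}"
        )
    d, v = _arrays(estimates)
    if spec.tau2_estimator is Tau2Estimator.DL:
        tau2 = _tau2_dl(d, v)
    else:
        tau2 = _tau2_reml(d, v)
    return _wald_result(d, v, tau2, ModelType.RANDOM_EFFECTS, estimates, spec)


def _wald_result(
    d: np.ndarray, v: np.ndarray, tau2: float, model_type: ModelType,
    estimates: Sequence[EffectEstimate], spec: PoolingSpec,
    sigma2_between: Optional[float] = None, sigma2_within: Optional[float] = None,
) -> MetaResult:
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * d) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    zc = stats.norm.ppf(0.5 + spec.level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(mu) / se)) if se > 0 else 0.0
    Q, p_Q, I2 = heterogeneity_stats(estimates)
    return MetaResult(
        estimate=mu, ci_low=mu - zc * se, ci_high=mu + zc * se, se=se,
        p_value=p, k=len(d), tau2=tau2, Q=Q, I2=I2, p_Q=p_Q,
        model_type=model_type,
        sigma2_between=sigma2_between, sigma2_within=sigma2_within,
    )


def aggregate_within_sample(
    estimates: Sequence[EffectEstimate], rho: float = 0.5
) -> EffectEstimate:
    """Collapse several same-sample estimates into one.

    The aggregate is the inverse-variance weighted mean; its variance is the
    full quadratic form under a compound-symmetry correlation ``rho`` between
    every pair of constituent estimates, so for k equal-variance estimates it
    is ``v (1 + (k-1) rho) / k`` — larger than the naive independent value
    whenever rho > 0.
    """
    if len(estimates) < 2:
        raise ValidationError("aggregation requires k >= 2 same-sample estimates")
    sample_ids = {e.sample_id for e in estimates}
    if len(sample_ids) != 1:
        raise ValidationError(f"aggregation requires a single sample_id, got {sorted(sample_ids)}")
    if not 0 <= rho < 1:
        raise ValidationError("rho must lie in [0, 1)")
    d, v = _arrays(estimates)
    se = np.sqrt(v)
    w = 1.0 / v
    wsum = np.sum(w)
    d_agg = float(np.sum(w * d) / wsum)
    cov = rho * np.outer(se, se)
    np.fill_diagonal(cov, v)
    var_agg = float(w @ cov @ w / wsum**2)
    first = estimates[0]
    return EffectEstimate(
        d=d_agg, var_d=var_agg,
        n_effective=max(e.n_effective for e in estimates),
        sample_id=first.sample_id, design=first.design,
        predictor_class=first.predictor_class, symptom_profile=first.symptom_profile,
        study_id=first.study_id,
    )


# ---------------------------------------------------------------------------
# Three-level model

def _cluster_index(estimates: Sequence[EffectEstimate]) -> list[np.ndarray]:
    order: dict[str, list[int]] = {}
    for i, e in enumerate(estimates):
        order.setdefault(e.sample_id, []).append(i)
    return [np.array(ix) for ix in order.values()]


def _neg_reml_3level(
    params: np.ndarray, d: np.ndarray, v: np.ndarray, clusters: list[np.ndarray]
) -> float:
    """-2x restricted log-likelihood (up to a constant) of the three-level model.

    Within cluster j the marginal covariance is
    ``V_j = diag(v_ij + s2w) + s2b * 11'``; Sherman-Morrison keeps the
    per-cluster algebra O(size).
    """
    s2b, s2w = params
    logdet = 0.0
    xtvx = 0.0  # 1' V^-1 1 accumulated over clusters
    xtvy = 0.0
    ytvy = 0.0
    for ix in clusters:
        dj = d[ix]
        a = v[ix] + s2w  # diagonal part
        ai = 1.0 / a
        c = 1.0 + s2b * np.sum(ai)
        logdet += np.sum(np.log(a)) + np.log(c)
        # V^-1 x for x: ai*x - s2b * ai * (ai.x) / c
        one_vi = ai - s2b * ai * np.sum(ai) / c
        y_vi = ai * dj - s2b * ai * np.sum(ai * dj) / c
        xtvx += np.sum(one_vi)
        xtvy += np.sum(y_vi)
        ytvy += float(dj @ y_vi)
    mu = xtvy / xtvx
    quad = ytvy - 2.0 * mu * xtvy + mu * mu * xtvx
    return 0.5 * (logdet + math.log(xtvx) + quad)


def fit_multilevel(
    estimates: Sequence[EffectEstimate], spec: PoolingSpec = PoolingSpec()
) -> MetaResult:
    """Three-level random-effects pooling for clustered (same-sample) estimates.

    Random intercepts at the sample (cluster) level and at the estimate level
    give variance components ``sigma2_between`` and ``sigma2_within``; their
    sum plays the role of tau^2.  Components are fitted by restricted maximum
    likelihood over a bounded region with a deterministic start at the DL
    estimate split evenly.  When every cluster has a single estimate the
    layout carries no within/between information and the fit delegates to
    :func:`fit_random_effects`.
    """
    if len(estimates) < spec.min_k:
        raise ValidationError(
            f"pooling requires at least {spec.min_k} estimates, got {len(estimates)}"
        )
    clusters = _cluster_index(estimates)
    if len(clusters) < 2:
        raise ValidationError("multilevel pooling requires >= 2 clusters")
    if all(len(ix) == 1 for ix in clusters):
        logger.info("every cluster has size 1; delegating to the random-effects model")
        return fit_random_effects(estimates, spec)

    d, v = _arrays(estimates)
    tau2_0 = _tau2_dl(d, v)
    upper = 10.0 * (np.max(v) + (np.var(d, ddof=1) if len(d) > 1 else 0.0)) + 1e-8
    x0 = np.array([max(tau2_0 / 2.0, 1e-6), max(tau2_0 / 2.0, 1e-6)])
    res = optimize.minimize(
        _neg_reml_3level, x0, args=(d, v, clusters), method="L-BFGS-B",
        bounds=[(0.0, upper), (0.0, upper)],
    )
    if not res.success:
        logger.warning("three-level REML did not converge (%s); using best iterate", res.message)
    s2b, s2w = float(res.x[0]), float(res.x[1])

    # GLS fixed effect under the fitted covariance
    xtvx = 0.0
    xtvy = 0.0
    for ix in clusters:
        a = v[ix] + s2w
        ai = 1.0 / a
        c = 1.0 + s2b * np.sum(ai)
        one_vi = ai - s2b * ai * np.sum(ai) / c
        y_vi = ai * d[ix] - s2b * ai * np.sum(ai * d[ix]) / c
        xtvx += np.sum(one_vi)
        xtvy += np.sum(y_vi)
    mu = xtvy / xtvx
    se = math.sqrt(1.0 / xtvx)
    zc = stats.norm.ppf(0.5 + spec.level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(mu) / se))
    Q, p_Q, I2 = heterogeneity_stats(estimates)
    return MetaResult(
        estimate=float(mu), ci_low=float(mu - zc * se), ci_high=float(mu + zc * se),
        se=se, p_value=p, k=len(d), tau2=s2b + s2w, Q=Q, I2=I2, p_Q=p_Q,
        model_type=ModelType.MULTILEVEL, sigma2_between=s2b, sigma2_within=s2w,
    )


def choose_model(estimates: Sequence[EffectEstimate]) -> ModelType:
    """Pick the pooling model from the sample layout.

    One shared sample -> aggregation; all distinct samples -> random effects;
    a mixture -> multilevel.
    """
    ids = [e.sample_id for e in estimates]
    unique = set(ids)
    if len(unique) == 1:
        return ModelType.AGGREGATION
    if len(unique) == len(ids):
        return ModelType.RANDOM_EFFECTS
    return ModelType.MULTILEVEL


def pool_auto(
    estimates: Sequence[EffectEstimate], spec: PoolingSpec = PoolingSpec()
) -> MetaResult:
    """Pool with the model chosen by :func:`choose_model` (or forced by spec).

    Aggregation collapses the same-sample set to one estimate and reports it
    as a k-estimate result with the compound-symmetry variance; heterogeneity
    statistics are still computed across the constituent estimates.
    """
    model = spec.model_type or choose_model(estimates)
    if model is ModelType.AGGREGATION:
        agg = aggregate_within_sample(estimates, spec.within_sample_rho)
        zc = stats.norm.ppf(0.5 + spec.level / 2.0)
        se = agg.se_d
        Q, p_Q, I2 = heterogeneity_stats(estimates)
        return MetaResult(
            estimate=agg.d, ci_low=agg.d - zc * se, ci_high=agg.d + zc * se, se=se,
            p_value=float(2.0 * stats.norm.sf(abs(agg.d) / se)),
            k=len(estimates), tau2=0.0, Q=Q, I2=I2, p_Q=p_Q,
            model_type=ModelType.AGGREGATION,
        )
    if model is ModelType.MULTILEVEL:
        return fit_multilevel(estimates, spec)
    return fit_random_effects(estimates, spec)
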