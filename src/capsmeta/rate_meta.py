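"""Per-study CAPS rates, exact binomial intervals, pooling, and Peters' test.

A rate record is a count of cannabis-exposed individuals reporting
psychotic symptoms out of the exposed sample, R = X/N, with an exact
Clopper-Pearson confidence interval.  Rates are pooled with the same
random-effects machinery as effect sizes, either on the raw proportion
scale (default; symmetric CIs) or on the logit scale with a 1/2 continuity
correction (back-transformed bounds always inside (0, 1)).  Small-study
bias in rate models is probed with Peters' regression of the log-odds on
1/N, weighted by N p (1 - p).
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .evidence_model import (
    BiasReport,
    EffectEstimate,
    MetaResult,
    ModelType,
    RateRecord,
    ValidationError,
)
from .pooling import PoolingSpec, fit_multilevel, fit_random_effects, pool_auto

__all__ = [
    "clopper_pearson_ci",
    "make_rate_record",
    "pool_rates",
    "peters_test",
    "MIN_K_PETERS",
]

logger = logging.getLogger(__name__)

#: minimum model size for asymmetry testing (same rule as Egger's test)
MIN_K_PETERS = 6


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval by inverting the binomial test (beta quantiles).

    The lower bound is 0 when x = 0 and the upper bound is 1 when x = n.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValidationError(f"x={x} must lie in [0, n={n}]")
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    low, high = proportion_confint(x, n, alpha=1.0 - level, method="beta")
    # statsmodels returns NaN at the boundaries; the exact interval is closed there
    low = 0.0 if x == 0 or math.isnan(low) else float(low)
    high = 1.0 if x == n or math.isnan(high) else float(high)
    return low, high


def make_rate_record(
    x: int, n: int, level: float = 0.95, *,
    sample_id: str = "", design=None, symptom_profile=None, study_id: str = "",
) -> RateRecord:
    """Build a :class:`RateRecord` with rate x/n and its exact interval."""
    low, high = clopper_pearson_ci(x, n, level)
    return RateRecord(
        x_caps=x, n_exposed=n, rate=x / n, ci_low=low, ci_high=high, level=level,
        sample_id=sample_id, design=design, symptom_profile=symptom_profile,
        study_id=study_id,
    )


def _rate_to_effect(rec: RateRecord, scale: str) -> EffectEstimate:
    x, n = rec.x_caps, rec.n_exposed
    if scale == "logit":
        # 1/2 continuity correction keeps boundary counts finite
        y = math.log((x + 0.5) / (n - x + 0.5))
        v = 1.0 / (x + 0.5) + 1.0 / (n - x + 0.5)
    elif scale == "raw":
        p = x / n
        # clamp keeps the analytic variance positive at boundary counts
        p_v = min(max(p, 1.0 / (4 * n)), 1.0 - 1.0 / (4 * n))
        y = p
        v = p_v * (1.0 - p_v) / n
    else:
        raise ValidationError(f"scale must be 'raw' or 'logit', got {scale!r}")
    return EffectEstimate(
        d=y, var_d=v, n_effective=n, sample_id=rec.sample_id or rec.study_id or str(id(rec)),
        design=rec.design, symptom_profile=rec.symptom_profile, study_id=rec.study_id,
    )


def pool_rates(
    records: Sequence[RateRecord],
    scale: str = "raw",
    multilevel: bool = False,
    spec: PoolingSpec = PoolingSpec(),
) -> MetaResult:
    """Pool per-study rates into one random-effects estimate on the rate scale.

    Each record contributes its (possibly transformed) rate and an analytic
    sampling variance — p(1-p)/n on the raw scale, the continuity-corrected
    log-odds variance on the logit scale.  ``multilevel=True`` fits the
    three-level model over sample_id clusters.  The result is returned on
    the proportion scale; logit-scale estimates and bounds are inverse-logit
    transformed, so they always land inside (0, 1).
    """
    if len(records) < spec.min_k:
        raise ValidationError(f"pooling requires at least {spec.min_k} rate records")
    effects = [_rate_to_effect(r, scale) for r in records]
    if multilevel:
        if any(not r.sample_id for r in records):
            raise ValidationError("multilevel rate pooling requires sample_id on every record")
        res = fit_multilevel(effects, spec)
    elif len({e.sample_id for e in effects}) == 1 and len(effects) > 1:
        warnings.warn(
            "all rate records share one sample; aggregating instead of "
            "treating them as independent",
            stacklevel=2,
        )
        res = pool_auto(effects, spec)
    else:
        res = fit_random_effects(effects, spec)
    if scale == "logit":
        est, lo, hi = (float(expit(z)) for z in (res.estimate, res.ci_low, res.ci_high))
        res = MetaResult(
            estimate=est, ci_low=lo, ci_high=hi, se=res.se, p_value=res.p_value,
            k=res.k, tau2=res.tau2, Q=res.Q, I2=res.I2, p_Q=res.p_Q,
            model_type=res.model_type, sigma2_between=res.sigma2_between,
            sigma2_within=res.sigma2_within, label=res.label,
        )
    return res


def peters_test(records: Sequence[RateRecord]) -> BiasReport:
    """Peters' regression test for small-study effects in rate models.

    Weighted linear regression of the log-odds of each study's rate on 1/N,
    with weights N p (1 - p); counts at the boundaries get a 1/2 continuity
    correction.  A significant slope indicates that small studies report
    systematically different rates.  Requires at least six estimates, the
    same minimum as Egger's test.
    """
    k = len(records)
    if k < MIN_K_PETERS:
        raise ValidationError(
            f"insufficient estimates for Peters' test: k={k} < {MIN_K_PETERS}"
        )
    x = np.array([r.x_caps for r in records], dtype=float)
    n = np.array([r.n_exposed for r in records], dtype=float)
    inv_n = 1.0 / n
    if np.ptp(inv_n) <= 0:
        raise ValidationError("constant 1/n across records: Peters' design is singular")
    boundary = (x == 0) | (x == n)
    xc = np.where(boundary, x + 0.5, x)
    nc = np.where(boundary, n + 1.0, n)
    log_odds = np.log(xc / (nc - xc))
    p_hat = xc / nc
    weights = n * p_hat * (1.0 - p_hat)
    design = sm.add_constant(inv_n)
    fit = sm.WLS(log_odds, design, weights=weights).fit()
    return BiasReport(test_name="peters", p_bias=float(fit.pvalues[1]),
                      slope=float(fit.params[1]))
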