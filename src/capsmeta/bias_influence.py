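"""Publication-bias and influence diagnostics for effect-size models.

Covers Egger's regression test for funnel-plot asymmetry (only for models
with at least six estimates), the Duval-Tweedie trim-and-fill adjustment
(applied when Egger's p < 0.05), leave-one-out refits, and an outlier rule
that flags studies whose confidence interval falls entirely outside the
pooled interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .evidence_model import BiasReport, EffectEstimate, MetaResult, ValidationError
from .pooling import PoolingSpec, fit_random_effects

__all__ = [
    "MIN_K_EGGER",
    "egger_test",
    "trim_and_fill",
    "leave_one_out",
    "LeaveOneOutResult",
    "find_outliers",
    "OutlierReport",
]

logger = logging.getLogger(__name__)

MIN_K_EGGER = 6


def egger_test(estimates: Sequence[EffectEstimate]) -> BiasReport:
    """Egger's regression test for funnel-plot asymmetry.

    Regresses the standardized effect ``d_i / se_i`` on precision
    ``1 / se_i``; the intercept captures asymmetry (small imprecise studies
    drifting away from the common effect) and its two-sided p-value is the
    test.  This is algebraically the weighted regression of d on se with
    weights 1/v.  Refuses models with fewer than six estimates.
    """
    k = len(estimates)
    if k < MIN_K_EGGER:
        raise ValidationError(
            f"Egger's test needs at least {MIN_K_EGGER} effect estimates, got {k}"
        )
    d = np.array([e.d for e in estimates])
    se = np.array([e.se_d for e in estimates])
    if np.ptp(se) <= 0:
        raise ValidationError("constant standard errors: Egger's design is singular")
    z = d / se
    precision = 1.0 / se
    fit = sm.OLS(z, sm.add_constant(precision)).fit()
    # params[0] is the asymmetry intercept; its sign points to the side of excess
    return BiasReport(test_name="egger", p_bias=float(fit.pvalues[0]),
                      slope=float(fit.params[0]))


def _trimmed_center(d: np.ndarray, v: np.ndarray, k0: int, spec: PoolingSpec) -> float:
    keep = np.argsort(d)[: len(d) - k0] if k0 > 0 else np.arange(len(d))
    w = 1.0 / (v[keep])
    return float(np.sum(w * d[keep]) / np.sum(w))


def _estimate_k0(d: np.ndarray, center: float, estimator: str) -> int:
    """Rank-based estimators of the number of studies suppressed on the left.

    Left-side suppression leaves an excess of large positive deviations, so
    the Wilcoxon-type rank sum of positive deviations exceeds its null mean
    n(n+1)/4 and L0 comes out positive.
    """
    dev = d - center
    ranks = stats.rankdata(np.abs(dev))
    k = len(d)
    if estimator == "L0":
        t_sum = float(np.sum(ranks[dev > 0]))
        k0 = (4.0 * t_sum - k * (k + 1.0)) / (2.0 * k - 1.0)
        return max(0, int(round(k0)))
    if estimator == "R0":
        # length of the run of positive deviations among the largest |dev|
        order = np.argsort(ranks)  # ascending |dev|
        gamma = 0
        for idx in order[::-1]:
            if dev[idx] > 0:
                gamma += 1
            else:
                break
        return max(0, gamma - 1)
    raise ValidationError(f"estimator must be 'L0' or 'R0', got {estimator!r}")


def trim_and_fill(
    estimates: Sequence[EffectEstimate],
    side: str = "auto",
    estimator: str = "L0",
    spec: PoolingSpec = PoolingSpec(),
    max_iter: int = 50,
) -> BiasReport:
    """Duval-Tweedie trim-and-fill adjustment for one-sided suppression.

    Iteratively trims the most extreme studies on the asymmetric side,
    re-estimates the center, and re-counts the suppressed studies (L0 rank
    estimator by default, R0 available) until the count stabilizes; then
    fills mirror-image counterparts about the center and refits the
    random-effects model on observed + filled studies.

    ``side`` is where the *missing* studies lie: 'left' (suppressed negative
    effects), 'right', or 'auto', which takes the side opposite the sign of
    the Egger asymmetry when k allows the test, falling back to the skew of
    the estimates around their fixed-effect mean.
    """
    if len(estimates) < 3:
        raise ValidationError("trim-and-fill requires k >= 3")
    d0 = np.array([e.d for e in estimates])
    v0 = np.array([e.var_d for e in estimates])
    if side == "auto":
        if len(estimates) >= MIN_K_EGGER:
            asym = egger_test(estimates).slope
        else:
            w = 1.0 / v0
            asym = float(np.mean(d0 - np.sum(w * d0) / np.sum(w)))
        side = "left" if asym > 0 else "right"
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'auto', 'left' or 'right', got {side!r}")

    # canonical orientation: missing studies on the left (trim the rightmost,
    # fill their mirror images on the left)
    flip = -1.0 if side == "right" else 1.0
    d = flip * d0
    v = v0.copy()

    k0 = 0
    for it in range(max_iter):
        center = _trimmed_center(d, v, k0, spec)
        k0_new = min(_estimate_k0(d, center, estimator), len(d) - 1)
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(
            f"trim-and-fill did not stabilize after {max_iter} iterations "
            f"(last k0={k0}, side={side}, estimator={estimator})"
        )

    unadjusted = fit_random_effects(list(estimates), spec)
    if k0 == 0:
        return BiasReport(test_name="egger", p_bias=float("nan"),
                          applied_trim_fill=True, n_imputed=0, adjusted=unadjusted)

    center = _trimmed_center(d, v, k0, spec)
    order = np.argsort(d)
    fill_ix = order[-k0:]  # mirror the k0 most extreme right-side studies
    filled = [
        EffectEstimate(
            d=flip * (2.0 * center - d[i]), var_d=float(v[i]),
            n_effective=estimates[i].n_effective, sample_id=f"__filled_{j}",
            predictor_class=estimates[i].predictor_class,
        )
        for j, i in enumerate(fill_ix)
    ]
    adjusted = fit_random_effects(list(estimates) + filled, spec)
    return BiasReport(test_name="egger", p_bias=float("nan"),
                      applied_trim_fill=True, n_imputed=int(k0), adjusted=adjusted)


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_index: int
    omitted_study_id: str
    result: MetaResult


def leave_one_out(
    estimates: Sequence[EffectEstimate], spec: PoolingSpec = PoolingSpec()
) -> list[LeaveOneOutResult]:
    """Refit the pooled model k times, omitting each estimate in turn."""
    k = len(estimates)
    if k < 3:
        raise ValidationError(
            "leave-one-out requires k >= 3 (each refit must keep at least two estimates)"
        )
    out = []
    for i in range(k):
        rest = [e for j, e in enumerate(estimates) if j != i]
        out.append(LeaveOneOutResult(
            omitted_index=i, omitted_study_id=estimates[i].study_id,
            result=fit_random_effects(rest, spec),
        ))
    return out


@dataclass(frozen=True)
class OutlierReport:
    flagged_indices: list[int]
    flagged: list[EffectEstimate]
    repooled: MetaResult


def find_outliers(
    estimates: Sequence[EffectEstimate],
    pooled: MetaResult,
    spec: PoolingSpec = PoolingSpec(),
    level: float = 0.95,
) -> OutlierReport:
    """Flag studies that deviate from the pooled estimate and re-pool without them.

    A study is an outlier when its own confidence interval lies entirely
    outside the pooled estimate's interval (no overlap on either side).
    The re-pooled result omits the flagged studies; when fewer than two
    studies remain, or nothing is flagged, the original result is returned.
    """
    zc = stats.norm.ppf(0.5 + level / 2.0)
    flagged_ix = [
        i for i, e in enumerate(estimates)
        if e.d - zc * e.se_d > pooled.ci_high or e.d + zc * e.se_d < pooled.ci_low
    ]
    rest = [e for i, e in enumerate(estimates) if i not in set(flagged_ix)]
    if flagged_ix and len(rest) >= spec.min_k:
        repooled = fit_random_effects(rest, spec)
    else:
        repooled = pooled
    return OutlierReport(
        flagged_indices=flagged_ix,
        flagged=[estimates[i] for i in flagged_ix],
        repooled=repooled,
    )
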