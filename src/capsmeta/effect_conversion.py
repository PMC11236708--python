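"""Conversion of heterogeneous reported statistics into Cohen's d.

Every converter returns an :class:`~capsmeta.evidence_model.EffectEstimate`
carrying both the standardized mean difference ``d`` and its sampling
variance ``var_d``, so the pooling machinery can weight it by inverse
variance.  Sign convention throughout: positive d means more CAPS under the
exposure or condition of interest.

Supported inputs and formulas
-----------------------------
between-subject means   d = (M_E - M_C) / SD_P  with the Cohen pooled SD
within-subject means    d = (M_T1 - M_T2) / sqrt(SD1^2 + SD2^2 - 2 r SD1 SD2)
t statistic             d = t * sqrt(1/n_E + 1/n_C)
F statistic (1 df)      |d| = sqrt(F) * sqrt(1/n_E + 1/n_C), signed externally
correlation             d = 2r / sqrt(1 - r^2)
p-value only            invert the two-sided two-sample t-test; the
                        conservative convention maps "not significant,
                        no further data" to P = 1 and hence d = 0

Within-subject conversions default to a pre/post correlation of r = 0.5,
the analysis-wide convention; sensitivity reruns pass r = 0.3 or 0.7.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from scipy import stats

from .evidence_model import (
    Design,
    EffectEstimate,
    EffectInput,
    StatisticKind,
    SymptomProfile,
    ValidationError,
)

__all__ = [
    "DEFAULT_WITHIN_R",
    "d_between",
    "d_within",
    "d_from_t",
    "d_from_f",
    "d_from_r",
    "d_from_p",
    "p_of_d",
    "select_timepoint",
    "convert_effect_input",
]

#: analysis-wide pre/post correlation assumed for paired designs
DEFAULT_WITHIN_R = 0.5


def _two_group_var(d: float, n_e: int, n_c: int) -> float:
    return (n_e + n_c) / (n_e * n_c) + d * d / (2.0 * (n_e + n_c))


def _hedges_j(df: float) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _labels(kw: dict) -> dict:
    return {
        k: kw[k]
        for k in ("sample_id", "design", "predictor_class", "symptom_profile", "study_id")
        if k in kw
    }


def d_between(
    m_e: float, m_c: float, sd_e: float, sd_c: float, n_e: int, n_c: int,
    *, hedges_g: bool = False, **labels,
) -> EffectEstimate:
    """Standardized mean difference for two independent groups.

    Uses the Cohen pooled standard deviation
    ``SD_P = sqrt(((n_E-1) SD_E^2 + (n_C-1) SD_C^2) / (n_E + n_C - 2))``
    and variance ``(n_E + n_C)/(n_E n_C) + d^2 / (2 (n_E + n_C))``.
    ``hedges_g=True`` applies the small-sample correction J(df); off by
    default since the common metric here is Cohen's d.
    """
    if sd_e <= 0 or sd_c <= 0:
        raise ValidationError("standard deviations must be positive")
    if n_e < 2 or n_c < 2:
        raise ValidationError("group sizes must be >= 2")
    sd_p = math.sqrt(((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / (n_e + n_c - 2))
    d = (m_e - m_c) / sd_p
    if hedges_g:
        d *= _hedges_j(n_e + n_c - 2)
    return EffectEstimate(d=d, var_d=_two_group_var(d, n_e, n_c),
                          n_effective=n_e + n_c, **_labels(labels))


def d_within(
    m_t1: float, m_t2: float, sd_t1: float, sd_t2: float,
    r: float = DEFAULT_WITHIN_R, n: int = None,
    *, hedges_g: bool = False, **labels,
) -> EffectEstimate:
    """Standardized change for a paired (pre/post) comparison.

    The denominator is the SD of the difference score,
    ``sqrt(SD1^2 + SD2^2 - 2 r SD1 SD2)``, so d grows with the pre/post
    correlation r when SDs are equal.  Variance is the paired-design form
    ``(1/n + d^2/(2n)) * 2(1 - r)``.
    """
    if sd_t1 <= 0 or sd_t2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if n is None or n < 2:
        raise ValidationError("n must be >= 2")
    if not -1 < r < 1:
        raise ValidationError(f"|r| must be < 1, got {r}")
    denom_sq = sd_t1**2 + sd_t2**2 - 2.0 * r * sd_t1 * sd_t2
    if denom_sq <= 0:
        raise ValidationError("difference-score variance is non-positive")
    d = (m_t1 - m_t2) / math.sqrt(denom_sq)
    if hedges_g:
        d *= _hedges_j(n - 1)
    var_d = (1.0 / n + d * d / (2.0 * n)) * 2.0 * (1.0 - r)
    return EffectEstimate(d=d, var_d=var_d, n_effective=n, **_labels(labels))


def d_from_t(t: float, n_e: int, n_c: int, **labels) -> EffectEstimate:
    """d from a two-sample t statistic: ``d = t sqrt(1/n_E + 1/n_C)``."""
    if n_e < 2 or n_c < 2:
        raise ValidationError("group sizes must be >= 2")
    d = t * math.sqrt(1.0 / n_e + 1.0 / n_c)
    return EffectEstimate(d=d, var_d=_two_group_var(d, n_e, n_c),
                          n_effective=n_e + n_c, **_labels(labels))


def d_from_f(f: float, n_e: int, n_c: int, direction: str, **labels) -> EffectEstimate:
    """d from a one-numerator-df F statistic (two-group ANOVA), F = t^2.

    F carries no sign, so ``direction`` ('+', '-', or '0') is mandatory;
    '0' is accepted only at F = 0.
    """
    if f < 0:
        raise ValidationError(f"F must be >= 0, got {f}")
    if direction not in ("+", "-", "0"):
        raise ValidationError(f"direction must be one of +, -, 0, got {direction!r}")
    if direction == "0" and f > 0:
        raise ValidationError("direction '0' is only valid at F = 0; the sign is unrecoverable")
    sign = -1.0 if direction == "-" else 1.0
    return d_from_t(sign * math.sqrt(f), n_e, n_c, **labels)


def d_from_r(r: float, n: int, **labels) -> EffectEstimate:
    """d from a (point-biserial) correlation: ``d = 2r / sqrt(1 - r^2)``.

    Variance follows by the delta method from var(r) = (1 - r^2)^2 / (n - 1):
    ``var_d = 4 var(r) / (1 - r^2)^3``.
    """
    if not -1 < r < 1:
        raise ValidationError(f"|r| must be < 1, got {r}")
    if n < 4:
        raise ValidationError("n must be >= 4")
    one_minus = 1.0 - r * r
    d = 2.0 * r / math.sqrt(one_minus)
    var_r = one_minus**2 / (n - 1)
    var_d = 4.0 * var_r / one_minus**3
    return EffectEstimate(d=d, var_d=var_d, n_effective=n, **_labels(labels))


def r_of_d(d: float) -> float:
    """Inverse of :func:`d_from_r`'s point transform (round-trip helper)."""
    return d / math.sqrt(d * d + 4.0)


def d_from_p(p: float, n_e: int, n_c: int, direction: str, **labels) -> EffectEstimate:
    """d recovered by inverting a two-sided two-sample t-test at the reported p.

    |t| is the ``1 - p/2`` quantile of the central t with ``n_E + n_C - 2``
    degrees of freedom, then d follows as for a reported t.  The conservative
    non-significance convention P = 1 yields d = 0 exactly.  A direction of
    '0' is rejected for p < 1: the sign cannot be fabricated.
    """
    if not 0 < p <= 1:
        raise ValidationError(f"p must lie in (0, 1], got {p}")
    if direction not in ("+", "-", "0"):
        raise ValidationError(f"direction must be one of +, -, 0, got {direction!r}")
    if p == 1.0:
        return d_from_t(0.0, n_e, n_c, **labels)
    if direction == "0":
        raise ValidationError("direction '0' with p < 1: sign unrecoverable, supply + or -")
    sign = -1.0 if direction == "-" else 1.0
    # isf(p/2) rather than ppf(1 - p/2): exact for very small p
    t_abs = stats.t.isf(p / 2.0, df=n_e + n_c - 2)
    return d_from_t(sign * t_abs, n_e, n_c, **labels)


def p_of_d(estimate: EffectEstimate) -> float:
    """Two-sided p-value of d against zero under a normal reference."""
    z = abs(estimate.d) / estimate.se_d
    return 2.0 * stats.norm.sf(z)


def select_timepoint(candidates: Sequence[EffectInput]) -> EffectInput:
    """Pick the assessment closest in time to THC administration.

    Among candidates carrying ``timepoint_minutes``, returns the one with
    the smallest value; ties break by input order.  If no candidate has a
    timepoint the choice cannot be automated and an error says so.
    """
    timed = [c for c in candidates if c.timepoint_minutes is not None]
    if not timed:
        raise ValidationError(
            "no candidate carries timepoint_minutes; select the immediate "
            "post-administration assessment manually"
        )
    return min(timed, key=lambda c: c.timepoint_minutes)


def convert_effect_input(
    inp: EffectInput,
    within_r: float = DEFAULT_WITHIN_R,
    *, hedges_g: bool = False, **labels,
) -> EffectEstimate:
    """Dispatch an :class:`EffectInput` to the matching converter.

    ``within_r`` overrides the paired correlation for within-subject inputs
    unless the row itself recorded ``r_within``.  Regression inputs are
    routed through the correlation transform, assuming the coefficient was
    standardized upstream.
    """
    kind = inp.statistic_kind
    if kind is StatisticKind.MEANS_BETWEEN:
        return d_between(inp.m_e, inp.m_c, inp.sd_e, inp.sd_c, inp.n_e, inp.n_c,
                         hedges_g=hedges_g, **labels)
    if kind is StatisticKind.MEANS_WITHIN:
        r = inp.r_within if inp.r_within is not None else within_r
        return d_within(inp.m_t1, inp.m_t2, inp.sd_t1, inp.sd_t2, r, inp.n,
                        hedges_g=hedges_g, **labels)
    if kind is StatisticKind.T_STAT:
        return d_from_t(inp.t, inp.n_e, inp.n_c, **labels)
    if kind is StatisticKind.F_STAT:
        return d_from_f(inp.f, inp.n_e, inp.n_c, inp.direction, **labels)
    if kind in (StatisticKind.CORRELATION, StatisticKind.REGRESSION):
        return d_from_r(inp.r, inp.n, **labels)
    if kind is StatisticKind.P_ONLY:
        return d_from_p(inp.p, inp.n_e, inp.n_c, inp.direction, **labels)
    raise ValidationError(f"unsupported statistic kind: {kind}")
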