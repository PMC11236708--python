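"""End-to-end synthesis: rates by design, effects by predictor class,
publication-bias and influence diagnostics, within-subject-correlation
sensitivity, and cross-design triangulation.

Every function is a pure function of (evidence rows, configuration): the
same inputs give identical outputs.  Rows that cannot be used are never
silently dropped — conversion failures land in a row-addressed rejection
log, and classes with a single estimate are reported unpooled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias_influence import (
    MIN_K_EGGER,
    OutlierReport,
    egger_test,
    find_outliers,
    leave_one_out,
    trim_and_fill,
)
from .effect_conversion import DEFAULT_WITHIN_R, convert_effect_input, p_of_d
from .evidence_model import (
    BiasReport,
    Design,
    EffectEstimate,
    EvidenceRow,
    MetaResult,
    SymptomProfile,
    ValidationError,
)
from .pooling import PoolingSpec, choose_model, pool_auto
from .rate_meta import MIN_K_PETERS, peters_test, pool_rates

__all__ = [
    "SynthesisConfig",
    "StratumResult",
    "ClassResult",
    "run_rate_synthesis",
    "run_effect_synthesis",
    "sensitivity_over_r",
    "triangulate_by_design",
    "concordance_check",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

BIAS_ALPHA = 0.05  # trim-and-fill trigger: asymmetry test p below this


@dataclass(frozen=True)
class SynthesisConfig:
    """Pipeline-wide settings."""

    pooling: PoolingSpec = field(default_factory=PoolingSpec)
    rate_scale: str = "raw"
    within_r: float = DEFAULT_WITHIN_R
    run_diagnostics: bool = True
    hedges_g: bool = False


@dataclass(frozen=True)
class StratumResult:
    """Pooled rates for one design x symptom-profile stratum."""

    design: Optional[Design]
    symptom_profile: Optional[SymptomProfile]
    result: MetaResult
    bias: Optional[BiasReport] = None
    trimfill: Optional[BiasReport] = None


@dataclass(frozen=True)
class ClassResult:
    """Everything computed for one predictor class."""

    predictor_class: str
    estimates: list[EffectEstimate]
    result: Optional[MetaResult]  # None when unpooled (k < 2)
    unpooled: Optional[EffectEstimate] = None
    bias: Optional[BiasReport] = None
    trimfill: Optional[BiasReport] = None
    loo_range: Optional[tuple[float, float]] = None
    outliers: Optional[OutlierReport] = None
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (study_id, reason)


def run_rate_synthesis(
    rows: Sequence[EvidenceRow], config: SynthesisConfig = SynthesisConfig()
) -> list[StratumResult]:
    """Pool CAPS rates per design, plus full-episode rates across designs.

    Within each design all rate rows are pooled (multilevel when samples
    repeat); full-episode rows are additionally pooled across the three
    designs.  Peters' test runs on every stratum with at least six
    estimates, and a significant result (p < 0.05) triggers trim-and-fill.
    Strata with fewer than two records are skipped with a log entry.
    """
    rate_rows = [r for r in rows if r.rate is not None]
    out: list[StratumResult] = []
    strata: list[tuple[Optional[Design], Optional[SymptomProfile], list[EvidenceRow]]] = []
    for design in Design:
        # per-design strata cover intoxication-level symptom profiles;
        # full-blown episodes are a separate, rarer outcome pooled below
        sub = [r for r in rate_rows if r.study.design is design
               and r.study.symptom_profile is not SymptomProfile.FULL_EPISODE]
        if sub:
            strata.append((design, None, sub))
    full = [r for r in rate_rows if r.study.symptom_profile is SymptomProfile.FULL_EPISODE]
    if full:
        strata.append((None, SymptomProfile.FULL_EPISODE, full))
    for design, profile, sub in strata:
        if len(sub) < config.pooling.min_k:
            logger.info("stratum (%s, %s) has %d record(s); skipped", design, profile, len(sub))
            continue
        records = [r.rate for r in sub]
        multilevel = len({r.study.sample_id for r in sub}) < len(sub)
        result = pool_rates(records, scale=config.rate_scale,
                            multilevel=multilevel, spec=config.pooling)
        bias = trimfill = None
        if config.run_diagnostics and len(records) >= MIN_K_PETERS:
            try:
                bias = peters_test(records)
            except ValidationError as exc:
                logger.info("Peters' test skipped for (%s, %s): %s", design, profile, exc)
            if bias is not None and bias.p_bias < BIAS_ALPHA:
                from .rate_meta import _rate_to_effect

                effects = [_rate_to_effect(r, config.rate_scale) for r in records]
                trimfill = trim_and_fill(effects, spec=config.pooling)
        out.append(StratumResult(design=design, symptom_profile=profile,
                                 result=result, bias=bias, trimfill=trimfill))
    return out


def _convert_rows(
    rows: Sequence[EvidenceRow], config: SynthesisConfig, within_r: float
) -> tuple[list[EffectEstimate], list[tuple[str, str]]]:
    estimates: list[EffectEstimate] = []
    rejected: list[tuple[str, str]] = []
    for row in rows:
        try:
            estimates.append(convert_effect_input(
                row.effect, within_r=within_r, hedges_g=config.hedges_g,
                sample_id=row.study.sample_id, design=row.study.design,
                predictor_class=row.study.predictor_class,
                symptom_profile=row.study.symptom_profile,
                study_id=row.study.study_id,
            ))
        except ValidationError as exc:
            logger.warning("row %s rejected: %s", row.study.study_id, exc)
            rejected.append((row.study.study_id, str(exc)))
    return estimates, rejected


def run_effect_synthesis(
    rows: Sequence[EvidenceRow],
    config: SynthesisConfig = SynthesisConfig(),
    within_r: Optional[float] = None,
) -> list[ClassResult]:
    """Convert and pool effect estimates per predictor class.

    Per class: convert each row to Cohen's d, choose the pooling model from
    the sample layout, pool, then (when diagnostics are on) Egger's test at
    k >= 6, trim-and-fill at p_Egger < 0.05, leave-one-out, and the outlier
    re-pool.  Classes with one usable estimate are reported unpooled.
    """
    within_r = config.within_r if within_r is None else within_r
    eff_rows = [r for r in rows if r.effect is not None]
    classes: dict[str, list[EvidenceRow]] = {}
    for row in eff_rows:
        classes.setdefault(row.study.predictor_class, []).append(row)
    out: list[ClassResult] = []
    for cls in sorted(classes):
        sub = classes[cls]
        estimates, rejected = _convert_rows(sub, config, within_r)
        if len(estimates) == 0:
            out.append(ClassResult(cls, [], None, rejected=rejected))
            continue
        if len(estimates) < config.pooling.min_k:
            out.append(ClassResult(cls, estimates, None, unpooled=estimates[0],
                                   rejected=rejected))
            continue
        result = pool_auto(estimates, config.pooling)
        bias = trimfill = None
        loo_range = None
        outliers = None
        if config.run_diagnostics:
            if len(estimates) >= MIN_K_EGGER:
                try:
                    bias = egger_test(estimates)
                except ValidationError as exc:
                    logger.info("Egger skipped for %s: %s", cls, exc)
                if bias is not None and bias.p_bias < BIAS_ALPHA:
                    trimfill = trim_and_fill(estimates, spec=config.pooling)
            if len(estimates) >= 3:
                loo = leave_one_out(estimates, config.pooling)
                vals = [lr.result.estimate for lr in loo]
                loo_range = (min(vals), max(vals))
                outliers = find_outliers(estimates, result, config.pooling)
        out.append(ClassResult(cls, estimates, result, bias=bias, trimfill=trimfill,
                               loo_range=loo_range, outliers=outliers, rejected=rejected))
    return out


def sensitivity_over_r(
    rows: Sequence[EvidenceRow],
    r_values: Sequence[float] = (0.3, 0.5, 0.7),
    config: SynthesisConfig = SynthesisConfig(),
) -> pd.DataFrame:
    """Re-run the effect synthesis at several within-subject correlations.

    Only within-subject conversions depend on r, so classes without paired
    inputs are identical across columns.  Returns a table with one row per
    predictor class, the pooled d at each r, and the maximum absolute
    deviation across r values as a concordance summary.
    """
    cfg = replace(config, run_diagnostics=False)
    tables = {r: {c.predictor_class: c for c in run_effect_synthesis(rows, cfg, within_r=r)}
              for r in r_values}
    all_classes = sorted({cls for tab in tables.values() for cls in tab})
    recs = []
    for cls in all_classes:
        rec: dict = {"predictor_class": cls}
        vals = []
        for r in r_values:
            c = tables[r].get(cls)
            val = (c.result.estimate if c is not None and c.result is not None
                   else (c.unpooled.d if c is not None and c.unpooled is not None else np.nan))
            rec[f"d_r{r:g}"] = val
            vals.append(val)
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        rec["max_abs_deviation"] = (max(vals) - min(vals)) if vals else np.nan
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclass(frozen=True)
class TriangulationResult:
    predictor_class: str
    per_design: dict
    sign_concordant: bool


def triangulate_by_design(
    rows: Sequence[EvidenceRow],
    predictor_class: str,
    config: SynthesisConfig = SynthesisConfig(),
) -> TriangulationResult:
    """Pool one predictor class separately per study design and compare signs.

    Requires the class to appear in at least two designs with at least two
    estimates each; the verdict is sign-concordant iff every per-design
    pooled estimate has the same sign.
    """
    eff_rows = [r for r in rows
                if r.effect is not None and r.study.predictor_class == predictor_class]
    by_design: dict[Design, list[EvidenceRow]] = {}
    for row in eff_rows:
        by_design.setdefault(row.study.design, []).append(row)
    per_design: dict[Design, MetaResult] = {}
    for design, sub in by_design.items():
        estimates, _ = _convert_rows(sub, config, config.within_r)
        if len(estimates) >= config.pooling.min_k:
            per_design[design] = pool_auto(estimates, config.pooling)
    if len(per_design) < 2:
        raise ValidationError(
            f"triangulation of {predictor_class!r} needs >= 2 designs with "
            f">= {config.pooling.min_k} estimates each; found {len(per_design)}"
        )
    signs = {math.copysign(1.0, res.estimate) for res in per_design.values()}
    return TriangulationResult(
        predictor_class=predictor_class, per_design=per_design,
        sign_concordant=(len(signs) == 1),
    )


def concordance_check(
    converted_p: Sequence[float], reported_p: Sequence[float]
) -> float:
    """Pearson correlation between converted-d p-values and reported p-values.

    Pairs with a missing reported p are excluded pairwise.  A high
    correlation indicates the conversion to a common metric preserved the
    studies' significance information.
    """
    a = np.asarray(converted_p, dtype=float)
    b = np.asarray(reported_p, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("p-value vectors must be paired (same length)")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValidationError("concordance needs at least 3 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("zero variance in a p-value vector: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def results_to_frame(results: Sequence[ClassResult], adjust_p: bool = False) -> pd.DataFrame:
    """Flatten class results into a tidy table (one row per predictor class).

    p-values are reported uncorrected for multiple testing; ``adjust_p=True``
    adds a Benjamini-Hochberg ``p_bh`` column over the pooled models.
    """
    recs = []
    for c in results:
        rec: dict = {"predictor_class": c.predictor_class,
                     "k": len(c.estimates), "n_rejected": len(c.rejected)}
        if c.result is not None:
            r = c.result
            rec.update(d=r.estimate, ci_low=r.ci_low, ci_high=r.ci_high,
                       p_value=r.p_value, tau2=r.tau2, I2=r.I2,
                       model=r.model_type.value)
        elif c.unpooled is not None:
            rec.update(d=c.unpooled.d, model="unpooled_single")
        if c.bias is not None:
            rec["p_egger"] = c.bias.p_bias
        if c.trimfill is not None and c.trimfill.adjusted is not None:
            rec["d_trimfill"] = c.trimfill.adjusted.estimate
            rec["n_imputed"] = c.trimfill.n_imputed
        if c.outliers is not None and c.outliers.flagged:
            rec["d_outlier_corrected"] = c.outliers.repooled.estimate
            rec["n_outliers"] = len(c.outliers.flagged)
        recs.append(rec)
    frame = pd.DataFrame(recs)
    if adjust_p and "p_value" in frame.columns:
        from statsmodels.stats.multitest import multipletests

        mask = frame["p_value"].notna()
        frame["p_bh"] = np.nan
        if mask.any():
            frame.loc[mask, "p_bh"] = multipletests(
                frame.loc[mask, "p_value"], method="fdr_bh")[1]
    return frame
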