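"""Synthetic evidence bases with known ground truth.

The generator produces study-level records with the same statistical
structure the analysis assumes of the real literature on cannabis-associated
psychotic symptoms (CAPS):

- per-design true CAPS rates with log-odds-scale between-study
  heterogeneity and binomial within-study sampling;
- heterogeneous true standardized effects per predictor class
  (``theta_i ~ N(mu, tau2)``), reported through a mixture of statistic
  types (group means/SDs, paired means, t, F, correlation, p-only);
- clustered estimates: a configurable fraction of samples contributes two
  estimates that share a sample-level random effect (intra-sample
  correlation 0.5 of the true effects, matching the aggregation model's
  rho);
- significance-censored reporting ("P > 0.05" rows collapse to the
  conservative P = 1 input);
- a publication-bias selection mechanism that retains studies with
  probability decreasing in their realized p-value.

Every generated row is paired with its ground truth (the drawn true rate
or true d), so downstream estimates can be validated against known values.
All randomness flows from the seed in :class:`SimConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .evidence_model import (
    Design,
    EffectInput,
    EvidenceRow,
    StatisticKind,
    StudyRecord,
    SymptomProfile,
    ValidationError,
)
from .rate_meta import make_rate_record

__all__ = [
    "SimConfig",
    "simulate_rate_studies",
    "simulate_effect_studies",
    "apply_publication_bias",
    "censor_nonsignificant",
    "simulate_evidence_base",
]

# Default study conditions: headline per-design rates ~19.4% (observational),
# 21% (experimental), 1.5% (medicinal), 0.52% for full-blown episodes, and
# predictor-class true effects matching the headline pooled d values.
DEFAULT_TRUE_RATES = {
    Design.OBSERVATIONAL: 0.194,
    Design.EXPERIMENTAL: 0.21,
    Design.MEDICINAL: 0.015,
}
DEFAULT_FULL_EPISODE_RATE = 0.0052
DEFAULT_TRUE_MU = {
    "THC_single_dose": 0.70,
    "THC_dose_response": 0.42,
    "medicinal_cannabis": 0.14,
    "bipolar_disorder": 0.80,
    "dopamine_activity": 0.40,
    "age": -0.20,
    "gender_female": -0.09,
}
# designs each predictor class is studied under; classes listed with several
# designs are split across them, enabling cross-design triangulation
DEFAULT_CLASS_DESIGNS = {
    "THC_single_dose": (Design.EXPERIMENTAL,),
    "THC_dose_response": (Design.EXPERIMENTAL,),
    "medicinal_cannabis": (Design.MEDICINAL,),
    "bipolar_disorder": (Design.OBSERVATIONAL,),
    "dopamine_activity": (Design.EXPERIMENTAL,),
    "age": (Design.OBSERVATIONAL, Design.EXPERIMENTAL, Design.QUASI_EXPERIMENTAL),
    "gender_female": (Design.OBSERVATIONAL, Design.EXPERIMENTAL,
                      Design.QUASI_EXPERIMENTAL),
}
DEFAULT_STATISTIC_MIX = {
    StatisticKind.MEANS_BETWEEN: 0.35,
    StatisticKind.MEANS_WITHIN: 0.25,
    StatisticKind.T_STAT: 0.15,
    StatisticKind.F_STAT: 0.05,
    StatisticKind.CORRELATION: 0.10,
    StatisticKind.P_ONLY: 0.10,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic evidence base.

    ``n_range`` holds (mean, sigma) of a log-normal for per-study sample
    sizes (log scale).  ``rate_tau`` is the SD of true logit rates across
    studies; ``tau2`` the between-study variance of true d within a
    predictor class.  ``cluster_frac`` is the fraction of samples that
    contribute two dependent estimates.  ``censor_alpha`` is the reporting
    threshold: p-only rows with realized p above it are published only as
    "not significant".  ``selection_strength`` is the slope of the logistic
    publication-selection function (0 = no selection).
    """

    seed: int = 0
    k_per_design: dict = field(default_factory=lambda: {
        Design.OBSERVATIONAL: 25, Design.EXPERIMENTAL: 15, Design.MEDICINAL: 30,
    })
    n_range: tuple[float, float] = (4.5, 0.8)
    true_rates: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    rate_tau: float = 0.6
    true_mu: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_MU))
    k_per_class: int = 12
    tau2: float = 0.04
    cluster_frac: float = 0.25
    class_designs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_DESIGNS))
    full_episode_rate: float = DEFAULT_FULL_EPISODE_RATE
    k_full_episode: int = 4  # per design
    statistic_mix: dict = field(default_factory=lambda: dict(DEFAULT_STATISTIC_MIX))
    censor_alpha: float = 1.0
    selection_strength: float = 0.0
    intra_sample_rho: float = 0.5

    def __post_init__(self) -> None:
        mix = {StatisticKind(k): float(v) for k, v in self.statistic_mix.items()}
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValidationError("statistic_mix probabilities must sum to 1")
        if self.tau2 < 0 or self.rate_tau < 0:
            raise ValidationError("variance parameters must be >= 0")
        if not 0 <= self.cluster_frac <= 1:
            raise ValidationError("cluster_frac must lie in [0, 1]")
        if not 0 < self.censor_alpha <= 1:
            raise ValidationError("censor_alpha must lie in (0, 1]")
        object.__setattr__(self, "statistic_mix", mix)
        object.__setattr__(
            self, "true_rates", {Design(k): float(v) for k, v in self.true_rates.items()}
        )


def _draw_n(rng: np.random.Generator, cfg: SimConfig, low: int = 10) -> int:
    mu, sigma = cfg.n_range
    return max(low, int(round(float(rng.lognormal(mu, sigma)))))


def simulate_rate_studies(
    cfg: SimConfig,
    symptom_profile: SymptomProfile = SymptomProfile.PSYCHOSIS_LIKE,
    id_prefix: str = "",
) -> tuple[list[EvidenceRow], pd.DataFrame]:
    """Draw per-design rate studies; returns rows plus a ground-truth table.

    For each study the true rate is a logit-normal draw around the design's
    mean with SD ``rate_tau``; the observed count is binomial at the drawn
    sample size.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[EvidenceRow] = []
    truth: list[dict] = []
    for design, k in cfg.k_per_design.items():
        design = Design(design)
        base = cfg.true_rates.get(design)
        if base is None:
            continue
        for j in range(k):
            n = _draw_n(rng, cfg)
            p_true = float(expit(rng.normal(logit(base), cfg.rate_tau)))
            x = int(rng.binomial(n, p_true))
            sid = f"{id_prefix}{design.value}_rate_{j:03d}"
            study = StudyRecord(
                study_id=sid, sample_id=sid, design=design, year=2000 + j % 24,
                n_total=n, symptom_profile=symptom_profile,
            )
            rows.append(EvidenceRow(
                study=study,
                rate=make_rate_record(x, n, sample_id=sid, design=design,
                                      symptom_profile=symptom_profile, study_id=sid),
            ))
            truth.append({"study_id": sid, "design": design.value,
                          "true_rate": p_true, "n": n, "x": x})
    return rows, pd.DataFrame(truth)


def _summaries_from_theta(
    rng: np.random.Generator, theta: float, n_e: int, n_c: int
) -> tuple[float, float, float, float]:
    """Observed group means/SDs for a standardized true difference theta.

    Population SD is 1 in both groups, so the sample statistics have the
    usual normal/chi-square sampling distributions.
    """
    m_e = float(rng.normal(theta, 1.0 / math.sqrt(n_e)))
    m_c = float(rng.normal(0.0, 1.0 / math.sqrt(n_c)))
    sd_e = float(math.sqrt(rng.chisquare(n_e - 1) / (n_e - 1)))
    sd_c = float(math.sqrt(rng.chisquare(n_c - 1) / (n_c - 1)))
    return m_e, m_c, sd_e, sd_c


def _exact_p_and_d(m_e, m_c, sd_e, sd_c, n_e, n_c) -> tuple[float, float, float]:
    """(two-sided p, t, d) of the exact two-sample t-test on the summaries."""
    sd_p = math.sqrt(((n_e - 1) * sd_e**2 + (n_c - 1) * sd_c**2) / (n_e + n_c - 2))
    t = (m_e - m_c) / (sd_p * math.sqrt(1.0 / n_e + 1.0 / n_c))
    p = float(2.0 * stats.t.sf(abs(t), df=n_e + n_c - 2))
    d = (m_e - m_c) / sd_p
    return p, t, d


def simulate_effect_studies(cfg: SimConfig) -> tuple[list[EvidenceRow], pd.DataFrame]:
    """Draw per-predictor-class effect studies with a mixture of statistic kinds.

    True effects follow ``theta ~ N(mu_class, tau2)``; clustered samples
    share a sample-level component so that same-sample thetas correlate at
    ``intra_sample_rho``.  Reported statistics (t, F, r, p) are computed
    exactly from the drawn group summaries, so conversion back to d can be
    validated row by row.  The truth table carries the true theta, the
    realized summary-level d, and the realized two-sided p of every row.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    kinds = list(cfg.statistic_mix.keys())
    probs = np.array([cfg.statistic_mix[k] for k in kinds])
    rows: list[EvidenceRow] = []
    truth: list[dict] = []
    rho = cfg.intra_sample_rho
    for cls, mu in cfg.true_mu.items():
        designs = cfg.class_designs.get(cls, (Design.OBSERVATIONAL,))
        j = 0
        while j < cfg.k_per_class:
            design = designs[j % len(designs)]
            sample_id = f"{cls}_s{j:03d}"
            clustered = bool(rng.random() < cfg.cluster_frac) and (j + 1 < cfg.k_per_class)
            n_in_sample = 2 if clustered else 1
            b = float(rng.normal(0.0, math.sqrt(cfg.tau2 * rho))) if cfg.tau2 > 0 else 0.0
            for _ in range(n_in_sample):
                w = (float(rng.normal(0.0, math.sqrt(cfg.tau2 * (1 - rho))))
                     if cfg.tau2 > 0 else 0.0)
                theta = mu + (b + w if clustered else
                              float(rng.normal(0.0, math.sqrt(cfg.tau2))) if cfg.tau2 > 0 else 0.0)
                kind = kinds[int(rng.choice(len(kinds), p=probs))]
                n_e = _draw_n(rng, cfg, low=10)
                n_c = _draw_n(rng, cfg, low=10)
                row, p_real, d_real = _make_effect_row(
                    rng, cfg, kind, theta, n_e, n_c, cls, design, sample_id, j,
                )
                rows.append(row)
                truth.append({
                    "study_id": row.study.study_id, "sample_id": sample_id,
                    "predictor_class": cls, "statistic_kind": kind.value,
                    "true_theta": theta, "realized_d": d_real, "realized_p": p_real,
                })
                j += 1
    return rows, pd.DataFrame(truth)


def _make_effect_row(
    rng, cfg, kind, theta, n_e, n_c, cls, design, sample_id, j,
) -> tuple[EvidenceRow, float, float]:
    study_id = f"{cls}_{j:03d}"
    if kind is StatisticKind.MEANS_WITHIN:
        n = n_e
        r = cfg.intra_sample_rho
        # paired difference of standardized scores: var(diff) = 2(1-r)
        diff_sd = math.sqrt(2.0 * (1.0 - r))
        m_diff = float(rng.normal(theta * diff_sd, diff_sd / math.sqrt(n)))
        sd_t1 = float(math.sqrt(rng.chisquare(n - 1) / (n - 1)))
        sd_t2 = float(math.sqrt(rng.chisquare(n - 1) / (n - 1)))
        denom = math.sqrt(max(sd_t1**2 + sd_t2**2 - 2 * r * sd_t1 * sd_t2, 1e-12))
        d_real = m_diff / denom
        t_real = d_real * math.sqrt(n)  # paired t-test on the difference scores
        p_real = float(2.0 * stats.t.sf(abs(t_real), df=n - 1))
        eff = EffectInput(
            statistic_kind=kind, m_t1=m_diff, m_t2=0.0, sd_t1=sd_t1, sd_t2=sd_t2,
            n=n, timepoint_minutes=float(rng.choice([15, 30, 60, 120])),
        )
    else:
        m_e, m_c, sd_e, sd_c = _summaries_from_theta(rng, theta, n_e, n_c)
        p_real, t_real, d_real = _exact_p_and_d(m_e, m_c, sd_e, sd_c, n_e, n_c)
        if kind is StatisticKind.MEANS_BETWEEN:
            eff = EffectInput(statistic_kind=kind, m_e=m_e, m_c=m_c,
                              sd_e=sd_e, sd_c=sd_c, n_e=n_e, n_c=n_c)
        elif kind is StatisticKind.T_STAT:
            eff = EffectInput(statistic_kind=kind, t=t_real, n_e=n_e, n_c=n_c)
        elif kind is StatisticKind.F_STAT:
            eff = EffectInput(statistic_kind=kind, f=t_real**2, n_e=n_e, n_c=n_c,
                              direction="+" if t_real >= 0 else "-")
        elif kind is StatisticKind.CORRELATION:
            r_val = d_real / math.sqrt(d_real**2 + 4.0)
            eff = EffectInput(statistic_kind=kind, r=r_val, n=n_e + n_c)
        elif kind is StatisticKind.P_ONLY:
            eff = EffectInput(statistic_kind=kind, p=max(p_real, 1e-300),
                              n_e=n_e, n_c=n_c,
                              direction="+" if t_real >= 0 else "-")
        else:
            raise ValidationError(f"unsupported kind in generator: {kind}")
    study = StudyRecord(
        study_id=study_id, sample_id=sample_id, design=design,
        year=1990 + j % 34, n_total=n_e + n_c,
        symptom_profile=SymptomProfile.PSYCHOSIS_LIKE, predictor_class=cls,
    )
    return EvidenceRow(study=study, effect=eff), p_real, d_real


def apply_publication_bias(
    rows: Sequence[EvidenceRow], truth: pd.DataFrame, cfg: SimConfig
) -> tuple[list[EvidenceRow], pd.DataFrame]:
    """Thin the evidence base by p-value-dependent selection.

    Each study is retained with probability ``min(1, 2*expit(-s*(p-0.05)))``
    — a logistic taper in the realized p with slope ``s =
    selection_strength``; s = 0 retains everything.
    """
    if cfg.selection_strength == 0:
        return list(rows), truth.copy()
    rng = np.random.default_rng(cfg.seed + 2)
    p = truth["realized_p"].to_numpy()
    keep_prob = np.minimum(1.0, 2.0 * expit(-cfg.selection_strength * (p - 0.05)))
    keep = rng.random(len(rows)) < keep_prob
    kept_rows = [r for r, k in zip(rows, keep) if k]
    return kept_rows, truth.loc[keep].reset_index(drop=True)


def censor_nonsignificant(
    rows: Sequence[EvidenceRow], truth: pd.DataFrame, cfg: SimConfig
) -> tuple[list[EvidenceRow], pd.DataFrame]:
    """Replace non-significant rows by the bare "P > alpha" report.

    Rows whose realized p exceeds ``censor_alpha`` lose their payload: all
    that survives is a p-only input with the conservative P = 1 (which
    converts to d = 0).  The truth table gains a ``censored`` flag so the
    induced attenuation can be quantified.
    """
    truth = truth.copy()
    truth["censored"] = truth["realized_p"] > cfg.censor_alpha
    out: list[EvidenceRow] = []
    for row, censored in zip(rows, truth["censored"].tolist()):
        if not censored:
            out.append(row)
            continue
        eff = row.effect
        n_e = eff.n_e if eff.n_e is not None else eff.n
        n_c = eff.n_c if eff.n_c is not None else eff.n
        out.append(replace(row, effect=EffectInput(
            statistic_kind=StatisticKind.P_ONLY, p=1.0, n_e=n_e, n_c=n_c, direction="0",
        )))
    return out, truth


def simulate_evidence_base(cfg: SimConfig) -> tuple[list[EvidenceRow], pd.DataFrame]:
    """Full generator: rate studies + effect studies, with censoring/selection.

    Returns all rows (rates first) and a concatenated truth table.
    """
    rate_rows, rate_truth = simulate_rate_studies(cfg)
    if cfg.k_full_episode > 0:
        import dataclasses

        fe_cfg = dataclasses.replace(
            cfg, seed=cfg.seed + 3,
            true_rates={d: cfg.full_episode_rate for d in cfg.true_rates},
            k_per_design={d: cfg.k_full_episode for d in cfg.k_per_design},
            n_range=(8.0, 0.7),  # full-episode rates come from large cohorts/trials
            k_full_episode=0,
        )
        fe_rows, fe_truth = simulate_rate_studies(
            fe_cfg, symptom_profile=SymptomProfile.FULL_EPISODE, id_prefix="fe_")
        rate_rows += fe_rows
        rate_truth = pd.concat([rate_truth, fe_truth], ignore_index=True)
    eff_rows, eff_truth = simulate_effect_studies(cfg)
    eff_rows, eff_truth = apply_publication_bias(eff_rows, eff_truth, cfg)
    if cfg.censor_alpha < 1.0:
        eff_rows, eff_truth = censor_nonsignificant(eff_rows, eff_truth, cfg)
    truth = pd.concat([rate_truth, eff_truth], ignore_index=True, sort=False)
    return rate_rows + eff_rows, truth
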