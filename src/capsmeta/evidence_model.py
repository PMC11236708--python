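"""Domain types and CSV I/O for the CAPS evidence base.

The evidence base is a long-format table with one row per extracted study
estimate.  A row is either a *rate* record (a count of individuals with
cannabis-associated psychotic symptoms, CAPS, out of the cannabis-exposed
sample) or an *effect* record (some reported statistic — group means and SDs,
a t or F statistic, a correlation, or a bare p-value — that downstream code
converts into Cohen's d).  Rows from the same underlying participant sample
share a ``sample_id``; that identifier, and nothing else, encodes statistical
dependence between estimates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Union

import pandas as pd

__all__ = [
    "Design",
    "SymptomProfile",
    "StatisticKind",
    "ModelType",
    "StudyRecord",
    "EffectInput",
    "EffectEstimate",
    "RateRecord",
    "MetaResult",
    "BiasReport",
    "EvidenceRow",
    "SchemaError",
    "ValidationError",
    "read_evidence_csv",
    "write_evidence_csv",
]


class SchemaError(ValueError):
    """The CSV header does not match the documented evidence schema."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


class Design(str, enum.Enum):
    OBSERVATIONAL = "observational"
    EXPERIMENTAL = "experimental"
    QUASI_EXPERIMENTAL = "quasi_experimental"
    MEDICINAL = "medicinal"


class SymptomProfile(str, enum.Enum):
    PSYCHOSIS_LIKE = "psychosis_like"
    HALLUCINATIONS = "hallucinations"
    DELUSIONS = "delusions"
    PARANOIA = "paranoia"
    FULL_EPISODE = "full_episode"


class StatisticKind(str, enum.Enum):
    MEANS_BETWEEN = "means_between"
    MEANS_WITHIN = "means_within"
    T_STAT = "t_stat"
    F_STAT = "f_stat"
    CORRELATION = "correlation"
    REGRESSION = "regression"
    P_ONLY = "p_only"


class ModelType(str, enum.Enum):
    AGGREGATION = "aggregation"
    RANDOM_EFFECTS = "random_effects"
    MULTILEVEL = "multilevel"


@dataclass(frozen=True)
class StudyRecord:
    """Bibliographic and sampling metadata shared by every estimate of a study."""

    study_id: str
    sample_id: str
    design: Design
    year: int
    n_total: int
    symptom_profile: SymptomProfile
    predictor_class: str = ""
    mean_age: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.n_total < 1:
            raise ValidationError(f"n_total must be >= 1, got {self.n_total}")
        object.__setattr__(self, "design", Design(self.design))
        object.__setattr__(self, "symptom_profile", SymptomProfile(self.symptom_profile))


@dataclass(frozen=True)
class EffectInput:
    """One study's raw reported statistic, before conversion to Cohen's d.

    Exactly the payload fields required by ``statistic_kind`` must be set:

    - ``means_between``: m_e, m_c, sd_e, sd_c, n_e, n_c
    - ``means_within``:  m_t1, m_t2, sd_t1, sd_t2, n (r_within optional;
      the analysis-wide within-subject correlation applies when absent)
    - ``t_stat``:        t, n_e, n_c
    - ``f_stat``:        f, n_e, n_c, direction
    - ``correlation`` / ``regression``: r, n
    - ``p_only``:        p, n_e, n_c, direction
    """

    statistic_kind: StatisticKind
    m_e: Optional[float] = None
    m_c: Optional[float] = None
    sd_e: Optional[float] = None
    sd_c: Optional[float] = None
    n_e: Optional[int] = None
    n_c: Optional[int] = None
    m_t1: Optional[float] = None
    m_t2: Optional[float] = None
    sd_t1: Optional[float] = None
    sd_t2: Optional[float] = None
    n: Optional[int] = None
    r_within: Optional[float] = None
    t: Optional[float] = None
    f: Optional[float] = None
    r: Optional[float] = None
    p: Optional[float] = None
    direction: Optional[str] = None
    timepoint_minutes: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "statistic_kind", StatisticKind(self.statistic_kind))
        kind = self.statistic_kind
        if kind is StatisticKind.MEANS_BETWEEN:
            self._require("m_e", "m_c", "sd_e", "sd_c", "n_e", "n_c")
            if self.sd_e <= 0 or self.sd_c <= 0:
                raise ValidationError("SDs must be positive")
            if self.n_e < 2 or self.n_c < 2:
                raise ValidationError("group sizes must be >= 2")
        elif kind is StatisticKind.MEANS_WITHIN:
            self._require("m_t1", "m_t2", "sd_t1", "sd_t2", "n")
            if self.sd_t1 <= 0 or self.sd_t2 <= 0:
                raise ValidationError("SDs must be positive")
            if self.n < 2:
                raise ValidationError("n must be >= 2")
            if self.r_within is not None and not -1 < self.r_within < 1:
                raise ValidationError("|r_within| must be < 1")
        elif kind is StatisticKind.T_STAT:
            self._require("t", "n_e", "n_c")
            if self.n_e < 2 or self.n_c < 2:
                raise ValidationError("group sizes must be >= 2")
        elif kind is StatisticKind.F_STAT:
            self._require("f", "n_e", "n_c", "direction")
            if self.f < 0:
                raise ValidationError("F must be >= 0")
            if self.n_e < 2 or self.n_c < 2:
                raise ValidationError("group sizes must be >= 2")
        elif kind in (StatisticKind.CORRELATION, StatisticKind.REGRESSION):
            self._require("r", "n")
            if not -1 < self.r < 1:
                raise ValidationError(f"|r| must be < 1, got {self.r}")
            if self.n < 4:
                raise ValidationError("n must be >= 4 for a correlation input")
        elif kind is StatisticKind.P_ONLY:
            self._require("p", "n_e", "n_c", "direction")
            if not 0 < self.p <= 1:
                raise ValidationError(f"p must lie in (0, 1], got {self.p}")
            if self.n_e < 2 or self.n_c < 2:
                raise ValidationError("group sizes must be >= 2")
        if self.direction is not None and self.direction not in ("+", "-", "0"):
            raise ValidationError(f"direction must be one of +, -, 0, got {self.direction!r}")
        if self.timepoint_minutes is not None and self.timepoint_minutes < 0:
            raise ValidationError("timepoint_minutes must be non-negative")

    def _require(self, *names: str) -> None:
        missing = [nm for nm in names if getattr(self, nm) is None]
        if missing:
            raise ValidationError(
                f"{self.statistic_kind.value} input missing field(s): {', '.join(missing)}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """A Cohen's d with its sampling variance and carried labels."""

    d: float
    var_d: float
    n_effective: int
    sample_id: str = ""
    design: Optional[Design] = None
    predictor_class: str = ""
    symptom_profile: Optional[SymptomProfile] = None
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.var_d > 0:
            raise ValidationError(f"var_d must be positive, got {self.var_d}")

    @property
    def se_d(self) -> float:
        return math.sqrt(self.var_d)


@dataclass(frozen=True)
class RateRecord:
    """A per-study CAPS rate x/n with its exact binomial confidence interval."""

    x_caps: int
    n_exposed: int
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    sample_id: str = ""
    design: Optional[Design] = None
    symptom_profile: Optional[SymptomProfile] = None
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.n_exposed < 1:
            raise ValidationError("n_exposed must be >= 1")
        if not 0 <= self.x_caps <= self.n_exposed:
            raise ValidationError(
                f"x_caps={self.x_caps} must lie in [0, n_exposed={self.n_exposed}]"
            )
        if not (0.0 <= self.ci_low <= self.rate <= self.ci_high <= 1.0):
            raise ValidationError("CI bounds must satisfy 0 <= low <= rate <= high <= 1")


@dataclass(frozen=True)
class MetaResult:
    """A pooled estimate with heterogeneity statistics.

    ``estimate`` is on the analysis scale (Cohen's d, or a proportion for
    rate models).  ``sigma2_between``/``sigma2_within`` are populated only by
    three-level models, where ``tau2`` is their sum.
    """

    estimate: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    k: int
    tau2: float
    Q: float
    I2: float
    p_Q: float
    model_type: ModelType
    sigma2_between: Optional[float] = None
    sigma2_within: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValidationError("estimate must lie inside its CI")
        if self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        if not 0 <= self.I2 <= 100:
            raise ValidationError("I2 must lie in [0, 100]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        object.__setattr__(self, "model_type", ModelType(self.model_type))


@dataclass(frozen=True)
class BiasReport:
    """Outcome of a funnel-asymmetry test, optionally with a trim-and-fill refit."""

    test_name: str  # "egger" or "peters"
    p_bias: float
    slope: float = float("nan")
    applied_trim_fill: bool = False
    n_imputed: int = 0
    adjusted: Optional[MetaResult] = None

    def __post_init__(self) -> None:
        if self.test_name not in ("egger", "peters"):
            raise ValidationError("test_name must be 'egger' or 'peters'")
        if self.n_imputed < 0:
            raise ValidationError("n_imputed must be >= 0")
        if self.applied_trim_fill and self.adjusted is None:
            raise ValidationError("applied_trim_fill requires an adjusted result")


@dataclass(frozen=True)
class EvidenceRow:
    """One evidence-base row: study metadata plus exactly one payload."""

    study: StudyRecord
    effect: Optional[EffectInput] = None
    rate: Optional[RateRecord] = None

    def __post_init__(self) -> None:
        if (self.effect is None) == (self.rate is None):
            raise ValidationError("a row carries exactly one of an effect input or a rate record")

    @property
    def record_kind(self) -> str:
        return "rate" if self.rate is not None else "effect"


# ---------------------------------------------------------------------------
# CSV schema

CSV_COLUMNS = [
    "study_id", "sample_id", "design", "year", "n_total", "mean_age",
    "symptom_profile", "predictor_class", "record_kind", "x_caps", "n_exposed",
    "statistic_kind", "m_e", "m_c", "sd_e", "sd_c", "n_e", "n_c", "n",
    "m_t1", "m_t2", "sd_t1", "sd_t2", "r_within", "t", "f", "r", "p",
    "direction", "timepoint_minutes",
]

_EFFECT_FLOAT_FIELDS = [
    "m_e", "m_c", "sd_e", "sd_c", "m_t1", "m_t2", "sd_t1", "sd_t2",
    "r_within", "t", "f", "r", "p", "timepoint_minutes",
]
_EFFECT_INT_FIELDS = ["n_e", "n_c", "n"]


def _cell(row: pd.Series, name: str):
    val = row.get(name)
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    return val


def read_evidence_csv(path) -> list[EvidenceRow]:
    """Parse an evidence CSV into validated :class:`EvidenceRow` objects.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`ValidationError` naming the offending row (1-based data-row
    index) when a cell violates a domain invariant.
    """
    frame = pd.read_csv(path, dtype={"study_id": str, "sample_id": str, "direction": str},
                        float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns and c != "mean_age"]
    # mean_age optional in files; everything else mandatory
    mandatory = [c for c in missing if c != "mean_age"]
    if mandatory:
        raise SchemaError(f"missing mandatory column(s): {', '.join(mandatory)}")
    rows: list[EvidenceRow] = []
    for i, row in frame.iterrows():
        rownum = i + 1
        try:
            rows.append(_parse_row(row))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
    return rows


def _parse_row(row: pd.Series) -> EvidenceRow:
    study = StudyRecord(
        study_id=str(_cell(row, "study_id") or ""),
        sample_id=str(_cell(row, "sample_id") or ""),
        design=Design(_cell(row, "design")),
        year=int(_cell(row, "year")),
        n_total=int(_cell(row, "n_total")),
        mean_age=(lambda v: float(v) if v is not None else None)(_cell(row, "mean_age")),
        symptom_profile=SymptomProfile(_cell(row, "symptom_profile")),
        predictor_class=str(_cell(row, "predictor_class") or ""),
    )
    kind = _cell(row, "record_kind")
    if kind == "rate":
        from .rate_meta import make_rate_record  # deferred: avoids module cycle

        x = int(_cell(row, "x_caps"))
        n = int(_cell(row, "n_exposed"))
        rate = make_rate_record(
            x, n,
            sample_id=study.sample_id, design=study.design,
            symptom_profile=study.symptom_profile, study_id=study.study_id,
        )
        return EvidenceRow(study=study, rate=rate)
    if kind == "effect":
        kwargs = {"statistic_kind": StatisticKind(_cell(row, "statistic_kind"))}
        for name in _EFFECT_FLOAT_FIELDS:
            val = _cell(row, name)
            if val is not None:
                kwargs[name] = float(val)
        for name in _EFFECT_INT_FIELDS:
            if name in row.index:
                val = _cell(row, name)
                if val is not None:
                    kwargs[name] = int(val)
        direction = _cell(row, "direction")
        if direction is not None:
            kwargs["direction"] = str(direction)
        return EvidenceRow(study=study, effect=EffectInput(**kwargs))
    raise ValidationError(f"record_kind must be 'rate' or 'effect', got {kind!r}")


def write_evidence_csv(rows: list[EvidenceRow], path) -> None:
    """Serialize rows to the evidence CSV schema (round-trips with the reader)."""
    out = []
    for erow in rows:
        s = erow.study
        rec: dict = {c: "" for c in CSV_COLUMNS}
        rec.update(
            study_id=s.study_id, sample_id=s.sample_id, design=s.design.value,
            year=s.year, n_total=s.n_total,
            mean_age="" if s.mean_age is None else repr(float(s.mean_age)),
            symptom_profile=s.symptom_profile.value, predictor_class=s.predictor_class,
            record_kind=erow.record_kind,
        )
        if erow.rate is not None:
            rec["x_caps"] = erow.rate.x_caps
            rec["n_exposed"] = erow.rate.n_exposed
        else:
            eff = erow.effect
            rec["statistic_kind"] = eff.statistic_kind.value
            for name in _EFFECT_FLOAT_FIELDS:
                val = getattr(eff, name)
                if val is not None:
                    rec[name] = repr(float(val))  # full precision round-trip
            for name in _EFFECT_INT_FIELDS:
                val = getattr(eff, name)
                if val is not None:
                    rec[name] = val
            if eff.direction is not None:
                rec["direction"] = eff.direction
        out.append(rec)
    pd.DataFrame(out, columns=CSV_COLUMNS).to_csv(path, index=False)
    if not out:  # ensure header-only file still has the schema
        pd.DataFrame(columns=CSV_COLUMNS).to_csv(path, index=False)
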