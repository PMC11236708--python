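import numpy as np
import pytest

from capsmeta.evidence_model import (
    Design,
    EffectEstimate,
    EffectInput,
    EvidenceRow,
    StatisticKind,
    StudyRecord,
    SymptomProfile,
)
from capsmeta.rate_meta import make_rate_record


def make_est(d, v, sample_id="s", **kw):
    return EffectEstimate(d=d, var_d=v, n_effective=kw.pop("n_effective", 50),
                          sample_id=sample_id, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_symmetric_estimates():
    """The classic hand-computable pair: Q = 2, DL tau2 = 0.04, I2 = 50%."""
    return [make_est(0.2, 0.04, "a"), make_est(0.6, 0.04, "b")]


def make_study(study_id="s1", sample_id=None, design=Design.OBSERVATIONAL,
               profile=SymptomProfile.PSYCHOSIS_LIKE, predictor_class="", n_total=100):
    return StudyRecord(
        study_id=study_id, sample_id=sample_id or study_id, design=design,
        year=2015, n_total=n_total, symptom_profile=profile,
        predictor_class=predictor_class,
    )


def rate_row(study_id, x, n, design=Design.OBSERVATIONAL,
             profile=SymptomProfile.PSYCHOSIS_LIKE):
    study = make_study(study_id, design=design, profile=profile, n_total=n)
    return EvidenceRow(study=study, rate=make_rate_record(
        x, n, sample_id=study.sample_id, design=design,
        symptom_profile=profile, study_id=study_id))


def effect_row(study_id, predictor_class="exposure", sample_id=None,
               design=Design.EXPERIMENTAL, **payload):
    kind = payload.pop("statistic_kind", StatisticKind.MEANS_BETWEEN)
    study = make_study(study_id, sample_id=sample_id, design=design,
                       predictor_class=predictor_class)
    return EvidenceRow(study=study, effect=EffectInput(statistic_kind=kind, **payload))


@pytest.fixture
def mixed_evidence_rows(rng):
    """A small evidence base: 8 rate rows + 6 between-means effect rows."""
    rows = [rate_row(f"r{i}", int(x), int(n))
            for i, (x, n) in enumerate(zip(rng.binomial(100, 0.2, 8),
                                           np.full(8, 100)))]
    for i in range(6):
        n = 40
        rows.append(effect_row(
            f"e{i}", m_e=float(0.5 + 0.1 * rng.normal()), m_c=0.0,
            sd_e=1.0, sd_c=1.0, n_e=n, n_c=n))
    return rows
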