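import numpy as np
import pandas as pd
import pytest

from smoketrends.harmonize import SmokingDefinition, harmonize_records
from smoketrends.survey_synth import (PrevalenceSurface, SexParams,
                                      SurveyDesign, generate_survey)


@pytest.fixture(scope="session")
def default_surface():
    return PrevalenceSurface.default()


@pytest.fixture(scope="session")
def flat_gradient_surface():
    """No age, period or sex structure; pure education gradient (low vs high
    log OR = log 3.5, secondary log 2) on a logit(-0.5) baseline."""
    sp = SexParams(base_logodds=-0.5, age_offsets=(0.0, 0.0, 0.0, 0.0),
                   edu_low=float(np.log(3.5)), edu_secondary=float(np.log(2.0)))
    return PrevalenceSurface(male=sp, female=sp)


@pytest.fixture(scope="session")
def survey_2016(default_surface):
    design = SurveyDesign("RLMS-2016", 2016, (18, 79), 20000)
    rec = generate_survey(design, default_surface, 123)
    return harmonize_records(rec, SmokingDefinition("who_current"))


def make_records(daily, occasional, flags=None, **extra):
    """Tiny record frame from explicit flag vectors."""
    n = len(daily)
    base = {
        "survey": extra.pop("survey", "S"),
        "year": extra.pop("year", 2000),
        "sex": extra.pop("sex", "male"),
        "age": extra.pop("age", 40),
        "education": extra.pop("education", "secondary"),
        "smokes_daily": np.asarray(daily, dtype=bool),
        "smokes_occasionally": np.asarray(occasional, dtype=bool),
        "lifetime_cigarettes_ge_100": (np.ones(n, dtype=bool) if flags is None
                                       else np.asarray(flags, dtype=bool)),
        "former_smoker": np.zeros(n, dtype=bool),
        "years_since_quit": np.nan,
    }
    base.update(extra)
    return pd.DataFrame(base)
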