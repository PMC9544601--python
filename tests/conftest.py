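import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pwidtrends as pt

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(
    survey_year=2019,
    age=None,
    age_first_inj=None,
    year_first_inj=None,
    duration=None,
    recent_inj=1,
    psychoactive=1,
    survey="synthetic",
    region="",
    sex="male",
):
    return {
        "survey": survey,
        "survey_year": survey_year,
        "region": region,
        "sex": sex,
        "age": age,
        "age_first_inj": age_first_inj,
        "year_first_inj": year_first_inj,
        "duration": duration,
        "recent_inj": recent_inj,
        "psychoactive": psychoactive,
    }


def records_frame(records):
    df = pd.DataFrame(records, columns=pt.simulate.SURVEY_COLUMNS)
    for col in [
        "survey_year",
        "age",
        "age_first_inj",
        "year_first_inj",
        "duration",
        "recent_inj",
        "psychoactive",
    ]:
        df[col] = pd.array(df[col], dtype="Int64")
    return df


@pytest.fixture
def toy_cascade_table():
    """Six records: one per exclusion rule plus two valid."""
    return records_frame(
        [
            make_record(age=40, age_first_inj=22, recent_inj=0),
            make_record(age=40, age_first_inj=22, psychoactive=0),
            make_record(),  # all core fields missing
            make_record(age=30, age_first_inj=35),
            make_record(age=40, age_first_inj=22),
            make_record(age=35, age_first_inj=20, year_first_inj=2004),
        ]
    )


@pytest.fixture(scope="session")
def england_like():
    """Scaled England-like epidemic: initiation wave peaking in 1998, mean
    duration 15 y, 30 annual surveys of 2000 records each (1990-2019)."""
    scenario = pt.make_scenario(
        "gaussian_peak",
        years=(1960, 2019),
        amplitude=10_000,
        peak_year=1998,
        width=5.0,
        age_mean_start=20.0,
        age_mean_end=30.0,
        age_sd=5.0,
    )
    population = pt.simulate_population(scenario, mu=15.0, seed=20_101)
    design = pt.SurveyDesign(
        survey_years=list(range(1990, 2020)),
        sample_size={t: 2000 for t in range(1990, 2020)},
        seed=20_102,
    )
    table = pt.simulate_surveys(population, design)
    clean, log = pt.clean_survey_table(table)
    hists = pt.initiation_histograms(clean)
    return {
        "scenario": scenario,
        "population": population,
        "table": table,
        "clean": clean,
        "log": log,
        "hists": hists,
        "mu": 15.0,
    }


@pytest.fixture(scope="session")
def england_like_fit(england_like):
    model = pt.IncidenceModel(england_like["hists"], mu=england_like["mu"])
    return model.fit(n_mc=500, seed=20_103)


@pytest.fixture(scope="session")
def drifting_age_survey():
    """Constant-rate epidemic whose mean age at initiation drifts upward;
    used to check quantile-trend recovery of the median age."""
    scenario = pt.make_scenario(
        "constant",
        years=(1960, 2009),
        amplitude=2000,
        age_mean_start=20.0,
        age_mean_end=30.0,
        age_sd=5.0,
    )
    population = pt.simulate_population(scenario, mu=15.0, seed=30_201)
    years = list(range(1990, 2010))
    design = pt.SurveyDesign(
        survey_years=years, sample_size={t: 2000 for t in years}, seed=30_202
    )
    table = pt.simulate_surveys(population, design)
    clean, _ = pt.clean_survey_table(table)
    return {"scenario": scenario, "clean": clean, "years": years}
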