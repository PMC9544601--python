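"""Synthetic populations of people who inject drugs, and cross-sectional surveys of them.

The generative model: in each calendar year ``c`` a Poisson number of people
inject for the first time, with rate given by an :class:`InitiationScenario`.
Each person injects for an exponentially distributed duration (constant hazard
of cessation, mean ``mu`` years) and their age at first injection is drawn from
a normal distribution truncated below at ``age_min``, whose mean may drift over
calendar time.  Surveys sample uniformly, without replacement, from the people
currently injecting in the survey year, and the sampled records are then
corrupted (item non-response, non-recent injectors, image-and-performance-only
injectors, implausible ages) to emulate real self-completed questionnaires.

Time is discrete at whole calendar years: a person initiating in year ``c``
with duration ``D`` is currently injecting in survey year ``t`` iff
``c <= t`` and ``t - c < D``.  Under this convention the probability of still
injecting ``d`` whole years after initiation is ``S(d) = exp(-d/mu)``, the same
survival function the back-calculation assumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: canonical column order of the participant-level survey CSV
SURVEY_COLUMNS = [
    "survey",
    "survey_year",
    "region",
    "sex",
    "age",
    "age_first_inj",
    "year_first_inj",
    "duration",
    "recent_inj",
    "psychoactive",
]


@dataclass(frozen=True)
class InitiationScenario:
    """True initiation curve and age-at-initiation structure of a simulated epidemic.

    Parameters
    ----------
    years
        Inclusive calendar-year range ``(first, last)``.
    rate
        Expected number of new injectors per year, keyed by calendar year.
    age_at_init_mean
        Mean age at first injection per calendar year of initiation.
    age_at_init_sd
        Standard deviation of age at first injection (years).
    age_min
        Lower truncation point for age at initiation.
    """

    years: tuple[int, int]
    rate: Mapping[int, float]
    age_at_init_mean: Mapping[int, float]
    age_at_init_sd: float
    age_min: float = 15.0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"empty scenario: year range {self.years}")
        if self.age_min < 0:
            raise ValueError("age_min must be >= 0")
        if self.age_at_init_sd <= 0:
            raise ValueError("age_at_init_sd must be > 0")
        for c in self.year_list():
            r = self.rate.get(c)
            if r is None or not np.isfinite(r) or r < 0:
                raise ValueError(f"rate missing, non-finite or negative for year {c}")
            if c not in self.age_at_init_mean:
                raise ValueError(f"age_at_init_mean missing for year {c}")

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def true_curve(self) -> pd.Series:
        """Expected number of new injectors per year (the ground-truth N(c))."""
        years = self.year_list()
        return pd.Series([float(self.rate[c]) for c in years], index=years, name="rate")


@dataclass(frozen=True)
class Person:
    """One simulated injector: initiation year, age at initiation, injecting duration."""

    init_year: int
    init_age: float
    duration: float


@dataclass(frozen=True)
class CorruptionParams:
    """Per-record corruption probabilities applied after survey sampling.

    Missingness is independent per field; ``p_non_recent`` flags a record as not
    injecting recently, ``p_performance_only`` as injecting image-and-performance
    drugs only, and ``p_implausible`` sets the reported age at first injection
    greater than the current age.
    """

    p_missing_age: float = 0.0
    p_missing_age_first: float = 0.0
    p_missing_year_first: float = 0.0
    p_non_recent: float = 0.0
    p_performance_only: float = 0.0
    p_implausible: float = 0.0

    def __post_init__(self) -> None:
        for name, p in asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class SurveyDesign:
    """Which calendar years are surveyed, how many records per year, and corruption."""

    survey_years: Sequence[int]
    sample_size: Mapping[int, int]
    corruption: CorruptionParams = field(default_factory=CorruptionParams)
    seed: int = 0
    survey_label: str = "synthetic"
    region: str = ""
    p_male: float = 0.745

    def __post_init__(self) -> None:
        for t in self.survey_years:
            n = self.sample_size.get(t)
            if n is None or n < 0:
                raise ValueError(f"sample size missing or negative for survey year {t}")


def make_scenario(
    shape: str,
    *,
    years: tuple[int, int] = (1960, 2019),
    amplitude: float = 1000.0,
    peak_year: int | None = None,
    width: float = 5.0,
    age_mean_start: float = 22.0,
    age_mean_end: float | None = None,
    age_sd: float = 5.0,
    age_min: float = 15.0,
) -> InitiationScenario:
    """Build an :class:`InitiationScenario` from a named preset.

    Presets
    -------
    ``"constant"``
        The same expected number of new injectors (``amplitude``) every year.
    ``"gaussian_peak"``
        ``rate(c) = amplitude * exp(-(c - peak_year)**2 / (2 * width**2))`` — a
        single epidemic wave, e.g. the UK's late-1990s peak of injecting initiation.

    The mean age at initiation drifts linearly from ``age_mean_start`` in the
    first year to ``age_mean_end`` in the last (constant if ``age_mean_end`` is
    None), emulating the observed rise in age at first injection.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    y0, y1 = years
    yrs = list(range(y0, y1 + 1))
    if shape == "constant":
        rate = {c: float(amplitude) for c in yrs}
    elif shape == "gaussian_peak":
        if peak_year is None:
            raise ValueError("gaussian_peak preset requires peak_year")
        if not (y0 <= peak_year <= y1):
            raise ValueError(f"peak_year {peak_year} outside year range {years}")
        if width <= 0:
            raise ValueError("width must be positive")
        rate = {
            c: float(amplitude * np.exp(-((c - peak_year) ** 2) / (2.0 * width**2)))
            for c in yrs
        }
    else:
        raise ValueError(f"unknown preset {shape!r}")

    if age_mean_end is None:
        age_mean_end = age_mean_start
    if len(yrs) == 1:
        means = {yrs[0]: float(age_mean_start)}
    else:
        span = y1 - y0
        means = {
            c: float(age_mean_start + (age_mean_end - age_mean_start) * (c - y0) / span)
            for c in yrs
        }
    return InitiationScenario(
        years=years,
        rate=rate,
        age_at_init_mean=means,
        age_at_init_sd=age_sd,
        age_min=age_min,
    )


def simulate_population(
    scenario: InitiationScenario,
    mu: float,
    seed: int,
    duration_age_gradient: float = 0.0,
) -> pd.DataFrame:
    """Simulate everyone who ever starts injecting under ``scenario``.

    The number initiating in year ``c`` is Poisson with mean ``rate(c)``;
    durations are i.i.d. exponential with mean ``mu`` years; ages at initiation
    are normal truncated below at ``scenario.age_min``.

    ``duration_age_gradient`` optionally makes attrition age-correlated: a
    person's mean duration becomes ``mu * exp(-gradient * (init_age - m(c)))``
    with ``m(c)`` the cohort's mean age at initiation, so with a positive
    gradient people who start younger inject for longer.  Off (0) by default;
    it exists to exercise the survivorship bias that restricting to recent
    initiates is designed to avoid.

    Returns a DataFrame with columns ``init_year``, ``init_age``, ``duration``,
    one row per person.  Deterministic for a fixed seed.
    """
    if mu <= 0:
        raise ValueError("mean duration mu must be > 0")
    rng = np.random.default_rng(seed)
    years = np.array(scenario.year_list())
    rates = np.array([scenario.rate[c] for c in years], dtype=float)
    counts = rng.poisson(rates)
    init_year = np.repeat(years, counts)
    n = init_year.size
    means = np.repeat(
        np.array([scenario.age_at_init_mean[c] for c in years], dtype=float), counts
    )
    sd = scenario.age_at_init_sd
    a = (scenario.age_min - means) / sd  # per-person lower truncation in sd units
    init_age = stats.truncnorm.rvs(a, np.inf, loc=means, scale=sd, random_state=rng)
    init_age = np.atleast_1d(init_age).astype(float)
    person_mu = mu * np.exp(-duration_age_gradient * (init_age - means))
    duration = rng.exponential(person_mu) if n else np.empty(0)
    return pd.DataFrame(
        {
            "init_year": init_year.astype(int),
            "init_age": init_age,
            "duration": np.asarray(duration, dtype=float),
        }
    )


def _as_population_frame(population: pd.DataFrame | Iterable[Person]) -> pd.DataFrame:
    if isinstance(population, pd.DataFrame):
        return population
    rows = [(p.init_year, p.init_age, p.duration) for p in population]
    return pd.DataFrame(rows, columns=["init_year", "init_age", "duration"])


def currently_injecting(population: pd.DataFrame | Iterable[Person], year: int) -> pd.DataFrame:
    """People still injecting in ``year``: initiated at or before it, duration not yet elapsed."""
    pop = _as_population_frame(population)
    mask = (pop["init_year"] <= year) & ((year - pop["init_year"]) < pop["duration"])
    return pop[mask]


def simulate_surveys(
    population: pd.DataFrame | Iterable[Person], design: SurveyDesign
) -> pd.DataFrame:
    """Cross-sectional surveys of the currently injecting, with corruption.

    For each survey year ``t``, samples ``n(t)`` people uniformly without
    replacement from those currently injecting, emitting one record per person
    with ``age = age_first_inj + (t - init_year)`` (ages reported in whole
    years).  Corruption is then applied independently per record in the order:
    field deletion, recency / performance flags, implausibility injection
    (age at first injection set above current age, when both are present).

    If ``n(t)`` exceeds the number currently injecting, the sample is truncated
    with a warning.  Deterministic for a fixed ``design.seed``.
    """
    pop = _as_population_frame(population)
    rng = np.random.default_rng(design.seed)
    cp = design.corruption
    frames: list[pd.DataFrame] = []
    for t in design.survey_years:
        eligible = currently_injecting(pop, t)
        n_want = int(design.sample_size[t])
        n_take = min(n_want, len(eligible))
        if n_take < n_want:
            warnings.warn(
                f"survey year {t}: requested {n_want} records but only "
                f"{len(eligible)} people currently injecting; sample truncated",
                stacklevel=2,
            )
        idx = rng.choice(len(eligible), size=n_take, replace=False)
        chosen = eligible.iloc[np.sort(idx)]
        afi = np.round(chosen["init_age"].to_numpy()).astype(int)
        init_year = chosen["init_year"].to_numpy()
        age = afi + (t - init_year)
        rec = pd.DataFrame(
            {
                "survey": design.survey_label,
                "survey_year": t,
                "region": design.region,
                "sex": np.where(
                    rng.random(n_take) < design.p_male, "male", "female"
                ),
                "age": pd.array(age, dtype="Int64"),
                "age_first_inj": pd.array(afi, dtype="Int64"),
                "year_first_inj": pd.array(init_year, dtype="Int64"),
                "duration": pd.array([pd.NA] * n_take, dtype="Int64"),
                "recent_inj": pd.array(np.ones(n_take, dtype=int), dtype="Int64"),
                "psychoactive": pd.array(np.ones(n_take, dtype=int), dtype="Int64"),
            }
        )
        # field deletion (item non-response), independent per field
        for col, p in [
            ("age", cp.p_missing_age),
            ("age_first_inj", cp.p_missing_age_first),
            ("year_first_inj", cp.p_missing_year_first),
        ]:
            if p > 0:
                rec.loc[rng.random(n_take) < p, col] = pd.NA
        if cp.p_non_recent > 0:
            rec.loc[rng.random(n_take) < cp.p_non_recent, "recent_inj"] = 0
        if cp.p_performance_only > 0:
            rec.loc[rng.random(n_take) < cp.p_performance_only, "psychoactive"] = 0
        if cp.p_implausible > 0:
            hit = rng.random(n_take) < cp.p_implausible
            both = rec["age"].notna().to_numpy() & rec["age_first_inj"].notna().to_numpy()
            hit &= both
            bump = rng.integers(1, 11, size=n_take)
            rec.loc[hit, "age_first_inj"] = rec.loc[hit, "age"] + bump[hit]
        frames.append(rec)
    if not frames:
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[SURVEY_COLUMNS]


def write_survey_csv(table: pd.DataFrame, path) -> None:
    """Write a survey table in the canonical schema (empty string = missing)."""
    table[SURVEY_COLUMNS].to_csv(path, index=False, na_rep="")


def write_true_curve(scenario: InitiationScenario, path) -> None:
    """Sidecar JSON recording the ground-truth initiation curve, for recovery tests."""
    curve = {int(c): float(r) for c, r in scenario.true_curve().items()}
    with open(path, "w") as fh:
        json.dump({"years": list(scenario.years), "rate": curve}, fh, indent=1)
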