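"""Back-calculation of the annual number of people injecting for the first time.

A survey in year ``t`` samples people currently injecting; the share reporting
initiation year ``c`` is proportional to ``N(c) * S(t - c)``, where ``N(c)`` is
the number who started in ``c`` and ``S(d) = exp(-d/mu)`` is the probability of
still injecting ``d`` years after starting (constant cessation hazard, mean
duration ``mu``).  Dividing the observed initiation-year counts by ``S(t - c)``
therefore recovers the initiation curve up to scale.  Evidence from all survey
years is combined by a Monte-Carlo scheme: histogram counts are redrawn from a
multinomial, each replicate is inverted per survey and averaged across surveys
with weights proportional to survey size, and the 2.5th/97.5th percentiles of
the replicates give 95% prediction intervals.  An external prevalence estimate
(number currently injecting in a reference year) converts the relative curve
into absolute annual counts.

The Monte-Carlo combination scheme here is this package's own reconstruction
of "combining evidence across survey years": per-survey multinomial
resampling, inversion per replicate, survey-total-weighted mean, percentile
intervals.  It produces wider intervals for cohorts informed by few surveys,
as expected, but is not a transcription of any particular published supplement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trends import InitiationHistogram

DEFAULT_MU = 15.0


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential injecting-career survival: S(d) = exp(-d/mu), mu in years."""

    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError("mean duration mu must be positive and finite")

    def survival(self, d) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("duration since initiation cannot be negative")
        out = np.exp(-d / self.mu)
        return out if out.ndim else float(out)

    @property
    def d_max(self) -> int:
        """Longest duration inverted: beyond ~5 mean durations, S(d) < e^-5 and
        dividing by it amplifies noise explosively."""
        return math.ceil(5.0 * self.mu)


@dataclass(frozen=True)
class CalibrationAnchor:
    """External prevalence estimate used to put the relative curve on an absolute scale."""

    ref_year: int
    prevalence: float
    source: str = ""
    prevalence_low: float | None = None
    prevalence_high: float | None = None

    def __post_init__(self) -> None:
        if self.prevalence <= 0:
            raise ValueError("anchor prevalence must be positive")
        if (self.prevalence_low is None) != (self.prevalence_high is None):
            raise ValueError("provide both or neither of prevalence_low/high")
        if self.prevalence_low is not None and not (
            0 < self.prevalence_low <= self.prevalence <= self.prevalence_high
        ):
            raise ValueError("anchor interval must bracket the point estimate")


@dataclass
class CohortCurve:
    """Per-calendar-year initiation counts N(c), relative or absolute."""

    values: pd.Series  # index: cohort year c, values: N(c)
    scale: str  # "relative" | "absolute"
    mu: float
    pri: pd.DataFrame | None = None  # columns pri_low, pri_high, same index
    n_surveys_informing: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cohort_year": self.values.index, "n_hat": self.values.values})
        if self.pri is not None:
            df["pri_low"] = self.pri["pri_low"].values
            df["pri_high"] = self.pri["pri_high"].values
        else:
            df["pri_low"] = np.nan
            df["pri_high"] = np.nan
        if self.n_surveys_informing is not None:
            df["n_surveys_informing"] = self.n_surveys_informing.values
        return df


def forward_expected_counts(
    curve: Mapping[int, float] | pd.Series, survey_year: int, model: SurvivalModel
) -> InitiationHistogram:
    """Expected initiation-year histogram a survey at ``survey_year`` would see.

    The forward map of the back-calculation: counts proportional to
    ``N(c) * S(t - c)`` for cohorts at or before the survey year.  Used as the
    independent oracle for inversion tests.
    """
    s = pd.Series(curve, dtype=float).sort_index()
    s = s[s.index <= survey_year]
    d = survey_year - s.index.to_numpy()
    expected = s.to_numpy() * np.asarray(model.survival(d))
    counts = {int(c): float(v) for c, v in zip(s.index, expected)}
    return InitiationHistogram(
        survey_year=survey_year, counts=counts, total=float(expected.sum())
    )


def backcalc_single(
    hist: InitiationHistogram, model: SurvivalModel, normalise: bool = True
) -> CohortCurve:
    """Invert one survey's initiation histogram through the survival model.

    Each cohort's estimate is ``n_t(c) / S(t - c)``; zero-count cohorts keep an
    estimate of zero (no pseudo-count).  Normalised to sum to one unless
    ``normalise=False`` (raw inverted counts, useful for closed-form checks).
    """
    if hist.total <= 0:
        raise ValueError("histogram has no records")
    years = np.array(sorted(hist.counts), dtype=int)
    d = hist.survey_year - years
    if np.any(d < 0):
        raise ValueError("initiation year after survey year")
    n = np.array([hist.counts[int(c)] for c in years], dtype=float)
    est = n / np.asarray(model.survival(d))
    if normalise:
        tot = est.sum()
        if tot <= 0:
            raise ValueError("all inverted counts are zero")
        est = est / tot
    values = pd.Series(est, index=years, name="n_hat")
    n_inform = pd.Series(np.ones(len(years), dtype=int), index=years)
    return CohortCurve(
        values=values,
        scale="relative" if normalise else "raw",
        mu=model.mu,
        n_surveys_informing=n_inform,
    )


class IncidenceModel:
    """Back-calculation model for the annual number of new injectors.

    Built from per-survey-year initiation histograms and an exponential
    survival assumption; ``fit`` combines the surveys and attaches Monte-Carlo
    prediction intervals.

    Parameters
    ----------
    histograms
        One :class:`InitiationHistogram` per survey year (a single stratum).
    mu
        Assumed mean duration of injecting, years.
    d_max
        Longest time-since-initiation inverted; defaults to ``ceil(5 * mu)``.
        Cohorts only observable at longer lags are dropped (their survival
        weight is below ``e^-5`` and estimates explode numerically).
    pseudo_count
        Optional add-``pseudo_count`` smoothing of histogram cells covered by a
        survey; 0 (off) by default so the estimator stays transparent.
    """

    def __init__(
        self,
        histograms: Sequence[InitiationHistogram],
        mu: float = DEFAULT_MU,
        d_max: int | None = None,
        pseudo_count: float = 0.0,
    ):
        if len(histograms) == 0:
            raise ValueError("at least one histogram required")
        self.histograms = sorted(histograms, key=lambda h: h.survey_year)
        self.survival = SurvivalModel(mu)
        self.d_max = self.survival.d_max if d_max is None else int(d_max)
        self.pseudo_count = float(pseudo_count)
        self._build_matrices()

    @classmethod
    def from_survey_table(
        cls, table: pd.DataFrame, mu: float = DEFAULT_MU, **kwargs
    ) -> "IncidenceModel":
        """Build from a clean participant-level table (histograms computed internally)."""
        from .trends import initiation_histograms

        return cls(initiation_histograms(table), mu=mu, **kwargs)

    @property
    def mu(self) -> float:
        return self.survival.mu

    def _build_matrices(self) -> None:
        t_arr = np.array([h.survey_year for h in self.histograms])
        c_min = min(min(h.counts) for h in self.histograms if h.counts)
        c_max = max(max(h.counts) for h in self.histograms if h.counts)
        cohorts = np.arange(c_min, c_max + 1)
        # coverage: survey t informs cohort c iff c <= t and t - c <= d_max
        lag = t_arr[:, None] - cohorts[None, :]
        cover = (lag >= 0) & (lag <= self.d_max)
        counts = np.zeros((len(t_arr), len(cohorts)))
        for i, h in enumerate(self.histograms):
            for c, n in h.counts.items():
                j = c - c_min
                if cover[i, j]:
                    counts[i, j] = n
        informed = cover.sum(axis=0) > 0
        self.cohorts = cohorts[informed]
        self._cover = cover[:, informed]
        self._counts = counts[:, informed]
        self._lag = lag[:, informed]
        with np.errstate(divide="ignore"):
            inv_s = np.where(self._cover, np.exp(np.where(self._cover, self._lag, 0) / self.mu), 0.0)
        self._inv_survival = inv_s  # 1/S(t-c) where covered, else 0
        self._weights = np.array([h.total for h in self.histograms], dtype=float)

    def _combine(self, counts: np.ndarray) -> np.ndarray:
        """Survey-total-weighted mean of per-survey normalised inverted curves.

        ``counts`` has shape (..., n_surveys, n_cohorts); pseudo-counts, if
        configured, are added to every covered cell before inversion.
        """
        if self.pseudo_count:
            counts = counts + self.pseudo_count * self._cover
        inverted = counts * self._inv_survival
        row_tot = inverted.sum(axis=-1, keepdims=True)
        row_tot = np.where(row_tot > 0, row_tot, 1.0)
        rel = inverted / row_tot
        w = self._weights[:, None] * self._cover
        denom = w.sum(axis=-2)
        denom = np.where(denom > 0, denom, 1.0)
        combined = (self._weights[:, None] * rel).sum(axis=-2) / denom
        tot = combined.sum(axis=-1, keepdims=True)
        tot = np.where(tot > 0, tot, 1.0)
        return combined / tot

    def fit(self, n_mc: int = 1000, seed: int | None = None) -> "IncidenceResults":
        """Combine all surveys; Monte-Carlo prediction intervals if ``n_mc > 0``.

        Each replicate redraws every histogram's counts from a multinomial with
        the observed proportions, re-inverts and re-combines; the prediction
        interval is the 2.5th–97.5th percentile band of replicates.  All
        randomness derives from ``(seed, mu)`` so sensitivity runs over several
        ``mu`` values do not perturb one another.
        """
        point = self._combine(self._counts)
        replicates = None
        if n_mc > 0:
            if seed is None:
                raise ValueError("seed is required when n_mc > 0")
            if n_mc < 100:
                raise ValueError("n_mc must be 0 or >= 100")
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), int(round(self.mu * 1000))))
            )
            reps_counts = np.zeros((n_mc, *self._counts.shape))
            for i, h in enumerate(self.histograms):
                total = int(round(h.total))
                row = self._counts[i]
                row_sum = row.sum()
                if total <= 0 or row_sum <= 0:
                    continue
                p = row / row_sum
                reps_counts[:, i, :] = rng.multinomial(total, p, size=n_mc)
            replicates = self._combine(reps_counts)
        return IncidenceResults(self, point, replicates)


class IncidenceResults:
    """Fitted initiation curve with prediction intervals and calibration."""

    def __init__(
        self,
        model: IncidenceModel,
        point: np.ndarray,
        replicates: np.ndarray | None,
        scale: str = "relative",
        scale_factor: float = 1.0,
    ):
        self.model = model
        self._point = point
        self._replicates = replicates
        self.scale = scale
        self.scale_factor = scale_factor

    @property
    def mu(self) -> float:
        return self.model.mu

    @property
    def cohort_years(self) -> np.ndarray:
        return self.model.cohorts

    @property
    def n_surveys_informing(self) -> pd.Series:
        return pd.Series(self.model._cover.sum(axis=0), index=self.model.cohorts)

    def _pri_bounds(self) -> tuple[np.ndarray, np.ndarray] | None:
        if self._replicates is None:
            return None
        lo = np.percentile(self._replicates, 2.5, axis=0)
        hi = np.percentile(self._replicates, 97.5, axis=0)
        # the percentile band is forced to bracket the point estimate
        lo = np.minimum(lo, self._point)
        hi = np.maximum(hi, self._point)
        return lo * self.scale_factor, hi * self.scale_factor

    @property
    def curve(self) -> CohortCurve:
        values = pd.Series(
            self._point * self.scale_factor, index=self.model.cohorts, name="n_hat"
        )
        bounds = self._pri_bounds()
        pri = None
        if bounds is not None:
            pri = pd.DataFrame(
                {"pri_low": bounds[0], "pri_high": bounds[1]}, index=self.model.cohorts
            )
        return CohortCurve(
            values=values,
            scale=self.scale,
            mu=self.mu,
            pri=pri,
            n_surveys_informing=self.n_surveys_informing,
        )

    def to_frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    @property
    def peak_year(self) -> int:
        return int(self.model.cohorts[np.argmax(self._point)])

    def implied_prevalence(self, year: int) -> float:
        """Number currently injecting in ``year`` implied by the fitted curve."""
        c = self.model.cohorts
        mask = c <= year
        if not mask.any():
            raise ValueError(f"no cohorts at or before {year}")
        s = np.asarray(self.model.survival.survival(year - c[mask]))
        return float((self._point[mask] * self.scale_factor * s).sum())

    def calibrate(self, anchor: CalibrationAnchor, seed: int | None = None) -> "IncidenceResults":
        """Scale the curve so the implied prevalence at the anchor year matches it.

        Multiplies point estimate and prediction bounds by
        ``k = P / sum_c N(c) * S(t* - c)``.  If the anchor has an uncertainty
        interval and replicates exist, each replicate's ``k`` is additionally
        scaled by a uniform draw between the interval bounds (requires ``seed``).
        """
        c = self.model.cohorts
        if anchor.ref_year < c.min():
            raise ValueError("anchor year precedes every cohort")
        implied = self.implied_prevalence(anchor.ref_year) / self.scale_factor
        if implied <= 0:
            raise ValueError("implied prevalence at anchor year is zero")
        k = anchor.prevalence / implied
        replicates = self._replicates
        if (
            replicates is not None
            and anchor.prevalence_low is not None
            and anchor.prevalence_high is not None
        ):
            if seed is None:
                raise ValueError("seed required to propagate anchor uncertainty")
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), int(anchor.ref_year)))
            )
            draw = rng.uniform(
                anchor.prevalence_low / anchor.prevalence,
                anchor.prevalence_high / anchor.prevalence,
                size=replicates.shape[0],
            )
            replicates = replicates * draw[:, None]
        return IncidenceResults(
            self.model,
            self._point,
            replicates,
            scale="absolute",
            scale_factor=self.scale_factor * k,
        )

    def summary(self) -> str:
        df = self.to_frame()
        peak = self.peak_year
        lines = [
            "Back-calculated initiation curve",
            f"  scale: {self.scale}; mean duration mu = {self.mu:g} y;"
            f" cohorts {df.cohort_year.min()}-{df.cohort_year.max()}",
            f"  surveys combined: {len(self.model.histograms)}"
            f" ({sum(h.total for h in self.model.histograms):.0f} records)",
            f"  peak cohort year: {peak}"
            f" (N_hat = {df.set_index('cohort_year').n_hat[peak]:.4g})",
        ]
        if self._replicates is not None:
            lines.append(
                f"  95% prediction intervals from {self._replicates.shape[0]}"
                " multinomial replicates"
            )
        return "\n".join(lines)


def combine_surveys(
    hists: Sequence[InitiationHistogram],
    model: SurvivalModel,
    n_mc: int = 1000,
    seed: int | None = None,
    pseudo_count: float = 0.0,
) -> CohortCurve:
    """Functional wrapper: combined relative curve with prediction intervals."""
    res = IncidenceModel(hists, mu=model.mu, pseudo_count=pseudo_count).fit(
        n_mc=n_mc, seed=seed
    )
    return res.curve


def calibrate(
    curve_results: IncidenceResults, anchor: CalibrationAnchor, seed: int | None = None
) -> CohortCurve:
    """Functional wrapper: absolute curve after prevalence calibration."""
    return curve_results.calibrate(anchor, seed=seed).curve


def sensitivity(
    hists: Sequence[InitiationHistogram],
    mus: Sequence[float],
    anchor: CalibrationAnchor | None = None,
    n_mc: int = 1000,
    seed: int | None = None,
) -> dict[float, IncidenceResults]:
    """Repeat the combine (+ optional calibration) for each assumed mean duration.

    Because each fit seeds its generator from ``(seed, mu)``, adding or
    removing a ``mu`` leaves the other curves bit-identical.
    """
    if len(mus) == 0:
        raise ValueError("mus must be non-empty")
    out: dict[float, IncidenceResults] = {}
    for mu in mus:
        res = IncidenceModel(hists, mu=mu).fit(n_mc=n_mc, seed=seed)
        if anchor is not None:
            res = res.calibrate(anchor, seed=seed)
        out[float(mu)] = res
    return out
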