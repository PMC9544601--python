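"""Quantile trends in age, age at first injection and injecting duration.

Conditional quantiles of an outcome are modelled as a quadratic in calendar
year, fitted by minimising the check (pinball) loss
``rho_tau(u) = u * (tau - 1{u < 0})`` — quantile regression.  With tens of
thousands of records per survey the fitted quartiles summarise the shifting
age structure of the injecting population; reported values by year are the
model's fitted quantiles, not raw per-year sample quantiles.

Also provides the 3-year initiation window used to estimate age at first
injection by year of initiation with minimal survivorship bias, and
per-survey-year histograms of reported initiation year (the input to the
incidence back-calculation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_TAUS = (0.25, 0.5, 0.75)
MIN_STRATUM_SIZE = 30


@dataclass
class QuantileTrend:
    """One fitted quantile-by-year curve."""

    outcome: str
    tau: float
    coefficients: tuple[float, float, float]  # intercept, linear, quadratic (centred year)
    fitted: dict[int, float]
    ci: dict[int, tuple[float, float]] | None = None
    stratum: str | None = None


@dataclass
class InitiationHistogram:
    """Counts of reported year of first injection among one survey year's records."""

    survey_year: int
    counts: dict[int, float]
    total: float
    stratum: str | None = None

    def __post_init__(self) -> None:
        if any(c > self.survey_year for c in self.counts):
            raise ValueError("initiation year after survey year")
        if not np.isclose(sum(self.counts.values()), self.total):
            raise ValueError("histogram counts do not sum to total")

    @property
    def modal_init_year(self) -> int | None:
        if not self.counts or self.total == 0:
            return None
        return max(self.counts, key=lambda c: (self.counts[c], c))

    @property
    def modal_duration(self) -> int | None:
        m = self.modal_init_year
        return None if m is None else self.survey_year - m


def _pinball_fit(y: np.ndarray, years: np.ndarray, tau: float):
    """Fit quantile tau of y on (1, yc, yc^2), yc the year centred at its midpoint.

    Returns (coefficients, centre).  If the outcome is exactly quadratic in
    year (including constant and linear signals), the least-squares
    interpolant has zero residuals and therefore minimises the check loss for
    every tau; it is returned directly.  Otherwise statsmodels' quantile
    regression does the work.
    """
    centre = (years.min() + years.max()) / 2.0
    yc = years - centre
    X = np.column_stack([np.ones_like(yc), yc, yc**2])
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.max(np.abs(X @ beta_ls - y)) < 1e-8:
        return beta_ls, centre
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, X).fit(q=tau, p_tol=1e-9, max_iter=5000)
    return np.asarray(res.params, dtype=float), centre


def _fitted_by_year(beta: np.ndarray, centre: float, years: Sequence[int]) -> dict[int, float]:
    out = {}
    for yr in years:
        yc = yr - centre
        out[int(yr)] = float(beta[0] + beta[1] * yc + beta[2] * yc**2)
    return out


class QuantileTrendModel:
    """Quantile regression of an outcome on a quadratic in calendar year.

    Parameters
    ----------
    data
        Clean participant-level table.
    outcome
        Column to model (``age``, ``age_first_inj`` or ``duration``).
    time
        Column giving the calendar year (survey year, or initiation year for
        the recent-initiates analysis).
    taus
        Quantile levels; quartiles by default.
    strata
        Optional column to stratify by (e.g. region); the same quadratic form
        is refitted per stratum.  Strata with fewer than ``MIN_STRATUM_SIZE``
        records are skipped with a warning.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        time: str = "survey_year",
        taus: Sequence[float] = DEFAULT_TAUS,
        strata: str | None = None,
    ):
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} not in table")
        if data[outcome].isna().any():
            raise ValueError(f"outcome column {outcome!r} contains missing values")
        self.data = data
        self.outcome = outcome
        self.time = time
        self.taus = tuple(sorted(taus))
        self.strata = strata

    def _groups(self):
        if self.strata is None:
            yield None, self.data
        else:
            for key, grp in self.data.groupby(self.strata, dropna=False):
                yield key, grp

    def fit(self, n_boot: int = 0, seed: int | None = None) -> "QuantileTrendResults":
        """Fit all quantiles (per stratum); optional percentile-bootstrap CIs.

        ``n_boot`` resamples records with replacement and refits; the CI per
        year is the 2.5th–97.5th percentile of refitted values.
        """
        trends: list[QuantileTrend] = []
        rng = np.random.default_rng(seed) if n_boot else None
        for key, grp in self._groups():
            if len(grp) < MIN_STRATUM_SIZE:
                warnings.warn(
                    f"stratum {key!r}: {len(grp)} records < {MIN_STRATUM_SIZE}; skipped",
                    stacklevel=2,
                )
                continue
            y = grp[self.outcome].to_numpy(dtype=float)
            years = grp[self.time].to_numpy(dtype=float)
            obs_years = sorted(int(v) for v in np.unique(years))
            fits = {}
            for tau in self.taus:
                beta, centre = _pinball_fit(y, years, tau)
                fits[tau] = (beta, centre, _fitted_by_year(beta, centre, obs_years))
            # resolve quantile crossing: sort fitted values across taus per year
            for yr in obs_years:
                vals = sorted(fits[tau][2][yr] for tau in self.taus)
                for tau, v in zip(self.taus, vals):
                    fits[tau][2][yr] = v
            cis: dict[float, dict[int, tuple[float, float]]] = {t: {} for t in self.taus}
            if n_boot:
                boot_vals = {t: np.empty((n_boot, len(obs_years))) for t in self.taus}
                n = len(grp)
                for b in range(n_boot):
                    idx = rng.integers(0, n, size=n)
                    yb, yrb = y[idx], years[idx]
                    for tau in self.taus:
                        beta_b, centre_b = _pinball_fit(yb, yrb, tau)
                        fb = _fitted_by_year(beta_b, centre_b, obs_years)
                        boot_vals[tau][b] = [fb[yr] for yr in obs_years]
                for tau in self.taus:
                    lo = np.percentile(boot_vals[tau], 2.5, axis=0)
                    hi = np.percentile(boot_vals[tau], 97.5, axis=0)
                    cis[tau] = {
                        yr: (float(lo[i]), float(hi[i]))
                        for i, yr in enumerate(obs_years)
                    }
            for tau in self.taus:
                beta, centre, fitted = fits[tau]
                trends.append(
                    QuantileTrend(
                        outcome=self.outcome,
                        tau=tau,
                        coefficients=tuple(float(b) for b in beta),
                        fitted=fitted,
                        ci=cis[tau] or None,
                        stratum=None if key is None else str(key),
                    )
                )
        return QuantileTrendResults(self, trends)


class QuantileTrendResults:
    """Fitted quantile trends with export and calibration diagnostics."""

    def __init__(self, model: QuantileTrendModel, trends: list[QuantileTrend]):
        self.model = model
        self.trends = trends

    def fitted_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trends:
            for yr, val in tr.fitted.items():
                lo, hi = (tr.ci or {}).get(yr, (np.nan, np.nan))
                rows.append(
                    (tr.outcome, tr.stratum or "", tr.tau, yr, val, lo, hi)
                )
        return pd.DataFrame(
            rows,
            columns=["outcome", "stratum", "tau", "year", "fitted", "ci_low", "ci_high"],
        )

    def fitted_at(self, tau: float, year: int, stratum: str | None = None) -> float:
        for tr in self.trends:
            if tr.tau == tau and tr.stratum == stratum:
                return tr.fitted[year]
        raise KeyError(f"no trend for tau={tau}, stratum={stratum}")

    def residual_sign_proportions(self) -> pd.DataFrame:
        """Proportion of residuals below the fitted quantile, per trend.

        For a calibrated quantile fit this proportion is close to tau
        (within ~2/sqrt(n)).
        """
        rows = []
        for tr in self.trends:
            if tr.stratum is None:
                grp = self.model.data
            else:
                grp = self.model.data[
                    self.model.data[self.model.strata].astype(str) == tr.stratum
                ]
            y = grp[self.model.outcome].to_numpy(dtype=float)
            yrs = grp[self.model.time].to_numpy()
            fitted = np.array([tr.fitted[int(v)] for v in yrs])
            prop_below = float(np.mean(y < fitted))
            rows.append((tr.outcome, tr.stratum or "", tr.tau, len(grp), prop_below))
        return pd.DataFrame(
            rows, columns=["outcome", "stratum", "tau", "n", "prop_below"]
        )

    def summary(self) -> str:
        lines = [
            f"Quantile trend of {self.model.outcome!r} on quadratic in {self.model.time!r}",
            f"taus: {self.model.taus}",
        ]
        for tr in self.trends:
            b0, b1, b2 = tr.coefficients
            yrs = sorted(tr.fitted)
            lines.append(
                f"  tau={tr.tau:.2f}"
                + (f" stratum={tr.stratum}" if tr.stratum else "")
                + f": beta=({b0:.3f}, {b1:.4f}, {b2:.5f});"
                + f" fitted {yrs[0]}: {tr.fitted[yrs[0]]:.1f}, {yrs[-1]}: {tr.fitted[yrs[-1]]:.1f}"
            )
        return "\n".join(lines)


def recent_initiates(table: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Restrict to people who started injecting within ``window`` years of survey.

    Keeps records with ``0 <= survey_year - year_first_inj < window`` (so the
    default window of 3 keeps gaps 0, 1 and 2: someone initiating in 2000 is
    counted from surveys 2000–2002).  Sampling long after initiation
    over-represents those who started young — they are likelier to still be
    injecting — so age at first injection for year ``c`` is estimated from the
    surveys immediately after ``c``, indexed by ``year_first_inj``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    gap = table["survey_year"] - table["year_first_inj"]
    return table[(gap >= 0) & (gap < window)]


def initiation_histograms(
    table: pd.DataFrame, strata: str | None = None
) -> list[InitiationHistogram]:
    """One histogram of reported initiation year per survey year (x stratum)."""
    hists = []
    if strata is None:
        groups = [((t, None), grp) for t, grp in table.groupby("survey_year")]
    else:
        groups = [
            ((t, s), grp)
            for (t, s), grp in table.groupby(["survey_year", strata], dropna=False)
        ]
    for (t, s), grp in groups:
        vc = grp["year_first_inj"].value_counts()
        counts = {int(c): float(n) for c, n in vc.items()}
        hists.append(
            InitiationHistogram(
                survey_year=int(t),
                counts=counts,
                total=float(len(grp)),
                stratum=None if s is None else str(s),
            )
        )
    return hists


def histograms_to_table(hists: Sequence[InitiationHistogram]) -> pd.DataFrame:
    rows = [
        (h.survey_year, h.stratum or "", c, n)
        for h in hists
        for c, n in sorted(h.counts.items())
    ]
    return pd.DataFrame(rows, columns=["survey_year", "stratum", "init_year", "count"])
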