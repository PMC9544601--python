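"""End-to-end orchestration: simulate -> clean -> trends -> incidence -> sensitivity.

`run_pipeline` takes a :class:`RunConfig` and either a participant-level survey
CSV or a simulation scenario config, and writes a reproducible output bundle:
clean table, exclusion log, quantile-trend CSV, initiation histograms,
incidence curves (with prediction intervals), the mean-duration sensitivity
analysis, and a machine-readable manifest sufficient to rerun the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .backcalc import CalibrationAnchor, IncidenceModel
from .cleaning import clean_survey_table, read_survey_csv
from .simulate import (
    CorruptionParams,
    SurveyDesign,
    make_scenario,
    simulate_population,
    simulate_surveys,
    write_survey_csv,
    write_true_curve,
)
from .trends import (
    DEFAULT_TAUS,
    QuantileTrendModel,
    histograms_to_table,
    initiation_histograms,
    recent_initiates,
)

logger = logging.getLogger("pwidtrends")


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the analysis' primary settings
    (mean duration 15 years, 3-year initiation window, quartile trends)."""

    seed: int = 0
    recency_mode: str = "strict"
    taus: tuple[float, ...] = DEFAULT_TAUS
    window: int = 3
    mu: float = 15.0
    mus_sensitivity: tuple[float, ...] = (10.0, 12.5, 15.0, 17.5, 20.0)
    n_mc: int = 1000
    n_boot: int = 0
    anchors: list[dict] = field(default_factory=list)
    strata: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.taus = tuple(cfg.taus)
        cfg.mus_sensitivity = tuple(cfg.mus_sensitivity)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taus"] = list(self.taus)
        d["mus_sensitivity"] = list(self.mus_sensitivity)
        return d


def _anchor_for(config: RunConfig, stratum: str) -> CalibrationAnchor | None:
    for a in config.anchors:
        if str(a.get("stratum", "")) == stratum:
            kw = {k: v for k, v in a.items() if k != "stratum"}
            return CalibrationAnchor(**kw)
    return None


def simulate_from_config(scenario_cfg: dict, outdir: Path, seed: int) -> Path:
    """Simulate a population + surveys from a scenario/design config dict.

    Expected keys: ``scenario`` (kwargs of :func:`make_scenario` plus ``shape``),
    ``mu`` (mean duration), ``design`` (survey_years, sample_size, optional
    corruption kwargs).  Writes ``survey.csv`` and a ground-truth sidecar
    ``true_curve.json``; returns the survey CSV path.
    """
    sc_kw = dict(scenario_cfg["scenario"])
    shape = sc_kw.pop("shape")
    if "years" in sc_kw:
        sc_kw["years"] = tuple(sc_kw["years"])
    scenario = make_scenario(shape, **sc_kw)
    mu = float(scenario_cfg.get("mu", 15.0))
    design_kw = dict(scenario_cfg["design"])
    corruption = CorruptionParams(**design_kw.pop("corruption", {}))
    sample_size = design_kw.pop("sample_size")
    if isinstance(sample_size, dict):
        sample_size = {int(k): int(v) for k, v in sample_size.items()}
    else:
        sample_size = {int(t): int(sample_size) for t in design_kw["survey_years"]}
    design = SurveyDesign(
        survey_years=[int(t) for t in design_kw.pop("survey_years")],
        sample_size=sample_size,
        corruption=corruption,
        seed=int(design_kw.pop("seed", seed)),
        **design_kw,
    )
    population = simulate_population(scenario, mu=mu, seed=design.seed)
    table = simulate_surveys(population, design)
    out_csv = outdir / "survey.csv"
    population.to_csv(outdir / "population.csv", index=False)
    write_survey_csv(table, out_csv)
    write_true_curve(scenario, outdir / "true_curve.json")
    logger.info("simulated %d records across %d surveys", len(table), len(design.survey_years))
    return out_csv


def _incidence_frames(
    clean: pd.DataFrame, config: RunConfig, mus: tuple[float, ...]
) -> pd.DataFrame:
    frames = []
    if config.strata is None:
        groups = [("", clean)]
    else:
        groups = [(str(k), g) for k, g in clean.groupby(config.strata, dropna=False)]
    for stratum, grp in groups:
        hists = initiation_histograms(grp)
        anchor = _anchor_for(config, stratum)
        for mu in mus:
            res = IncidenceModel(hists, mu=mu).fit(
                n_mc=config.n_mc, seed=config.seed if config.n_mc else None
            )
            if anchor is not None:
                res = res.calibrate(anchor, seed=config.seed)
            df = res.to_frame()
            df.insert(0, "mu", mu)
            df.insert(0, "stratum", stratum)
            frames.append(df)
            logger.info(
                "incidence stratum=%r mu=%g: peak cohort %d", stratum, mu, res.peak_year
            )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, input_path, outdir) -> Path:
    """Run the full analysis and write the output bundle to ``outdir``.

    ``input_path`` is either a participant-level survey CSV or a YAML/JSON
    scenario config (simulation first).  On failure no partial outputs are
    left behind.  Returns ``outdir``.
    """
    outdir = Path(outdir)
    input_path = Path(input_path)
    outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".stage-", dir=outdir.parent))
    try:
        if input_path.suffix.lower() == ".csv":
            survey_csv = input_path
        else:
            with open(input_path) as fh:
                scenario_cfg = yaml.safe_load(fh)
            survey_csv = simulate_from_config(scenario_cfg, staging, seed=config.seed)

        raw = read_survey_csv(survey_csv)
        clean, log = clean_survey_table(raw, recency_mode=config.recency_mode)
        logger.info(
            "exclusions: input=%d not_recent=%d performance_only=%d "
            "insufficient=%d implausible=%d retained=%d",
            log.input,
            log.excluded_not_recent,
            log.excluded_performance_only,
            log.excluded_insufficient,
            log.excluded_implausible,
            log.retained,
        )
        clean.to_csv(staging / "clean.csv", index=False, na_rep="")
        log.to_json(staging / "exclusion_log.json")

        trend_frames = []
        for outcome, tbl, time_col in [
            ("age", clean, "survey_year"),
            ("duration", clean, "survey_year"),
            (
                "age_first_inj",
                recent_initiates(clean, window=config.window),
                "year_first_inj",
            ),
        ]:
            res = QuantileTrendModel(
                tbl, outcome, time=time_col, taus=config.taus, strata=config.strata
            ).fit(n_boot=config.n_boot, seed=config.seed)
            trend_frames.append(res.fitted_table())
            logger.info("fitted %s quantile trends (%d records)", outcome, len(tbl))
        pd.concat(trend_frames, ignore_index=True).to_csv(
            staging / "trends.csv", index=False, na_rep=""
        )

        hists = initiation_histograms(clean, strata=config.strata)
        histograms_to_table(hists).to_csv(staging / "histograms.csv", index=False)

        _incidence_frames(clean, config, (config.mu,)).to_csv(
            staging / "incidence.csv", index=False, na_rep=""
        )
        _incidence_frames(clean, config, config.mus_sensitivity).to_csv(
            staging / "sensitivity.csv", index=False, na_rep=""
        )

        import numpy, scipy, statsmodels

        manifest = {
            "config": config.to_dict(),
            "input": str(input_path),
            "exclusions": log.to_dict(),
            "versions": {
                "pwidtrends": __version__,
                "numpy": numpy.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

        for f in sorted(staging.iterdir()):
            shutil.move(str(f), outdir / f.name)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return outdir
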