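"""Back-calculation: inversion, Monte-Carlo combination, calibration, sensitivity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pwidtrends as pt
from pwidtrends.backcalc import forward_expected_counts


class TestSurvivalModel:
    def test_survival_shape(self):
        m = pt.SurvivalModel(15)
        assert m.survival(0) == 1.0
        d = np.arange(0, 80)
        s = m.survival(d)
        assert np.all(np.diff(s) < 0)  # strictly decreasing
        assert m.survival(15) == pytest.approx(math.exp(-1))

    @pytest.mark.parametrize("mu", [0, -3, math.inf])
    def test_invalid_mu(self, mu):
        with pytest.raises(ValueError):
            pt.SurvivalModel(mu)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            pt.SurvivalModel(15).survival(-1)


class TestBackcalcSingle:
    def test_closed_form_ratio(self):
        h = pt.InitiationHistogram(2000, {1990: 10, 2000: 10}, 20)
        cur = pt.backcalc_single(h, pt.SurvivalModel(15))
        assert cur.values[1990] / cur.values[2000] == pytest.approx(
            math.exp(10 / 15), rel=1e-12
        )
        assert cur.values.sum() == pytest.approx(1.0)

    def test_point_mass(self):
        h = pt.InitiationHistogram(2000, {1995: 7}, 7)
        cur = pt.backcalc_single(h, pt.SurvivalModel(15))
        assert cur.values.to_dict() == {1995: 1.0}

    def test_zero_count_cohort_stays_zero(self):
        h = pt.InitiationHistogram(2000, {1990: 10, 1995: 0, 2000: 10}, 20)
        cur = pt.backcalc_single(h, pt.SurvivalModel(15))
        assert cur.values[1995] == 0.0

    def test_noise_free_round_trip(self):
        rng = np.random.default_rng(3)
        true = pd.Series(rng.uniform(0.5, 20, 40), index=range(1970, 2010))
        model = pt.SurvivalModel(12)
        h = forward_expected_counts(true, 2010, model)
        rec = pt.backcalc_single(h, model).values
        expect = true / true.sum()
        assert np.max(np.abs(rec.values - expect.values)) <= 1e-10

    def test_empty_histogram_rejected(self):
        h = pt.InitiationHistogram(2000, {}, 0)
        with pytest.raises(ValueError):
            pt.backcalc_single(h, pt.SurvivalModel(15))

    @given(
        mu=st.sampled_from([5.0, 10.0, 15.0, 40.0]),
        seed=st.integers(0, 10_000),
    )
    def test_forward_inverse_identity_property(self, mu, seed):
        rng = np.random.default_rng(seed)
        n_years = rng.integers(3, 30)
        start = int(rng.integers(1960, 1990))
        true = pd.Series(
            rng.uniform(0, 50, n_years), index=range(start, start + n_years)
        )
        true.iloc[0] += 1e-6  # keep at least one cohort positive
        model = pt.SurvivalModel(mu)
        t = start + n_years - 1 + int(rng.integers(0, 5))
        h = forward_expected_counts(true, t, model)
        rec = pt.backcalc_single(h, model).values
        expect = true / true.sum()
        assert np.max(np.abs(rec.values - expect.values)) <= 1e-10

    def test_misspecified_mu_bias_closed_form(self):
        """Inverting with the wrong mean duration scales cohort c by
        exp(d * (1/mu_wrong - 1/mu_true)), d the time since initiation."""
        true = pd.Series(np.linspace(5, 30, 26), index=range(1980, 2006))
        mu_true, mu_wrong = 15.0, 10.0
        h = forward_expected_counts(true, 2005, pt.SurvivalModel(mu_true))
        raw = pt.backcalc_single(h, pt.SurvivalModel(mu_wrong), normalise=False).values
        d = 2005 - raw.index.to_numpy()
        factor = np.exp(d * (1 / mu_wrong - 1 / mu_true))
        assert np.max(np.abs(raw.values / true.values - factor) / factor) <= 1e-8


class TestCombineSurveys:
    def test_single_histogram_matches_backcalc_single(self):
        h = pt.InitiationHistogram(2000, {1990: 12, 1995: 30, 2000: 8}, 50)
        model = pt.SurvivalModel(15)
        single = pt.backcalc_single(h, model)
        combined = pt.combine_surveys([h], model, n_mc=0)
        for c, v in single.values.items():
            assert combined.values[c] == pytest.approx(v, rel=1e-12)

    def test_identical_surveys_same_point_narrower_pri(self):
        true = pd.Series(np.linspace(2, 12, 16), index=range(1985, 2001))
        model = pt.SurvivalModel(15)
        h = forward_expected_counts(true * 40, 2000, model)
        h = pt.InitiationHistogram(
            2000, {c: round(n) for c, n in h.counts.items()},
            sum(round(n) for n in h.counts.values()),
        )
        one = pt.combine_surveys([h], model, n_mc=1000, seed=5)
        two = pt.combine_surveys(
            [h, pt.InitiationHistogram(2000, dict(h.counts), h.total)],
            model,
            n_mc=1000,
            seed=5,
        )
        w1 = (one.pri["pri_high"] - one.pri["pri_low"]).mean()
        w2 = (two.pri["pri_high"] - two.pri["pri_low"]).mean()
        for c in one.values.index:
            assert two.values[c] == pytest.approx(one.values[c], rel=1e-9)
        assert w2 < w1

    def test_seed_required_for_monte_carlo(self):
        h = pt.InitiationHistogram(2000, {1995: 10, 2000: 10}, 20)
        model = pt.IncidenceModel([h], mu=15)
        with pytest.raises(ValueError, match="seed"):
            model.fit(n_mc=500)

    def test_pri_brackets_point_estimate(self, england_like_fit):
        df = england_like_fit.to_frame()
        assert (df["pri_low"] <= df["n_hat"] + 1e-12).all()
        assert (df["pri_high"] >= df["n_hat"] - 1e-12).all()

    def test_relative_curve_sums_to_one(self, england_like_fit):
        assert england_like_fit.curve.values.sum() == pytest.approx(1.0)

    def test_peak_year_recovered(self, england_like, england_like_fit):
        assert abs(england_like_fit.peak_year - 1998) <= 2

    def test_recent_cohorts_have_wider_intervals(self, england_like_fit):
        """Cohorts seen by only the last few surveys have wider relative
        prediction intervals than cohorts informed by many surveys."""
        df = england_like_fit.to_frame().set_index("cohort_year")
        df = df[df["n_hat"] > 0]
        rel_width = (df["pri_high"] - df["pri_low"]) / df["n_hat"]
        last3 = rel_width.loc[df.index.max() - 2 :].mean()
        well_informed = rel_width[df["n_surveys_informing"] >= 10].mean()
        assert last3 > well_informed

    def test_prediction_interval_coverage(self):
        """Over repeated survey realisations of a fixed epidemic, the 95%
        interval covers the true relative cohort size for 85-100% of
        well-populated cohorts (>= 5 expected counts per survey), and for at
        least half of (replication, cohort) pairs overall."""
        rng = np.random.default_rng(606)
        true = pd.Series(
            np.exp(-((np.arange(1980, 1996) - 1990) ** 2) / (2 * 4.0**2)),
            index=range(1980, 1996),
        )
        model = pt.SurvivalModel(15)
        survey_years = list(range(1996, 2011))
        total = 500
        expected = {
            t: forward_expected_counts(true, t, model) for t in survey_years
        }
        probs = {
            t: np.array([h.counts[c] for c in true.index]) / h.total
            for t, h in expected.items()
        }
        # expected counts per cohort, averaged over surveys
        exp_counts = np.mean([total * probs[t] for t in survey_years], axis=0)
        hits_dense, n_dense, hits_sparse, n_sparse = 0, 0, 0, 0
        for _ in range(200):
            hists = [
                pt.InitiationHistogram(
                    t,
                    dict(zip(true.index, rng.multinomial(total, probs[t]).tolist())),
                    total,
                )
                for t in survey_years
            ]
            res = pt.IncidenceModel(hists, mu=15).fit(n_mc=200, seed=int(rng.integers(2**31)))
            df = res.to_frame().set_index("cohort_year")
            truth_rel = (true / true.sum()).reindex(df.index).fillna(0.0)
            inside = (df["pri_low"] <= truth_rel) & (truth_rel <= df["pri_high"])
            dense = pd.Series(exp_counts >= 5, index=true.index).reindex(
                df.index
            ).fillna(False)
            hits_dense += int(inside[dense].sum())
            n_dense += int(dense.sum())
            hits_sparse += int(inside[~dense].sum())
            n_sparse += int((~dense).sum())
        assert 0.85 <= hits_dense / n_dense <= 1.0
        if n_sparse:
            assert hits_sparse / n_sparse >= 0.5


class TestCalibration:
    @staticmethod
    def _flat_results():
        """Relative curve flat at 0.2 over 1996-2000 via a survey whose counts
        are proportional to the survival weights."""
        model = pt.SurvivalModel(15)
        counts = {c: math.exp(-(2000 - c) / 15.0) for c in range(1996, 2001)}
        h = pt.InitiationHistogram(2000, counts, sum(counts.values()))
        return pt.IncidenceModel([h], mu=15).fit(n_mc=0)

    def test_worked_flat_curve_example(self):
        res = self._flat_results()
        assert np.allclose(res.curve.values.values, 0.2)
        implied = res.implied_prevalence(2000)
        assert implied == pytest.approx(
            0.2 * sum(math.exp(-d / 15) for d in range(5)), rel=1e-12
        )
        assert implied == pytest.approx(0.87907, abs=5e-6)
        anchor = pt.CalibrationAnchor(ref_year=2000, prevalence=1000.0)
        cal = res.calibrate(anchor)
        assert cal.scale_factor == pytest.approx(1137.6, abs=0.1)
        assert np.allclose(cal.curve.values.values, 227.5, atol=0.05)

    def test_calibration_identity(self):
        res = self._flat_results()
        anchor = pt.CalibrationAnchor(ref_year=2000, prevalence=1234.5)
        cal = res.calibrate(anchor)
        assert abs(cal.implied_prevalence(2000) - 1234.5) / 1234.5 <= 1e-9

    def test_linearity_in_prevalence(self, england_like_fit):
        a1 = england_like_fit.calibrate(pt.CalibrationAnchor(2011, 1000.0))
        a2 = england_like_fit.calibrate(pt.CalibrationAnchor(2011, 2000.0))
        assert np.allclose(2 * a1.curve.values.values, a2.curve.values.values)
        assert np.allclose(
            2 * a1.curve.pri.to_numpy(), a2.curve.pri.to_numpy()
        )

    def test_anchor_before_cohorts_rejected(self):
        res = self._flat_results()
        with pytest.raises(ValueError):
            res.calibrate(pt.CalibrationAnchor(ref_year=1990, prevalence=100.0))

    def test_anchor_validation(self):
        with pytest.raises(ValueError):
            pt.CalibrationAnchor(ref_year=2000, prevalence=0)
        with pytest.raises(ValueError):
            pt.CalibrationAnchor(
                ref_year=2000, prevalence=100, prevalence_low=50, prevalence_high=None
            )

    def test_anchor_uncertainty_widens_intervals(self, england_like_fit):
        tight = england_like_fit.calibrate(pt.CalibrationAnchor(2011, 1000.0))
        wide = england_like_fit.calibrate(
            pt.CalibrationAnchor(
                2011, 1000.0, prevalence_low=600.0, prevalence_high=1600.0
            ),
            seed=9,
        )
        wt = (tight.curve.pri["pri_high"] - tight.curve.pri["pri_low"]).mean()
        ww = (wide.curve.pri["pri_high"] - wide.curve.pri["pri_low"]).mean()
        assert ww > wt


class TestSensitivity:
    def test_single_mu_matches_direct_fit(self, england_like):
        hists = england_like["hists"]
        direct = pt.IncidenceModel(hists, mu=15).fit(n_mc=300, seed=21)
        (res,) = pt.sensitivity(hists, [15.0], n_mc=300, seed=21).values()
        assert np.array_equal(direct._point, res._point)
        assert np.array_equal(direct._replicates, res._replicates)

    def test_adding_mu_does_not_perturb_others(self, england_like):
        hists = england_like["hists"]
        few = pt.sensitivity(hists, [10.0, 15.0], n_mc=300, seed=22)
        more = pt.sensitivity(hists, [10.0, 12.5, 15.0], n_mc=300, seed=22)
        for mu in (10.0, 15.0):
            assert np.array_equal(few[mu]._replicates, more[mu]._replicates)

    def test_early_late_ratio_decreases_with_mu(self, england_like):
        """Shorter assumed durations inflate early cohorts and deflate recent
        ones, so N(1985)/N(2010) falls as mu rises."""
        sens = pt.sensitivity(england_like["hists"], [10.0, 15.0, 20.0], n_mc=0)
        ratios = [
            sens[mu].curve.values[1985] / sens[mu].curve.values[2010]
            for mu in (10.0, 15.0, 20.0)
        ]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_calibration_identity_for_every_mu(self, england_like):
        anchor = pt.CalibrationAnchor(2011, 5000.0)
        sens = pt.sensitivity(
            england_like["hists"], [10.0, 15.0, 20.0], anchor=anchor, n_mc=0
        )
        for res in sens.values():
            assert res.implied_prevalence(2011) == pytest.approx(5000.0, rel=1e-9)

    def test_empty_mus_rejected(self, england_like):
        with pytest.raises(ValueError):
            pt.sensitivity(england_like["hists"], [], n_mc=0)
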