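"""Random-slope progression model: estimation, MSDR, prediction, residuals."""

import warnings

import numpy as np
import pandas as pd
import pytest

import stargardt_endpoint as se
from stargardt_endpoint.mixedmodel import _Z_95


def _common_slope_frame(slope=0.5, n=6):
    rows = []
    for i in range(n):
        for eye in ("OD", "OS"):
            for t in (0.0, 1.0, 2.5, 4.0):
                rows.append(
                    {"patient_id": f"P{i}", "eye": eye, "dt_years": t, "delta_c": slope * t}
                )
    return pd.DataFrame(rows)


class TestFitProgression:
    def test_noise_free_common_slope_recovered_exactly(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = se.fit_progression(_common_slope_frame(0.5))
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert fit.sd_patient < 1e-6 and fit.sd_eye < 1e-6
        assert fit.rmse < 1e-6

    def test_matches_statsmodels_reml(self):
        """Independent oracle: the same model expressed as a MixedLM with a
        patient random slope and an eye-within-patient variance component."""
        import statsmodels.formula.api as smf

        df = se.generate_delta_table(
            30, slope=0.4, sd_patient=0.15, sd_eye=0.08, resid_sd=0.13, seed=5
        )
        fit = se.fit_progression(df)
        sub = df[df.dt_years > 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = smf.mixedlm(
                "delta_c ~ 0 + dt_years",
                data=sub,
                groups="patient_id",
                re_formula="0 + dt_years",
                vc_formula={"eye": "0 + C(eye):dt_years"},
            ).fit(reml=True)
        assert fit.slope == pytest.approx(oracle.fe_params.iloc[0], rel=1e-4)
        assert fit.se_slope == pytest.approx(oracle.bse_fe.iloc[0], rel=1e-3)
        assert fit.sd_patient == pytest.approx(np.sqrt(oracle.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sd_eye == pytest.approx(np.sqrt(oracle.vcomp[0]), rel=1e-2)
        assert fit.rmse == pytest.approx(np.sqrt(oracle.scale), rel=1e-3)

    def test_wald_interval_uses_z(self):
        df = se.generate_delta_table(10, 0.4, 0.1, 0.05, 0.1, seed=3)
        fit = se.fit_progression(df)
        lo, hi = fit.ci_slope
        assert lo == pytest.approx(fit.slope - _Z_95 * fit.se_slope)
        assert hi == pytest.approx(fit.slope + _Z_95 * fit.se_slope)

    def test_scale_equivariance_and_msdr_invariance(self):
        df = se.generate_delta_table(12, 0.4, 0.1, 0.05, 0.12, seed=11)
        k = 3.7
        scaled = df.assign(delta_c=df.delta_c * k)
        f1, f2 = se.fit_progression(df), se.fit_progression(scaled)
        assert f2.slope == pytest.approx(k * f1.slope, rel=1e-5)
        assert f2.rmse == pytest.approx(k * f1.rmse, rel=1e-4)
        assert se.msdr(f2).msdr == pytest.approx(se.msdr(f1).msdr, rel=1e-4)

    def test_no_eye_effects_in_generator_shrinks_sd_eye(self):
        df = se.generate_delta_table(60, 0.4, 0.15, 0.0, 0.1, visits_range=(3, 5), seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = se.fit_progression(df)
        assert fit.sd_eye < 0.05

    def test_conditional_residuals_centred(self, dev_fit, dev_deltas):
        sub = dev_deltas[(dev_deltas.dt_years > 0) & dev_deltas.delta_c.notna()]
        resid = [
            row.delta_c - dev_fit.conditional_slopes[(row.patient_id, row.eye)] * row.dt_years
            for row in sub.itertuples()
        ]
        assert abs(np.mean(resid)) < 0.05 * np.std(resid) + 0.01

    def test_random_slopes_improve_on_slope_only_likelihood(self, dev_deltas):
        from stargardt_endpoint.mixedmodel import ModelBlocks, _neg2loglik

        fit = se.fit_progression(dev_deltas)
        dt = dev_deltas["dt_years"].to_numpy(float)
        y = dev_deltas["delta_c"].to_numpy(float)
        keep = (dt > 0) & ~np.isnan(y)
        blocks = ModelBlocks(
            dev_deltas.patient_id.to_numpy(str)[keep],
            dev_deltas.eye.to_numpy(str)[keep],
            dt[keep],
        )
        null_neg2, *_ = _neg2loglik(np.array([-30.0, -30.0]), blocks, y[keep], True)
        assert -2 * fit.loglik <= null_neg2 + 1e-6

    def test_too_few_patients_rejected(self):
        df = se.generate_delta_table(1, 0.4, 0.1, 0.05, 0.1, seed=1)
        with pytest.raises(ValueError, match="patients"):
            se.fit_progression(df)

    def test_fit_excludes_baseline_rows(self, dev_deltas):
        fit = se.fit_progression(dev_deltas)
        n_follow = int(((dev_deltas.dt_years > 0) & dev_deltas.delta_c.notna()).sum())
        assert fit.n_obs == n_follow


class TestMsdr:
    def test_zero_slope_gives_zero(self, dev_fit):
        flat = se.ProgressionFit(**{**dev_fit.__dict__, "slope": 0.0})
        assert se.msdr(flat).msdr == 0.0

    def test_zero_rmse_flagged_infinite(self, dev_fit):
        degen = se.ProgressionFit(**{**dev_fit.__dict__, "rmse": 0.0})
        res = se.msdr(degen)
        assert res.infinite and np.isinf(res.msdr)

    def test_ratio_uses_unrounded_fit(self, dev_fit):
        res = se.msdr(dev_fit)
        assert res.msdr == pytest.approx(dev_fit.slope / dev_fit.rmse, rel=1e-12)


class TestPrediction:
    def test_zero_horizon_predicts_zero(self, dev_fit):
        pid, eye = next(iter(dev_fit.conditional_slopes))
        assert se.predict_change(dev_fit, pid, eye, 0.0) == 0.0

    def test_noise_free_fit_predicts_linearly(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = se.fit_progression(_common_slope_frame(0.5))
        assert se.predict_change(fit, "P0", "OD", 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_unseen_eye_falls_back_to_population_slope(self, dev_fit):
        with pytest.warns(UserWarning, match="population"):
            val = se.predict_change(dev_fit, "nobody", "OD", 2.0)
        assert val == pytest.approx(dev_fit.slope * 2.0)

    def test_negative_horizon_rejected(self, dev_fit):
        with pytest.raises(ValueError):
            se.predict_change(dev_fit, "S01", "OD", -1.0)

    def test_more_visits_shrink_prediction_error(self):
        """With a known simulated random-effect structure, eyes observed at
        more follow-up visits get conditional slopes closer to their truth."""
        rng = np.random.default_rng(99)
        truth = {}
        rows = []
        slope, sd_p, sd_e, noise = 0.4, 0.2, 0.1, 0.1
        for n_visits, tag in ((2, "few"), (8, "many")):
            for i in range(40):
                pid = f"{tag}{i}"
                s_i = rng.normal(0, sd_p)
                for eye in ("OD", "OS"):
                    s_ij = rng.normal(0, sd_e)
                    truth[(pid, eye)] = slope + s_i + s_ij
                    times = np.linspace(0, 6, n_visits + 1)
                    for t in times:
                        y = truth[(pid, eye)] * t + (rng.normal(0, noise) if t > 0 else 0.0)
                        rows.append(
                            {"patient_id": pid, "eye": eye, "dt_years": t, "delta_c": y}
                        )
        fit = se.fit_progression(pd.DataFrame(rows))
        err = {"few": [], "many": []}
        for (pid, eye), sl in fit.conditional_slopes.items():
            tag = "few" if pid.startswith("few") else "many"
            err[tag].append(abs(sl - truth[(pid, eye)]))
        assert np.mean(err["many"]) < np.mean(err["few"])


class TestAdjustedRmse:
    def test_noise_free_is_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = se.fit_progression(_common_slope_frame(0.5))
            val = se.adjusted_rmse(fit, _common_slope_frame(0.5))
        assert val < 1e-6

    def test_symmetric_residuals_closed_form(self, dev_fit):
        pid, eye = next(iter(dev_fit.conditional_slopes))
        sl = dev_fit.conditional_slopes[(pid, eye)]
        r = 0.3
        frame = pd.DataFrame(
            [
                {"patient_id": pid, "eye": eye, "dt_years": 1.0, "delta_c": sl * 1.0 + r},
                {"patient_id": pid, "eye": eye, "dt_years": 2.0, "delta_c": sl * 2.0 - r},
            ]
        )
        assert se.adjusted_rmse(dev_fit, frame) == pytest.approx(r, rel=1e-9)

    def test_recovers_generating_residual_sd(self):
        """Conditional residuals slightly underestimate σ (the BLUPs absorb
        part of the noise), so recovery is checked at a visit density where
        the absorption is small."""
        vals = []
        for seed in range(20):
            df = se.generate_delta_table(
                25, 0.4, 0.15, 0.05, 0.13, visits_range=(6, 8), seed=seed
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = se.fit_progression(df)
            vals.append(se.adjusted_rmse(fit, df))
        assert abs(np.mean(vals) - 0.13) < 0.15 * 0.13

    def test_no_followup_records_rejected(self, dev_fit):
        frame = pd.DataFrame(
            [{"patient_id": "S01", "eye": "OD", "dt_years": 0.0, "delta_c": 0.0}]
        )
        with pytest.raises(ValueError):
            se.adjusted_rmse(dev_fit, frame)
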