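import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from brainpbpk import iv_bolus
from brainpbpk.estimation import (
    FitResult,
    asymptotic_cv,
    fit_stage1_serum,
    fit_stage2_brain,
    inv_logit,
    local_sensitivity,
    logit,
    prediction_error,
)

BW = 0.310


class TestLogit:
    def test_half_maps_to_zero_and_back(self):
        assert logit(0.5) == 0.0
        assert inv_logit(0.0) == 0.5

    def test_table_value(self):
        assert logit(0.9853) == pytest.approx(np.log(0.9853 / 0.0147), rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            logit(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_round_trip(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)


class TestStage1:
    def test_requires_serum_records(self, phys, egfr, noisefree_df):
        no_serum = noisefree_df[noisefree_df["matrix"] != "serum"]
        with pytest.raises(ValueError):
            fit_stage1_serum(no_serum, phys, egfr)

    def test_exact_data_gives_zero_objective(self, phys, egfr, noisefree_df):
        fit = fit_stage1_serum(noisefree_df, phys, egfr)
        assert fit.objective == pytest.approx(0.0, abs=1e-12)
        assert fit.cv_percent["log_k_deg"] == pytest.approx(0.0, abs=1e-6)

    def test_single_time_point_flagged(self, phys, egfr, noisefree_df):
        one_time = noisefree_df[
            (noisefree_df["matrix"] == "serum") & (noisefree_df["time_h"] == 6.0)
        ]
        fit = fit_stage1_serum(one_time, phys, egfr)
        assert any("single time point" in f for f in fit.flags)

    def test_objective_trace_is_monotone(self, phys, egfr, noisefree_df):
        fit = fit_stage1_serum(noisefree_df, phys, egfr.replace(k_deg=20.0))
        assert np.all(np.diff(fit.objective_trace) <= 0)


class TestStage2:
    def test_empty_free_set_rejected(self, phys, egfr, noisefree_df):
        with pytest.raises(ValueError):
            fit_stage2_brain(noisefree_df, phys, egfr, free=())

    def test_sigma_csf_isf_not_identifiable_from_iv_only(self, phys, egfr, noisefree_df):
        iv_only = noisefree_df[noisefree_df["route"] == "iv"]
        with pytest.raises(ValueError):
            fit_stage2_brain(iv_only, phys, egfr)

    def test_estimates_invariant_to_row_order(self, phys, egfr, noisefree_df):
        sub = noisefree_df[
            (noisefree_df["route"] == "iv")
            & noisefree_df["time_h"].isin([1.0, 3.0, 6.0, 12.0, 24.0, 2.25, 10.0])
        ]
        start = egfr.replace(sigma_BBB=0.97, sigma_BCSFB=0.97)
        free = ("sigma_BBB", "sigma_BCSFB")
        f1 = fit_stage2_brain(sub, phys, start, free=free, n_starts=1)
        shuffled = sub.sample(frac=1.0, random_state=5)
        f2 = fit_stage2_brain(shuffled, phys, start, free=free, n_starts=1)
        for k in f1.transformed_estimates:
            assert f1.transformed_estimates[k] == pytest.approx(
                f2.transformed_estimates[k], rel=1e-6
            )


class TestAsymptoticCV:
    def test_linear_model_matches_closed_form(self):
        # y = theta * x with known data: SE^2 = s2 / sum(x^2)
        rng = np.random.default_rng(0)
        x = np.linspace(1, 5, 20)
        y = 2.0 * x + rng.normal(0, 0.3, size=x.size)
        res = least_squares(lambda th: y - th[0] * x, x0=[1.0])
        fit = FitResult(
            stage="brain",
            estimates={"theta": res.x[0]},
            transformed_estimates={"theta": res.x[0]},
            cv_percent={},
            objective=float(res.fun @ res.fun),
            n_obs=x.size,
            residuals=res.fun,
            converged=True,
            jacobian=res.jac,
        )
        s2 = fit.objective / (x.size - 1)
        expected = 100 * np.sqrt(s2 / np.sum(x**2)) / abs(res.x[0])
        assert asymptotic_cv(fit)["theta"] == pytest.approx(expected, rel=1e-6)

    def test_singular_information_flagged_infinite(self):
        fit = FitResult(
            stage="brain",
            estimates={"a": 1.0, "b": 1.0},
            transformed_estimates={"a": 1.0, "b": 1.0},
            cv_percent={},
            objective=1.0,
            n_obs=5,
            residuals=np.ones(5),
            converged=True,
            jacobian=np.ones((5, 2)),  # rank 1: a and b indistinguishable
        )
        cvs = asymptotic_cv(fit)
        assert any(not np.isfinite(v) or v > 100 for v in cvs.values())


class TestPredictionError:
    @pytest.mark.parametrize(
        "pred,obs,expected", [(100, 100, 0.0), (150, 100, 50.0), (50, 100, -50.0)]
    )
    def test_formula(self, pred, obs, expected):
        assert prediction_error(pred, obs) == expected

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(10.0, 0.0)


class TestLocalSensitivity:
    def test_dilution_volume_has_unit_negative_sensitivity(self, phys, egfr):
        # serum concentration just after an IV bolus is dose / V_plasma,
        # a pure power law in the plasma volume
        doses = [iv_bolus(15.0, BW, egfr.MW)]
        grid = np.array([0.0, 1e-4, 1.0])
        out = local_sensitivity(
            phys, egfr, doses,
            output=lambda sim: float(sim.conc("plasma")[0]),
            perturbation=0.05,
            parameters=["V_plasma"],
            t_grid=grid,
        )
        assert out["V_plasma"] == pytest.approx(-1.0, abs=1e-6)

    def test_blocked_route_parameter_has_zero_sensitivity(self, phys, egfr):
        # with sigma_TV = 1 and FR = 1 nothing ever reaches tissue ISF, so
        # the downstream lymphatic reflection cannot influence serum AUC
        blocked = phys.replace(sigma_TV=1.0, FR=1.0)
        doses = [iv_bolus(15.0, BW, egfr.MW)]
        grid = np.linspace(0, 24, 25)
        out = local_sensitivity(
            blocked, egfr, doses,
            output=lambda sim: float(np.trapezoid(sim.conc("plasma"), sim.t)),
            parameters=["sigma_TL"],
            t_grid=grid,
        )
        assert out["sigma_TL"] == pytest.approx(0.0, abs=1e-9)

    def test_power_law_output_is_step_independent(self, phys, egfr):
        doses = [iv_bolus(15.0, BW, egfr.MW)]
        grid = np.array([0.0, 1e-4, 1.0])
        vals = [
            local_sensitivity(
                phys, egfr, doses,
                output=lambda sim: float(sim.conc("plasma")[0]),
                perturbation=h,
                parameters=["V_plasma"],
                t_grid=grid,
            )["V_plasma"]
            for h in (0.05, 0.2)
        ]
        assert vals[0] == pytest.approx(vals[1], abs=1e-3)

    def test_bad_perturbation_rejected(self, phys, egfr):
        with pytest.raises(ValueError):
            local_sensitivity(
                phys, egfr, [iv_bolus(15.0, BW, egfr.MW)],
                output=lambda sim: 1.0, perturbation=0.9,
            )
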