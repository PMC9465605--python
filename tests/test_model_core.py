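import numpy as np
import pytest

from brainpbpk import (
    DoseEvent,
    STATES,
    default_time_grid,
    dose_from_mgkg,
    icv_infusion,
    iv_bolus,
    rhs,
    simulate,
)
from brainpbpk.params import STATE_INDEX

BW = 0.310


class TestDoseArithmetic:
    @pytest.mark.parametrize(
        "mgkg,expected_nmol",
        [(15.0, 23.846), (3.0, 4.7692), (1.0, 1.5897)],
    )
    def test_mgkg_to_nmol(self, mgkg, expected_nmol):
        assert dose_from_mgkg(mgkg, BW, 195_000.0) == pytest.approx(
            expected_nmol, rel=1e-3
        )

    @pytest.mark.parametrize("bad", [(0, 0.3, 195e3), (1, -1, 195e3), (1, 0.3, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            dose_from_mgkg(*bad)

    def test_icv_infusion_duration_follows_pump_arithmetic(self):
        # 3 mg/kg at 20 mg/ml is 46.5 ul, i.e. 15.5 min at 3 ul/min
        ev = icv_infusion(3.0, BW, 195_000.0, 20.0, 3.0)
        assert ev.amount == pytest.approx(4.7692, rel=1e-4)
        assert ev.duration == pytest.approx(15.5 / 60.0, rel=1e-9)
        assert ev.route == "icv" and ev.target == "csf_LV"
        # 1 mg/kg is a 5.167-min infusion
        assert icv_infusion(1.0, BW, 195_000.0).duration == pytest.approx(
            5.1667 / 60.0, rel=1e-4
        )

    def test_zero_flow_rate_rejected(self):
        with pytest.raises(ValueError):
            icv_infusion(3.0, BW, 195_000.0, 20.0, 0.0)

    def test_route_target_consistency_enforced(self):
        with pytest.raises(ValueError):
            DoseEvent(route="iv", amount=1.0, target="csf_LV")


class TestRHS:
    def test_derivatives_conserve_mass_without_degradation(self, phys, egfr):
        drug = egfr.replace(k_deg=0.0)
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 5, size=13)
        drug_idx = [i for i, s in enumerate(STATES) if s != "tissue_endo_FcRn"]
        dy = rhs(y, 0.0, phys, drug)
        assert sum(dy[i] for i in drug_idx) == pytest.approx(0.0, abs=1e-12)
        dy = rhs(y, 0.0, phys, drug, infusion_rate={"csf_LV": 7.5})
        assert sum(dy[i] for i in drug_idx) == pytest.approx(7.5, rel=1e-12)

    def test_fully_reflecting_barriers_keep_brain_empty(self, phys, egfr):
        drug = egfr.replace(sigma_BBB=1 - 1e-15, sigma_BCSFB=1 - 1e-15)
        y = np.zeros(13)
        y[STATE_INDEX["plasma"]] = 10.0
        y[STATE_INDEX["tissue_endo_FcRn"]] = phys.FcRn_SS * phys.V_tissue_endo
        dy = rhs(y, 0.0, phys, drug)
        brain = ["csf_LV", "csf_TFV", "csf_CM", "csf_SAS", "brain_isf"]
        for s in brain:
            assert dy[STATE_INDEX[s]] == pytest.approx(0.0, abs=1e-12)

    def test_bbb_influx_matches_hand_arithmetic(self, phys, egfr):
        # (1 - 0.9853) * 3.0e-5 L/h * 1 nM = 4.41e-7 nmol/h into brain ISF
        y = np.zeros(13)
        y[STATE_INDEX["brain_vasc"]] = phys.V_brain_vasc * 1.0  # C_bv = 1 nM
        dy = rhs(y, 0.0, phys, egfr)
        assert dy[STATE_INDEX["brain_isf"]] == pytest.approx(4.41e-7, rel=1e-6)

    def test_nonfinite_state_rejected(self, phys, egfr):
        y = np.zeros(13)
        y[0] = np.nan
        with pytest.raises(ValueError):
            rhs(y, 0.0, phys, egfr)


class TestSimulate:
    def test_zero_doses_gives_zero_drug_and_constant_fcrn(self, phys, egfr):
        sim = simulate(phys, egfr, [], np.linspace(0, 10, 11))
        assert np.all(sim.total_drug() == 0.0)
        fcrn = sim.amount("tissue_endo_FcRn")
        np.testing.assert_allclose(fcrn, phys.FcRn_SS * phys.V_tissue_endo, rtol=1e-9)

    def test_mass_balance_without_degradation(self, phys, egfr):
        drug = egfr.replace(k_deg=0.0)
        dose = iv_bolus(15.0, BW, drug.MW)
        sim = simulate(phys, drug, [dose], default_time_grid(48.0))
        np.testing.assert_allclose(sim.total_drug(), dose.amount, rtol=1e-6)

    def test_mass_balance_with_infusion_schedule(self, phys, egfr):
        drug = egfr.replace(k_deg=0.0)
        ev = icv_infusion(3.0, BW, drug.MW)
        sim = simulate(phys, drug, [ev], default_time_grid(8.0))
        administered = ev.rate * np.clip(sim.t, 0.0, ev.duration)
        np.testing.assert_allclose(sim.total_drug(), administered, atol=ev.amount * 1e-6)

    def test_initial_serum_concentration_is_dose_over_plasma_volume(self, iv_sim, phys):
        assert iv_sim.conc("plasma")[0] == pytest.approx(
            iv_sim.doses[0].amount / phys.V_plasma, rel=1e-9
        )

    def test_fcrn_pool_is_conserved(self, iv_sim, phys):
        total = iv_sim.amount("tissue_endo_FcRn") + iv_sim.amount("tissue_endo_complex")
        np.testing.assert_allclose(total, phys.FcRn_SS * phys.V_tissue_endo, rtol=1e-6)

    def test_states_stay_nonnegative(self, iv_sim, icv3_sim):
        assert np.all(iv_sim.amounts >= 0)
        assert np.all(icv3_sim.amounts >= 0)

    def test_dose_normalised_icv_profiles_superimpose(self, phys, egfr):
        # linear disposition: with a common input shape, 1 and 3 mg/kg ICV
        # overlay after dose normalisation (endosomal drug << FcRn pool)
        grid = default_time_grid(48.0)
        dur = icv_infusion(3.0, BW, egfr.MW).duration
        sims = {
            mgkg: simulate(
                phys,
                egfr,
                [DoseEvent("icv", dose_from_mgkg(mgkg, BW, egfr.MW), 0.0, dur)],
                grid,
            )
            for mgkg in (1.0, 3.0)
        }
        mask = grid >= 0.5
        for state in ("csf_CM", "brain_isf"):
            c1 = sims[1.0].conc(state)[mask] / sims[1.0].doses[0].amount
            c3 = sims[3.0].conc(state)[mask] / sims[3.0].doses[0].amount
            np.testing.assert_allclose(c1, c3, rtol=0.01)

    def test_brain_vascular_tracks_plasma_after_distribution(self, iv_sim):
        mask = iv_sim.t >= 1.0
        ratio = iv_sim.conc("brain_vasc")[mask] / iv_sim.conc("plasma")[mask]
        np.testing.assert_allclose(ratio, 1.0, atol=0.01)

    def test_state_layout_is_thirteen(self):
        assert len(STATES) == 13

    def test_dose_outside_grid_rejected(self, phys, egfr):
        with pytest.raises(ValueError):
            simulate(
                phys, egfr, [iv_bolus(15.0, BW, egfr.MW, t_start=100.0)],
                np.linspace(0, 48, 10),
            )

    def test_concentrations_are_amounts_over_volume(self, iv_sim, phys):
        vols = phys.state_volumes()
        for i, s in enumerate(STATES):
            np.testing.assert_allclose(
                iv_sim.concentrations[i], iv_sim.amounts[i] / vols[s], rtol=1e-12
            )
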