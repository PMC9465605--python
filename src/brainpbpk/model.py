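"""The 13-state reduced brain PBPK ODE system and its simulator.

All fluxes are convective: a flow Q (L/h) carries drug at concentration C
(nM) past a barrier with reflection coefficient sigma, delivering
``(1 - sigma) * Q * C`` nmol/h.  The only elimination is first-order
degradation of unbound antibody in the rest-of-body endosomal space;
the brain has no elimination pathway.  FcRn binding in the endosome
rescues drug: the complex is exocytosed at the uptake rate, a fraction FR
returning to the tissue vasculature and the rest delivered to tissue ISF,
with the receptor recycled to the free pool either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import (
    DRUG_STATES,
    STATE_INDEX,
    STATES,
    DoseEvent,
    DrugParameterSet,
    PhysiologicalParameterSet,
)

__all__ = [
    "SimulationResult",
    "rhs",
    "simulate",
    "dose_from_mgkg",
    "iv_bolus",
    "icv_infusion",
    "default_time_grid",
]

_I = STATE_INDEX
_DRUG_IDX = np.array([_I[s] for s in DRUG_STATES])


def rhs(
    state: np.ndarray,
    t: float,
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    infusion_rate: dict[str, float] | None = None,
) -> np.ndarray:
    """Time derivative (nmol/h) of the 13 state amounts (nmol).

    ``infusion_rate`` maps target state names to constant input rates in
    nmol/h (active infusions at time ``t``).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (13,):
        raise ValueError(f"state must be a 13-vector, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs")
    p, d = phys, drug

    C_p = y[0] / p.V_plasma
    C_ly = y[1] / p.V_lymph
    C_tv = y[2] / p.V_tissue_vasc
    C_ef = y[3] / p.V_tissue_endo
    C_R = y[5] / p.V_tissue_endo
    C_ti = y[6] / p.V_tissue_isf
    C_bv = y[7] / p.V_brain_vasc
    C_lv = y[8] / p.V_LV
    C_tfv = y[9] / p.V_TFV
    C_cm = y[10] / p.V_CM
    C_sas = y[11] / p.V_SAS
    C_isf = y[12] / p.V_brain_isf

    # rest-of-body endosomal FcRn cycle
    uptake = p.k_CLupT * p.V_tissue_endo * C_tv
    bind = p.k_on_FcRn * C_ef * C_R * p.V_tissue_endo
    dissoc = p.k_off_FcRn * y[4]
    exo = p.k_CLupT * y[4]
    deg = d.k_deg * y[3]

    # tissue convection
    tv_to_tisf = (1.0 - p.sigma_TV) * p.L_t * C_tv
    tisf_to_ly = (1.0 - p.sigma_TL) * p.L_t * C_ti

    # brain barriers and CSF chain
    q_half = 0.5 * (p.Q_CSF + p.Q_ISF)  # flow leaving LV
    q_full = p.Q_CSF + p.Q_ISF  # flow leaving TFV and CM
    bcsfb = (1.0 - d.sigma_BCSFB) * p.Q_CSF * C_bv  # split LV/TFV
    bbb = (1.0 - d.sigma_BBB) * p.Q_ISF * C_bv
    glymph = (1.0 - d.sigma_CSF_ISF) * p.Q_ISF * C_sas
    isf_recycle = (1.0 - p.sigma_BISF) * (0.5 * p.Q_ISF) * C_isf  # to LV and to TFV
    isf_to_ly = (1.0 - p.sigma_BISF) * p.Q_ISF * C_isf
    sas_to_ly = (1.0 - p.sigma_CSF) * p.Q_CSF * C_sas

    dy = np.empty(13)
    dy[0] = (
        (p.Q_t - p.L_t) * C_tv
        + (p.Q_b - p.L_b) * C_bv
        + (p.L_t + p.L_b) * C_ly
        - (p.Q_t + p.Q_b) * C_p
    )
    dy[1] = tisf_to_ly + sas_to_ly + isf_to_ly - (p.L_t + p.L_b) * C_ly
    dy[2] = p.Q_t * C_p - (p.Q_t - p.L_t) * C_tv - tv_to_tisf - uptake + p.FR * exo
    dy[3] = uptake - bind + dissoc - deg
    dy[4] = bind - dissoc - exo
    dy[5] = -bind + dissoc + exo
    dy[6] = tv_to_tisf + (1.0 - p.FR) * exo - tisf_to_ly
    dy[7] = p.Q_b * C_p - (p.Q_b - p.L_b) * C_bv - bcsfb - bbb
    dy[8] = 0.5 * bcsfb + isf_recycle - q_half * C_lv
    dy[9] = 0.5 * bcsfb + isf_recycle + q_half * C_lv - q_full * C_tfv
    dy[10] = q_full * C_tfv - q_full * C_cm
    dy[11] = q_full * C_cm - glymph - sas_to_ly
    dy[12] = bbb + glymph - 2.0 * isf_recycle - isf_to_ly

    if infusion_rate:
        for target, rate in infusion_rate.items():
            try:
                dy[_I[target]] += rate
            except KeyError:
                raise ValueError(f"unknown infusion target {target!r}") from None
    return dy


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories of all 13 states on the requested output grid."""

    t: np.ndarray  # (n,) h
    amounts: np.ndarray  # (13, n) nmol
    doses: tuple[DoseEvent, ...]
    volumes: dict[str, float]

    @property
    def concentrations(self) -> np.ndarray:
        v = np.array([self.volumes[s] for s in STATES])
        return self.amounts / v[:, None]

    def amount(self, state: str) -> np.ndarray:
        return self.amounts[_I[state]]

    def conc(self, state: str) -> np.ndarray:
        """Concentration trajectory (nM) of one state."""
        return self.amounts[_I[state]] / self.volumes[state]

    def total_drug(self) -> np.ndarray:
        """Total drug amount (nmol) summed over the 12 drug-carrying states."""
        return self.amounts[_DRUG_IDX].sum(axis=0)

    def to_frame(self, concentrations: bool = True) -> pd.DataFrame:
        data = self.concentrations if concentrations else self.amounts
        df = pd.DataFrame(data.T, columns=list(STATES))
        df.insert(0, "time_h", self.t)
        return df


def default_time_grid(t_end: float = 48.0) -> np.ndarray:
    """Output grid: 0.01 h steps over the first hour, 0.1 h thereafter."""
    fine = np.arange(0.0, min(1.0, t_end), 0.01)
    coarse = np.arange(1.0, t_end + 1e-12, 0.1)
    return np.unique(np.concatenate([fine, coarse, [t_end]]))


def _initial_state(phys: PhysiologicalParameterSet) -> np.ndarray:
    y0 = np.zeros(13)
    y0[_I["tissue_endo_FcRn"]] = phys.FcRn_SS * phys.V_tissue_endo
    return y0


def simulate(
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    doses: list[DoseEvent] | tuple[DoseEvent, ...],
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model over ``t_grid`` with the given dose schedule.

    Bolus doses are instantaneous additions to the target state; infusions
    are constant-rate inputs.  Integration is piecewise between dose-event
    breakpoints so that short ICV infusions are resolved exactly.
    """
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a sorted 1-D array of >= 2 distinct times")
    t0, t_end = t_grid[0], t_grid[-1]
    doses = tuple(doses)
    for ev in doses:
        if ev.t_start < t0 or ev.t_end > t_end:
            raise ValueError(
                f"dose event [{ev.t_start}, {ev.t_end}] h outside the "
                f"simulation span [{t0}, {t_end}] h"
            )

    breaks = {t0, t_end}
    for ev in doses:
        breaks.add(ev.t_start)
        if ev.duration > 0:
            breaks.add(ev.t_end)
    breaks = np.array(sorted(breaks))

    y = _initial_state(phys)
    out = np.empty((13, t_grid.size))
    filled = np.zeros(t_grid.size, dtype=bool)

    def fun(t, y, rates):
        return rhs(y, t, phys, drug, rates)

    for a, b in zip(breaks[:-1], breaks[1:]):
        for ev in doses:
            if ev.duration == 0 and ev.t_start == a:
                y[_I[ev.target]] += ev.amount
        rates: dict[str, float] = {}
        for ev in doses:
            if ev.duration > 0 and ev.t_start <= a and ev.t_end >= b:
                rates[ev.target] = rates.get(ev.target, 0.0) + ev.rate
        mask = (t_grid >= a) & (t_grid <= b) & ~filled
        t_eval = np.unique(np.concatenate([t_grid[mask], [b]]))
        sol = solve_ivp(
            fun,
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(rates,),
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{a}, {b}] h: {sol.message}")
        if mask.any():
            cols = np.searchsorted(sol.t, t_grid[mask])
            out[:, mask] = sol.y[:, cols]
            filled |= mask
        y = sol.y[:, -1].copy()

    # boluses at the very end of the grid (degenerate but legal)
    for ev in doses:
        if ev.duration == 0 and ev.t_start == t_end:
            out[_I[ev.target], -1] += ev.amount

    out[out < 0] = np.where(out[out < 0] > -10 * atol, 0.0, out[out < 0])
    return SimulationResult(t=t_grid, amounts=out, doses=doses, volumes=phys.state_volumes())


def dose_from_mgkg(dose_mgkg: float, body_weight_kg: float, MW: float) -> float:
    """Convert a mg/kg dose to nmol for a given body weight and MW (g/mol)."""
    if dose_mgkg <= 0 or body_weight_kg <= 0 or MW <= 0:
        raise ValueError("dose, body weight and molecular weight must be positive")
    return dose_mgkg * body_weight_kg / MW * 1e6


def iv_bolus(
    dose_mgkg: float, body_weight_kg: float, MW: float, t_start: float = 0.0
) -> DoseEvent:
    """IV tail-vein injection modelled as an instantaneous plasma bolus."""
    return DoseEvent(
        route="iv",
        amount=dose_from_mgkg(dose_mgkg, body_weight_kg, MW),
        t_start=t_start,
    )


def icv_infusion(
    dose_mgkg: float,
    body_weight_kg: float,
    MW: float,
    formulation_conc_mg_ml: float = 20.0,
    flow_rate_ul_min: float = 3.0,
    t_start: float = 0.0,
) -> DoseEvent:
    """ICV dose into the lateral ventricle as a constant-rate infusion.

    The infusion duration follows from the formulation concentration and
    the pump flow rate: a 3 mg/kg dose in a 310 g rat at 20 mg/ml and
    3 ul/min is 46.5 ul over 15.5 min.
    """
    if formulation_conc_mg_ml <= 0 or flow_rate_ul_min <= 0:
        raise ValueError("formulation concentration and flow rate must be positive")
    amount = dose_from_mgkg(dose_mgkg, body_weight_kg, MW)
    volume_ul = dose_mgkg * body_weight_kg / formulation_conc_mg_ml * 1000.0
    duration_h = volume_ul / flow_rate_ul_min / 60.0
    return DoseEvent(
        route="icv", amount=amount, t_start=t_start, duration=duration_h
    )
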