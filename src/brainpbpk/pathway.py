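"""Pathway analyses: where the antibody in brain ISF comes from and how
much of the serum exposure it represents.

Two convective routes feed the brain interstitial fluid: the serum route
across the BBB, with instantaneous flux ``(1 - sigma_BBB) * Q_ISF *
C_serum``, and the direct CSF route across the CSF-ISF barrier, with flux
``(1 - sigma_CSF_ISF) * Q_ISF * C_SAS``.  Integrating both over the
observation window and normalising gives each route's share of total ISF
input.  The exposure share ISF/serum% = AUC_ISF / (AUC_serum + AUC_ISF)
* 100 scales those shares to the fraction of serum exposure reaching ISF.

A separate, model-agnostic utility apportions endosomal elimination
between brain and rest-of-body for models that carry brain endosomal
compartments (the reduced model here deliberately does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SimulationResult
from .nca import auc_trapezoid
from .params import DrugParameterSet, PhysiologicalParameterSet

__all__ = [
    "PathwayResult",
    "isf_source_contributions",
    "isf_serum_share",
    "elimination_pathway_share",
]


@dataclass(frozen=True)
class PathwayResult:
    """Source apportionment of brain-ISF input over a time window."""

    frac_serum_to_isf: float  # % of ISF input via the BBB (serum route)
    frac_csf_to_isf: float  # % of ISF input via the CSF-ISF barrier
    isf_serum_share: float  # % exposure share, AUC_ISF/(AUC_serum+AUC_ISF)
    scaled_serum_contribution: float  # route share x exposure share, %
    scaled_csf_contribution: float
    auc_serum: float  # nM*h over the window
    auc_sas: float
    auc_isf: float
    window: tuple[float, float]


def _window_slice(sim: SimulationResult, T: float):
    if T <= sim.t[0] or T > sim.t[-1] + 1e-12:
        raise ValueError(f"window end {T} h outside simulated span")
    mask = sim.t <= T
    return sim.t[mask]


def isf_source_contributions(
    sim: SimulationResult,
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    T: float = 48.0,
) -> PathwayResult:
    """Apportion ISF input between the serum (BBB) and CSF routes.

    Both route fluxes are integrated by linear trapezoid over [0, T] on
    the simulation grid; the serum-route flux uses the serum (plasma)
    concentration as printed in the flux definition, not the
    brain-vascular concentration (the two track within ~1%).
    """
    t = _window_slice(sim, T)
    n = t.size
    c_serum = sim.conc("plasma")[:n]
    c_sas = sim.conc("csf_SAS")[:n]
    c_isf = sim.conc("brain_isf")[:n]

    flux_serum = (1.0 - drug.sigma_BBB) * phys.Q_ISF * c_serum
    flux_csf = (1.0 - drug.sigma_CSF_ISF) * phys.Q_ISF * c_sas
    a_serum_route = auc_trapezoid(t, flux_serum)
    a_csf_route = auc_trapezoid(t, flux_csf)
    total = a_serum_route + a_csf_route
    if total <= 0:
        raise ValueError("no antibody input into ISF over the window")
    frac_serum = 100.0 * (a_serum_route / total)  # ratio first: exact at 0/1
    frac_csf = 100.0 - frac_serum

    auc_serum = auc_trapezoid(t, c_serum)
    auc_isf = auc_trapezoid(t, c_isf)
    share = isf_serum_share(auc_isf, auc_serum)
    return PathwayResult(
        frac_serum_to_isf=frac_serum,
        frac_csf_to_isf=frac_csf,
        isf_serum_share=share,
        scaled_serum_contribution=frac_serum * share / 100.0,
        scaled_csf_contribution=frac_csf * share / 100.0,
        auc_serum=auc_serum,
        auc_sas=auc_trapezoid(t, c_sas),
        auc_isf=auc_isf,
        window=(float(t[0]), float(t[-1])),
    )


def isf_serum_share(auc_isf: float, auc_serum: float) -> float:
    """Exposure share ISF/serum% = AUC_ISF / (AUC_serum + AUC_ISF) * 100."""
    if auc_isf < 0 or auc_serum < 0:
        raise ValueError("AUCs must be non-negative")
    if auc_isf + auc_serum == 0:
        raise ValueError("both AUCs are zero")
    return 100.0 * auc_isf / (auc_serum + auc_isf)


def elimination_pathway_share(
    t,
    brain_endosome_conc: dict[str, np.ndarray],
    brain_endosome_volumes: dict[str, float],
    tissue_endosome_conc: dict[str, np.ndarray],
    tissue_endosome_volumes: dict[str, float],
    k_deg: float,
    T: float | None = None,
) -> float:
    """Brain share (%) of total endosomal elimination up to T.

    Degradation in each endosomal pool proceeds at ``k_deg * C * V``;
    integrating over time and forming brain / (brain + tissue) gives the
    brain's percentage contribution to total clearance.  Generic over any
    model that reports endosomal concentration trajectories (e.g. a full
    minimal-PBPK model with BBB and BCSFB endosomes).
    """
    t = np.asarray(t, dtype=float)
    if k_deg < 0:
        raise ValueError("k_deg must be >= 0")
    T = float(t[-1]) if T is None else float(T)
    mask = t <= T
    tt = t[mask]
    if tt.size < 2:
        raise ValueError("need at least 2 time points inside the window")

    def cleared(conc_map, vol_map):
        total = 0.0
        for name, conc in conc_map.items():
            conc = np.asarray(conc, dtype=float)
            if conc.shape != t.shape:
                raise ValueError(f"trajectory {name!r} not on the common time grid")
            total += vol_map[name] * auc_trapezoid(tt, conc[mask])
        return k_deg * total

    brain = cleared(brain_endosome_conc, brain_endosome_volumes)
    tissue = cleared(tissue_endosome_conc, tissue_endosome_volumes)
    if brain + tissue == 0:
        return 0.0
    return 100.0 * brain / (brain + tissue)
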