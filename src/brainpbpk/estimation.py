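"""Two-stage naive-pooled nonlinear least-squares estimation.

Stage 1 fits the endosomal degradation rate ``k_deg`` (log scale) to
pooled serum concentrations after IV dosing with a proportional error
model.  Stage 2 fixes ``k_deg`` and fits the logit-transformed barrier
reflection coefficients simultaneously to CSF and recovery-corrected ISF
data across all dose groups with a constant (additive) error model.
Precision is reported as asymptotic CV% from the linearised covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import dose_from_mgkg, icv_infusion, iv_bolus, simulate
from .params import (
    STATE_INDEX as _STATE_I,
    DoseEvent,
    DrugParameterSet,
    PhysiologicalParameterSet,
)

__all__ = [
    "FitResult",
    "logit",
    "inv_logit",
    "doses_for_group",
    "fit_stage1_serum",
    "fit_stage2_brain",
    "asymptotic_cv",
    "prediction_error",
    "local_sensitivity",
]

SIGMA_NAMES = ("sigma_BBB", "sigma_BCSFB", "sigma_CSF_ISF")


def logit(p):
    """log(p / (1-p)); defined only strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires 0 < p < 1")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return float(out) if out.ndim == 0 else out


@dataclass
class FitResult:
    """Outcome of one estimation stage."""

    stage: str  # "serum" | "brain"
    estimates: dict[str, float]  # natural scale
    transformed_estimates: dict[str, float]  # log / logit scale
    cv_percent: dict[str, float]  # on the estimation scale
    objective: float  # final weighted SSR
    n_obs: int
    residuals: np.ndarray
    converged: bool
    message: str = ""
    flags: list[str] = field(default_factory=list)
    objective_trace: np.ndarray | None = None  # accepted objective values
    jacobian: np.ndarray | None = None  # at the solution, estimation scale

    @property
    def scale(self) -> str:
        """Scale on which transformed estimates, CV% and the Jacobian live."""
        return "log" if self.stage == "serum" else "logit"


def doses_for_group(
    route: str,
    dose_mgkg: float,
    drug: DrugParameterSet,
    body_weight_kg: float = 0.310,
) -> list[DoseEvent]:
    """Dose schedule implied by a study arm (route, mg/kg dose)."""
    if route.lower() == "iv":
        return [iv_bolus(dose_mgkg, body_weight_kg, drug.MW)]
    if route.lower() == "icv":
        return [icv_infusion(dose_mgkg, body_weight_kg, drug.MW)]
    raise ValueError(f"unknown route {route!r}")


def _clean(data: pd.DataFrame, matrices: tuple[str, ...]) -> pd.DataFrame:
    """Fitting subset: requested matrices, post-dose, above LLOQ."""
    m = (
        data["matrix"].isin(matrices)
        & (data["time_h"] > 0)
        & ~data["bloq"].astype(bool)
    )
    return data.loc[m]

_CHANNELS = {"serum": "plasma", "csf": "csf_CM", "isf_dialysate": "brain_isf"}


class _Predictor:
    """Per-row model predictions over pooled dose groups.

    Each group is simulated once per call on the union of its observation
    times; row lookups (state channel, time index) are precomputed so a
    residual evaluation costs one simulation per group.
    """

    def __init__(self, data, phys, body_weight_kg, rtol, atol):
        self.phys, self.rtol, self.atol = phys, rtol, atol
        self.n = len(data)
        self.groups = []
        order = np.arange(self.n)
        for (grp, route, mgkg), sub_idx in data.groupby(
            ["group", "route", "dose_mgkg"], sort=False
        ).indices.items():
            sub = data.iloc[sub_idx]
            times = np.unique(sub["time_h"].to_numpy(float))
            grid = np.unique(np.concatenate([[0.0], times]))
            lookup = {}
            for matrix, state in _CHANNELS.items():
                sel = (sub["matrix"] == matrix).to_numpy()
                if sel.any():
                    lookup[state] = (
                        order[sub_idx][sel],
                        np.searchsorted(grid, sub["time_h"].to_numpy(float)[sel]),
                    )
            self.groups.append(
                {
                    "route": route,
                    "mgkg": mgkg,
                    "bw": body_weight_kg,
                    "grid": grid,
                    "lookup": lookup,
                }
            )

    def __call__(self, drug: DrugParameterSet) -> np.ndarray:
        pred = np.empty(self.n)
        for g in self.groups:
            doses = doses_for_group(g["route"], g["mgkg"], drug, g["bw"])
            sim = simulate(
                self.phys, drug, doses, g["grid"], rtol=self.rtol, atol=self.atol
            )
            for state, (rows, tidx) in g["lookup"].items():
                pred[rows] = sim.amounts[_STATE_I[state], tidx] / sim.volumes[state]
        return pred


class _TracedResiduals:
    """Wrap a residual function, recording accepted (improving) objectives."""

    def __init__(self, fun):
        self.fun = fun
        self.trace: list[float] = []

    def __call__(self, x):
        r = self.fun(x)
        ssr = float(r @ r)
        if not self.trace or ssr < self.trace[-1]:
            self.trace.append(ssr)
        return r


def _finish(
    stage: str,
    names: list[str],
    res,
    trace,
    n_obs: int,
    to_natural,
    flags: list[str],
) -> FitResult:
    theta = dict(zip(names, res.x))
    natural = to_natural(theta)
    ssr = float(res.fun @ res.fun)
    fit = FitResult(
        stage=stage,
        estimates=natural,
        transformed_estimates=theta,
        cv_percent={},
        objective=ssr,
        n_obs=n_obs,
        residuals=res.fun,
        converged=bool(res.success),
        message=res.message,
        flags=flags,
        objective_trace=np.asarray(trace),
        jacobian=res.jac,
    )
    if not res.success:
        fit.flags.append("optimizer did not report convergence")
    fit.cv_percent = asymptotic_cv(fit)
    if any(not math.isfinite(v) or v > 100 for v in fit.cv_percent.values()):
        fit.flags.append("poorly identified parameter (CV% > 100 or singular)")
    return fit


def fit_stage1_serum(
    data: pd.DataFrame,
    phys: PhysiologicalParameterSet,
    drug_init: DrugParameterSet,
    body_weight_kg: float = 0.310,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Stage 1: estimate ``k_deg`` from pooled serum data (proportional
    error, residuals weighted by the model prediction)."""
    obs = _clean(data, ("serum",))
    obs = obs[obs["route"].str.lower() == "iv"]
    if len(obs) < 3:
        raise ValueError("need at least 3 quantifiable IV serum observations")
    flags = []
    if obs["time_h"].nunique() < 2:
        flags.append("non-identifiable: all serum observations at a single time point")
    y = obs["conc_nM"].to_numpy(float)
    predictor = _Predictor(obs, phys, body_weight_kg, rtol, atol)

    def residuals(x):
        pred = predictor(drug_init.replace(k_deg=float(np.exp(x[0]))))
        pred = np.maximum(pred, 1e-300)
        return (y - pred) / pred

    k0 = drug_init.k_deg if drug_init.k_deg > 0 else 10.0
    fun = _TracedResiduals(residuals)
    res = least_squares(fun, x0=[np.log(k0)], method="lm", xtol=1e-12, ftol=1e-12)
    return _finish(
        "serum",
        ["log_k_deg"],
        res,
        fun.trace,
        len(obs),
        lambda th: {"k_deg": float(np.exp(th["log_k_deg"]))},
        flags,
    )


def fit_stage2_brain(
    data: pd.DataFrame,
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    free: tuple[str, ...] = SIGMA_NAMES,
    body_weight_kg: float = 0.310,
    n_starts: int = 5,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Stage 2: fit reflection coefficients to CSF + ISF data.

    ``k_deg`` stays fixed at ``drug.k_deg`` (the stage-1 estimate).  The
    objective is the unweighted SSR over both matrices and all dose
    groups, minimised in logit space.  Multi-start (``n_starts`` jittered
    initial points, deterministic in ``seed``) guards against local
    minima; ``n_starts=1`` reproduces a plain local fit.
    """
    free = tuple(free)
    if not free or any(f not in SIGMA_NAMES for f in free):
        raise ValueError(f"free must be a non-empty subset of {SIGMA_NAMES}")
    obs = _clean(data, ("csf", "isf_dialysate"))
    if obs.empty:
        raise ValueError("no quantifiable CSF/ISF observations to fit")
    routes = set(obs["route"].str.lower())
    if "sigma_CSF_ISF" in free and len(routes) < 2:
        raise ValueError(
            "sigma_CSF_ISF is not identifiable from single-route data; "
            "fix it (e.g. to the EGFRvIII-TCB estimate) and refit"
        )
    y = obs["conc_nM"].to_numpy(float)
    # dialysate measurements are corrected to ISF scale before fitting
    isf = (obs["matrix"] == "isf_dialysate").to_numpy()
    y = np.where(isf, y / drug.recovery, y)
    predictor = _Predictor(obs, phys, body_weight_kg, rtol, atol)

    def residuals(x):
        d = drug.replace(**{n: float(inv_logit(v)) for n, v in zip(free, x)})
        return y - predictor(d)

    x0 = np.array([logit(getattr(drug, n)) for n in free])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0, 1.0, size=len(free)) for _ in range(n_starts - 1)]
    best, best_fun = None, None
    for s in starts:
        fun = _TracedResiduals(residuals)
        res = least_squares(fun, x0=s, method="trf", xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best, best_fun = res, fun
    names = [f"logit_{n}" for n in free]
    return _finish(
        "brain",
        names,
        best,
        best_fun.trace,
        len(obs),
        lambda th: {n: float(inv_logit(th[f"logit_{n}"])) for n in free},
        [],
    )


def asymptotic_cv(fit: FitResult) -> dict[str, float]:
    """Per-parameter CV% = 100*SE/|estimate| on the estimation scale.

    SE comes from the linearised covariance ``(J'J)^-1 * s2`` with
    ``s2 = SSR / (n - p)``.  A singular information matrix yields inf.
    """
    J = fit.jacobian
    names = list(fit.transformed_estimates)
    if J is None:
        raise ValueError("fit carries no Jacobian")
    n, p = fit.n_obs, len(names)
    s2 = fit.objective / max(n - p, 1)
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    out = {}
    for i, name in enumerate(names):
        th = fit.transformed_estimates[name]
        out[name] = float(100.0 * se[i] / abs(th)) if th != 0 else float("inf")
    return out


def prediction_error(auc_pred: float, auc_obs: float) -> float:
    """PE% = (AUC_pred - AUC_obs) / AUC_obs * 100."""
    if auc_obs <= 0:
        raise ValueError("observed AUC must be positive")
    return (auc_pred - auc_obs) / auc_obs * 100.0


# Physiological parameters whose perturbation must keep the brain fluid
# balance L_b = Q_CSF + Q_ISF intact: L_b is treated as derived.
_FLUID_COUPLED = {"Q_CSF", "Q_ISF"}
_BOUNDED01 = {"sigma_TV", "sigma_TL", "sigma_BISF", "sigma_CSF", "FR",
              "sigma_BBB", "sigma_BCSFB", "sigma_CSF_ISF"}


def local_sensitivity(
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    doses: list[DoseEvent],
    output,
    perturbation: float = 0.05,
    parameters: list[str] | None = None,
    t_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Normalised local sensitivities d log(output) / d log(parameter).

    ``output`` maps a SimulationResult to a positive scalar (e.g. serum
    AUC).  Central finite differences with relative step ``perturbation``;
    for parameters bounded in (0,1) the step shrinks as needed to stay in
    the domain, and ``L_b`` is re-derived when Q_CSF or Q_ISF move.
    """
    if not 0 < perturbation <= 0.5:
        raise ValueError("perturbation must lie in (0, 0.5]")
    phys_names = [
        f for f in phys.__dataclass_fields__ if f != "L_b"
    ]
    drug_names = ["sigma_BBB", "sigma_BCSFB", "sigma_CSF_ISF", "k_deg"]
    if parameters is None:
        parameters = phys_names + drug_names
    base = output(simulate(phys, drug, doses, t_grid))
    if not (math.isfinite(base) and base > 0):
        raise ValueError(f"output metric must be positive and finite, got {base}")

    def evaluate(name, value):
        if name in drug_names:
            sim = simulate(phys, drug.replace(**{name: value}), doses, t_grid)
        else:
            kw = {name: value}
            if name in _FLUID_COUPLED:
                q_csf = value if name == "Q_CSF" else phys.Q_CSF
                q_isf = value if name == "Q_ISF" else phys.Q_ISF
                kw["L_b"] = q_csf + q_isf
            sim = simulate(phys.replace(**kw), drug, doses, t_grid)
        return output(sim)

    out = {}
    for name in parameters:
        p0 = getattr(drug if name in drug_names else phys, name)
        if p0 == 0:
            out[name] = 0.0
            continue
        h = perturbation
        if name in _BOUNDED01:
            h = min(h, 0.5 * (1.0 - p0) / p0) if p0 * (1 + h) >= 1.0 else h
        hi, lo = evaluate(name, p0 * (1 + h)), evaluate(name, p0 * (1 - h))
        if not (hi > 0 and lo > 0):
            raise ValueError(f"output metric non-positive when perturbing {name}")
        out[name] = float((math.log(hi) - math.log(lo)) / math.log((1 + h) / (1 - h)))
    return out
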