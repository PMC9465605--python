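"""Synthetic PK study generator mirroring the rat study design.

Emulates the in-vivo protocol: serum and cisterna-magna CSF sampled at
-0.5, 0.5, 1, 3, 4.5, 6, 12, 24 and 48 h post-dose; prefrontal-cortex
microdialysate collected as 30-min interval averages for the first 8 h
and 4-h interval averages thereafter, scaled by the in-vitro probe
recovery.  Residual error is proportional (mean-1 log-normal) on serum
and additive (normal, truncated at zero) on CSF and dialysate;
concentrations below the assay LLOQ are reported as censored (BLQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import doses_for_group
from .microdialysis import window_average_sampling
from .model import default_time_grid, simulate
from .params import DrugParameterSet, PhysiologicalParameterSet

__all__ = ["StudyDesign", "OBSERVATION_COLUMNS", "default_design", "generate_dataset"]

#: Observation-table schema shared by the generator, readers and fits.
OBSERVATION_COLUMNS = (
    "subject",
    "group",
    "route",
    "dose_mgkg",
    "matrix",
    "time_h",
    "conc_nM",
    "bloq",
)

SERUM_CSF_TIMES = (-0.5, 0.5, 1.0, 3.0, 4.5, 6.0, 12.0, 24.0, 48.0)


def _default_windows() -> tuple[tuple[float, float], ...]:
    half_hour = [(0.5 * i, 0.5 * (i + 1)) for i in range(16)]  # 0-8 h
    four_hour = [(8.0 + 4.0 * i, 8.0 + 4.0 * (i + 1)) for i in range(10)]  # 8-48 h
    return tuple(half_hour + four_hour)


@dataclass(frozen=True)
class StudyDesign:
    """Arms, sampling schedule, body weight, assay floor and error model."""

    groups: tuple[tuple[str, float, int], ...]  # (route, dose mg/kg, n animals)
    serum_csf_times_h: tuple[float, ...] = SERUM_CSF_TIMES
    dialysate_windows_h: tuple[tuple[float, float], ...] = field(
        default_factory=_default_windows
    )
    body_weight_kg: float = 0.310
    lloq_ng_ml: float = 2.5
    prop_sd_serum: float = 0.15  # CV fraction, serum proportional error
    add_sd_csf_nM: float = 10.0  # additive SD on CSF concentrations
    add_sd_isf_nM: float = 0.5  # additive SD on dialysate concentrations
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("design needs at least one dose group")
        for route, mgkg, n in self.groups:
            if route.lower() not in ("iv", "icv"):
                raise ValueError(f"unknown route {route!r}")
            if mgkg <= 0 or n < 1:
                raise ValueError("dose must be positive and n >= 1")
        times = np.asarray(self.serum_csf_times_h, float)
        if times.min() < -0.5 or times.max() > 48.0:
            raise ValueError("sample times must lie within [-0.5, 48] h")
        for sd in (self.prop_sd_serum, self.add_sd_csf_nM, self.add_sd_isf_nM):
            if sd < 0:
                raise ValueError("error-model SDs must be >= 0")
        if self.body_weight_kg <= 0 or self.lloq_ng_ml <= 0:
            raise ValueError("body weight and LLOQ must be positive")

    def replace(self, **kw) -> "StudyDesign":
        return replace(self, **kw)


def default_design(drug: DrugParameterSet | None = None, seed: int = 0) -> StudyDesign:
    """The three-arm design (15 mg/kg IV, 3 mg/kg ICV, 1 mg/kg ICV; n = 5
    each) with the drug's assay LLOQ when a drug is given."""
    lloq = 2.5 if drug is None or drug.lloq_ng_ml is None else drug.lloq_ng_ml
    return StudyDesign(
        groups=(("iv", 15.0, 5), ("icv", 3.0, 5), ("icv", 1.0, 5)),
        lloq_ng_ml=lloq,
        seed=seed,
    )


def generate_dataset(
    design: StudyDesign,
    phys: PhysiologicalParameterSet,
    drug: DrugParameterSet,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate every arm and emit a noisy observation table.

    Deterministic in ``seed`` (falls back to ``design.seed``).  Noise-free
    generation (all SDs zero) returns the model values exactly; negative
    noisy values are truncated to zero and, like anything below the LLOQ,
    flagged as censored.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lloq_nM = design.lloq_ng_ml * 1000.0 / drug.MW
    times = np.asarray(design.serum_csf_times_h, float)
    post = times[times > 0]
    rows: list[dict] = []

    for gi, (route, mgkg, n_animals) in enumerate(design.groups):
        group = f"{route.lower()}_{mgkg:g}mgkg"
        doses = doses_for_group(route, mgkg, drug, design.body_weight_kg)
        grid = np.unique(np.concatenate([default_time_grid(48.0), post]))
        sim = simulate(phys, drug, doses, grid)
        tpos = np.searchsorted(sim.t, post)
        serum = sim.conc("plasma")[tpos]
        csf = sim.conc("csf_CM")[tpos]
        mids, dialysate = window_average_sampling(
            sim, "brain_isf", design.dialysate_windows_h, recovery=drug.recovery
        )
        sd_ln = np.sqrt(np.log1p(design.prop_sd_serum**2))

        for a in range(n_animals):
            subject = f"{group}_r{a + 1}"

            def emit(matrix, t_obs, true_vals, kind):
                for t, c in zip(np.atleast_1d(t_obs), np.atleast_1d(true_vals)):
                    if kind == "prop":
                        z = rng.standard_normal()
                        c_noisy = c * np.exp(sd_ln * z - 0.5 * sd_ln**2)
                    else:
                        sd = design.add_sd_csf_nM if matrix == "csf" else design.add_sd_isf_nM
                        c_noisy = c + sd * rng.standard_normal()
                    c_noisy = max(c_noisy, 0.0)
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "route": route.lower(),
                            "dose_mgkg": mgkg,
                            "matrix": matrix,
                            "time_h": float(t),
                            "conc_nM": float(c_noisy),
                            "bloq": bool(c_noisy < lloq_nM),
                        }
                    )

            # pre-dose serum and CSF samples: drug-free by design, censored
            for t in times[times <= 0]:
                for matrix in ("serum", "csf"):
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "route": route.lower(),
                            "dose_mgkg": mgkg,
                            "matrix": matrix,
                            "time_h": float(t),
                            "conc_nM": 0.0,
                            "bloq": True,
                        }
                    )
            emit("serum", post, serum, "prop")
            emit("csf", post, csf, "add")
            emit("isf_dialysate", mids, dialysate, "add")

    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
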