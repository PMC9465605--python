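"""Readers, writers and run configuration.

Observation tables are delimited text with header
``subject,group,route,dose_mgkg,matrix,time_h,conc_nM,bloq``; times in
hours (pre-dose at -0.5 h), concentrations in nM (an optional ``units``
column saying ``ng/ml`` is converted at ingestion using the drug MW).
Simulation trajectories round-trip through CSV at 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import SimulationResult
from .params import (
    DoseEvent,
    DrugParameterSet,
    PhysiologicalParameterSet,
    STATES,
    default_physiology,
    load_drug,
)
from .synth import OBSERVATION_COLUMNS

__all__ = [
    "read_pk_table",
    "write_pk_table",
    "write_simulation_csv",
    "read_simulation_csv",
    "RunConfig",
    "load_config",
]

_MATRICES = {"serum", "csf", "isf_dialysate"}


def read_pk_table(path) -> pd.DataFrame:
    """Read and validate an observation table.

    Raises with the offending row number on unknown matrices, negative
    concentrations or negative times other than the -0.5 h pre-dose.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["matrix"] = df["matrix"].str.lower()
    df["route"] = df["route"].str.lower()
    df["bloq"] = df["bloq"].astype(bool)
    if "units" in df.columns:
        ngml = df["units"].str.lower().eq("ng/ml")
        if ngml.any():
            if "MW" not in df.columns:
                raise ValueError(f"{path}: ng/ml rows need an MW column to convert")
            df.loc[ngml, "conc_nM"] = (
                df.loc[ngml, "conc_nM"] * 1000.0 / df.loc[ngml, "MW"]
            )
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["matrix"] not in _MATRICES:
            raise ValueError(
                f"{path}: row {rowno}: unknown matrix {row['matrix']!r} "
                f"(expected one of {sorted(_MATRICES)})"
            )
        if row["route"] not in ("iv", "icv"):
            raise ValueError(f"{path}: row {rowno}: unknown route {row['route']!r}")
        if row["time_h"] < 0 and row["time_h"] != -0.5:
            raise ValueError(
                f"{path}: row {rowno}: negative time {row['time_h']} h "
                "(only the -0.5 h pre-dose sample is allowed)"
            )
        if not np.isfinite(row["conc_nM"]) or row["conc_nM"] < 0:
            raise ValueError(f"{path}: row {rowno}: invalid concentration")
    return df[list(OBSERVATION_COLUMNS)]


def write_pk_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def write_simulation_csv(sim: SimulationResult, path) -> None:
    """Time vs per-compartment concentration, 12 significant digits."""
    sim.to_frame(concentrations=True).to_csv(path, index=False, float_format="%.12g")


def read_simulation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["time_h", *STATES]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return df


@dataclass
class RunConfig:
    """Parsed run configuration: physiology, drug, doses, options."""

    phys: PhysiologicalParameterSet
    drug: DrugParameterSet
    doses: list[DoseEvent]
    t_end: float = 48.0
    seed: int = 0
    body_weight_kg: float = 0.310
    options: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON config with blocks physiology, drug, doses, simulation.

    ``drug`` may be a packaged preset name or a full parameter block;
    ``physiology`` entries override the packaged defaults; each dose is
    either explicit (``amount_nmol``/``t_start``/``duration``) or given
    as ``route`` + ``dose_mgkg`` and converted with the body weight.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phys_kw = raw.get("physiology") or {}
    phys = (
        default_physiology()
        if not phys_kw
        else default_physiology().replace(**phys_kw)
    )
    drug_block = raw.get("drug")
    if drug_block is None:
        raise ValueError(f"{path}: config needs a 'drug' block or preset name")
    if isinstance(drug_block, str):
        drug = load_drug(drug_block)
    else:
        drug = DrugParameterSet(**drug_block)
    sim_block = raw.get("simulation") or {}
    bw = float(sim_block.get("body_weight_kg", 0.310))
    doses = []
    for spec in raw.get("doses") or []:
        if "amount_nmol" in spec:
            doses.append(
                DoseEvent(
                    route=spec["route"],
                    amount=float(spec["amount_nmol"]),
                    t_start=float(spec.get("t_start", 0.0)),
                    duration=float(spec.get("duration", 0.0)),
                )
            )
        else:
            from .estimation import doses_for_group

            doses.extend(
                doses_for_group(spec["route"], float(spec["dose_mgkg"]), drug, bw)
            )
    return RunConfig(
        phys=phys,
        drug=drug,
        doses=doses,
        t_end=float(sim_block.get("t_end", 48.0)),
        seed=int(sim_block.get("seed", 0)),
        body_weight_kg=bw,
        options=raw.get("options") or {},
    )
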