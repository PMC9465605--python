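"""Parameter containers for the reduced brain PBPK model.

The model carves the rat into a systemic block (plasma, lymph, lumped
rest-of-body with an endosomal FcRn sub-compartment) and a brain block
(vascular plasma, a four-segment CSF chain LV -> TFV -> CM -> SAS, and
brain interstitial fluid).  Physiology is fixed; the drug contributes the
three barrier reflection coefficients, the endosomal degradation rate and
the microdialysis probe recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import yaml

__all__ = [
    "PhysiologicalParameterSet",
    "DrugParameterSet",
    "DoseEvent",
    "STATES",
    "STATE_INDEX",
    "DRUG_STATES",
    "default_physiology",
    "load_drug",
    "available_drugs",
]

#: Ordered state layout of the 13-ODE system.  All states are amounts in
#: nmol (the FcRn species in nmol of receptor).
STATES = (
    "plasma",
    "lymph",
    "tissue_vasc",
    "tissue_endo_free",
    "tissue_endo_complex",
    "tissue_endo_FcRn",
    "tissue_isf",
    "brain_vasc",
    "csf_LV",
    "csf_TFV",
    "csf_CM",
    "csf_SAS",
    "brain_isf",
)

STATE_INDEX = {name: i for i, name in enumerate(STATES)}

#: States carrying drug (everything except the free-receptor pool).
DRUG_STATES = tuple(s for s in STATES if s != "tissue_endo_FcRn")


def _check_positive(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{n} must be a positive finite number, got {v!r}")


def _check_fraction(obj, names, open_interval=False):
    for n in names:
        v = getattr(obj, n)
        ok = 0.0 < v < 1.0 if open_interval else 0.0 <= v <= 1.0
        if not ok:
            kind = "(0, 1)" if open_interval else "[0, 1]"
            raise ValueError(f"{n} must lie in {kind}, got {v!r}")


@dataclass(frozen=True)
class PhysiologicalParameterSet:
    """The 26 fixed physiological constants (volumes L, flows L/h).

    Invariant: brain lymph flow equals the total brain fluid production,
    ``L_b = Q_CSF + Q_ISF`` — fluid formed at the blood-CSF barrier and
    the BBB ultimately drains via brain lymphatics.
    """

    V_plasma: float
    V_lymph: float
    V_tissue_vasc: float
    V_tissue_endo: float
    V_tissue_isf: float
    V_brain_vasc: float
    V_brain_isf: float
    V_LV: float
    V_TFV: float
    V_CM: float
    V_SAS: float
    Q_t: float
    Q_b: float
    L_t: float
    L_b: float
    Q_CSF: float
    Q_ISF: float
    sigma_TV: float
    sigma_TL: float
    sigma_BISF: float
    sigma_CSF: float
    FcRn_SS: float
    FR: float
    k_CLupT: float
    k_on_FcRn: float
    k_off_FcRn: float

    def __post_init__(self):
        _check_positive(
            self,
            [f.name for f in fields(self) if f.name.startswith(("V_", "Q_", "L_"))],
        )
        _check_positive(self, ["FcRn_SS", "k_CLupT", "k_on_FcRn", "k_off_FcRn"])
        _check_fraction(self, ["sigma_TV", "sigma_TL", "sigma_BISF", "sigma_CSF", "FR"])
        if abs(self.L_b - (self.Q_CSF + self.Q_ISF)) > 1e-9 * self.L_b:
            raise ValueError(
                "brain lymph flow must balance brain fluid production: "
                f"L_b={self.L_b} != Q_CSF+Q_ISF={self.Q_CSF + self.Q_ISF}"
            )
        if self.Q_t <= self.L_t or self.Q_b <= self.L_b:
            raise ValueError("blood flows must exceed the matching lymph flows")

    def state_volumes(self) -> dict[str, float]:
        """Distribution volume (L) of each of the 13 states.

        The three endosomal species share the tissue endosomal volume.
        """
        return {
            "plasma": self.V_plasma,
            "lymph": self.V_lymph,
            "tissue_vasc": self.V_tissue_vasc,
            "tissue_endo_free": self.V_tissue_endo,
            "tissue_endo_complex": self.V_tissue_endo,
            "tissue_endo_FcRn": self.V_tissue_endo,
            "tissue_isf": self.V_tissue_isf,
            "brain_vasc": self.V_brain_vasc,
            "csf_LV": self.V_LV,
            "csf_TFV": self.V_TFV,
            "csf_CM": self.V_CM,
            "csf_SAS": self.V_SAS,
            "brain_isf": self.V_brain_isf,
        }

    def replace(self, **kw) -> "PhysiologicalParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class DrugParameterSet:
    """Drug-specific parameters.

    The reflection coefficients live strictly inside (0,1): they are
    estimated on the logit scale, which cannot represent the endpoints.
    """

    name: str
    MW: float
    sigma_BBB: float
    sigma_BCSFB: float
    sigma_CSF_ISF: float
    k_deg: float
    recovery: float = 1.0
    lloq_ng_ml: float | None = None

    def __post_init__(self):
        _check_positive(self, ["MW"])
        _check_fraction(
            self, ["sigma_BBB", "sigma_BCSFB", "sigma_CSF_ISF"], open_interval=True
        )
        if not (math.isfinite(self.k_deg) and self.k_deg >= 0):
            raise ValueError(f"k_deg must be >= 0, got {self.k_deg!r}")
        if not (0.0 < self.recovery <= 1.0):
            raise ValueError(f"recovery must lie in (0, 1], got {self.recovery!r}")

    @property
    def lloq_nM(self) -> float | None:
        """Assay LLOQ converted from ng/ml to nM via the molecular weight."""
        if self.lloq_ng_ml is None:
            return None
        return self.lloq_ng_ml * 1000.0 / self.MW

    def replace(self, **kw) -> "DrugParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseEvent:
    """One administration: IV into plasma or ICV into the lateral ventricle.

    ``duration == 0`` encodes a bolus; otherwise a constant-rate infusion of
    ``amount / duration`` nmol/h over ``[t_start, t_start + duration]``.
    """

    route: str  # "iv" | "icv"
    amount: float  # nmol
    t_start: float = 0.0  # h
    duration: float = 0.0  # h
    target: str = field(default="")

    def __post_init__(self):
        route = self.route.lower()
        if route not in ("iv", "icv"):
            raise ValueError(f"route must be 'iv' or 'icv', got {self.route!r}")
        object.__setattr__(self, "route", route)
        expected = "plasma" if route == "iv" else "csf_LV"
        target = self.target or expected
        if target != expected:
            raise ValueError(f"{route} dose must target {expected}, got {target!r}")
        object.__setattr__(self, "target", target)
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0 nmol, got {self.amount!r}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0 h, got {self.duration!r}")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def rate(self) -> float:
        """Infusion rate in nmol/h (0 for a bolus)."""
        return self.amount / self.duration if self.duration > 0 else 0.0


def _load_yaml_asset(name: str) -> dict:
    with resources.files("brainpbpk.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_physiology() -> PhysiologicalParameterSet:
    """The packaged fixed rat physiology."""
    return PhysiologicalParameterSet(**_load_yaml_asset("rat_physiology.yaml"))


def available_drugs() -> list[str]:
    return sorted(_load_yaml_asset("drugs.yaml"))


def load_drug(name: str) -> DrugParameterSet:
    """Load a packaged drug parameter set (e.g. ``"EGFRvIII-TCB"``)."""
    table = _load_yaml_asset("drugs.yaml")
    if name not in table:
        raise KeyError(f"unknown drug {name!r}; available: {sorted(table)}")
    return DrugParameterSet(name=name, **table[name])
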