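"""Parameter set for the mechanistic T-cell-engager (TCE) cytokine-release model.

The model couples a one-compartment TCE pharmacokinetic model to three T-cell
states (naive, activated-in-transit, desensitized), an IL6 turnover equation,
and a tumor growth/killing block.  :class:`ParameterSet` carries every rate
constant of that system with its published default; all defaults describe a
tumor-bearing mouse dosed with an anti-HER2 TCE at 0.5 mg/kg.

Parameter files (YAML or JSON, flat key/value, keys equal to the field names)
can override any default; ``tcesim/data/defaults.yaml`` ships the defaults.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "CYTOKINE_BASELINE",
    "ParameterSet",
    "ValidationError",
    "load_parameters",
    "save_parameters",
    "default_parameter_file",
]

#: Physiological IL6 baseline, pg/mL.  The cytokine synthesis rate is locked
#: to this baseline: k_in_cyt = CYTOKINE_BASELINE * k_deg_cyt.
CYTOKINE_BASELINE = 10.0


class ValidationError(ValueError):
    """Raised when a parameter set, regimen or input table fails validation."""


# fields that must be strictly positive
_POSITIVE = (
    "V", "CL", "k_in_naive", "k_apop", "Emax_act", "EC50_act", "k_delay",
    "k_deg_cyt", "Emax_cyt", "EC50_cyt", "alpha", "k_IL2", "EC50_ET_IL2",
    "k_g", "k_delay_tumor", "Emax_kill", "EC50_kill",
)
# Hill coefficients, >= 1
_HILL = ("h_act", "h_cyt", "h_IL2")


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the cytokine-release PKPD model.

    Units follow the source publication conventions: volumes in mL, clearances
    in mL/h, cell pools in cells/µL, TCE concentration in µg/mL, cytokine in
    pg/mL, all rates in 1/h.

    Attributes
    ----------
    V : float
        Central compartment volume, mL.
    CL : float
        Linear TCE clearance, mL/h.
    k_in_naive : float
        Zero-order synthesis of naive T-cells, cells/µL/h.
    k_apop : float
        First-order T-cell apoptosis rate (all T-cell states), 1/h.
    Emax_act, h_act, EC50_act : float
        Hill parameters of the T-cell activation signal fK_act versus plasma
        TCE concentration (max 1/h, dimensionless, µg/mL).
    k_delay : float
        Transit rate through the five activated compartments and into the
        desensitized state, 1/h.
    k_deg_cyt : float
        First-order IL6 degradation rate, 1/h.  Synthesis is derived:
        ``k_in_cyt = 10 pg/mL * k_deg_cyt``.
    Emax_cyt, h_cyt, EC50_cyt, alpha : float
        Cytokine release function fK_cyt: maximum release coefficient, Hill
        coefficient, half-max TCE concentration (µg/mL) and the exponent on
        the fifth activated compartment.
    k_IL2, I_max, h_IL2, EC50_ET_IL2 : float
        IL2-driven proliferation of activated/desensitized T-cells: maximum
        rate (1/h), maximum inhibition (0..1), Hill coefficient, and the
        effector:target ratio giving half-maximal inhibition.
    k_g : float
        Exponential tumor growth rate, 1/h.
    k_delay_tumor : float
        Transit rate through the three dying-tumor compartments, 1/h.
    Emax_kill : float
        Maximum killing coefficient, 1/(cells/µL)/h.
    EC50_kill : float
        TCE concentration at half-maximal killing, µg/mL.
    """

    V: float = 2.3
    CL: float = 0.025
    k_in_naive: float = 16.0
    k_apop: float = 0.01
    Emax_act: float = 1.5
    h_act: float = 2.0
    EC50_act: float = 1.0
    k_delay: float = 2.5
    k_deg_cyt: float = 0.41
    Emax_cyt: float = 0.00086
    h_cyt: float = 2.5
    EC50_cyt: float = 5.0
    alpha: float = 2.0
    k_IL2: float = 0.0008
    I_max: float = 1.0
    h_IL2: float = 5.0
    EC50_ET_IL2: float = 7.0
    k_g: float = 0.006
    k_delay_tumor: float = 0.02
    Emax_kill: float = 0.000025
    EC50_kill: float = 1.0

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive, got "
                                      f"{getattr(self, name)!r}")
        for name in _HILL:
            if not getattr(self, name) >= 1:
                raise ValidationError(f"Hill coefficient {name} must be >= 1, "
                                      f"got {getattr(self, name)!r}")
        if not 0.0 <= self.I_max <= 1.0:
            raise ValidationError(f"I_max must lie in [0, 1], got {self.I_max!r}")

    @property
    def k_in_cyt(self) -> float:
        """Zero-order IL6 synthesis, pg/mL/h; locked to the 10 pg/mL baseline."""
        return CYTOKINE_BASELINE * self.k_deg_cyt

    @property
    def naive_baseline(self) -> float:
        """Drug-free naive T-cell steady state k_in_naive / k_apop, cells/µL."""
        return self.k_in_naive / self.k_apop

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        """Return a copy with one named parameter multiplied by ``factor``."""
        return self.replace(**{name: getattr(self, name) * factor})

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ParameterSet":
        """Build from a flat mapping; unknown keys raise, ``k_in_cyt`` is
        accepted only if consistent with ``10 * k_deg_cyt``."""
        data = dict(mapping)
        k_in_cyt = data.pop("k_in_cyt", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        ps = cls(**{k: float(v) for k, v in data.items()})
        if k_in_cyt is not None and abs(float(k_in_cyt) - ps.k_in_cyt) > 1e-9:
            raise ValidationError(
                f"k_in_cyt={k_in_cyt!r} inconsistent with 10*k_deg_cyt="
                f"{ps.k_in_cyt!r}; k_in_cyt is a derived quantity")
        return ps


def default_parameter_file() -> Path:
    """Path of the bundled default parameter file."""
    return Path(importlib.resources.files("tcesim") / "data" / "defaults.yaml")


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter set from a YAML or JSON file (defaults when ``None``)."""
    if path is None:
        return ParameterSet()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse parameter file {path}: {exc}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"parameter file {path} must hold a flat mapping")
    return ParameterSet.from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as YAML (``.json`` extension switches to JSON)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
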