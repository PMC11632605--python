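"""Model parameters for the two-compartment ET-1 kinetics model.

The parameter set mirrors the calibrated physiological model: ECE-mediated
conversion of Big ET-1 to ET-1 in a tissue compartment, first-order
distribution of free ET-1 between tissue and plasma, and clearance by
internalization of ET-1/receptor complexes in both compartments.

Two of the quantities — the endothelin-converting-enzyme concentration
``[ECE]`` and the tissue receptor pool ``R_tot,t`` — are linked through the
baseline steady-state constraint: fixing one determines the other (together
with the ET-1 production rate).  A :class:`ModelParameters` instance
therefore specifies exactly one of them and the other is derived at
initialization time (see :func:`etkinetics.kinetics.steady_state_init`).
The default set keeps the calibrated ``R_tot,t`` and derives the baseline
ECE concentration.

Units: concentrations pmol/L (``[ECE]`` in nmol/L, as conventionally
reported), volumes L, times minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParameters", "STUDY_ECE_NMOL", "load_parameters", "save_parameters"]

#: Study-specific ECE concentrations (nmol/L) from the simultaneous
#: three-study calibration: radiolabeled ET-1 bolus (Parker), stepped ET-1
#: infusion (Hunter), stepped Big ET-1 infusion (Kaasjager).
STUDY_ECE_NMOL: dict[str, float] = {
    "parker": 162.6,
    "hunter": 98.0,
    "kaasjager": 27.0,
}

# serialization keys follow the conventional symbol names
_FIELD_TO_KEY = {
    "big_et_0": "BigET_0",
    "et1_p0": "ET1_p0",
    "kcat_km": "Kcat_Km",
    "k_d": "K_d",
    "v_p": "V_p",
    "v_t": "V_t",
    "ece_nmol": "ECE",
    "k_pt": "K_pt",
    "k_tp": "K_tp",
    "k_int": "K_int",
    "r_tot_p": "R_tot_p",
    "r_tot_t": "R_tot_t",
    "f_b_t": "f_B_t",
    "f_b_c": "f_B_c",
}
_KEY_TO_FIELD = {v: k for k, v in _FIELD_TO_KEY.items()}


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the ET-1 kinetics model (calibrated defaults).

    Attributes
    ----------
    big_et_0 : float
        Normal plasma/tissue Big ET-1 concentration (pmol/L), initial
        condition of the precursor pool.
    et1_p0 : float
        Normal free plasma ET-1 concentration (pmol/L), the baseline anchor.
    kcat_km : float
        ECE catalytic efficiency, kcat/Km (L/min/pmol).
    k_d : float
        ET-1 dissociation constant, shared by ET_A and ET_B (pmol/L).
    v_p, v_t : float
        Central (plasma) and tissue compartment volumes (L).
    k_pt, k_tp : float
        Plasma-to-tissue and tissue-to-plasma distribution rates (/min).
    k_int : float
        First-order internalization rate of receptor-ligand complexes (/min).
    r_tot_p : float
        Total receptor concentration in the plasma compartment (pmol/L).
    r_tot_t : float or None
        Total receptor concentration in the tissue compartment (pmol/L).
        ``None`` derives it from the baseline steady-state constraint and the
        given ``ece_nmol``.
    ece_nmol : float or None
        ECE concentration (nmol/L).  ``None`` derives it from the baseline
        steady-state constraint and the given ``r_tot_t``.
    f_b_t, f_b_c : float
        Fraction of receptors that are ET_B in the tissue and plasma
        (central) compartments.
    """

    big_et_0: float = 0.93
    et1_p0: float = 3.2
    kcat_km: float = 2.64e-4
    k_d: float = 400.0
    v_p: float = 81.6
    v_t: float = 2.64
    k_pt: float = 0.87
    k_tp: float = 0.98
    k_int: float = 0.0095
    r_tot_p: float = 460.0
    r_tot_t: float | None = 7738.0
    ece_nmol: float | None = None
    f_b_t: float = 0.65
    f_b_c: float = 0.8

    def __post_init__(self) -> None:
        for name in ("big_et_0", "et1_p0", "kcat_km", "k_d", "v_p", "v_t",
                     "k_pt", "k_tp", "k_int", "r_tot_p"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive (got {value})")
        for name in ("f_b_t", "f_b_c"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {value})")
        if self.r_tot_t is None and self.ece_nmol is None:
            raise ValueError(
                "one of r_tot_t or ece_nmol must be given; the other is "
                "derived from the baseline steady-state constraint"
            )
        if self.r_tot_t is not None and not self.r_tot_t > 0:
            raise ValueError(f"r_tot_t must be positive (got {self.r_tot_t})")
        if self.ece_nmol is not None and not self.ece_nmol > 0:
            raise ValueError(f"ece_nmol must be positive (got {self.ece_nmol})")

    @property
    def ece_pmol(self) -> float | None:
        """ECE concentration in pmol/L (model-internal units)."""
        return None if self.ece_nmol is None else 1e3 * self.ece_nmol

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced.

        Setting ``ece_nmol`` clears ``r_tot_t`` (and vice versa) unless both
        are passed explicitly, preserving the one-free-member rule.
        """
        if "ece_nmol" in changes and "r_tot_t" not in changes:
            changes["r_tot_t"] = None
        if "r_tot_t" in changes and "ece_nmol" not in changes:
            changes["ece_nmol"] = None
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, float | None]:
        return {_FIELD_TO_KEY[f.name]: getattr(self, f.name)
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        unknown = set(data) - set(_KEY_TO_FIELD)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{_KEY_TO_FIELD[k]: v for k, v in data.items()})


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON (by file extension)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter set from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ModelParameters.from_dict(data)
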