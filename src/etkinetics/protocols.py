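"""Infusion protocols: the calibration and validation study designs.

Four human study designs drive calibration and validation of the model:

1. *Radiolabeled ET-1 bolus* — a tracer bolus (dose unknown, tiny relative to
   the endogenous pool) infused over 5 min, plasma sampled densely to
   240 min; only relative (baseline-subtracted, peak-normalized)
   concentrations are meaningful.
2. *Stepped ET-1 infusion* — 0.5 / 1.0 / 2.0 ng/kg/min for 60 min each,
   plasma sampled at 0, 75, 125 and 225 min.
3. *Stepped Big ET-1 infusion* — 0.75 / 15 / 300 pmol/min for 30 min each,
   plasma sampled every 30 min through 150 min.
4. *Receptor-antagonist validation* — saline, the ET_A antagonist BQ123 or
   the ET_B antagonist BQ788, followed by an ET-1 infusion
   (4 pmol/kg/min from minute 30 for 20 min), plasma sampled at
   0, 15, 30, 40 and 50 min.

Antagonist exposure model
-------------------------
The published studies report antagonist infusion rates, not plasma
concentrations, and no antagonist pharmacokinetics are specified anywhere in
the source studies.  By default the plasma antagonist concentration follows a
one-compartment infusion model (volume defaulting to the model's central
volume, elimination half-life 60 min) — an explicit modeling **assumption**,
configurable per protocol, with a zero-order "step exposure" mode (a held
concentration during the infusion window) also available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import yaml

from .binding import AntagonistSpec

__all__ = [
    "ET1_MW_G_PER_MOL",
    "Segment",
    "InfusionProtocol",
    "convert_dose_rate",
    "builtin_protocol",
    "BUILTIN_PROTOCOLS",
    "load_protocol",
    "save_protocol",
]

#: Molecular weight of ET-1 (21-residue peptide), used for ng -> pmol
#: conversion of mass-based doses.  Overridable per call.
ET1_MW_G_PER_MOL = 2492.0

_SUPPORTED_UNITS = ("ng/kg/min", "pmol/min", "pmol/kg/min", "nmol/kg/min")

SPECIES = ("ET1", "BigET", "antagonist")
_DEFAULT_COMPARTMENT = {"ET1": "plasma", "BigET": "tissue", "antagonist": "plasma"}


def convert_dose_rate(
    rate: float,
    unit: str,
    species: str = "ET1",
    mass_kg: float = 70.0,
    mw_g_per_mol: float = ET1_MW_G_PER_MOL,
) -> float:
    """Convert a published dose rate to pmol/min.

    Mass-based units use the ET-1 molecular weight (2,492 g/mol) by default;
    molar units convert exactly.
    """
    if unit not in _SUPPORTED_UNITS:
        raise ValueError(
            f"unsupported dose unit {unit!r}; supported: {_SUPPORTED_UNITS}"
        )
    if rate < 0:
        raise ValueError(f"dose rate must be non-negative (got {rate})")
    if unit == "pmol/min":
        return rate
    if unit == "pmol/kg/min":
        return rate * mass_kg
    if unit == "nmol/kg/min":
        return rate * mass_kg * 1e3
    # ng/kg/min: ng/min / (g/mol) = nmol/min -> pmol/min
    return rate * mass_kg / mw_g_per_mol * 1e3


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant infusion segment."""

    t_start: float
    t_end: float
    species: str
    rate: float
    unit: str = "pmol/min"
    compartment: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; one of {SPECIES}")
        if not self.t_start < self.t_end:
            raise ValueError(f"segment needs t_start < t_end (got {self.t_start}, {self.t_end})")
        if self.rate < 0:
            raise ValueError(f"segment rate must be non-negative (got {self.rate})")
        if self.unit not in _SUPPORTED_UNITS:
            raise ValueError(f"unsupported unit {self.unit!r}")
        if not self.compartment:
            object.__setattr__(self, "compartment", _DEFAULT_COMPARTMENT[self.species])

    def rate_pmol_per_min(self, mass_kg: float) -> float:
        return convert_dose_rate(self.rate, self.unit, self.species, mass_kg)


@dataclass(frozen=True)
class InfusionProtocol:
    """A study design: infusion segments, sampling schedule and antagonist.

    ``tracer_fraction`` marks the radiolabeled-bolus design: a tracer dose of
    that fraction of the baseline plasma ET-1 pool is infused over
    ``tracer_duration_min`` minutes and the plasma output is reported in
    relative (baseline-subtracted, peak-normalized) form.
    """

    name: str
    segments: tuple[Segment, ...] = ()
    sampling_times: tuple[float, ...] = ()
    antagonist: AntagonistSpec | None = None
    antagonist_mode: str = "pk"  # "pk" (one-compartment) or "step"
    antagonist_half_life_min: float = 60.0
    antagonist_volume_L: float | None = None  # None -> model central volume
    subject_mass_kg: float = 70.0
    relative_output: bool = False
    tracer_fraction: float | None = None
    tracer_duration_min: float = 5.0

    def __post_init__(self) -> None:
        if self.antagonist_mode not in ("pk", "step"):
            raise ValueError("antagonist_mode must be 'pk' or 'step'")
        segs = tuple(sorted(self.segments, key=lambda s: (s.species, s.t_start)))
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "sampling_times", tuple(float(t) for t in self.sampling_times))
        # non-overlap per species
        by_species: dict[str, list[Segment]] = {}
        for s in segs:
            prev = by_species.setdefault(s.species, [])
            if prev and s.t_start < prev[-1].t_end - 1e-12:
                raise ValueError(
                    f"overlapping {s.species} segments at t={s.t_start}"
                )
            prev.append(s)
        has_antag_seg = any(s.species == "antagonist" for s in segs)
        if has_antag_seg and self.antagonist is None:
            raise ValueError("antagonist segments given without an AntagonistSpec")

    # ----------------------------------------------------------- queries
    @property
    def horizon(self) -> float:
        ends = [s.t_end for s in self.segments]
        if self.sampling_times:
            ends.append(max(self.sampling_times))
        if self.tracer_fraction is not None:
            ends.append(self.tracer_duration_min)
        if not ends:
            raise ValueError(f"protocol {self.name!r} has no horizon")
        return max(ends)

    def breakpoints(self) -> list[float]:
        """Sorted distinct times at which any input rate changes."""
        pts = {0.0, self.horizon}
        for s in self.segments:
            pts.update((s.t_start, s.t_end))
        if self.tracer_fraction is not None:
            pts.add(self.tracer_duration_min)
        return sorted(t for t in pts if 0.0 <= t <= self.horizon)

    def rate_at(self, t: float, species: str) -> float:
        """Total infusion rate (pmol/min) of one species at time ``t``.

        Segments are half-open ``[t_start, t_end)``.
        """
        total = 0.0
        for s in self.segments:
            if s.species == species and s.t_start <= t < s.t_end:
                total += s.rate_pmol_per_min(self.subject_mass_kg)
        return total

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "species": s.species,
                 "rate": s.rate, "unit": s.unit, "compartment": s.compartment}
                for s in self.segments
            ],
            "sampling_times": list(self.sampling_times),
            "antagonist_mode": self.antagonist_mode,
            "antagonist_half_life_min": self.antagonist_half_life_min,
            "antagonist_volume_L": self.antagonist_volume_L,
            "subject_mass_kg": self.subject_mass_kg,
            "relative_output": self.relative_output,
            "tracer_fraction": self.tracer_fraction,
            "tracer_duration_min": self.tracer_duration_min,
        }
        if self.antagonist is not None:
            d["antagonist"] = {
                "K_ia": self.antagonist.K_ia,
                "K_ib": self.antagonist.K_ib,
                "name": self.antagonist.name,
            }
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "InfusionProtocol":
        data = dict(data)
        segments = tuple(Segment(**s) for s in data.pop("segments", []))
        antag = data.pop("antagonist", None)
        spec = AntagonistSpec(**antag) if antag is not None else None
        return cls(segments=segments, antagonist=spec, **data)


def save_protocol(protocol: InfusionProtocol, path: str | Path) -> None:
    path = Path(path)
    data = protocol.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_protocol(path: str | Path) -> InfusionProtocol:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return InfusionProtocol.from_dict(data)


# --------------------------------------------------------------- built-ins

#: BQ123 (ET_A-selective) affinities in human tissue: K_ia 0.78 nM,
#: K_ib 24.3 uM; BQ788 (ET_B-selective): K_ia 1 uM, K_ib 9.8 nM.  pmol/L.
BQ123 = AntagonistSpec(K_ia=780.0, K_ib=2.43e7, name="BQ123")
BQ788 = AntagonistSpec(K_ia=1e6, K_ib=9.8e3, name="BQ788")

_TRACER_SAMPLING = (0, 1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20, 25, 30,
                    35, 40, 45, 50, 60, 70, 80, 100, 120, 150, 180, 210, 240)

_VALIDATION_SAMPLING = (0.0, 15.0, 30.0, 40.0, 50.0)
_VALIDATION_ET1 = Segment(30.0, 50.0, "ET1", 4.0, "pmol/kg/min")


def _builtins() -> dict[str, InfusionProtocol]:
    return {
        "bolus_tracer": InfusionProtocol(
            name="bolus_tracer",
            sampling_times=tuple(float(t) for t in _TRACER_SAMPLING),
            relative_output=True,
            tracer_fraction=1e-3,
            tracer_duration_min=5.0,
        ),
        "stepped_et1": InfusionProtocol(
            name="stepped_et1",
            segments=(
                Segment(0.0, 60.0, "ET1", 0.5, "ng/kg/min"),
                Segment(60.0, 120.0, "ET1", 1.0, "ng/kg/min"),
                Segment(120.0, 180.0, "ET1", 2.0, "ng/kg/min"),
            ),
            sampling_times=(0.0, 75.0, 125.0, 225.0),
        ),
        "stepped_biget": InfusionProtocol(
            name="stepped_biget",
            segments=(
                Segment(0.0, 30.0, "BigET", 0.75, "pmol/min"),
                Segment(30.0, 60.0, "BigET", 15.0, "pmol/min"),
                Segment(60.0, 90.0, "BigET", 300.0, "pmol/min"),
            ),
            sampling_times=(0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
        ),
        "validation_placebo": InfusionProtocol(
            name="validation_placebo",
            segments=(_VALIDATION_ET1,),
            sampling_times=_VALIDATION_SAMPLING,
        ),
        # BQ123 published range is 2.5-5 nmol/kg/min; 4 nmol/kg/min matches
        # the more specific published statement and is used as default.
        "validation_bq123": InfusionProtocol(
            name="validation_bq123",
            segments=(
                _VALIDATION_ET1,
                Segment(0.0, 50.0, "antagonist", 4.0, "nmol/kg/min"),
            ),
            sampling_times=_VALIDATION_SAMPLING,
            antagonist=BQ123,
        ),
        "validation_bq788": InfusionProtocol(
            name="validation_bq788",
            segments=(
                _VALIDATION_ET1,
                Segment(0.0, 15.0, "antagonist", 4.0, "nmol/kg/min"),
            ),
            sampling_times=_VALIDATION_SAMPLING,
            antagonist=BQ788,
        ),
    }


BUILTIN_PROTOCOLS: tuple[str, ...] = tuple(_builtins())


def builtin_protocol(name: str, **overrides: Any) -> InfusionProtocol:
    """Return a built-in study protocol by name.

    ``overrides`` replace protocol fields (e.g. ``subject_mass_kg=80``).
    """
    protos = _builtins()
    if name not in protos:
        raise ValueError(
            f"unknown protocol {name!r}; available: {sorted(protos)}"
        )
    proto = protos[name]
    return replace(proto, **overrides) if overrides else proto
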