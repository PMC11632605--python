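"""Steady-state antagonist concentration x selectivity sweeps.

The headline simulations of the analysis: for an endothelin receptor
antagonist of given selectivity (``K_ib/K_ia``; > 1 means ET_A-selective),
the steady state of the kinetics model is computed over a log-spaced grid of
drug concentrations and the percent changes from the drug-free baseline of
the bound complexes [ET1-ET_A] and [ET1-ET_B] and of free ET-1 are reported
in both compartments.

Perfectly selective antagonists follow the convention of setting the
off-target affinity effectively infinite (1e20, or the analytic ``inf``
flag).  Blocking either receptor reduces ET-1 clearance, so the ligand
accumulates and binding through the *non*-antagonized receptor rises; at
high enough concentrations a finitely selective drug starts occupying the
other receptor too and the non-antagonized complex falls back below
baseline — the characteristic rise-then-fall of [ET1-ET_B] under
ET_A-selective antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import AntagonistSpec
from .kinetics import quasi_steady_state, steady_state_with_antagonist
from .parameters import ModelParameters

__all__ = [
    "SweepSpec",
    "SweepResult",
    "DRUG_SELECTIVITY",
    "concentration_grid",
    "run_sweep",
    "summarize_sweep",
    "fb_scenario",
]

#: Approximate published ET_A:ET_B selectivities (K_ib/K_ia) of marketed /
#: investigated antagonists.  Reported values vary widely between assays;
#: these are order-of-magnitude placeholders meant to be overridden, not a
#: reproduction surface.
DRUG_SELECTIVITY: dict[str, float] = {
    "bosentan": 20.0,
    "ambrisentan": 4000.0,
    "atrasentan": 1800.0,
    "sitaxentan": 6500.0,
    "zibotentan": 16000.0,
}


def concentration_grid(
    lo_multiple: float = 1e-3,
    hi_multiple: float = 1e3,
    points_per_decade: int = 25,
) -> np.ndarray:
    """Log-spaced concentration multiples of the reference affinity."""
    if not 0 < lo_multiple < hi_multiple:
        raise ValueError("need 0 < lo_multiple < hi_multiple")
    decades = math.log10(hi_multiple / lo_multiple)
    n = max(2, int(round(decades * points_per_decade)) + 1)
    return np.geomspace(lo_multiple, hi_multiple, n)


@dataclass(frozen=True)
class SweepSpec:
    """Concentration x selectivity grid specification.

    ``mode``:

    * ``"eta_perfect"`` — perfectly selective ET_A antagonist (K_ia = 1,
      K_ib = inf), concentrations 0.001-1,000x K_ia by default;
    * ``"etb_perfect"`` — perfectly selective ET_B antagonist (K_ib = 1,
      K_ia = inf), concentrations 0.001-100,000x K_ib;
    * ``"grid"`` — finite selectivities (``selectivities`` = K_ib/K_ia
      values, K_ia = 1), concentrations relative to K_ia;
    * ``"drugs"`` — the preset drug table (finite selectivities).

    ``f_b`` overrides the ET_B fraction in *both* compartments.
    """

    mode: str = "eta_perfect"
    selectivities: tuple[float, ...] = ()
    multiples: tuple[float, ...] = ()
    f_b: float | None = None
    points_per_decade: int = 25
    drugs: tuple[str, ...] = ()
    #: None = asymptotic (algebraic) steady state; a number = minutes of
    #: constant exposure (quasi-steady state).  "auto" resolves to the
    #: asymptote for perfectly selective modes and 24 h for finite
    #: selectivities, where the rise-then-fall behavior lives on clinical
    #: timescales (the asymptote washes it out; see kinetics module notes).
    horizon_min: float | None | str = "auto"

    def __post_init__(self) -> None:
        if self.mode not in ("eta_perfect", "etb_perfect", "grid", "drugs"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if self.f_b is not None and not 0.0 <= self.f_b <= 1.0:
            raise ValueError("f_b override must lie in [0, 1]")
        if any(m <= 0 for m in self.multiples):
            raise ValueError("concentration multiples must be positive")
        if list(self.multiples) != sorted(self.multiples):
            raise ValueError("concentration multiples must be increasing")

    def resolved_horizon(self) -> float | None:
        if self.horizon_min == "auto":
            return None if self.mode in ("eta_perfect", "etb_perfect") else 1440.0
        return self.horizon_min  # type: ignore[return-value]

    def resolved_multiples(self) -> np.ndarray:
        if self.multiples:
            return np.asarray(self.multiples, dtype=float)
        hi = 1e5 if self.mode in ("etb_perfect", "grid", "drugs") else 1e3
        return concentration_grid(1e-3, hi, self.points_per_decade)

    def antagonists(self) -> list[tuple[str, float, AntagonistSpec]]:
        """(label, selectivity, spec) triples; concentration multiples are
        relative to K_ia except for ET_B-selective cases (K_ib)."""
        if self.mode == "eta_perfect":
            return [("perfect_ETA", math.inf, AntagonistSpec(1.0, math.inf, "perfect_ETA"))]
        if self.mode == "etb_perfect":
            return [("perfect_ETB", 0.0, AntagonistSpec(math.inf, 1.0, "perfect_ETB"))]
        if self.mode == "drugs":
            names = self.drugs or tuple(DRUG_SELECTIVITY)
            return [
                (name, DRUG_SELECTIVITY[name],
                 AntagonistSpec(1.0, DRUG_SELECTIVITY[name], name))
                for name in names
            ]
        if not self.selectivities:
            raise ValueError("grid mode requires selectivities")
        return [
            (f"selectivity_{s:g}", s, AntagonistSpec(1.0, s, f"selectivity_{s:g}"))
            for s in self.selectivities
        ]


@dataclass
class SweepResult:
    """Tidy per-grid-point table of steady-state percent changes.

    Columns: label, selectivity, multiple (of the reference affinity),
    I_pmol_per_L, compartment, variable
    (``et1_eta_complex`` / ``et1_etb_complex`` / ``et1_free``), value,
    baseline, pct_change.
    """

    frame: pd.DataFrame
    spec: SweepSpec

    def pct(self, label: str, compartment: str, variable: str) -> pd.DataFrame:
        f = self.frame
        sel = f[(f.label == label) & (f.compartment == compartment) & (f.variable == variable)]
        return sel.sort_values("multiple")

    def max_pct_change(self, compartment: str, variable: str, label: str | None = None) -> float:
        f = self.frame
        if label is not None:
            f = f[f.label == label]
        sel = f[(f.compartment == compartment) & (f.variable == variable)]
        return float(sel["pct_change"].max())


def run_sweep(
    spec: SweepSpec,
    params: ModelParameters | None = None,
) -> SweepResult:
    """Run the steady-state sweep over the concentration (x selectivity)
    grid; percent changes are relative to the drug-free steady state."""
    params = params or ModelParameters()
    fbs = {} if spec.f_b is None else {"f_b_t": spec.f_b, "f_b_c": spec.f_b}
    multiples = spec.resolved_multiples()
    horizon = spec.resolved_horizon()

    def solve(antag: AntagonistSpec, conc: float):
        if horizon is None:
            return steady_state_with_antagonist(params, antag, conc, **fbs)
        return quasi_steady_state(params, antag, conc, horizon, **fbs)

    rows: list[dict] = []
    for label, selectivity, antag in spec.antagonists():
        ref_k = antag.K_ib if spec.mode == "etb_perfect" else antag.K_ia
        _, p0, t0 = solve(antag, 0.0)
        base = {
            ("plasma", "et1_eta_complex"): p0.ET1_RA,
            ("plasma", "et1_etb_complex"): p0.ET1_RB,
            ("plasma", "et1_free"): p0.ET1_free,
            ("tissue", "et1_eta_complex"): t0.ET1_RA,
            ("tissue", "et1_etb_complex"): t0.ET1_RB,
            ("tissue", "et1_free"): t0.ET1_free,
        }
        for mult in multiples:
            conc = float(mult) * ref_k
            try:
                _, sol_p, sol_t = solve(antag, conc)
            except RuntimeError as exc:  # keep sweeping the rest of the grid
                rows.append({"label": label, "selectivity": selectivity,
                             "multiple": float(mult), "I_pmol_per_L": conc,
                             "compartment": "error", "variable": str(exc),
                             "value": np.nan, "baseline": np.nan,
                             "pct_change": np.nan})
                continue
            vals = {
                ("plasma", "et1_eta_complex"): sol_p.ET1_RA,
                ("plasma", "et1_etb_complex"): sol_p.ET1_RB,
                ("plasma", "et1_free"): sol_p.ET1_free,
                ("tissue", "et1_eta_complex"): sol_t.ET1_RA,
                ("tissue", "et1_etb_complex"): sol_t.ET1_RB,
                ("tissue", "et1_free"): sol_t.ET1_free,
            }
            for (comp, var), v in vals.items():
                b = base[(comp, var)]
                rows.append(
                    {
                        "label": label,
                        "selectivity": selectivity,
                        "multiple": float(mult),
                        "I_pmol_per_L": conc,
                        "compartment": comp,
                        "variable": var,
                        "value": v,
                        "baseline": b,
                        "pct_change": 100.0 * (v / b - 1.0) if b > 0 else np.nan,
                    }
                )
    return SweepResult(frame=pd.DataFrame(rows), spec=spec)


def _interp_crossing(mult: np.ndarray, pct: np.ndarray, level: float) -> float:
    """First concentration multiple at which ``pct`` falls through
    ``level``, log-interpolated; NaN if not reached on the grid."""
    below = pct <= level
    if not below.any():
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(mult[0])
    x0, x1 = math.log10(mult[i - 1]), math.log10(mult[i])
    y0, y1 = pct[i - 1], pct[i]
    if y1 == y0:
        return float(mult[i])
    return float(10 ** (x0 + (level - y0) * (x1 - x0) / (y1 - y0)))


def summarize_sweep(result: SweepResult) -> pd.DataFrame:
    """Per-antagonist summary metrics.

    For each label and compartment: the maximum percent rise of the
    non-antagonized complex, the concentration multiple producing 50%
    suppression of the antagonized complex, and the multiple at which the
    non-antagonized complex's change turns negative (NaN = "not reached"
    within the grid).
    """
    if result.frame.empty:
        raise ValueError("empty sweep result")
    mode = result.spec.mode
    etb_selective = mode == "etb_perfect"
    rows = []
    for label, grp in result.frame.groupby("label", sort=False):
        sel = grp["selectivity"].iloc[0]
        if mode == "grid" or mode == "drugs":
            target_b = sel > 1.0  # ET_A-selective drugs antagonize ET_A
        else:
            target_b = not etb_selective
        antagonized = "et1_eta_complex" if target_b else "et1_etb_complex"
        spared = "et1_etb_complex" if target_b else "et1_eta_complex"
        for comp in ("plasma", "tissue"):
            sub = grp[grp.compartment == comp]
            if sub.empty:
                continue
            ant = sub[sub.variable == antagonized].sort_values("multiple")
            spa = sub[sub.variable == spared].sort_values("multiple")
            mult = ant["multiple"].to_numpy()
            rows.append(
                {
                    "label": label,
                    "selectivity": sel,
                    "compartment": comp,
                    "max_spared_rise_pct": float(spa["pct_change"].max()),
                    "i50_multiple": _interp_crossing(
                        mult, ant["pct_change"].to_numpy(), -50.0
                    ),
                    "spared_zero_cross_multiple": _interp_crossing(
                        spa["multiple"].to_numpy(), spa["pct_change"].to_numpy(), 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FbComparison:
    """Paired perfectly selective sweeps at one receptor-fraction value."""

    f_b: float
    eta_sweep: SweepResult
    etb_sweep: SweepResult

    def spared_rise(self, compartment: str = "plasma") -> tuple[float, float]:
        """(rise of ET1-ETB under ET_A antagonism,
        rise of ET1-ETA under ET_B antagonism), percent."""
        return (
            self.eta_sweep.max_pct_change(compartment, "et1_etb_complex"),
            self.etb_sweep.max_pct_change(compartment, "et1_eta_complex"),
        )


def fb_scenario(
    f_b: float | None,
    params: ModelParameters | None = None,
    multiples: Sequence[float] | None = None,
    points_per_decade: int = 25,
) -> FbComparison:
    """Run both perfectly selective sweeps with the ET_B fraction of *both*
    compartments overridden (``None`` keeps the calibrated per-compartment
    values).  Both sweeps use the same concentration grid so the
    ``f_b = 0.5`` symmetry between the two antagonists is directly
    comparable."""
    mults = tuple(multiples) if multiples is not None else tuple(
        concentration_grid(1e-3, 1e5, points_per_decade)
    )
    eta = run_sweep(
        SweepSpec(mode="eta_perfect", f_b=f_b, multiples=mults), params
    )
    etb = run_sweep(
        SweepSpec(mode="etb_perfect", f_b=f_b, multiples=mults), params
    )
    return FbComparison(f_b=f_b if f_b is not None else math.nan,
                        eta_sweep=eta, etb_sweep=etb)
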