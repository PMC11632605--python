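"""Variance-based global sensitivity analysis (Sobol indices).

Saltelli-style sampling: two independent quasi-random matrices ``A`` and
``B`` (a scrambled Sobol sequence in 2k dimensions, split in half) plus the
``k`` hybrid matrices ``AB_i`` in which column ``i`` of ``A`` is replaced by
column ``i`` of ``B`` — ``N * (k + 2)`` model evaluations in total.

Estimators (for output variance ``V``):

* first-order (Saltelli 2010):  ``S_i = mean(f(B) * (f(AB_i) - f(A))) / V``
* total-order (Jansen 1999):    ``T_i = mean((f(A) - f(AB_i))^2) / (2 V)``

``S_i`` is the fraction of output variance attributable to parameter ``i``
alone; ``T_i`` additionally counts all interactions involving it, so
``S_i <= T_i`` up to Monte-Carlo error.  Bootstrap confidence intervals
resample the ``N`` sample rows.

The built-in model functional used for ranking parameter importance is the
maximum steady-state percent rise of the plasma ET1-ET_B complex under a
perfectly selective ET_A antagonist — the headline quantity of the
selectivity analysis.  Default parameter ranges are uniform bands of +/- 3
calibration relative standard errors around the calibrated values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .binding import AntagonistSpec
from .kinetics import steady_state_with_antagonist
from .parameters import ModelParameters

__all__ = [
    "SensitivitySpec",
    "SaltelliDesign",
    "generate_design",
    "evaluate_design",
    "sobol_indices",
    "CALIBRATION_RSE_PERCENT",
    "model_sensitivity_spec",
    "eta_antagonism_etb_rise",
    "run_model_sobol",
]

#: calibration relative standard errors (percent) of the estimated
#: parameters, used for the default sensitivity ranges.
CALIBRATION_RSE_PERCENT: dict[str, float] = {
    "v_p": 1.1,
    "v_t": 7.0,
    "k_pt": 18.5,
    "k_tp": 2.3,
    "k_int": 0.4,
    "r_tot_p": 1.2,
    "f_b_t": 11.0,
    "f_b_c": 15.0,
}


@dataclass(frozen=True)
class SensitivitySpec:
    """Parameter names/ranges and sampling settings for a Sobol analysis."""

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    n: int = 256
    seed: int = 0
    log_uniform: bool = False

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ValueError("names and bounds must align")
        if self.n < 64 or self.n & (self.n - 1):
            raise ValueError(f"n must be a power of two >= 64 (got {self.n})")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
            if self.log_uniform and lo <= 0:
                raise ValueError(f"log-uniform range for {name} must be positive")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SaltelliDesign:
    """A, B and the k column-swapped AB matrices; rows are parameter draws."""

    spec: SensitivitySpec
    A: np.ndarray          # (n, k)
    B: np.ndarray          # (n, k)
    AB: np.ndarray         # (k, n, k)

    @property
    def n_evaluations(self) -> int:
        return self.spec.n * (self.spec.k + 2)

    def all_rows(self) -> np.ndarray:
        """All design rows stacked: A, B, AB_1..AB_k -> (n*(k+2), k)."""
        return np.vstack([self.A, self.B, self.AB.reshape(-1, self.spec.k)])


def generate_design(spec: SensitivitySpec) -> SaltelliDesign:
    """Deterministic (seeded) Saltelli sample over the parameter box."""
    sampler = qmc.Sobol(d=2 * spec.k, scramble=True, seed=spec.seed)
    base = sampler.random(spec.n)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])

    def scale(u: np.ndarray) -> np.ndarray:
        if spec.log_uniform:
            return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
        return lo + u * (hi - lo)

    A = scale(base[:, : spec.k])
    B = scale(base[:, spec.k:])
    AB = np.empty((spec.k, spec.n, spec.k))
    for i in range(spec.k):
        AB[i] = A
        AB[i, :, i] = B[:, i]
    return SaltelliDesign(spec=spec, A=A, B=B, AB=AB)


def evaluate_design(
    design: SaltelliDesign,
    func: Callable[[dict[str, float]], float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate a scalar model ``func(draw_dict)`` over the whole design."""
    names = design.spec.names

    def run(mat: np.ndarray) -> np.ndarray:
        return np.array([func(dict(zip(names, row))) for row in mat])

    fA = run(design.A)
    fB = run(design.B)
    fAB = np.stack([run(design.AB[i]) for i in range(design.spec.k)])
    return fA, fB, fAB


def sobol_indices(
    fA: np.ndarray,
    fB: np.ndarray,
    fAB: np.ndarray,
    names: Sequence[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """First-order and total-order Sobol indices with bootstrap CIs.

    Returns a frame with columns parameter, S1, S1_CI_low, S1_CI_high, ST,
    ST_CI_low, ST_CI_high.  A zero-variance output yields all-zero indices
    with a warning.
    """
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    fAB = np.asarray(fAB, dtype=float)
    if not (np.all(np.isfinite(fA)) and np.all(np.isfinite(fB)) and np.all(np.isfinite(fAB))):
        raise ValueError("model outputs must be finite")
    k, n = fAB.shape
    names = list(names) if names is not None else [f"x{i+1}" for i in range(k)]

    def estimate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b, ab = fA[idx], fB[idx], fAB[:, idx]
        var = np.var(np.concatenate([a, b]))
        if var <= 0.0:
            return np.zeros(k), np.zeros(k)
        s1 = np.mean(b * (ab - a), axis=1) / var
        st = 0.5 * np.mean((a - ab) ** 2, axis=1) / var
        return s1, st

    full = np.arange(n)
    S1, ST = estimate(full)
    if np.var(np.concatenate([fA, fB])) <= 0.0:
        warnings.warn("zero-variance model output; Sobol indices set to 0", stacklevel=2)

    rng = np.random.default_rng(seed)
    boots_s1 = np.empty((n_boot, k))
    boots_st = np.empty((n_boot, k))
    for b_ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots_s1[b_], boots_st[b_] = estimate(idx)
    alpha = 0.5 * (1.0 - ci_level)
    qs = [100 * alpha, 100 * (1 - alpha)]
    s1_lo, s1_hi = np.percentile(boots_s1, qs, axis=0)
    st_lo, st_hi = np.percentile(boots_st, qs, axis=0)

    return pd.DataFrame(
        {
            "parameter": names,
            "S1": S1,
            "S1_CI_low": s1_lo,
            "S1_CI_high": s1_hi,
            "ST": ST,
            "ST_CI_low": st_lo,
            "ST_CI_high": st_hi,
        }
    )


# ------------------------------------------------- model output functional


def eta_antagonism_etb_rise(
    draw: dict[str, float],
    base: ModelParameters | None = None,
    multiples: Sequence[float] | None = None,
) -> float:
    """Max steady-state % rise of plasma [ET1-ET_B] under a perfectly
    selective ET_A antagonist, for one parameter draw."""
    base = base or ModelParameters()
    draw = dict(draw)
    for fb_name in ("f_b_t", "f_b_c"):
        if fb_name in draw:
            draw[fb_name] = min(draw[fb_name], 1.0)
    params = base.replace(**draw)
    eta = AntagonistSpec(K_ia=1.0, K_ib=math.inf, name="perfect_ETA")
    if multiples is None:
        multiples = np.geomspace(1e-3, 1e3, 13)
    _, sol_p0, _ = steady_state_with_antagonist(params, eta, 0.0)
    best = 0.0
    for mult in multiples:
        _, sol_p, _ = steady_state_with_antagonist(params, eta, float(mult))
        best = max(best, 100.0 * (sol_p.ET1_RB / sol_p0.ET1_RB - 1.0))
    return best


def model_sensitivity_spec(
    base: ModelParameters | None = None,
    names: Sequence[str] | None = None,
    n: int = 128,
    seed: int = 0,
    rse_multiple: float = 3.0,
) -> SensitivitySpec:
    """Default sensitivity spec: uniform +/- ``rse_multiple`` calibration
    RSEs around the calibrated values (fractions capped at 1)."""
    base = base or ModelParameters()
    names = tuple(names) if names else tuple(CALIBRATION_RSE_PERCENT)
    bounds = []
    for name in names:
        center = getattr(base, name)
        half = rse_multiple * CALIBRATION_RSE_PERCENT[name] / 100.0 * center
        lo, hi = center - half, center + half
        if name.startswith("f_b"):
            hi = min(hi, 1.0)
        lo = max(lo, 1e-12)
        bounds.append((lo, hi))
    return SensitivitySpec(names=names, bounds=tuple(bounds), n=n, seed=seed)


def run_model_sobol(
    spec: SensitivitySpec | None = None,
    base: ModelParameters | None = None,
    func: Callable[[dict[str, float]], float] | None = None,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Sobol indices of the selectivity-analysis output functional."""
    spec = spec or model_sensitivity_spec(base)
    func = func or (lambda draw: eta_antagonism_etb_rise(draw, base))
    design = generate_design(spec)
    fA, fB, fAB = evaluate_design(design, func)
    return sobol_indices(fA, fB, fAB, names=spec.names, n_boot=n_boot, seed=spec.seed)
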