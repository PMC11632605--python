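"""Quasi-equilibrium receptor binding algebra for endothelin-1 (ET-1).

ET-1 binds the ET_A and ET_B receptors with a shared dissociation constant
``K_d``.  Binding and dissociation are several orders of magnitude faster than
production, distribution and internalization, so at every instant the free
ligand, free receptors and receptor-ligand complexes satisfy algebraic
equilibrium (the quasi-equilibrium, TMDD-like approximation):

    K_d = [R] * [ET1] / [ET1-R]

With a competitive antagonist at concentration ``I`` (affinity ``K_ia`` for
ET_A, ``K_ib`` for ET_B), each receptor behaves as if its dissociation
constant were inflated to ``K_d * (1 + I / K_i)``:

    [ET1-RA] = RA_tot * [ET1] / (K_d*(1 + I/K_ia) + [ET1])
    [ET1-RB] = RB_tot * [ET1] / (K_d*(1 + I/K_ib) + [ET1])

Free ET-1 given total ET-1 is the physical root of the resulting third-order
polynomial; this module solves it by safeguarded bracketed root-finding on
[0, ET1_tot], which is robust for extreme affinity ratios (a "perfectly
selective" antagonist is encoded as ``K_i = inf`` or the conventional 1e20).

Units: concentrations in pmol/L throughout the package; times in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "ReceptorPool",
    "BindingConstants",
    "AntagonistSpec",
    "BindingSolution",
    "PERFECTLY_SELECTIVE",
    "split_receptor_pool",
    "free_ligand_no_inhibitor",
    "bound_complex",
    "free_ligand_with_inhibitor",
    "inhibited_binding_solution",
]

#: Conventional "infinitely weak" affinity used to encode a perfectly
#: selective antagonist; ``math.inf`` is also accepted and drops the
#: corresponding inhibition term analytically.
PERFECTLY_SELECTIVE = math.inf

# Solver tolerances: concentrations span ~1e-3 .. 1e7 pmol/L across the
# selectivity sweeps, so both an absolute floor and a relative target are set.
_XTOL = 1e-24  # pmol/L; effectively machine precision for any scale
_RTOL = 8.9e-16  # ~4 eps, brentq's floor — mass balance must hold to 1e-9
                 # relative even for totals of ~1e-3 pmol/L


def _validate_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) and not (name.startswith("K_i") and value == math.inf):
            raise ValueError(f"{name} must be finite (got {value!r})")
        if value < 0:
            raise ValueError(f"{name} must be non-negative (got {value!r})")


def _validate_pos(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive (got {value!r})")


@dataclass(frozen=True)
class ReceptorPool:
    """Total receptor pool split into ET_A and ET_B fractions.

    Parameters
    ----------
    R_tot : float
        Total receptor concentration (pmol/L).
    f_B : float
        Fraction of receptors that are ET_B, in [0, 1].  ``f_B`` of 0 or 1
        degenerates gracefully to a single-receptor system.
    """

    R_tot: float
    f_B: float

    def __post_init__(self) -> None:
        if self.R_tot < 0:
            raise ValueError(f"R_tot must be non-negative (got {self.R_tot})")
        if not 0.0 <= self.f_B <= 1.0:
            raise ValueError(f"f_B must lie in [0, 1] (got {self.f_B})")

    @property
    def RB_tot(self) -> float:
        return self.f_B * self.R_tot

    @property
    def RA_tot(self) -> float:
        # Complement of RB so that RA_tot + RB_tot == R_tot exactly in floats.
        return self.R_tot - self.f_B * self.R_tot


@dataclass(frozen=True)
class BindingConstants:
    """ET-1 dissociation constant, shared by ET_A and ET_B (pmol/L)."""

    K_d: float

    def __post_init__(self) -> None:
        _validate_pos(K_d=self.K_d)


@dataclass(frozen=True)
class AntagonistSpec:
    """Competitive antagonist affinities.

    ``K_ia``/``K_ib`` are the inhibition constants for ET_A/ET_B (pmol/L);
    ``selectivity = K_ib / K_ia`` (> 1 means ET_A-selective).  ``math.inf``
    (or the conventional 1e20) encodes no measurable affinity.
    """

    K_ia: float
    K_ib: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.K_ia > 0:
            raise ValueError(f"K_ia must be positive (got {self.K_ia})")
        if not self.K_ib > 0:
            raise ValueError(f"K_ib must be positive (got {self.K_ib})")

    @property
    def selectivity(self) -> float:
        return self.K_ib / self.K_ia


@dataclass(frozen=True)
class BindingSolution:
    """Free/bound ET-1 and free receptors at quasi-equilibrium (pmol/L)."""

    ET1_free: float
    ET1_RA: float
    ET1_RB: float
    RA_free: float
    RB_free: float

    @property
    def ET1_tot(self) -> float:
        return self.ET1_free + self.ET1_RA + self.ET1_RB

    @property
    def complex_total(self) -> float:
        return self.ET1_RA + self.ET1_RB


def split_receptor_pool(R_tot: float, f_B: float) -> tuple[float, float]:
    """Split a total receptor pool into (RA_tot, RB_tot).

    ``RB_tot = f_B * R_tot`` and ``RA_tot = R_tot - RB_tot`` so the two parts
    sum to ``R_tot`` exactly.
    """
    pool = ReceptorPool(R_tot, f_B)
    return pool.RA_tot, pool.RB_tot


def _inflated_kd(K_d: float, I: float, K_i: float) -> float:
    """Apparent dissociation constant under competitive inhibition."""
    if math.isinf(K_i) or I == 0.0:
        return K_d
    return K_d * (1.0 + I / K_i)


def free_ligand_no_inhibitor(ET1_tot: float, R_tot: float, K_d: float) -> float:
    """Free ET-1 given total ET-1 and a lumped receptor pool (no antagonist).

    Solves the quadratic mass balance
    ``ET1_tot = x + R_tot*x/(K_d + x)`` for the non-negative root, using the
    cancellation-free form of the quadratic formula.
    """
    _validate_nonneg(ET1_tot=ET1_tot, R_tot=R_tot)
    _validate_pos(K_d=K_d)
    if ET1_tot == 0.0:
        return 0.0
    b = ET1_tot - R_tot - K_d
    disc = math.sqrt(b * b + 4.0 * K_d * ET1_tot)
    if b > 0:
        x = 0.5 * (b + disc)
    else:
        # avoid catastrophic cancellation when b << 0 (receptor excess)
        x = 2.0 * K_d * ET1_tot / (disc - b)
    return min(x, ET1_tot)


def bound_complex(R_tot: float, ET1_free: float, K_d: float) -> float:
    """Receptor-ligand complex ``R_tot * x / (K_d + x)`` (pmol/L)."""
    _validate_nonneg(R_tot=R_tot, ET1_free=ET1_free)
    _validate_pos(K_d=K_d)
    return R_tot * ET1_free / (K_d + ET1_free)


def _mass_balance_residual(
    x: float,
    ET1_tot: float,
    RA_tot: float,
    RB_tot: float,
    KA: float,
    KB: float,
) -> float:
    return x + RA_tot * x / (KA + x) + RB_tot * x / (KB + x) - ET1_tot


def free_ligand_with_inhibitor(
    ET1_tot: float,
    RA_tot: float,
    RB_tot: float,
    K_d: float,
    I: float,
    K_ia: float,
    K_ib: float,
) -> float:
    """Free ET-1 under competitive antagonism.

    The unique physical root of the third-order mass-balance polynomial,
    bracketed on [0, ET1_tot].  With ``I == 0`` or ``K_ia == K_ib`` the
    problem collapses to the quadratic case and is solved in closed form.
    """
    _validate_nonneg(ET1_tot=ET1_tot, RA_tot=RA_tot, RB_tot=RB_tot, I=I)
    _validate_pos(K_d=K_d, K_ia=K_ia, K_ib=K_ib)
    if ET1_tot == 0.0:
        return 0.0
    KA = _inflated_kd(K_d, I, K_ia)
    KB = _inflated_kd(K_d, I, K_ib)
    if math.isinf(KA) and math.isinf(KB):
        return ET1_tot
    if math.isinf(KA):
        return free_ligand_no_inhibitor(ET1_tot, RB_tot, KB)
    if math.isinf(KB):
        return free_ligand_no_inhibitor(ET1_tot, RA_tot, KA)
    if KA == KB:
        # symmetric inhibition: one pool with apparent K_d' = K_d*(1 + I/K_i)
        return free_ligand_no_inhibitor(ET1_tot, RA_tot + RB_tot, KA)

    lo, hi = 0.0, ET1_tot
    f_hi = _mass_balance_residual(hi, ET1_tot, RA_tot, RB_tot, KA, KB)
    if f_hi <= 0.0:  # all ligand effectively free (within round-off)
        return ET1_tot
    try:
        x = brentq(
            _mass_balance_residual,
            lo,
            hi,
            args=(ET1_tot, RA_tot, RB_tot, KA, KB),
            xtol=_XTOL,
            rtol=_RTOL,
            maxiter=200,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "free-ligand solve failed for "
            f"ET1_tot={ET1_tot}, RA_tot={RA_tot}, RB_tot={RB_tot}, "
            f"K_d={K_d}, I={I}, K_ia={K_ia}, K_ib={K_ib}"
        ) from exc
    return min(max(x, 0.0), ET1_tot)


def inhibited_binding_solution(
    ET1_tot: float,
    RA_tot: float,
    RB_tot: float,
    K_d: float,
    I: float,
    K_ia: float,
    K_ib: float,
) -> BindingSolution:
    """Full quasi-equilibrium solution in the presence of an antagonist.

    Returns free ET-1 (from the cubic), both receptor-ligand complexes and
    both free-receptor concentrations.  Mass balance
    ``ET1_free + ET1_RA + ET1_RB == ET1_tot`` holds to solver tolerance.
    """
    x = free_ligand_with_inhibitor(ET1_tot, RA_tot, RB_tot, K_d, I, K_ia, K_ib)
    KA = _inflated_kd(K_d, I, K_ia)
    KB = _inflated_kd(K_d, I, K_ib)
    ET1_RA = 0.0 if math.isinf(KA) else RA_tot * x / (KA + x)
    ET1_RB = 0.0 if math.isinf(KB) else RB_tot * x / (KB + x)
    # Free receptors: R_tot / (1 + x/K_d + I/K_i)
    ia = 0.0 if math.isinf(K_ia) else I / K_ia
    ib = 0.0 if math.isinf(K_ib) else I / K_ib
    RA_free = RA_tot / (1.0 + x / K_d + ia)
    RB_free = RB_tot / (1.0 + x / K_d + ib)
    return BindingSolution(x, ET1_RA, ET1_RB, RA_free, RB_free)
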