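import math

import numpy as np
import pytest

from etkinetics import ModelParameters
from etkinetics.kinetics import resolve_baseline


@pytest.fixture(scope="session")
def calibrated_params() -> ModelParameters:
    """The calibrated (default) parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline(calibrated_params):
    return resolve_baseline(calibrated_params)


def bisect_cubic_free_ligand(
    tot: float, RA: float, RB: float, Kd: float, I: float,
    Kia: float, Kib: float, iters: int = 200,
) -> float:
    """Independent oracle: plain bisection on the expanded third-order
    polynomial for free ligand under competitive antagonism.

    Works from the polynomial coefficients (denominators cleared), a
    different formulation from the implementation's bracketed solve of the
    mass-balance residual.
    """
    KA = Kd * (1.0 + (0.0 if math.isinf(Kia) else I / Kia))
    KB = Kd * (1.0 + (0.0 if math.isinf(Kib) else I / Kib))
    a3 = 1.0
    a2 = KA + KB + RA + RB - tot
    a1 = KA * KB + RA * KB + RB * KA - tot * (KA + KB)
    a0 = -tot * KA * KB

    def poly(x: float) -> float:
        return ((a3 * x + a2) * x + a1) * x + a0

    lo, hi = 0.0, tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if poly(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def cubic_oracle():
    return bisect_cubic_free_ligand


def random_binding_draws(n: int, seed: int = 0) -> np.ndarray:
    """Randomized valid binding problems spanning the sweep's ranges:
    columns tot, RA, RB, Kd, I, Kia, Kib (log-uniform scales)."""
    rng = np.random.default_rng(seed)
    tot = 10 ** rng.uniform(-3, 5, n)
    ra = 10 ** rng.uniform(-2, 4, n)
    rb = 10 ** rng.uniform(-2, 4, n)
    kd = 10 ** rng.uniform(1, 4, n)
    i = 10 ** rng.uniform(-3, 6, n)
    kia = 10 ** rng.uniform(-2, 7, n)
    kib = 10 ** rng.uniform(-2, 7, n)
    return np.column_stack([tot, ra, rb, kd, i, kia, kib])
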