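"""Synthetic observation sets for exercising the calibration pipeline.

The original calibration used digitized published mean time courses; no raw
data are available.  This module generates observation sets with the same
sampling schedules and the statistical structure the estimator assumes:
plasma ET-1 simulated under a study protocol at the protocol's printed
sampling times, perturbed by mean-zero proportional (plus optional additive)
Gaussian noise and truncated at zero — immunoassay ET-1 measurement error
scales with the measured level, and concentrations cannot be negative.

The default conditions mirror the three-study calibration: tracer bolus,
stepped ET-1 infusion and stepped Big ET-1 infusion, each with its
study-specific ECE concentration and the tissue receptor pool derived from
the steady-state constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import ObservationSet
from .kinetics import SimulateOptions, simulate
from .parameters import ModelParameters, STUDY_ECE_NMOL
from .protocols import InfusionProtocol, builtin_protocol

__all__ = ["NoiseModel", "generate", "generate_tristudy", "generate_suite"]

#: calibration designs: study id -> (protocol name, ECE nmol/L)
CALIBRATION_STUDIES: dict[str, tuple[str, float]] = {
    "parker": ("bolus_tracer", STUDY_ECE_NMOL["parker"]),
    "hunter": ("stepped_et1", STUDY_ECE_NMOL["hunter"]),
    "kaasjager": ("stepped_biget", STUDY_ECE_NMOL["kaasjager"]),
}


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise, truncated at zero.

    ``cv`` is the proportional coefficient of variation (default 10%, a
    typical immunoassay precision); ``sd`` an additive component in pmol/L.
    """

    cv: float = 0.1
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise cv and sd must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        noisy = values * (1.0 + self.cv * rng.standard_normal(values.shape))
        if self.sd > 0:
            noisy = noisy + self.sd * rng.standard_normal(values.shape)
        return np.maximum(noisy, 0.0)


def generate(
    protocol: InfusionProtocol,
    true_params: ModelParameters,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    study_id: str | None = None,
    ece_group: str = "",
) -> ObservationSet:
    """Simulate one protocol and emit noisy observations at its printed
    sampling times.

    Tracer protocols emit relative (baseline-subtracted, peak-normalized)
    values; noise applies after normalization.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = protocol.sampling_times
    if not times:
        raise ValueError(f"protocol {protocol.name!r} has no sampling times")
    sim = simulate(protocol, true_params, SimulateOptions(output_times=times))
    clean = sim.at_times(times)
    values = noise.apply(clean, rng)
    return ObservationSet(
        study_id=study_id or protocol.name,
        protocol=protocol,
        times=tuple(times),
        values=tuple(values),
        relative=protocol.relative_output,
        ece_group=ece_group,
    )


def generate_tristudy(
    true_params: ModelParameters | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    subject_mass_kg: float = 70.0,
) -> list[ObservationSet]:
    """The simultaneous-calibration bundle: three studies, shared
    physiology, study-specific ECE (tissue receptor pool derived from the
    steady-state constraint per study)."""
    base = true_params or ModelParameters()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(CALIBRATION_STUDIES))
    out = []
    for child, (study, (proto_name, ece)) in zip(children, CALIBRATION_STUDIES.items()):
        proto = builtin_protocol(proto_name, subject_mass_kg=subject_mass_kg)
        params = base.replace(ece_nmol=ece)
        out.append(generate(proto, params, noise, child, study_id=study))
    return out


def generate_suite(
    true_params: ModelParameters | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 20,
    seed: int | None = None,
) -> list[list[ObservationSet]]:
    """Independent replicate tri-study bundles for estimator robustness
    studies; replicate seeds derive deterministically from the master seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = np.random.SeedSequence(seed)
    return [
        generate_tristudy(true_params, noise, child)
        for child in master.spawn(n_replicates)
    ]
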