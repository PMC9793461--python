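"""Apparent partition coefficient and sink-condition volume calculators.

The apparent partition coefficient P_app quantifies how strongly the
drug prefers the oil formulation over the aqueous release medium at
equilibrium.  Only the aqueous-phase concentration is measured; the
oil-phase concentration is recovered by mass balance from the prepared
oil-solution concentration and the two phase volumes:

    P_app = (c_i * V_u - c_v * V_v) / (c_v * V_u)

where c_i is the drug concentration of the prepared oil solution,
c_v the measured aqueous concentration at equilibrium, and V_u, V_v
the oil- and aqueous-phase volumes.  log10 P_app > 1 is the usual
screen for a formulation capable of prolonged release.

Sink conditions require the medium volume to be a comfortable multiple
of the volume that the dose would just saturate (dose / solubility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PartitionExperiment:
    """Two-phase equilibrium experiment measurements.

    c_i: mg/mL drug concentration of the prepared oil solution.
    c_v: mg/mL aqueous-phase drug concentration at equilibrium.
    V_u: mL oil-phase volume; V_v: mL aqueous-phase volume.
    """

    c_i: float
    c_v: float
    V_u: float
    V_v: float

    def __post_init__(self):
        for name in ("c_i", "c_v", "V_u", "V_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # the aqueous phase cannot hold more drug than total mass allows
        if self.c_v > self.c_i * self.V_u / self.V_v * (1 + 1e-12):
            raise ValueError(
                "c_v exceeds the total-mass bound c_i * V_u / V_v"
            )


@dataclass(frozen=True)
class SinkSpec:
    """Inputs for the sink-volume calculation.

    sink_factor is the required multiple of the saturation volume;
    3 is the classical choice, 10 a conservative one.
    """

    dose_mass: float  # mg
    medium_solubility: float  # mg/mL
    sink_factor: float = 3.0

    def __post_init__(self):
        if self.dose_mass <= 0 or self.medium_solubility <= 0:
            raise ValueError("dose_mass and medium_solubility must be positive")
        if self.sink_factor < 1:
            raise ValueError("sink_factor must be >= 1")


def apparent_partition_coefficient(exp: PartitionExperiment) -> float:
    """Mass-balance apparent partition coefficient (dimensionless).

    Equals the oil-phase concentration inferred by mass balance divided
    by the measured aqueous concentration.  c_v -> 0 means effectively
    infinite partitioning and is rejected at construction.
    """
    return (exp.c_i * exp.V_u - exp.c_v * exp.V_v) / (exp.c_v * exp.V_u)


def partition_ratio(c_oil: float, c_aq: float) -> float:
    """Directly measured oil/aqueous concentration ratio."""
    if c_oil <= 0 or c_aq <= 0:
        raise ValueError("concentrations must be positive")
    return c_oil / c_aq


def log_partition(P: float) -> float:
    """Base-10 logarithm of a partition coefficient."""
    if P <= 0:
        raise ValueError("P must be positive")
    return math.log10(P)


def sink_volume(spec: SinkSpec) -> float:
    """Minimum medium volume (mL) satisfying the sink criterion:
    sink_factor * dose_mass / medium_solubility."""
    return spec.sink_factor * spec.dose_mass / spec.medium_solubility


def is_sink(medium_volume: float, spec: SinkSpec) -> bool:
    """True iff the medium volume meets or exceeds the sink volume."""
    if medium_volume <= 0:
        raise ValueError("medium_volume must be positive")
    return medium_volume >= sink_volume(spec)
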