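"""Physical constants and unit conversions.

Unit conventions, fixed project-wide: times in ms, gradient amplitudes in
mT/m, diffusivities in mm^2/s, b-values in s/mm^2, angles in degrees at all
public interfaces (radians internally).  Signals are fractions of M0; reported
"signal" columns are percent of M0.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.6752e8

#: Default system maximum gradient amplitude, mT/m.
G_MAX_DEFAULT = 38.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Scanner/physics constants shared by the signal models.

    gamma : proton gyromagnetic ratio, rad s^-1 T^-1
    G_max : maximum gradient amplitude, mT/m
    """

    gamma: float = GAMMA
    G_max: float = G_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.G_max <= 0:
            raise ValueError(f"G_max must be > 0, got {self.G_max}")


def q_rad_per_mm(G: float, delta: float, gamma: float = GAMMA) -> float:
    """Dephasing moment q = gamma * G * delta of one rectangular gradient lobe.

    Parameters are in project units (G in mT/m, delta in ms); the result is in
    rad/mm, the natural unit for b-value arithmetic in s/mm^2:
    b contributions are q^2 [rad^2/mm^2] * time [s].
    """
    return gamma * (G * 1e-3) * (delta * 1e-3) * 1e-3
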