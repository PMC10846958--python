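"""Hertzian contact mechanics for a pyramidal indenter.

For a rigid four-sided pyramidal tip pressed into an incompressible
elastic half-space, the load grows quadratically with indentation depth:

    F = (2/pi) * E / (1 - nu^2) * tan(alpha) * delta^2

with E the Young's modulus, nu the Poisson's ratio, alpha the half
opening angle of the tip and delta the indentation depth.  Working units
throughout the package are kPa for moduli, micrometres for depths and
nanonewtons for forces; conveniently 1 kPa = 1 nN/um^2, so the prefactor
is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TipGeometry:
    """Pyramidal tip geometry and sample compressibility.

    Parameters
    ----------
    half_angle_deg:
        Half opening angle of the pyramid, degrees. Default 20 deg,
        the effective half-angle convention for sharp silicon-nitride
        probes of the MSNL family.
    poisson_ratio:
        Poisson's ratio of the sample. Default 0.5 (incompressible),
        the standard assumption for soft hydrated tissue.
    """

    half_angle_deg: float = 20.0
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValueError(f"half_angle_deg must be in (0, 90), got {self.half_angle_deg}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")

    @property
    def prefactor(self) -> float:
        """C such that F[nN] = C * E[kPa] * delta[um]**2."""
        alpha = np.radians(self.half_angle_deg)
        return float(2.0 / np.pi * np.tan(alpha) / (1.0 - self.poisson_ratio**2))


def hertz_force(delta_um, modulus_kPa: float, tip: TipGeometry):
    """Force (nN) exerted by a pyramidal tip at indentation depth delta (um)."""
    delta = np.asarray(delta_um, dtype=float)
    return tip.prefactor * modulus_kPa * delta**2
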