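"""Nondimensionalization scale registry.

All solver internals are nondimensional.  Dimensional quantities (Pa, seconds,
m/s) enter and leave through a :class:`ScaleRegistry`, which fixes the three
primary scales: a characteristic velocity ``U``, a characteristic length ``L``
and the blood mass density ``rho``.  The defaults are the rheometry scales
(U = 3.33e-3 m/s, L = 3e-4 m, rho = 1000 kg/m^3); virtual experiments that use
different physical scales construct their own registry.

Derived scales:

===========  =================  ======================
quantity     scale              default value
===========  =================  ======================
time         L / U              9.009e-2 s
stress       rho U^2            1.10889e-2 Pa
viscosity    rho U L            9.99e-4 Pa s
pressure     rho U^2            1.10889e-2 Pa
===========  =================  ======================
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleRegistry:
    """Primary scales used to (non)dimensionalize solver quantities."""

    velocity: float = 3.33e-3  # m/s
    length: float = 3.0e-4     # m
    density: float = 1000.0    # kg/m^3

    def __post_init__(self) -> None:
        if self.velocity <= 0 or self.length <= 0 or self.density <= 0:
            raise ValueError("all primary scales must be strictly positive")

    # -- derived scales ----------------------------------------------------
    @property
    def time(self) -> float:
        return self.length / self.velocity

    @property
    def stress(self) -> float:
        return self.density * self.velocity**2

    @property
    def viscosity(self) -> float:
        return self.density * self.velocity * self.length

    # -- conversions -------------------------------------------------------
    def modulus_to_nondim(self, pa: float) -> float:
        return pa / self.stress

    def modulus_to_pa(self, nd: float) -> float:
        return nd * self.stress

    def time_to_seconds(self, nd: float) -> float:
        return nd * self.time

    def seconds_to_nondim(self, s: float) -> float:
        return s / self.time

    def viscosity_to_nondim(self, pa_s: float) -> float:
        return pa_s / self.viscosity

    def frequency_to_nondim(self, hz: float) -> float:
        """Convert a dimensional frequency (Hz) to cycles per time unit."""
        return hz * self.time

    def frequency_to_hz(self, nd: float) -> float:
        return nd / self.time


#: Registry of the oscillatory-shear calibration (gap 300 um, plate 6.67e-4 m/s).
RHEOMETRY_SCALES = ScaleRegistry()
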