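"""Saw-tooth load protocols for the extension-inflation-torsion test.

Pseudo-time runs over [0, 1.6] with one physiological and one
supra-physiological cycle.  Snapshot instants: A = 0.4 (peak physiological
state), B = 1.2 (supra-physiological peak), C = 1.6 (end of simulation).
Pressures are entered in mmHg and converted with 1 mmHg = 0.133322 kPa; the
axial displacement ramps to its physiological peak and is then held constant;
the twist angle follows the same saw-tooth shape as the pressure.  All
intra-cycle ramps are piecewise linear and synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MMHG_TO_KPA", "mmhg_to_kpa", "PiecewiseLinear", "TubeProtocol",
           "INSTANT_A", "INSTANT_B", "INSTANT_C"]

MMHG_TO_KPA = 0.133322

INSTANT_A = 0.4
INSTANT_B = 1.2
INSTANT_C = 1.6


def mmhg_to_kpa(p_mmhg) -> float:
    return np.asarray(p_mmhg, dtype=float) * MMHG_TO_KPA


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear history t -> value with clamped extrapolation."""

    times: tuple
    values: tuple

    def __call__(self, t):
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class TubeProtocol:
    """Two-cycle saw-tooth loading of the aortic segment.

    Defaults: physiological pressure peak 120 mmHg falling back to 80 mmHg,
    supra-physiological peak 600 mmHg; axial displacement 8 mm (axial
    stretch 1.2 on the 40 mm segment), reached at the physiological peak and
    then held; twist 10 deg physiological, 30 deg supra-physiological.
    """

    peak_phys_mmhg: float = 120.0
    valley_mmhg: float = 80.0
    peak_supra_mmhg: float = 600.0
    u_z_peak: float = 8.0        # mm
    twist_phys: float = 10.0     # degrees
    twist_supra: float = 30.0    # degrees
    t_end: float = INSTANT_C

    @property
    def pressure_kpa(self) -> PiecewiseLinear:
        t = (0.0, INSTANT_A, 0.8, INSTANT_B, INSTANT_C)
        p = (0.0, self.peak_phys_mmhg, self.valley_mmhg, self.peak_supra_mmhg, 0.0)
        return PiecewiseLinear(times=t, values=tuple(v * MMHG_TO_KPA for v in p))

    @property
    def axial_displacement(self) -> PiecewiseLinear:
        # held constant after the physiological peak
        return PiecewiseLinear(times=(0.0, INSTANT_A, INSTANT_C),
                               values=(0.0, self.u_z_peak, self.u_z_peak))

    @property
    def twist_deg(self) -> PiecewiseLinear:
        return PiecewiseLinear(
            times=(0.0, INSTANT_A, 0.8, INSTANT_B, INSTANT_C),
            values=(0.0, self.twist_phys, 0.0, self.twist_supra, 0.0),
        )

    def axial_stretch(self, segment_height: float) -> float:
        """Axial stretch implied by the held displacement peak."""
        return 1.0 + self.u_z_peak / segment_height
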