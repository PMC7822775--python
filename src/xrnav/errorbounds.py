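"""Closed-form bounds on overlay misalignment from display rounding.

The live geometry panel shows table positions, SID and FD in whole
centimeters and angulations in whole degrees.  Two acquisitions with
identical displayed values can therefore differ by up to 1 cm in a table
coordinate and 1 degree in an angulation, and the resulting overlay
displacement on the detector is bounded in closed form, evaluated at the
largest projection magnification (maximal SID).

* Table rounding: an in-plane table shift of ``table_rounding`` mm magnifies
  onto the detector by SID_max/SPD, giving
  ``eps_table = table_rounding / SPD * SID_max``.
* Angulation rounding: an object at the largest distance from the optical
  axis still projected at maximal magnification sits SID_max - SPD from the
  iso... the displaced and undisplaced positions span an isoceles-like
  triangle whose third side follows from the law of cosines,
  ``eps_angulation = sqrt(b^2 + c^2 - 2 b c cos(theta))`` with
  ``c = SID_max - SPD`` and ``b = sin(90 deg) * c / sin(90 deg - theta)``.

Both bounds are worst cases for a single rounded parameter; simultaneous
rounding of several parameters can accumulate and is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorBoundQuery", "eps_angulation", "eps_table"]


@dataclass(frozen=True)
class ErrorBoundQuery:
    """Inputs of the rounding-error bounds.

    Parameters
    ----------
    sid_max : float
        Maximal source-image distance of the C-arm, mm.
    spd : float
        Source-to-patient distance of the C-arm, mm (vendor constant; must be
        provided explicitly).
    table_rounding : float
        Worst-case table display rounding span, mm (1 cm display -> 10 mm).
    angle_rounding : float
        Worst-case angulation display rounding span, degrees.
    """

    sid_max: float
    spd: float
    table_rounding: float = 10.0
    angle_rounding: float = 1.0

    def __post_init__(self):
        if not (self.sid_max > self.spd > 0):
            raise ValueError(
                f"require sid_max > spd > 0, got sid_max={self.sid_max}, spd={self.spd}"
            )
        if self.table_rounding < 0:
            raise ValueError("table_rounding must be non-negative")
        if not (0 <= self.angle_rounding < 90):
            raise ValueError("angle_rounding must be in [0, 90) degrees")


def eps_table(q: ErrorBoundQuery) -> float:
    """Worst-case detector displacement (mm) from table display rounding."""
    return q.table_rounding / q.spd * q.sid_max


def eps_angulation(q: ErrorBoundQuery) -> float:
    """Worst-case detector displacement (mm) from angulation display rounding."""
    theta = np.radians(q.angle_rounding)
    c = q.sid_max - q.spd
    b = np.sin(np.pi / 2) * c / np.sin(np.pi / 2 - theta)
    return float(np.sqrt(b**2 + c**2 - 2 * b * c * np.cos(theta)))
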