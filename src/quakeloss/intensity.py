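"""PGV to macroseismic intensity conversion.

A single log-linear law ``I = c0 + c1 * log10(PGV)`` with clamping, the
form used by instrumental-intensity scales.  The shipped default
coefficients (c0=9.77, c1=3.00, PGV in m/s) approximate the China Seismic
Intensity Scale (GB/T 17742-2020) PGV branch; they are configuration, not
an assertion of the standard's text, and should be replaced from the
standard itself for operational use.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import IntensityGrid, PGVGrid

__all__ = ["IntensityLaw", "pgv_to_intensity", "intensity_to_pgv"]


@dataclasses.dataclass(frozen=True)
class IntensityLaw:
    """Log-linear intensity law I = clamp(c0 + c1*log10(PGV), lo, hi).

    ``c1`` is intensity units per decade of PGV and must be positive so the
    law is monotone; PGV is in m/s. Zero PGV maps to the lower clamp.
    """

    c0: float = 9.77
    c1: float = 3.00
    clamp: tuple[float, float] = (1.0, 12.0)

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError("c1 must be positive (monotone law)")
        if not self.clamp[0] < self.clamp[1]:
            raise ValueError("clamp interval must be increasing")

    def apply(self, pgv: np.ndarray) -> np.ndarray:
        pgv = np.asarray(pgv, dtype=float)
        if np.any(pgv < 0):
            raise ValueError("PGV must be non-negative")
        lo, hi = self.clamp
        with np.errstate(divide="ignore"):
            raw = self.c0 + self.c1 * np.log10(pgv)
        raw = np.where(pgv > 0, raw, lo)
        return np.clip(raw, lo, hi)

    def invert(self, intensity: np.ndarray) -> np.ndarray:
        """PGV giving the stated intensity; exact inside the clamp interval."""
        intensity = np.asarray(intensity, dtype=float)
        return 10.0 ** ((intensity - self.c0) / self.c1)


def pgv_to_intensity(pgv: PGVGrid, law: IntensityLaw = IntensityLaw()) -> IntensityGrid:
    """Convert a PGV raster to a continuous intensity raster, cellwise."""
    return IntensityGrid(pgv.spec, law.apply(pgv.values))


def intensity_to_pgv(intensity: IntensityGrid, law: IntensityLaw = IntensityLaw()) -> PGVGrid:
    """Inverse conversion (useful for round-trip checks and test fixtures)."""
    return PGVGrid(intensity.spec, law.invert(intensity.values))
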