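"""Intensity x population overlay producing per-intensity exposure.

Population cells are the accumulation unit: intensity is sampled by
nearest neighbor at each population cell center and the cell's persons are
added to the binned intensity class.  Persons are never resampled, so
total population is conserved across the output buckets:

    sum_I Pe(I) + below_minimum + unassessed == total population.

``unassessed`` counts persons in population cells whose centers fall
outside the intensity grid extent; they are reported, never dropped.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .fatality import INTENSITY_CLASSES, INTENSITY_MAX, INTENSITY_MIN, ExposureVector
from .raster import IntensityGrid, PopulationGrid

__all__ = ["ExposureResult", "bin_intensity", "compute_exposure"]


@dataclasses.dataclass
class ExposureResult:
    """Per-class exposure plus the conservation buckets and diagnostics."""

    exposure: ExposureVector
    below_minimum: float     # persons at intensity < V
    unassessed: float        # persons outside the intensity grid extent
    total_population: float
    nodata_cells: int = 0

    def conservation_residual(self) -> float:
        """Relative mass-balance error; ~0 by construction."""
        assigned = self.exposure.total + self.below_minimum + self.unassessed
        denom = max(self.total_population, 1.0)
        return abs(assigned - self.total_population) / denom


def bin_intensity(x: float) -> int | None:
    """Discretize continuous intensity to a class: round half up.

    Values below IV.5 fall under the damaging range and return ``None``;
    values above XI clamp to XI with a warning.
    """
    if not np.isfinite(x):
        raise ValueError(f"non-finite intensity {x}")
    klass = int(np.floor(x + 0.5))
    if klass < INTENSITY_MIN:
        return None
    if klass > INTENSITY_MAX:
        warnings.warn(
            f"intensity {x} above class XI; clamped to XI", stacklevel=2
        )
        return INTENSITY_MAX
    return klass


def compute_exposure(intensity: IntensityGrid, pop: PopulationGrid) -> ExposureResult:
    """Overlay an intensity raster with a population raster.

    Both rasters must be in the same CRS; their extents must overlap.
    Nearest-neighbor sampling keeps ordinal class boundaries sharp.
    """
    if intensity.spec.crs != pop.spec.crs:
        raise ValueError(
            f"CRS mismatch: intensity {intensity.spec.crs!r} vs population {pop.spec.crs!r}"
        )
    if not np.all(np.isfinite(intensity.values)):
        raise ValueError("intensity grid contains non-finite values")

    ispec = intensity.spec
    lon, lat = pop.spec.cell_centers()

    # fractional index of each population cell center in the intensity grid
    col = (lon - ispec.origin_lon) / ispec.cell_size
    north_lat = ispec.origin_lat + (ispec.nrows - 1) * ispec.cell_size
    row = (north_lat - lat) / ispec.cell_size
    ic = np.round(col).astype(int)
    ir = np.round(row).astype(int)
    inside = (ic >= 0) & (ic < ispec.ncols) & (ir >= 0) & (ir < ispec.nrows)
    if not inside.any():
        raise ValueError("population and intensity extents are disjoint")

    persons = pop.values
    total = float(persons.sum())
    unassessed = float(persons[~inside].sum())

    sampled = intensity.values[ir[inside], ic[inside]]
    weights = persons[inside]

    klass = np.floor(sampled + 0.5).astype(int)
    n_over = int(np.count_nonzero(klass > INTENSITY_MAX))
    if n_over:
        warnings.warn(
            f"{n_over} population cell(s) sampled intensity above XI; clamped",
            stacklevel=2,
        )
    klass = np.minimum(klass, INTENSITY_MAX)

    below = float(weights[klass < INTENSITY_MIN].sum())
    damaging = klass >= INTENSITY_MIN
    counts = np.bincount(
        klass[damaging] - INTENSITY_MIN,
        weights=weights[damaging],
        minlength=len(INTENSITY_CLASSES),
    )
    pe = ExposureVector(dict(zip(INTENSITY_CLASSES, counts)))
    return ExposureResult(
        exposure=pe,
        below_minimum=below,
        unassessed=unassessed,
        total_population=total,
        nodata_cells=pop.nodata_count,
    )
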