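"""Empirical earthquake fatality model for Mainland China.

The model estimates expected fatalities from per-intensity population
exposure through a log-linear fatality-ratio function fitted per sub-region
on a historical damaging-earthquake catalog, with a human-development-index
(HDI) correction for societal change over time, and expresses uncertainty
as lognormal probabilities over the four NEEP emergency-response ranges.

Core quantities
---------------
fatality ratio      log10 r(I) = beta + theta * I,  clamped to r <= 1
expectation         E = sum_{I=V..XI} r(I) * (HDI_max / HDI_event) * Pe(I)
fit objective       eps = ln[(1/N) sum (E_i - O_i)^2] + (1/N) sum ln(E_i/O_i)^2
log residual        zeta = RMS of ln(E_i / O_i)
range probability   P(a < fatalities <= b) = Phi((ln b - ln E)/zeta)
                                            - Phi((ln a - ln E)/zeta)

NEEP response levels: IV (<=10), III (10-50], II (50-300], I (>300).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "INTENSITY_MIN",
    "INTENSITY_MAX",
    "INTENSITY_CLASSES",
    "REGIONS",
    "NEEP_RANGES",
    "HDITable",
    "ExposureVector",
    "CatalogEvent",
    "FatalityModelParams",
    "FatalityEstimate",
    "fatality_ratio",
    "hdi_factor",
    "estimate_fatalities",
    "fit_objective",
    "log_residual",
    "fit_params",
    "range_probability",
    "level_probabilities",
    "round_half_up",
]

#: Intensity classes of damaging earthquakes in the catalog (V through XI).
INTENSITY_MIN = 5
INTENSITY_MAX = 11
INTENSITY_CLASSES = tuple(range(INTENSITY_MIN, INTENSITY_MAX + 1))

#: The five sub-regions of Mainland China used for stratified fitting.
REGIONS: dict[str, str] = {
    "a": "Xinjiang",
    "b": "Qinghai-Tibet Plateau",
    "c": "Northeast",
    "d": "North China",
    "e": "South China",
}

#: NEEP fatality ranges (a, b] and their emergency-response levels, mildest
#: first.  Level IV is a "General Earthquake Disaster Event".
NEEP_RANGES: tuple[tuple[float, float, str], ...] = (
    (0.0, 10.0, "IV"),
    (10.0, 50.0, "III"),
    (50.0, 300.0, "II"),
    (300.0, math.inf, "I"),
)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five up."""
    return int(math.floor(x + 0.5))


def _check_intensity(I: int) -> int:
    I = int(I)
    if not INTENSITY_MIN <= I <= INTENSITY_MAX:
        raise ValueError(
            f"intensity {I} outside the damaging range "
            f"[{INTENSITY_MIN}, {INTENSITY_MAX}]"
        )
    return I


class ExposureVector(dict):
    """Population exposure per intensity class, persons.

    A mapping ``{intensity class (5..11) -> persons >= 0}``; missing classes
    count as zero exposure.
    """

    def __init__(self, data: Mapping[int, float] | None = None):
        super().__init__()
        for klass in INTENSITY_CLASSES:
            self[klass] = 0.0
        if data:
            for klass, persons in data.items():
                klass = _check_intensity(klass)
                persons = float(persons)
                if persons < 0:
                    raise ValueError(f"negative exposure {persons} at intensity {klass}")
                self[klass] = persons

    def as_array(self) -> np.ndarray:
        """Persons per class as a length-7 array ordered V..XI."""
        return np.array([self[k] for k in INTENSITY_CLASSES], dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self.values()))

    def scaled(self, c: float) -> "ExposureVector":
        return ExposureVector({k: c * v for k, v in self.items()})


@dataclasses.dataclass(frozen=True)
class HDITable:
    """Human development index by calendar year.

    The HDI factor ``HDI(max_year) / HDI(event_year)`` scales historical
    fatality ratios up to account for weaker building resilience and social
    development in earlier eras.  Years between tabulated entries are
    linearly interpolated; years outside the coverage raise.
    """

    entries: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("HDI table is empty")
        for year, value in self.entries.items():
            if not 0.0 < value <= 1.0:
                raise ValueError(f"HDI({year})={value} outside (0, 1]")

    @property
    def max_year(self) -> int:
        return max(self.entries)

    @property
    def min_year(self) -> int:
        return min(self.entries)

    def value(self, year: int) -> float:
        if year in self.entries:
            return self.entries[year]
        if not self.min_year <= year <= self.max_year:
            raise ValueError(
                f"year {year} outside HDI table coverage "
                f"[{self.min_year}, {self.max_year}]"
            )
        years = sorted(self.entries)
        return float(np.interp(year, years, [self.entries[y] for y in years]))


@dataclasses.dataclass
class CatalogEvent:
    """One historical damaging earthquake: the unit of the fit.

    ``recorded_fatalities`` is the official death toll O_i; events with
    O_i = 0 are excluded from fitting because the log-ratio term of the
    objective is undefined there.
    """

    id: str
    region: str
    year: int
    exposure: ExposureVector
    recorded_fatalities: int
    magnitude: float | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region code {self.region!r}; expected one of {sorted(REGIONS)}")
        if self.recorded_fatalities < 0:
            raise ValueError("recorded fatalities must be non-negative")
        if not isinstance(self.exposure, ExposureVector):
            self.exposure = ExposureVector(self.exposure)


@dataclasses.dataclass
class FatalityModelParams:
    """Fitted model: per-region (beta, theta) and the pooled log residual zeta."""

    per_region: dict[str, tuple[float, float]]
    zeta: float
    fit_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        for code, (beta, theta) in self.per_region.items():
            if code not in REGIONS:
                raise ValueError(f"unknown region code {code!r}")
            if theta <= 0:
                warnings.warn(
                    f"region {code!r}: fitted theta={theta:.4g} <= 0; the fatality "
                    "ratio does not increase with intensity", stacklevel=2,
                )

    def to_dict(self) -> dict:
        return {
            "per_region": {c: {"beta": b, "theta": t} for c, (b, t) in self.per_region.items()},
            "zeta": self.zeta,
            "fit_meta": self.fit_meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FatalityModelParams":
        per_region = {c: (v["beta"], v["theta"]) for c, v in d["per_region"].items()}
        return cls(per_region=per_region, zeta=d["zeta"], fit_meta=dict(d.get("fit_meta", {})))


@dataclasses.dataclass
class FatalityEstimate:
    """The pipeline product: expectation, NEEP range probabilities, level."""

    expected: float
    range_probs: dict[str, float]
    level: str
    rounded: int

    def __post_init__(self) -> None:
        total = sum(self.range_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"range probabilities sum to {total}, not 1")


# ---------------------------------------------------------------------------
# ratio, expectation
# ---------------------------------------------------------------------------

def fatality_ratio(
    I: int, beta: float, theta: float, *, base: float = 10.0, clamp: bool = True
) -> float:
    """Fatality ratio r(I) = base**(beta + theta*I), clamped to at most 1.

    The ratio is deaths per exposed person, so values above 1 are clipped;
    the log-linear form makes it strictly increasing in intensity whenever
    ``theta > 0``.
    """
    I = _check_intensity(I)
    r = base ** (beta + theta * I)
    return min(r, 1.0) if clamp else r


def hdi_factor(table: HDITable, event_year: int) -> float:
    """HDI correction HDI(max_year) / HDI(event_year) for an event."""
    return table.value(table.max_year) / table.value(event_year)


def estimate_fatalities(
    exposure: ExposureVector | Mapping[int, float],
    region: str,
    event_year: int,
    params: FatalityModelParams,
    hdi: HDITable,
) -> float:
    """Expected fatalities E for one event.

    Sums the HDI-corrected fatality ratio times exposure over the damaging
    intensity classes V..XI using the region's fitted (beta, theta).
    Linear in exposure; zero when all exposure is zero.
    """
    if region not in params.per_region:
        raise KeyError(f"no fitted parameters for region {region!r}")
    if not isinstance(exposure, ExposureVector):
        exposure = ExposureVector(exposure)
    beta, theta = params.per_region[region]
    factor = hdi_factor(hdi, event_year)
    return float(
        sum(
            fatality_ratio(I, beta, theta) * factor * exposure[I]
            for I in INTENSITY_CLASSES
        )
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_objective(E: Sequence[float], O: Sequence[float]) -> float:
    """Fit objective: log mean squared error plus mean squared log ratio.

    Returns ``-inf`` for a perfect fit (every E_i equal to O_i): the first
    term's infimum.  Callers must pre-filter zero-fatality events; any
    non-positive E or O raises.
    """
    E = np.asarray(E, dtype=float)
    O = np.asarray(O, dtype=float)
    if E.shape != O.shape or E.ndim != 1 or E.size == 0:
        raise ValueError("E and O must be equal-length non-empty 1-D sequences")
    if np.any(O <= 0) or np.any(E <= 0):
        raise ValueError("fit objective requires strictly positive E and O")
    mse = float(np.mean((E - O) ** 2))
    log_term = float(np.mean(np.log(E / O) ** 2))
    if mse == 0.0:
        return -math.inf
    return math.log(mse) + log_term


def log_residual(E: Sequence[float], O: Sequence[float]) -> float:
    """RMS of ln(E_i / O_i): the lognormal scale zeta of the range model."""
    E = np.asarray(E, dtype=float)
    O = np.asarray(O, dtype=float)
    if E.size == 0 or E.shape != O.shape:
        raise ValueError("E and O must be equal-length non-empty sequences")
    if np.any(E <= 0) or np.any(O <= 0):
        raise ValueError("log residual requires strictly positive E and O")
    return float(np.sqrt(np.mean(np.log(E / O) ** 2)))


def _exposure_matrix(
    events: Sequence[CatalogEvent], hdi: HDITable
) -> tuple[np.ndarray, np.ndarray]:
    """HDI-weighted exposure matrix (N, 7) and recorded fatalities (N,)."""
    B = np.stack([ev.exposure.as_array() * hdi_factor(hdi, ev.year) for ev in events])
    O = np.array([ev.recorded_fatalities for ev in events], dtype=float)
    return B, O


def _objective_on_grid(
    B: np.ndarray, O: np.ndarray, betas: np.ndarray, thetas: np.ndarray
) -> np.ndarray:
    """Vectorized objective over a (beta, theta) grid -> (nb, nt) array."""
    I = np.array(INTENSITY_CLASSES, dtype=float)
    # ratios r[b, t, I] clamped to 1
    expo = betas[:, None, None] + thetas[None, :, None] * I[None, None, :]
    r = np.minimum(10.0 ** expo, 1.0)
    E = np.einsum("btk,nk->btn", r, B)
    diff2 = np.mean((E - O) ** 2, axis=-1)
    with np.errstate(divide="ignore"):
        first = np.where(diff2 > 0, np.log(diff2), -np.inf)
    second = np.mean(np.log(np.maximum(E, 1e-300) / O) ** 2, axis=-1)
    return first + second


def _events_objective(B: np.ndarray, O: np.ndarray, beta: float, theta: float) -> float:
    I = np.array(INTENSITY_CLASSES, dtype=float)
    r = np.minimum(10.0 ** (beta + theta * I), 1.0)
    E = B @ r
    if np.any(E <= 0):
        return math.inf
    return fit_objective(E, O)


def fit_params(
    catalog: Iterable[CatalogEvent],
    hdi: HDITable,
    region: str,
    *,
    beta_range: tuple[float, float] = (-20.0, 0.0),
    theta_range: tuple[float, float] = (0.0, 3.0),
    grid_step: float = 0.1,
    refine: bool = True,
) -> tuple[float, float, dict]:
    """Fit (beta, theta) for one region by minimizing the fit objective.

    Deterministic: a coarse grid search over ``beta_range`` x ``theta_range``
    at ``grid_step`` resolution followed by derivative-free Nelder-Mead
    refinement from the best grid cell.  Events with zero recorded
    fatalities or all-zero exposure are excluded (and counted in the
    diagnostics); at least two usable events are required.

    Returns
    -------
    (beta, theta, diagnostics)
        ``diagnostics`` holds the final objective value ``epsilon``, the
        number of events used and excluded, per-event ``log_ratios``
        ln(E_i/O_i), and a ``degenerate`` flag raised when the usable
        events expose only a single intensity class, leaving only the
        combination beta + theta*I identified.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region code {region!r}")
    events = [ev for ev in catalog if ev.region == region]
    usable = [
        ev for ev in events
        if ev.recorded_fatalities >= 1 and ev.exposure.total > 0
    ]
    n_excluded = len(events) - len(usable)
    if len(usable) < 2:
        raise ValueError(
            f"region {region!r} ({REGIONS[region]}): {len(usable)} usable "
            "event(s); at least 2 with recorded fatalities >= 1 and non-zero "
            "exposure are required"
        )
    B, O = _exposure_matrix(usable, hdi)

    active_classes = np.nonzero(B.sum(axis=0) > 0)[0]
    degenerate = active_classes.size < 2

    betas = np.arange(beta_range[0], beta_range[1] + grid_step / 2, grid_step)
    thetas = np.arange(theta_range[0], theta_range[1] + grid_step / 2, grid_step)
    eps_grid = _objective_on_grid(B, O, betas, thetas)
    ib, it = np.unravel_index(np.argmin(eps_grid), eps_grid.shape)
    beta, theta = float(betas[ib]), float(thetas[it])
    eps = float(eps_grid[ib, it])

    if refine and np.isfinite(eps):
        res = minimize(
            lambda p: _events_objective(B, O, p[0], p[1]),
            x0=[beta, theta],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.fun <= eps:
            beta, theta = float(res.x[0]), float(res.x[1])
            eps = float(res.fun)

    I = np.array(INTENSITY_CLASSES, dtype=float)
    E = B @ np.minimum(10.0 ** (beta + theta * I), 1.0)
    log_ratios = np.log(E / O)
    diagnostics = {
        "epsilon": eps,
        "n_events": len(usable),
        "n_excluded_zero_fatality_or_exposure": n_excluded,
        "log_ratios": log_ratios.tolist(),
        "degenerate": bool(degenerate),
        "region": region,
    }
    if degenerate:
        klass = INTENSITY_CLASSES[active_classes[0]] if active_classes.size else None
        diagnostics["identified_combination"] = (
            f"beta + {klass}*theta" if klass is not None else "none"
        )
        warnings.warn(
            f"region {region!r}: exposure spans a single intensity class; "
            "beta and theta are not separately identifiable", stacklevel=2,
        )
    return beta, theta, diagnostics


# ---------------------------------------------------------------------------
# lognormal range probabilities and NEEP levels
# ---------------------------------------------------------------------------

def range_probability(E: float, zeta: float, a: float, b: float) -> float:
    """P(a < fatalities <= b) under ln(fatalities) ~ Normal(ln E, zeta^2).

    ``a = 0`` and ``b = inf`` are the natural boundary cases (terms 0 and 1).
    """
    if not a < b:
        raise ValueError(f"range bounds must satisfy a < b, got a={a}, b={b}")
    if a < 0:
        raise ValueError("lower bound must be non-negative")
    if E <= 0 or zeta <= 0:
        raise ValueError("E and zeta must be positive")
    upper = 1.0 if math.isinf(b) else float(norm.cdf((math.log(b) - math.log(E)) / zeta))
    lower = 0.0 if a == 0 else float(norm.cdf((math.log(a) - math.log(E)) / zeta))
    return upper - lower


def level_probabilities(E: float, zeta: float) -> FatalityEstimate:
    """Probabilities over the four NEEP fatality ranges and the response level.

    The level is the range with the highest probability (first in
    mildest-to-severest order on exact ties), mapped IV/III/II/I.
    """
    if E <= 0 or zeta <= 0:
        raise ValueError("E and zeta must be positive")
    probs: dict[str, float] = {}
    labels = []
    for a, b, level in NEEP_RANGES:
        key = f"({a:g},{b:g}]" if math.isfinite(b) else f"({a:g},inf)"
        probs[key] = range_probability(E, zeta, a, b)
        labels.append(level)
    values = np.array(list(probs.values()))
    # renormalize the tiny truncation slack so the partition sums to 1 exactly
    values = values / values.sum()
    probs = dict(zip(probs.keys(), values.tolist()))
    level = labels[int(np.argmax(values))]
    return FatalityEstimate(
        expected=float(E),
        range_probs=probs,
        level=level,
        rounded=round_half_up(E),
    )
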