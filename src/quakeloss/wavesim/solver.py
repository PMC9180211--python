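"""Desk-scale 3-D elastic velocity-stress finite-difference solver.

RK4 time marching with alternating forward/backward biased MacCormack-type
spatial operators on a collocated grid, a traction-image free surface, an
exponential-damping absorbing sponge on the sides and bottom, and point or
finite-fault moment-tensor (or body-force) sources.  Outputs surface
velocity histories, receiver seismograms and peak ground velocity.

Axes: x = north, y = east, z = down (depth); the free surface is z = 0.
All quantities are SI (m, s, kg, Pa, N·m).

Alternation schedule: the bias direction of the spatial operators along
axis q in stage s of step n is forward iff (s + n + q) is even — swapped
every stage and cycled per axis per step, which cancels the one-sided
truncation asymmetry over the march (the MacCormack construction).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import kernels
from .kernels import G
from .stencil import StencilCoefficients

__all__ = [
    "MaterialModel",
    "SimGrid",
    "BoundaryConfig",
    "SourceTimeFunction",
    "PointSource",
    "FiniteFaultSource",
    "moment_tensor_from_sdr",
    "read_fault_table",
    "Simulation",
    "SurfaceRecord",
    "build_simulation",
    "rk4_step",
    "run",
    "apply_free_surface",
    "extract_pgv",
    "elastic_energy",
]


# ---------------------------------------------------------------------------
# material and grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MaterialModel:
    """Cellwise density and Lamé constants on the interior grid."""

    rho: np.ndarray
    lam: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.ascontiguousarray(self.rho, dtype=np.float64)
        self.lam = np.ascontiguousarray(self.lam, dtype=np.float64)
        self.mu = np.ascontiguousarray(self.mu, dtype=np.float64)
        if not (self.rho.shape == self.lam.shape == self.mu.shape):
            raise ValueError("rho, lambda, mu must share a shape")
        if np.any(self.rho <= 0):
            raise ValueError("density must be positive")
        if np.any(self.mu < 0):
            raise ValueError("mu must be non-negative")
        if np.any(self.lam + 2 * self.mu <= 0):
            raise ValueError("lambda + 2*mu must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rho.shape

    @property
    def vp(self) -> np.ndarray:
        return np.sqrt((self.lam + 2 * self.mu) / self.rho)

    @property
    def vs(self) -> np.ndarray:
        return np.sqrt(self.mu / self.rho)

    @property
    def vp_max(self) -> float:
        return float(self.vp.max())

    @classmethod
    def from_velocities(cls, vp, vs, rho) -> "MaterialModel":
        vp = np.asarray(vp, dtype=float)
        vs = np.asarray(vs, dtype=float)
        rho = np.asarray(rho, dtype=float)
        mu = rho * vs**2
        lam = rho * vp**2 - 2 * mu
        return cls(rho=rho, lam=lam, mu=mu)

    @classmethod
    def homogeneous(cls, shape, vp=6000.0, vs=3464.0, rho=2700.0) -> "MaterialModel":
        ones = np.ones(shape)
        return cls.from_velocities(vp * ones, vs * ones, rho * ones)

    @classmethod
    def layered(
        cls, shape, dx: float,
        depths: Sequence[float], vp: Sequence[float],
        vs: Sequence[float], rho: Sequence[float],
    ) -> "MaterialModel":
        """Horizontally layered model; ``depths`` are layer-top depths (m),
        the first must be 0."""
        if len(depths) != len(vp) or len(vp) != len(vs) or len(vs) != len(rho):
            raise ValueError("layer arrays must have equal length")
        if depths[0] != 0:
            raise ValueError("first layer top must be depth 0")
        nz = shape[2]
        z = (np.arange(nz) + 0.5) * dx
        idx = np.searchsorted(np.asarray(depths), z, side="right") - 1
        vp3 = np.broadcast_to(np.asarray(vp)[idx], shape).copy()
        vs3 = np.broadcast_to(np.asarray(vs)[idx], shape).copy()
        rho3 = np.broadcast_to(np.asarray(rho)[idx], shape).copy()
        return cls.from_velocities(vp3, vs3, rho3)


@dataclasses.dataclass
class SimGrid:
    """Uniform computational grid: nx x ny x nz cells of spacing dx, nt
    steps of dt.  ``dt=None`` picks the largest stable step from the CFL
    number and the material's maximum P speed at build time."""

    nx: int
    ny: int
    nz: int
    dx: float
    nt: int
    dt: float | None = None
    cfl: float = 0.4

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 5:
            raise ValueError("each grid dimension must be at least the stencil width (5)")
        if self.dx <= 0 or self.nt < 1:
            raise ValueError("dx must be positive and nt >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)


@dataclasses.dataclass
class BoundaryConfig:
    """Boundary treatment.

    ``free_surface`` puts a traction-image free surface at z=0; otherwise
    the top is absorbing like the other faces.  ``periodic`` wraps all axes
    (used for plane-wave and energy verification runs) and is mutually
    exclusive with the free surface and sponge.
    """

    free_surface: bool = True
    periodic: bool = False
    sponge_width: int = 12
    sponge_alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.periodic and self.free_surface:
            raise ValueError("periodic boundaries exclude a free surface")


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SourceTimeFunction:
    """Moment-rate pulse.

    ``gaussian`` (default): unit-integral Gaussian moment-rate of corner
    frequency f0, so the injected stress glut integrates to the full moment
    tensor.  ``ricker``: zero-integral Ricker wavelet of peak amplitude 1
    (useful for band-limited tests; carries no static moment).
    ``t0`` defaults to 1.2/f0 so the pulse starts smoothly from zero.
    """

    kind: str = "gaussian"
    f0: float = 1.0
    t0: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"gaussian", "ricker"}:
            raise ValueError("source-time function must be 'gaussian' or 'ricker'")
        if self.f0 <= 0:
            raise ValueError("corner frequency must be positive")

    @property
    def delay(self) -> float:
        return self.t0 if self.t0 is not None else 1.2 / self.f0

    def rate(self, t: np.ndarray | float) -> np.ndarray | float:
        tau = np.asarray(t, dtype=float) - self.delay
        arg = (math.pi * self.f0) ** 2 * tau**2
        if self.kind == "gaussian":
            return math.sqrt(math.pi) * self.f0 * np.exp(-arg)
        return (1.0 - 2.0 * arg) * np.exp(-arg)


@dataclasses.dataclass
class PointSource:
    """Point moment-tensor and/or body-force source.

    ``moment`` is (Mxx, Myy, Mzz, Mxy, Mxz, Myz) in N·m; ``force`` is
    (Fx, Fy, Fz) in N.  Position is metres from the grid origin (x north,
    y east, z down).  ``onset`` shifts the source-time function.
    """

    x: float
    y: float
    z: float
    moment: tuple[float, ...] | None = None
    force: tuple[float, float, float] | None = None
    stf: SourceTimeFunction = dataclasses.field(default_factory=SourceTimeFunction)
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.moment is None and self.force is None:
            raise ValueError("source needs a moment tensor or a force vector")
        if self.moment is not None and len(self.moment) != 6:
            raise ValueError("moment must be (Mxx, Myy, Mzz, Mxy, Mxz, Myz)")


@dataclasses.dataclass
class FiniteFaultSource:
    """A kinematic finite fault: a list of subfault point sources."""

    subfaults: list[PointSource]

    def __post_init__(self) -> None:
        if not self.subfaults:
            raise ValueError("finite fault needs at least one subfault")


def moment_tensor_from_sdr(
    strike_deg: float, dip_deg: float, rake_deg: float, m0: float
) -> tuple[float, float, float, float, float, float]:
    """Double-couple moment tensor (x north, y east, z down convention)."""
    ps = math.radians(strike_deg)
    d = math.radians(dip_deg)
    r = math.radians(rake_deg)
    mxx = -m0 * (math.sin(d) * math.cos(r) * math.sin(2 * ps)
                 + math.sin(2 * d) * math.sin(r) * math.sin(ps) ** 2)
    mxy = m0 * (math.sin(d) * math.cos(r) * math.cos(2 * ps)
                + 0.5 * math.sin(2 * d) * math.sin(r) * math.sin(2 * ps))
    mxz = -m0 * (math.cos(d) * math.cos(r) * math.cos(ps)
                 + math.cos(2 * d) * math.sin(r) * math.sin(ps))
    myy = m0 * (math.sin(d) * math.cos(r) * math.sin(2 * ps)
                - math.sin(2 * d) * math.sin(r) * math.cos(ps) ** 2)
    myz = -m0 * (math.cos(d) * math.cos(r) * math.sin(ps)
                 - math.cos(2 * d) * math.sin(r) * math.cos(ps))
    mzz = m0 * math.sin(2 * d) * math.sin(r)
    return (mxx, myy, mzz, mxy, mxz, myz)


def read_fault_table(path: str | Path) -> FiniteFaultSource:
    """Read a plain-text subfault table into a finite-fault source.

    Whitespace-separated columns with a header line.  Required: ``x_m y_m
    depth_m strike_deg dip_deg rake_deg onset_s f0_hz`` plus either
    ``moment_nm`` or the triple ``slip_m area_m2 mu_pa`` (then
    M0 = mu * slip * area).
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    subs = []
    for _, row in df.iterrows():
        if "moment_nm" in df.columns:
            m0 = float(row["moment_nm"])
        else:
            m0 = float(row["mu_pa"]) * float(row["slip_m"]) * float(row["area_m2"])
        moment = moment_tensor_from_sdr(
            row["strike_deg"], row["dip_deg"], row["rake_deg"], m0
        )
        subs.append(
            PointSource(
                x=float(row["x_m"]), y=float(row["y_m"]), z=float(row["depth_m"]),
                moment=moment,
                stf=SourceTimeFunction(f0=float(row["f0_hz"])),
                onset=float(row["onset_s"]),
            )
        )
    return FiniteFaultSource(subs)


# ---------------------------------------------------------------------------
# boundary handling
# ---------------------------------------------------------------------------

_TRACTION = (5, 7, 8)  # szz, sxz, syz vanish on the free surface


def apply_free_surface(U: np.ndarray) -> np.ndarray:
    """Traction-image free surface at the top interior layer (k = G).

    Traction stresses are zeroed on the surface and mirrored with opposite
    sign into the ghost layers above it; all other components are mirrored
    symmetrically.  Operates in place and returns U.
    """
    for c in range(9):
        if c in _TRACTION:
            U[c, :, :, G] = 0.0
            for m in range(1, G + 1):
                U[c, :, :, G - m] = -U[c, :, :, G + m]
        else:
            for m in range(1, G + 1):
                U[c, :, :, G - m] = U[c, :, :, G + m]
    return U


def _fill_ghosts(U: np.ndarray, shape, boundary: BoundaryConfig) -> None:
    nx, ny, nz = shape
    if boundary.periodic:
        U[:, :G] = U[:, nx:nx + G]
        U[:, nx + G:] = U[:, G:2 * G]
        U[:, :, :G] = U[:, :, ny:ny + G]
        U[:, :, ny + G:] = U[:, :, G:2 * G]
        U[:, :, :, :G] = U[:, :, :, nz:nz + G]
        U[:, :, :, nz + G:] = U[:, :, :, G:2 * G]
        return
    U[:, :G] = 0.0
    U[:, nx + G:] = 0.0
    U[:, :, :G] = 0.0
    U[:, :, ny + G:] = 0.0
    U[:, :, :, nz + G:] = 0.0
    if boundary.free_surface:
        apply_free_surface(U)
    else:
        U[:, :, :, :G] = 0.0


def _sponge_weights(shape, boundary: BoundaryConfig) -> np.ndarray:
    """Cerjan-style exponential damping weights on absorbing faces."""
    nx, ny, nz = shape
    w = boundary.sponge_width
    alpha = boundary.sponge_alpha

    def profile(n: int, damp_lo: bool, damp_hi: bool) -> np.ndarray:
        g = np.ones(n)
        for d in range(min(w, n)):
            factor = math.exp(-((alpha * (w - d)) ** 2))
            if damp_lo:
                g[d] = min(g[d], factor)
            if damp_hi:
                g[n - 1 - d] = min(g[n - 1 - d], factor)
        return g

    gx = profile(nx, True, True)
    gy = profile(ny, True, True)
    gz = profile(nz, not boundary.free_surface, True)
    return gx[:, None, None] * gy[None, :, None] * gz[None, None, :]


# ---------------------------------------------------------------------------
# simulation handle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurfaceRecord:
    """Solver output: PGV and receiver velocity histories on/inside the grid."""

    pgv: np.ndarray                  # (nx, ny) max over time of component norm
    times: np.ndarray                # (nsamples,)
    receivers: np.ndarray            # (nsamples, nrec, 3) velocities
    receiver_nodes: list[tuple[int, int, int]]
    dx: float
    dt: float
    pgv_components: str
    snapshots: np.ndarray | None = None  # optional (nsnap, 3, nx, ny)
    snapshot_times: np.ndarray | None = None


class Simulation:
    """Allocated state plus the march; create with :func:`build_simulation`."""

    def __init__(
        self,
        material: MaterialModel,
        grid: SimGrid,
        source: PointSource | FiniteFaultSource,
        boundary: BoundaryConfig,
        coeffs: StencilCoefficients,
        elevation: np.ndarray | None,
        receivers: Sequence[tuple[float, float, float]],
        pgv_components: str,
        snapshot_every: int,
    ):
        self.material = material
        self.grid = grid
        self.boundary = boundary
        self.coeffs = coeffs
        self.pgv_components = pgv_components
        self.snapshot_every = snapshot_every
        shape = grid.shape

        # CFL
        vpmax = material.vp_max
        dt_max = grid.cfl * grid.dx / vpmax
        if grid.dt is None:
            grid.dt = dt_max
        elif grid.dt > dt_max * (1 + 1e-12):
            raise ValueError(
                f"dt={grid.dt:g} violates the CFL condition; "
                f"maximum stable dt = {dt_max:g} s (CFL {grid.cfl}, "
                f"dx {grid.dx} m, vp_max {vpmax:g} m/s)"
            )
        self.dt = grid.dt

        # terrain-following vertical stretch (gentle-slope approximation)
        if elevation is not None:
            elevation = np.asarray(elevation, dtype=float)
            if elevation.shape != (grid.nx, grid.ny):
                raise ValueError("elevation grid must be (nx, ny)")
            depth = grid.nz * grid.dx
            thickness = depth + (elevation - elevation.min())
            self.zfac = np.ascontiguousarray(depth / thickness)
        else:
            self.zfac = np.ones((grid.nx, grid.ny))

        # sources
        subs = source.subfaults if isinstance(source, FiniteFaultSource) else [source]
        self.sources = subs
        self.src_nodes = []
        for s in subs:
            node = (round(s.x / grid.dx), round(s.y / grid.dx), round(s.z / grid.dx))
            if not all(0 <= node[q] < shape[q] for q in range(3)):
                raise ValueError(
                    f"source at ({s.x}, {s.y}, {s.z}) m maps to node {node}, "
                    f"outside the {shape} grid"
                )
            self.src_nodes.append(node)

        self.rec_nodes = []
        for rx, ry, rz in receivers:
            node = (round(rx / grid.dx), round(ry / grid.dx), round(rz / grid.dx))
            if not all(0 <= node[q] < shape[q] for q in range(3)):
                raise ValueError(f"receiver at ({rx}, {ry}, {rz}) m outside grid")
            self.rec_nodes.append(node)

        full = (9, grid.nx + 2 * G, grid.ny + 2 * G, grid.nz + 2 * G)
        self.U = np.zeros(full)
        # zeros, not empty: the RHS kernel writes interior nodes only, and
        # stage ghosts must never fold heap garbage into the state
        self._k = np.zeros(full)
        self._acc = np.zeros(full)
        self._Ustage = np.zeros(full)
        self.sponge = None if boundary.periodic else _sponge_weights(shape, boundary)
        self.step_index = 0
        self.pgv = np.zeros((grid.nx, grid.ny))
        self.rec_hist: list[np.ndarray] = []
        self.snapshots: list[np.ndarray] = []
        self.snapshot_times: list[float] = []
        self.cell_volume = grid.dx**3

    # -- helpers ----------------------------------------------------------

    def _inject(self, dU: np.ndarray, t: float) -> None:
        inv_v = 1.0 / self.cell_volume
        for s, (si, sj, sk) in zip(self.sources, self.src_nodes):
            rate = float(s.stf.rate(t - s.onset))
            if rate == 0.0:
                continue
            ii, jj, kk = si + G, sj + G, sk + G
            if s.moment is not None:
                for c, m in zip((3, 4, 5, 6, 7, 8), s.moment):
                    dU[c, ii, jj, kk] += m * rate * inv_v
            if s.force is not None:
                rho = self.material.rho[si, sj, sk]
                for c, f in zip((0, 1, 2), s.force):
                    dU[c, ii, jj, kk] += f * rate / (rho * self.cell_volume)

    def _rhs(self, U: np.ndarray, stage: int, t: float) -> np.ndarray:
        _fill_ghosts(U, self.grid.shape, self.boundary)
        n = self.step_index
        fx = (stage + n) % 2 == 0
        fy = (stage + n + 1) % 2 == 0
        fz = (stage + n + 2) % 2 == 0
        kernels.rhs(
            U, self.material.rho, self.material.lam, self.material.mu,
            self.coeffs.a, 1.0 / self.grid.dx, self.zfac, fx, fy, fz, self._k,
        )
        self._inject(self._k, t)
        return self._k

    def _record(self) -> None:
        surf = self.U[:3, G:-G, G:-G, G]
        if self.pgv_components == "horizontal":
            speed = np.hypot(surf[0], surf[1])
        elif self.pgv_components == "3c":
            speed = np.sqrt(surf[0] ** 2 + surf[1] ** 2 + surf[2] ** 2)
        else:  # per-component max
            speed = np.abs(surf).max(axis=0)
        np.maximum(self.pgv, speed, out=self.pgv)
        if self.rec_nodes:
            vals = np.array(
                [[self.U[c, i + G, j + G, k + G] for c in range(3)]
                 for (i, j, k) in self.rec_nodes]
            )
            self.rec_hist.append(vals)
        else:
            self.rec_hist.append(np.zeros((0, 3)))
        if self.snapshot_every and self.step_index % self.snapshot_every == 0:
            self.snapshots.append(surf.copy())
            self.snapshot_times.append(self.step_index * self.dt)


def build_simulation(
    material: MaterialModel,
    grid: SimGrid,
    source: PointSource | FiniteFaultSource,
    boundary: BoundaryConfig | None = None,
    coeffs: StencilCoefficients | None = None,
    elevation: np.ndarray | None = None,
    receivers: Sequence[tuple[float, float, float]] = (),
    pgv_components: str = "horizontal",
    snapshot_every: int = 0,
) -> Simulation:
    """Validate inputs, allocate state, and discretize sources to nodes."""
    if material.shape != grid.shape:
        raise ValueError(
            f"material shape {material.shape} does not match grid {grid.shape}"
        )
    if pgv_components not in {"horizontal", "3c", "per_component"}:
        raise ValueError("pgv_components must be horizontal, 3c or per_component")
    return Simulation(
        material, grid, source,
        boundary or BoundaryConfig(),
        coeffs or StencilCoefficients(dx=grid.dx),
        elevation, receivers, pgv_components, snapshot_every,
    )


def rk4_step(sim: Simulation) -> None:
    """Advance the state one step with classical RK4.

    The bias-direction schedule rotates per stage and per step (module
    docstring); NaN/Inf in the state aborts with the step index.
    """
    U, dt = sim.U, sim.dt
    t = sim.step_index * dt
    k1 = sim._rhs(U, 0, t)
    np.copyto(sim._acc, k1)
    np.multiply(k1, dt / 2, out=sim._Ustage)
    sim._Ustage += U

    k2 = sim._rhs(sim._Ustage, 1, t + dt / 2)
    sim._acc += 2 * k2
    np.multiply(k2, dt / 2, out=sim._Ustage)
    sim._Ustage += U

    k3 = sim._rhs(sim._Ustage, 2, t + dt / 2)
    sim._acc += 2 * k3
    np.multiply(k3, dt, out=sim._Ustage)
    sim._Ustage += U

    k4 = sim._rhs(sim._Ustage, 3, t + dt)
    sim._acc += k4

    U += (dt / 6) * sim._acc
    if sim.sponge is not None:
        kernels.apply_sponge(U, sim.sponge)
    sim.step_index += 1
    center = U[:, G + sim.grid.nx // 2, G + sim.grid.ny // 2, G + sim.grid.nz // 2]
    if not np.all(np.isfinite(center)):
        raise FloatingPointError(
            f"instability: non-finite field at step {sim.step_index}"
        )


def run(sim: Simulation) -> SurfaceRecord:
    """March nt steps and return PGV plus receiver histories."""
    sim._record()
    for _ in range(sim.grid.nt):
        rk4_step(sim)
        sim._record()
    if not np.all(np.isfinite(sim.U)):
        raise FloatingPointError(
            f"instability: non-finite field after step {sim.step_index}"
        )
    times = np.arange(sim.step_index + 1) * sim.dt
    return SurfaceRecord(
        pgv=sim.pgv.copy(),
        times=times,
        receivers=np.array(sim.rec_hist),
        receiver_nodes=list(sim.rec_nodes),
        dx=sim.grid.dx,
        dt=sim.dt,
        pgv_components=sim.pgv_components,
        snapshots=np.array(sim.snapshots) if sim.snapshots else None,
        snapshot_times=np.array(sim.snapshot_times) if sim.snapshot_times else None,
    )


def extract_pgv(record: SurfaceRecord) -> np.ndarray:
    """Peak ground velocity array (m/s) from a finished run."""
    if record.pgv.size == 0:
        raise ValueError("empty record")
    return record.pgv


def elastic_energy(sim: Simulation) -> float:
    """Total kinetic plus strain energy in the interior (J); needs mu > 0."""
    g = slice(G, -G)
    v = sim.U[:3, g, g, g]
    s = sim.U[3:, g, g, g]
    rho, lam, mu = sim.material.rho, sim.material.lam, sim.material.mu
    if np.any(mu <= 0):
        raise ValueError("energy helper requires mu > 0 everywhere")
    kinetic = 0.5 * rho * (v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    ss = s[0] ** 2 + s[1] ** 2 + s[2] ** 2 + 2 * (s[3] ** 2 + s[4] ** 2 + s[5] ** 2)
    tr = s[0] + s[1] + s[2]
    strain = (ss - lam / (3 * lam + 2 * mu) * tr**2) / (4 * mu)
    return float((kinetic + strain).sum() * sim.cell_volume)
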