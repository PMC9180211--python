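"""Tests for the elastic finite-difference solver.

The expensive physics benchmarks (plane-wave speeds, ray travel times,
radiation pattern) come from session fixtures; the tests here assert their
documented tolerances and exercise the solver building blocks on small
grids.
"""

import numpy as np
import pytest

from quakeloss.wavesim import (
    BoundaryConfig,
    FiniteFaultSource,
    MaterialModel,
    PointSource,
    SimGrid,
    SourceTimeFunction,
    StencilCoefficients,
    apply_free_surface,
    build_simulation,
    moment_tensor_from_sdr,
    read_fault_table,
    rk4_step,
    run,
    spatial_derivative,
)
from quakeloss.wavesim.kernels import G
from quakeloss.wavesim.verification import plane_wave_speed, xcorr_lag

VP, VS, RHO = 6000.0, 3464.0, 2700.0


# ---------------------------------------------------------------------------
# stencil
# ---------------------------------------------------------------------------

def test_default_coefficients_satisfy_exactness_invariants():
    c = StencilCoefficients()
    assert abs(c.a.sum()) < 1e-14
    assert float(np.arange(-1, 4) @ c.a) == pytest.approx(1.0)
    assert c.order == 4


@pytest.mark.parametrize(
    "bad",
    [np.ones(5), np.array([0.0, -1.0, 1.0, 0.0, 0.1])],
)
def test_invalid_coefficients_rejected(bad):
    with pytest.raises(ValueError):
        StencilCoefficients(a=bad)


def test_derivative_annihilates_constants():
    f = np.full((12, 8, 8), 3.7)
    for direction in ("forward", "backward"):
        d = spatial_derivative(f, 0, direction)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)


def test_derivative_exact_on_linear_ramp():
    x = np.arange(16, dtype=float)
    f = np.broadcast_to(2.5 * x[:, None], (16, 6)).copy()
    d = spatial_derivative(f, 0, "forward", StencilCoefficients(dx=1.0))
    np.testing.assert_allclose(d[4:-4], 2.5, rtol=1e-12)


def test_derivative_exact_on_cubic():
    x = np.arange(20, dtype=float)
    f = x**3 - 2 * x**2 + 4 * x
    expected = 3 * x**2 - 4 * x + 4
    for direction in ("forward", "backward"):
        d = spatial_derivative(f, 0, direction)
        np.testing.assert_allclose(d[4:-4], expected[4:-4], rtol=1e-10)


def test_backward_is_mirrored_negated_forward():
    # L^B(f) = -reverse(L^F(reverse(f))): the mirrored-negated forward operator
    rng = np.random.default_rng(0)
    f = rng.normal(size=30)
    fwd = spatial_derivative(f[::-1], 0, "forward")[::-1]
    bwd = spatial_derivative(f, 0, "backward")
    np.testing.assert_allclose(bwd[4:-4], -fwd[4:-4], rtol=1e-12)


def test_derivative_rejects_bad_axis_and_direction():
    f = np.zeros((8, 8))
    with pytest.raises(ValueError):
        spatial_derivative(f, 2, "forward")
    with pytest.raises(ValueError):
        spatial_derivative(f, 0, "sideways")


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def small_setup(n=24, nt=10, dt=None, cfl=0.4, depth_cells=12):
    mat = MaterialModel.homogeneous((n, n, n), VP, VS, RHO)
    grid = SimGrid(n, n, n, 200.0, nt=nt, dt=dt, cfl=cfl)
    src = PointSource(
        n // 2 * 200.0, n // 2 * 200.0, depth_cells * 200.0,
        moment=(1e14, 1e14, 1e14, 0, 0, 0), stf=SourceTimeFunction(f0=2.0),
    )
    return mat, grid, src


def test_build_echoes_duration_and_sets_cfl_dt():
    mat, grid, src = small_setup(nt=25)
    sim = build_simulation(mat, grid, src)
    assert sim.dt == pytest.approx(0.4 * 200.0 / VP)
    assert grid.nt * sim.dt == pytest.approx(25 * 0.4 * 200.0 / VP)


def test_build_rejects_unstable_dt_and_names_limit():
    mat, grid, src = small_setup(dt=1.0)
    with pytest.raises(ValueError, match="maximum stable dt"):
        build_simulation(mat, grid, src)


def test_build_rejects_source_outside_grid():
    mat, grid, _ = small_setup()
    outside = PointSource(1e9, 0.0, 0.0, moment=(1e14,) * 3 + (0, 0, 0))
    with pytest.raises(ValueError, match="outside"):
        build_simulation(mat, grid, outside)


def test_material_validation():
    with pytest.raises(ValueError, match="density"):
        MaterialModel(rho=np.zeros((5, 5, 5)), lam=np.ones((5, 5, 5)),
                      mu=np.ones((5, 5, 5)))


# ---------------------------------------------------------------------------
# marching
# ---------------------------------------------------------------------------

def test_zero_state_zero_source_is_fixed_point():
    mat, grid, _ = small_setup(n=16, nt=5)
    silent = PointSource(1600.0, 1600.0, 1600.0, moment=(0.0,) * 6)
    sim = build_simulation(mat, grid, silent)
    for _ in range(5):
        rk4_step(sim)
    assert np.all(sim.U == 0.0)


def test_free_surface_traction_zero_and_ghost_antisymmetry():
    rng = np.random.default_rng(1)
    U = rng.normal(size=(9, 12, 12, 12))
    apply_free_surface(U)
    for c in (5, 7, 8):  # szz, sxz, syz
        np.testing.assert_array_equal(U[c, :, :, G], 0.0)
        for m in range(1, G + 1):
            np.testing.assert_array_equal(U[c, :, :, G - m], -U[c, :, :, G + m])
    for c in (0, 1, 2, 3, 4, 6):
        for m in range(1, G + 1):
            np.testing.assert_array_equal(U[c, :, :, G - m], U[c, :, :, G + m])


def test_surface_traction_vanishes_during_run():
    mat, grid, src = small_setup(n=24, nt=30, depth_cells=6)
    sim = build_simulation(mat, grid, src)
    for _ in range(30):
        rk4_step(sim)
    from quakeloss.wavesim.solver import _fill_ghosts
    _fill_ghosts(sim.U, grid.shape, sim.boundary)
    for c in (5, 7, 8):
        np.testing.assert_array_equal(sim.U[c, :, :, G], 0.0)


def test_shallow_source_amplitude_decays_with_depth():
    """Surface-guided motion: peak amplitude decreases into the half-space."""
    n, dx = 56, 200.0
    mat = MaterialModel.homogeneous((n, n, 36), VP, VS, RHO)
    grid = SimGrid(n, n, 36, dx, nt=140, cfl=0.4)
    cx = n // 2 * dx
    src = PointSource(cx, cx, 3 * dx, moment=(0, 0, 0, 1e15, 0, 0),
                      stf=SourceTimeFunction(f0=1.5))
    offset = 16 * dx
    depths = [0, 4, 8, 14]
    recs = [(cx + offset, cx, d * dx) for d in depths]
    sim = build_simulation(mat, grid, src, receivers=recs)
    rec = run(sim)
    peak = [np.abs(rec.receivers[:, i, :]).max() for i in range(len(depths))]
    assert peak[0] > peak[1] > peak[2] > peak[3]


def test_doubling_moment_doubles_velocities():
    mat, grid, src = small_setup(n=24, nt=40, depth_cells=8)
    recs = [(2000.0, 2400.0, 0.0)]
    r1 = run(build_simulation(mat, grid, src, receivers=recs))
    double = PointSource(src.x, src.y, src.z,
                         moment=tuple(2 * m for m in src.moment), stf=src.stf)
    mat2, grid2, _ = small_setup(n=24, nt=40)
    r2 = run(build_simulation(mat2, grid2, double, receivers=recs))
    np.testing.assert_allclose(r2.receivers, 2 * r1.receivers, rtol=1e-12, atol=1e-300)
    np.testing.assert_allclose(r2.pgv, 2 * r1.pgv, rtol=1e-12)


def test_superposition_of_sources():
    recs = [(2600.0, 2000.0, 0.0)]
    srcs = [
        PointSource(2000.0, 2000.0, 1600.0, moment=(1e14, 0, 0, 5e13, 0, 0),
                    stf=SourceTimeFunction(f0=2.0)),
        PointSource(2800.0, 2400.0, 2000.0, moment=(0, 0, 1e14, 0, 0, 7e13),
                    stf=SourceTimeFunction(f0=1.5), onset=0.1),
    ]
    outs = []
    for source in [srcs[0], srcs[1], FiniteFaultSource(list(srcs))]:
        mat, grid, _ = small_setup(n=24, nt=40)
        outs.append(run(build_simulation(mat, grid, source, receivers=recs)).receivers)
    combined = outs[2]
    summed = outs[0] + outs[1]
    scale = np.abs(summed).max()
    np.testing.assert_allclose(combined, summed, atol=1e-10 * scale)


def test_single_subfault_equals_point_source():
    mat, grid, src = small_setup(n=20, nt=30, depth_cells=8)
    recs = [(1600.0, 2000.0, 0.0)]
    r_point = run(build_simulation(mat, grid, src, receivers=recs))
    mat2, grid2, _ = small_setup(n=20, nt=30)
    r_fault = run(
        build_simulation(mat2, grid2, FiniteFaultSource([src]), receivers=recs)
    )
    np.testing.assert_allclose(r_fault.receivers, r_point.receivers, rtol=1e-12)


def test_reciprocity_force_swap():
    """Swapping a vertical point force and receiver reproduces the vertical
    waveform within 2% RMS on a homogeneous model."""
    n, dx = 40, 200.0
    A = (14 * dx, 20 * dx, 18 * dx)
    B = (26 * dx, 22 * dx, 24 * dx)
    traces = []
    for pos, rec in [(A, B), (B, A)]:
        mat = MaterialModel.homogeneous((n, n, n), VP, VS, RHO)
        grid = SimGrid(n, n, n, dx, nt=70, cfl=0.4)
        src = PointSource(*pos, force=(0.0, 0.0, 1e10),
                          stf=SourceTimeFunction(f0=2.0))
        sim = build_simulation(mat, grid, src,
                               BoundaryConfig(free_surface=False), receivers=[rec])
        traces.append(run(sim).receivers[:, 0, 2])
    misfit = np.linalg.norm(traces[0] - traces[1]) / np.linalg.norm(traces[0])
    assert misfit <= 0.02


def test_waveform_misfit_decreases_with_resolution():
    """Halving dx at fixed physics reduces the misfit vs the analytic
    translated pulse, monotonically."""
    errors = []
    for nx, dx in [(120, 200.0), (240, 100.0), (480, 50.0)]:
        out = plane_wave_speed("P", points_per_wavelength=int(2000.0 / dx),
                               nx=nx, dx=dx)
        x = out["x"]
        sigma = 1000.0  # fixed physical pulse width
        analytic = np.exp(-((x - out["expected_shift_m"]) ** 2) / (2 * sigma**2))
        err = np.linalg.norm(out["final_profile"] - analytic) / np.linalg.norm(analytic)
        errors.append(err)
    assert errors[0] > errors[1] > errors[2]


# ---------------------------------------------------------------------------
# physics benchmarks (session fixtures)
# ---------------------------------------------------------------------------

def test_plane_p_wave_speed_within_one_percent(plane_p):
    assert plane_p["rel_error"] <= 0.01


def test_plane_s_wave_speed_within_one_percent(plane_s):
    assert plane_s["rel_error"] <= 0.01


def test_energy_conserved_in_lossless_interior(plane_p, plane_s):
    assert plane_p["energy_drift"] <= 0.01
    assert plane_s["energy_drift"] <= 0.01


def test_first_arrival_matches_ray_time_homogeneous(tt_homog):
    assert tt_homog["error"] <= tt_homog["tolerance"]


def test_first_arrival_matches_ray_time_two_layer(tt_layer):
    assert tt_layer["error"] <= tt_layer["tolerance"]


def test_strike_slip_radiation_is_four_lobed(radiation):
    assert radiation["n_lobes"] == 4
    assert radiation["nodal_ratio"] < 0.10


# ---------------------------------------------------------------------------
# PGV and sources
# ---------------------------------------------------------------------------

def test_pgv_zero_for_silent_run():
    mat, grid, _ = small_setup(n=16, nt=5)
    silent = PointSource(1600.0, 1600.0, 1600.0, moment=(0.0,) * 6)
    rec = run(build_simulation(mat, grid, silent))
    assert np.all(rec.pgv == 0.0)


def test_pgv_is_max_horizontal_speed():
    mat, grid, _ = small_setup(n=16, nt=5)
    silent = PointSource(1600.0, 1600.0, 1600.0, moment=(0.0,) * 6)
    sim = build_simulation(mat, grid, silent)
    sim.U[0, G:-G, G:-G, G] = 3.0   # vx on the surface layer
    sim.U[1, G:-G, G:-G, G] = 4.0   # vy
    sim._record()
    np.testing.assert_allclose(sim.pgv, 5.0)


def test_moment_tensor_pure_strike_slip():
    m = moment_tensor_from_sdr(0.0, 90.0, 0.0, 1e15)
    np.testing.assert_allclose(m, (0, 0, 0, 1e15, 0, 0), atol=1e-1)


def test_fault_table_reading(tmp_path):
    path = tmp_path / "fault.txt"
    path.write_text(
        "x_m y_m depth_m strike_deg dip_deg rake_deg onset_s f0_hz moment_nm\n"
        "2000 2000 1500 0 90 0 0.0 2.0 1e15\n"
    )
    fault = read_fault_table(path)
    assert len(fault.subfaults) == 1
    np.testing.assert_allclose(fault.subfaults[0].moment, (0, 0, 0, 1e15, 0, 0),
                               atol=1e-1)

    path2 = tmp_path / "fault_slip.txt"
    path2.write_text(
        "x_m y_m depth_m strike_deg dip_deg rake_deg onset_s f0_hz slip_m area_m2 mu_pa\n"
        "2000 2000 1500 0 90 0 0.0 2.0 0.5 1e6 3e10\n"
    )
    fault2 = read_fault_table(path2)
    assert fault2.subfaults[0].moment[3] == pytest.approx(1.5e16)


def test_ricker_and_gaussian_stf_properties():
    stf = SourceTimeFunction("gaussian", f0=2.0)
    t = np.linspace(0, 3, 6001)
    integral = np.trapezoid(stf.rate(t), t)
    assert integral == pytest.approx(1.0, abs=1e-6)
    ricker = SourceTimeFunction("ricker", f0=2.0)
    assert ricker.rate(ricker.delay) == pytest.approx(1.0)
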