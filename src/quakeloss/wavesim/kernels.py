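"""Numba kernels for the collocated velocity-stress update.

Field layout: U has shape (9, nx+2G, ny+2G, nz+2G) with ghost width G=3.
Component order: vx, vy, vz, sxx, syy, szz, sxy, sxz, syz.
Axes: x = north (rows of the surface grid), y = east, z = down.

Within a stage all spatial derivatives along an axis use one bias
direction; the direction alternates across Runge-Kutta stages (and cycles
per axis per step), the MacCormack construction that keeps the one-sided
operators stable and suppresses collocated-grid checkerboard modes.
"""

import numba as nb
import numpy as np

G = 3  # ghost width; matches the biased stencil reach


@nb.njit(inline="always")
def _dfx(U, c, i, j, k, a):
    return (a[0] * U[c, i - 1, j, k] + a[1] * U[c, i, j, k]
            + a[2] * U[c, i + 1, j, k] + a[3] * U[c, i + 2, j, k]
            + a[4] * U[c, i + 3, j, k])


@nb.njit(inline="always")
def _dbx(U, c, i, j, k, a):
    return -(a[0] * U[c, i + 1, j, k] + a[1] * U[c, i, j, k]
             + a[2] * U[c, i - 1, j, k] + a[3] * U[c, i - 2, j, k]
             + a[4] * U[c, i - 3, j, k])


@nb.njit(inline="always")
def _dfy(U, c, i, j, k, a):
    return (a[0] * U[c, i, j - 1, k] + a[1] * U[c, i, j, k]
            + a[2] * U[c, i, j + 1, k] + a[3] * U[c, i, j + 2, k]
            + a[4] * U[c, i, j + 3, k])


@nb.njit(inline="always")
def _dby(U, c, i, j, k, a):
    return -(a[0] * U[c, i, j + 1, k] + a[1] * U[c, i, j, k]
             + a[2] * U[c, i, j - 1, k] + a[3] * U[c, i, j - 2, k]
             + a[4] * U[c, i, j - 3, k])


@nb.njit(inline="always")
def _dfz(U, c, i, j, k, a):
    return (a[0] * U[c, i, j, k - 1] + a[1] * U[c, i, j, k]
            + a[2] * U[c, i, j, k + 1] + a[3] * U[c, i, j, k + 2]
            + a[4] * U[c, i, j, k + 3])


@nb.njit(inline="always")
def _dbz(U, c, i, j, k, a):
    return -(a[0] * U[c, i, j, k + 1] + a[1] * U[c, i, j, k]
             + a[2] * U[c, i, j, k - 1] + a[3] * U[c, i, j, k - 2]
             + a[4] * U[c, i, j, k - 3])


@nb.njit(inline="always")
def _dx(U, c, i, j, k, a, fwd):
    if fwd:
        return _dfx(U, c, i, j, k, a)
    return _dbx(U, c, i, j, k, a)


@nb.njit(inline="always")
def _dy(U, c, i, j, k, a, fwd):
    if fwd:
        return _dfy(U, c, i, j, k, a)
    return _dby(U, c, i, j, k, a)


@nb.njit(inline="always")
def _dz(U, c, i, j, k, a, fwd):
    if fwd:
        return _dfz(U, c, i, j, k, a)
    return _dbz(U, c, i, j, k, a)


@nb.njit(cache=True, fastmath=True)
def rhs(U, rho, lam, mu, a, inv_dx, zfac, fx, fy, fz, dU):
    """Semi-discrete right-hand side of the velocity-stress system.

    fx/fy/fz: True = forward bias along that axis for this stage.  zfac is
    the per-column terrain stretch factor multiplying z-derivatives.
    """
    nx, ny, nz = rho.shape
    for i in range(nx):
        ii = i + G
        for j in range(ny):
            jj = j + G
            zf = zfac[i, j] * inv_dx
            for k in range(nz):
                kk = k + G
                ro = rho[i, j, k]
                la = lam[i, j, k]
                m = mu[i, j, k]

                dsxx_x = _dx(U, 3, ii, jj, kk, a, fx) * inv_dx
                dsxy_y = _dy(U, 6, ii, jj, kk, a, fy) * inv_dx
                dsxz_z = _dz(U, 7, ii, jj, kk, a, fz) * zf
                dsxy_x = _dx(U, 6, ii, jj, kk, a, fx) * inv_dx
                dsyy_y = _dy(U, 4, ii, jj, kk, a, fy) * inv_dx
                dsyz_z = _dz(U, 8, ii, jj, kk, a, fz) * zf
                dsxz_x = _dx(U, 7, ii, jj, kk, a, fx) * inv_dx
                dsyz_y = _dy(U, 8, ii, jj, kk, a, fy) * inv_dx
                dszz_z = _dz(U, 5, ii, jj, kk, a, fz) * zf

                dU[0, ii, jj, kk] = (dsxx_x + dsxy_y + dsxz_z) / ro
                dU[1, ii, jj, kk] = (dsxy_x + dsyy_y + dsyz_z) / ro
                dU[2, ii, jj, kk] = (dsxz_x + dsyz_y + dszz_z) / ro

                dvx_x = _dx(U, 0, ii, jj, kk, a, fx) * inv_dx
                dvy_y = _dy(U, 1, ii, jj, kk, a, fy) * inv_dx
                dvz_z = _dz(U, 2, ii, jj, kk, a, fz) * zf
                dvx_y = _dy(U, 0, ii, jj, kk, a, fy) * inv_dx
                dvx_z = _dz(U, 0, ii, jj, kk, a, fz) * zf
                dvy_x = _dx(U, 1, ii, jj, kk, a, fx) * inv_dx
                dvy_z = _dz(U, 1, ii, jj, kk, a, fz) * zf
                dvz_x = _dx(U, 2, ii, jj, kk, a, fx) * inv_dx
                dvz_y = _dy(U, 2, ii, jj, kk, a, fy) * inv_dx

                lp2m = la + 2.0 * m
                dU[3, ii, jj, kk] = lp2m * dvx_x + la * (dvy_y + dvz_z)
                dU[4, ii, jj, kk] = lp2m * dvy_y + la * (dvx_x + dvz_z)
                dU[5, ii, jj, kk] = lp2m * dvz_z + la * (dvx_x + dvy_y)
                dU[6, ii, jj, kk] = m * (dvx_y + dvy_x)
                dU[7, ii, jj, kk] = m * (dvx_z + dvz_x)
                dU[8, ii, jj, kk] = m * (dvy_z + dvz_y)


@nb.njit(cache=True)
def apply_sponge(U, w):
    """Multiply interior fields by the absorbing-sponge weights."""
    nx, ny, nz = w.shape
    for c in range(9):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    U[c, i + G, j + G, k + G] *= w[i, j, k]
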