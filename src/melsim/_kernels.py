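"""Fused numba kernel for the 4D cell-density right-hand side.

The kernel computes, in one pass over the (nx, nx, ny, ny) density array,
the conservative divergence of all four transport fluxes plus the local
reaction term.  It is numerically identical (up to floating-point
associativity) to the composable numpy operators in
:mod:`melsim.structural_fluxes` / :mod:`melsim.spatial_fluxes` /
:mod:`melsim.solver`, which remain the readable reference path and are
cross-checked against the kernel in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def rhs_cell_density(
    c,
    out,
    # structural y1 faces: upwind velocities (ny-1, ny), D_h per y2 (ny,)
    u_plus,
    u_minus,
    dh,
    # structural y2 faces: D_v per y1 (ny,)
    dv,
    inv_dy,
    # spatial axis-0 faces: upwind taxis velocity (nx-1, nx), D_x*phi (nx-1, nx)
    ux_plus,
    ux_minus,
    dx_coef,
    # spatial axis-1 faces
    uy_plus,
    uy_minus,
    dy_coef,
    inv_dx,
    # reaction: grow (nx, nx), kill coefficients (nx, nx), profiles (ny, ny)
    grow,
    kill_b,
    kill_h,
    prof_p,
    psi_b,
    psi_h,
):
    nx = c.shape[0]
    ny = c.shape[2]
    for i1 in range(nx):
        for i2 in range(nx):
            g = grow[i1, i2]
            kb = kill_b[i1, i2]
            kh = kill_h[i1, i2]
            for j1 in range(ny):
                for j2 in range(ny):
                    cc = c[i1, i2, j1, j2]
                    acc = (g * prof_p[j1, j2] - kb * psi_b[j1, j2] - kh * psi_h[j1, j2]) * cc
                    # structural y1 fluxes
                    if j1 < ny - 1:
                        cr = c[i1, i2, j1 + 1, j2]
                        f = u_plus[j1, j2] * cc + u_minus[j1, j2] * cr - dh[j2] * (cr - cc) * inv_dy
                        acc -= f * inv_dy
                    if j1 > 0:
                        cl = c[i1, i2, j1 - 1, j2]
                        f = u_plus[j1 - 1, j2] * cl + u_minus[j1 - 1, j2] * cc - dh[j2] * (cc - cl) * inv_dy
                        acc += f * inv_dy
                    # structural y2 fluxes (diffusion only)
                    if j2 < ny - 1:
                        cr = c[i1, i2, j1, j2 + 1]
                        acc += dv[j1] * (cr - cc) * inv_dy * inv_dy
                    if j2 > 0:
                        cl = c[i1, i2, j1, j2 - 1]
                        acc -= dv[j1] * (cc - cl) * inv_dy * inv_dy
                    # spatial axis-0 fluxes
                    if i1 < nx - 1:
                        cr = c[i1 + 1, i2, j1, j2]
                        f = ux_plus[i1, i2] * cc + ux_minus[i1, i2] * cr - dx_coef[i1, i2] * (cr - cc) * inv_dx
                        acc -= f * inv_dx
                    if i1 > 0:
                        cl = c[i1 - 1, i2, j1, j2]
                        f = ux_plus[i1 - 1, i2] * cl + ux_minus[i1 - 1, i2] * cc - dx_coef[i1 - 1, i2] * (cc - cl) * inv_dx
                        acc += f * inv_dx
                    # spatial axis-1 fluxes
                    if i2 < nx - 1:
                        cr = c[i1, i2 + 1, j1, j2]
                        f = uy_plus[i1, i2] * cc + uy_minus[i1, i2] * cr - dy_coef[i1, i2] * (cr - cc) * inv_dx
                        acc -= f * inv_dx
                    if i2 > 0:
                        cl = c[i1, i2 - 1, j1, j2]
                        f = uy_plus[i1, i2 - 1] * cl + uy_minus[i1, i2 - 1] * cc - dy_coef[i1, i2 - 1] * (cc - cl) * inv_dx
                        acc += f * inv_dx
                    out[i1, i2, j1, j2] = acc
    return out
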