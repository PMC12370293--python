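"""Independent finite-difference oracle for the rectangular-duct flow.

Solves the Poisson problem for pressure-driven Stokes flow,
``laplacian(u) = const`` with no-slip walls, on a uniform grid with a
sparse direct solve, then rescales the field to carry a prescribed flow
rate.  Used only to cross-check the series solution; never part of the
library's computation path.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def solve_duct(half_width: float, half_height: float, flow_rate: float, nx: int, ny: int):
    """Velocity field on a (nx, ny) grid over [-W, W] x [-H, H].

    Returns (x, y, U) with U[i, j] = u(x[i], y[j]), scaled so that the
    trapezoidal integral of U equals ``flow_rate``.
    """
    xs = np.linspace(-half_width, half_width, nx)
    ys = np.linspace(-half_height, half_height, ny)
    dx, dy = xs[1] - xs[0], ys[1] - ys[0]
    nix, niy = nx - 2, ny - 2
    dxx = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(nix, nix)) / dx**2
    dyy = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(niy, niy)) / dy**2
    lap = sp.kron(dxx, sp.identity(niy)) + sp.kron(sp.identity(nix), dyy)
    u = spla.spsolve(lap.tocsr(), -np.ones(nix * niy)).reshape(nix, niy)
    U = np.zeros((nx, ny))
    U[1:-1, 1:-1] = u
    q = np.trapezoid(np.trapezoid(U, ys, axis=1), xs)
    U *= flow_rate / q
    return xs, ys, U


def wall_shear_centerline(U: np.ndarray, ys: np.ndarray, viscosity: float) -> float:
    """|mu du/dy| at the bottom wall, centerline x = 0 (2nd-order one-sided)."""
    dy = ys[1] - ys[0]
    mid = U.shape[0] // 2
    dudy = (-3.0 * U[mid, 0] + 4.0 * U[mid, 1] - U[mid, 2]) / (2.0 * dy)
    return abs(viscosity * dudy)
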