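"""Steady incompressible 2-D Stokes flow driven by electroosmotic wall slip.

At these scales (100 um cell, ~100 um/s velocities, water) the Reynolds
number is ~1e-2, so inertia is dropped and the time-averaged slip drives a
steady creeping flow.  The solver uses the stream-function/vorticity
formulation: with u = dpsi/dy, v = -dpsi/dx and vorticity w = -lap(psi),

    lap(psi) + w = 0,     lap(w) = 0,

which makes the velocity field exactly divergence-free at the continuous
level and reduces the boundary conditions to

* psi = 0 on every boundary (closed cell, no net through-flow),
* prescribed tangential velocity on the top/bottom walls (the ACEO slip on
  electrode portions, zero elsewhere), imposed through a Thom-type wall
  vorticity formula,
* symmetry side walls: zero wall vorticity (zero shear); optionally solid
  no-slip side walls for closed-cavity verification problems.

Pressure is not a primal unknown; it is recovered afterwards by line
integration of the Stokes momentum balance grad(p) = mu (-dw/dy, dw/dx)
and gauged to zero at the bottom-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import cumulative_trapezoid

from . import _grid
from .core import ChamberGeometry2D, SolverError, SolverSettings
from .electrostatics import SlipProfile

__all__ = ["FlowField", "solve_stokes", "streamfunction"]


@dataclass(frozen=True)
class FlowField:
    """Steady Stokes velocity/pressure field on the shared chamber grid."""

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    psi: np.ndarray
    divergence_norm: float
    geometry: ChamberGeometry2D


def _full_wall_slip(x: np.ndarray, profile: SlipProfile | None) -> np.ndarray:
    """Map an electrode slip profile onto the full wall coordinate array."""
    u = np.zeros_like(x)
    if profile is None:
        return u
    sel = np.isin(x, profile.s)
    if sel.sum() != profile.s.size or not np.allclose(x[sel], profile.s):
        raise SolverError(
            "slip profile positions do not coincide with the flow grid; "
            "solve potential and flow with the same geometry and settings"
        )
    u[sel] = profile.u_slip
    return u


def solve_stokes(
    geometry: ChamberGeometry2D,
    slip_bottom: SlipProfile | None,
    slip_top: SlipProfile | None = None,
    settings: SolverSettings | None = None,
    viscosity: float = 0.89e-3,
) -> FlowField:
    settings = settings or SolverSettings()
    x, y = _grid.build_grid(geometry, settings)
    nx, ny = x.size, y.size
    n = nx * ny

    ub = _full_wall_slip(x, slip_bottom)
    ut = _full_wall_slip(x, slip_top)

    ax, bx, cx = _grid.d2_coeffs(x)
    ay, by, cy = _grid.d2_coeffs(y)

    def idx(i, j):
        return j * nx + i

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(2 * n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    interior_i = np.arange(1, nx - 1)
    interior_j = np.arange(1, ny - 1)

    # psi equations -------------------------------------------------------
    for j in range(ny):
        for i in range(nx):
            r = idx(i, j)
            if i == 0 or i == nx - 1 or j == 0 or j == ny - 1:
                add(r, r, 1.0)  # psi = 0 on all boundaries
            else:
                A = ax[i - 1]
                B = bx[i - 1] + by[j - 1]
                C = cx[i - 1]
                D = ay[j - 1]
                E = cy[j - 1]
                add(r, idx(i - 1, j), A)
                add(r, idx(i + 1, j), C)
                add(r, idx(i, j - 1), D)
                add(r, idx(i, j + 1), E)
                add(r, r, B)
                add(r, n + r, 1.0)  # + w = 0

    # vorticity equations -------------------------------------------------
    h0 = y[1] - y[0]
    h1 = y[-1] - y[-2]
    hx0 = x[1] - x[0]
    hx1 = x[-1] - x[-2]
    side_wall = settings.side_walls == "wall"
    for j in range(ny):
        for i in range(nx):
            r = n + idx(i, j)
            if 0 < i < nx - 1 and 0 < j < ny - 1:
                add(r, n + idx(i - 1, j), ax[i - 1])
                add(r, n + idx(i + 1, j), cx[i - 1])
                add(r, n + idx(i, j - 1), ay[j - 1])
                add(r, n + idx(i, j + 1), cy[j - 1])
                add(r, r, bx[i - 1] + by[j - 1])
            elif i in (0, nx - 1):
                # side walls (corners included): symmetry -> w = 0;
                # solid wall -> Thom formula with zero tangential velocity
                add(r, r, 1.0)
                if side_wall and 0 < j < ny - 1:
                    h = hx0 if i == 0 else hx1
                    ii = 1 if i == 0 else nx - 2
                    add(r, idx(ii, j), 2.0 / h**2)
            elif j == 0:
                # Thom: w = 2 (h u_wall - psi_int) / h^2
                add(r, r, 1.0)
                add(r, idx(i, 1), 2.0 / h0**2)
                rhs[r] = 2.0 * ub[i] / h0
            else:  # j == ny - 1
                add(r, r, 1.0)
                add(r, idx(i, ny - 2), 2.0 / h1**2)
                rhs[r] = -2.0 * ut[i] / h1

    A = sp.csr_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n))
    # The psi rows are O(1), the vorticity rows O(1/h^2): equilibrate by
    # max-abs row and column scaling before factorizing, and polish with one
    # step of iterative refinement; otherwise the LU solution loses several
    # digits to the scale disparity.
    dr = 1.0 / np.abs(A).max(axis=1).toarray().ravel()
    A_r = sp.diags(dr) @ A
    dc = 1.0 / np.abs(A_r).max(axis=0).toarray().ravel()
    A_eq = (A_r @ sp.diags(dc)).tocsc()
    lu = spla.splu(A_eq)
    b_eq = dr * rhs
    w = lu.solve(b_eq)
    w = w + lu.solve(b_eq - A_eq @ w)
    sol = dc * w
    if not np.isfinite(sol).all():
        raise SolverError("Stokes solve returned non-finite values")
    scaled_resid = float(np.linalg.norm(dr * (A @ sol - rhs)))
    b_scale = float(np.linalg.norm(b_eq))
    if b_scale > 0 and scaled_resid / b_scale > 1e-3:
        raise SolverError(
            f"Stokes solve did not converge: scaled residual {scaled_resid / b_scale:.3e}"
        )
    psi = sol[:n].reshape(ny, nx)
    w = sol[n:].reshape(ny, nx)

    u = np.gradient(psi, y, axis=0)
    v = -np.gradient(psi, x, axis=1)
    # boundary values are known exactly from the BCs
    u[0, :] = ub
    u[-1, :] = ut
    v[0, :] = 0.0
    v[-1, :] = 0.0
    u[:, 0] = 0.0
    u[:, -1] = 0.0
    if side_wall:
        v[:, 0] = 0.0
        v[:, -1] = 0.0

    div = np.gradient(u, x, axis=1) + np.gradient(v, y, axis=0)
    div_norm = float(np.abs(div[1:-1, 1:-1]).max()) if nx > 2 and ny > 2 else 0.0

    # pressure recovery: grad p = mu * (-dw/dy, dw/dx), gauged at (0, 0)
    dw_dy, dw_dx = np.gradient(w, y, x)
    p = np.zeros_like(psi)
    p[0, :] = cumulative_trapezoid(-viscosity * dw_dy[0, :], x, initial=0.0)
    p[:, :] = p[0, :][None, :] + cumulative_trapezoid(
        viscosity * dw_dx, y, axis=0, initial=0.0
    )

    return FlowField(
        x=x, y=y, u=u, v=v, p=p, psi=psi, divergence_norm=div_norm, geometry=geometry
    )


def streamfunction(flow: FlowField, rel_div_tol: float = 0.05) -> np.ndarray:
    """Stream function recomputed by vertical integration of u.

    psi(x, y) = int_0^y u(x, y') dy', anchored at the (no-through-flow)
    bottom wall.  Rejects fields whose reported divergence is large compared
    with the velocity scale over a cell.
    """
    umax = float(max(np.abs(flow.u).max(), np.abs(flow.v).max()))
    if umax > 0:
        h = min(np.diff(flow.x).min(), np.diff(flow.y).min())
        if flow.divergence_norm * h / umax > rel_div_tol:
            raise SolverError(
                f"flow field is too divergent for a stream function "
                f"(max|div u| = {flow.divergence_norm:.3e} 1/s)"
            )
    return cumulative_trapezoid(flow.u, flow.y, axis=0, initial=0.0)
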