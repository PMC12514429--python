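"""Complex-phasor electrostatics of the chamber with double-layer impedance.

In the thin-double-layer, linear (low double-layer voltage) regime the bulk
electrolyte is purely resistive and the potential phasor satisfies
Laplace's equation.  Each electrode couples to the bulk through its
double-layer capacitance, which appears as a Robin boundary condition on
the outer edge of the double layer::

    sigma  dphi/dn_out = j omega C_DL (V_j - phi)

with ``V_j`` the applied electrode phasor (+V0 on the bottom finger, -V0 on
the planar top wall), ``n_out`` the outward normal of the fluid domain.
Non-electrode wall portions are insulating and the side walls of the unit
cell are symmetry planes (zero normal current).

The time-averaged AC-electroosmotic slip on an electrode follows from the
potential drop across its double layer::

    u(s) = -(eps_m / (4 eta)) * Lambda_eff * d/dx |phi(s) - V_j|^2

where ``Lambda_eff`` is the empirical slip correction factor (default 0.02)
absorbing both the Stern-layer voltage division and the breakdown of linear
theory at multi-volt drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _grid
from .core import (
    ChamberGeometry2D,
    ConfigError,
    DoubleLayerModel,
    DriveSignal,
    Medium,
    SolverError,
    SolverSettings,
    double_layer_capacitance,
)

__all__ = [
    "ComplexPotentialField",
    "SlipProfile",
    "BulkField",
    "solve_potential",
    "slip_profile",
    "bulk_field",
]


@dataclass(frozen=True)
class ComplexPotentialField:
    """Converged potential phasor on the rectilinear chamber grid.

    ``phi`` has shape (ny, nx), row j at height y[j].  ``residual`` is the
    relative linear-system residual of the reported solution.
    """

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    geometry: ChamberGeometry2D
    medium: Medium
    drive: DriveSignal
    dlm: DoubleLayerModel
    c_dl: float
    residual: float


@dataclass(frozen=True)
class SlipProfile:
    """Tangential time-averaged slip velocity along one electrode.

    ``s`` are arclength positions (equal to x on these straight electrodes),
    ``u_slip`` is signed in +x.
    """

    electrode_id: str
    s: np.ndarray
    u_slip: np.ndarray


@dataclass(frozen=True)
class BulkField:
    """Bulk electric field phasor and the DEP drive quantity |E_rms|^2.

    ``e_rms_sq = (|Ex|^2 + |Ey|^2) / 2`` for peak-amplitude phasors;
    ``grad_x/grad_y`` are its centered-difference gradient components.
    """

    x: np.ndarray
    y: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    e_rms_sq: np.ndarray
    grad_x: np.ndarray
    grad_y: np.ndarray


def solve_potential(
    geometry: ChamberGeometry2D,
    medium: Medium,
    drive: DriveSignal,
    dlm: DoubleLayerModel,
    settings: SolverSettings | None = None,
) -> ComplexPotentialField:
    """Solve the phasor Laplace problem with double-layer impedance walls.

    Finite-volume discretization on the graded tensor grid; boundary half
    cells balance lateral bulk conduction against the capacitive electrode
    flux, which makes the scheme conservative and keeps the discrete
    maximum principle (|phi| <= V0).  The sparse complex system is solved
    directly (sparse LU).
    """
    settings = settings or SolverSettings()
    if geometry.electrode_width > geometry.cell_width:
        raise ConfigError("chamber.electrode_width: exceeds cell_width")
    x, y = _grid.build_grid(geometry, settings)
    nx, ny = x.size, y.size
    n = nx * ny
    sigma = medium.conductivity
    omega = drive.omega
    v0 = drive.amplitude
    c_dl = double_layer_capacitance(medium, dlm)

    wx = _grid.control_widths(x)
    wy = _grid.control_widths(y)
    dx = np.diff(x)
    dy = np.diff(y)
    bottom_mask = _grid.electrode_mask(x, geometry)

    def idx(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return j * nx + i

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n, dtype=complex)
    rhs = np.zeros(n, dtype=complex)

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    ii, jj = ii.ravel(), jj.ravel()
    p = idx(ii, jj)

    # bulk conduction through the four faces of each control volume
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
        if di != 0:
            d = dx[np.minimum(ii, ni)[ok]]
            area = wy[jj[ok]]
        else:
            d = dy[np.minimum(jj, nj)[ok]]
            area = wx[ii[ok]]
        g = sigma * area / d
        rows.append(p[ok])
        cols.append(idx(ni, nj)[ok])
        vals.append(-g)
        np.add.at(diag, p[ok], g)

    # capacitive electrode faces: j*omega*C_DL*(phi - Vj) * face_width
    jwc = 1j * omega * c_dl
    bot = np.where(bottom_mask)[0]
    pb = idx(bot, np.zeros_like(bot))
    diag[pb] += jwc * wx[bot]
    rhs[pb] += jwc * wx[bot] * (+v0)
    top = np.arange(nx)
    pt = idx(top, np.full_like(top, ny - 1))
    diag[pt] += jwc * wx[top]
    rhs[pt] += jwc * wx[top] * (-v0)

    rows.append(p)
    cols.append(p)
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    phi = spla.spsolve(A, rhs)
    bnorm = np.linalg.norm(rhs)
    residual = float(np.linalg.norm(A @ phi - rhs) / bnorm) if bnorm > 0 else float(np.linalg.norm(A @ phi))
    if not np.isfinite(phi).all() or residual > settings.residual_tol:
        raise SolverError(
            f"potential solve failed: relative residual {residual:.3e} "
            f"exceeds tolerance {settings.residual_tol:.1e}"
        )
    return ComplexPotentialField(
        x=x,
        y=y,
        phi=phi.reshape(ny, nx),
        geometry=geometry,
        medium=medium,
        drive=drive,
        dlm=dlm,
        c_dl=c_dl,
        residual=residual,
    )


def slip_profile(
    field: ComplexPotentialField,
    dlm: DoubleLayerModel | None = None,
    electrode: str = "bottom",
    edge_clamp: bool | None = None,
) -> SlipProfile:
    """Time-averaged ACEO slip velocity along one electrode.

    The 1/4 prefactor already contains the time average of the quadratic
    slip for peak-amplitude phasors, so the formula is applied directly to
    |phi - Vj|^2.  Endpoint derivatives at interior electrode edges are
    one-sided and, by default, clamped to the adjacent interior value to
    avoid mesh-dependent blow-up at the edge singularity; endpoints falling
    on a symmetry plane keep their (vanishing) one-sided value.
    """
    dlm = dlm or field.dlm
    if edge_clamp is None:
        edge_clamp = True
    v0 = field.drive.amplitude
    if electrode == "bottom":
        mask = _grid.electrode_mask(field.x, field.geometry)
        s = field.x[mask]
        phi_e = field.phi[0, mask]
        vj = +v0
    elif electrode == "top":
        s = field.x
        phi_e = field.phi[-1, :]
        vj = -v0
    else:
        raise ConfigError(
            f"electrode: no electrode named {electrode!r} (walls other than "
            "'bottom'/'top' electrodes carry no slip)"
        )
    g = np.abs(phi_e - vj) ** 2
    dg = np.gradient(g, s)
    if edge_clamp and s.size > 2:
        W = field.geometry.cell_width
        tol = 1e-9 * W
        if s[0] > tol:  # interior electrode edge, not a symmetry plane
            dg[0] = dg[1]
        if s[-1] < W - tol:
            dg[-1] = dg[-2]
    pref = -field.medium.epsilon / (4.0 * field.medium.viscosity)
    u = pref * dlm.correction_factor * dg
    return SlipProfile(electrode_id=electrode, s=s, u_slip=u)


def bulk_field(field: ComplexPotentialField) -> BulkField:
    """Electric-field phasor E = -grad(phi) and |E_rms|^2 with its gradient.

    Centered differences on the non-uniform grid, one-sided at walls.
    """
    dphi_dy, dphi_dx = np.gradient(field.phi, field.y, field.x)
    ex = -dphi_dx
    ey = -dphi_dy
    e_rms_sq = (np.abs(ex) ** 2 + np.abs(ey) ** 2) / 2.0
    gy, gx = np.gradient(e_rms_sq, field.y, field.x)
    return BulkField(
        x=field.x, y=field.y, ex=ex, ey=ey, e_rms_sq=e_rms_sq, grad_x=gx, grad_y=gy
    )
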