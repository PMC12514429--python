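"""Dielectrophoresis: Clausius-Mossotti factor, crossover, force field.

A polarizable sphere of radius r in a non-uniform AC field experiences the
time-averaged DEP force

    F = 2 pi eps_m r^3 Re(f_cm) grad(|E_rms|^2)

with the Clausius-Mossotti contrast factor

    f_cm = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),   eps* = eps - j sigma / omega.

Re(f_cm) in [-1/2, 1] sets sign and strength: positive DEP pulls particles
toward field maxima (the electrode edges), negative DEP repels them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import DriveSignal, Medium, ParticleSpec, SolverError
from .electrostatics import ComplexPotentialField, bulk_field

__all__ = ["DEPForceField", "cm_factor", "crossover_conductivity", "dep_force_field"]


@dataclass(frozen=True)
class DEPForceField:
    """Time-averaged DEP force components on the chamber grid (N)."""

    x: np.ndarray
    y: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    re_fcm: float


def cm_factor(particle: ParticleSpec, medium: Medium, frequency: float) -> complex:
    """Clausius-Mossotti factor at the given drive frequency (Hz)."""
    omega = 2.0 * np.pi * frequency
    ep = particle.epsilon - 1j * particle.conductivity / omega
    em = medium.epsilon - 1j * medium.conductivity / omega
    return complex((ep - em) / (ep + 2.0 * em))


def crossover_conductivity(
    particle: ParticleSpec,
    frequency: float,
    bracket: tuple[float, float] = (1e-5, 1.0),
    medium_rel_permittivity: float = 78.5,
    medium_template: Medium | None = None,
) -> float:
    """Medium conductivity (S/m) at which Re(f_cm) changes sign.

    Bracketed root search over sigma_m; raises when Re(f_cm) has the same
    sign at both bracket ends (e.g. a perfectly insulating particle never
    shows positive DEP at low frequency).
    """

    def f(sig: float) -> float:
        med = (
            medium_template.with_conductivity(sig)
            if medium_template is not None
            else Medium(conductivity=sig, rel_permittivity=medium_rel_permittivity)
        )
        return cm_factor(particle, med, frequency).real

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise SolverError(
            f"Re(f_cm) does not change sign over the bracket: "
            f"Re(f_cm)({lo:g} S/m) = {flo:+.4f}, Re(f_cm)({hi:g} S/m) = {fhi:+.4f}"
        )
    return float(brentq(f, lo, hi, xtol=1e-16, rtol=1e-14))


def dep_force_field(
    potential_field: ComplexPotentialField,
    particle: ParticleSpec,
    medium: Medium,
    drive: DriveSignal,
) -> DEPForceField:
    """DEP force on the potential solver's grid, from the bulk (outer) field."""
    bf = bulk_field(potential_field)
    refcm = cm_factor(particle, medium, drive.frequency).real
    pref = 2.0 * np.pi * medium.epsilon * particle.radius**3 * refcm
    return DEPForceField(
        x=bf.x, y=bf.y, fx=pref * bf.grad_x, fy=pref * bf.grad_y, re_fcm=refcm
    )
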