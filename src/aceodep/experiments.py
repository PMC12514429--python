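"""Parameter-sweep drivers: geometry optimization and drive-response studies.

`run_case` executes the full chain for one configuration:

    potential (Robin-BC Laplace) -> ACEO slip -> Stokes flow -> DEP force
    -> overdamped tracing with stick walls -> trap counting

`geometry_sweep` repeats it over chamber heights or comb gaps to locate the
geometry that maximizes the proportion of particles captured on the
electrodes within the tracing window; `drive_sweep` scans voltage,
frequency or conductivity and reports the peak slip speed (tracing
optional).  Everything is deterministic: rerunning a sweep bit-reproduces
its table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Config, ConfigError
from .dep import DEPForceField, dep_force_field
from .electrostatics import ComplexPotentialField, SlipProfile, slip_profile, solve_potential
from .stokesflow import FlowField, solve_stokes
from .tracing import TrajectorySet, TrapResult, count_trapped, release_grid, trace

__all__ = [
    "CaseResult",
    "SweepResult",
    "run_case",
    "geometry_sweep",
    "drive_sweep",
    "peak_slip",
    "peak_frequency",
]

logger = logging.getLogger("aceodep")


@dataclass(frozen=True)
class CaseResult:
    """All artifacts of one full-chain simulation."""

    config: Config
    potential: ComplexPotentialField
    slip_bottom: SlipProfile
    slip_top: SlipProfile
    flow: FlowField
    dep: DEPForceField
    trajectories: TrajectorySet
    trap: TrapResult

    @property
    def max_slip(self) -> float:
        return float(
            max(np.abs(self.slip_bottom.u_slip).max(), np.abs(self.slip_top.u_slip).max())
        )


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-value metrics plus the record of what was held fixed."""

    variable: str
    units: str
    table: pd.DataFrame
    fixed: dict

    def argmax(self, metric: str = "proportion_trapped") -> float:
        """Swept value maximizing the given metric column."""
        return float(self.table.loc[self.table[metric].idxmax(), "value"])


def run_case(config: Config, with_tracing: bool = True) -> CaseResult:
    field = solve_potential(
        config.chamber, config.medium, config.drive, config.dl, config.solver
    )
    sb = slip_profile(field, config.dl, "bottom", config.solver.edge_clamp)
    st = slip_profile(field, config.dl, "top", config.solver.edge_clamp)
    flow = solve_stokes(
        config.chamber, sb, st, config.solver, viscosity=config.medium.viscosity
    )
    force = dep_force_field(field, config.particle, config.medium, config.drive)
    trajs = trap = None
    if with_tracing:
        starts = release_grid(config.chamber, config.solver.release_pitch)
        trajs = trace(
            flow,
            force,
            config.particle,
            config.medium,
            starts,
            config.solver.duration,
            config.solver,
        )
        trap = count_trapped(trajs)
    return CaseResult(config, field, sb, st, flow, force, trajs, trap)


def peak_slip(config: Config) -> float:
    """Maximum |u_slip| over both electrodes (m/s), no flow/tracing stages."""
    field = solve_potential(
        config.chamber, config.medium, config.drive, config.dl, config.solver
    )
    sb = slip_profile(field, config.dl, "bottom", config.solver.edge_clamp)
    st = slip_profile(field, config.dl, "top", config.solver.edge_clamp)
    return float(max(np.abs(sb.u_slip).max(), np.abs(st.u_slip).max()))


def peak_frequency(config: Config, f_bounds: tuple[float, float] = (10.0, 1e6)) -> float:
    """Drive frequency (Hz) maximizing the peak slip speed.

    The slip response vs frequency is bell-shaped (the double layer blocks
    DC and shorts out at high frequency); the maximum is located by
    golden-section search in log-frequency.
    """
    from scipy.optimize import minimize_scalar

    def neg(logf: float) -> float:
        cfg = dataclasses.replace(
            config, drive=dataclasses.replace(config.drive, frequency=10.0**logf)
        )
        return -peak_slip(cfg)

    res = minimize_scalar(
        neg,
        bounds=(np.log10(f_bounds[0]), np.log10(f_bounds[1])),
        method="bounded",
        options={"xatol": 5e-3},
    )
    return float(10.0 ** res.x)


def _with_geometry(config: Config, variable: str, value: float) -> Config:
    if variable == "height":
        geom = dataclasses.replace(config.chamber, height=value, cell_width=None)
    elif variable == "gap":
        geom = dataclasses.replace(config.chamber, gap=value, cell_width=None)
    else:
        raise ConfigError(f"sweep.variable: unknown geometry variable {variable!r}")
    return dataclasses.replace(config, chamber=geom)


def geometry_sweep(variable: str, values, config: Config) -> SweepResult:
    """Full-chain sweep over chamber height or inter-electrode gap (m)."""
    rows = []
    for v in values:
        try:
            case = run_case(_with_geometry(config, variable, float(v)))
        except Exception as exc:  # noqa: BLE001 - annotate the failing value
            raise type(exc)(f"{variable} = {v * 1e6:g} um: {exc}") from exc
        rows.append(
            {
                "value": float(v),
                "value_um": float(v) * 1e6,
                "n_released": case.trap.n_released,
                "n_trapped": case.trap.n_trapped_electrode,
                "proportion_trapped": case.trap.proportion_trapped,
                "max_slip_m_per_s": case.max_slip,
            }
        )
        logger.info(
            "%s sweep: %g um -> trapped %d/%d (%.3f)",
            variable,
            v * 1e6,
            case.trap.n_trapped_electrode,
            case.trap.n_released,
            case.trap.proportion_trapped,
        )
    fixed = config.resolved()
    fixed["chamber"].pop("height" if variable == "height" else "gap", None)
    return SweepResult(variable=variable, units="m", table=pd.DataFrame(rows), fixed=fixed)


def _with_drive(config: Config, variable: str, value: float) -> Config:
    if variable == "voltage":
        return dataclasses.replace(
            config, drive=dataclasses.replace(config.drive, v_pp=value)
        )
    if variable == "frequency":
        return dataclasses.replace(
            config, drive=dataclasses.replace(config.drive, frequency=value)
        )
    if variable == "conductivity":
        return dataclasses.replace(config, medium=config.medium.with_conductivity(value))
    raise ConfigError(f"sweep.variable: unknown drive variable {variable!r}")


def drive_sweep(
    variable: str, values, config: Config, with_tracing: bool = False
) -> SweepResult:
    """Sweep voltage (V_pp), frequency (Hz) or conductivity (S/m).

    Reports the maximum slip speed per value; the full tracing chain runs
    only when requested.
    """
    unit_map = {"voltage": "V_pp", "frequency": "Hz", "conductivity": "S/m"}
    if variable not in unit_map:
        raise ConfigError(f"sweep.variable: unknown drive variable {variable!r}")
    units = unit_map[variable]
    rows = []
    for v in values:
        try:
            cfg = _with_drive(config, variable, float(v))
            if with_tracing:
                case = run_case(cfg)
                row = {
                    "value": float(v),
                    "max_slip_m_per_s": case.max_slip,
                    "n_released": case.trap.n_released,
                    "n_trapped": case.trap.n_trapped_electrode,
                    "proportion_trapped": case.trap.proportion_trapped,
                }
            else:
                row = {"value": float(v), "max_slip_m_per_s": peak_slip(cfg)}
        except Exception as exc:  # noqa: BLE001
            raise type(exc)(f"{variable} = {v:g} {units}: {exc}") from exc
        rows.append(row)
    return SweepResult(
        variable=variable, units=units, table=pd.DataFrame(rows), fixed=config.resolved()
    )
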