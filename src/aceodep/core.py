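"""Domain types, physical constants and configuration handling.

The simulator models a 2-D cross-section of a microfluidic chamber bounded
below by a micro-structured (comb) gold electrode and above by a planar
counter-electrode.  Everything downstream (phasor electrostatics, Stokes
flow, dielectrophoretic forces, particle tracing) consumes the small set of
value objects defined here:

* :class:`Medium` -- the electrolyte (conductivity, permittivity, viscosity,
  temperature, ion content),
* :class:`ParticleSpec` -- the tracer/target particle,
* :class:`DriveSignal` -- the applied AC signal,
* :class:`DoubleLayerModel` -- the linear electrical-double-layer closure,
* :class:`ChamberGeometry2D` -- the simulated unit cell,
* :class:`SolverSettings` -- discretization and tracing controls.

All internal quantities are strictly SI.  User-facing configuration files
carry explicit unit suffixes (``height_um``, ``conductivity_mS_per_m``, ...)
and are converted exactly once, at the parsing boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Any

import yaml
from scipy import constants as _const

__all__ = [
    "EPSILON_0",
    "GAS_CONSTANT",
    "FARADAY",
    "BOLTZMANN",
    "MOLAR_CONDUCTIVITY_KCL",
    "ConfigError",
    "SolverError",
    "Medium",
    "ParticleSpec",
    "DriveSignal",
    "DoubleLayerModel",
    "ChamberGeometry2D",
    "SolverSettings",
    "Config",
    "debye_length",
    "double_layer_capacitance",
    "kcl_concentration_from_conductivity",
    "load_config",
    "loads_config",
    "dump_config",
    "dumps_config",
    "baseline_config",
]

logger = logging.getLogger("aceodep")

EPSILON_0: float = _const.epsilon_0
GAS_CONSTANT: float = _const.R
FARADAY: float = _const.physical_constants["Faraday constant"][0]
BOLTZMANN: float = _const.k

#: Limiting molar conductivity of KCl at 25 C (S m^2 / mol).  Used to map a
#: measured bulk conductivity to a KCl concentration for dilute solutions.
MOLAR_CONDUCTIVITY_KCL: float = 149.85e-4


class ConfigError(ValueError):
    """A configuration value violates an invariant (message names the field)."""


class SolverError(RuntimeError):
    """A numerical stage failed to converge or was asked the impossible."""


def _require(cond: bool, field_name: str, rule: str, value: Any) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {rule} (got {value!r})")


# ---------------------------------------------------------------------------
# value objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Medium:
    """Bulk electrolyte properties.

    Parameters
    ----------
    conductivity:
        Bulk electrical conductivity sigma_m (S/m).
    rel_permittivity:
        Relative permittivity eps_r (dimensionless); absolute permittivity is
        ``eps_r * eps_0``.
    viscosity:
        Dynamic viscosity eta (Pa s).
    temperature:
        Absolute temperature (K).
    ions:
        Optional electroneutral ion content as ``((z_i, c_i), ...)`` with
        integer valency ``z_i`` and concentration ``c_i`` in mol/m^3.  Needed
        to compute the Debye length; may be omitted when the double-layer
        capacitance is supplied directly.
    """

    conductivity: float
    rel_permittivity: float = 78.5
    viscosity: float = 0.89e-3
    temperature: float = 298.15
    ions: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        _require(self.conductivity > 0, "medium.conductivity", "must be > 0", self.conductivity)
        _require(self.rel_permittivity >= 1, "medium.rel_permittivity", "must be >= 1", self.rel_permittivity)
        _require(self.viscosity > 0, "medium.viscosity", "must be > 0", self.viscosity)
        _require(self.temperature > 0, "medium.temperature", "must be > 0", self.temperature)
        if self.ions is not None:
            ions = tuple((int(z), float(c)) for z, c in self.ions)
            object.__setattr__(self, "ions", ions)
            _require(len(ions) > 0, "medium.ions", "must be non-empty when given", ions)
            for z, c in ions:
                _require(c > 0, "medium.ions", "concentrations must be > 0", c)
            scale = max(abs(z) * c for z, c in ions)
            net = sum(z * c for z, c in ions)
            _require(
                abs(net) <= 1e-9 * scale,
                "medium.ions",
                "must be electroneutral (sum z_i*c_i = 0)",
                net,
            )

    @property
    def epsilon(self) -> float:
        """Absolute permittivity eps_m (F/m)."""
        return self.rel_permittivity * EPSILON_0

    @classmethod
    def kcl(
        cls,
        conductivity: float,
        *,
        concentration: float | None = None,
        rel_permittivity: float = 78.5,
        viscosity: float = 0.89e-3,
        temperature: float = 298.15,
    ) -> "Medium":
        """KCl-in-water medium; concentration derived from conductivity if absent."""
        if concentration is None:
            concentration = kcl_concentration_from_conductivity(conductivity)
        ions = ((1, concentration), (-1, concentration))
        return cls(conductivity, rel_permittivity, viscosity, temperature, ions)

    def with_conductivity(self, conductivity: float) -> "Medium":
        """Copy with a new conductivity; KCl ion content is re-derived when present."""
        if self.ions is not None:
            c = kcl_concentration_from_conductivity(conductivity)
            return dataclasses.replace(self, conductivity=conductivity, ions=((1, c), (-1, c)))
        return dataclasses.replace(self, conductivity=conductivity)


def kcl_concentration_from_conductivity(conductivity: float) -> float:
    """KCl concentration (mol/m^3) producing a given dilute-limit conductivity (S/m)."""
    _require(conductivity > 0, "medium.conductivity", "must be > 0", conductivity)
    return conductivity / MOLAR_CONDUCTIVITY_KCL


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical dielectric particle with a thin conducting surface layer.

    The effective particle conductivity follows the standard surface-
    conductance model ``sigma_p = sigma_bulk + 2 Ks / r``; for sub-micron
    latex beads the surface term dominates entirely.
    """

    radius: float
    rel_permittivity: float = 2.55
    bulk_conductivity: float = 0.0
    surface_conductance: float = 1e-9

    def __post_init__(self) -> None:
        _require(self.radius > 0, "particle.radius", "must be > 0", self.radius)
        _require(self.rel_permittivity > 0, "particle.rel_permittivity", "must be > 0", self.rel_permittivity)
        _require(
            self.bulk_conductivity >= 0,
            "particle.bulk_conductivity",
            "must be >= 0",
            self.bulk_conductivity,
        )
        _require(
            self.surface_conductance >= 0,
            "particle.surface_conductance",
            "must be >= 0",
            self.surface_conductance,
        )

    @property
    def conductivity(self) -> float:
        """Effective conductivity sigma_p = sigma_bulk + 2 Ks / r (S/m)."""
        return self.bulk_conductivity + 2.0 * self.surface_conductance / self.radius

    @property
    def epsilon(self) -> float:
        return self.rel_permittivity * EPSILON_0


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal AC drive, specified by peak-to-peak voltage and frequency."""

    v_pp: float
    frequency: float

    def __post_init__(self) -> None:
        _require(self.v_pp > 0, "drive.v_pp", "must be > 0", self.v_pp)
        _require(self.frequency > 0, "drive.frequency", "must be > 0", self.frequency)

    @property
    def omega(self) -> float:
        """Angular frequency (rad/s)."""
        return 2.0 * math.pi * self.frequency

    @property
    def amplitude(self) -> float:
        """Phasor (peak) amplitude V0 = v_pp / 2 (V)."""
        return self.v_pp / 2.0

    @property
    def v_rms(self) -> float:
        return self.v_pp / (2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class DoubleLayerModel:
    """Linear (low-voltage) electrical double layer.

    The double layer is a Stern (compact) capacitor ``Cs`` in series with the
    diffuse-layer capacitor ``Cd = eps_m / debye_length``, giving the ratio
    ``capacitance_ratio = Cs / (Cd + Cs)`` and a total capacitance per area
    ``C_DL = capacitance_ratio * Cd``.

    ``correction_factor`` is the empirical multiplier applied to the
    theoretical slip velocity: at multi-volt drive the linear double-layer
    theory over-predicts slip, and a factor of order 0.02 brings simulated
    velocities in line with tracked-particle measurements.

    ``c_dl`` allows supplying the total capacitance per unit area directly,
    bypassing the ion-composition route.
    """

    capacitance_ratio: float = 0.25
    correction_factor: float = 0.02
    stern_capacitance: float | None = None
    c_dl: float | None = None

    def __post_init__(self) -> None:
        _require(
            0 < self.capacitance_ratio <= 1,
            "dl.lambda",
            "must be in (0, 1]",
            self.capacitance_ratio,
        )
        _require(
            0 < self.correction_factor <= 1,
            "dl.lambda_exp",
            "must be in (0, 1]",
            self.correction_factor,
        )
        if self.stern_capacitance is not None:
            _require(
                self.stern_capacitance > 0,
                "dl.stern_capacitance",
                "must be > 0",
                self.stern_capacitance,
            )
        if self.c_dl is not None:
            _require(self.c_dl > 0, "dl.c_dl", "must be > 0", self.c_dl)


@dataclass(frozen=True)
class ChamberGeometry2D:
    """The simulated unit cell of the chamber cross-section.

    Coordinates: x horizontal along the bottom wall, y vertical, origin at
    the bottom-left corner.  The bottom electrode (one comb finger) of width
    ``electrode_width`` is centered at ``x = cell_width / 2`` on ``y = 0``;
    the planar counter-electrode occupies the entire top wall ``y = height``.
    The side walls ``x = 0`` and ``x = cell_width`` are symmetry planes, so
    the cell is the periodic image of an infinite comb.  ``cell_width``
    defaults to ``electrode_width + gap`` (one comb period).
    """

    height: float
    electrode_width: float = 100e-6
    gap: float = 200e-6
    cell_width: float | None = None

    def __post_init__(self) -> None:
        _require(self.height > 0, "chamber.height", "must be > 0", self.height)
        _require(self.electrode_width > 0, "chamber.electrode_width", "must be > 0", self.electrode_width)
        _require(self.gap >= 0, "chamber.gap", "must be >= 0", self.gap)
        if self.cell_width is None:
            object.__setattr__(self, "cell_width", self.electrode_width + self.gap)
        _require(
            self.electrode_width <= self.cell_width + 1e-15,
            "chamber.electrode_width",
            "must not exceed cell_width",
            self.electrode_width,
        )

    @property
    def electrode_span(self) -> tuple[float, float]:
        """(x_left, x_right) extent of the bottom electrode on y = 0."""
        w2 = self.electrode_width / 2.0
        mid = self.cell_width / 2.0
        return (mid - w2, mid + w2)


@dataclass(frozen=True)
class SolverSettings:
    """Discretization, tracing and output controls (all SI).

    ``target_spacing`` is the nominal grid spacing away from electrode
    edges; the mesh is geometrically refined down to ``min_spacing`` toward
    each electrode edge and toward both electrode walls, where the field has
    an integrable corner singularity.  ``cfl`` bounds the advection distance
    per tracing step to that fraction of the smallest grid cell.
    """

    target_spacing: float = 3e-6
    min_spacing: float = 0.75e-6
    growth: float = 1.3
    dep_drift_cap: float = 2.0
    residual_tol: float = 1e-8
    edge_clamp: bool = True
    side_walls: str = "symmetry"  # "symmetry" | "wall"
    dt: float | None = None
    cfl: float = 0.4
    duration: float = 60.0
    release_pitch: float = 15e-6
    output_stride: int = 100
    brownian: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.target_spacing > 0, "solver.target_spacing", "must be > 0", self.target_spacing)
        _require(
            0 < self.min_spacing <= self.target_spacing,
            "solver.min_spacing",
            "must be in (0, target_spacing]",
            self.min_spacing,
        )
        _require(self.growth > 1, "solver.growth", "must be > 1", self.growth)
        _require(self.dep_drift_cap > 0, "solver.dep_drift_cap", "must be > 0", self.dep_drift_cap)
        _require(self.side_walls in ("symmetry", "wall"), "solver.side_walls", "must be 'symmetry' or 'wall'", self.side_walls)
        _require(0 < self.cfl <= 1, "solver.cfl", "must be in (0, 1]", self.cfl)
        _require(self.duration > 0, "solver.duration", "must be > 0", self.duration)
        _require(self.release_pitch > 0, "solver.release_pitch", "must be > 0", self.release_pitch)
        _require(self.output_stride >= 1, "solver.output_stride", "must be >= 1", self.output_stride)
        if self.dt is not None:
            _require(self.dt > 0, "solver.dt", "must be > 0", self.dt)


# ---------------------------------------------------------------------------
# derived scalars
# ---------------------------------------------------------------------------


def debye_length(medium: Medium) -> float:
    """Debye screening length kappa^-1 (m) of the diffuse double layer.

    ``kappa^-1 = sqrt(eps_m R T / (F^2 sum_i z_i^2 c_i))`` with the gas
    constant R, the Faraday constant F and ion concentrations in mol/m^3.
    Decreases as the inverse square root of ionic strength.
    """
    if medium.ions is None:
        raise ConfigError(
            "medium.ions: ion composition required to compute the Debye length; "
            "provide ions (e.g. kcl_mM) or a direct double-layer capacitance (dl.c_dl)"
        )
    strength = sum(z * z * c for z, c in medium.ions)
    return math.sqrt(
        medium.epsilon * GAS_CONSTANT * medium.temperature / (FARADAY**2 * strength)
    )


def double_layer_capacitance(medium: Medium, dlm: DoubleLayerModel) -> float:
    """Total double-layer capacitance per unit area C_DL (F/m^2).

    Series combination of Stern and diffuse layers: ``C_DL = Lambda * Cd``
    with ``Cd = eps_m / debye_length`` and ``Lambda = Cs / (Cd + Cs)``.
    When the model carries an explicit ``c_dl`` it wins outright; when it
    carries a Stern capacitance, Lambda is recomputed from it.
    """
    if dlm.c_dl is not None:
        return dlm.c_dl
    cd = medium.epsilon / debye_length(medium)
    if dlm.stern_capacitance is not None:
        ratio = dlm.stern_capacitance / (cd + dlm.stern_capacitance)
    else:
        ratio = dlm.capacitance_ratio
    return ratio * cd


# ---------------------------------------------------------------------------
# configuration file handling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Config:
    """Fully-resolved simulation configuration (all SI)."""

    chamber: ChamberGeometry2D
    medium: Medium
    particle: ParticleSpec
    drive: DriveSignal
    dl: DoubleLayerModel
    solver: SolverSettings = field(default_factory=SolverSettings)

    def resolved(self) -> dict[str, Any]:
        """Nested plain-dict echo of the configuration in SI units."""
        return {
            "chamber": dataclasses.asdict(self.chamber),
            "medium": dataclasses.asdict(self.medium),
            "particle": dataclasses.asdict(self.particle),
            "drive": {
                **dataclasses.asdict(self.drive),
                "omega_rad_per_s": self.drive.omega,
                "amplitude_V": self.drive.amplitude,
                "convention": "anti-symmetric drive: bottom +V0, top -V0, V0 = v_pp/2",
            },
            "dl": dataclasses.asdict(self.dl),
            "solver": dataclasses.asdict(self.solver),
        }


# (section, config key) -> (dataclass field, multiplicative SI factor)
_SCHEMA: dict[str, dict[str, tuple[str, float]]] = {
    "chamber": {
        "height_um": ("height", 1e-6),
        "electrode_width_um": ("electrode_width", 1e-6),
        "gap_um": ("gap", 1e-6),
        "cell_width_um": ("cell_width", 1e-6),
    },
    "medium": {
        "conductivity_mS_per_m": ("conductivity", 1e-3),
        "rel_permittivity": ("rel_permittivity", 1.0),
        "viscosity_mPa_s": ("viscosity", 1e-3),
        "temperature_K": ("temperature", 1.0),
        "kcl_mM": ("kcl_mM", 1.0),  # 1 mM == 1 mol/m^3
    },
    "particle": {
        "radius_um": ("radius", 1e-6),
        "rel_permittivity": ("rel_permittivity", 1.0),
        "bulk_conductivity_S_per_m": ("bulk_conductivity", 1.0),
        "surface_conductance_nS": ("surface_conductance", 1e-9),
    },
    "drive": {
        "v_pp": ("v_pp", 1.0),
        "frequency_Hz": ("frequency", 1.0),
        "frequency_kHz": ("frequency", 1e3),
    },
    "dl": {
        "lambda": ("capacitance_ratio", 1.0),
        "lambda_exp": ("correction_factor", 1.0),
        "stern_capacitance_F_per_m2": ("stern_capacitance", 1.0),
        "c_dl_F_per_m2": ("c_dl", 1.0),
    },
    "solver": {
        "target_spacing_um": ("target_spacing", 1e-6),
        "min_spacing_um": ("min_spacing", 1e-6),
        "growth": ("growth", 1.0),
        "residual_tol": ("residual_tol", 1.0),
        "edge_clamp": ("edge_clamp", 1.0),
        "side_walls": ("side_walls", 1.0),
        "dt_ms": ("dt", 1e-3),
        "cfl": ("cfl", 1.0),
        "dep_drift_cap": ("dep_drift_cap", 1.0),
        "duration_s": ("duration", 1.0),
        "release_pitch_um": ("release_pitch", 1e-6),
        "output_stride": ("output_stride", 1.0),
        "brownian": ("brownian", 1.0),
        "seed": ("seed", 1.0),
    },
}

_SECTION_TYPES = {
    "chamber": ChamberGeometry2D,
    "particle": ParticleSpec,
    "drive": DriveSignal,
    "dl": DoubleLayerModel,
    "solver": SolverSettings,
}


def _parse_section(section: str, raw: dict[str, Any]) -> dict[str, Any]:
    schema = _SCHEMA[section]
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in schema:
            raise ConfigError(
                f"{section}.{key}: unknown key (known: {', '.join(sorted(schema))})"
            )
        attr, factor = schema[key]
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            out[attr] = value  # strings / booleans pass through untouched
        else:
            out[attr] = float(value) * factor
        if attr in ("output_stride", "seed"):
            out[attr] = int(value)
    return out


def loads_config(text: str) -> Config:
    """Parse a YAML configuration string into a validated :class:`Config`."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config: top level must be a mapping of sections")
    known = set(_SCHEMA)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"config: unknown section(s) {sorted(unknown)} (known: {sorted(known)})"
        )
    for required in ("chamber", "medium", "drive"):
        if required not in raw:
            raise ConfigError(f"config: missing required section '{required}'")

    sections = {
        name: _parse_section(name, raw.get(name, {}) or {}) for name in _SCHEMA
    }

    med_kwargs = sections["medium"]
    kcl_mM = med_kwargs.pop("kcl_mM", None)
    dl = DoubleLayerModel(**sections["dl"])
    if kcl_mM is not None:
        med_kwargs["ions"] = ((1, float(kcl_mM)), (-1, float(kcl_mM)))
        medium = Medium(**med_kwargs)
    elif dl.c_dl is not None:
        medium = Medium(**med_kwargs)  # capacitance given directly; no ions needed
    else:
        medium = Medium.kcl(**med_kwargs)

    cfg = Config(
        chamber=ChamberGeometry2D(**sections["chamber"]),
        medium=medium,
        particle=ParticleSpec(**sections["particle"]) if sections["particle"] else ParticleSpec(radius=0.5e-6),
        drive=DriveSignal(**sections["drive"]),
        dl=dl,
        solver=SolverSettings(**sections["solver"]),
    )
    logger.info("resolved configuration: %s", cfg.resolved())
    return cfg


def load_config(path: str) -> Config:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def dumps_config(cfg: Config) -> str:
    """Serialize a :class:`Config` to the canonical YAML dialect.

    Inverse of :func:`loads_config` up to floating-point unit conversion
    round-trip (identity to ~1e-15 relative).
    """
    doc: dict[str, dict[str, Any]] = {}
    objmap = {
        "chamber": cfg.chamber,
        "medium": cfg.medium,
        "particle": cfg.particle,
        "drive": cfg.drive,
        "dl": cfg.dl,
        "solver": cfg.solver,
    }
    for section, schema in _SCHEMA.items():
        obj = objmap[section]
        sec: dict[str, Any] = {}
        emitted: set[str] = set()
        for key, (attr, factor) in schema.items():
            if attr in emitted or attr == "kcl_mM" or key == "frequency_kHz":
                continue
            value = getattr(obj, attr, None)
            if value is None:
                continue
            if isinstance(value, bool) or isinstance(value, str):
                sec[key] = value
            elif isinstance(value, (int, float)):
                v = value / factor
                sec[key] = int(v) if attr in ("output_stride", "seed") else float(v)
            emitted.add(attr)
        doc[section] = sec
    if cfg.medium.ions is not None:
        # canonical dialect stores the KCl content explicitly
        pos = [c for z, c in cfg.medium.ions if z > 0]
        doc["medium"]["kcl_mM"] = float(pos[0])
    return yaml.safe_dump(doc, sort_keys=True)


def dump_config(cfg: Config, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_config(cfg))


def baseline_config(**overrides: Any) -> Config:
    """The reference operating point: H = 160 um chamber, 100 um electrode,
    200 um comb gap, 1 mS/m KCl medium, 1 um latex bead, 6 Vpp at 1 kHz,
    slip correction factor 0.02."""
    cfg = Config(
        chamber=ChamberGeometry2D(height=160e-6, electrode_width=100e-6, gap=200e-6),
        medium=Medium.kcl(1e-3),
        particle=ParticleSpec(radius=0.5e-6),
        drive=DriveSignal(v_pp=6.0, frequency=1e3),
        dl=DoubleLayerModel(),
        solver=SolverSettings(),
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
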