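"""Physical constants, model parameters and experiment-geometry helpers.

The package works in the dimensionless unit system of the lattice model:
lengths in units of the cell size/lattice spacing ``b̄`` (10 μm by default),
energies in units of ``k_B T``, concentrations in units of the saturation
concentration ``c_s``.  The film height is carried separately in millimetres,
because the dimensionless field amplitude factorises as ``κ · h[mm]`` with κ
the single parameter combining consumption, diffusivity and saturation.
Conversions to physical units happen only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PhysicalConstants",
    "ModelParams",
    "InvalidParameterError",
    "compute_kappa",
    "equivalent_height",
    "max_flux",
    "capillary_length",
    "meniscus_rise",
    "meniscus_profile",
    "meniscus_volume",
    "load_config",
    "resolve_params",
]


class InvalidParameterError(ValueError):
    """A physical constant or model parameter is out of its valid range."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Measured physical constants of the cell/medium system.

    Attributes
    ----------
    D : float
        Oxygen diffusivity in water, cm²/s.
    c_s_uM : float
        Oxygen saturation concentration of the medium, μM.
    q_max : float
        Maximal per-cell oxygen consumption rate, mol/s.
    b_um : float
        Cell size and lattice spacing b̄, μm.
    liquid_density : float
        Medium density, kg/m³ (capillary length).
    g : float
        Gravitational acceleration, m/s².
    gamma_mN_m : float
        Surface tension of the medium, mN/m.
    theta_deg : float
        Contact angle at the dish wall, degrees.
    """

    D: float = 2e-5
    c_s_uM: float = 250.0
    q_max: float = 4.2e-17
    b_um: float = 10.0
    liquid_density: float = 1000.0
    g: float = 9.81
    gamma_mN_m: float = 55.0
    theta_deg: float = 48.0

    def __post_init__(self) -> None:
        for name in ("D", "c_s_uM", "b_um", "liquid_density", "g", "gamma_mN_m"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.q_max < 0:
            raise InvalidParameterError("q_max must be non-negative")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise InvalidParameterError("theta_deg must lie in [0, 90]")

    @property
    def c_s_mol_cm3(self) -> float:
        """Saturation concentration in mol/cm³."""
        return self.c_s_uM * 1e-9

    @property
    def b_cm(self) -> float:
        """Lattice spacing in cm."""
        return self.b_um * 1e-4


@dataclass
class ModelParams:
    """Parameters of the lattice model (dimensionless unless suffixed).

    ``kappa`` defaults to 0.85/1.2: the bare field parameter κ = 0.85 reduced
    by a factor 1.2 to compensate for the effective two-dimensional treatment
    of multilayer aggregates.  ``heaviside_width`` is the smoothing width (in
    units of c_s) of the aerotaxis onset step; the step form itself is an
    artifact choice, see :mod:`oxyphase.lattice`.
    """

    epsilon: float = 0.15
    chi: float = 2.0
    c_aer: float = 0.1
    c_csm: float = 0.02
    eta_max: int = 4
    kappa: float = 0.85 / 1.2
    h_mm: float = 1.0
    L: int = 100
    T_sim: int = 1_000_000
    mean_density: float = 1.0
    seed: int = 0
    heaviside_width: float = 0.01
    b_um: float = 10.0

    def __post_init__(self) -> None:
        if self.eta_max < 1:
            raise InvalidParameterError("eta_max must be >= 1")
        if not 0.0 < self.c_csm < self.c_aer < 1.0:
            raise InvalidParameterError("need 0 < c_csm < c_aer < 1")
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be positive")
        if self.h_mm <= 0:
            raise InvalidParameterError("h_mm must be positive")
        if self.L < 1:
            raise InvalidParameterError("L must be >= 1")
        if self.mean_density > self.eta_max:
            raise InvalidParameterError("mean_density cannot exceed eta_max")
        if self.mean_density < 0:
            raise InvalidParameterError("mean_density must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(round(self.mean_density * self.L**2))

    def replace(self, **kw: Any) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def compute_kappa(pc: PhysicalConstants) -> float:
    """Dimensionless field parameter κ per millimetre of film height.

    κ = q_max / (b̄² c_s D) × 10⁻³ evaluated in SI units (b̄ in m, c_s in
    mol/m³, D in m²/s); the 10⁻³ converts the per-metre result to per-mm so
    that the field amplitude is κ·h with h in millimetres.  Defaults give
    0.84 with the default constants (0.85 when rounded to two figures).
    """
    b_m = pc.b_um * 1e-6
    c_s = pc.c_s_uM * 1e-3          # μM -> mol/m³
    D = pc.D * 1e-4                 # cm²/s -> m²/s
    return pc.q_max / (b_m**2 * c_s * D) * 1e-3


def equivalent_height(h_mm: float, o2_fraction: float,
                      reference_fraction: float = 0.21) -> float:
    """Equivalent film height h_eq = h·c_s/c_s′ under Henry's law.

    A lower oxygen partial pressure lowers the saturation concentration
    proportionally, which is equivalent to a thicker film at the reference
    atmosphere.
    """
    if o2_fraction <= 0 or reference_fraction <= 0:
        raise InvalidParameterError("oxygen fractions must be positive")
    if h_mm <= 0:
        raise InvalidParameterError("h_mm must be positive")
    return h_mm * reference_fraction / o2_fraction


def max_flux(h_mm: float, pc: PhysicalConstants = PhysicalConstants()) -> float:
    """Maximal diffusive oxygen flux j_m = D·c_s/h, in mol cm⁻² s⁻¹."""
    if h_mm <= 0:
        raise InvalidParameterError("h_mm must be positive")
    return pc.D * pc.c_s_mol_cm3 / (h_mm * 0.1)


def capillary_length(pc: PhysicalConstants = PhysicalConstants()) -> float:
    """Capillary length L_c = sqrt(γ/ρg), in mm."""
    lc_m = math.sqrt(pc.gamma_mN_m * 1e-3 / (pc.liquid_density * pc.g))
    return lc_m * 1e3


def meniscus_rise(pc: PhysicalConstants = PhysicalConstants()) -> float:
    """Meniscus height at the wall, δh(0) = L_c·sqrt(2(1−sinθ)), in mm."""
    return capillary_length(pc) * math.sqrt(2.0 * (1.0 - math.sin(math.radians(pc.theta_deg))))


def meniscus_profile(x_mm, h_mm: float,
                     pc: PhysicalConstants = PhysicalConstants()):
    """Small-slope meniscus profile h(x) = h + δh(0)·exp(−x/L_c), in mm.

    ``x_mm`` is the distance from the dish wall; scalar or array.
    """
    import numpy as np

    if h_mm <= 0:
        raise InvalidParameterError("h_mm must be positive")
    x = np.asarray(x_mm, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("x must be >= 0")
    return h_mm + meniscus_rise(pc) * np.exp(-x / capillary_length(pc))


def meniscus_volume(perimeter_mm: float,
                    pc: PhysicalConstants = PhysicalConstants(),
                    integrated: bool = True) -> float:
    """Meniscus volume correction, mm³.

    With ``integrated=True`` (default) returns 𝒫·δh(0)·L_c, the integral of
    the exponential rise along the wall, which is dimensionally a volume.
    With ``integrated=False`` returns the bare product 𝒫·δh(0) (an area),
    kept for comparison with protocols that use it directly.
    """
    v = perimeter_mm * meniscus_rise(pc)
    if integrated:
        v *= capillary_length(pc)
    return v


# -- configuration files ------------------------------------------------------

def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML mapping of parameter overrides."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise InvalidParameterError("config file must contain a mapping")
    return dict(data)


def resolve_params(config: Mapping[str, Any] | None = None,
                   **overrides: Any) -> ModelParams:
    """Build :class:`ModelParams` from a config mapping plus keyword overrides.

    Overrides with value ``None`` are ignored so CLI flags can be passed
    through unconditionally.
    """
    merged: dict[str, Any] = {}
    if config:
        merged.update(config)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(merged) - valid
    if unknown:
        raise InvalidParameterError(f"unknown parameter(s): {sorted(unknown)}")
    return ModelParams(**merged)
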