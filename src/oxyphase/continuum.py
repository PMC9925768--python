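"""Continuum prediction of the aggregate size from oxygen depletion.

The aggregate is idealised as a disk of radius ``a`` and projected density
ρ_a at the bottom of a cylindrical Wigner–Seitz-like cell of radius ``b``
(surface fraction φ = a²/b², maximal value φ_max = ρ̄/ρ_a), under a liquid
film of height ``h`` saturated at its top surface.  The background gas of
cells, density ρ_b = ρ̄ − φ·ρ_a, covers the whole substrate — including
under the aggregate — so that φ = φ_max corresponds exactly to an empty
background.  Every cell consumes at the maximal rate q, giving the bottom
flux j(r) = q·(ρ_b + ρ_a·1_{r<a}).

The steady diffusion problem in the cell (no lateral flux at r = b,
c = c_s at z = h) has the Bessel-series solution

    1 − c(0,0)/c_s = (q/(D c_s)) · [ ρ̄·h + ρ_a·a·S(√φ, h/b) ],
    S(u, v) = Σ_n 2 J1(μ_n u) tanh(μ_n v) / (μ_n² J0(μ_n)²),

with μ_n the positive zeros of J1.  The preferred aggregate size is the
radius at which the minimal concentration c(0,0) reaches the critical
value ĉ; it exists only for film heights between h_min = ξDc_s/(qρ_a) and
h_max = ξDc_s/(qρ̄), ξ = 1 − ĉ/c_s.  When the mean density itself follows
from oxygen-limited growth, ρ̄ = ξ_div·Dc_s/(q·h), the size condition
collapses to a·S = (Δξ/ξ)·h_min at every height, Δξ = ξ − ξ_div.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1, jn_zeros

from .params import InvalidParameterError, PhysicalConstants

__all__ = [
    "ContinuumParams",
    "ContinuumGeometry",
    "min_concentration",
    "psi_value",
    "bessel_depletion_sum",
    "density_from_height",
    "height_bounds",
    "solve_size_fixed_density",
    "solve_size_coupled",
]

_N_MODES = 4000
_MU = jn_zeros(1, _N_MODES)
_J0MU2 = j0(_MU) ** 2
_SERIES_WEIGHT = 2.0 * _MU ** -2 / _J0MU2


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the minimal model (densities in cm⁻², heights in mm)."""

    pc: PhysicalConstants = PhysicalConstants()
    rho_a: float = 2e6
    c_hat: float = 0.01     # critical concentration, units of c_s
    xi_div: float = 0.95    # 1 − c_div/c_s

    def __post_init__(self) -> None:
        if not 0.0 < self.c_hat < 1.0:
            raise InvalidParameterError("c_hat/c_s must lie in (0, 1)")
        if not 0.0 < self.xi_div <= self.xi:
            raise InvalidParameterError("need 0 < xi_div <= xi")
        if self.rho_a <= 0:
            raise InvalidParameterError("rho_a must be positive")

    @property
    def xi(self) -> float:
        return 1.0 - self.c_hat

    @property
    def delta_xi(self) -> float:
        return self.xi - self.xi_div

    @property
    def Dcs(self) -> float:
        """D·c_s in mol cm⁻¹ s⁻¹."""
        return self.pc.D * self.pc.c_s_mol_cm3

    @property
    def q(self) -> float:
        return self.pc.q_max


@dataclass(frozen=True)
class ContinuumGeometry:
    """Disk-in-cylinder geometry: radii in μm, height in mm, densities cm⁻²."""

    a_um: float
    b_um: float
    h_mm: float
    rho_bar: float
    rho_a: float = 2e6

    def __post_init__(self) -> None:
        if not 0.0 < self.a_um < self.b_um:
            raise InvalidParameterError("need 0 < a < b")
        if self.h_mm <= 0:
            raise InvalidParameterError("h must be positive")
        if self.rho_b < -1e-9 * self.rho_a:
            raise InvalidParameterError("background density would be negative "
                                        "(phi exceeds phi_max)")

    @property
    def phi(self) -> float:
        return (self.a_um / self.b_um) ** 2

    @property
    def phi_max(self) -> float:
        return self.rho_bar / self.rho_a

    @property
    def rho_b(self) -> float:
        """Background density from conservation, ρ_b = ρ̄ − φ·ρ_a."""
        return self.rho_bar - self.phi * self.rho_a


def bessel_depletion_sum(u: float, v: float) -> float:
    """S(u, v) = Σ_n 2 J1(μ_n u) tanh(μ_n v)/(μ_n² J0(μ_n)²).

    ``u`` = a/b = √φ, ``v`` = h/b (``np.inf`` allowed: tanh saturates).
    The oscillating tail is handled by averaging the last two partial sums.
    """
    if not 0.0 < u < 1.0:
        raise InvalidParameterError("u = sqrt(phi) must lie in (0, 1)")
    if v <= 0:
        raise InvalidParameterError("v = h/b must be positive")
    if math.isinf(v):
        t = j1(_MU * u) * _SERIES_WEIGHT
    else:
        t = j1(_MU * u) * np.tanh(np.minimum(_MU * v, 60.0)) * _SERIES_WEIGHT
    s = np.cumsum(t)
    return float(0.5 * (s[-1] + s[-2]))


def min_concentration(geom: ContinuumGeometry,
                      params: ContinuumParams = ContinuumParams()) -> float:
    """Minimal oxygen concentration c(0,0), at the aggregate centre, in c_s units."""
    h_cm = geom.h_mm * 0.1
    a_cm = geom.a_um * 1e-4
    b_cm = geom.b_um * 1e-4
    S = bessel_depletion_sum(a_cm / b_cm, h_cm / b_cm)
    f00 = (params.q / params.Dcs) * (geom.rho_bar * h_cm + geom.rho_a * a_cm * S)
    return 1.0 - f00


def psi_value(sqrt_phi: float, ratio: float,
              params: ContinuumParams = ContinuumParams(),
              rho_bar: float = 1e6) -> float:
    """ψ(√φ, (h/a)√φ) as defined by rearranging the size condition.

    ψ is the factor for which (a/h)·ψ = (ξ·j_m(h)/q − ρ̄)/(ρ_a − ρ̄) at the
    geometry where c(0,0) = ĉ; for this boundary-value problem it evaluates
    in closed form to ρ_a·S(√φ, ratio·√φ... i.e. S at v = h/b)/(ρ_a − ρ̄),
    independent of the absolute scale.  ``ratio`` = (h/a)·√φ = h/b may be
    ``np.inf`` (thick-film limit).
    """
    if rho_bar >= params.rho_a:
        raise InvalidParameterError("rho_bar must be below rho_a")
    return params.rho_a * bessel_depletion_sum(sqrt_phi, ratio) / (params.rho_a - rho_bar)


def density_from_height(h_mm: float,
                        params: ContinuumParams = ContinuumParams()) -> float:
    """Oxygen-limited mean density ρ̄_exp = ξ_div·D·c_s/(q·h), in cm⁻²."""
    if h_mm <= 0:
        raise InvalidParameterError("h must be positive")
    return params.xi_div * params.Dcs / (params.q * h_mm * 0.1)


def height_bounds(rho_bar: float,
                  params: ContinuumParams = ContinuumParams()) -> tuple[float, float]:
    """(h_min, h_max) in mm between which finite aggregates exist."""
    if not 0.0 < rho_bar < params.rho_a:
        raise InvalidParameterError("need 0 < rho_bar < rho_a")
    h_min = params.xi * params.Dcs / (params.q * params.rho_a) * 10.0
    h_max = params.xi * params.Dcs / (params.q * rho_bar) * 10.0
    return h_min, h_max


def solve_size_fixed_density(rho_bar: float, h_mm: float, phi: float,
                             params: ContinuumParams = ContinuumParams(),
                             rtol: float = 1e-4) -> float | Literal["continuous", "none"]:
    """Aggregate radius (μm) at which c(0,0) = ĉ, at fixed mean density.

    Returns ``"continuous"`` when the film is at or below the thickness at
    which even an unbounded aggregate stays above ĉ, and ``"none"`` at or
    above h_max where a vanishing aggregate already drops below ĉ.
    """
    if not 0.0 < phi <= rho_bar / params.rho_a + 1e-12:
        raise InvalidParameterError("need 0 < phi <= phi_max = rho_bar/rho_a")
    if not 0.0 < rho_bar < params.rho_a:
        raise InvalidParameterError("need 0 < rho_bar < rho_a")
    u = math.sqrt(phi)
    h_cm = h_mm * 0.1
    pref = params.q / params.Dcs
    rho_b = rho_bar - phi * params.rho_a

    def depletion(a_cm: float) -> float:
        b_cm = a_cm / u
        S = bessel_depletion_sum(u, h_cm / b_cm)
        return pref * (rho_bar * h_cm + params.rho_a * a_cm * S) - params.xi

    if depletion(1e-12) >= 0.0:
        return "none"
    # a -> inf at fixed phi: the whole substrate consumes at rho_a + rho_b
    f_inf = pref * h_cm * (params.rho_a + rho_b)
    if f_inf <= params.xi:
        return "continuous"
    a_hi = h_cm
    while depletion(a_hi) < 0.0:
        a_hi *= 2.0
        if a_hi > 1e3:  # pragma: no cover - guarded by f_inf check
            raise RuntimeError("no sign change found for the size root")
    a_cm = brentq(depletion, 1e-12, a_hi, rtol=rtol)
    return float(a_cm * 1e4)


def solve_size_coupled(h_mm: float, phi_frac: float = 1.0,
                       params: ContinuumParams = ContinuumParams(),
                       rtol: float = 1e-4) -> float | Literal["continuous", "none"]:
    """Aggregate radius (μm) with the mean density coupled to the height.

    Substitutes ρ̄ = ρ̄_exp(h) (oxygen-limited growth) into the size
    condition; ``phi_frac`` is the surface fraction as a fraction of the
    height-dependent φ_max.  For Δξ > 0 a finite size exists at every
    height above h_min·ξ_div/ξ, approaching (Δξ/ξ)·h_min / S(√φ, ∞) for
    thick films.
    """
    if not 0.0 < phi_frac <= 1.0:
        raise InvalidParameterError("phi_frac must lie in (0, 1]")
    rho_bar = density_from_height(h_mm, params)
    if rho_bar >= params.rho_a:
        return "continuous"
    phi = phi_frac * rho_bar / params.rho_a
    return solve_size_fixed_density(rho_bar, h_mm, phi, params, rtol)
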