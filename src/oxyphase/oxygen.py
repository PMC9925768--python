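"""Steady-state oxygen field above a consuming cell monolayer.

The liquid film (height h) is in contact with air at its top surface, where
the concentration is pinned at saturation, and absorbs a cell-consumption
flux at the bottom substrate.  For the shifted concentration f = 1 − c/c_s
the steady diffusion problem is a Laplace equation with a Dirichlet top and
a Neumann (flux) bottom boundary, which a lateral Fourier transform reduces
to one independent mode equation per in-plane wavevector k:

    f(k, z=0) = 𝒥(k) · tanh(h k)/(h k) · κ · h[mm],

with 𝒥 the dimensionless per-site consumption map, κ the field parameter
(:func:`oxyphase.params.compute_kappa`) and h expressed in lattice units
inside the tanh kernel.  Lateral boundary conditions are periodic.  The
per-cell consumption q = tanh(c/c_csm) depends on the local concentration,
so field and consumption are solved together by Anderson-accelerated
fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InvalidParameterError, ModelParams

__all__ = [
    "SurfaceOxygenField",
    "ConsumptionState",
    "UnphysicalRegimeError",
    "ConvergenceError",
    "consumption_rate",
    "site_flux_map",
    "surface_kernel",
    "depth_kernel",
    "solve_surface_field",
    "field_at_depth",
    "self_consistent_solve",
]


class UnphysicalRegimeError(RuntimeError):
    """The solved field implies a negative oxygen concentration somewhere."""


class ConvergenceError(RuntimeError):
    """The consumption/field fixed point did not converge."""

    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"fixed point not converged after {iterations} iterations "
            f"(residual {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


@dataclass
class SurfaceOxygenField:
    """Shifted concentration f = 1 − c/c_s at the substrate plus gradients.

    ``grad_x``/``grad_y`` are the in-plane components of ∇c (in units of c_s
    per lattice spacing), computed spectrally.
    """

    f: np.ndarray
    grad_x: np.ndarray
    grad_y: np.ndarray

    @property
    def c(self) -> np.ndarray:
        return 1.0 - self.f

    def validate(self) -> "SurfaceOxygenField":
        if np.any(self.f >= 1.0):
            raise UnphysicalRegimeError(
                "f >= 1 somewhere: negative oxygen concentration"
            )
        return self


@dataclass
class ConsumptionState:
    """Per-site rescaled consumption q ∈ [0,1] (shared by co-located cells).

    ``stiff`` records whether the last solve needed the Newton fallback, so
    consecutive solves in an anoxic regime skip the futile fast path.
    """

    q: np.ndarray
    residual: float = 0.0
    iterations: int = 0
    stiff: bool = False
    stiff_streak: int = 0


def consumption_rate(c, c_csm: float):
    """Rescaled per-cell consumption q = tanh(c/c_csm).

    Nearly constant (≈1) above c_csm, approximately linear below it.
    ``c`` is in units of c_s; scalar or array.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentration must be non-negative")
    out = np.tanh(c / c_csm)
    return out if out.ndim else float(out)


def site_flux_map(eta: np.ndarray, consumption: ConsumptionState | np.ndarray) -> np.ndarray:
    """Per-site dimensionless consumption map 𝒥 = η·q.

    Cells on a site share one concentration, hence one q; their
    contributions add.
    """
    q = consumption.q if isinstance(consumption, ConsumptionState) else np.asarray(consumption)
    if q.shape != eta.shape:
        raise ValueError(f"occupancy {eta.shape} and consumption {q.shape} shapes differ")
    return eta * q


from functools import lru_cache


@lru_cache(maxsize=32)
def _k_grids_cached(L: int):
    kx = 2.0 * np.pi * np.fft.fftfreq(L)
    ky = 2.0 * np.pi * np.fft.rfftfreq(L)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    KX.setflags(write=False)
    KY.setflags(write=False)
    return KX, KY


def _k_grids(L: int):
    return _k_grids_cached(L)


@lru_cache(maxsize=32)
def _grad_kernels(L: int):
    """ik multipliers with the unpaired Nyquist column zeroed (real gradient)."""
    kx, ky = _k_grids_cached(L)
    if L % 2 == 0:
        kx = np.where(np.isclose(np.abs(kx), np.pi), 0.0, kx)
        ky = np.where(np.isclose(np.abs(ky), np.pi), 0.0, ky)
    gx, gy = 1j * kx, 1j * ky
    gx.setflags(write=False)
    gy.setflags(write=False)
    return gx, gy


def surface_kernel(L: int, h_mm: float, kappa: float, b_um: float = 10.0) -> np.ndarray:
    """Spectral kernel K(k) = tanh(h̃k)/(h̃k) · κ·h_mm on the rfft2 grid.

    h̃ is the film height in lattice units; K(0) = κ·h_mm is the analytic
    k→0 limit (uniform-consumption mean field).  Cached per (L, h, κ, b̄);
    the returned array is read-only.
    """
    return _surface_kernel_cached(L, float(h_mm), float(kappa), float(b_um))


@lru_cache(maxsize=64)
def _surface_kernel_cached(L: int, h_mm: float, kappa: float, b_um: float) -> np.ndarray:
    if h_mm <= 0:
        raise InvalidParameterError("h_mm must be positive")
    h_lat = h_mm * 1000.0 / b_um
    kx, ky = _k_grids(L)
    k = np.hypot(kx, ky)
    hk = h_lat * k
    with np.errstate(invalid="ignore", divide="ignore"):
        kern = np.where(hk > 0, np.tanh(hk) / np.where(hk > 0, hk, 1.0), 1.0)
    kern = kern * kappa * h_mm
    kern.setflags(write=False)
    return kern


def depth_kernel(L: int, z: float, h_mm: float, kappa: float, b_um: float = 10.0) -> np.ndarray:
    """Kernel at relative depth z ∈ [0,1] (z=0 substrate, z=1 air interface).

    Per mode sinh(h̃k(1−z))/(h̃k cosh(h̃k)) · κ·h_mm, evaluated in
    overflow-safe exponential form; k→0 limit is (1−z)·κ·h_mm.
    """
    if not 0.0 <= z <= 1.0:
        raise InvalidParameterError("z must lie in [0, 1]")
    h_lat = h_mm * 1000.0 / b_um
    kx, ky = _k_grids(L)
    k = np.hypot(kx, ky)
    hk = h_lat * k
    # sinh(A(1-z))/cosh(A) = (exp(-Az) - exp(-A(2-z))) / (1 + exp(-2A))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.exp(-hk * z) - np.exp(-hk * (2.0 - z))
        ratio = num / (1.0 + np.exp(-2.0 * hk))
        kern = np.where(hk > 0, ratio / np.where(hk > 0, hk, 1.0), 1.0 - z)
    return kern * kappa * h_mm


def _solve_f(flux: np.ndarray, kern: np.ndarray) -> np.ndarray:
    L = flux.shape[0]
    return np.fft.irfft2(np.fft.rfft2(flux) * kern, s=(L, L))


def solve_surface_field(flux: np.ndarray, h_mm: float, kappa: float,
                        b_um: float = 10.0, check: bool = True) -> SurfaceOxygenField:
    """Solve for the substrate oxygen field given a consumption map.

    Returns f, and ∇c computed spectrally (∇c = −∇f in c_s units).  With
    ``check=True`` a field with f ≥ 1 anywhere (negative concentration)
    raises :class:`UnphysicalRegimeError` instead of being returned.
    """
    flux = np.asarray(flux, dtype=float)
    if not np.all(np.isfinite(flux)):
        raise InvalidParameterError("flux map must be finite")
    L = flux.shape[0]
    kern = surface_kernel(L, h_mm, kappa, b_um)
    fk = np.fft.rfft2(flux) * kern
    f = np.fft.irfft2(fk, s=(L, L))
    gx_k, gy_k = _grad_kernels(L)
    grad_x = -np.fft.irfft2(gx_k * fk, s=(L, L))
    grad_y = -np.fft.irfft2(gy_k * fk, s=(L, L))
    field = SurfaceOxygenField(f=f, grad_x=grad_x, grad_y=grad_y)
    return field.validate() if check else field


def field_at_depth(flux: np.ndarray, z: float, h_mm: float, kappa: float,
                   b_um: float = 10.0) -> np.ndarray:
    """Shifted concentration at relative height z above the substrate."""
    flux = np.asarray(flux, dtype=float)
    L = flux.shape[0]
    kern = depth_kernel(L, z, h_mm, kappa, b_um)
    return _solve_f(flux, kern)


def self_consistent_solve(eta: np.ndarray, params: ModelParams,
                          warm_start: ConsumptionState | None = None,
                          tol: float = 1e-8, max_iter_fast: int = 12,
                          max_iter: int = 200) -> tuple[SurfaceOxygenField, ConsumptionState]:
    """Joint fixed point of the oxygen field and per-cell consumption.

    Iterates q → tanh(c(q)/c_csm) to max|Δq| < ``tol``.  An Anderson-
    accelerated fixed-point loop handles the common saturated-consumption
    regime in a few warm-started steps.  Strongly anoxic states make the
    bare Picard map expansive (the slope of tanh(c/c_csm) around c ≈ c_csm,
    times the field response, exceeds unity) and the accelerated iteration
    stalls; those fall through to an inexact Newton solve whose
    Jacobian-vector products (I + diag(tanh′/c_csm)·K∗(η·)) are applied
    analytically in Fourier space.  A warm start that needed Newton marks
    the state stiff and later solves go straight to Newton, re-probing the
    fast path periodically.

    The q grid is defined on every site (empty sites carry the consumption
    a cell arriving there would adopt; they contribute nothing to the flux
    η·q), keeping warm starts continuous across cell moves.  During
    iteration the concentration is floored at zero for evaluating tanh; the
    final field must imply strictly positive concentrations or
    :class:`UnphysicalRegimeError` is raised.  Raises
    :class:`ConvergenceError` if the iteration caps are exhausted.
    """
    eta = np.asarray(eta)
    occupied = eta > 0
    if not occupied.any():
        zeros = np.zeros_like(eta, dtype=float)
        field = SurfaceOxygenField(f=zeros, grad_x=zeros.copy(), grad_y=zeros.copy())
        return field, ConsumptionState(q=zeros.copy(), residual=0.0, iterations=0)

    warm_ok = warm_start is not None and warm_start.q.shape == eta.shape
    q = warm_start.q.copy() if warm_ok else np.ones_like(eta, dtype=float)
    kern = surface_kernel(eta.shape[0], params.h_mm, params.kappa, params.b_um)
    L = eta.shape[0]
    inv_csm = 1.0 / params.c_csm

    def conv(v: np.ndarray) -> np.ndarray:
        return np.fft.irfft2(np.fft.rfft2(eta * v) * kern, s=(L, L))

    def picard_map(qq: np.ndarray) -> np.ndarray:
        return np.tanh(np.maximum(1.0 - conv(qq), 0.0) * inv_csm)

    stiff = bool(warm_ok and warm_start.stiff
                 and warm_start.stiff_streak % 64 != 0)
    streak = warm_start.stiff_streak if warm_ok else 0
    q_start = q.copy()
    residual = np.inf
    it = 0

    if not stiff:
        # fast path: Anderson-accelerated fixed-point iteration (depth 3)
        depth = 3
        hist_q: list[np.ndarray] = []
        hist_r: list[np.ndarray] = []
        for it in range(1, max_iter_fast + 1):
            g = picard_map(q)
            r = g - q
            residual = float(np.max(np.abs(r)))
            if residual < tol:
                break
            hist_q.append(q.ravel().copy())
            hist_r.append(r.ravel().copy())
            if len(hist_q) > depth:
                hist_q.pop(0)
                hist_r.pop(0)
            if len(hist_q) >= 2:
                dR = np.diff(np.stack(hist_r, axis=0), axis=0).T
                dQ = np.diff(np.stack(hist_q, axis=0), axis=0).T
                normal = dR.T @ dR
                reg = 1e-10 * max(np.trace(normal), 1e-30)
                try:
                    gamma = np.linalg.solve(normal + reg * np.eye(dR.shape[1]),
                                            dR.T @ r.ravel())
                    q = np.clip((q.ravel() + r.ravel() - (dQ + dR) @ gamma)
                                .reshape(eta.shape), 0.0, 1.0)
                except np.linalg.LinAlgError:
                    q = g
            else:
                q = g

    used_newton = False
    if residual >= tol:
        from scipy.sparse.linalg import LinearOperator, lgmres

        q = q_start
        used_newton = True
        for it_newton in range(1, max_iter + 1):
            c_raw = 1.0 - conv(q)
            g = np.tanh(np.maximum(c_raw, 0.0) * inv_csm)
            F = q - g
            residual = float(np.max(np.abs(F)))
            if residual < tol:
                break
            weight = np.where(c_raw > 0, (1.0 - g * g) * inv_csm, 0.0)

            def jv(v: np.ndarray) -> np.ndarray:
                vv = v.reshape(eta.shape)
                return (vv + weight * conv(vv)).ravel()

            # mean-field preconditioner: the ill-conditioned directions are
            # long-wavelength collective modes, well captured by replacing
            # weight and occupancy with their means, which is diagonal in
            # Fourier space
            wbar = float(weight[occupied].mean())
            ebar = float(eta[occupied].mean()) * float(occupied.mean())
            pre = 1.0 / (1.0 + wbar * ebar * kern)

            def mv(v: np.ndarray) -> np.ndarray:
                vv = v.reshape(eta.shape)
                return np.fft.irfft2(np.fft.rfft2(vv) * pre, s=(L, L)).ravel()

            A = LinearOperator((L * L, L * L), matvec=jv)
            M = LinearOperator((L * L, L * L), matvec=mv)
            delta, _ = lgmres(A, -F.ravel(), M=M, rtol=0.05, atol=0.0,
                              maxiter=50)
            delta = delta.reshape(eta.shape)
            # backtracking on the residual max-norm guards against the
            # overshoot of full steps across the tanh saturation knee
            alpha = 1.0
            for _ in range(8):
                q_try = np.clip(q + alpha * delta, 0.0, 1.0)
                r_try = float(np.max(np.abs(q_try - picard_map(q_try))))
                if r_try < residual:
                    break
                alpha *= 0.5
            q = q_try
        else:
            raise ConvergenceError(residual, max_iter)
        it = max_iter_fast + it_newton

    streak = streak + 1 if used_newton else 0
    field = solve_surface_field(eta * q, params.h_mm, params.kappa, params.b_um,
                                check=True)
    return field, ConsumptionState(q=q, residual=residual, iterations=it,
                                   stiff=used_newton, stiff_streak=streak)
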