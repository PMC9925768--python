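"""Shared fixtures and independent finite-difference oracles.

The oracles discretise the same boundary-value problems as the package's
spectral/series solvers but by sparse finite differences, so spectral and
FD routes only share the problem statement, not the numerics.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import splu


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fd_surface_field_factory(L: int, h_mm: float, kappa: float,
                             b_um: float = 10.0, dz: float = 1.0):
    """3D finite-difference solver for the film diffusion problem.

    Periodic lateral boundaries, Dirichlet f=0 at the air interface,
    Neumann consumption flux at the substrate; lateral spacing is one
    lattice unit, vertical spacing ``dz`` (lattice units).  Returns a
    function mapping a flux map J to the substrate field f, with the
    factorisation reused across calls.
    """
    h_lat = h_mm * 1000.0 / b_um
    nz = int(round(h_lat / dz))
    # lateral periodic 1D Laplacian
    e = np.ones(L)
    lap1 = sp.diags([e[:-1], -2 * e, e[:-1]], [-1, 0, 1], format="lil")
    lap1[0, -1] = 1.0
    lap1[-1, 0] = 1.0
    lap1 = lap1.tocsr()
    eye_L = sp.identity(L, format="csr")
    lap_xy = sp.kron(lap1, eye_L) + sp.kron(eye_L, lap1)
    # vertical operator: unknowns z-index 0..nz-1, f=0 at nz (top),
    # ghost-node Neumann at 0 (d_z f = -amp*J)
    main = -2.0 * np.ones(nz)
    lower = np.ones(nz - 1)
    upper = np.ones(nz - 1)
    lap_z = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    lap_z[0, 1] = 2.0
    lap_z = lap_z.tocsr() / dz**2
    eye_xy = sp.identity(L * L, format="csr")
    eye_z = sp.identity(nz, format="csr")
    A = sp.kron(lap_xy, eye_z) + sp.kron(eye_xy, lap_z)
    # weighting the ghost-node (bottom) rows by 1/2 symmetrises the operator,
    # so conjugate gradients applies to the (negated) system
    w = np.ones(nz)
    w[0] = 0.5
    D = sp.diags(np.tile(w, L * L))
    A_sym = (-(D @ A)).tocsr()
    amp = kappa * h_mm / h_lat

    def solve(J: np.ndarray) -> np.ndarray:
        from scipy.sparse.linalg import cg

        rhs = np.zeros((L * L, nz))
        rhs[:, 0] = -2.0 * amp * J.ravel() / dz * w[0]
        f, info = cg(A_sym, -rhs.ravel(), rtol=1e-12, atol=0.0, maxiter=20000)
        assert info == 0, f"CG did not converge (info={info})"
        return f.reshape(L, L, nz)[:, :, 0]

    return solve


def fd_axisymmetric_min_concentration(a_cm: float, b_cm: float, h_cm: float,
                                      flux_in: float, flux_out: float,
                                      Dcs: float, Nr: int = 160,
                                      Nz: int = 160) -> float:
    """Axisymmetric FD solve of the disk-aggregate depletion problem.

    Cylinder 0<r<b, 0<z<h; consumption flux ``flux_in`` (mol cm⁻² s⁻¹) for
    r<a and ``flux_out`` outside, saturation at z=h, no lateral flux at
    r=b.  Returns c(0,0)/c_s.
    """
    dr = b_cm / Nr
    dz = h_cm / Nz
    r = np.arange(Nr + 1) * dr
    nunk = (Nr + 1) * Nz

    def idx(i, k):
        return i * Nz + k

    rows, cols, vals = [], [], []
    rhs = np.zeros(nunk)
    jflux = np.where(r < a_cm, flux_in, flux_out) / Dcs
    for i in range(Nr + 1):
        for k in range(Nz):
            m = idx(i, k)
            if i == 0:
                rows += [m, m]
                cols += [idx(0, k), idx(1, k)]
                vals += [-4 / dr**2, 4 / dr**2]
            elif i == Nr:
                rows += [m, m]
                cols += [idx(Nr, k), idx(Nr - 1, k)]
                vals += [-2 / dr**2, 2 / dr**2]
            else:
                rp, rm = r[i] + dr / 2, r[i] - dr / 2
                rows += [m, m, m]
                cols += [idx(i + 1, k), idx(i - 1, k), idx(i, k)]
                vals += [rp / (r[i] * dr**2), rm / (r[i] * dr**2),
                         -(rp + rm) / (r[i] * dr**2)]
            if k == 0:
                rows += [m, m]
                cols += [idx(i, 1), idx(i, 0)]
                vals += [2 / dz**2, -2 / dz**2]
                rhs[m] -= 2 * jflux[i] / dz
            elif k == Nz - 1:
                rows += [m, m]
                cols += [idx(i, k - 1), idx(i, k)]
                vals += [1 / dz**2, -2 / dz**2]
            else:
                rows += [m, m, m]
                cols += [idx(i, k + 1), idx(i, k - 1), idx(i, k)]
                vals += [1 / dz**2, 1 / dz**2, -2 / dz**2]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(nunk, nunk))
    f = splu(A.tocsc()).solve(rhs)
    return 1.0 - f[idx(0, 0)]


def smooth_flux_map(L: int, rng: np.random.Generator, eta_max: int = 4,
                    sigma: float = 3.0) -> np.ndarray:
    """Band-limited random consumption map in [0, eta_max]."""
    from scipy.ndimage import gaussian_filter

    J = gaussian_filter(rng.random((L, L)), sigma, mode="wrap")
    J -= J.min()
    if J.max() > 0:
        J *= eta_max / J.max()
    return J
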