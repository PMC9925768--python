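"""Cell-based lattice Monte Carlo of adhesion, aerotaxis and crowding.

Each cell occupies one site of an L×L periodic square lattice; a site holds
at most ``eta_max`` cells (an effective cap on aggregate thickness).  Two
cells in contact — on the same site or on Moore-neighbouring sites —
contribute an adhesion energy −ε, counted once per pair so that the move
energetics derive from a consistent Hamiltonian.  Below the onset
concentration ``c_aer`` a move also carries an aerotactic energy favouring
motion up the oxygen gradient, with logarithmic sensing (the gradient is
divided by the local concentration).  Moves to one of the 8 Moore
neighbours are proposed once per cell per sweep and accepted by the
Metropolis criterion at unit temperature; the oxygen field is frozen within
a sweep and re-solved self-consistently after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal

import numpy as np
from numba import njit

from . import aggregates as agg
from .oxygen import ConsumptionState, SurfaceOxygenField, self_consistent_solve
from .params import InvalidParameterError, ModelParams

__all__ = [
    "SimulationState",
    "Trajectory",
    "REJECT",
    "MOORE_OFFSETS",
    "adhesion_energy_site",
    "adhesion_delta",
    "aerotaxis_delta",
    "total_move_energy",
    "metropolis_accept",
    "total_adhesion_energy",
    "initialize_state",
    "mc_sweep",
    "run_simulation",
    "plateau_reached",
]

#: Sentinel energy encoding a definite rejection (target at full occupancy).
REJECT = np.inf

#: The 8 Moore displacement vectors, index-addressable by the proposal draw.
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass
class SimulationState:
    """Occupancy, cell coordinates, oxygen field and RNG of one realization."""

    eta: np.ndarray                  # L×L int64 occupancy
    cells: np.ndarray                # N×2 int64 site coordinates per cell
    field: SurfaceOxygenField
    consumption: ConsumptionState
    params: ModelParams
    rng: np.random.Generator
    sweep: int = 0

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


@dataclass
class Trajectory:
    """Time series of aggregate statistics recorded during a run."""

    sweeps: list = dc_field(default_factory=list)
    radius_um: list = dc_field(default_factory=list)
    n_aggregates: list = dc_field(default_factory=list)
    energy: list = dc_field(default_factory=list)
    snapshots: dict = dc_field(default_factory=dict)

    def record(self, sweep: int, a_um: float, n_agg: int, energy: float) -> None:
        if self.sweeps and sweep <= self.sweeps[-1]:
            raise ValueError("sweep indices must be strictly increasing")
        self.sweeps.append(sweep)
        self.radius_um.append(a_um)
        self.n_aggregates.append(n_agg)
        self.energy.append(energy)


# -- single-move energetics (reference implementations) -----------------------

def _moore_sum(eta: np.ndarray, i: int, j: int) -> int:
    L = eta.shape[0]
    total = 0
    for di, dj in MOORE_OFFSETS:
        total += eta[(i + di) % L, (j + dj) % L]
    return int(total)


def adhesion_energy_site(eta: np.ndarray, site: tuple[int, int],
                         epsilon: float) -> float:
    """Adhesion energy of one cell at ``site``: −ε·[η_m − 1 + Σ_Moore η]."""
    i, j = site
    if eta[i, j] < 1:
        raise InvalidParameterError("queried site holds no cell")
    return -epsilon * (eta[i, j] - 1 + _moore_sum(eta, i, j))


def adhesion_delta(eta: np.ndarray, source: tuple[int, int],
                   target: tuple[int, int], epsilon: float) -> float:
    """Adhesion energy change for moving one cell from source to target.

    Contacts of the mover are counted pairwise-once: before the move it has
    (η_m − 1) on-site partners plus the Moore neighbourhood; after the move
    the same count is taken around the target with the mover removed from
    the source.
    """
    i, j = source
    if eta[i, j] < 1:
        raise InvalidParameterError("source site holds no cell")
    before = eta[i, j] - 1 + _moore_sum(eta, i, j)
    work = eta.copy()
    work[i, j] -= 1
    i2, j2 = target
    after = work[i2, j2] + _moore_sum(work, i2, j2)
    return epsilon * (before - after)


def aerotaxis_delta(field: SurfaceOxygenField, source: tuple[int, int],
                    displacement: tuple[int, int], chi: float, c_aer: float,
                    width: float) -> float:
    """Aerotactic energy −χ·H[c_aer − c_m]·(∇c·Δr)/c_m of a proposed move.

    H is the smoothed step H(x) = (1 + tanh(x/w))/2; Δr is the displacement
    vector, so diagonal moves weight the gradient by their geometric dot
    product.
    """
    i, j = source
    c_m = float(field.c[i, j])
    if c_m <= 0:
        raise UnphysicalFieldError("non-positive concentration at source site")
    gate = 0.5 * (1.0 + np.tanh((c_aer - c_m) / width))
    directional = field.grad_x[i, j] * displacement[0] + field.grad_y[i, j] * displacement[1]
    return -chi * gate * directional / c_m


class UnphysicalFieldError(RuntimeError):
    """The frozen field presented a non-positive concentration."""


def total_move_energy(state: SimulationState, source: tuple[int, int],
                      displacement: tuple[int, int]) -> float:
    """ΔE = ΔE_adh + ΔE_aer + ΔE_occ; returns the REJECT sentinel at η_max."""
    p = state.params
    L = p.L
    target = ((source[0] + displacement[0]) % L, (source[1] + displacement[1]) % L)
    if state.eta[target] >= p.eta_max:
        return REJECT
    dE = adhesion_delta(state.eta, source, target, p.epsilon)
    if p.chi != 0.0:
        dE += aerotaxis_delta(state.field, source, displacement, p.chi,
                              p.c_aer, p.heaviside_width)
    return dE


def metropolis_accept(dE: float, u: float) -> bool:
    """Accept iff u < min[1, exp(−ΔE)] (unit energy k_BT = 1)."""
    if not np.isfinite(dE):
        return False
    return u < min(1.0, np.exp(-dE))


def total_adhesion_energy(eta: np.ndarray, epsilon: float) -> float:
    """System adhesion energy with each cell–cell contact counted once."""
    onsite = np.sum(eta * (eta - 1)) / 2.0
    moore = 0.0
    for di, dj in MOORE_OFFSETS:
        moore += np.sum(eta * np.roll(np.roll(eta, di, axis=0), dj, axis=1))
    return -epsilon * (onsite + moore / 2.0)


# -- jitted sweep kernel ------------------------------------------------------

@njit(cache=True)
def _sweep_kernel(eta, cells, order, dirs, us, offsets, eta_max, epsilon,
                  chi, c_aer, inv_width, c_grid, gx, gy, use_field):
    L = eta.shape[0]
    accepted = 0
    for n in range(order.shape[0]):
        idx = order[n]
        i = cells[idx, 0]
        j = cells[idx, 1]
        di = offsets[dirs[n], 0]
        dj = offsets[dirs[n], 1]
        i2 = (i + di) % L
        j2 = (j + dj) % L
        if eta[i2, j2] >= eta_max:
            continue
        # pairwise-once contact count of the mover, before vs after
        before = eta[i, j] - 1
        after = eta[i2, j2]
        for oo in range(8):
            oi = offsets[oo, 0]
            oj = offsets[oo, 1]
            before += eta[(i + oi) % L, (j + oj) % L]
        eta[i, j] -= 1
        for oo in range(8):
            oi = offsets[oo, 0]
            oj = offsets[oo, 1]
            after += eta[(i2 + oi) % L, (j2 + oj) % L]
        dE = epsilon * (before - after)
        if use_field and chi != 0.0:
            c_m = c_grid[i, j]
            gate = 0.5 * (1.0 + np.tanh((c_aer - c_m) * inv_width))
            dE += -chi * gate * (gx[i, j] * di + gy[i, j] * dj) / c_m
        if dE <= 0.0 or us[n] < np.exp(-dE):
            eta[i2, j2] += 1
            cells[idx, 0] = i2
            cells[idx, 1] = j2
            accepted += 1
        else:
            eta[i, j] += 1
    return accepted


def mc_sweep(state: SimulationState, update_field: bool = True) -> int:
    """One Monte Carlo sweep: one proposed move per cell, then field update.

    Cells are visited in a fresh random permutation; each receives a
    uniformly drawn Moore-neighbour proposal evaluated against the field
    frozen at the start of the sweep.  With ``update_field=False`` the
    field/consumption fixed point is skipped (adhesion-only dynamics).
    Returns the number of accepted moves.
    """
    p = state.params
    n = state.n_cells
    if n == 0:
        state.sweep += 1
        return 0
    rng = state.rng
    order = rng.permutation(n)
    dirs = rng.integers(0, 8, size=n)
    us = rng.random(n)
    accepted = _sweep_kernel(
        state.eta, state.cells, order, dirs, us, MOORE_OFFSETS,
        p.eta_max, p.epsilon, p.chi, p.c_aer, 1.0 / p.heaviside_width,
        state.field.c, state.field.grad_x, state.field.grad_y,
        update_field,
    )
    if update_field:
        state.field, state.consumption = self_consistent_solve(
            state.eta, p, warm_start=state.consumption
        )
    state.sweep += 1
    return int(accepted)


# -- initial conditions and the run loop --------------------------------------

def initialize_state(mode: Literal["random", "disk"], params: ModelParams,
                     rng: np.random.Generator | None = None,
                     update_field: bool = True) -> SimulationState:
    """Initial occupancy: uniformly random placements or one maximal disk.

    ``random`` drops N = round(ρ̄L²) cells uniformly over sites subject to
    the η_max cap; ``disk`` packs them at η = η_max in a centred disk (the
    boundary ring may be partially filled).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.L
    n = params.n_cells
    if n > params.eta_max * L**2:
        raise InvalidParameterError("requested cell count exceeds lattice capacity")
    eta = np.zeros((L, L), dtype=np.int64)
    cells = np.empty((n, 2), dtype=np.int64)
    if mode == "random":
        placed = 0
        while placed < n:
            m = n - placed
            ii = rng.integers(0, L, size=m)
            jj = rng.integers(0, L, size=m)
            for i, j in zip(ii, jj):
                if eta[i, j] < params.eta_max:
                    eta[i, j] += 1
                    cells[placed] = (i, j)
                    placed += 1
                    if placed == n:
                        break
    elif mode == "disk":
        centre = L / 2.0 - 0.5
        ii, jj = np.indices((L, L))
        r2 = (ii - centre) ** 2 + (jj - centre) ** 2
        order = np.argsort(r2, axis=None)
        placed = 0
        for flat in order:
            i, j = divmod(int(flat), L)
            add = min(params.eta_max, n - placed)
            eta[i, j] = add
            cells[placed:placed + add] = (i, j)
            placed += add
            if placed == n:
                break
    else:
        raise InvalidParameterError(f"unknown initialization mode {mode!r}")

    state = SimulationState(
        eta=eta, cells=cells,
        field=_uniform_field(L), consumption=ConsumptionState(q=np.zeros((L, L))),
        params=params, rng=rng,
    )
    if update_field and n > 0:
        state.field, state.consumption = self_consistent_solve(eta, params)
    return state


def _uniform_field(L: int) -> SurfaceOxygenField:
    z = np.zeros((L, L))
    return SurfaceOxygenField(f=z, grad_x=z.copy(), grad_y=z.copy())


def run_simulation(params: ModelParams, init: Literal["random", "disk"] = "random",
                   sweeps: int | None = None, cadence: int | None = None,
                   update_field: bool = True,
                   callback: Callable[[SimulationState], None] | None = None,
                   state: SimulationState | None = None,
                   snapshot_every: int | None = None) -> tuple[SimulationState, Trajectory]:
    """Run ``sweeps`` MC sweeps (default T_sim), recording the typical radius.

    The typical aggregate radius a = √(⟨A⟩/π)·b̄ is measured on sites with
    η ≥ 3 at the given cadence (default sweeps/200, at least 1).  An
    existing ``state`` may be passed to continue a run.
    """
    if state is None:
        state = initialize_state(init, params, update_field=update_field)
    sweeps = params.T_sim if sweeps is None else sweeps
    cadence = max(1, sweeps // 200) if cadence is None else cadence
    traj = Trajectory()
    _record(state, traj)
    for _ in range(sweeps):
        mc_sweep(state, update_field=update_field)
        if state.sweep % cadence == 0:
            _record(state, traj)
            if callback is not None:
                callback(state)
        if snapshot_every and state.sweep % snapshot_every == 0:
            traj.snapshots[state.sweep] = state.eta.copy()
    return state, traj


def _record(state: SimulationState, traj: Trajectory) -> None:
    aset = agg.label_lattice_aggregates(state.eta)
    if aset.components:
        a_um = agg.representative_radius(aset, b_um=state.params.b_um)
    else:
        a_um = 0.0
    traj.record(state.sweep, a_um, len(aset.components),
                total_adhesion_energy(state.eta, state.params.epsilon))


def plateau_reached(traj: Trajectory, rel_tol: float = 0.05,
                    window: int | None = None) -> bool:
    """Whether the radius series has saturated.

    Compares the means of the last two non-overlapping windows (default a
    quarter of the series each); plateau if they differ by < ``rel_tol``
    relative to their average.
    """
    a = np.asarray(traj.radius_um, dtype=float)
    if window is None:
        window = max(2, len(a) // 4)
    if len(a) < 2 * window:
        return False
    m1 = a[-2 * window:-window].mean()
    m2 = a[-window:].mean()
    denom = 0.5 * (abs(m1) + abs(m2))
    if denom == 0:
        return True
    return abs(m2 - m1) / denom < rel_tol
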