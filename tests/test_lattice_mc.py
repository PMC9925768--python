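"""Move energetics, Metropolis sampling and the sweep loop."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from oxyphase import (
    ModelParams,
    REJECT,
    SurfaceOxygenField,
    adhesion_delta,
    adhesion_energy_site,
    aerotaxis_delta,
    initialize_state,
    mc_sweep,
    metropolis_accept,
    run_simulation,
    total_adhesion_energy,
    total_move_energy,
)
from oxyphase.lattice import MOORE_OFFSETS, _sweep_kernel

EPS = 0.15


def uniform_field(L, c0=0.5):
    z = np.zeros((L, L))
    return SurfaceOxygenField(f=np.full((L, L), 1.0 - c0), grad_x=z, grad_y=z.copy())


class TestAdhesionEnergy:
    def test_isolated_cell(self):
        eta = np.zeros((5, 5), dtype=np.int64)
        eta[2, 2] = 1
        assert adhesion_energy_site(eta, (2, 2), EPS) == 0.0

    def test_two_cells_one_site(self):
        eta = np.zeros((5, 5), dtype=np.int64)
        eta[2, 2] = 2
        assert adhesion_energy_site(eta, (2, 2), EPS) == pytest.approx(-EPS)

    def test_centre_of_full_block(self):
        eta = np.zeros((7, 7), dtype=np.int64)
        eta[2:5, 2:5] = 4
        # eta_m - 1 + 8 neighbours at 4 = 3 + 32
        assert adhesion_energy_site(eta, (3, 3), EPS) == pytest.approx(-35 * EPS)

    def test_empty_site_rejected(self):
        from oxyphase import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            adhesion_energy_site(np.zeros((4, 4), dtype=np.int64), (1, 1), EPS)


class TestAdhesionDelta:
    def test_uniform_sea_is_flat(self):
        for eta0 in (1, 2, 3):
            eta = np.full((6, 6), eta0, dtype=np.int64)
            assert adhesion_delta(eta, (2, 2), (3, 3), EPS) == pytest.approx(0.0)

    def test_breaking_a_pair_costs_one_contact(self):
        eta = np.zeros((7, 7), dtype=np.int64)
        eta[0, 0] = eta[1, 0] = 1
        assert adhesion_delta(eta, (1, 0), (2, 0), EPS) == pytest.approx(EPS)

    def test_onsite_contact_exchanged_for_moore_contact(self):
        eta = np.zeros((7, 7), dtype=np.int64)
        eta[3, 3] = 2
        assert adhesion_delta(eta, (3, 3), (3, 4), EPS) == pytest.approx(0.0)

    def test_consistent_with_hamiltonian_difference(self, rng):
        # delta from the move must equal the difference of total energies
        from oxyphase.synthetic import synth_lattice

        for _ in range(20):
            eta = synth_lattice("random", L=6, n_cells=20, eta_max=4, rng=rng)
            occ = np.argwhere(eta > 0)
            i, j = occ[rng.integers(len(occ))]
            d = MOORE_OFFSETS[rng.integers(8)]
            i2, j2 = (i + d[0]) % 6, (j + d[1]) % 6
            if eta[i2, j2] >= 4:
                continue
            dE = adhesion_delta(eta, (i, j), (i2, j2), EPS)
            e_before = total_adhesion_energy(eta, EPS)
            eta2 = eta.copy()
            eta2[i, j] -= 1
            eta2[i2, j2] += 1
            assert dE == pytest.approx(total_adhesion_energy(eta2, EPS) - e_before)


class TestAerotaxisDelta:
    def test_uniform_field_is_neutral(self):
        field = uniform_field(8, c0=0.05)
        assert aerotaxis_delta(field, (2, 2), (1, 0), 2.0, 0.1, 0.01) == 0.0

    def test_suppressed_far_above_onset(self):
        L = 8
        gx = np.full((L, L), 0.3)
        field = SurfaceOxygenField(f=np.full((L, L), 0.5), grad_x=gx,
                                   grad_y=np.zeros((L, L)))
        # c = 0.5 = 5*c_aer: the smoothed gate leaves < 1e-3 of the drive
        dE = aerotaxis_delta(field, (2, 2), (1, 0), 2.0, 0.1, 0.01)
        assert abs(dE) < 2.0 * 1e-3 * 0.3 / 0.5

    def test_antisymmetric_in_displacement(self):
        L = 8
        field = SurfaceOxygenField(f=np.full((L, L), 0.98),
                                   grad_x=np.full((L, L), 0.02),
                                   grad_y=np.full((L, L), -0.01))
        up = aerotaxis_delta(field, (3, 3), (1, -1), 2.0, 0.1, 0.01)
        down = aerotaxis_delta(field, (3, 3), (-1, 1), 2.0, 0.1, 0.01)
        assert up == pytest.approx(-down)
        assert up < 0  # moving up-gradient is favoured


class TestTotalMoveEnergy:
    def test_full_target_is_always_rejected(self):
        p = ModelParams(L=6, mean_density=0.0, chi=0.0)
        state = initialize_state("random", p)
        state.eta[2, 2] = 1
        state.eta[2, 3] = p.eta_max
        assert total_move_energy(state, (2, 2), (0, 1)) == REJECT
        assert metropolis_accept(REJECT, 0.0) is False

    def test_neutral_move_on_empty_neighbourhood(self):
        p = ModelParams(L=6, mean_density=0.0, chi=0.0)
        state = initialize_state("random", p)
        state.eta[2, 2] = 1
        assert total_move_energy(state, (2, 2), (1, 0)) == pytest.approx(0.0)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        for u in (0.0, 0.5, 0.999999):
            assert metropolis_accept(-0.3, u)

    @pytest.mark.parametrize("dE", [0.15, 1.0])
    def test_acceptance_rate_matches_closed_form(self, dE, rng):
        n = 100_000
        us = rng.random(n)
        frac = np.mean([metropolis_accept(dE, u) for u in us])
        p = np.exp(-dE)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


def boltzmann_reference(L, n_cells, eta_max, eps):
    """Exact Boltzmann distribution over occupancy configurations.

    Enumerates ordered placements of distinguishable cells; configurations
    are occupancy multisets, weighted by multiplicity × exp(−E).
    """
    weights = {}
    for sites in itertools.product(range(L * L), repeat=n_cells):
        eta = np.zeros((L, L), dtype=np.int64)
        ok = True
        for s in sites:
            i, j = divmod(s, L)
            eta[i, j] += 1
            if eta[i, j] > eta_max:
                ok = False
                break
        if not ok:
            continue
        key = tuple(eta.ravel())
        weights[key] = weights.get(key, 0.0) + np.exp(-total_adhesion_energy(eta, eps))
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def sample_configurations(L, n_cells, eta_max, eps, n_sweeps, seed,
                          sample_every=10):
    """Adhesion-only MC sampling of occupancy configurations."""
    rng = np.random.default_rng(seed)
    eta = np.zeros((L, L), dtype=np.int64)
    cells = np.empty((n_cells, 2), dtype=np.int64)
    for n in range(n_cells):  # deterministic initial placement
        i, j = divmod(n % (L * L), L)
        eta[i, j] += 1
        cells[n] = (i, j)
    zeros = np.zeros((L, L))
    counts = {}
    for sweep in range(n_sweeps):
        order = rng.permutation(n_cells)
        dirs = rng.integers(0, 8, size=n_cells)
        us = rng.random(n_cells)
        _sweep_kernel(eta, cells, order, dirs, us, MOORE_OFFSETS, eta_max,
                      eps, 0.0, 0.1, 100.0, zeros, zeros, zeros, False)
        if sweep % sample_every == 0:
            key = tuple(eta.ravel())
            counts[key] = counts.get(key, 0) + 1
    return counts


class TestEquilibriumSampling:
    def test_matches_exact_boltzmann_on_discriminating_lattice(self):
        # 4x4 lattice, 2 cells: adjacent/on-site pairs carry -eps, distant
        # pairs zero, so the test is sensitive to both proposal symmetry
        # and the acceptance rule
        L, n_cells, eps = 4, 2, 0.8
        ref = boltzmann_reference(L, n_cells, 4, eps)
        counts = sample_configurations(L, n_cells, 4, eps, n_sweeps=300_000,
                                       seed=7)
        keys = sorted(ref)
        obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
        exp = np.array([ref[k] for k in keys]) * obs.sum()
        _, pval = chisquare(obs, exp)
        assert pval > 0.01


class TestSweepLoop:
    def test_zero_cells_is_noop(self):
        p = ModelParams(L=8, mean_density=0.0)
        state = initialize_state("random", p)
        assert mc_sweep(state) == 0
        assert state.sweep == 1

    def test_conservation_and_capacity(self):
        p = ModelParams(L=16, mean_density=1.5, h_mm=1.0, seed=3)
        state = initialize_state("random", p)
        n0 = state.eta.sum()
        for _ in range(30):
            mc_sweep(state)
            assert state.eta.sum() == n0
            assert state.eta.max() <= p.eta_max
            assert state.eta.min() >= 0

    def test_cells_array_consistent_with_occupancy(self):
        p = ModelParams(L=12, mean_density=1.0, seed=4)
        state = initialize_state("random", p)
        for _ in range(10):
            mc_sweep(state)
        rebuilt = np.zeros_like(state.eta)
        for i, j in state.cells:
            rebuilt[i, j] += 1
        assert np.array_equal(rebuilt, state.eta)


class TestInitialization:
    def test_cell_count_from_density(self):
        p = ModelParams(L=100, mean_density=1.0)
        state = initialize_state("random", p, update_field=False)
        assert state.n_cells == 10_000
        assert state.eta.sum() == 10_000

    def test_disk_mode_area(self):
        p = ModelParams(L=40, mean_density=0.25, seed=0)
        state = initialize_state("disk", p, update_field=False)
        n = state.eta.sum()
        filled = np.count_nonzero(state.eta == p.eta_max)
        assert n == p.n_cells
        # all sites except possibly one boundary ring site are full
        assert np.count_nonzero(state.eta) - filled <= 1
        assert filled == pytest.approx(n / p.eta_max, abs=1)

    def test_random_mode_deterministic_under_seed(self):
        p = ModelParams(L=20, mean_density=0.7, seed=11)
        s1 = initialize_state("random", p, update_field=False)
        s2 = initialize_state("random", p, update_field=False)
        assert np.array_equal(s1.eta, s2.eta)

    def test_overfull_request_rejected(self):
        from oxyphase import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            ModelParams(L=10, mean_density=5.0)


class TestRunSimulation:
    def test_short_run_records_strictly_increasing_sweeps(self):
        p = ModelParams(L=16, h_mm=1.0, seed=5)
        state, traj = run_simulation(p, sweeps=50, cadence=10)
        assert traj.sweeps == sorted(set(traj.sweeps))
        assert state.sweep == 50

    def test_adhesion_only_dynamics_coarsen(self):
        # without aerotaxis the mean aggregate area creeps upward
        p = ModelParams(L=32, chi=0.0, h_mm=1.0, seed=6)
        state, traj = run_simulation(p, sweeps=2000, cadence=100,
                                     update_field=False)
        a = np.array(traj.radius_um)
        assert a[-5:].mean() > a[1:6].mean()
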