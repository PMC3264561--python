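"""Auxin transport ODE system: derivatives, integration, conservation."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import florasim as fs
from florasim.fixtures import grid_tissue, ring_tissue
from florasim.transport import (
    CellState,
    TransportParams,
    TransportSystem,
    influx_active,
    rk5_step,
    saturation,
    update_differentiation,
)

from conftest import states_of


class TestSaturation:
    @pytest.mark.parametrize(
        "x,K,expected",
        [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5), (1e6, 1.0, 1.0), (2.0, 0.5, 0.8)],
    )
    def test_values(self, x, K, expected):
        assert saturation(x, K) == pytest.approx(expected, abs=1e-6)

    def test_monotone_and_bounded(self):
        xs = np.linspace(0, 100, 500)
        ys = saturation(xs, 2.0)
        assert np.all(np.diff(ys) > 0)
        assert np.all((ys >= 0) & (ys < 1))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            saturation(-0.1, 1.0)
        with pytest.raises(ValueError):
            saturation(1.0, 0.0)


class TestInfluxWindow:
    @pytest.mark.parametrize(
        "n,expected", [(49, False), (50, True), (75, True), (100, True), (101, False)]
    )
    def test_window_bounds(self, n, expected):
        params = TransportParams(influx_cell_window=(50, 100))
        assert influx_active(n, params) is expected


def oracle_derivatives(mesh, states, params, n_cells):
    """Independent, loop-based term-by-term evaluation of the RHS."""
    adj = mesh.adjacency
    boundary = mesh.boundary_cells()
    inflow_on = influx_active(n_cells, params)
    out = {}
    for i, sti in states.items():
        dA = -(
            params.d_decay + (params.d_depletion if sti.differentiated else 0.0)
        ) * sti.auxin
        if n_cells >= params.production_cell_onset:
            dA += params.p_production
        if inflow_on and i in boundary:
            dA += params.f_influx
        dPw = {}
        dPe = 0.0
        for j in adj[i]:
            stj = states[j]
            S = mesh.shared_wall_length(i, j)
            gi = sti.auxin / (params.K_transport + sti.auxin)
            gj = stj.auxin / (params.K_transport + stj.auxin)
            if not params.export_saturation:
                gi, gj = sti.auxin, stj.auxin
            pij = sti.pin_wall.get(j, 0.0)
            pji = stj.pin_wall.get(i, 0.0)
            dA += params.T_active * (pji * gj - pij * gi)
            dA += params.D_passive * S * (stj.auxin - sti.auxin)
            hj = stj.auxin / (params.K_mm + stj.auxin)
            recruit = params.k1 * sti.pin_endosome * hj
            dPw[j] = recruit - params.k2 * pij
            dPe += params.k2 * pij - recruit
        out[i] = (dA, dPe, dPw)
    return out


class TestDerivatives:
    def test_isolated_cell_at_rest(self):
        mesh = fs.build_initial_tissue(1, 1.0)
        mesh.cells[0].state = CellState(auxin=1.0, pin_endosome=5.0)
        params = TransportParams(T_active=1.0, D_passive=1.0, k1=0.5, k2=0.5)
        d = fs.derivatives(mesh, states_of(mesh), params)
        dA, dPe, dPw = d[0]
        assert dA == pytest.approx(0.0)
        assert dPe == pytest.approx(0.0)
        assert dPw == {}

    def test_symmetric_pair_has_no_net_transport(self, two_cell_mesh):
        params = TransportParams(
            T_active=0.3, D_passive=0.2, p_production=0.01, d_decay=0.02,
            k1=1.0, k2=0.5,
        )
        for cell in two_cell_mesh.cells.values():
            cell.state.pin_wall = {
                j: 0.7 for j in two_cell_mesh.adjacency[cell.id]
            }
        d = fs.derivatives(two_cell_mesh, states_of(two_cell_mesh), params)
        expected = 0.01 - 0.02 * 1.0
        assert d[0][0] == pytest.approx(expected)
        assert d[1][0] == pytest.approx(expected)

    def test_matches_term_by_term_oracle_on_asymmetric_pair(self, two_cell_mesh):
        i, j = sorted(two_cell_mesh.cells)
        two_cell_mesh.cells[i].state = CellState(
            auxin=2.0, pin_endosome=3.0, pin_wall={j: 1.0}
        )
        two_cell_mesh.cells[j].state = CellState(
            auxin=1.0, pin_endosome=4.0, pin_wall={i: 0.5}
        )
        params = TransportParams(
            T_active=0.4, D_passive=0.15, p_production=0.003, d_decay=0.01,
            d_depletion=0.1, k1=2.0, k2=0.7, K_mm=1.5, K_transport=0.2,
            f_influx=0.05, influx_cell_window=(1, 10),
        )
        states = states_of(two_cell_mesh)
        got = fs.derivatives(two_cell_mesh, states, params, n_cells=2)
        want = oracle_derivatives(two_cell_mesh, states, params, n_cells=2)
        for cid in states:
            assert got[cid][0] == pytest.approx(want[cid][0], rel=1e-12)
            assert got[cid][1] == pytest.approx(want[cid][1], rel=1e-12)
            assert got[cid][2] == pytest.approx(want[cid][2], rel=1e-12)

    def test_matches_oracle_on_random_grid(self, rng):
        mesh = grid_tissue(3, 3)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0, 2)),
                pin_endosome=float(rng.uniform(0, 5)),
                pin_wall={
                    j: float(rng.uniform(0, 1)) for j in mesh.adjacency[cid]
                },
                differentiated=bool(rng.random() < 0.3),
            )
        params = TransportParams(
            T_active=0.2, D_passive=0.1, p_production=0.002, d_decay=0.01,
            d_depletion=0.1, k1=3.0, k2=1.0, K_mm=2.0, K_transport=0.1,
            f_influx=0.2, influx_cell_window=(5, 20),
        )
        states = states_of(mesh)
        got = fs.derivatives(mesh, states, params, n_cells=9)
        want = oracle_derivatives(mesh, states, params, n_cells=9)
        for cid in states:
            assert got[cid][0] == pytest.approx(want[cid][0], rel=1e-10)
            assert got[cid][1] == pytest.approx(want[cid][1], rel=1e-10)
            assert got[cid][2] == pytest.approx(want[cid][2], rel=1e-10)

    def test_pin_rows_sum_to_zero_per_cell(self, rng):
        mesh = grid_tissue(3, 2)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0, 2)),
                pin_endosome=float(rng.uniform(1, 5)),
                pin_wall={j: float(rng.uniform(0, 1)) for j in mesh.adjacency[cid]},
            )
        params = TransportParams(T_active=0.2, D_passive=0.1, k1=2.0, k2=0.5)
        d = fs.derivatives(mesh, states_of(mesh), params)
        for cid, (dA, dPe, dPw) in d.items():
            assert dPe + sum(dPw.values()) == pytest.approx(0.0, abs=1e-12)


class TestRungeKutta:
    def test_fifth_order_convergence_on_exponential_decay(self):
        # dA/dt = -d A has the closed form A exp(-d t); halving the step
        # should shrink the global error by about 2^5 = 32
        d_rate = 0.8
        params = TransportParams(d_decay=d_rate)
        t_final = 2.0
        errors = []
        for h in (0.5, 0.25, 0.125):
            mesh = fs.build_initial_tissue(1, 1.0)
            mesh.cells[0].state = CellState(auxin=1.0)
            states = states_of(mesh)
            fs.integrate(mesh, states, params, t_final, h)
            errors.append(abs(states[0].auxin - math.exp(-d_rate * t_final)))
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 20 < r1 < 45
        assert 20 < r2 < 45

    def test_zero_rates_leave_states_unchanged(self, two_cell_mesh):
        states = states_of(two_cell_mesh)
        before = {c: (s.auxin, s.pin_endosome) for c, s in states.items()}
        rk5_step(two_cell_mesh, states, TransportParams(), dt=1.0)
        after = {c: (s.auxin, s.pin_endosome) for c, s in states.items()}
        assert before == after

    def test_rejects_nonpositive_dt(self, two_cell_mesh):
        with pytest.raises(ValueError):
            rk5_step(two_cell_mesh, states_of(two_cell_mesh), TransportParams(), 0.0)

    def test_matches_reference_integrator_on_random_fixture(self, rng):
        # independent oracle: scipy's adaptive RK45 at very tight tolerance
        mesh = grid_tissue(5, 2)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0.1, 1.5)),
                pin_endosome=float(rng.uniform(1, 5)),
                pin_wall={j: float(rng.uniform(0, 0.5)) for j in mesh.adjacency[cid]},
            )
        params = TransportParams(
            T_active=0.25, D_passive=0.2, p_production=0.002, d_decay=0.01,
            k1=3.0, k2=1.0, K_mm=2.0, K_transport=0.1,
        )
        sys_ref = TransportSystem(mesh, states_of(mesh), params, n_cells=10)
        y0 = sys_ref.y.copy()
        sol = solve_ivp(
            lambda _t, y: sys_ref.rhs(y), (0.0, 10.0), y0,
            method="RK45", rtol=1e-12, atol=1e-14,
        )
        sys_mine = TransportSystem(mesh, states_of(mesh), params, n_cells=10)
        sys_mine.y = y0.copy()
        for _ in range(100):
            sys_mine.step(0.1)
        np.testing.assert_allclose(sys_mine.y, sol.y[:, -1], rtol=1e-6)

    def test_adaptive_mode_matches_fixed_step(self, rng):
        mesh = grid_tissue(3, 2)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0.2, 1.0)), pin_endosome=4.0
            )
        params = TransportParams(
            T_active=0.2, D_passive=0.15, k1=3.0, k2=1.0, K_mm=1.0,
        )
        fixed = TransportSystem(mesh, states_of(mesh), params, n_cells=6)
        y0 = fixed.y.copy()
        fixed.integrate(20.0, 0.05)
        adaptive = TransportSystem(mesh, states_of(mesh), params, n_cells=6)
        adaptive.y = y0
        adaptive.integrate(20.0, 0.5, adaptive=True)
        np.testing.assert_allclose(adaptive.y, fixed.y, rtol=1e-5, atol=1e-8)

    def test_pin_total_conserved_through_steps(self, rng):
        mesh = grid_tissue(3, 3)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0, 2)), pin_endosome=5.0
            )
        params = TransportParams(
            T_active=0.3, D_passive=0.2, k1=5.0, k2=1.0, K_mm=1.0, pin_total=5.0
        )
        states = states_of(mesh)
        fs.integrate(mesh, states, params, 50.0, 0.1)
        for st in states.values():
            assert st.pin_total == pytest.approx(5.0, abs=1e-8)


class TestConservationLaws:
    def test_total_auxin_conserved_on_closed_mesh(self, rng):
        # no production, no decay, no influx: transport only redistributes
        mesh = grid_tissue(4, 3)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0.2, 1.5)), pin_endosome=5.0
            )
        params = TransportParams(
            T_active=0.3, D_passive=0.2, k1=5.0, k2=1.5, K_mm=1.0,
            K_transport=0.1, pin_total=5.0,
        )
        states = states_of(mesh)
        total0 = sum(s.auxin for s in states.values())
        fs.integrate(mesh, states, params, 40.0, 0.1)
        assert sum(s.auxin for s in states.values()) == pytest.approx(
            total0, rel=1e-9
        )

    def test_auxin_stays_nonnegative(self, rng):
        mesh = grid_tissue(3, 3)
        for cid, cell in mesh.cells.items():
            cell.state = CellState(
                auxin=float(rng.uniform(0, 0.1)), pin_endosome=5.0
            )
        params = TransportParams(
            T_active=0.3, D_passive=0.3, d_decay=0.1, k1=5.0, k2=1.0
        )
        states = states_of(mesh)
        fs.integrate(mesh, states, params, 30.0, 0.2)
        assert all(s.auxin >= 0 for s in states.values())


class TestUpTheGradient:
    def _two_cells(self, a1, a2):
        mesh = fs.build_initial_tissue(2, 1.0)
        i, j = sorted(mesh.cells)
        mesh.cells[i].state = CellState(auxin=a1, pin_endosome=5.0)
        mesh.cells[j].state = CellState(auxin=a2, pin_endosome=5.0)
        return mesh, i, j

    def test_difference_grows_with_strong_active_transport(self):
        mesh, i, j = self._two_cells(0.5, 0.3)
        params = TransportParams(
            T_active=0.4, D_passive=0.01, k1=3.0, k2=0.9,
            K_mm=2.0, K_transport=0.05, pin_total=5.0,
        )
        states = states_of(mesh)
        d0 = states[i].auxin - states[j].auxin
        fs.integrate(mesh, states, params, 10.0, 0.05)
        assert states[i].auxin - states[j].auxin > d0

    def test_pure_diffusion_decays_difference_monotonically(self):
        mesh, i, j = self._two_cells(0.5, 0.3)
        params = TransportParams(T_active=0.0, D_passive=0.1)
        states = states_of(mesh)
        diffs = [states[i].auxin - states[j].auxin]
        for _ in range(20):
            fs.integrate(mesh, states, params, 2.0, 0.05)
            diffs.append(states[i].auxin - states[j].auxin)
        assert all(d > 0 for d in diffs)
        assert all(b < a for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 0.05 * diffs[0]

    def test_matches_brute_force_fine_step_euler(self):
        # oracle: explicit Euler at a very small step on the same RHS
        mesh, i, j = self._two_cells(0.5, 0.3)
        params = TransportParams(
            T_active=0.4, D_passive=0.01, k1=3.0, k2=0.9,
            K_mm=2.0, K_transport=0.05, pin_total=5.0,
        )
        sys_e = TransportSystem(mesh, states_of(mesh), params, n_cells=2)
        y = sys_e.y.copy()
        h = 1e-4
        for _ in range(int(5.0 / h)):
            y = y + h * sys_e.rhs(y)
        sys_rk = TransportSystem(mesh, states_of(mesh), params, n_cells=2)
        for _ in range(50):
            sys_rk.step(0.1)
        np.testing.assert_allclose(sys_rk.y, y, rtol=2e-3)


class TestInfluxModes:
    def test_per_length_mode_weights_by_boundary_wall_length(self):
        # 2x1 strip: each cell exposes 3 unit boundary walls
        mesh = grid_tissue(2, 1)
        for cell in mesh.cells.values():
            cell.state = CellState(auxin=0.0, pin_endosome=0.0)
        params = TransportParams(
            f_influx=0.1, influx_cell_window=(1, 10), influx_mode="per_length"
        )
        d = fs.derivatives(mesh, states_of(mesh), params, n_cells=2)
        for cid in mesh.cells:
            assert d[cid][0] == pytest.approx(0.1 * 3.0)


class TestDifferentiation:
    def test_strict_threshold(self):
        params = TransportParams(A_threshold=1.0)
        states = {
            0: CellState(auxin=1.0),
            1: CellState(auxin=1.1),
            2: CellState(auxin=0.2),
        }
        update_differentiation(states, params, t=5.0)
        assert not states[0].differentiated  # exactly at threshold: no
        assert states[1].differentiated
        assert states[1].differentiation_time == 5.0
        assert not states[2].differentiated

    def test_flag_is_monotone(self):
        params = TransportParams(A_threshold=1.0)
        states = {0: CellState(auxin=2.0)}
        update_differentiation(states, params, t=1.0)
        states[0].auxin = 0.0
        update_differentiation(states, params, t=2.0)
        assert states[0].differentiated
        assert states[0].differentiation_time == 1.0

    def test_depletion_switches_on_after_differentiation(self):
        mesh = fs.build_initial_tissue(1, 1.0)
        mesh.cells[0].state = CellState(auxin=2.0, differentiated=True)
        params = TransportParams(d_decay=0.01, d_depletion=0.1)
        d = fs.derivatives(mesh, states_of(mesh), params)
        assert d[0][0] == pytest.approx(-(0.01 + 0.1) * 2.0)


class TestPeakSpacing:
    def test_mean_spacing_nonincreasing_in_active_transport(self):
        """More active transport packs auxin maxima closer on a cell ring."""

        def n_peaks(A):
            n = len(A)
            return sum(
                1
                for k in range(n)
                if A[k] > A[k - 1] and A[k] >= A[(k + 1) % n]
            )

        ratios = (0.07, 0.15, 0.3)  # T_active at fixed D_passive
        mean_spacing = []
        for T in ratios:
            spacings = []
            for seed in range(10):
                mesh = ring_tissue(40)
                gen = np.random.default_rng(seed)
                for cid, cell in mesh.cells.items():
                    cell.state = CellState(
                        auxin=0.3 * (1.0 + 0.2 * gen.random()), pin_endosome=5.0
                    )
                params = TransportParams(
                    T_active=T, D_passive=0.15, k1=3.0, k2=0.9,
                    K_mm=1.0, K_transport=0.1, pin_total=5.0,
                )
                states = states_of(mesh)
                fs.integrate(mesh, states, params, 400.0, 0.2)
                A = np.array([states[c].auxin for c in sorted(states)])
                k = n_peaks(A) if A.std() > 0.05 * A.mean() else 1
                spacings.append(40.0 / max(k, 1))
            mean_spacing.append(np.mean(spacings))
        assert mean_spacing[0] >= mean_spacing[1] >= mean_spacing[2]
        assert mean_spacing[0] > mean_spacing[2]
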