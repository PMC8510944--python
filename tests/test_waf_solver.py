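"""WAF scheme verification: Sod accuracy, TVD, conservation, axisymmetry,
wall reflection, AMR, and Godunov cross-checks."""

import numpy as np
import pytest

from blasttube import gasdynamics as gd
from blasttube.waf_solver import (AxiField, AxiGrid, PositivityError, Probe,
                                  SolverConfig, StagnationError, advance,
                                  amr_solution_on_base, flag_cells_1d,
                                  godunov_update_1d, run, run_1d_amr,
                                  waf_update_1d)

from conftest import run_1d, sod_initial

GAMMA = 1.4


def box_grid(nz, nr, h=0.01):
    return AxiGrid(np.arange(nz + 1) * h, np.arange(nr + 1) * h,
                   np.zeros((nr, nz), dtype=bool))


class TestWafUpdate1D:
    def test_uniform_state_unchanged(self):
        U = np.stack([np.full(50, 1.2), np.full(50, 0.36),
                      np.full(50, 2.5)])
        Un = waf_update_1d(U, 1e-4, 0.01, GAMMA)
        np.testing.assert_allclose(Un, U, rtol=1e-13, atol=1e-13)

    def test_sod_l1_error(self, sod_solutions):
        _, U, exact = sod_solutions[400]
        assert np.mean(np.abs(U[0] - exact[0])) < 0.01

    def test_grid_convergence_monotone(self, sod_solutions):
        errs = [np.mean(np.abs(sod_solutions[n][1][0]
                               - sod_solutions[n][2][0]))
                for n in (100, 200, 400)]
        assert errs[0] > errs[1] > errs[2]

    def test_tvd_on_monotone_density(self):
        """Scalar-monotone data: a contact discontinuity in density with
        uniform velocity and pressure advects like a scalar, so the total
        variation of density must not increase."""
        n = 200
        x = (np.arange(n) + 0.5) / n
        rho = np.where(x < 0.3, 2.0, 1.0)
        u0, p0 = 100.0, 1.0e5
        U = np.stack([rho, rho * u0,
                      p0 / (GAMMA - 1) + 0.5 * rho * u0**2])
        tv0 = np.sum(np.abs(np.diff(U[0])))
        U = run_1d(U, 1.0 / n, 2e-3)
        tv1 = np.sum(np.abs(np.diff(U[0])))
        assert tv1 <= tv0 * (1 + 1e-10)
        # and monotonicity is preserved (no new extrema)
        assert np.all(np.diff(U[0]) <= 1e-10)

    def test_shock_front_speed_matches_theory(self):
        """A 1D shock tube at the study's operating ratio: the tracked
        front moves at Ms * a1 from the ideal closure, within 1%."""
        p1 = 101.3e3
        p4 = 22.5 * p1
        rho1 = gd.air().density
        rho4 = rho1 * p4 / p1
        n = 900
        dx = 9.0 / n
        x = (np.arange(n) + 0.5) * dx
        rho = np.where(x < 1.0, rho4, rho1)
        p = np.where(x < 1.0, p4, p1)
        U = np.stack([rho, np.zeros(n), p / (GAMMA - 1)])
        t, rec = 0.0, []
        while t < 7e-3:
            u = U[1] / U[0]
            pr = (GAMMA - 1) * (U[2] - 0.5 * U[0] * u**2)
            a = np.sqrt(GAMMA * pr / U[0])
            dt = 0.4 * dx / np.max(np.abs(u) + a)
            U = waf_update_1d(U, dt, dx, GAMMA, bc=("wall", "wall"))
            t += dt
            pr = (GAMMA - 1) * (U[2] - 0.5 * U[1]**2 / U[0])
            idx = np.where(pr - p1 > 5e3)[0]
            if idx.size:
                rec.append((t, x[idx.max()]))
        rec = np.array(rec)
        sel = (rec[:, 1] > 3.0) & (rec[:, 1] < 7.5)
        speed = np.polyfit(rec[sel, 0], rec[sel, 1], 1)[0]
        expected = gd.mach_from_diaphragm_ratio(22.5) * gd.air().sound_speed
        assert speed == pytest.approx(expected, rel=0.01)

    def test_reflected_shock_wall_pressure(self):
        """Post-shock inflow onto a closed end reproduces the analytic
        reflected-shock pressure within 2%."""
        Ms = 2.0
        s = gd.normal_shock_from_mach(Ms)
        rho1, p1 = gd.air().density, gd.air().pressure
        rho2, p2, u2 = rho1 * s.rho_ratio, p1 * s.p_ratio, s.u2
        n = 400
        dx = 1.0 / n
        U = np.stack([np.full(n, rho2), np.full(n, rho2 * u2),
                      np.full(n, p2 / (GAMMA - 1) + 0.5 * rho2 * u2**2)])
        U = run_1d(U, dx, 8e-4, bc=("transmissive", "wall"))
        p_wall = (GAMMA - 1) * (U[2, -1] - 0.5 * U[1, -1]**2 / U[0, -1])
        assert p_wall == pytest.approx(
            gd.reflected_shock_pressure_ratio(Ms) * p1, rel=0.02)

    def test_positivity_failure_reports_cell(self):
        # Sod data with a grossly CFL-violating time step
        _, U = sod_initial(40)
        with pytest.raises(PositivityError, match=r"cell"):
            waf_update_1d(U, 0.5, 1.0 / 40, GAMMA)

    def test_agrees_with_godunov_on_smooth_data(self):
        """WAF and exact-solver Godunov converge to each other at least at
        first order on a smooth acoustic pulse."""
        diffs = []
        for n in (100, 200, 400):
            x = (np.arange(n) + 0.5) / n
            rho = 1.0 + 0.1 * np.exp(-((x - 0.5) / 0.1) ** 2)
            p = rho ** GAMMA
            U0 = np.stack([rho, np.zeros(n), p / (GAMMA - 1)])
            dx = 1.0 / n
            Uw = U0.copy()
            Ug = U0.copy()
            t = 0.0
            while t < 0.05:
                u = Uw[1] / Uw[0]
                pr = (GAMMA - 1) * (Uw[2] - 0.5 * Uw[0] * u**2)
                a = np.sqrt(GAMMA * pr / Uw[0])
                dt = min(0.4 * dx / np.max(np.abs(u) + a), 0.05 - t)
                Uw = waf_update_1d(Uw, dt, dx, GAMMA)
                Ug = godunov_update_1d(Ug, dt, dx, GAMMA)
                t += dt
            diffs.append(np.mean(np.abs(Uw[0] - Ug[0])))
        # halving dx must at least halve the difference
        assert diffs[1] < 0.6 * diffs[0]
        assert diffs[2] < 0.6 * diffs[1]


class TestAxisymmetric2D:
    def test_uniform_preserved(self):
        grid = box_grid(40, 30)
        U = np.zeros((4, 30, 40))
        U[0] = 1.2
        U[3] = 101.3e3 / (GAMMA - 1)
        f = advance(AxiField(U.copy()), grid, SolverConfig(t_end=1.0))
        np.testing.assert_allclose(f.U, U, rtol=1e-12, atol=1e-9)

    def test_closed_box_conservation(self):
        """Mass and energy conserved to 1e-10 relative over 1000 steps in a
        fully closed axisymmetric box with a pressure bump."""
        grid = box_grid(60, 40)
        zc, rc = np.meshgrid(grid.z_centers, grid.r_centers)
        p = 101.3e3 * (1 + 2 * np.exp(-((zc - 0.3)**2 + (rc - 0.15)**2)
                                      / 0.002))
        U = np.zeros((4, 40, 60))
        U[0] = 1.2
        U[3] = p / (GAMMA - 1)
        f = AxiField(U)
        cfg = SolverConfig(t_end=1.0)
        w = rc  # cell volume ~ r dz dr
        m0 = np.sum(f.U[0] * w)
        e0 = np.sum(f.U[3] * w)
        for n in range(1000):
            f = advance(f, grid, cfg, step_parity=n)
        assert abs(np.sum(f.U[0] * w) - m0) / m0 < 1e-10
        assert abs(np.sum(f.U[3] * w) - e0) / e0 < 1e-10

    def test_spherical_pulse_stays_mirror_symmetric(self):
        grid = box_grid(80, 40)
        zc, rc = np.meshgrid(grid.z_centers, grid.r_centers)
        p = 101.3e3 * (1 + 1.5 * np.exp(-((zc - 0.4)**2 + rc**2) / 0.003))
        U = np.zeros((4, 40, 80))
        U[0] = 1.2
        U[3] = p / (GAMMA - 1)
        f = AxiField(U)
        cfg = SolverConfig(t_end=1.0)
        for n in range(200):
            f = advance(f, grid, cfg, step_parity=n)
        pf = f.pressure(GAMMA)
        assert np.max(np.abs(pf - pf[:, ::-1])) / 101.3e3 < 1e-6

    def test_r_invariant_data_matches_1d_rowwise(self):
        """z-direction Riemann problem with r-invariant data: every row of
        the axisymmetric update equals the 1D update."""
        nz, nr = 200, 8
        grid = AxiGrid(np.arange(nz + 1) * 0.005, np.arange(nr + 1) * 0.005,
                       np.zeros((nr, nz), dtype=bool))
        rho = np.where(np.arange(nz) < 100, 1.0, 0.125)
        p = np.where(np.arange(nz) < 100, 1.0, 0.1)
        U1 = np.stack([rho, np.zeros(nz), p / (GAMMA - 1)])
        U2 = np.zeros((4, nr, nz))
        U2[0] = rho
        U2[3] = p / (GAMMA - 1)
        dt = 1e-4
        f = advance(AxiField(U2), grid, SolverConfig(t_end=1.0), dt=dt)
        U1n = waf_update_1d(U1, dt, 0.005, GAMMA, bc=("wall", "wall"))
        for row in range(nr):
            np.testing.assert_allclose(f.U[[0, 1, 3], row, :], U1n,
                                       rtol=1e-12, atol=1e-12)

    def test_stagnation_error(self):
        grid = box_grid(10, 10)
        U = np.zeros((4, 10, 10))
        U[0] = 1.2
        U[3] = 101.3e3 / (GAMMA - 1)
        with pytest.raises(StagnationError):
            advance(AxiField(U), grid, SolverConfig(t_end=1.0), dt=1e-13)


class TestRun:
    def make_quiet(self, nz=30, nr=20):
        grid = box_grid(nz, nr)
        U = np.zeros((4, nr, nz))
        U[0] = SolverConfig().ambient_density
        U[3] = 101.3e3 / (GAMMA - 1)
        return grid, AxiField(U)

    def test_quiescent_traces_flat(self):
        grid, f = self.make_quiet()
        cfg = SolverConfig(t_end=2e-4, trace_dt=2e-5)
        res = run(f, grid, cfg, probes=[Probe("P", 0.15, 0.05)])
        assert len(res.traces) == 1
        assert np.max(np.abs(res.traces[0].overpressure)) < 1.0

    def test_probe_in_solid_rejected(self):
        grid, f = self.make_quiet()
        grid.solid[5, 5] = True
        with pytest.raises(ValueError, match="solid"):
            run(f, grid, SolverConfig(t_end=1e-4),
                probes=[Probe("bad", 0.055, 0.055)])

    def test_active_window_equivalent_to_full_sweep(self):
        """The quiescent-far-field window optimisation reproduces the full
        run: identical probe traces up to round-off."""
        grid, f = self.make_quiet(nz=60, nr=12)
        zc, rc = np.meshgrid(grid.z_centers, grid.r_centers)
        f.U[3] *= 1 + 1.0 * np.exp(-((zc - 0.05)**2 + rc**2) / 5e-4)
        base = dict(t_end=4e-4, trace_dt=2e-5)
        r_full = run(f.copy(), grid, SolverConfig(**base),
                     probes=[Probe("P", 0.45, 0.05)])
        r_win = run(f.copy(), grid, SolverConfig(active_window=True, **base),
                    probes=[Probe("P", 0.45, 0.05)])
        np.testing.assert_allclose(r_win.field.U, r_full.field.U,
                                   rtol=1e-10, atol=1e-8)
        np.testing.assert_allclose(r_win.traces[0].overpressure,
                                   r_full.traces[0].overpressure,
                                   rtol=1e-8, atol=1e-5)

    def test_deterministic_repeat(self):
        grid, f = self.make_quiet()
        zc, rc = np.meshgrid(grid.z_centers, grid.r_centers)
        f.U[3] *= 1 + 0.5 * np.exp(-((zc - 0.1)**2 + rc**2) / 1e-3)
        cfg = SolverConfig(t_end=2e-4)
        r1 = run(f.copy(), grid, cfg, probes=[Probe("P", 0.25, 0.05)])
        r2 = run(f.copy(), grid, cfg, probes=[Probe("P", 0.25, 0.05)])
        np.testing.assert_array_equal(r1.traces[0].overpressure,
                                      r2.traces[0].overpressure)
        np.testing.assert_array_equal(r1.field.U, r2.field.U)


class TestAmr1D:
    def test_uniform_field_not_flagged(self):
        U = np.stack([np.full(50, 1.2), np.zeros(50), np.full(50, 2.5)])
        assert not flag_cells_1d(U, 0.01).any()

    def test_infinite_threshold_matches_uniform(self):
        n = 200
        x, U0 = sod_initial(n)
        mesh, U = run_1d_amr(U0, 0.0, 1.0, 0.1, max_level=1,
                             threshold=np.inf)
        assert U.shape[1] == n
        U_ref = run_1d(U0, 1.0 / n, 0.1)
        np.testing.assert_allclose(U, U_ref, rtol=1e-9, atol=1e-9)

    def test_sod_amr_matches_fine_uniform(self, sod_solutions):
        """Base 200 + one 2:1 level tracks the uniform 400-cell solution."""
        _, U0 = sod_initial(200)
        mesh, U = run_1d_amr(U0, 0.0, 1.0, 0.25, max_level=1,
                             threshold=0.01)
        assert (mesh.level > 0).any()
        _, U400, _ = sod_solutions[400]
        coarse = amr_solution_on_base(mesh, U)
        fine = np.repeat(coarse, 2, axis=1)
        assert np.mean(np.abs(fine[0] - U400[0])) < 0.005

    def test_negative_level_rejected(self):
        _, U0 = sod_initial(50)
        with pytest.raises(ValueError):
            run_1d_amr(U0, 0.0, 1.0, 0.01, max_level=-1)
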