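"""Exact and HLLC solvers for the 1D Euler Riemann problem.

The exact solver (two-wave pressure iteration plus self-similar sampling) is
the verification oracle for the finite-volume scheme; the HLLC approximate
solver supplies the wave fan the WAF flux averages over.  Both assume a
calorically perfect gas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "PrimitiveState1D",
    "RiemannSolution",
    "VacuumError",
    "solve_exact",
    "sample_exact",
    "star_pressure",
    "hllc_flux",
    "euler_flux",
]


class VacuumError(ValueError):
    """The two initial states generate a vacuum region (no solution)."""


@dataclass(frozen=True)
class PrimitiveState1D:
    """Primitive state (density, velocity, pressure) of a 1D Euler gas."""

    density: float
    velocity: float
    pressure: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.pressure <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure}")

    def sound_speed(self, gamma: float) -> float:
        return float(np.sqrt(gamma * self.pressure / self.density))


@dataclass(frozen=True)
class RiemannSolution:
    """Star-region state and sampling function of an exact Riemann solution."""

    p_star: float
    u_star: float
    left_wave: str        # "shock" | "rarefaction"
    right_wave: str
    sample: Callable[[float], PrimitiveState1D]  # similarity variable x/t


def euler_flux(U: np.ndarray, gamma: float) -> np.ndarray:
    """Physical Euler flux of conserved variables (rho, rho*u, [rho*v,] E).

    Works on arrays of shape (neq, ...) with neq 3 (1D) or 4 (1D plus a
    passively advected transverse momentum in row 2).
    """
    rho = U[0]
    u = U[1] / rho
    if U.shape[0] == 4:
        v = U[2] / rho
        E = U[3]
        p = (gamma - 1.0) * (E - 0.5 * rho * (u * u + v * v))
        return np.stack([rho * u, rho * u * u + p, rho * u * v, u * (E + p)])
    E = U[2]
    p = (gamma - 1.0) * (E - 0.5 * rho * u * u)
    return np.stack([rho * u, rho * u * u + p, u * (E + p)])


# ---------------------------------------------------------------------------
# exact solver
# ---------------------------------------------------------------------------

def _pressure_function(p, rho_k, p_k, a_k, gamma):
    """Toro's f_K(p): velocity change across the K wave, and its derivative."""
    g = gamma
    A = 2.0 / ((g + 1) * rho_k)
    B = (g - 1) / (g + 1) * p_k
    shock = p > p_k
    sqrt_term = np.sqrt(A / (p + B))
    f_shock = (p - p_k) * sqrt_term
    df_shock = sqrt_term * (1.0 - 0.5 * (p - p_k) / (p + B))
    pr = np.maximum(p, 1e-300) / p_k
    f_rare = 2 * a_k / (g - 1) * (pr ** ((g - 1) / (2 * g)) - 1.0)
    df_rare = 1.0 / (rho_k * a_k) * pr ** (-(g + 1) / (2 * g))
    return np.where(shock, f_shock, f_rare), np.where(shock, df_shock, df_rare)


def star_pressure(rho_l, u_l, p_l, rho_r, u_r, p_r, gamma,
                  tol: float = 1e-14, max_iter: int = 60):
    """Star-region pressure and velocity (vectorised Newton iteration).

    Accepts scalars or arrays; returns (p_star, u_star).  Raises
    :class:`VacuumError` if the pressure-positivity condition fails, i.e.
    the rarefactions would generate vacuum.
    """
    rho_l, u_l, p_l, rho_r, u_r, p_r = map(
        lambda v: np.asarray(v, dtype=float),
        (rho_l, u_l, p_l, rho_r, u_r, p_r))
    g = gamma
    a_l = np.sqrt(g * p_l / rho_l)
    a_r = np.sqrt(g * p_r / rho_r)
    du = u_r - u_l
    if np.any(2 * (a_l + a_r) / (g - 1) <= du):
        raise VacuumError("initial states generate vacuum "
                          "(2(aL+aR)/(gamma-1) <= uR-uL)")

    # PVRS initial guess, clipped positive
    p0 = (0.5 * (p_l + p_r)
          - 0.125 * du * (rho_l + rho_r) * (a_l + a_r))
    p = np.maximum(p0, 1e-8 * np.minimum(p_l, p_r))
    for _ in range(max_iter):
        f_l, df_l = _pressure_function(p, rho_l, p_l, a_l, g)
        f_r, df_r = _pressure_function(p, rho_r, p_r, a_r, g)
        f = f_l + f_r + du
        step = f / (df_l + df_r)
        p_new = p - step
        p_new = np.where(p_new <= 0, 0.5 * p, p_new)  # bisect toward zero
        converged = np.abs(p_new - p) <= tol * np.abs(p_new)
        p = p_new
        if np.all(converged):
            break
    f_l, _ = _pressure_function(p, rho_l, p_l, a_l, g)
    f_r, _ = _pressure_function(p, rho_r, p_r, a_r, g)
    u = 0.5 * (u_l + u_r) + 0.5 * (f_r - f_l)
    return p, u


def solve_exact(left: PrimitiveState1D, right: PrimitiveState1D,
                gamma: float = 1.4) -> RiemannSolution:
    """Exact solution of the Riemann problem between two states.

    Returns the star pressure/velocity, the wave types, and a sampling
    function over the similarity variable xi = x/t.
    """
    g = gamma
    p_star, u_star = star_pressure(
        left.density, left.velocity, left.pressure,
        right.density, right.velocity, right.pressure, g)
    p_star = float(p_star)
    u_star = float(u_star)
    left_wave = "shock" if p_star > left.pressure else "rarefaction"
    right_wave = "shock" if p_star > right.pressure else "rarefaction"

    rho_l, u_l, p_l = left.density, left.velocity, left.pressure
    rho_r, u_r, p_r = right.density, right.velocity, right.pressure
    a_l = left.sound_speed(g)
    a_r = right.sound_speed(g)
    gm, gp = g - 1, g + 1

    def sample(xi: float) -> PrimitiveState1D:
        if xi <= u_star:  # left of contact
            if left_wave == "shock":
                S = u_l - a_l * np.sqrt(gp / (2 * g) * p_star / p_l + gm / (2 * g))
                if xi <= S:
                    return left
                rho = rho_l * ((p_star / p_l + gm / gp)
                               / (gm / gp * p_star / p_l + 1.0))
                return PrimitiveState1D(rho, u_star, p_star)
            head = u_l - a_l
            a_star = a_l * (p_star / p_l) ** (gm / (2 * g))
            tail = u_star - a_star
            if xi <= head:
                return left
            if xi >= tail:
                rho = rho_l * (p_star / p_l) ** (1.0 / g)
                return PrimitiveState1D(rho, u_star, p_star)
            u = 2.0 / gp * (a_l + gm / 2.0 * u_l + xi)
            a = 2.0 / gp * (a_l + gm / 2.0 * (u_l - xi))
            rho = rho_l * (a / a_l) ** (2.0 / gm)
            p = p_l * (a / a_l) ** (2.0 * g / gm)
            return PrimitiveState1D(rho, u, p)
        # right of contact
        if right_wave == "shock":
            S = u_r + a_r * np.sqrt(gp / (2 * g) * p_star / p_r + gm / (2 * g))
            if xi >= S:
                return right
            rho = rho_r * ((p_star / p_r + gm / gp)
                           / (gm / gp * p_star / p_r + 1.0))
            return PrimitiveState1D(rho, u_star, p_star)
        head = u_r + a_r
        a_star = a_r * (p_star / p_r) ** (gm / (2 * g))
        tail = u_star + a_star
        if xi >= head:
            return right
        if xi <= tail:
            rho = rho_r * (p_star / p_r) ** (1.0 / g)
            return PrimitiveState1D(rho, u_star, p_star)
        u = 2.0 / gp * (-a_r + gm / 2.0 * u_r + xi)
        a = 2.0 / gp * (a_r - gm / 2.0 * (u_r - xi))
        rho = rho_r * (a / a_r) ** (2.0 / gm)
        p = p_r * (a / a_r) ** (2.0 * g / gm)
        return PrimitiveState1D(rho, u, p)

    return RiemannSolution(p_star=p_star, u_star=u_star, left_wave=left_wave,
                           right_wave=right_wave, sample=sample)


def sample_exact(left: PrimitiveState1D, right: PrimitiveState1D,
                 gamma: float, xi: np.ndarray) -> np.ndarray:
    """Exact solution sampled on an array of similarity variables.

    Returns an array of shape (3, len(xi)) with rows (density, velocity,
    pressure).  Convenience wrapper over :func:`solve_exact` for building
    reference profiles.
    """
    sol = solve_exact(left, right, gamma)
    out = np.empty((3, len(xi)))
    for i, x in enumerate(np.asarray(xi, dtype=float)):
        w = sol.sample(float(x))
        out[:, i] = (w.density, w.velocity, w.pressure)
    return out


# ---------------------------------------------------------------------------
# HLLC
# ---------------------------------------------------------------------------

def hllc_wave_speeds(rho_l, u_l, p_l, a_l, rho_r, u_r, p_r, a_r, gamma):
    """Pressure-based (PVRS) wave-speed estimates with direct-bound fallback.

    Returns (S_L, S_star, S_R) as arrays.  The PVRS star pressure sets
    shock-corrected speeds; Davis-type direct bounds guard the estimates for
    very strong waves.
    """
    g = gamma
    p_pvrs = (0.5 * (p_l + p_r)
              - 0.125 * (u_r - u_l) * (rho_l + rho_r) * (a_l + a_r))
    p_star = np.maximum(p_pvrs, 0.0)
    q_l = np.where(p_star <= p_l, 1.0,
                   np.sqrt(1.0 + (g + 1) / (2 * g) * (p_star / p_l - 1.0)))
    q_r = np.where(p_star <= p_r, 1.0,
                   np.sqrt(1.0 + (g + 1) / (2 * g) * (p_star / p_r - 1.0)))
    S_l = np.minimum(u_l - a_l * q_l, u_r - a_r)
    S_r = np.maximum(u_r + a_r * q_r, u_l + a_l)
    num = (p_r - p_l + rho_l * u_l * (S_l - u_l) - rho_r * u_r * (S_r - u_r))
    den = rho_l * (S_l - u_l) - rho_r * (S_r - u_r)
    den = np.where(np.abs(den) < 1e-300, 1e-300, den)
    S_star = num / den
    return S_l, S_star, S_r


def hllc_flux(left: PrimitiveState1D, right: PrimitiveState1D,
              gamma: float = 1.4) -> np.ndarray:
    """HLLC intercell flux between two primitive states (3-equation 1D).

    Consistent (flux(U, U) = F(U)) and upwind in the supersonic limits.
    """
    g = gamma
    rho_l, u_l, p_l = left.density, left.velocity, left.pressure
    rho_r, u_r, p_r = right.density, right.velocity, right.pressure
    a_l = left.sound_speed(g)
    a_r = right.sound_speed(g)
    if 2 * (a_l + a_r) / (g - 1) <= u_r - u_l:
        raise VacuumError("initial states generate vacuum")
    S_l, S_star, S_r = hllc_wave_speeds(
        np.float64(rho_l), np.float64(u_l), np.float64(p_l), np.float64(a_l),
        np.float64(rho_r), np.float64(u_r), np.float64(p_r), np.float64(a_r), g)
    E_l = p_l / (g - 1) + 0.5 * rho_l * u_l**2
    E_r = p_r / (g - 1) + 0.5 * rho_r * u_r**2
    U_l = np.array([rho_l, rho_l * u_l, E_l])
    U_r = np.array([rho_r, rho_r * u_r, E_r])
    F_l = euler_flux(U_l, g)
    F_r = euler_flux(U_r, g)
    if S_l >= 0:
        return F_l
    if S_r <= 0:
        return F_r

    def star(U, rho, u, p, E, S):
        coef = rho * (S - u) / (S - S_star)
        return coef * np.array([
            1.0, S_star,
            E / rho + (S_star - u) * (S_star + p / (rho * (S - u)))])

    if S_star >= 0:
        U_sl = star(U_l, rho_l, u_l, p_l, E_l, S_l)
        return F_l + S_l * (U_sl - U_l)
    U_sr = star(U_r, rho_r, u_r, p_r, E_r, S_r)
    return F_r + S_r * (U_sr - U_r)
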