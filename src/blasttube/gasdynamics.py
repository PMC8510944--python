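"""Ideal shock-tube theory.

Normal-shock jump relations and the closure between the diaphragm pressure
ratio P4/P1 of a shock tube and the incident-shock Mach number Ms.  The
driver (state 4) and driven (state 1) gases are treated as calorically
perfect; the diaphragm is assumed to vanish instantaneously, so the relation
is the classical one-dimensional result with no rupture dynamics, wall
friction or heat exchange.

Conventions follow the standard shock-tube numbering: state 1 is the
undisturbed driven gas, state 2 the post-incident-shock gas, state 4 the
driver gas.  ``Ms`` is the incident shock speed divided by the driven-gas
sound speed a1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GasState",
    "NormalShockSolution",
    "ShockTubeCondition",
    "air",
    "normal_shock_from_mach",
    "reflected_shock_pressure_ratio",
    "diaphragm_ratio_from_mach",
    "mach_from_diaphragm_ratio",
    "mach_from_arrival_times",
]

R_AIR = 287.0  # J/(kg K)
T_DEFAULT = 293.0  # K; ambient laboratory temperature assumed for both sections


@dataclass(frozen=True)
class GasState:
    """Thermodynamic state of a calorically perfect gas.

    Parameters
    ----------
    gamma : heat-capacity ratio (> 1).
    pressure : static pressure, Pa.
    temperature : static temperature, K.
    specific_gas_constant : J/(kg K).
    """

    gamma: float = 1.4
    pressure: float = 101.3e3
    temperature: float = T_DEFAULT
    specific_gas_constant: float = R_AIR

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError(f"gamma must exceed 1, got {self.gamma}")
        if self.pressure <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def sound_speed(self) -> float:
        """a = sqrt(gamma R T), m/s."""
        return math.sqrt(self.gamma * self.specific_gas_constant * self.temperature)

    @property
    def density(self) -> float:
        """rho = p / (R T), kg/m^3."""
        return self.pressure / (self.specific_gas_constant * self.temperature)


def air(pressure: float = 101.3e3, temperature: float = T_DEFAULT) -> GasState:
    """Air at the given pressure and temperature (gamma 1.4, R 287)."""
    return GasState(gamma=1.4, pressure=pressure, temperature=temperature,
                    specific_gas_constant=R_AIR)


@dataclass(frozen=True)
class NormalShockSolution:
    """Rankine-Hugoniot jump ratios across a normal shock of Mach number Ms."""

    Ms: float
    p_ratio: float       # p2/p1
    rho_ratio: float     # rho2/rho1
    T_ratio: float       # T2/T1
    u2: float            # post-shock gas speed in the lab frame, m/s


@dataclass(frozen=True)
class ShockTubeCondition:
    """Driver (state 4) and driven (state 1) gases of a shock tube."""

    driver: GasState
    driven: GasState = field(default_factory=air)

    @property
    def diaphragm_ratio(self) -> float:
        return self.driver.pressure / self.driven.pressure

    def __post_init__(self) -> None:
        if self.diaphragm_ratio < 1:
            raise ValueError(
                "driver pressure below driven pressure: "
                f"P4/P1 = {self.diaphragm_ratio:.4g} < 1")


def normal_shock_from_mach(Ms: float, gamma: float = 1.4,
                           driven: GasState | None = None) -> NormalShockSolution:
    """Rankine-Hugoniot jump relations for a normal shock.

    Parameters
    ----------
    Ms : incident shock Mach number (>= 1).
    gamma : heat-capacity ratio of the gas the shock runs into.
    driven : optional driven-gas state; sets the sound speed a1 used to put
        the post-shock gas speed ``u2`` in m/s.  Defaults to ambient air.

    Returns
    -------
    NormalShockSolution with p2/p1, rho2/rho1, T2/T1 and u2 (lab frame,
    shock advancing into gas at rest).
    """
    if Ms < 1:
        raise ValueError(f"no shock for Ms < 1 (got {Ms})")
    if gamma <= 1:
        raise ValueError(f"gamma must exceed 1, got {gamma}")
    if driven is None:
        driven = air()
    g = gamma
    p_ratio = (2 * g * Ms**2 - (g - 1)) / (g + 1)
    rho_ratio = (g + 1) * Ms**2 / ((g - 1) * Ms**2 + 2)
    T_ratio = p_ratio / rho_ratio
    u2 = (2.0 / (g + 1)) * driven.sound_speed * (Ms - 1.0 / Ms)
    return NormalShockSolution(Ms=Ms, p_ratio=p_ratio, rho_ratio=rho_ratio,
                               T_ratio=T_ratio, u2=u2)


def reflected_shock_pressure_ratio(Ms: float, gamma: float = 1.4) -> float:
    """Pressure ratio p5/p1 behind the shock reflected off a closed end wall.

    p5 is the pressure between the end wall and the reflected shock after a
    normal shock of Mach ``Ms`` hits a rigid wall head-on; the standard
    ideal-gas relation in terms of p2/p1.
    """
    g = gamma
    p21 = normal_shock_from_mach(Ms, g).p_ratio
    p52 = ((3 * g - 1) * p21 - (g - 1)) / ((g - 1) * p21 + (g + 1))
    return p52 * p21


def _feasible_mach_upper(condition: ShockTubeCondition) -> float:
    """Largest Ms the driver can sustain (bracketed term reaches zero)."""
    g4 = condition.driver.gamma
    g1 = condition.driven.gamma
    a1 = condition.driven.sound_speed
    a4 = condition.driver.sound_speed
    # 1 - (g4-1)/(g1+1) * (a1/a4) * (Ms - 1/Ms) = 0
    c = (g1 + 1) / (g4 - 1) * (a4 / a1)
    # Ms - 1/Ms = c  ->  Ms = (c + sqrt(c^2+4))/2
    return (c + math.sqrt(c * c + 4.0)) / 2.0


def diaphragm_ratio_from_mach(Ms: float, condition: ShockTubeCondition) -> float:
    """Diaphragm pressure ratio P4/P1 producing incident shock Mach ``Ms``.

    The ideal shock-tube relation: the incident shock strength p2/p1 is
    matched to the driver expansion through

        P4/P1 = p2/p1 * [1 - (g4-1)/(g1+1) * (a1/a4) * (Ms - 1/Ms)]^(-2 g4/(g4-1))

    Strictly increasing in Ms up to the Mach number at which the bracketed
    term vanishes (driver fully expanded).
    """
    if Ms < 1:
        raise ValueError(f"no shock for Ms < 1 (got {Ms})")
    g4 = condition.driver.gamma
    g1 = condition.driven.gamma
    a1 = condition.driven.sound_speed
    a4 = condition.driver.sound_speed
    bracket = 1.0 - (g4 - 1) / (g1 + 1) * (a1 / a4) * (Ms - 1.0 / Ms)
    if bracket <= 0:
        raise ValueError(
            f"Ms = {Ms:.4g} infeasible for this driver: maximum attainable "
            f"Ms is {_feasible_mach_upper(condition):.4g}")
    p21 = normal_shock_from_mach(Ms, g1).p_ratio
    return p21 * bracket ** (-2 * g4 / (g4 - 1))


def mach_from_diaphragm_ratio(ratio: float,
                              condition: ShockTubeCondition | None = None,
                              rtol: float = 1e-12) -> float:
    """Incident shock Mach number for a diaphragm pressure ratio P4/P1.

    Inverts :func:`diaphragm_ratio_from_mach` by bracketed root finding on
    the monotone feasible interval, then polishes with Newton steps to a
    relative tolerance of ``rtol``.
    """
    if ratio < 1:
        raise ValueError(f"P4/P1 must be >= 1, got {ratio}")
    if condition is None:
        condition = ShockTubeCondition(driver=air(), driven=air())
    if ratio == 1:
        return 1.0

    hi = _feasible_mach_upper(condition) * (1 - 1e-12)

    def f(Ms: float) -> float:
        return diaphragm_ratio_from_mach(Ms, condition) - ratio

    if f(hi) < 0:
        raise ValueError(
            f"P4/P1 = {ratio:.4g} exceeds what this driver can produce")
    Ms = brentq(f, 1.0 + 1e-14, hi, xtol=1e-14, rtol=8.9e-16)

    # Newton polish (analytic-free secant derivative is enough at this point)
    for _ in range(3):
        h = max(Ms * 1e-7, 1e-9)
        d = (f(Ms + h) - f(Ms - h)) / (2 * h)
        if d == 0:
            break
        step = f(Ms) / d
        Ms_new = Ms - step
        if Ms_new <= 1:
            break
        Ms = Ms_new
        if abs(step) <= rtol * Ms:
            break
    return Ms


def mach_from_arrival_times(positions, times, driven: GasState | None = None):
    """Shock Mach number from transducer arrival times.

    Fits a least-squares line to position vs time and divides the slope by
    the driven-gas sound speed, the usual time-of-flight estimate from a
    row of pressure transducers.

    Parameters
    ----------
    positions : transducer positions along the tube, m (strictly increasing).
    times : shock arrival times at those positions, s (strictly increasing).
    driven : driven gas (sets a1); ambient air by default.

    Returns
    -------
    (Ms, interval_speeds) where ``interval_speeds`` are the per-interval
    finite-difference speeds in m/s.
    """
    x = np.asarray(positions, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two transducer stations")
    if np.any(np.diff(x) <= 0):
        raise ValueError("transducer positions must be strictly increasing")
    if np.any(np.diff(t) <= 0):
        raise ValueError("arrival times must be strictly increasing "
                         "(mis-ordered transducers?)")
    if driven is None:
        driven = air()
    slope = np.polyfit(t, x, 1)[0]
    interval_speeds = np.diff(x) / np.diff(t)
    return slope / driven.sound_speed, interval_speeds
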