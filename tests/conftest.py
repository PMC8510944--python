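import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    from blasttube.injury_stats import load_packaged_cohort
    return load_packaged_cohort()


def sod_initial(n, gamma=1.4):
    """Sod shock-tube initial condition on [0, 1], diaphragm at 0.5."""
    x = (np.arange(n) + 0.5) / n
    rho = np.where(x < 0.5, 1.0, 0.125)
    p = np.where(x < 0.5, 1.0, 0.1)
    return x, np.stack([rho, np.zeros(n), p / (gamma - 1)])


def run_1d(U, dx, t_end, gamma=1.4, cfl=0.4, bc=("transmissive",
                                                 "transmissive")):
    """Drive waf_update_1d to t_end with a CFL-limited step."""
    from blasttube.waf_solver import waf_update_1d

    t = 0.0
    while t < t_end - 1e-15:
        u = U[1] / U[0]
        p = (gamma - 1) * (U[2] - 0.5 * U[0] * u**2)
        a = np.sqrt(gamma * p / U[0])
        dt = min(cfl * dx / np.max(np.abs(u) + a), t_end - t)
        U = waf_update_1d(U, dt, dx, gamma, bc=bc)
        t += dt
    return U


@pytest.fixture(scope="session")
def sod_solutions():
    """WAF Sod solutions at 100/200/400 cells with exact references."""
    from blasttube.riemann import PrimitiveState1D, sample_exact

    t_end = 0.25
    out = {}
    for n in (100, 200, 400):
        x, U = sod_initial(n)
        U = run_1d(U, 1.0 / n, t_end)
        exact = sample_exact(PrimitiveState1D(1, 0, 1),
                             PrimitiveState1D(0.125, 0, 0.1),
                             1.4, (x - 0.5) / t_end)
        out[n] = (x, U, exact)
    return out
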