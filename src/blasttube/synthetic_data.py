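"""Synthetic cohorts, physiology time series, and pressure traces.

Stand-ins for the live-animal experiment with the statistical structure the
analyses assume, so the whole pipeline can be exercised and calibrated
without measured data.

Cohort model (a generative hypothesis, not a fitted estimate): per animal

    arrest  ~ Bernoulli( logistic(beta0 + beta1 * alpha^armor * dose) )
    recover | arrest ~ Bernoulli(rho)
    death  <=>  arrest and not recover

``dose`` is the peak overpressure at the animal in kPa; ``alpha`` in (0, 1]
is the armor attenuation factor multiplying the effective dose (alpha = 1:
no protection).  Every exposed animal gets lung hemorrhage; other organ
flags are sampled at rates matching the observed cohort.  The default
parameters are chosen so the expected cohort reproduces the observed
margins (8 arrests of 17, of which 3 recover) at the default dose.

Physiology model: group-mean trajectories per variable at the five
timepoints (pre-injury, 5 min, 1 h, 2 h, 3 h) plus AR(1) within-subject
noise; animals that die contribute only the pre and 5-min values, since
unrecovered arrest is fatal within the first hour.  The default
trajectories are illustrative — no numeric physiology is published.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .injury_stats import AnimalRecord, Cohort
from .waveform import FriedlanderParams, PressureTrace, friedlander

__all__ = [
    "CohortModel",
    "PhysiologyModel",
    "DEFAULT_DOSE_KPA",
    "generate_cohort",
    "expected_arrest_rates",
    "ArmorEffectFit",
    "recover_armor_effect",
    "generate_physiology",
    "generate_trace",
    "TIMEPOINTS",
]

TIMEPOINTS = ("pre", "5min", "1h", "2h", "3h")
DEFAULT_DOSE_KPA = 200.0

# Defaults tuned so that, at the default dose, expected arrest probabilities
# are 6/11 (no armor) and 1/3 (armor): 17 animals with a 6/17 armor fraction
# then give 8 expected arrests, of which rho = 3/8 recover.
_BETA0 = -3.0
_BETA1 = (logit(6 / 11) - _BETA0) / DEFAULT_DOSE_KPA
_ALPHA = (logit(1 / 3) - _BETA0) / (logit(6 / 11) - _BETA0)


@dataclass(frozen=True)
class CohortModel:
    """Generative parameters of a synthetic cohort."""

    n: int = 17
    armor_fraction: float = 6 / 17
    beta0: float = _BETA0            # baseline arrest log-odds
    beta1: float = float(_BETA1)     # per-kPa dose coefficient
    alpha: float = float(_ALPHA)     # armor dose attenuation, (0, 1]
    rho: float = 3 / 8               # recovery probability given arrest
    mean_body_weight: float = 38.0   # kg
    sd_body_weight: float = 3.2      # kg
    # organ-flag probabilities besides the always-present lung hemorrhage
    p_splenic_iah: float = 14 / 17   # joint splenic injury + IAH
    p_hemothorax: float = 5 / 17
    p_br: float = 2 / 17
    p_liver: float = 1 / 17
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("armor_fraction", "rho", "p_splenic_iah",
                     "p_hemothorax", "p_br", "p_liver"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n < 1:
            raise ValueError("n must be positive")


def expected_arrest_rates(model: CohortModel, dose_kpa: float):
    """Closed-form arrest probabilities (no-armor, armor) at a dose."""
    p_no = expit(model.beta0 + model.beta1 * dose_kpa)
    p_ar = expit(model.beta0 + model.beta1 * model.alpha * dose_kpa)
    return float(p_no), float(p_ar)


def generate_cohort(model: CohortModel, dose_kpa: float = DEFAULT_DOSE_KPA,
                    seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort at the given peak-overpressure dose (kPa).

    Reproducible for a fixed (model, seed); ``seed`` overrides the model's.
    Death occurs exactly when arrest is not followed by spontaneous
    recovery, so death implies arrest in every generated cohort.
    """
    if dose_kpa <= 0:
        raise ValueError("dose must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n_armor = int(round(model.n * model.armor_fraction))
    armor = np.zeros(model.n, dtype=bool)
    armor[:n_armor] = True
    p_no, p_ar = expected_arrest_rates(model, dose_kpa)
    p_arrest = np.where(armor, p_ar, p_no)
    arrest = rng.random(model.n) < p_arrest
    recover = rng.random(model.n) < model.rho
    died = arrest & ~recover
    bw = np.maximum(rng.normal(model.mean_body_weight, model.sd_body_weight,
                               model.n), 1.0)
    spleen = rng.random(model.n) < model.p_splenic_iah
    hemo = rng.random(model.n) < model.p_hemothorax
    br = rng.random(model.n) < model.p_br
    liver = rng.random(model.n) < model.p_liver
    records = []
    for i in range(model.n):
        flags = {"LH"}
        if spleen[i]:
            flags |= {"splenic", "IAH"}
        if hemo[i]:
            flags.add("hemothorax")
        if br[i]:
            flags.add("BR")
        if liver[i]:
            flags.add("liver")
        records.append(AnimalRecord(
            animal_id=i + 1, body_weight=float(bw[i]), armor=bool(armor[i]),
            organ_flags=frozenset(flags),
            respiratory_arrest=bool(arrest[i]),
            outcome="death" if died[i] else "survival"))
    cohort = Cohort(records=records)
    cohort.dose_kpa = dose_kpa
    return cohort


@dataclass(frozen=True)
class ArmorEffectFit:
    alpha: float
    beta0: float
    beta1: float
    identifiable: bool
    converged: bool
    n: int
    log_likelihood: float
    alpha_ci: tuple | None = None   # 95% Wald CI on the alpha scale
    message: str = ""


def recover_armor_effect(cohorts, doses_kpa=None,
                         with_ci: bool = False) -> ArmorEffectFit:
    """Maximum-likelihood fit of the logistic arrest model on pooled data.

    ``cohorts`` is a sequence of cohorts (each carrying ``dose_kpa`` unless
    ``doses_kpa`` supplies one per cohort).  Fits (beta0, beta1, alpha) by
    maximising the Bernoulli likelihood of arrest; alpha is parameterised
    through a logit to keep it in (0, 1].  When the fitted dose effect is
    negligible, alpha is flagged non-identifiable instead of being
    reported as an estimate.
    """
    arrests, armor_v, dose_v = [], [], []
    for k, cohort in enumerate(cohorts):
        d = (doses_kpa[k] if doses_kpa is not None
             else getattr(cohort, "dose_kpa", None))
        if d is None:
            raise ValueError("cohort carries no dose; pass doses_kpa")
        for r in cohort:
            arrests.append(r.respiratory_arrest)
            armor_v.append(r.armor)
            dose_v.append(d)
    y = np.asarray(arrests, dtype=float)
    a = np.asarray(armor_v, dtype=float)
    d = np.asarray(dose_v, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("too few pooled animals for a stable fit")

    def nll(theta):
        b0, b1, la = theta
        alpha = expit(la)
        eta = b0 + b1 * np.where(a > 0, alpha, 1.0) * d
        # stable Bernoulli log-likelihood
        return float(np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta))

    x0 = np.array([0.0, 0.01, 0.0])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
    b0, b1, la = res.x
    alpha = float(expit(la))
    # alpha is identified only through the dose term.  Compare against the
    # dose-free null (intercept-only) model by likelihood ratio; if adding
    # (beta1, alpha) does not improve the fit beyond chi-square(2) at the
    # 5% level, alpha is flagged non-identifiable rather than reported.
    p_null = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    nll_null = -n * (p_null * np.log(p_null)
                     + (1 - p_null) * np.log(1 - p_null))
    lrt = 2.0 * (nll_null - res.fun)
    identifiable = lrt > 5.99
    ci = None
    if with_ci and identifiable:
        H = _fd_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            var_la = cov[2, 2]
            if var_la > 0:
                se_alpha = np.sqrt(var_la) * alpha * (1 - alpha)
                ci = (max(alpha - 1.96 * se_alpha, 0.0),
                      min(alpha + 1.96 * se_alpha, 1.0))
        except np.linalg.LinAlgError:
            ci = (0.0, 1.0)
    return ArmorEffectFit(alpha=alpha, beta0=float(b0), beta1=float(b1),
                          identifiable=bool(identifiable),
                          converged=bool(res.success), n=n,
                          log_likelihood=-float(res.fun), alpha_ci=ci,
                          message=res.message)


def _fd_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (observed information here)."""
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
    return H


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def _default_trajectories() -> dict:
    """Illustrative group-mean trajectories (survivor, dead) per variable.

    Values are physiologically plausible for anesthetised ~40 kg swine; the
    published study shows its physiology only graphically, so these numbers
    parameterise the generator and are not estimates of it.  The dead
    stratum diverges sharply at 5 min (deep hypoxaemia and hypercapnia).
    """
    return {
        "SBP": {"survival": [110, 95, 100, 105, 105],
                "death": [110, 60, np.nan, np.nan, np.nan]},
        "pulse": {"survival": [95, 110, 105, 100, 100],
                  "death": [95, 60, np.nan, np.nan, np.nan]},
        "SpO2": {"survival": [97, 90, 94, 95, 96],
                 "death": [97, 55, np.nan, np.nan, np.nan]},
        "Hb": {"survival": [10.5, 11.0, 10.5, 10.0, 9.8],
               "death": [10.5, 11.5, np.nan, np.nan, np.nan]},
        "PaO2": {"survival": [95, 75, 85, 88, 90],
                 "death": [95, 40, np.nan, np.nan, np.nan]},
        "PaCO2": {"survival": [40, 45, 42, 41, 40],
                  "death": [40, 70, np.nan, np.nan, np.nan]},
        "pH": {"survival": [7.45, 7.38, 7.40, 7.42, 7.43],
               "death": [7.45, 7.15, np.nan, np.nan, np.nan]},
    }


_DEFAULT_NOISE_SD = {"SBP": 8.0, "pulse": 10.0, "SpO2": 2.5, "Hb": 0.8,
                     "PaO2": 8.0, "PaCO2": 4.0, "pH": 0.03}


@dataclass(frozen=True)
class PhysiologyModel:
    """AR(1)-noise physiology generator around group-mean trajectories."""

    trajectories: dict = field(default_factory=_default_trajectories)
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    phi: float = 0.5            # within-subject AR(1) autocorrelation
    stratify_by: str = "outcome"  # "outcome" or "armor"
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")


def generate_physiology(cohort: Cohort, model: PhysiologyModel,
                        seed: int | None = None) -> pd.DataFrame:
    """Long-format physiology table for a cohort.

    Columns: subject, group, armor, time, variable, value.  Survivors have
    all five timepoints; dead animals only pre and 5 min (death occurs
    within the first hour).  Deviations from the group-mean trajectory are
    stationary AR(1) in time with marginal SD ``noise_sd[variable]``.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rows = []
    T = len(TIMEPOINTS)
    phi = model.phi
    innov_scale = np.sqrt(1 - phi**2)
    for r in cohort:
        if model.stratify_by == "outcome":
            g = "death" if r.died else "survival"
        else:
            g = "armor" if r.armor else "no_armor"
        n_obs = 2 if r.died else T
        for var, by_group in model.trajectories.items():
            means = np.asarray(by_group[g], dtype=float)
            sd = model.noise_sd.get(var, 0.0)
            dev = np.empty(T)
            dev[0] = rng.normal(0.0, 1.0)
            for k in range(1, T):
                dev[k] = phi * dev[k - 1] + innov_scale * rng.normal(0.0, 1.0)
            for k in range(n_obs):
                rows.append((r.animal_id, g, r.armor, TIMEPOINTS[k], var,
                             means[k] + sd * dev[k]))
    return pd.DataFrame(rows, columns=["subject", "group", "armor", "time",
                                       "variable", "value"])


def generate_trace(params: FriedlanderParams, noise_sd: float,
                   sample_rate: float, seed: int = 0,
                   t_start: float = 0.0, arrival: float | None = None,
                   record_durations: float = 3.0) -> PressureTrace:
    """Synthetic transducer record: Friedlander waveform plus white noise.

    The record spans ``record_durations`` positive-phase durations past the
    arrival (default 10% of the record before it).  The sample rate must
    resolve the positive phase with at least 100 samples.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    t_plus = params.positive_duration
    if sample_rate * t_plus < 100:
        raise ValueError(
            f"sample rate {sample_rate:.3g} Hz under-resolves the positive "
            f"phase ({t_plus:.3g} s); need >= {100 / t_plus:.3g} Hz")
    if arrival is None:
        arrival = 0.1 * record_durations * t_plus
    dt = 1.0 / sample_rate
    n = int(np.ceil((arrival + record_durations * t_plus) / dt)) + 1
    t = t_start + np.arange(n) * dt
    p = friedlander(t - t_start - arrival, params.peak_overpressure,
                    t_plus, params.decay_shape)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, n)
    return PressureTrace(time=t, overpressure=p, probe_id="synthetic")
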