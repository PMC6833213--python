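"""Synthetic fed-batch cultures for testing the soft sensor end to end.

The generator emulates the two regimes the stoichiometric model assumes: a
lag/exponential growth phase at constant specific growth rate ``mu_max``,
followed by a post-induction deceleration where the growth rate decays
exponentially (``mu(t) = mu_max * exp(-decel_rate * (t - t_induction))``)
while oxygen consumption for maintenance becomes appreciable.  The biomass
trajectory has a closed form under this growth law, so the dense truth
carries no integration error; only the cumulative-OUR rectangle rule
introduces the O(dt) discretization the online estimator must cope with.

Maintenance can be generated either as a biomass polynomial (the online
estimator's parameterization) or as a time-linear ramp ``k1 * (t - t_i)``
(the identification stage's parameterization).  For exact stage-A recovery
tests, :func:`discrete_stage_a_experiment` produces offline observations
straight from the discrete gray-box predictor, i.e. data for which the
identification equations hold with zero residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .exceptions import InvalidInputError
from .model_core import (
    MaintenanceModel,
    OfflineDataset,
    OURSeries,
    beta_of_biomass,
    beta_of_time,
    cumulative_our,
    discrete_cour_prediction,
)
from .strains import ecoli_maintenance

__all__ = [
    "SimulationConfig",
    "TruthTrajectory",
    "SyntheticExperiment",
    "two_phase_biomass",
    "simulate_culture",
    "add_noise",
    "sample_offline",
    "discrete_stage_a_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated fed-batch culture.

    Defaults describe a recombinant E. coli run: inoculation at 0.2 g/l,
    exponential growth at 0.35 1/h, IPTG induction at 10 h after which the
    growth rate decays at 0.2 1/h while the published parabolic maintenance
    law applies; 24 h total, 1-min online grid, hourly offline sampling,
    2% multiplicative noise on cOUR and 5% on DCW.
    """

    alpha_true: float = 1.01
    beta_mode: str = "biomass"  # "biomass" | "time" | "none"
    maintenance: MaintenanceModel = field(default_factory=ecoli_maintenance)
    k1_true: float = 4e-3
    mu_max: float = 0.35
    decel_rate: float = 0.2
    x0: float = 0.2
    t_end: float = 24.0
    induction_time: float = 10.0
    our_noise_cv: float = 0.02
    dcw_noise_cv: float = 0.05
    offline_interval: float = 1.0
    online_interval: float = 1.0 / 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_mode not in ("biomass", "time", "none"):
            raise InvalidInputError(f"unknown beta_mode {self.beta_mode!r}")
        for name in ("alpha_true", "mu_max", "decel_rate", "our_noise_cv", "dcw_noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.offline_interval <= 0 or self.online_interval <= 0:
            raise InvalidInputError("sampling intervals must be positive")
        if not self.t_end > self.induction_time > 0:
            raise InvalidInputError("need t_end > induction_time > 0")
        if not self.x0 > 0:
            raise InvalidInputError("x0 must be positive")


@dataclass(frozen=True)
class TruthTrajectory:
    """Dense noise-free state of a simulated culture."""

    times: NDArray[np.float64]
    x: NDArray[np.float64]
    x_prime: NDArray[np.float64]
    our: NDArray[np.float64]
    cour: NDArray[np.float64]


@dataclass(frozen=True)
class SyntheticExperiment:
    """Ground truth plus the noisy observables a real run would provide."""

    truth: TruthTrajectory
    observed_our_series: OURSeries
    offline_dataset: OfflineDataset
    config: SimulationConfig


def two_phase_biomass(
    t: NDArray[np.float64] | float,
    mu_max: float,
    decel_rate: float,
    x0: float,
    induction_time: float,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Closed-form biomass ``X(t)`` and derivative for the two-phase growth law.

    Pre-induction: ``X = x0 * exp(mu_max * t)``.  Post-induction the specific
    growth rate decays exponentially, giving
    ``X = X(t_ind) * exp(mu_max * (1 - exp(-d*(t - t_ind))) / d)``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    x_ind = x0 * np.exp(mu_max * induction_time)
    tau = t_arr - induction_time
    if decel_rate > 0:
        growth_int = mu_max * (1.0 - np.exp(-decel_rate * tau)) / decel_rate
    else:
        growth_int = mu_max * tau
    x = np.where(
        t_arr <= induction_time,
        x0 * np.exp(mu_max * t_arr),
        x_ind * np.exp(growth_int),
    )
    mu = np.where(
        t_arr <= induction_time,
        mu_max,
        mu_max * np.exp(-decel_rate * np.maximum(tau, 0.0)),
    )
    return x, mu * x


def simulate_culture(config: SimulationConfig) -> SyntheticExperiment:
    """Noise-free simulated culture on the online grid.

    The truth satisfies the forward oxygen balance pointwise on its grid;
    cOUR is accumulated with the same right-endpoint rectangle rule the
    estimators use.  Observables equal the truth (add noise separately with
    :func:`add_noise`).
    """
    n = int(round(config.t_end / config.online_interval))
    times = np.linspace(0.0, n * config.online_interval, n + 1)
    x, x_prime_analytic = two_phase_biomass(
        times, config.mu_max, config.decel_rate, config.x0, config.induction_time
    )
    # The growth rate is represented by backward differences of the exact
    # biomass so that the right-endpoint cumulative rule telescopes:
    # cOUR_m = alpha*(X_m - X_0) + sum beta_j X_j dt exactly on the grid.
    x_prime = np.empty_like(x)
    x_prime[1:] = np.diff(x) / np.diff(times)
    x_prime[0] = x_prime_analytic[0]
    if config.beta_mode == "biomass":
        beta = np.asarray(beta_of_biomass(config.maintenance, x))
    elif config.beta_mode == "time":
        beta = np.asarray(beta_of_time(config.k1_true, config.induction_time, times))
    else:
        beta = np.zeros_like(times)
    our = config.alpha_true * x_prime + beta * x
    cour = cumulative_our(times, our)
    truth = TruthTrajectory(times=times, x=x, x_prime=x_prime, our=our, cour=cour)
    series = OURSeries(times, our, cour)
    offline = sample_offline(truth, config.offline_interval, config.x0)
    offline = replace(offline, induction_time=config.induction_time, label="synthetic")
    return SyntheticExperiment(
        truth=truth, observed_our_series=series, offline_dataset=offline, config=config
    )


def add_noise(
    experiment: SyntheticExperiment,
    k_exp_for_variance: float | None = None,
    seed: int | None = None,
) -> SyntheticExperiment:
    """Return a copy with multiplicative Gaussian noise on the observables.

    cOUR and offline DCW are perturbed independently; the dense truth is
    untouched.  With ``k_exp_for_variance`` the cOUR noise standard
    deviation follows the Monod-form variance
    ``sigma_m ∝ sqrt(X_m^2 / (1 - K + K X_m^2))`` instead of being
    proportional to the signal.  Reproducible for a fixed seed (defaults to
    the config seed).
    """
    cfg = experiment.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = experiment.truth

    if k_exp_for_variance is None:
        sd = cfg.our_noise_cv * np.abs(truth.cour)
    else:
        k = float(k_exp_for_variance)
        if not 0.0 <= k <= 1.0:
            raise InvalidInputError("k_exp_for_variance must lie in [0, 1]")
        sd = cfg.our_noise_cv * np.sqrt(truth.x**2 / (1.0 - k + k * truth.x**2))
        sd[0] = 0.0  # the integral starts exactly at zero
    cour_noisy = truth.cour + sd * rng.standard_normal(truth.cour.size)
    cour_noisy[0] = 0.0
    series = OURSeries.from_cour(truth.times, cour_noisy)

    ds = experiment.offline_dataset
    dcw_noisy = ds.biomass * (
        1.0 + cfg.dcw_noise_cv * rng.standard_normal(ds.biomass.size)
    )
    offline = OfflineDataset(
        sample_times=ds.sample_times,
        biomass=np.maximum(dcw_noisy, 1e-9),
        x0=ds.x0,
        induction_time=ds.induction_time,
        label=ds.label,
    )
    return SyntheticExperiment(
        truth=truth, observed_our_series=series, offline_dataset=offline, config=cfg
    )


def sample_offline(
    truth: TruthTrajectory, offline_interval: float, x0: float
) -> OfflineDataset:
    """Pick offline DCW observations at multiples of ``offline_interval``.

    Nearest dense-grid point is used for each nominal sampling time; the
    last sample is the largest multiple not exceeding the trajectory end.
    """
    if offline_interval <= 0:
        raise InvalidInputError("offline_interval must be positive")
    t_end = float(truth.times[-1])
    n = int(np.floor(t_end / offline_interval + 1e-9))
    if n < 1:
        raise InvalidInputError(
            f"offline interval {offline_interval} h exceeds the trajectory span {t_end} h"
        )
    nominal = offline_interval * np.arange(1, n + 1)
    idx = np.searchsorted(truth.times, nominal)
    idx = np.clip(idx, 0, truth.times.size - 1)
    left = np.clip(idx - 1, 0, truth.times.size - 1)
    idx = np.where(
        np.abs(truth.times[left] - nominal) < np.abs(truth.times[idx] - nominal),
        left,
        idx,
    )
    return OfflineDataset(
        sample_times=truth.times[idx], biomass=truth.x[idx], x0=x0, label="synthetic"
    )


def discrete_stage_a_experiment(
    alpha: float,
    k1: float,
    t_i: float,
    mu_max: float = 0.35,
    decel_rate: float = 0.2,
    x0: float = 0.2,
    t_end: float = 24.0,
    offline_interval: float = 1.0,
    label: str = "discrete-synthetic",
) -> tuple[OfflineDataset, OURSeries]:
    """Offline observations generated exactly by the discrete gray-box model.

    Biomass follows the two-phase growth law (induction at ``t_i``); the
    cOUR observations at the offline sample times are the discrete piecewise
    predictions themselves, so the identification equations hold with zero
    residual and stage A must recover ``(alpha, k1, t_i)`` to numerical
    precision.  The returned series lives on the offline grid.
    """
    n = int(np.floor(t_end / offline_interval + 1e-9))
    if n < 2:
        raise InvalidInputError("need at least two offline samples")
    sample_times = offline_interval * np.arange(1, n + 1)
    x, _ = two_phase_biomass(sample_times, mu_max, decel_rate, x0, t_i)
    cour = discrete_cour_prediction(sample_times, x, x0, alpha, k1, t_i)
    dataset = OfflineDataset(sample_times=sample_times, biomass=x, x0=x0, label=label)
    series = OURSeries.from_cour(
        np.concatenate(([0.0], sample_times)), np.concatenate(([0.0], cour))
    )
    return dataset, series
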