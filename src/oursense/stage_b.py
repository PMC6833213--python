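"""Online recursive biomass estimation from cumulative oxygen uptake (stage B).

With the strain stoichiometry known, biomass is recovered from the cOUR
stream alone.  Below the maintenance threshold ``X_specific`` the estimator
is the linear map

    X_m = cOUR_m / alpha + X_0,

and above it the maintenance consumption accrued so far is subtracted first:

    X_m = (cOUR_m - sum_l beta(X_l) * X_l * dt_l) / alpha + X_0,

where the running sum uses the previous biomass estimate over each interval
(previous-point rule, computed once per sample, no inner iteration).  The
regime switch is latched: once the estimate has crossed ``X_specific`` the
maintenance correction stays on, which avoids chattering near the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from sklearn.base import BaseEstimator

from .exceptions import DataQualityWarning, InvalidInputError
from .model_core import MaintenanceModel, OURSeries, StrainParameters, beta_of_biomass

__all__ = [
    "EstimatorState",
    "BiomassTrajectory",
    "initialize_estimator",
    "update_estimate",
    "estimate_trajectory",
    "OnlineBiomassEstimator",
    "od_to_dcw",
]

#: default optical-density to dry-cell-weight conversion, g/l per optical unit
OD_TO_DCW_DEFAULT = 0.4

# sensor glitches: a cOUR drop larger than this (g O2/l) triggers a warning
_COUR_DROP_TOL = 1e-6


def od_to_dcw(od: float, factor: float = OD_TO_DCW_DEFAULT) -> float:
    """Convert an optical density (o.u.) to dry cell weight (g/l)."""
    return od * factor


@dataclass(frozen=True)
class EstimatorState:
    """Running state of the online estimator."""

    x_current: float
    maintenance_integral: float  # g O2 / l accrued by the maintenance term
    t_last: float
    x0: float
    above_specific: bool
    cour_last: float = 0.0


@dataclass(frozen=True)
class BiomassTrajectory:
    """Estimated biomass over time with the active regime per point."""

    times: NDArray[np.float64]
    x_estimates: NDArray[np.float64]
    regime: NDArray[np.str_]  # "growth" or "maintenance"

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x_estimates) == len(self.regime)):
            raise InvalidInputError("trajectory fields must have equal length")


def initialize_estimator(
    params: StrainParameters, x0: float, t0: float = 0.0
) -> EstimatorState:
    """Start a fresh estimate at inoculation.

    ``x0`` is the initial biomass in g/l — a DCW measurement directly, or an
    optical density converted via :func:`od_to_dcw`.
    """
    if not x0 > 0:
        raise InvalidInputError(f"initial biomass must be positive, got {x0}")
    return EstimatorState(
        x_current=x0,
        maintenance_integral=0.0,
        t_last=t0,
        x0=x0,
        above_specific=x0 > params.maintenance.x_specific,
        cour_last=0.0,
    )


def update_estimate(
    state: EstimatorState,
    cour_m: float,
    t_m: float,
    params: StrainParameters,
) -> tuple[EstimatorState, float]:
    """Advance the estimator by one cOUR sample.

    Returns the new state and the biomass estimate at ``t_m``.  A slightly
    decreasing cOUR (sensor glitch) is tolerated; a larger drop raises a
    data-quality warning and the value is used as-is.  Estimates are floored
    at zero with a warning.
    """
    if not t_m > state.t_last:
        raise InvalidInputError(
            f"time must advance monotonically (t={t_m} after t={state.t_last})"
        )
    if cour_m < state.cour_last - _COUR_DROP_TOL:
        warnings.warn(
            f"cOUR decreased from {state.cour_last:.6g} to {cour_m:.6g} at t={t_m} h; "
            "using the stream value as-is",
            DataQualityWarning,
            stacklevel=2,
        )
    maintenance = state.maintenance_integral
    if state.above_specific:
        # previous-point rule over [t_last, t_m]
        beta_prev = float(beta_of_biomass(params.maintenance, max(state.x_current, 0.0)))
        maintenance += beta_prev * state.x_current * (t_m - state.t_last)
    x_m = (cour_m - maintenance) / params.alpha + state.x0
    if x_m < 0.0:
        warnings.warn(
            f"biomass estimate {x_m:.6g} g/l at t={t_m} h floored at 0",
            DataQualityWarning,
            stacklevel=2,
        )
        x_m = 0.0
    new_state = EstimatorState(
        x_current=x_m,
        maintenance_integral=maintenance,
        t_last=t_m,
        x0=state.x0,
        # latched: never reverts below the threshold
        above_specific=state.above_specific or x_m > params.maintenance.x_specific,
        cour_last=cour_m,
    )
    return new_state, x_m


def estimate_trajectory(
    params: StrainParameters,
    our_series: OURSeries,
    x0: float,
    t0: float | None = None,
) -> BiomassTrajectory:
    """Fold the online estimator over a full cOUR series.

    The first point of the series is taken as the initialization point; its
    estimate is ``x0``.  Deterministic given identical inputs.
    """
    if t0 is None:
        t0 = float(our_series.times[0])
    state = initialize_estimator(params, x0, t0)
    n = our_series.times.size
    x_est = np.empty(n)
    regime = np.empty(n, dtype=object)
    x_est[0] = x0
    regime[0] = "maintenance" if state.above_specific else "growth"
    # collect per-point data-quality warnings into one summary per stream
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DataQualityWarning)
        for m in range(1, n):
            state, x_m = update_estimate(
                state, float(our_series.cour_values[m]), float(our_series.times[m]), params
            )
            x_est[m] = x_m
            regime[m] = "maintenance" if state.above_specific else "growth"
    n_quality = sum(issubclass(w.category, DataQualityWarning) for w in caught)
    if n_quality:
        warnings.warn(
            f"{n_quality} data-quality events (cOUR drops or floored estimates) "
            f"over {n} samples",
            DataQualityWarning,
            stacklevel=2,
        )
    return BiomassTrajectory(
        times=our_series.times.copy(),
        x_estimates=x_est,
        regime=np.asarray(regime, dtype=str),
    )


class OnlineBiomassEstimator(BaseEstimator):
    """Stage-B estimator: biomass from a cOUR stream, scikit-learn style.

    ``fit`` stores (or identifies nothing — the strain parameters are the
    model) and validates the configuration; ``predict(X)`` maps a cOUR
    series to biomass estimates.

    Parameters
    ----------
    strain_parameters : StrainParameters
        Output of stage A (or a published parameter set).
    x0 : float or None
        Initial biomass g/l.  Alternatively give ``od0`` in optical units.
    od0 : float or None
        Initial optical density; converted at ``od_factor`` g/l per o.u.
    od_factor : float, default 0.4
    """

    def __init__(
        self,
        strain_parameters: StrainParameters | None = None,
        x0: float | None = None,
        od0: float | None = None,
        od_factor: float = OD_TO_DCW_DEFAULT,
    ):
        self.strain_parameters = strain_parameters
        self.x0 = x0
        self.od0 = od0
        self.od_factor = od_factor

    def _resolve_x0(self) -> float:
        if self.x0 is not None:
            return float(self.x0)
        if self.od0 is not None:
            return od_to_dcw(float(self.od0), self.od_factor)
        raise InvalidInputError("either x0 (g/l) or od0 (o.u.) must be given")

    def fit(self, X=None, y=None):
        """Validate the configuration; no free parameters are learned."""
        if self.strain_parameters is None:
            raise InvalidInputError("strain_parameters must be set before use")
        self.x0_ = self._resolve_x0()
        return self

    def predict(self, X: OURSeries) -> NDArray[np.float64]:
        """Biomass estimates (g/l) for each point of the series ``X``."""
        return self.predict_trajectory(X).x_estimates

    def predict_trajectory(self, X: OURSeries) -> BiomassTrajectory:
        """Full trajectory with per-point regime flags."""
        if not hasattr(self, "x0_"):
            self.fit()
        return estimate_trajectory(self.strain_parameters, X, self.x0_)
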