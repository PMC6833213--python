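"""Luedeking–Piret oxygen stoichiometry: core model and containers.

The oxygen balance of an aerobic culture is written as

    OUR(t) = alpha * X'(t) + beta * X(t)

where ``alpha`` (g O2 per g DCW) is the specific oxygen yield for growth and
``beta`` (1/h scaled by the same mass ratio) the maintenance coefficient,
covering cell upkeep and product formation.  Integrating from inoculation
gives the cumulative uptake cOUR, the sole online driver of the soft sensor.

Two parameterizations of ``beta`` are used at different stages: a time-linear
ramp ``beta(t) = k1 * (t - t_i)`` activated at an induction/onset time
``t_i`` (identification stage), and a biomass polynomial
``beta(X) = k_b2*X^2 + k_b1*X + k_b0`` activated above a strain-specific
biomass ``X_specific`` (online estimation stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import InvalidInputError

__all__ = [
    "OURSeries",
    "OfflineDataset",
    "MaintenanceModel",
    "StrainParameters",
    "cumulative_our",
    "beta_of_time",
    "beta_of_biomass",
    "forward_our",
    "maintenance_riemann_terms",
    "discrete_cour_prediction",
]


def _as_1d_float(x: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def cumulative_our(times: ArrayLike, our_values: ArrayLike) -> NDArray[np.float64]:
    """Cumulative oxygen uptake by the right-endpoint rectangle rule.

    ``c[0] = 0`` and ``c[m] = c[m-1] + OUR(t_m) * (t_m - t_{m-1})`` — the
    integrand is taken at the right endpoint of each subinterval, mirroring
    the discretization used throughout the identification equations.

    Parameters
    ----------
    times : array-like, hours, strictly increasing.
    our_values : array-like, g O2 / l / h, same length.

    Returns
    -------
    ndarray, g O2 / l, same length, starting at 0.
    """
    t = _as_1d_float(times, "times")
    our = _as_1d_float(our_values, "our_values")
    if t.shape != our.shape:
        raise InvalidInputError(
            f"times and our_values must have equal length ({t.size} != {our.size})"
        )
    if t.size == 0:
        raise InvalidInputError("empty time vector")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise InvalidInputError(f"times must be strictly increasing (violated at index {bad})")
    c = np.empty_like(t)
    c[0] = 0.0
    np.cumsum(our[1:] * dt, out=c[1:])
    return c


def beta_of_time(k1: float, t_i: float, t: ArrayLike) -> NDArray[np.float64] | float:
    """Time-linear maintenance coefficient ``max(0, k1 * (t - t_i))``.

    Zero before the activation time ``t_i``; clamped at zero afterwards so a
    negative slope can never produce an unphysical oxygen credit.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.maximum(0.0, k1 * (t_arr - t_i))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class MaintenanceModel:
    """Polynomial maintenance coefficient ``beta(X)`` with activation threshold.

    ``beta(X) = 0`` for ``X <= x_specific`` and
    ``max(0, k_beta2*X^2 + k_beta1*X + k_beta0)`` above it.
    ``degree`` is 1 (linear, yeast-like) or 2 (parabolic, E. coli-like);
    degree 1 forces ``k_beta2 = 0``.
    """

    k_beta2: float
    k_beta1: float
    k_beta0: float
    x_specific: float
    degree: int = 2
    x_specific_from_stationary_point: bool = False

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise InvalidInputError(f"degree must be 1 or 2, got {self.degree}")
        if self.degree == 1 and self.k_beta2 != 0.0:
            raise InvalidInputError("degree-1 maintenance model requires k_beta2 = 0")
        if not self.x_specific > 0:
            raise InvalidInputError(f"x_specific must be positive, got {self.x_specific}")

    def beta(self, x: ArrayLike) -> NDArray[np.float64] | float:
        return beta_of_biomass(self, x)


def beta_of_biomass(model: MaintenanceModel, x: ArrayLike) -> NDArray[np.float64] | float:
    """Biomass-dependent maintenance coefficient (piecewise, clamped at zero)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InvalidInputError("biomass must be non-negative")
    poly = model.k_beta2 * x_arr**2 + model.k_beta1 * x_arr + model.k_beta0
    out = np.where(x_arr <= model.x_specific, 0.0, np.maximum(0.0, poly))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def forward_our(
    alpha: float,
    model: MaintenanceModel,
    times: ArrayLike,
    x_values: ArrayLike,
    x_derivatives: ArrayLike,
) -> NDArray[np.float64]:
    """Forward oxygen uptake rate ``alpha * X'(t) + beta(X(t)) * X(t)``.

    The switch between the growth-only and growth-plus-maintenance regimes at
    ``X_specific`` is internal to :func:`beta_of_biomass`.
    """
    t = _as_1d_float(times, "times")
    x = _as_1d_float(x_values, "x_values")
    dx = _as_1d_float(x_derivatives, "x_derivatives")
    if not (t.shape == x.shape == dx.shape):
        raise InvalidInputError("times, x_values and x_derivatives must have equal length")
    return alpha * dx + np.asarray(beta_of_biomass(model, x)) * x


@dataclass(frozen=True)
class OURSeries:
    """Sampled oxygen-uptake-rate signal with its cumulative integral.

    times are hours since inoculation (first entry is t0); our_values in
    g O2/l/h; cour_values in g O2/l, derived, with cour_values[0] = 0.
    """

    times: NDArray[np.float64]
    our_values: NDArray[np.float64]
    cour_values: NDArray[np.float64]

    def __post_init__(self) -> None:
        t = _as_1d_float(self.times, "times")
        our = _as_1d_float(self.our_values, "our_values")
        cour = _as_1d_float(self.cour_values, "cour_values")
        if not (t.size == our.size == cour.size):
            raise InvalidInputError("times, our_values, cour_values must have equal length")
        if t.size < 2:
            raise InvalidInputError("a series needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if cour[0] != 0.0:
            raise InvalidInputError("cour_values must start at 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "our_values", our)
        object.__setattr__(self, "cour_values", cour)

    @classmethod
    def from_our(cls, times: ArrayLike, our_values: ArrayLike) -> "OURSeries":
        """Build a series from an OUR signal, integrating to get cOUR."""
        t = _as_1d_float(times, "times")
        our = _as_1d_float(our_values, "our_values")
        return cls(t, our, cumulative_our(t, our))

    @classmethod
    def from_cour(cls, times: ArrayLike, cour_values: ArrayLike) -> "OURSeries":
        """Build a series from a cumulative signal, differencing to get OUR."""
        t = _as_1d_float(times, "times")
        cour = _as_1d_float(cour_values, "cour_values")
        if cour.size < 2:
            raise InvalidInputError("a series needs at least 2 points")
        if cour[0] != 0.0:
            cour = cour - cour[0]  # re-base at inoculation
        our = np.empty_like(cour)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidInputError("times must be strictly increasing")
        our[1:] = np.diff(cour) / dt
        our[0] = our[1]
        return cls(t, our, cour)

    def cour_at(self, sample_times: ArrayLike, tol: float | None = None) -> NDArray[np.float64]:
        """cOUR at given times by nearest-grid lookup within ``tol`` hours.

        Default tolerance is half the median grid spacing.
        """
        st = _as_1d_float(sample_times, "sample_times")
        if tol is None:
            tol = 0.5 * float(np.median(np.diff(self.times)))
        idx = np.searchsorted(self.times, st)
        idx = np.clip(idx, 0, self.times.size - 1)
        left = np.clip(idx - 1, 0, self.times.size - 1)
        pick_left = np.abs(self.times[left] - st) < np.abs(self.times[idx] - st)
        idx = np.where(pick_left, left, idx)
        off = np.abs(self.times[idx] - st)
        if np.any(off > tol + 1e-12):
            bad = st[off > tol + 1e-12]
            raise InvalidInputError(
                f"sample times {bad.tolist()} not matched on the series grid within {tol} h"
            )
        return self.cour_values[idx]


@dataclass(frozen=True)
class OfflineDataset:
    """Sparse timed biomass observations (DCW, g/l) for one experiment."""

    sample_times: NDArray[np.float64]
    biomass: NDArray[np.float64]
    x0: float
    induction_time: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        t = _as_1d_float(self.sample_times, "sample_times")
        x = _as_1d_float(self.biomass, "biomass")
        if t.size != x.size:
            raise InvalidInputError("sample_times and biomass must have equal length")
        if t.size < 2:
            raise InvalidInputError("need at least 2 offline samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("sample_times must be strictly increasing")
        if np.any(x < 0):
            raise InvalidInputError("biomass must be non-negative")
        if not self.x0 > 0:
            raise InvalidInputError(f"x0 must be positive, got {self.x0}")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "biomass", x)

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)


@dataclass(frozen=True)
class StrainParameters:
    """Everything the online estimator needs for one cell strain."""

    alpha: float
    k1: float
    t_i: float
    k_exp: float
    maintenance: MaintenanceModel
    strain_label: str = ""

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidInputError(f"alpha must be positive, got {self.alpha}")
        if not 0.0 <= self.k_exp <= 1.0:
            raise InvalidInputError(f"k_exp must lie in [0, 1], got {self.k_exp}")


def maintenance_riemann_terms(
    sample_times: ArrayLike,
    biomass: ArrayLike,
    t_i: float,
    t0: float = 0.0,
) -> NDArray[np.float64]:
    """Cumulative maintenance regressor over the offline grid.

    Returns ``M`` with ``M[m] = sum_{l<=m, t_l > t_i} (t_l - t_i) * X_l * dt_l``
    where ``dt_l = t_l - t_{l-1}`` (``t_0`` prepended as the inoculation
    time).  Terms at or before ``t_i`` contribute zero, so the cumulative
    sum is monotone non-decreasing for non-negative biomass.  ``k1 * M[m]``
    is the maintenance part of the discrete cOUR prediction.
    """
    t = _as_1d_float(sample_times, "sample_times")
    x = _as_1d_float(biomass, "biomass")
    if t.shape != x.shape:
        raise InvalidInputError("sample_times and biomass must have equal length")
    dt = np.diff(np.concatenate(([t0], t)))
    terms = np.where(t > t_i, (t - t_i) * x * dt, 0.0)
    return np.cumsum(terms)


def discrete_cour_prediction(
    sample_times: ArrayLike,
    biomass: ArrayLike,
    x0: float,
    alpha: float,
    k1: float,
    t_i: float,
    t0: float = 0.0,
) -> NDArray[np.float64]:
    """Piecewise gray-box cOUR prediction on the offline grid.

    ``cOUR_m = alpha * (X_m - X_0)`` for ``t_m <= t_i`` and
    ``alpha * (X_m - X_0) + k1 * M[m]`` after, with ``M`` the maintenance
    Riemann sum of :func:`maintenance_riemann_terms`.
    """
    x = _as_1d_float(biomass, "biomass")
    growth = alpha * (x - x0)
    return growth + k1 * maintenance_riemann_terms(sample_times, x, t_i, t0=t0)
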