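"""Validation indicators for biomass estimates.

MAE, MAPE and RMSE between estimated and observed biomass, evaluated at the
offline sampling times, over two accounting windows: since inoculation and
since the start of substrate feeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .exceptions import InvalidInputError
from .model_core import OfflineDataset
from .stage_b import BiomassTrajectory

__all__ = ["EvaluationReport", "mae", "mape", "rmse", "evaluate_estimation"]


def _paired(estimates: ArrayLike, observations: ArrayLike):
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if est.shape != obs.shape or est.ndim != 1:
        raise InvalidInputError(
            f"estimates and observations must be equal-length 1-d arrays "
            f"(shapes {est.shape} vs {obs.shape})"
        )
    if est.size == 0:
        raise InvalidInputError("empty input")
    return est, obs


def mae(estimates: ArrayLike, observations: ArrayLike) -> float:
    """Mean absolute error, g/l."""
    est, obs = _paired(estimates, observations)
    return float(np.mean(np.abs(est - obs)))


def mape(estimates: ArrayLike, observations: ArrayLike) -> float:
    """Mean absolute percentage error, %.  Zero observations are an error."""
    est, obs = _paired(estimates, observations)
    if np.any(obs == 0):
        raise InvalidInputError("MAPE undefined for zero observations")
    return float(100.0 * np.mean(np.abs((est - obs) / obs)))


def rmse(estimates: ArrayLike, observations: ArrayLike) -> float:
    """Root mean square error, g/l.  Never smaller than the MAE."""
    est, obs = _paired(estimates, observations)
    return float(np.sqrt(np.mean((est - obs) ** 2)))


@dataclass(frozen=True)
class EvaluationReport:
    """Windowed error report for one estimated trajectory."""

    mae_since_inoculation: float
    mae_since_feed_start: float
    mape_since_inoculation: float
    mape_since_feed_start: float
    rmse_since_inoculation: float
    rmse_since_feed_start: float
    n_since_inoculation: int
    n_since_feed_start: int

    @property
    def rmse(self) -> float:
        return self.rmse_since_inoculation

    def as_dict(self) -> dict[str, float]:
        return {
            "mae_since_inoculation_g_per_l": self.mae_since_inoculation,
            "mae_since_feed_start_g_per_l": self.mae_since_feed_start,
            "mape_since_inoculation_pct": self.mape_since_inoculation,
            "mape_since_feed_start_pct": self.mape_since_feed_start,
            "rmse_since_inoculation_g_per_l": self.rmse_since_inoculation,
            "rmse_since_feed_start_g_per_l": self.rmse_since_feed_start,
            "n_since_inoculation": self.n_since_inoculation,
            "n_since_feed_start": self.n_since_feed_start,
        }


def evaluate_estimation(
    trajectory: BiomassTrajectory,
    offline: OfflineDataset,
    feed_start: float = 0.0,
) -> EvaluationReport:
    """Compare an estimated trajectory with offline DCW observations.

    Each offline sample is matched to the nearest trajectory point; samples
    farther than half the trajectory's median sampling interval are an
    error.  Metrics are reported over the full run and over
    ``t >= feed_start``.
    """
    t_traj = trajectory.times
    tol = 0.5 * float(np.median(np.diff(t_traj)))
    st = offline.sample_times
    idx = np.searchsorted(t_traj, st)
    idx = np.clip(idx, 0, t_traj.size - 1)
    left = np.clip(idx - 1, 0, t_traj.size - 1)
    idx = np.where(np.abs(t_traj[left] - st) < np.abs(t_traj[idx] - st), left, idx)
    off = np.abs(t_traj[idx] - st)
    if np.any(off > tol + 1e-12):
        bad = st[off > tol + 1e-12].tolist()
        raise InvalidInputError(f"offline samples at {bad} h not matched on the trajectory")
    est = trajectory.x_estimates[idx]
    obs = offline.biomass

    window = st >= feed_start
    if not np.any(window):
        raise InvalidInputError(f"no offline samples at or after feed_start = {feed_start} h")
    return EvaluationReport(
        mae_since_inoculation=mae(est, obs),
        mae_since_feed_start=mae(est[window], obs[window]),
        mape_since_inoculation=mape(est, obs),
        mape_since_feed_start=mape(est[window], obs[window]),
        rmse_since_inoculation=rmse(est, obs),
        rmse_since_feed_start=rmse(est[window], obs[window]),
        n_since_inoculation=int(st.size),
        n_since_feed_start=int(np.count_nonzero(window)),
    )
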