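"""Offline identification of oxygen-consumption stoichiometry (stage A).

Given per-experiment cumulative oxygen uptake (cOUR) and sparse offline
dry-cell-weight samples, this module identifies the strain's stoichiometric
parameters: the growth yield ``alpha``, the maintenance ramp slope ``k1``
with its activation time ``t_i``, and the biomass-polynomial maintenance
model ``beta(X)`` with its threshold ``X_specific``.

The fitting criterion is the entropy-style negative weighted sum of squared
cOUR residuals, with per-sample inverse variances of Monod form

    sigma^2_m  ∝  X_m^2 / (1 - K_exp + X_m^2 * K_exp),

so ``K_exp = 1`` is ordinary least squares and ``K_exp = 0`` weights
residuals by 1/X_m^2 (squared-percentage-error).  Maximizing the criterion
in (alpha, k1) is a weighted linear least-squares problem with a closed-form
2x2 normal system; the activation time ``t_i`` is found by exhaustive search
over a candidate grid when it is not known a priori (yeast cultures), and is
taken as given when it is (IPTG induction of E. coli).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator

from .exceptions import (
    DataQualityWarning,
    DegenerateFitError,
    InvalidInputError,
    InvalidModelError,
)
from .model_core import (
    MaintenanceModel,
    OfflineDataset,
    OURSeries,
    StrainParameters,
    discrete_cour_prediction,
    maintenance_riemann_terms,
)

__all__ = [
    "WeightedCriterionValue",
    "ExperimentFit",
    "StageAFitReport",
    "XSpecificResult",
    "uncertainty_weight",
    "entropy_criterion",
    "solve_stoichiometry",
    "find_induction_time",
    "fit_maintenance_polynomial",
    "compute_x_specific",
    "fit_strain",
    "StoichiometryIdentifier",
]

# Relative determinant threshold below which the 2x2 normal system is
# declared collinear.
_SINGULAR_RTOL = 1e-12


@dataclass(frozen=True)
class WeightedCriterionValue:
    """Entropy criterion value S (non-positive) at one parameter point."""

    s_value: float
    alpha: float
    k1: float
    t_i: float
    k_exp: float


@dataclass(frozen=True)
class ExperimentFit:
    """Per-experiment stage-A solution and its precision weights."""

    label: str
    alpha: float
    k1: float
    t_i: float
    weight_alpha: float  # B of the normal system: precision of alpha
    weight_k1: float  # F of the normal system: precision of k1
    s_value: float
    residuals: NDArray[np.float64]  # weighted residuals, one per offline sample


@dataclass
class StageAFitReport:
    """Aggregate result of a strain fit."""

    strain_parameters: StrainParameters
    per_experiment: list[ExperimentFit]
    beta_samples: NDArray[np.float64]  # shape (n, 2): columns (X_m, beta(t_m))
    criterion_trace: list[tuple[float, float]]  # (t_i candidate, S), sorted
    x_specific_from_stationary_point: bool = False
    degree_downgraded: bool = False

    @property
    def per_experiment_residuals(self) -> dict[str, NDArray[np.float64]]:
        return {f.label: f.residuals for f in self.per_experiment}


class XSpecificResult(NamedTuple):
    value: float
    from_stationary_point: bool


def uncertainty_weight(x_m: ArrayLike, k_exp: float) -> NDArray[np.float64] | float:
    """Inverse-variance weight ``(K_exp*X^2 + (1 - K_exp)) / X^2``.

    The reciprocal of the Monod-form proportional variance.  ``K_exp = 1``
    gives uniform weights (plain least squares); ``K_exp = 0`` gives 1/X^2.
    """
    if not 0.0 <= k_exp <= 1.0:
        raise InvalidInputError(f"k_exp must lie in [0, 1], got {k_exp}")
    x = np.asarray(x_m, dtype=float)
    if np.any((x == 0) & (k_exp < 1.0)):
        raise InvalidInputError("weight diverges at x_m = 0 for k_exp < 1")
    if np.any(x < 0):
        raise InvalidInputError("biomass must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(x > 0, (k_exp * x**2 + (1.0 - k_exp)) / np.where(x > 0, x, 1.0) ** 2, 1.0)
    return float(w) if np.isscalar(x_m) or x.ndim == 0 else w


def _aligned_cour(dataset: OfflineDataset, cour: ArrayLike) -> NDArray[np.float64]:
    c = np.asarray(cour, dtype=float)
    if c.shape != dataset.sample_times.shape:
        raise InvalidInputError(
            "cOUR values must be aligned to the offline sample times "
            f"({c.size} values for {dataset.n_samples} samples)"
        )
    return c


def entropy_criterion(
    dataset: OfflineDataset,
    cour: ArrayLike,
    alpha: float,
    k1: float,
    t_i: float,
    k_exp: float,
) -> WeightedCriterionValue:
    """Negative weighted sum of squared cOUR residuals at (alpha, k1, t_i).

    Zero iff the gray-box model reproduces every offline sample exactly;
    more negative is worse.  Residuals are taken against the discrete
    piecewise prediction (growth term always, maintenance Riemann sum for
    samples after ``t_i``).
    """
    c = _aligned_cour(dataset, cour)
    pred = discrete_cour_prediction(
        dataset.sample_times, dataset.biomass, dataset.x0, alpha, k1, t_i
    )
    w = np.asarray(uncertainty_weight(dataset.biomass, k_exp))
    s = -float(np.sum(w * (c - pred) ** 2))
    return WeightedCriterionValue(s_value=s, alpha=alpha, k1=k1, t_i=t_i, k_exp=k_exp)


def _normal_system(
    dataset: OfflineDataset, cour: NDArray[np.float64], t_i: float, k_exp: float
) -> tuple[float, float, float, float, float]:
    """Coefficients (A, B, C, D, F) of the weighted 2x2 normal system.

    The system is [[B, C], [C, F]] @ [alpha, k1] = [A, D]; the two
    off-diagonal coefficients coincide (the printed "E" equals "C"), as they
    must for normal equations of a weighted linear model with regressors
    (X_m - X0) and the maintenance Riemann sum M_m.
    """
    x = dataset.biomass
    w = np.asarray(uncertainty_weight(x, k_exp))
    g = x - dataset.x0
    m_sum = maintenance_riemann_terms(dataset.sample_times, x, t_i)
    a = float(np.sum(w * g * cour))
    b = float(np.sum(w * g * g))
    c_ = float(np.sum(w * g * m_sum))
    d = float(np.sum(w * cour * m_sum))
    f = float(np.sum(w * m_sum * m_sum))
    return a, b, c_, d, f


def solve_stoichiometry(
    dataset: OfflineDataset,
    cour: ArrayLike,
    t_i: float,
    k_exp: float,
) -> tuple[float, float]:
    """Closed-form maximizer of the entropy criterion in (alpha, k1).

    Solves the weighted normal equations.  With no offline samples after
    ``t_i`` the maintenance regressor vanishes and the fit degenerates to
    the one-parameter growth yield ``alpha = A/B`` with ``k1 = 0``.
    """
    c_obs = _aligned_cour(dataset, cour)
    a, b, c_, d, f = _normal_system(dataset, c_obs, t_i, k_exp)
    if b <= 0:
        raise DegenerateFitError(
            "all offline biomass samples equal x0: growth regressor is zero"
        )
    if f == 0.0:  # no samples after t_i
        return a / b, 0.0
    det = b * f - c_ * c_
    if det <= _SINGULAR_RTOL * b * f:
        raise DegenerateFitError(
            "singular normal system: growth and maintenance regressors are collinear "
            f"(det = {det:.3e}, B*F = {b * f:.3e})"
        )
    alpha = (a * f - c_ * d) / det
    k1 = (b * d - a * c_) / det
    return alpha, k1


def find_induction_time(
    dataset: OfflineDataset,
    cour: ArrayLike,
    k_exp: float,
    candidates: ArrayLike | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Exhaustive search for the maintenance activation time ``t_i``.

    For each candidate, solve the closed-form system and score it with the
    entropy criterion; return the maximizer (ties broken toward the earliest
    candidate, which activates maintenance sooner).  Default candidates are
    the offline sample times themselves.  Used for cultures without a known
    induction event; when the induction time is known it should be passed
    directly to :func:`solve_stoichiometry` instead.
    """
    c_obs = _aligned_cour(dataset, cour)
    if candidates is None:
        cand = dataset.sample_times.copy()
    else:
        cand = np.sort(np.asarray(candidates, dtype=float))
    if cand.size == 0:
        raise InvalidInputError("candidate grid for t_i is empty")
    trace: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None  # (s, t_i)
    any_solved = False
    for t_i in cand:
        try:
            alpha, k1 = solve_stoichiometry(dataset, c_obs, float(t_i), k_exp)
        except DegenerateFitError:
            continue
        any_solved = True
        s = entropy_criterion(dataset, c_obs, alpha, k1, float(t_i), k_exp).s_value
        trace.append((float(t_i), s))
        # strict improvement only: ties keep the earliest candidate
        if best is None or s > best[0]:
            best = (s, float(t_i))
    if not any_solved or best is None:
        raise DegenerateFitError("every t_i candidate produced a degenerate fit")
    t_best = best[1]
    if not np.any(dataset.sample_times > t_best):
        warnings.warn(
            "no offline samples fall after the selected t_i: the maintenance "
            "slope is unidentifiable and the criterion is flat in t_i",
            DataQualityWarning,
            stacklevel=2,
        )
    return t_best, sorted(trace)


def fit_maintenance_polynomial(
    beta_samples: ArrayLike,
    degree: int = 2,
    auto_downgrade: bool = False,
) -> MaintenanceModel:
    """Ordinary least-squares polynomial fit of beta against biomass.

    ``beta_samples`` is an (n, 2) array of (X_m, beta_m) pairs pooled across
    experiments, with ``beta_m = k1 * (t_m - t_i)`` from the time-linear
    stage.  With ``auto_downgrade`` a degree-2 fit whose parabola is
    decreasing at the top of the observed biomass range is refit at degree 1
    (a maintenance demand that falls with biomass is not physical here).
    """
    pts = np.asarray(beta_samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("beta_samples must be an (n, 2) array of (X, beta) pairs")
    if degree not in (1, 2):
        raise InvalidInputError(f"degree must be 1 or 2, got {degree}")
    x, b = pts[:, 0], pts[:, 1]
    if np.unique(x).size < degree + 1:
        raise InvalidInputError(
            f"need at least {degree + 1} distinct biomass values for a degree-{degree} fit"
        )
    design = np.vander(x, degree + 1)  # columns: highest power first
    coef, _, rank, _ = np.linalg.lstsq(design, b, rcond=None)
    if rank < degree + 1:
        raise DegenerateFitError("rank-deficient maintenance regression")
    if degree == 2:
        k2, k1_, k0 = (float(v) for v in coef)
        if auto_downgrade and 2.0 * k2 * float(np.max(x)) + k1_ < 0:
            model = fit_maintenance_polynomial(pts, degree=1, auto_downgrade=False)
            return model
    else:
        k2 = 0.0
        k1_, k0 = (float(v) for v in coef)
    xs = compute_x_specific(k2, k1_, k0, degree)
    return MaintenanceModel(
        k_beta2=k2,
        k_beta1=k1_,
        k_beta0=k0,
        x_specific=xs.value,
        degree=degree,
        x_specific_from_stationary_point=xs.from_stationary_point,
    )


def compute_x_specific(
    k_beta2: float, k_beta1: float, k_beta0: float, degree: int
) -> XSpecificResult:
    """Biomass threshold above which the maintenance term applies.

    Degree 1: the root ``-k_beta0 / k_beta1``.  Degree 2: the largest real
    root of the parabola; when the discriminant is negative (the parabola
    never crosses zero) fall back to its stationary point
    ``-k_beta1 / (2 k_beta2)`` and flag the fallback.  The result must be
    positive to be a usable threshold.
    """
    if degree == 1:
        if k_beta1 == 0.0:
            raise InvalidModelError("degree-1 maintenance model with zero slope has no root")
        xs = -k_beta0 / k_beta1
        if not xs > 0:
            raise InvalidModelError(f"non-positive x_specific {xs} from linear model")
        return XSpecificResult(float(xs), False)
    if degree == 2:
        if k_beta2 == 0.0:
            return compute_x_specific(0.0, k_beta1, k_beta0, degree=1)
        disc = k_beta1 * k_beta1 - 4.0 * k_beta2 * k_beta0
        if disc >= 0:
            r = np.sqrt(disc)
            roots = ((-k_beta1 - r) / (2 * k_beta2), (-k_beta1 + r) / (2 * k_beta2))
            xs = max(roots)
            if not xs > 0:
                raise InvalidModelError(f"non-positive x_specific {xs} from quadratic model")
            return XSpecificResult(float(xs), False)
        xs = -k_beta1 / (2.0 * k_beta2)
        if not xs > 0:
            raise InvalidModelError(
                f"non-positive stationary point {xs}; maintenance model unusable"
            )
        return XSpecificResult(float(xs), True)
    raise InvalidInputError(f"degree must be 1 or 2, got {degree}")


class StoichiometryIdentifier(BaseEstimator):
    """Stage-A estimator: strain stoichiometry from offline experiments.

    Scikit-learn style: ``fit(X)`` with ``X`` a sequence of
    ``(OfflineDataset, OURSeries)`` pairs, one per cultivation experiment of
    the same strain.  Fitted attributes carry the identified parameters.

    Parameters
    ----------
    k_exp : float, default 0.4
        Monod-form weight coefficient in [0, 1].  1 is plain least squares,
        0 weights residuals by 1/X^2.  0.4 is the empirically recommended
        compromise for both bacterial and yeast cultures.
    degree : {1, 2}, default 2
        Degree of the beta(X) maintenance polynomial (1 linear / yeast-like,
        2 parabolic / E. coli-like).
    induction_time : float or None
        Known activation time in hours; overrides any per-dataset value and
        skips the t_i search.  When neither is given, t_i is found by
        exhaustive entropy maximization over ``candidate_grid``.
    candidate_grid : array-like or None
        t_i candidates for the search; default is each experiment's offline
        sample times.
    auto_degree : bool, default True
        Downgrade a decreasing degree-2 maintenance fit to degree 1.
    strain_label : str
        Free-text label stored on the result.

    Attributes
    ----------
    strain_parameters_ : StrainParameters
    report_ : StageAFitReport
    alpha_, k1_, t_i_ : float
    maintenance_ : MaintenanceModel
    """

    def __init__(
        self,
        k_exp: float = 0.4,
        degree: int = 2,
        induction_time: float | None = None,
        candidate_grid: Sequence[float] | None = None,
        auto_degree: bool = True,
        strain_label: str = "",
    ):
        self.k_exp = k_exp
        self.degree = degree
        self.induction_time = induction_time
        self.candidate_grid = candidate_grid
        self.auto_degree = auto_degree
        self.strain_label = strain_label

    def fit(self, X: Sequence[tuple[OfflineDataset, OURSeries]], y=None):
        """Identify stoichiometric parameters from experiments ``X``."""
        if not 0.0 <= self.k_exp <= 1.0:
            raise InvalidInputError(f"k_exp must lie in [0, 1], got {self.k_exp}")
        experiments = list(X)
        if not experiments:
            raise InvalidInputError("need at least one experiment")
        fits: list[ExperimentFit] = []
        beta_pts: list[tuple[float, float]] = []
        trace: list[tuple[float, float]] = []
        for idx, (dataset, series) in enumerate(experiments):
            label = dataset.label or f"experiment-{idx}"
            try:
                cour = series.cour_at(dataset.sample_times)
                t_i = self.induction_time
                if t_i is None:
                    t_i = dataset.induction_time
                if t_i is None:
                    t_i, tr = find_induction_time(
                        dataset, cour, self.k_exp, self.candidate_grid
                    )
                    trace.extend(tr)
                alpha, k1 = solve_stoichiometry(dataset, cour, t_i, self.k_exp)
                crit = entropy_criterion(dataset, cour, alpha, k1, t_i, self.k_exp)
                _, b, _, _, f = _normal_system(dataset, cour, t_i, self.k_exp)
                pred = discrete_cour_prediction(
                    dataset.sample_times, dataset.biomass, dataset.x0, alpha, k1, t_i
                )
                w = np.asarray(uncertainty_weight(dataset.biomass, self.k_exp))
                resid = np.sqrt(w) * (cour - pred)
            except (InvalidInputError, DegenerateFitError) as err:
                raise type(err)(f"[{label}] {err}") from err
            fits.append(
                ExperimentFit(
                    label=label,
                    alpha=alpha,
                    k1=k1,
                    t_i=t_i,
                    weight_alpha=b,
                    weight_k1=f,
                    s_value=crit.s_value,
                    residuals=resid,
                )
            )
            post = dataset.sample_times > t_i
            beta_pts.extend(
                zip(
                    dataset.biomass[post].tolist(),
                    (k1 * (dataset.sample_times[post] - t_i)).tolist(),
                )
            )

        b_tot = sum(f.weight_alpha for f in fits)
        alpha = sum(f.alpha * f.weight_alpha for f in fits) / b_tot
        f_tot = sum(f.weight_k1 for f in fits)
        k1 = sum(f.k1 * f.weight_k1 for f in fits) / f_tot if f_tot > 0 else 0.0
        t_i = float(np.median([f.t_i for f in fits]))

        beta_samples = np.asarray(beta_pts, dtype=float).reshape(-1, 2)
        maintenance = None
        downgraded = False
        if beta_samples.shape[0] >= self.degree + 1:
            try:
                maintenance = fit_maintenance_polynomial(
                    beta_samples, degree=self.degree, auto_downgrade=self.auto_degree
                )
            except InvalidModelError:
                if self.auto_degree and self.degree == 2:
                    try:
                        maintenance = fit_maintenance_polynomial(beta_samples, degree=1)
                    except (InvalidModelError, InvalidInputError):
                        maintenance = None
            if maintenance is not None:
                downgraded = maintenance.degree < self.degree
        if maintenance is None:
            warnings.warn(
                "maintenance law unidentifiable from the post-t_i samples; "
                "maintenance disabled (beta = 0)",
                DataQualityWarning,
                stacklevel=2,
            )
            maintenance = MaintenanceModel(0.0, 0.0, 0.0, np.inf, degree=1)

        params = StrainParameters(
            alpha=alpha,
            k1=k1,
            t_i=t_i,
            k_exp=self.k_exp,
            maintenance=maintenance,
            strain_label=self.strain_label,
        )
        self.strain_parameters_ = params
        self.report_ = StageAFitReport(
            strain_parameters=params,
            per_experiment=fits,
            beta_samples=beta_samples,
            criterion_trace=sorted(trace),
            x_specific_from_stationary_point=maintenance.x_specific_from_stationary_point,
            degree_downgraded=downgraded,
        )
        self.alpha_ = alpha
        self.k1_ = k1
        self.t_i_ = t_i
        self.maintenance_ = maintenance
        self.n_experiments_ = len(fits)
        return self


def fit_strain(
    experiments: Sequence[tuple[OfflineDataset, OURSeries]],
    k_exp: float = 0.4,
    degree: int = 2,
    induction_time: float | None = None,
    candidate_grid: Sequence[float] | None = None,
    auto_degree: bool = True,
    strain_label: str = "",
) -> StageAFitReport:
    """Functional wrapper over :class:`StoichiometryIdentifier`."""
    est = StoichiometryIdentifier(
        k_exp=k_exp,
        degree=degree,
        induction_time=induction_time,
        candidate_grid=candidate_grid,
        auto_degree=auto_degree,
        strain_label=strain_label,
    )
    est.fit(experiments)
    return est.report_
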