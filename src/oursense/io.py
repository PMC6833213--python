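"""Delimited-text interchange: time series CSVs and strain-parameter files.

All time series travel as headered CSV with time in hours; strain parameters
as a flat JSON document mirroring the published parameter-table field set.
Reading is line-number-aware so malformed process data is reported usably.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .model_core import MaintenanceModel, StrainParameters
from .stage_b import BiomassTrajectory

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_strain_parameters",
    "read_strain_parameters",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

_REQUIRED_PARAM_FIELDS = (
    "alpha",
    "k1",
    "t_i",
    "k_exp",
    "degree",
    "k_beta2",
    "k_beta1",
    "k_beta0",
    "x_specific",
)


def read_timeseries_csv(
    path: str | Path, time_column: str, value_column: str
) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column time series; returns (times, values).

    Blank lines and ``#`` comment lines are skipped; CRLF and LF files parse
    identically.  Non-numeric cells and non-monotone time raise a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    header: list[str] | None = None
    ti = vi = -1
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                if time_column not in header:
                    raise ParseError(f"missing column {time_column!r} in {path}", lineno)
                if value_column not in header:
                    raise ParseError(f"missing column {value_column!r} in {path}", lineno)
                ti, vi = header.index(time_column), header.index(value_column)
                continue
            if len(cells) <= max(ti, vi):
                raise ParseError(f"too few columns in {path}", lineno)
            try:
                t = float(cells[ti])
                v = float(cells[vi])
            except ValueError:
                raise ParseError(f"non-numeric cell in {path}", lineno) from None
            if times and t <= times[-1]:
                raise ParseError(
                    f"non-monotone time {t} after {times[-1]} in {path}", lineno
                )
            times.append(t)
            values.append(v)
    if header is None:
        raise ParseError(f"empty file {path}")
    return np.asarray(times), np.asarray(values)


def write_timeseries_csv(
    path: str | Path, columns: dict[str, np.ndarray]
) -> None:
    """Write named columns as a headered CSV."""
    pd.DataFrame(columns).to_csv(path, index=False)


def write_strain_parameters(params: StrainParameters, path: str | Path) -> None:
    """Serialize strain parameters as a flat JSON document (lossless floats)."""
    m = params.maintenance
    doc = {
        "strain_label": params.strain_label,
        "alpha": params.alpha,
        "k1": params.k1,
        "t_i": params.t_i,
        "k_exp": params.k_exp,
        "degree": m.degree,
        "k_beta2": m.k_beta2,
        "k_beta1": m.k_beta1,
        "k_beta0": m.k_beta0,
        "x_specific": m.x_specific,
        "x_specific_from_stationary_point": m.x_specific_from_stationary_point,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_strain_parameters(path: str | Path) -> StrainParameters:
    """Inverse of :func:`write_strain_parameters`.

    Missing required fields are a :class:`ParseError`; unknown extra fields
    are ignored with a warning (forward compatibility).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"invalid JSON in {path}: {err}") from err
    if not isinstance(doc, dict):
        raise ParseError(f"{path} does not contain a parameter object")
    for field_name in _REQUIRED_PARAM_FIELDS:
        if field_name not in doc:
            raise ParseError(f"missing field {field_name!r} in {path}")
    known = set(_REQUIRED_PARAM_FIELDS) | {
        "strain_label",
        "x_specific_from_stationary_point",
    }
    extra = sorted(set(doc) - known)
    if extra:
        warnings.warn(f"ignoring unknown fields {extra} in {path}", stacklevel=2)
    maintenance = MaintenanceModel(
        k_beta2=float(doc["k_beta2"]),
        k_beta1=float(doc["k_beta1"]),
        k_beta0=float(doc["k_beta0"]),
        x_specific=float(doc["x_specific"]),
        degree=int(doc["degree"]),
        x_specific_from_stationary_point=bool(
            doc.get("x_specific_from_stationary_point", False)
        ),
    )
    return StrainParameters(
        alpha=float(doc["alpha"]),
        k1=float(doc["k1"]),
        t_i=float(doc["t_i"]),
        k_exp=float(doc["k_exp"]),
        maintenance=maintenance,
        strain_label=str(doc.get("strain_label", "")),
    )


def write_trajectory_csv(trajectory: BiomassTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_h": trajectory.times,
            "x_est_g_per_l": trajectory.x_estimates,
            "regime": trajectory.regime,
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> BiomassTrajectory:
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "x_est_g_per_l"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    regime = (
        df["regime"].astype(str).to_numpy()
        if "regime" in df.columns
        else np.full(len(df), "unknown")
    )
    return BiomassTrajectory(
        times=df["time_h"].to_numpy(float),
        x_estimates=df["x_est_g_per_l"].to_numpy(float),
        regime=regime,
    )
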