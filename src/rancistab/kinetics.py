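"""Log-linear OSI-temperature kinetics: shelf-life extrapolation and Q10.

Accelerated oxidation shortens the induction time roughly geometrically
with temperature, so over a modest range the model

    log10 OSI(T) = A * T + B

is fitted by ordinary least squares to the cell-mean OSI at each elevated
temperature (typically 110/120/130 C).  Derived quantities:

* temperature coefficient ``t_coeff`` = 100 * A (slope in units of 1e-2),
* extrapolated shelf life ``osi_22`` = 10**(22 A + B) at a 22 C shelf,
* ``q10``, the factor by which stability drops per 10 C, computed as the
  arithmetic mean of successive ratios OSI(T) / OSI(T + 10).

The Q10 ratio rule and the slope rule 10**(-10 A) coincide exactly when
the data follow the model without noise; on real replicate means they
differ slightly, and the ratio mean is the canonical value here with the
slope-based figure exposed as ``q10_from_slope``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTemperatures,
    EmptyCell,
    FewerThanTwoTemperatures,
    NonPositiveOSI,
    NonUniformSpacing,
)

__all__ = [
    "KineticFit",
    "summarize_osi",
    "fit_log_linear",
    "predict_osi",
    "compute_q10",
    "q10_from_slope",
    "fit_osi_table",
]

#: Required columns of an OSI table (one row per replicate measurement).
OSI_COLUMNS = ("temperature_C", "airflow_L_h", "replicate", "osi_h")


@dataclass(frozen=True)
class KineticFit:
    """OLS fit of log10(OSI) on temperature for one airflow.

    ``a`` is the slope in log10(hours) per degree C, ``b`` the intercept in
    log10(hours); ``t_coeff`` = 100 * a.  ``osi_22`` (hours) and ``q10``
    (unitless) are attached by :func:`fit_osi_table` / the caller.
    """

    airflow: float
    a: float
    b: float
    se_a: float
    se_b: float
    r_squared: float
    t_coeff: float
    osi_22: float
    q10: float
    n_points: int


def _validate_osi_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OSI_COLUMNS if c not in table.columns]
    if missing:
        raise EmptyCell(f"OSI table missing columns: {missing}")
    if table.empty:
        raise EmptyCell("OSI table has no rows")
    if (table["osi_h"] <= 0).any() or not np.isfinite(table["osi_h"]).all():
        raise NonPositiveOSI("all OSI values must be finite and > 0")
    return table


def summarize_osi(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell replicate summary: mean OSI, CV and n.

    The coefficient of variance is the conventional percent CV,
    ``100 * sample SD / mean`` (SD with ddof=1).  Cells with a single
    replicate get ``cv = NaN`` rather than zero.

    Parameters
    ----------
    table : DataFrame
        Replicate-level OSI table with columns ``temperature_C,
        airflow_L_h, replicate, osi_h``.

    Returns
    -------
    DataFrame
        One row per (temperature, airflow) cell, sorted by temperature
        then airflow, with columns ``temperature_C, airflow_L_h, mean_osi_h,
        cv_pct, n``.
    """
    table = _validate_osi_table(table)
    grouped = table.groupby(["temperature_C", "airflow_L_h"], sort=True)["osi_h"]
    out = grouped.agg(mean_osi_h="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    out["cv_pct"] = np.where(out["n"] >= 2, 100.0 * out["sd"] / out["mean_osi_h"], np.nan)
    out["n"] = out["n"].astype(int)
    return out[["temperature_C", "airflow_L_h", "mean_osi_h", "cv_pct", "n"]]


def fit_log_linear(
    points: Iterable[tuple[float, float]], airflow: float = float("nan")
) -> KineticFit:
    """OLS fit of log10(mean OSI) against temperature.

    Parameters
    ----------
    points : iterable of (temperature_C, mean_osi_h)
        At least three distinct temperatures, all OSI > 0.
    airflow : float, optional
        Airflow label carried through to the result.

    Returns
    -------
    KineticFit
        With ``q10`` computed by :func:`compute_q10` when the temperatures
        form an exact 10 C chain, else NaN, and ``osi_22`` from
        :func:`predict_osi` at 22 C.
    """
    pts = sorted((float(T), float(o)) for T, o in points)
    T = np.array([p[0] for p in pts])
    osi = np.array([p[1] for p in pts])
    if np.unique(T).size < 3:
        raise DegenerateTemperatures("need >= 3 distinct temperatures")
    if np.any(osi <= 0) or not np.all(np.isfinite(osi)):
        raise NonPositiveOSI("all OSI values must be finite and > 0")

    lr = stats.linregress(T, np.log10(osi))
    try:
        q10 = compute_q10(pts)
    except (NonUniformSpacing, FewerThanTwoTemperatures):
        q10 = float("nan")
    fit = KineticFit(
        airflow=airflow,
        a=float(lr.slope),
        b=float(lr.intercept),
        se_a=float(lr.stderr),
        se_b=float(lr.intercept_stderr),
        r_squared=float(lr.rvalue**2),
        t_coeff=100.0 * float(lr.slope),
        osi_22=float("nan"),
        q10=q10,
        n_points=len(pts),
    )
    return _with_osi22(fit)


def _with_osi22(fit: KineticFit) -> KineticFit:
    from dataclasses import replace

    return replace(fit, osi_22=predict_osi(fit, 22.0))


def predict_osi(fit: KineticFit, temperature: float) -> float:
    """Model OSI (hours) at ``temperature``: ``10**(a * T + b)``."""
    if not np.isfinite(fit.a) or not np.isfinite(fit.b):
        raise ValueError("invalid fit: non-finite coefficients")
    return float(10.0 ** (fit.a * temperature + fit.b))


def compute_q10(points: Sequence[tuple[float, float]]) -> float:
    """Mean of successive ratios OSI(T) / OSI(T + 10) over a 10 C chain.

    Raises
    ------
    FewerThanTwoTemperatures
        If fewer than two temperatures are supplied.
    NonUniformSpacing
        If the sorted temperatures are not spaced by exactly 10 C.
    """
    pts = sorted((float(T), float(o)) for T, o in points)
    if len(pts) < 2:
        raise FewerThanTwoTemperatures("Q10 needs at least two temperatures")
    T = np.array([p[0] for p in pts])
    osi = np.array([p[1] for p in pts])
    if np.any(osi <= 0):
        raise NonPositiveOSI("all OSI values must be > 0")
    if not np.allclose(np.diff(T), 10.0, rtol=0, atol=1e-9):
        raise NonUniformSpacing(f"temperatures {T.tolist()} not on an exact 10 C chain")
    ratios = osi[:-1] / osi[1:]
    return float(np.mean(ratios))


def q10_from_slope(fit: KineticFit) -> float:
    """Slope-based Q10 diagnostic, ``10**(-10 a)``.

    Equals the ratio-based :func:`compute_q10` exactly when the input data
    follow the log-linear model without noise.
    """
    return float(10.0 ** (-10.0 * fit.a))


def fit_osi_table(table: pd.DataFrame) -> list[KineticFit]:
    """Fit the log-linear model per airflow from a replicate-level OSI table.

    Cell means are computed with :func:`summarize_osi` and each airflow's
    (temperature, mean OSI) points are fitted; this mirrors the standard
    reporting layout of one fit row per airflow.
    """
    summary = summarize_osi(table)
    fits = []
    for airflow, grp in summary.groupby("airflow_L_h", sort=True):
        pts = list(zip(grp["temperature_C"], grp["mean_osi_h"]))
        fits.append(fit_log_linear(pts, airflow=float(airflow)))
    return fits
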