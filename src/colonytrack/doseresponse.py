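"""Dose-response analysis for colony-forming assays.

Cluster+colony counts per replicate are normalized to the vehicle
(DMSO) control, then the half-maximal inhibitory concentration (IC50) is
estimated by fitting a four-parameter logistic (4PL) curve in the
inhibitor-response form

    y(x) = bottom + (top - bottom) / (1 + 10**((x - logIC50) * hill))

on x = log10(concentration) — response falls from ``top`` (vehicle
control) toward ``bottom`` with increasing dose when hill > 0 — or — when the 4PL is unidentifiable or does
not converge — by ordinary least squares of the normalized response on
log10(concentration), solving the fitted line for the response level 0.5.

The normalized response is a fraction (control mean = 1.0); the linear
IC50 crossing level defaults to 0.5 on that scale and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit",
    "four_param_logistic",
    "normalize_to_control",
    "fit_4pl",
    "fit_linear_ic50",
    "select_and_fit",
]


def four_param_logistic(
    x: np.ndarray | float, top: float, bottom: float, logic50: float, hill: float
) -> np.ndarray | float:
    """4PL response at x = log10(concentration), base-10 Hill inhibitor
    form: decreasing in x for hill > 0, top at zero dose."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((x - logic50) * hill))


@dataclass
class DoseResponseFit:
    """Result of an IC50 fit.

    ``model`` is "fourPL" or "linear". For the 4PL, ``params`` holds
    (top, bottom, logIC50, hill); for the linear model (intercept, slope).
    ``ic50_nM`` is on the concentration scale (nM).
    """

    model: str
    params: dict[str, float]
    ic50_nM: float
    r_squared: float
    converged: bool
    message: str = ""


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"concentration_nM", "response"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    if (table["concentration_nM"] <= 0).any():
        raise ValueError("concentrations must be strictly positive (log scale)")
    return table


def normalize_to_control(
    treated_counts: pd.DataFrame, control_counts: np.ndarray | list[float]
) -> pd.DataFrame:
    """Normalize per-replicate cluster+colony totals to the control mean.

    ``treated_counts`` needs columns concentration_nM, replicate, count.
    Returns a table with a ``response`` column = count / mean(control);
    by construction the control replicates map to mean 1.0.
    """
    control = np.asarray(control_counts, dtype=float)
    if control.size == 0 or control.mean() == 0:
        raise ValueError("control mean must be positive for normalization")
    out = treated_counts.copy()
    out["response"] = out["count"] / control.mean()
    return out


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_4pl(
    table: pd.DataFrame,
    init: tuple[float, float, float, float] | None = None,
    constrain: dict[str, float] | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of response on log10(concentration).

    Self-starting defaults: top = max response, bottom = min response,
    logIC50 = median log-concentration, hill = 1 (inhibition). Requires
    at least 4
    distinct concentrations; fewer raises ValueError (use the linear
    fallback). Non-convergence is flagged, parameters still returned.
    """
    table = _as_table(table)
    x = np.log10(table["concentration_nM"].to_numpy(dtype=float))
    y = table["response"].to_numpy(dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError(
            "4PL needs >= 4 distinct concentrations; use fit_linear_ic50"
        )
    if init is None:
        init = (float(y.max()), float(y.min()), float(np.median(x)), 1.0)
    constrain = constrain or {}

    names = ["top", "bottom", "logIC50", "hill"]
    free = [n for n in names if n not in constrain]

    def model(xv, *theta):
        full = dict(zip(free, theta))
        full.update(constrain)
        return four_param_logistic(
            xv, full["top"], full["bottom"], full["logIC50"], full["hill"]
        )

    p0 = [init[names.index(n)] for n in free]
    converged = True
    message = ""
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # no convergence within maxfev
        converged = False
        message = str(exc)
        popt = np.asarray(p0, dtype=float)
    params = dict(zip(free, (float(v) for v in popt)))
    params.update(constrain)
    fitted = four_param_logistic(
        x, params["top"], params["bottom"], params["logIC50"], params["hill"]
    )
    return DoseResponseFit(
        model="fourPL",
        params=params,
        ic50_nM=float(10.0 ** params["logIC50"]),
        r_squared=_r_squared(y, np.asarray(fitted)),
        converged=converged,
        message=message,
    )


def fit_linear_ic50(
    table: pd.DataFrame, crossing_level: float = 0.5
) -> DoseResponseFit:
    """OLS of response on log10(concentration); IC50 where the line
    crosses ``crossing_level`` (default 0.5 of control)."""
    table = _as_table(table)
    x = np.log10(table["concentration_nM"].to_numpy(dtype=float))
    y = table["response"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("linear IC50 needs >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("fitted slope is zero: IC50 undefined")
    log_ic50 = (crossing_level - res.intercept) / res.slope
    fitted = res.intercept + res.slope * x
    return DoseResponseFit(
        model="linear",
        params={"intercept": float(res.intercept), "slope": float(res.slope)},
        ic50_nM=float(10.0 ** log_ic50),
        r_squared=_r_squared(y, fitted),
        converged=True,
    )


def select_and_fit(table: pd.DataFrame) -> DoseResponseFit:
    """Fit the 4PL; fall back to the linear model when the 4PL is not
    applicable (fewer than 4 concentrations) or does not converge.

    The engaged fallback is recorded in the returned fit's ``message``.
    """
    try:
        fit = fit_4pl(table)
        if fit.converged:
            return fit
        reason = f"4PL did not converge: {fit.message}"
    except ValueError as exc:
        reason = str(exc)
    try:
        linear = fit_linear_ic50(table)
    except ValueError as exc:
        raise ValueError(
            f"both models failed — 4PL: {reason}; linear: {exc}"
        ) from exc
    linear.message = f"fallback from 4PL ({reason})"
    return linear
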