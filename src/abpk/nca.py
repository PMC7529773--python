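"""Noncompartmental (moment) analysis of concentration-time profiles.

AUC by trapezoid (linear or linear-up/log-down), terminal slope lambda_z
by log-linear regression over terminal points, then the standard chain:

    AUC(0-inf) = AUC(0-tlast) + C_last / lambda_z
    CL  = dose / AUC(0-inf)        (mL/day/kg; dose in μg/kg)
    Vd  = CL / lambda_z            (mL/kg)
    t1/2 = ln 2 / lambda_z         (reported in hours)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .quantities import ConcentrationTimeProfile, NCAResult

__all__ = ["auc_0_t", "estimate_lambda_z", "nca_summary", "LambdaZError"]

AUCMethod = Literal["linear", "linear_up_log_down"]


class LambdaZError(RuntimeError):
    """Terminal slope could not be estimated (e.g. non-declining tail)."""


def auc_0_t(profile: ConcentrationTimeProfile, method: AUCMethod = "linear_up_log_down") -> float:
    """AUC from the first to the last observation, μg·day/mL.

    ``linear`` is the plain trapezoid.  ``linear_up_log_down`` applies the
    log trapezoid on strictly decreasing segments with both endpoints
    positive (the standard choice for declining IV profiles) and the
    linear trapezoid elsewhere.
    """
    if len(profile) < 2:
        raise ValueError("AUC requires at least two observations")
    t = profile.times
    c = profile.concentrations
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "linear_up_log_down":
        raise ValueError(f"unknown AUC method {method!r}")
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    return float(total)


@dataclass(frozen=True)
class LambdaZEstimate:
    lambda_z: float  # 1/day
    n_points: int
    r2_adjusted: float


def estimate_lambda_z(
    profile: ConcentrationTimeProfile,
    selection: Literal["best_fit", "last_n"] = "best_fit",
    last_n: int = 3,
) -> LambdaZEstimate:
    """Terminal elimination rate from log-linear regression.

    ``best_fit`` scans terminal suffixes of length >= 3 (excluding Cmax)
    and keeps the one maximizing adjusted R^2, mirroring common NCA
    software defaults; ``last_n`` uses exactly the last ``last_n`` points.
    A nonpositive fitted slope raises :class:`LambdaZError`.
    """
    t = profile.times
    c = profile.concentrations
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        raise LambdaZError("need at least three positive terminal concentrations")
    logc = np.log(c)

    def fit_suffix(k: int) -> tuple[float, float]:
        ts, ys = t[-k:], logc[-k:]
        res = stats.linregress(ts, ys)
        slope = res.slope
        r2 = res.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        return -slope, r2_adj

    if selection == "last_n":
        if last_n < 3:
            raise ValueError("last_n must be >= 3")
        lam, r2a = fit_suffix(min(last_n, len(t)))
        if lam <= 0:
            raise LambdaZError("terminal concentrations are not declining")
        return LambdaZEstimate(lam, min(last_n, len(t)), r2a)

    i_cmax = int(np.argmax(c))
    max_k = len(t) - (i_cmax + 1)  # points strictly after Cmax
    best: LambdaZEstimate | None = None
    for k in range(3, max(max_k, 0) + 1):
        lam, r2a = fit_suffix(k)
        if lam <= 0:
            continue
        if best is None or r2a > best.r2_adjusted + 1e-12:
            best = LambdaZEstimate(lam, k, r2a)
    if best is None:
        raise LambdaZError("no declining terminal segment of >= 3 points found")
    return best


def nca_summary(
    profile: ConcentrationTimeProfile,
    dose_mg_per_kg: float | None = None,
    auc_method: AUCMethod = "linear_up_log_down",
    selection: Literal["best_fit", "last_n"] = "best_fit",
) -> NCAResult:
    """Full noncompartmental summary for one dose group."""
    dose = profile.dose_mg_per_kg if dose_mg_per_kg is None else dose_mg_per_kg
    if dose <= 0:
        raise ValueError("NCA requires a positive dose")
    lam = estimate_lambda_z(profile, selection=selection)
    auc_t = auc_0_t(profile, method=auc_method)
    c_last = profile.concentrations[profile.concentrations > 0][-1]
    auc_tail = c_last / lam.lambda_z
    auc_inf = auc_t + auc_tail
    cl = dose * 1e3 / auc_inf  # (μg/kg) / (μg·day/mL) = mL/day/kg
    return NCAResult(
        half_life_h=math.log(2.0) / lam.lambda_z * 24.0,
        auc_0_inf=auc_inf,
        clearance=cl,
        vd=cl / lam.lambda_z,
        lambda_z=lam.lambda_z,
        auc_extrapolated_fraction=auc_tail / auc_inf,
        n_lambda_points=lam.n_points,
        r2_adjusted=lam.r2_adjusted,
    )
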