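"""Weighted nonlinear least-squares parameter estimation.

Two fits drive the hybrid workflow: the linear 2-compartment model
against the saturating-dose plasma profile, and the Michaelis-Menten
model against in vitro uptake velocities.  Both minimize

    sum_i w_i (obs_i - pred_i)^2,   w_i = 1/obs_i  ("1/Y" weighting)

the reciprocal-of-observed weighting customary in PK software; uniform
weighting is retained for sensitivity analysis.  Parameters are fitted
on a log scale to enforce positivity, with multi-start initialization
(deterministic heuristics plus seeded log-uniform restarts) to guard
against local minima.  CV% is 100 x SE / estimate with SE from the
linearized covariance at the optimum; on the log scale the SE of log p
is directly the relative SE of p.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import lmfit
import numpy as np

from . import nca
from .pk_model import analytic_linear_conc
from .quantities import (
    ConcentrationTimeProfile,
    FitResult,
    HillParams,
    MichaelisMentenParams,
    TwoCompartmentParams,
    UptakeDataset,
    VmaxScale,
)

__all__ = [
    "WeightingScheme",
    "weighted_objective",
    "fit_two_compartment",
    "fit_michaelis_menten",
    "fit_hill",
    "fit_one_site_binding",
    "OneSiteBindingParams",
    "FitError",
]


class FitError(RuntimeError):
    """Estimation failed to converge; best candidate attached when available."""

    def __init__(self, message: str, best: Optional[FitResult] = None):
        super().__init__(message)
        self.best = best


class WeightingScheme(enum.Enum):
    RECIPROCAL_OBSERVED = "reciprocal_observed"
    UNIFORM = "uniform"


def _weights(observed: np.ndarray, scheme: WeightingScheme) -> np.ndarray:
    if scheme is WeightingScheme.UNIFORM:
        return np.ones_like(observed)
    if np.any(observed <= 0):
        raise ValueError("reciprocal-observed weighting requires strictly positive observations")
    return 1.0 / observed


def weighted_objective(
    observed: Sequence[float],
    predicted: Sequence[float],
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
) -> float:
    """Weighted sum of squared residuals."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal shapes")
    w = _weights(obs, scheme)
    return float(np.sum(w * (obs - pred) ** 2))


# ---------------------------------------------------------------------------
# shared multi-start engine (log-scale parameters)
# ---------------------------------------------------------------------------


def _multistart(
    predict: Callable[[dict[str, float]], np.ndarray],
    observed: np.ndarray,
    scheme: WeightingScheme,
    starts: Sequence[dict[str, float]],
    report_names: dict[str, str],
    bounds: Optional[dict[str, tuple[float, float]]] = None,
) -> tuple[lmfit.minimizer.MinimizerResult, dict[str, float], dict[str, float]]:
    """Run lmfit from each start (parameters fitted as logs), keep the best.

    Ties on objective (within 1e-10 relative) break toward the smaller
    parameter-vector norm.  Returns (best result, estimates, cv_percent);
    ``report_names`` maps internal log-parameter names to reported names.
    ``bounds`` (natural units) constrain parameters whose extremes would
    make the model ill-posed (e.g. an ODE right-hand side approaching a
    discontinuity); they are applied on the log scale.
    """
    sqrt_w = np.sqrt(_weights(observed, scheme))
    bounds = bounds or {}

    def residual(params: lmfit.Parameters) -> np.ndarray:
        values = {k: math.exp(params[k].value) for k in params}
        return sqrt_w * (observed - predict(values))

    best = None
    best_norm = np.inf
    for start in starts:
        params = lmfit.Parameters()
        for name, value in start.items():
            kw = {}
            if name in bounds:
                lo, hi = bounds[name]
                kw = {"min": math.log(lo), "max": math.log(hi)}
                value = min(max(value, lo * (1 + 1e-9)), hi * (1 - 1e-9))
            params.add(name, value=math.log(value), **kw)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        norm = float(np.linalg.norm([p.value for p in res.params.values()]))
        if (
            best is None
            or res.chisqr < best.chisqr * (1 - 1e-10)
            or (abs(res.chisqr - best.chisqr) <= 1e-10 * max(best.chisqr, 1e-300) and norm < best_norm)
        ):
            best, best_norm = res, norm
    if best is None:
        raise FitError("all optimization starts failed")
    estimates = {report_names[k]: math.exp(best.params[k].value) for k in best.params}
    cv = {}
    for i, k in enumerate(best.var_names):
        if best.covar is not None and np.isfinite(best.covar[i, i]) and best.covar[i, i] >= 0:
            cv[report_names[k]] = 100.0 * math.sqrt(best.covar[i, i])
        else:
            cv[report_names[k]] = float("nan")
    return best, estimates, cv


def _clean_cv(cv: dict[str, float]) -> dict[str, float]:
    return {k: (v if np.isfinite(v) else 0.0) for k, v in cv.items()}


# ---------------------------------------------------------------------------
# 2-compartment fit
# ---------------------------------------------------------------------------


def _strip_biexponential(profile: ConcentrationTimeProfile) -> Optional[dict[str, float]]:
    """Curve-stripping start values: terminal fit for (B, beta), residual
    fit for (A, alpha), then the standard macro-to-micro identities."""
    t, c = profile.times, profile.concentrations
    keep = c > 0
    t, c = t[keep], c[keep]
    if len(t) < 4:
        return None
    try:
        lam = nca.estimate_lambda_z(profile)
    except nca.LambdaZError:
        return None
    beta = lam.lambda_z
    k = lam.n_points
    coeffs = np.polyfit(t[-k:], np.log(c[-k:]), 1)
    b_coef = math.exp(coeffs[1])
    resid = c - b_coef * np.exp(-beta * t)
    early = resid > 0
    # need >= 2 early points above the stripped terminal line
    if early.sum() < 2:
        return None
    ta, ra = t[early][:4], resid[early][:4]
    slope, intercept = np.polyfit(ta, np.log(ra), 1)
    alpha = -slope
    if alpha <= beta:
        return None
    a_coef = math.exp(intercept)
    c0 = a_coef + b_coef
    k21 = (a_coef * beta + b_coef * alpha) / c0
    k10 = alpha * beta / k21
    k12 = alpha + beta - k21 - k10
    v1 = profile.dose_mg_per_kg * 1e3 / c0
    if min(k10, k12, k21, v1) <= 0:
        return None
    return {"k10": k10, "k12": k12, "k21": k21, "V1": v1}


def fit_two_compartment(
    profile: ConcentrationTimeProfile,
    dose_mg_per_kg: Optional[float] = None,
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    n_random_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit k10, k12, k21, V1 to one (typically saturating-dose) profile.

    The caller is responsible for choosing a dose at which target-mediated
    clearance is saturated; a warning is attached when the fitted linear
    model systematically under-predicts the late observations (a symptom
    of unsaturated nonlinear elimination in the data).
    """
    dose = profile.dose_mg_per_kg if dose_mg_per_kg is None else dose_mg_per_kg
    keep = profile.concentrations > 0
    times = profile.times[keep]
    observed = profile.concentrations[keep]
    if len(observed) < 4:
        raise ValueError("need at least four positive observations to fit four parameters")

    def predict(values: dict[str, float]) -> np.ndarray:
        p = TwoCompartmentParams(values["k10"], values["k12"], values["k21"], values["V1"])
        return analytic_linear_conc(p, dose, times)

    starts: list[dict[str, float]] = []
    stripped = _strip_biexponential(
        ConcentrationTimeProfile(dose, times, observed, profile.n_animals)
    )
    if stripped is not None:
        starts.append(stripped)
    v1_guess = dose * 1e3 / observed[0]
    starts.append({"k10": 1.0, "k12": 10.0, "k21": 10.0, "V1": v1_guess})
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(
            {
                "k10": 10 ** rng.uniform(-1, 2),
                "k12": 10 ** rng.uniform(-1, 2),
                "k21": 10 ** rng.uniform(-1, 2),
                "V1": 10 ** rng.uniform(1, 2.5),
            }
        )
    names = {n: n for n in ("k10", "k12", "k21", "V1")}
    best, est, cv = _multistart(predict, observed, scheme, starts, names)
    params = TwoCompartmentParams(est["k10"], est["k12"], est["k21"], est["V1"])

    warnings = []
    pred = analytic_linear_conc(params, dose, times)
    late = times > np.median(times)
    if late.sum() >= 2 and np.all(pred[late] < observed[late] * 0.8):
        warnings.append(
            "fitted linear model systematically under-predicts late observations; "
            "target-mediated clearance may not be saturated at this dose"
        )
    return FitResult(
        estimates=params,
        cv_percent=_clean_cv(cv),
        objective_value=float(best.chisqr),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# saturable-uptake fits
# ---------------------------------------------------------------------------


def _uptake_starts(
    data: UptakeDataset, rng: np.random.Generator, n_random: int
) -> list[dict[str, float]]:
    s = data.concentrations_nM
    v = data.velocities
    vmax0 = max(float(v.max()), 1e-12)
    starts = [{"Km": float(np.median(s)), "Vmax": vmax0}]
    for _ in range(n_random):
        starts.append(
            {
                "Km": 10 ** rng.uniform(np.log10(s.min() / 10), np.log10(s.max() * 10)),
                "Vmax": vmax0 * 10 ** rng.uniform(-1, 1),
            }
        )
    return starts


def fit_michaelis_menten(
    data: UptakeDataset,
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    n_random_starts: int = 4,
    seed: int = 0,
) -> FitResult:
    """Fit v = Vmax S / (Km + S); Km in nM, Vmax per assay cell number.

    Attaches an identifiability warning when the Km CV% exceeds 100%
    (typically: all observations far below saturation, so only the
    ratio Vmax/Km is determined).
    """
    keep = data.velocities > 0
    s = data.concentrations_nM[keep]
    observed = data.velocities[keep]
    if len(observed) < 3:
        raise ValueError("need at least three positive velocities")

    def predict(values: dict[str, float]) -> np.ndarray:
        return values["Vmax"] * s / (values["Km"] + s)

    rng = np.random.default_rng(seed)
    sub = UptakeDataset(s, observed)
    best, est, cv = _multistart(
        predict, observed, scheme, _uptake_starts(sub, rng, n_random_starts),
        {"Km": "Km", "Vmax": "Vmax"},
    )
    warnings = []
    if not np.isfinite(cv["Km"]) or cv["Km"] > 100.0:
        warnings.append("Km is poorly identified (CV% > 100); data may not approach saturation")
    return FitResult(
        estimates=MichaelisMentenParams(est["Km"], est["Vmax"], VmaxScale.PER_ASSAY_CELLS),
        cv_percent=_clean_cv(cv),
        objective_value=float(best.chisqr),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        warnings=tuple(warnings),
    )


def fit_hill(
    data: UptakeDataset,
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    n_random_starts: int = 4,
    seed: int = 0,
    fix_n: Optional[float] = None,
) -> FitResult:
    """Fit v = Vmax S^n / (Km^n + S^n); with ``fix_n=1`` this reproduces
    the Michaelis-Menten fit exactly."""
    keep = data.velocities > 0
    s = data.concentrations_nM[keep]
    observed = data.velocities[keep]
    if len(observed) < 4 and fix_n is None:
        raise ValueError("need at least four positive velocities for the Hill fit")

    if fix_n is not None:

        def predict(values: dict[str, float]) -> np.ndarray:
            sn = s**fix_n
            return values["Vmax"] * sn / (values["Km"] ** fix_n + sn)

    else:

        def predict(values: dict[str, float]) -> np.ndarray:
            sn = s ** values["n"]
            return values["Vmax"] * sn / (values["Km"] ** values["n"] + sn)

    rng = np.random.default_rng(seed)
    sub = UptakeDataset(s, observed)
    starts = _uptake_starts(sub, rng, n_random_starts)
    if fix_n is None:
        for st in starts:
            st["n"] = 1.0
    best, est, cv = _multistart(
        predict, observed, scheme, starts, {"Km": "Km", "Vmax": "Vmax", "n": "n"}
    )
    n_hat = fix_n if fix_n is not None else est["n"]
    return FitResult(
        estimates=HillParams(est["Km"], est["Vmax"], n_hat, VmaxScale.PER_ASSAY_CELLS),
        cv_percent=_clean_cv(cv),
        objective_value=float(best.chisqr),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )


@dataclass(frozen=True)
class OneSiteBindingParams:
    """Equilibrium one-site binding: B = Bmax F / (KD + F)."""

    kd_nM: float
    bmax: float


def fit_one_site_binding(
    free_nM: Sequence[float],
    bound: Sequence[float],
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    n_random_starts: int = 4,
    seed: int = 0,
) -> FitResult:
    """Fit KD and Bmax from a bound-vs-free saturation binding table."""
    free = np.asarray(free_nM, dtype=float)
    b = np.asarray(bound, dtype=float)
    if free.shape != b.shape:
        raise ValueError("free and bound must have equal lengths")
    if np.all(b == 0):
        return FitResult(
            estimates=OneSiteBindingParams(kd_nM=float(np.median(free)), bmax=0.0),
            cv_percent={},
            objective_value=0.0,
            converged=True,
            n_iterations=0,
            warnings=("all bound values are zero; Bmax degenerate at 0",),
        )
    keep = b > 0
    data = UptakeDataset(free[keep], b[keep])
    res = fit_michaelis_menten(data, scheme=scheme, n_random_starts=n_random_starts, seed=seed)
    mm = res.estimates
    return FitResult(
        estimates=OneSiteBindingParams(kd_nM=mm.km_nM, bmax=mm.vmax),
        cv_percent={"KD": res.cv_percent["Km"], "Bmax": res.cv_percent["Vmax"]},
        objective_value=res.objective_value,
        converged=res.converged,
        n_iterations=res.n_iterations,
        warnings=res.warnings,
    )
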