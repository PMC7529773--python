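"""End-to-end hybrid PK prediction workflow.

The workflow mirrors the two-source design: (1) fit the linear
2-compartment parameters to the plasma profile at a saturating dose,
where target-mediated clearance contributes little; (2) fit
Michaelis-Menten uptake kinetics to the in vitro cellular assay;
(3) scale the in vitro Vmax to the whole body by target-expressing cell
number and body weight; (4) simulate the combined nonlinear model across
the dose range and compare against observations with fold-error metrics
and NCA exposure.  A joint nonlinear refit of (Km, Vmax) against all
in vivo dose groups is provided as the in vivo reference for the
in vitro estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import nca
from .fitting import WeightingScheme, _clean_cv, _multistart, fit_michaelis_menten, fit_two_compartment
from .ivive import scale_vmax, unscale_vmax
from .pk_model import simulate
from .quantities import (
    ConcentrationTimeProfile,
    FitResult,
    MichaelisMentenParams,
    ScalingContext,
    TwoCompartmentParams,
    VmaxScale,
)

__all__ = [
    "PredictionReport",
    "FoldErrorMetrics",
    "run_hybrid_prediction",
    "fold_error_metrics",
    "joint_fit_in_vivo_nonlinear",
    "dose_clearance_curve",
]

#: boundary-inclusive tolerance for fold windows (floating-point guard only)
_FOLD_EPS = 1e-9


@dataclass(frozen=True)
class FoldErrorMetrics:
    """Symmetric fold-error summary over matched (predicted, observed) pairs."""

    ratios: np.ndarray  # predicted / observed
    fraction_within_2fold: float
    fraction_within_3fold: float

    @property
    def fold_errors(self) -> np.ndarray:
        return np.maximum(self.ratios, 1.0 / self.ratios)


def fold_error_metrics(
    predicted: Sequence[float], observed: Sequence[float]
) -> FoldErrorMetrics:
    """Per-point prediction ratios and fractions within 2- and 3-fold.

    The window boundary is inclusive: a prediction exactly 3-fold off
    counts as within 3-fold.  Pairs with a nonpositive or missing
    observation are dropped.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal shapes")
    keep = np.isfinite(pred) & np.isfinite(obs) & (obs > 0) & (pred > 0)
    ratios = pred[keep] / obs[keep]
    if len(ratios) == 0:
        return FoldErrorMetrics(ratios, float("nan"), float("nan"))
    fold = np.maximum(ratios, 1.0 / ratios)
    return FoldErrorMetrics(
        ratios=ratios,
        fraction_within_2fold=float(np.mean(fold <= 2.0 * (1 + _FOLD_EPS))),
        fraction_within_3fold=float(np.mean(fold <= 3.0 * (1 + _FOLD_EPS))),
    )


@dataclass(frozen=True)
class PredictionReport:
    """Everything the hybrid workflow produced for one study."""

    linear_fit: FitResult  # TwoCompartmentParams from the saturating dose
    uptake_fit: FitResult  # MichaelisMentenParams, assay scale
    mm_per_kg: MichaelisMentenParams  # scaled parameters driving the simulation
    predicted: dict[float, ConcentrationTimeProfile]
    observed: dict[float, ConcentrationTimeProfile] = field(default_factory=dict)
    concentration_metrics: Optional[FoldErrorMetrics] = None
    auc_table: Optional[pd.DataFrame] = None  # dose, predicted/observed AUC, fold error
    n_dropped_observations: int = 0
    saturation_ratio: float = float("nan")  # min C(t)/Km over the linear-fit window

    def points_table(self) -> pd.DataFrame:
        """Long table of matched (dose, time, predicted, observed) points."""
        rows = []
        for dose, obs_profile in self.observed.items():
            pred_profile = self.predicted.get(dose)
            if pred_profile is None:
                continue
            for t, o in zip(obs_profile.times, obs_profile.concentrations):
                idx = np.argmin(np.abs(pred_profile.times - t))
                if not math.isclose(pred_profile.times[idx], t, rel_tol=1e-9, abs_tol=1e-12):
                    continue
                rows.append(
                    {
                        "dose_mg_per_kg": dose,
                        "time_day": t,
                        "predicted_ug_per_mL": pred_profile.concentrations[idx],
                        "observed_ug_per_mL": o,
                    }
                )
        return pd.DataFrame(rows)


def run_hybrid_prediction(
    high_dose_profile: ConcentrationTimeProfile,
    uptake_data,
    ctx: ScalingContext,
    doses: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 100.0),
    schedule_days: Optional[Sequence[float]] = None,
    observed: Optional[Mapping[float, ConcentrationTimeProfile]] = None,
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    seed: int = 0,
) -> PredictionReport:
    """Fit, scale, and predict across the dose range.

    ``high_dose_profile`` should come from a dose where target-mediated
    clearance is saturated (C(t) >> Km over the fit window); the report
    carries the minimum C(t)/Km ratio so the caller can check.  When
    ``observed`` mean profiles are supplied, fold-error metrics and an
    NCA AUC comparison are computed; observations <= 0 are dropped and
    counted.
    """
    linear_fit = fit_two_compartment(high_dose_profile, scheme=scheme, seed=seed)
    uptake_fit = fit_michaelis_menten(uptake_data, scheme=scheme, seed=seed)
    mm_per_kg = scale_vmax(uptake_fit.estimates, ctx)

    if schedule_days is None:
        schedule_days = high_dose_profile.times
    schedule_days = np.asarray(schedule_days, dtype=float)

    predicted = {
        float(d): simulate(linear_fit.estimates, mm_per_kg, float(d), schedule_days)
        for d in doses
    }

    keep = high_dose_profile.concentrations > 0
    sat = (
        float(np.min(high_dose_profile.concentrations[keep]) / mm_per_kg.km_ug_per_mL)
        if keep.any()
        else float("nan")
    )

    metrics = None
    auc_table = None
    n_dropped = 0
    observed = dict(observed) if observed else {}
    if observed:
        pairs_pred: list[float] = []
        pairs_obs: list[float] = []
        auc_rows = []
        for dose, obs_profile in observed.items():
            pred_profile = predicted.get(float(dose))
            if pred_profile is None:
                pred_profile = simulate(linear_fit.estimates, mm_per_kg, float(dose), schedule_days)
                predicted[float(dose)] = pred_profile
            for t, o in zip(obs_profile.times, obs_profile.concentrations):
                idx = int(np.argmin(np.abs(pred_profile.times - t)))
                if not math.isclose(pred_profile.times[idx], t, rel_tol=1e-9, abs_tol=1e-12):
                    continue
                if o <= 0 or not np.isfinite(o):
                    n_dropped += 1
                    continue
                pairs_pred.append(float(pred_profile.concentrations[idx]))
                pairs_obs.append(float(o))
            try:
                auc_pred = nca.nca_summary(pred_profile).auc_0_inf
                auc_obs = nca.nca_summary(obs_profile).auc_0_inf
                ratio = auc_pred / auc_obs
                auc_rows.append(
                    {
                        "dose_mg_per_kg": dose,
                        "auc_pred": auc_pred,
                        "auc_obs": auc_obs,
                        "fold_error": max(ratio, 1.0 / ratio),
                    }
                )
            except (nca.LambdaZError, ValueError):
                pass
        metrics = fold_error_metrics(pairs_pred, pairs_obs)
        if auc_rows:
            auc_table = pd.DataFrame(auc_rows)

    return PredictionReport(
        linear_fit=linear_fit,
        uptake_fit=uptake_fit,
        mm_per_kg=mm_per_kg,
        predicted=predicted,
        observed={float(d): p for d, p in observed.items()},
        concentration_metrics=metrics,
        auc_table=auc_table,
        n_dropped_observations=n_dropped,
        saturation_ratio=sat,
    )


def joint_fit_in_vivo_nonlinear(
    profiles: Mapping[float, ConcentrationTimeProfile],
    p_linear: TwoCompartmentParams,
    ctx: ScalingContext,
    scheme: WeightingScheme = WeightingScheme.RECIPROCAL_OBSERVED,
    free_linear: bool = False,
    n_random_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Fit (Km, Vmax) of the nonlinear model against all dose groups at once.

    The linear disposition parameters are fixed to the saturating-dose
    estimates by default (``free_linear=True`` refits all six).  Km and
    Vmax are estimated on the whole-body scale and reported back on the
    assay scale (pmol/min per assay cell number) via the inverse of the
    IVIVE scaling, so they are directly comparable with the in vitro fit.
    A warning is attached when Km is poorly identified, e.g. when only
    saturating doses are supplied and the saturable term is effectively a
    constant velocity.
    """
    doses = sorted(float(d) for d in profiles)
    obs_list, time_list = [], []
    for d in doses:
        prof = profiles[d]
        keep = prof.concentrations > 0
        obs_list.append(prof.concentrations[keep])
        time_list.append(prof.times[keep])
    observed = np.concatenate(obs_list)

    def predict(values: dict[str, float]) -> np.ndarray:
        if free_linear:
            lin = TwoCompartmentParams(values["k10"], values["k12"], values["k21"], values["V1"])
        else:
            lin = p_linear
        mm = MichaelisMentenParams(
            values["Km"], values["Vmax"], VmaxScale.PER_KG, molar_mass=ctx.molar_mass
        )
        preds = []
        for d, t in zip(doses, time_list):
            preds.append(simulate(lin, mm, d, t, rtol=1e-8, atol=1e-10).concentrations)
        return np.concatenate(preds)

    rng = np.random.default_rng(seed)
    starts: list[dict[str, float]] = [{"Km": 30.0, "Vmax": 5000.0}]
    for _ in range(n_random_starts):
        starts.append({"Km": 10 ** rng.uniform(0, 3), "Vmax": 10 ** rng.uniform(2.5, 4.5)})
    if free_linear:
        for st in starts:
            st.update(p_linear.as_dict())
    names = {k: k for k in starts[0]}
    # bounds keep trial parameters in the regime where the ODE stays
    # well-posed (Km below ~1e-3 nM turns the saturable term into a jump)
    bounds = {"Km": (1e-3, 1e9), "Vmax": (1e-6, 1e8)}
    if free_linear:
        bounds.update({k: (1e-4, 1e4) for k in ("k10", "k12", "k21")})
        bounds["V1"] = (0.1, 1e5)
    best, est, cv = _multistart(predict, observed, scheme, starts, names, bounds=bounds)

    mm_kg = MichaelisMentenParams(
        est["Km"], est["Vmax"], VmaxScale.PER_KG, molar_mass=ctx.molar_mass
    )
    mm_assay = unscale_vmax(mm_kg, ctx)
    warnings = []
    corr = float("nan")
    if best.covar is not None and {"Km", "Vmax"} <= set(best.var_names):
        i, j = best.var_names.index("Km"), best.var_names.index("Vmax")
        denom = math.sqrt(best.covar[i, i] * best.covar[j, j])
        if denom > 0:
            corr = best.covar[i, j] / denom
    if not np.isfinite(cv["Km"]) or cv["Km"] > 100.0 or abs(corr) > 0.999:
        warnings.append(
            "Km is poorly identified (CV% > 100 or Km/Vmax correlation ~ 1); "
            "the dose range may not span the unsaturated regime"
        )
    return FitResult(
        estimates=mm_assay,
        cv_percent=_clean_cv(cv),
        objective_value=float(best.chisqr),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        warnings=tuple(warnings),
    )


def dose_clearance_curve(
    profiles: Mapping[float, ConcentrationTimeProfile]
) -> pd.DataFrame:
    """NCA clearance per dose group, for inspecting clearance saturation."""
    rows = []
    for dose in sorted(float(d) for d in profiles):
        summary = nca.nca_summary(profiles[dose])
        rows.append({"dose_mg_per_kg": dose, "clearance_mL_per_day_per_kg": summary.clearance})
    return pd.DataFrame(rows)
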