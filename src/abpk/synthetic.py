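"""Synthetic in vivo PK studies and in vitro uptake assays.

Emulates the study design the analysis assumes: an IV-bolus dose-ranging
mouse study (doses 1-100 mg/kg, eight sampling times from 5 min to
2 days, n = 3 animals per dose) and a cellular uptake assay spanning
0.01-30 μg/mL at a fixed 15-min incubation.  Residual noise is
multiplicative-lognormal by default (positive values, median-unbiased
around the noise-free curve); a Gaussian proportional option is kept for
sensitivity checks.  Only residual-style noise is emulated — true
inter-animal variability in the disposition parameters is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .pk_model import simulate
from .quantities import (
    ConcentrationTimeProfile,
    HillParams,
    MichaelisMentenParams,
    TwoCompartmentParams,
    UptakeDataset,
    concentration_mass_to_nM,
)

__all__ = [
    "StudyDesign",
    "AssayDesign",
    "REFERENCE_SCHEDULE_DAYS",
    "generate_in_vivo_study",
    "generate_uptake_assay",
    "mean_profile",
]

#: standard sampling schedule: 5 min, 15 min, 30 min, 1 h, 2 h, 7 h, 1 d, 2 d
REFERENCE_SCHEDULE_DAYS: tuple[float, ...] = (
    5 / 1440,
    15 / 1440,
    30 / 1440,
    1 / 24,
    2 / 24,
    7 / 24,
    1.0,
    2.0,
)

ErrorKind = Literal["lognormal", "gaussian", "none"]


@dataclass(frozen=True)
class StudyDesign:
    """Design of an IV-bolus dose-ranging PK study."""

    doses_mg_per_kg: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0)
    schedule_days: tuple[float, ...] = REFERENCE_SCHEDULE_DAYS
    n_per_dose: int = 3
    cv: float = 0.10  # proportional residual CV
    error_kind: ErrorKind = "lognormal"
    lloq: float = 0.0  # quantification floor, μg/mL; values below are clipped to 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if np.any(np.diff(self.schedule_days) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.n_per_dose < 1:
            raise ValueError("need at least one animal per dose")


@dataclass(frozen=True)
class AssayDesign:
    """Design of the cellular uptake assay."""

    concentrations_ug_per_mL: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.geomspace(0.01, 30.0, 12))
    )
    incubation_minutes: float = 15.0
    n_replicates: int = 3
    cv: float = 0.15
    error_kind: ErrorKind = "lognormal"
    seed: int = 0
    molar_mass: float = 148_000.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if any(c <= 0 for c in self.concentrations_ug_per_mL):
            raise ValueError("assay concentrations must be positive")


def _noise_factors(rng: np.random.Generator, shape, cv: float, kind: ErrorKind) -> np.ndarray:
    if cv == 0 or kind == "none":
        return np.ones(shape)
    if kind == "lognormal":
        # sigma chosen so the empirical CV of the factors equals the design CV;
        # median of exp(sigma Z) is exactly 1 (median-unbiased)
        sigma = np.sqrt(np.log1p(cv * cv))
        return np.exp(sigma * rng.standard_normal(shape))
    if kind == "gaussian":
        return 1.0 + cv * rng.standard_normal(shape)
    raise ValueError(f"unknown error kind {kind!r}")


def generate_in_vivo_study(
    p: TwoCompartmentParams,
    mm: Optional[MichaelisMentenParams],
    design: StudyDesign = StudyDesign(),
) -> dict[float, list[ConcentrationTimeProfile]]:
    """Simulate the true model per dose and perturb each animal independently.

    Returns a mapping dose -> list of per-animal profiles.  Negative
    values (possible under Gaussian noise) and values below the
    quantification floor are clipped to 0.  Reproducible under the design
    seed.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.schedule_days, dtype=float)
    study: dict[float, list[ConcentrationTimeProfile]] = {}
    for dose in design.doses_mg_per_kg:
        clean = simulate(p, mm, dose, times).concentrations
        animals = []
        for animal in range(design.n_per_dose):
            factors = _noise_factors(rng, clean.shape, design.cv, design.error_kind)
            conc = clean * factors
            conc = np.where(conc < design.lloq, 0.0, np.maximum(conc, 0.0))
            animals.append(ConcentrationTimeProfile(dose, times, conc, n_animals=1))
        study[dose] = animals
    return study


def mean_profile(animals: Sequence[ConcentrationTimeProfile]) -> ConcentrationTimeProfile:
    """Per-time mean (with SD) across animals of one dose group."""
    if not animals:
        raise ValueError("empty dose group")
    times = animals[0].times
    dose = animals[0].dose_mg_per_kg
    for a in animals[1:]:
        if not np.array_equal(a.times, times) or a.dose_mg_per_kg != dose:
            raise ValueError("animals must share dose and sampling times")
    mat = np.vstack([a.concentrations for a in animals])
    sd = mat.std(axis=0, ddof=1) if len(animals) > 1 else None
    return ConcentrationTimeProfile(
        dose, times, mat.mean(axis=0), n_animals=len(animals), dispersion=sd
    )


def generate_uptake_assay(
    truth: MichaelisMentenParams | HillParams,
    design: AssayDesign = AssayDesign(),
) -> UptakeDataset:
    """Noise-perturbed uptake velocities over the assay concentration range."""
    rng = np.random.default_rng(design.seed)
    conc_nM = np.array(
        [concentration_mass_to_nM(c, design.molar_mass) for c in design.concentrations_ug_per_mL]
    )
    if isinstance(truth, HillParams):
        s_n = conc_nM**truth.n
        clean = truth.vmax * s_n / (truth.km_nM**truth.n + s_n)
    else:
        clean = truth.vmax * conc_nM / (truth.km_nM + conc_nM)
    all_conc, all_vel, all_rep = [], [], []
    for rep in range(design.n_replicates):
        factors = _noise_factors(rng, clean.shape, design.cv, design.error_kind)
        all_conc.append(conc_nM)
        all_vel.append(np.maximum(clean * factors, 0.0))
        all_rep.append(np.full(conc_nM.shape, rep))
    return UptakeDataset(
        np.concatenate(all_conc), np.concatenate(all_vel), np.concatenate(all_rep)
    )
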