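"""Domain types and unit conversions shared by all modules.

Canonical internal units
------------------------
* time: days
* plasma concentration: ``μg/mL``
* amounts per body weight: ``μg/kg``
* rate constants: ``1/day``
* central volume: ``mL/kg``

Substrate concentrations for cellular uptake kinetics are held in nM
(molar units are natural for receptor binding); the mass-unit view
``μg/mL`` is derived with the antibody molar mass.  Maximal uptake
velocities carry an explicit scale tag because the per-assay-well value
(pmol/min per 5 x 10^5 cells) and the whole-body value (μg/day/kg)
differ by several orders of magnitude and must never be mixed silently.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VmaxScale",
    "TwoCompartmentParams",
    "MichaelisMentenParams",
    "HillParams",
    "ConcentrationTimeProfile",
    "UptakeDataset",
    "ScalingContext",
    "NCAResult",
    "FitResult",
    "concentration_nM_to_mass",
    "concentration_mass_to_nM",
    "ScaleMismatchError",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440.0
HOURS_PER_DAY = 24.0


class ScaleMismatchError(ValueError):
    """Raised when a Vmax scale tag does not match an operation's contract."""


class VmaxScale(enum.Enum):
    """Scale on which a maximal uptake/elimination velocity is expressed."""

    PER_ASSAY_CELLS = "per_assay_cells"  # pmol/min per assay cell number
    PER_KG = "per_kg"  # μg/day/kg body weight


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


def concentration_nM_to_mass(c_nM: float, molar_mass: float) -> float:
    """Convert a molar concentration (nM) to a mass concentration (μg/mL).

    1 nM = 1e-9 mol/L, so c nM of a species of molar mass M g/mol is
    c * M * 1e-9 g/L = c * M * 1e-6 μg/mL; for a 148 kDa antibody,
    1 nM = 0.148 μg/mL.
    """
    _require_positive(molar_mass=molar_mass)
    if c_nM < 0:
        raise ValueError(f"concentration must be nonnegative, got {c_nM}")
    return c_nM * molar_mass * 1e-6


def concentration_mass_to_nM(c_ug_per_mL: float, molar_mass: float) -> float:
    """Convert a mass concentration (μg/mL) to a molar concentration (nM)."""
    _require_positive(molar_mass=molar_mass)
    if c_ug_per_mL < 0:
        raise ValueError(f"concentration must be nonnegative, got {c_ug_per_mL}")
    return c_ug_per_mL / (molar_mass * 1e-6)


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Linear (target-independent) disposition parameters.

    Attributes
    ----------
    k10 : elimination rate constant from the central compartment, 1/day
    k12 : central-to-peripheral transfer rate constant, 1/day
    k21 : peripheral-to-central transfer rate constant, 1/day
    V1 : central volume of distribution, mL/kg
    """

    k10: float
    k12: float
    k21: float
    V1: float

    def __post_init__(self) -> None:
        _require_positive(k10=self.k10, k12=self.k12, k21=self.k21, V1=self.V1)

    def as_dict(self) -> dict[str, float]:
        return {"k10": self.k10, "k12": self.k12, "k21": self.k21, "V1": self.V1}


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Saturable (target-mediated) uptake/elimination kinetics.

    ``km_nM`` is the half-saturation concentration in nM; the mass-unit
    view ``km_ug_per_mL`` needs the antibody molar mass.  ``vmax`` is
    tagged with its scale: per assay cell number (pmol/min per 5 x 10^5
    cells, the raw in vitro readout) or per kg body weight (μg/day/kg,
    the whole-body scale the disposition model consumes).
    """

    km_nM: float
    vmax: float
    vmax_scale: VmaxScale
    molar_mass: Optional[float] = None  # g/mol; required for the mass view of Km

    def __post_init__(self) -> None:
        _require_positive(km_nM=self.km_nM)
        if not math.isfinite(self.vmax) or self.vmax < 0:
            raise ValueError(f"vmax must be finite and nonnegative, got {self.vmax}")
        if self.molar_mass is not None:
            _require_positive(molar_mass=self.molar_mass)

    @property
    def km_ug_per_mL(self) -> float:
        if self.molar_mass is None:
            raise ValueError("molar_mass is required for the mass-unit view of Km")
        return concentration_nM_to_mass(self.km_nM, self.molar_mass)

    def require_scale(self, scale: VmaxScale) -> "MichaelisMentenParams":
        if self.vmax_scale is not scale:
            raise ScaleMismatchError(
                f"expected Vmax on scale {scale.value!r}, got {self.vmax_scale.value!r}"
            )
        return self


@dataclass(frozen=True)
class HillParams:
    """Hill (sigmoid) uptake kinetics; reduces to Michaelis-Menten at n=1."""

    km_nM: float
    vmax: float
    n: float
    vmax_scale: VmaxScale
    molar_mass: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive(km_nM=self.km_nM, n=self.n)
        if not math.isfinite(self.vmax) or self.vmax < 0:
            raise ValueError(f"vmax must be finite and nonnegative, got {self.vmax}")

    def to_michaelis_menten(self, atol: float = 1e-9) -> MichaelisMentenParams:
        if abs(self.n - 1.0) > atol:
            raise ValueError(f"Hill coefficient {self.n} != 1; not a Michaelis-Menten model")
        return MichaelisMentenParams(self.km_nM, self.vmax, self.vmax_scale, self.molar_mass)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """A dose-annotated plasma concentration-time series.

    times are days (strictly increasing, first >= 0); concentrations μg/mL.
    ``dispersion`` optionally carries a per-time SD across animals.
    """

    dose_mg_per_kg: float
    times: np.ndarray
    concentrations: np.ndarray
    n_animals: int = 1
    dispersion: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if self.dispersion is not None:
            object.__setattr__(self, "dispersion", np.asarray(self.dispersion, dtype=float))
        if times.ndim != 1 or conc.shape != times.shape:
            raise ValueError("times and concentrations must be 1-D arrays of equal length")
        if len(times) and times[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class UptakeDataset:
    """Substrate concentration vs uptake-velocity observations.

    Concentrations in nM (strictly positive); velocities in pmol/min per
    fixed assay cell number, nonnegative.  ``replicates`` indexes repeated
    wells at the same nominal concentration.
    """

    concentrations_nM: np.ndarray
    velocities: np.ndarray
    replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_nM, dtype=float)
        vel = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "concentrations_nM", conc)
        object.__setattr__(self, "velocities", vel)
        if conc.ndim != 1 or vel.shape != conc.shape:
            raise ValueError("concentrations and velocities must be 1-D arrays of equal length")
        if np.any(conc <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if np.any(vel < 0):
            raise ValueError("velocities must be nonnegative")
        if self.replicates is not None:
            reps = np.asarray(self.replicates)
            object.__setattr__(self, "replicates", reps)
            if reps.shape != conc.shape:
                raise ValueError("replicate index must match data length")

    def __len__(self) -> int:
        return len(self.concentrations_nM)

    def concentrations_ug_per_mL(self, molar_mass: float) -> np.ndarray:
        return np.array(
            [concentration_nM_to_mass(c, molar_mass) for c in self.concentrations_nM]
        )


@dataclass(frozen=True)
class ScalingContext:
    """Constants for in-vitro-to-in-vivo extrapolation (IVIVE).

    Defaults: 5 x 10^5 cells per assay well; 7.6 x 10^6 target-expressing
    cells (sinusoidal endothelial + Kupffer) per mouse liver; 148 kDa IgG;
    20 g mouse.
    """

    n_cells_assay: float = 5e5
    n_cells_liver: float = 7.6e6
    molar_mass: float = 148_000.0  # g/mol
    body_weight_kg: float = 0.020
    expression_ratio: float = 1.0  # optional in vivo/in vitro receptor-expression multiplier

    def __post_init__(self) -> None:
        _require_positive(
            n_cells_assay=self.n_cells_assay,
            n_cells_liver=self.n_cells_liver,
            molar_mass=self.molar_mass,
            body_weight_kg=self.body_weight_kg,
            expression_ratio=self.expression_ratio,
        )


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental exposure metrics for one dose group."""

    half_life_h: float
    auc_0_inf: float  # μg·day/mL
    clearance: float  # mL/day/kg
    vd: float  # mL/kg
    lambda_z: float  # 1/day
    auc_extrapolated_fraction: float
    n_lambda_points: int = 0
    r2_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.auc_extrapolated_fraction < 1):
            raise ValueError("extrapolated AUC fraction must lie in [0, 1)")

    @property
    def extrapolation_flagged(self) -> bool:
        """True when more than 20% of AUC(0-inf) is extrapolated."""
        return self.auc_extrapolated_fraction > 0.20


@dataclass(frozen=True)
class FitResult:
    """Outcome of a weighted nonlinear least-squares fit.

    ``estimates`` is the fitted parameter record (one of the parameter
    dataclasses above); ``cv_percent`` maps parameter names to the
    coefficient of variation of the estimate (100 x SE / estimate).
    """

    estimates: object
    cv_percent: dict[str, float]
    objective_value: float
    converged: bool
    n_iterations: int
    warnings: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.objective_value < 0:
            raise ValueError("objective value must be nonnegative")
        for name, cv in self.cv_percent.items():
            if cv < 0:
                raise ValueError(f"CV% for {name} must be nonnegative")
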