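import numpy as np
import pytest

from abpk import (
    MichaelisMentenParams,
    REFERENCE_SCHEDULE_DAYS,
    ScalingContext,
    TwoCompartmentParams,
    VmaxScale,
    scale_vmax,
)

# Reference mouse parameter set used throughout: linear disposition of the
# anti-FcgammaRIIB antibody fitted at the saturating dose, the in vitro
# cellular-uptake kinetics, and the in vivo joint-refit kinetics.
REF_LINEAR = TwoCompartmentParams(k10=2.46, k12=14.27, k21=25.35, V1=25.7)
REF_UPTAKE_VITRO = MichaelisMentenParams(
    km_nM=23.6, vmax=0.0269, vmax_scale=VmaxScale.PER_ASSAY_CELLS
)
REF_UPTAKE_VIVO = MichaelisMentenParams(
    km_nM=42.4, vmax=0.0627, vmax_scale=VmaxScale.PER_ASSAY_CELLS
)
#: ECL ligand-binding assays resolve to roughly this plasma level; points
#: below it would be unreportable in a real study
LLOQ_UG_PER_ML = 0.05


@pytest.fixture
def linear_params() -> TwoCompartmentParams:
    return REF_LINEAR


@pytest.fixture
def uptake_vitro() -> MichaelisMentenParams:
    return REF_UPTAKE_VITRO


@pytest.fixture
def uptake_vivo() -> MichaelisMentenParams:
    return REF_UPTAKE_VIVO


@pytest.fixture
def ctx() -> ScalingContext:
    return ScalingContext()


@pytest.fixture
def mm_per_kg(uptake_vitro, ctx) -> MichaelisMentenParams:
    return scale_vmax(uptake_vitro, ctx)


@pytest.fixture
def schedule() -> np.ndarray:
    return np.asarray(REFERENCE_SCHEDULE_DAYS)
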