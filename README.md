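# abpk — hybrid in vitro / in vivo prediction of nonlinear antibody PK

Monoclonal antibodies against internalizing cell-surface receptors are
cleared by two routes: slow, nonspecific (linear) elimination, and a
saturable, target-mediated route that dominates at low doses and shuts
off at high ones.  Characterizing the nonlinearity in vivo normally
requires dose-ranging studies in many animals.  `abpk` implements an
alternative: anchor the linear disposition with a **single**
saturating-dose study, measure the saturable route **in vitro** in
target-receptor-expressing cells, scale it to the whole body, and
predict full concentration–time profiles at any dose.  The reference
system is an anti-mouse FcγRIIB antibody, whose target is expressed
almost exclusively on liver sinusoidal endothelial and Kupffer cells.

The model is a two-compartment disposition model with parallel
first-order and Michaelis–Menten elimination from the central
compartment (amounts A₁, A₂ in μg/kg; C = A₁/V₁ in μg/mL):

    dA₁/dt = −(k₁₀ + k₁₂)·A₁ + k₂₁·A₂ − Vmax·C/(Km + C)
    dA₂/dt =  k₁₂·A₁ − k₂₁·A₂

* k₁₀, k₁₂, k₂₁ (1/day) and V₁ (mL/kg) are fitted by weighted (1/Y)
  nonlinear least squares to the plasma profile at a saturating dose,
  where C ≫ Km and the saturable term is a negligible constant.
* Km (nM) and Vmax (pmol/min per 5×10⁵ cells) are fitted to uptake
  velocities from a cellular assay spanning 0.01–30 μg/mL.
* The in vitro Vmax is scaled to whole-body units by the number of
  target-expressing cells per liver and the body weight:
  Vmax[μg/day/kg] = Vmax[pmol/min/well] × (N_liver/N_assay) × M×10⁻⁶ × 1440 / BW.

The package also provides noncompartmental analysis (AUC, λz, CL, Vd,
t½), a joint all-dose nonlinear refit (the in vivo reference for the in
vitro kinetics), a synthetic-data generator for both assay types, fold-
error prediction metrics, and a CLI.

## Worked example

```python
import numpy as np
from abpk import *

linear = TwoCompartmentParams(k10=2.46, k12=14.27, k21=25.35, V1=25.7)
vitro  = MichaelisMentenParams(km_nM=23.6, vmax=0.0269,
                               vmax_scale=VmaxScale.PER_ASSAY_CELLS)
ctx = ScalingContext()          # 5e5 assay cells, 7.6e6 liver cells,
                                # 148 kDa, 20 g mouse

print(terminal_half_life_h(linear))            # 10.815006077178934
print(concentration_nM_to_mass(23.6, 148e3))   # 3.4928  (μg/mL)

mm_kg = scale_vmax(vitro, ctx)
print(mm_kg.vmax)                              # 4357.02528  (μg/day/kg)

profile = simulate(linear, mm_kg, 1.0, np.asarray(REFERENCE_SCHEDULE_DAYS))
print(profile.concentrations[:3])              # [36.27 31.83 26.77]  (μg/mL)
```

The half-life (≈11 h) is the slow-phase value implied by the fitted
rate constants; 23.6 nM ↔ 3.49 μg/mL is the molar/mass view of the
half-saturation concentration; 4357 μg/day/kg is the whole-body maximal
target-mediated elimination velocity; the simulated 1 mg/kg profile
decays much faster than dose-proportional scaling of a high-dose
profile would suggest, because at these concentrations the saturable
route is fully active.

The same workflow from the shell:

```sh
abpk generate --params truth.json --cv 0.1 --seed 1 --out study.csv
abpk fit-iv    --profiles study.csv --out iv_params.csv
abpk fit-vitro --uptake uptake.csv  --out vitro_params.csv
abpk scale     --params vitro_params.csv --out scaled_params.csv
abpk predict   --profiles study.csv --uptake uptake.csv --out-prefix pred
abpk nca       --profiles study.csv --out nca.csv
```

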