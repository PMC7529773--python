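"""In-vitro-to-in-vivo extrapolation of uptake kinetics.

The raw in vitro Vmax is a velocity per assay well (pmol/min per
5 x 10^5 cells).  Scaling to the whole body multiplies by the number of
target-expressing cells per liver over the assay cell number, converts
pmol to μg with the antibody molar mass, minutes to days, and divides by
body weight:

    Vmax[μg/day/kg] = Vmax[pmol/min/well]
                      x (N_liver / N_assay)
                      x M[g/mol] x 1e-6        (μg per pmol)
                      x 1440                   (min per day)
                      / BW[kg]

Km is a concentration and scales only in units (nM -> μg/mL).  The
per-liver velocity is treated as the whole-animal velocity and divided
by body weight, not liver weight: the target receptor is expressed
almost exclusively on liver sinusoidal endothelial and Kupffer cells, so
the liver carries the entire saturable clearance.
"""

from __future__ import annotations

from .quantities import (
    MINUTES_PER_DAY,
    MichaelisMentenParams,
    ScalingContext,
    VmaxScale,
)

__all__ = ["scale_vmax", "unscale_vmax", "vivo_vmax_ratio"]


def scale_vmax(mm: MichaelisMentenParams, ctx: ScalingContext) -> MichaelisMentenParams:
    """Scale per-assay-cell Michaelis-Menten parameters to per-kg body weight.

    The optional ``ctx.expression_ratio`` multiplies Vmax to correct for
    in vivo/in vitro receptor-expression differences (default 1: no
    correction).
    """
    mm.require_scale(VmaxScale.PER_ASSAY_CELLS)
    vmax_vivo = (
        mm.vmax
        * (ctx.n_cells_liver / ctx.n_cells_assay)
        * ctx.molar_mass
        * 1e-6
        * MINUTES_PER_DAY
        / ctx.body_weight_kg
        * ctx.expression_ratio
    )
    return MichaelisMentenParams(
        km_nM=mm.km_nM,
        vmax=vmax_vivo,
        vmax_scale=VmaxScale.PER_KG,
        molar_mass=ctx.molar_mass,
    )


def unscale_vmax(mm: MichaelisMentenParams, ctx: ScalingContext) -> MichaelisMentenParams:
    """Inverse of :func:`scale_vmax`: per-kg back to the assay scale."""
    mm.require_scale(VmaxScale.PER_KG)
    vmax_vitro = (
        mm.vmax
        * ctx.body_weight_kg
        / (MINUTES_PER_DAY * ctx.molar_mass * 1e-6)
        / (ctx.n_cells_liver / ctx.n_cells_assay)
        / ctx.expression_ratio
    )
    return MichaelisMentenParams(
        km_nM=mm.km_nM,
        vmax=vmax_vitro,
        vmax_scale=VmaxScale.PER_ASSAY_CELLS,
        molar_mass=ctx.molar_mass,
    )


def vivo_vmax_ratio(
    mm_vivo: MichaelisMentenParams, mm_vitro: MichaelisMentenParams
) -> float:
    """Ratio of two Vmax values on the same scale (dimensionless)."""
    if mm_vivo.vmax_scale is not mm_vitro.vmax_scale:
        raise ValueError("Vmax ratio requires both parameter sets on the same scale")
    if mm_vitro.vmax == 0:
        raise ZeroDivisionError("in vitro Vmax is zero")
    return mm_vivo.vmax / mm_vitro.vmax
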