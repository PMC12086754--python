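"""Relative electron densities, mixture I-values, and Bethe stopping powers.

The relative stopping power (RSP) of a material is computed from the Bethe
formula without shell or density corrections, at a single fixed proton beam
energy (100 MeV by default):

    RSP = rho_e_rel * L(I) / L(I_w),
    L(I) = ln( 2 m_e c^2 beta^2 / (I (1 - beta^2)) ) - beta^2,

with the mixture mean excitation energy I from the Bragg additivity rule on
the electron scale, ``ln I = sum_i lambda_i ln I_i``.  The water I-value is
derived from the same elemental table and mixture rule, so ``RSP(water)=1``
holds structurally rather than by a hard-coded 75 eV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    DEFAULT_BEAM_ENERGY_MEV,
    ELECTRON_REST_ENERGY_EV,
    WATER_DENSITY,
    WATER_MASS_FRACTIONS,
    beta_squared,
)
from .exceptions import ValidationError
from .photon_model import electron_fractions, water_composition
from .reference_data import ElementTable, TissueComposition

__all__ = [
    "ProtonBeamContext",
    "electron_density_rel",
    "mixture_I",
    "bethe_rsp",
    "tissue_rsp_ref",
]


def electron_density_rel(comp: TissueComposition, elements: ElementTable) -> float:
    """Electron density relative to water at 1 g/cm^3.

    ``rho_e_rel = rho * sum_i w_i Z_i/A_i`` divided by the same expression
    for water.
    """
    za = sum(w * elements[s].Z / elements[s].A for s, w in comp.mass_fractions.items())
    za_w = sum(w * elements[s].Z / elements[s].A for s, w in WATER_MASS_FRACTIONS.items())
    return comp.density * za / (WATER_DENSITY * za_w)


def mixture_I(comp: TissueComposition, elements: ElementTable) -> float:
    """Mixture mean excitation energy (eV) by Bragg additivity on electrons."""
    lam = electron_fractions(comp, elements)
    ln_i = sum(l * math.log(elements[s].I) for s, l in lam.items())
    return math.exp(ln_i)


@dataclass(frozen=True)
class ProtonBeamContext:
    """Fixed beam energy plus derived kinematic and water reference values."""

    elements: ElementTable
    kinetic_energy_mev: float = DEFAULT_BEAM_ENERGY_MEV
    beta2: float = field(init=False)
    water_I: float = field(init=False)  # eV

    def __post_init__(self):
        b2 = beta_squared(self.kinetic_energy_mev)
        if not 0.0 < b2 < 1.0:
            raise ValidationError("beam energy yields nonphysical beta^2")
        object.__setattr__(self, "beta2", b2)
        object.__setattr__(self, "water_I", mixture_I(water_composition(), self.elements))

    def stopping_number(self, i_ev: float) -> float:
        """The Bethe stopping number L(I) for this beam."""
        if i_ev <= 0:
            raise ValidationError("I must be positive")
        arg = 2.0 * ELECTRON_REST_ENERGY_EV * self.beta2 / (i_ev * (1.0 - self.beta2))
        if arg <= 1.0:
            raise ValidationError(
                f"I = {i_ev:g} eV is nonphysical at {self.kinetic_energy_mev:g} MeV "
                "(stopping-number logarithm argument <= 1)"
            )
        return math.log(arg) - self.beta2


def bethe_rsp(rho_e_rel: float, i_ev: float, ctx: ProtonBeamContext) -> float:
    """Relative stopping power from relative electron density and I-value."""
    return rho_e_rel * ctx.stopping_number(i_ev) / ctx.stopping_number(ctx.water_I)


def tissue_rsp_ref(comp: TissueComposition, ctx: ProtonBeamContext) -> float:
    """Theoretical (reference) RSP of a tissue composition."""
    return bethe_rsp(
        electron_density_rel(comp, ctx.elements), mixture_I(comp, ctx.elements), ctx
    )
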