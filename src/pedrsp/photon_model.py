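"""Spectrum-averaged attenuation, theoretical CT numbers, and the
parameterized stoichiometric attenuation model.

Theoretical CT numbers are computed as

    HU = 1000 * (mu_bar - mu_bar_water) / mu_bar_water,

where ``mu_bar = rho * sum_E w(E) (mu/rho)(E)`` is the spectrum-averaged
linear attenuation coefficient of a mixture, with the elemental mass
attenuation coefficients combined by the mass-weighted mixture rule.  The
default spectral weight is energy fluence, ``w(E) ~ fluence(E) * E``,
emulating an energy-integrating CT detector; plain photon-fluence weighting
is available for sensitivity checks.

The stoichiometric parameterization expresses the attenuation of a material
relative to water through three fitted coefficients multiplying the
photoelectric (~Z^3.62), coherent-scatter (~Z^1.86) and Klein-Nishina terms
of the cross section per electron:

    mu/mu_w = rho_e_rel * (K_ph * Ztilde^3.62 + K_coh * Zhat^1.86 + K_KN),

with Ztilde^3.62 = sum_i lambda_i Z_i^3.62 and Zhat^1.86 = sum_i lambda_i
Z_i^1.86 over electron fractions lambda_i, and the K's normalized so that
water maps exactly to 0 HU.  Fitted to the phantom-insert CT numbers, the
model transfers the scanner's (here: the simulated spectrum's) energy
response to arbitrary tabulated human tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import WATER_DENSITY, WATER_MASS_FRACTIONS
from .exceptions import FitError, ValidationError
from .reference_data import (
    ElementTable,
    PhotonCrossSectionTable,
    Spectrum,
    TissueComposition,
)

__all__ = [
    "water_composition",
    "mixture_mu_over_rho",
    "spectrum_weights",
    "mean_mu_over_rho",
    "theoretical_hu",
    "electron_fractions",
    "SchneiderFit",
    "schneider_fit",
    "schneider_predict_hu",
]

_PH_EXP = 3.62
_COH_EXP = 1.86


def water_composition() -> TissueComposition:
    """Liquid water as a :class:`TissueComposition` (the HU/RSP reference)."""
    return TissueComposition(
        tissue_id=0, name="Water", mass_fractions=dict(WATER_MASS_FRACTIONS),
        density=WATER_DENSITY, group="soft", note="reference",
    )


def mixture_mu_over_rho(
    comp: TissueComposition, energy_kev, xs: PhotonCrossSectionTable
) -> np.ndarray | float:
    """Mass-weighted mixture mass attenuation coefficient, cm^2/g."""
    energy = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(energy)
    for sym, w in comp.mass_fractions.items():
        out = out + w * xs.mu_over_rho(sym, energy)
    return float(out) if np.isscalar(energy_kev) else out


def spectrum_weights(spectrum: Spectrum, weighting: str = "energy") -> np.ndarray:
    """Normalized spectral weights: energy fluence (default) or photon fluence."""
    if weighting == "energy":
        w = spectrum.fluence * spectrum.energies
    elif weighting == "photon":
        w = spectrum.fluence.copy()
    else:
        raise ValidationError(f"unknown weighting {weighting!r}; use 'energy' or 'photon'")
    return w / w.sum()


def mean_mu_over_rho(
    comp: TissueComposition,
    spectrum: Spectrum,
    xs: PhotonCrossSectionTable,
    weighting: str = "energy",
) -> float:
    """Spectrum-averaged mass attenuation coefficient, cm^2/g."""
    w = spectrum_weights(spectrum, weighting)
    return float(np.sum(w * mixture_mu_over_rho(comp, spectrum.energies, xs)))


def theoretical_hu(
    comp: TissueComposition,
    spectrum: Spectrum,
    xs: PhotonCrossSectionTable,
    weighting: str = "energy",
) -> float:
    """Theoretical CT number of a mixture for the given spectrum, HU."""
    mu_w = WATER_DENSITY * mean_mu_over_rho(water_composition(), spectrum, xs, weighting)
    mu = comp.density * mean_mu_over_rho(comp, spectrum, xs, weighting)
    return 1000.0 * (mu - mu_w) / mu_w


def electron_fractions(comp: TissueComposition, elements: ElementTable) -> dict[str, float]:
    """Electron fractions lambda_i = (w_i Z_i / A_i) / sum_j (w_j Z_j / A_j)."""
    ze = {sym: w * elements[sym].Z / elements[sym].A for sym, w in comp.mass_fractions.items()}
    total = sum(ze.values())
    return {sym: v / total for sym, v in ze.items()}


def _z_moments(comp: TissueComposition, elements: ElementTable) -> tuple[float, float]:
    lam = electron_fractions(comp, elements)
    z_ph = sum(l * elements[s].Z ** _PH_EXP for s, l in lam.items())
    z_coh = sum(l * elements[s].Z ** _COH_EXP for s, l in lam.items())
    return z_ph, z_coh


def _electron_density_rel(comp: TissueComposition, elements: ElementTable) -> float:
    za = sum(w * elements[s].Z / elements[s].A for s, w in comp.mass_fractions.items())
    za_w = sum(
        w * elements[s].Z / elements[s].A for s, w in WATER_MASS_FRACTIONS.items()
    )
    return comp.density * za / (WATER_DENSITY * za_w)


@dataclass(frozen=True)
class SchneiderFit:
    """Fitted coefficients of the parameterized attenuation model.

    The coefficients are normalized such that the model evaluated on water
    gives exactly ``mu/mu_w = 1`` (0 HU); the normalization absorbs the
    arbitrary overall scale of the parameterization.
    """

    k_ph: float
    k_coh: float
    k_kn: float
    spectrum_label: str
    rms_residual_hu: float = float("nan")

    def __post_init__(self):
        if self.k_kn <= 0:
            raise ValidationError("K_KN must be positive")


def schneider_fit(
    inserts: list[tuple[TissueComposition, float]],
    spectrum_label: str,
    elements: ElementTable,
) -> SchneiderFit:
    """Fit (K_ph, K_coh, K_KN) to phantom-insert CT numbers.

    Linear least squares on relative attenuation ``u = HU/1000 + 1`` subject
    to the water-normalization constraint, solved by eliminating the
    constraint through a null-space substitution.

    Raises
    ------
    FitError
        For fewer than 3 inserts or a rank-deficient design (e.g. all
        inserts compositionally identical).
    """
    if len(inserts) < 3:
        raise FitError(f"need at least 3 inserts, got {len(inserts)}")
    rows, targets = [], []
    for comp, hu in inserts:
        z_ph, z_coh = _z_moments(comp, elements)
        rho_e = _electron_density_rel(comp, elements)
        rows.append([rho_e * z_ph, rho_e * z_coh, rho_e])
        targets.append(hu / 1000.0 + 1.0)
    a = np.asarray(rows)
    y = np.asarray(targets)

    zw_ph, zw_coh = _z_moments(water_composition(), elements)
    c = np.array([zw_ph, zw_coh, 1.0])

    # particular solution of c.k = 1 plus null-space directions
    k0 = c / (c @ c)
    _, _, vt = np.linalg.svd(c[None, :])
    null = vt[1:].T  # 3x2
    design = a @ null
    if np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, np.abs(design).max())) < 2:
        raise FitError("rank-deficient insert design; inserts must span soft tissue and bone")
    z, *_ = np.linalg.lstsq(design, y - a @ k0, rcond=None)
    k = k0 + null @ z

    fit = SchneiderFit(
        k_ph=float(k[0]), k_coh=float(k[1]), k_kn=float(k[2]),
        spectrum_label=spectrum_label,
    )
    resid_hu = np.array(
        [schneider_predict_hu(fit, comp, elements) - hu for comp, hu in inserts]
    )
    object.__setattr__(fit, "rms_residual_hu", float(np.sqrt(np.mean(resid_hu**2))))
    return fit


def schneider_predict_hu(
    fit: SchneiderFit, comp: TissueComposition, elements: ElementTable
) -> float:
    """CT number of a composition predicted by the fitted parameterization."""
    z_ph, z_coh = _z_moments(comp, elements)
    rho_e = _electron_density_rel(comp, elements)
    u = rho_e * (fit.k_ph * z_ph + fit.k_coh * z_coh + fit.k_kn)
    return 1000.0 * (u - 1.0)
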