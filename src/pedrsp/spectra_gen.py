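"""Generation of the fixture x-ray tube spectra.

A deliberately simple tungsten-anode model: Kramers bremsstrahlung
(photon fluence per unit energy proportional to ``(E0 - E)/E``), tungsten
characteristic K lines for peak voltages above the K edge (69.5 keV), and
Beer-Lambert filtration through aluminium (inherent tube filtration) and,
for the dual-energy high channel, tin.  This reproduces the qualitative
shape and beam quality of generic CT spectra at 80-140 kVp; the analysis it
feeds is only weakly sensitive to the fine spectral shape because every CT
number is normalized to water computed with the same spectrum.

The shipped fixture spectra under ``pedrsp/data/spectra`` were produced by
:func:`generate_spectrum` via ``scripts/make_spectra.py`` and are loaded at
run time by :func:`pedrsp.reference_data.builtin_spectrum`.
"""

from __future__ import annotations

import numpy as np

from .reference_data import PhotonCrossSectionTable, Spectrum, load_cross_sections

__all__ = ["generate_spectrum", "TUBE_CONFIGS"]

# density of the filter metals, g/cm^3
_FILTER_DENSITY = {"Al": 2.699, "Sn": 7.31}

# tungsten K lines: (energy keV, relative intensity within the line group)
_W_K_LINES = ((59.32, 1.00), (57.98, 0.55), (67.24, 0.30))
_W_K_EDGE = 69.5

#: kVp and filtration (mm) per shipped spectrum label.
TUBE_CONFIGS = {
    "80kVp": {"kvp": 80.0, "filters": {"Al": 8.0}},
    "100kVp": {"kvp": 100.0, "filters": {"Al": 8.0}},
    "120kVp": {"kvp": 120.0, "filters": {"Al": 8.0}},
    "140kVp": {"kvp": 140.0, "filters": {"Al": 8.0}},
    "140kVp-Sn": {"kvp": 140.0, "filters": {"Al": 8.0, "Sn": 0.4}},
}


def generate_spectrum(
    label: str,
    kvp: float,
    filters: dict[str, float],
    xs: PhotonCrossSectionTable | None = None,
    e_min: float = 10.0,
    de: float = 1.0,
) -> Spectrum:
    """Generate a filtered tungsten-anode spectrum.

    Parameters
    ----------
    kvp:
        Tube peak voltage; the bremsstrahlung endpoint, keV.
    filters:
        Map of filter material symbol to thickness in mm.
    e_min, de:
        Low-energy cutoff and bin width of the energy grid, keV.
    """
    if xs is None:
        xs = load_cross_sections()
    energies = np.arange(e_min, kvp + de / 2, de)
    energies = energies[energies < kvp]
    fluence = (kvp - energies) / energies  # Kramers

    transmission = np.ones_like(energies)
    for sym, t_mm in filters.items():
        mu = xs.mu_over_rho(sym, energies) * _FILTER_DENSITY[sym]  # 1/cm
        transmission *= np.exp(-mu * t_mm / 10.0)
    fluence = fluence * transmission

    if kvp > _W_K_EDGE:
        # characteristic K lines; total line fraction grows with overvoltage
        line_fraction = 0.08 * np.sqrt(kvp / _W_K_EDGE - 1.0)
        weights = np.array([w for _, w in _W_K_LINES])
        line_fluences = weights / weights.sum() * line_fraction * fluence.sum() / (1 - line_fraction)
        for (e_line, _), phi in zip(_W_K_LINES, line_fluences):
            trans = 1.0
            for sym, t_mm in filters.items():
                trans *= np.exp(-xs.mu_over_rho(sym, e_line) * _FILTER_DENSITY[sym] * t_mm / 10.0)
            idx = int(np.argmin(np.abs(energies - e_line)))
            fluence[idx] += phi * trans

    return Spectrum(label, energies, fluence)
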