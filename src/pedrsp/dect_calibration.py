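"""Dual-energy CT stoichiometric calibration (effective-atomic-number route).

The pipeline estimates, voxel by voxel or tissue by tissue:

1. the dual-energy ratio ``Gamma = u_L / u_H`` of reduced CT numbers
   ``u = HU/1000 + 1`` (attenuation relative to water);
2. the effective atomic number ``Z_eff`` from a polynomial in ``Gamma``
   calibrated on the electron-density phantom inserts;
3. the relative electron density ``rho_e = u / F_spec(Z_eff)``, averaged
   over the two spectra, where ``F_spec(Z)`` is the spectrum-averaged
   electron cross section of atomic number Z relative to water, fitted as a
   polynomial in Z over the tissue-relevant range;
4. the mean excitation energy from a polynomial ``ln I(Z_eff)`` fitted on
   the adult reference tissues (calibration and evaluation tissue sets stay
   disjoint);
5. the stopping power through the Bethe formula.

``Z_eff`` here is defined *self-consistently* through the same parameterized
electron cross section used for the electron-density mapping: the effective
atomic number of a mixture is the Z at which the elemental dual-energy ratio
curve matches the mixture's ratio.  This avoids the classical fixed-exponent
power-mean formula and keeps the calibration internally consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .constants import ELECTRON_REST_ENERGY_EV
from .exceptions import CalibrationError, ValidationError
from .photon_model import (
    mean_mu_over_rho,
    theoretical_hu,
    water_composition,
)
from .proton_model import (
    ProtonBeamContext,
    electron_density_rel,
    mixture_I,
)
from .reference_data import (
    ElementTable,
    PhotonCrossSectionTable,
    Spectrum,
    TissueComposition,
    TissueDatabase,
)

__all__ = ["reduced_hu", "DECTModel", "calibrate_dect", "estimate_rsp_dect", "DECTEstimate"]

#: Z range over which the elemental cross-section polynomials are fitted.
_Z_FIT_RANGE = (1.0, 20.0)
#: Z range over which Z_eff estimates are considered valid (clamped outside).
_Z_VALID_RANGE = (4.0, 20.0)


def reduced_hu(hu):
    """Reduced CT number u = HU/1000 + 1 (attenuation relative to water)."""
    return np.asarray(hu, dtype=float) / 1000.0 + 1.0 if not np.isscalar(hu) else hu / 1000.0 + 1.0


class _ElementalCrossSections:
    """Spectrum-averaged electron cross sections of the elements, rel. water."""

    def __init__(self, spectrum: Spectrum, elements: ElementTable,
                 xs: PhotonCrossSectionTable, weighting: str = "energy"):
        water = water_composition()
        mu_w = mean_mu_over_rho(water, spectrum, xs, weighting)
        za_w = sum(
            w * elements[s].Z / elements[s].A for s, w in water.mass_fractions.items()
        )
        self.z = []
        self.f = []
        for sym in elements.symbols():
            el = elements[sym]
            if not (_Z_FIT_RANGE[0] <= el.Z <= _Z_FIT_RANGE[1]):
                continue
            comp = TissueComposition(
                tissue_id=0, name=sym, mass_fractions={sym: 1.0}, density=1.0
            )
            mu = mean_mu_over_rho(comp, spectrum, xs, weighting)
            sigma_rel = (mu * el.A / el.Z) / (mu_w / za_w)
            self.z.append(float(el.Z))
            self.f.append(sigma_rel)
        order = np.argsort(self.z)
        self.z = np.asarray(self.z)[order]
        self.f = np.asarray(self.f)[order]

    def fit_poly(self, order: int) -> np.ndarray:
        return np.polyfit(self.z, self.f, order)


class DECTEstimate(NamedTuple):
    """RSP with its intermediates; flags mark clamped/air-like inputs."""

    rsp: np.ndarray | float
    zeff: np.ndarray | float
    rho_e: np.ndarray | float
    i_ev: np.ndarray | float
    clamped: np.ndarray | bool
    air: np.ndarray | bool


@dataclass
class DECTModel:
    """Fitted DECT mappings Gamma -> Z_eff, (u, Z_eff) -> rho_e, Z_eff -> I."""

    low_label: str
    high_label: str
    zeff_coeffs: np.ndarray  # np.polyval convention (highest power first)
    f_low_coeffs: np.ndarray
    f_high_coeffs: np.ndarray
    lni_coeffs: np.ndarray
    gamma_range: tuple[float, float]
    zeff_range: tuple[float, float] = _Z_VALID_RANGE
    diagnostics: dict = field(default_factory=dict)

    def zeff_of_gamma(self, gamma):
        return np.polyval(self.zeff_coeffs, gamma)

    def f_low(self, z):
        return np.polyval(self.f_low_coeffs, z)

    def f_high(self, z):
        return np.polyval(self.f_high_coeffs, z)

    def i_of_zeff(self, z):
        return np.exp(np.polyval(self.lni_coeffs, z))

    def validate(self) -> None:
        g = np.linspace(*self.gamma_range, 200)
        z = self.zeff_of_gamma(g)
        if np.any(np.diff(z) <= 0):
            raise CalibrationError("Z_eff(Gamma) is not strictly monotone over the calibration range")
        zz = np.linspace(*self.zeff_range, 200)
        if np.any(self.f_low(zz) <= 0) or np.any(self.f_high(zz) <= 0):
            raise CalibrationError("F_spec(Z) must be positive over the validity range")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "low": self.low_label, "high": self.high_label,
            "zeff_coeffs": list(map(float, self.zeff_coeffs)),
            "f_low_coeffs": list(map(float, self.f_low_coeffs)),
            "f_high_coeffs": list(map(float, self.f_high_coeffs)),
            "lni_coeffs": list(map(float, self.lni_coeffs)),
            "gamma_range": list(self.gamma_range),
            "zeff_range": list(self.zeff_range),
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DECTModel":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        doc = json.loads(p.read_text() if p else str(text_or_path))
        return cls(
            low_label=doc["low"], high_label=doc["high"],
            zeff_coeffs=np.asarray(doc["zeff_coeffs"]),
            f_low_coeffs=np.asarray(doc["f_low_coeffs"]),
            f_high_coeffs=np.asarray(doc["f_high_coeffs"]),
            lni_coeffs=np.asarray(doc["lni_coeffs"]),
            gamma_range=tuple(doc["gamma_range"]),
            zeff_range=tuple(doc["zeff_range"]),
            diagnostics=doc.get("diagnostics", {}),
        )


def _theoretical_gamma(
    comp: TissueComposition, low: Spectrum, high: Spectrum,
    xs: PhotonCrossSectionTable, weighting: str = "energy",
) -> tuple[float, float, float]:
    u_l = reduced_hu(theoretical_hu(comp, low, xs, weighting))
    u_h = reduced_hu(theoretical_hu(comp, high, xs, weighting))
    return u_l, u_h, u_l / u_h


def calibrate_dect(
    phantom_db: TissueDatabase,
    low: Spectrum,
    high: Spectrum,
    reference_tissues: TissueDatabase,
    ctx: ProtonBeamContext,
    xs: PhotonCrossSectionTable,
    order_zeff: int = 3,
    order_f: int = 4,
    order_i: int = 3,
    weighting: str = "energy",
) -> DECTModel:
    """Calibrate the DECT model on phantom inserts with known compositions.

    ``phantom_db`` provides the calibration inserts (theoretical CT numbers
    stand in for a phantom scan); ``reference_tissues`` (the adult reference
    set) provides the ln I(Z_eff) parameterization so that calibration and
    evaluation tissues remain disjoint.
    """
    inserts = list(phantom_db)
    if len(inserts) < 6:
        raise CalibrationError(f"need >= 6 calibration inserts, got {len(inserts)}")
    elements = ctx.elements

    # elemental cross-section curves define the self-consistent Z_eff scale
    el_low = _ElementalCrossSections(low, elements, xs, weighting)
    el_high = _ElementalCrossSections(high, elements, xs, weighting)
    g_low = el_low.fit_poly(order_f)
    g_high = el_high.fit_poly(order_f)

    def gamma_of_z(z):
        return np.polyval(g_low, z) / np.polyval(g_high, z)

    # theoretical Gamma of the inserts and the self-consistent Z_eff targets
    gammas, zeffs = [], []
    for comp in inserts:
        _, u_h, gamma = _theoretical_gamma(comp, low, high, xs, weighting)
        if u_h <= 0:
            raise CalibrationError(f"insert {comp.name!r} has nonpositive reduced HU")
        lo, hi = _Z_VALID_RANGE
        try:
            z = brentq(lambda zz: gamma_of_z(zz) - gamma, lo, hi, xtol=1e-10)
        except ValueError as exc:
            raise CalibrationError(
                f"cannot invert Gamma={gamma:.4f} for insert {comp.name!r}: {exc}"
            ) from exc
        gammas.append(gamma)
        zeffs.append(z)
    gammas = np.asarray(gammas)
    zeffs = np.asarray(zeffs)
    if np.ptp(gammas) < 1e-3:
        raise CalibrationError(
            "degenerate calibration: inserts span no dual-energy-ratio range "
            "(all compositions photon-equivalent)"
        )

    zeff_coeffs = np.polyfit(gammas, zeffs, order_zeff)

    # electron-density curves F_spec(Z_eff): fitted on the inserts together
    # with the reference tissues, so that the mapping is well supported where
    # human tissues live (the epoxy surrogates alone leave a gap at
    # Z_eff 8-10 and have a slightly different mixture geometry)
    fit_u_low, fit_u_high, fit_zeff, fit_rho_e = [], [], [], []
    ref_list = [t for t in reference_tissues if t.group != "excluded"]
    for comp in inserts + ref_list:
        u_l, u_h, gamma = _theoretical_gamma(comp, low, high, xs, weighting)
        fit_u_low.append(u_l)
        fit_u_high.append(u_h)
        fit_zeff.append(float(np.polyval(zeff_coeffs, gamma)))
        fit_rho_e.append(electron_density_rel(comp, elements))
    fit_zeff = np.asarray(fit_zeff)
    fit_rho_e = np.asarray(fit_rho_e)
    f_low = np.polyfit(fit_zeff, np.asarray(fit_u_low) / fit_rho_e, order_f)
    f_high = np.polyfit(fit_zeff, np.asarray(fit_u_high) / fit_rho_e, order_f)

    # water-anchor the electron-density mappings: rho_e(water) = 1 exactly
    z_water = float(np.polyval(zeff_coeffs, 1.0))
    f_low = f_low / np.polyval(f_low, z_water)
    f_high = f_high / np.polyval(f_high, z_water)

    # ln I (Z_eff) parameterization on the reference tissue set
    z_ref, lni_ref = [], []
    for tissue in ref_list:
        _, _, gamma = _theoretical_gamma(tissue, low, high, xs, weighting)
        z_ref.append(float(np.polyval(zeff_coeffs, gamma)))
        lni_ref.append(np.log(mixture_I(tissue, elements)))
    lni_coeffs = np.polyfit(np.asarray(z_ref), np.asarray(lni_ref), order_i)

    model = DECTModel(
        low_label=low.label,
        high_label=high.label,
        zeff_coeffs=zeff_coeffs,
        f_low_coeffs=f_low,
        f_high_coeffs=f_high,
        lni_coeffs=lni_coeffs,
        gamma_range=(float(gammas.min()), float(gammas.max())),
        zeff_range=(float(fit_zeff.min()) - 0.5, float(fit_zeff.max()) + 0.5),
    )
    model.validate()

    # diagnostics: residuals of each fitted mapping
    rho_e_true = np.array([electron_density_rel(c, elements) for c in inserts])
    est = estimate_rsp_dect(
        model,
        np.array([theoretical_hu(c, low, xs, weighting) for c in inserts]),
        np.array([theoretical_hu(c, high, xs, weighting) for c in inserts]),
        ctx,
    )
    model.diagnostics = {
        "zeff_rms": float(np.sqrt(np.mean((np.polyval(zeff_coeffs, gammas) - zeffs) ** 2))),
        "rho_e_max_rel_err": float(np.max(np.abs(est.rho_e / rho_e_true - 1.0))),
        "lni_rms": float(
            np.sqrt(np.mean((np.polyval(lni_coeffs, np.asarray(z_ref)) - np.asarray(lni_ref)) ** 2))
        ),
    }
    return model


def estimate_rsp_dect(model: DECTModel, hu_low, hu_high, ctx: ProtonBeamContext) -> DECTEstimate:
    """Estimate RSP (with intermediates) from a dual-energy HU pair.

    Scalar inputs with a nonpositive high-channel reduced HU raise; in
    vectorized use such air-like voxels are flagged and given RSP 0.
    """
    scalar = np.isscalar(hu_low) and np.isscalar(hu_high)
    u_l = np.atleast_1d(np.asarray(reduced_hu(hu_low), dtype=float))
    u_h = np.atleast_1d(np.asarray(reduced_hu(hu_high), dtype=float))
    if u_l.shape != u_h.shape:
        raise ValidationError("low/high HU inputs must have matching shapes")
    air = u_h <= 0
    if scalar and air.any():
        raise ValidationError("nonpositive high-channel attenuation (air-like input)")

    u_h_safe = np.where(air, 1.0, u_h)
    gamma = u_l / u_h_safe
    zeff_raw = model.zeff_of_gamma(gamma)
    zeff = np.clip(zeff_raw, *model.zeff_range)
    clamped = (zeff_raw != zeff) & ~air

    rho_e = 0.5 * (u_l / model.f_low(zeff) + u_h_safe / model.f_high(zeff))
    i_ev = model.i_of_zeff(zeff)

    log_arg = 2.0 * ELECTRON_REST_ENERGY_EV * ctx.beta2 / (i_ev * (1.0 - ctx.beta2))
    if np.any(log_arg[~air] <= 1.0):
        raise ValidationError("estimated I-value nonphysical at this beam energy")
    l_w = ctx.stopping_number(ctx.water_I)
    rsp = rho_e * (np.log(log_arg) - ctx.beta2) / l_w
    rsp = np.where(air, 0.0, np.maximum(rsp, 0.0))

    if scalar:
        return DECTEstimate(
            rsp=float(rsp[0]), zeff=float(zeff[0]), rho_e=float(rho_e[0]),
            i_ev=float(i_ev[0]), clamped=bool(clamped[0]), air=bool(air[0]),
        )
    shape = np.broadcast(np.asarray(hu_low), np.asarray(hu_high)).shape
    return DECTEstimate(
        rsp=rsp.reshape(shape), zeff=zeff.reshape(shape), rho_e=rho_e.reshape(shape),
        i_ev=i_ev.reshape(shape), clamped=clamped.reshape(shape), air=air.reshape(shape),
    )
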