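"""Synthetic per-age/sex pediatric tissue database (53 tissues).

The published pediatric reference compositions (ICRP Publication 143,
Annex B) are not redistributable and are not shipped here.  This module
instead *generates* a synthetic stand-in database with the same structure
and numbering conventions:

* tissue 1: teeth (excluded from statistics), tissues 2-21: resegmented
  skeletal sites (spongiosa), tissues 22-25: medullary cavities of the long
  bones (soft group), tissues 26-52: soft organs, tissue 53: air inside the
  body (excluded);
* six age groups (newborn, 1y, 5y, 10y, 15y, adult), male and female, with
  sex differences confined to gonads, uterus/prostate and breast glandular
  tissue as in the reference data.

The construction is deterministic and physically motivated rather than
transcribed: soft organs of younger children are hydrated versions of the
adult reference organs (water content increases with youth, carbon is
displaced by oxygen); skeletal sites are mass mixtures of cortical bone,
unmineralized osteoid matrix, cartilage and age-appropriately red/yellow
marrow, with the mineralized fraction growing toward adulthood; medullary
cavities are marrow with a small admixture of bone mineral (hydroxyapatite)
that places them inside the bone region of the CT scale.  The mineral
admixture of the 1-year-old's humeral medullary cavity is anchored so that
its theoretical CT number at 140 kVp equals 309 HU, the one published
per-tissue value available for this tissue family.

Because the compositions are synthetic, per-tissue and per-group error
statistics computed from this database reproduce the *qualitative* behavior
of real pediatric tissues (systematic soft-tissue overestimation and bone
underestimation under an adult calibration, large positive medullary-cavity
errors, DECT accuracy roughly an order of magnitude better), not the
published numbers to printed precision.
"""

from __future__ import annotations

from functools import lru_cache

from scipy.optimize import brentq

from .exceptions import CalibrationError
from .photon_model import theoretical_hu
from .reference_data import (
    TissueComposition,
    TissueDatabase,
    adult70,
    builtin_spectrum,
    load_cross_sections,
)

__all__ = ["build_pediatric_database", "pediatric53", "MEDULLARY_IDS", "AGE_PARAMS"]

#: Soft-group ids of the medullary-cavity tissues (22-25).
MEDULLARY_IDS = (22, 23, 24, 25)

#: Age-scaling parameters of the synthetic construction.
AGE_PARAMS = {
    #          hydration  mineral  yellow  lung_rho  med_scale  med_yellow
    "newborn": dict(hyd=0.22, mineral=0.32, yellow=0.00, lung_rho=0.40, med=0.75, med_y=0.50),
    "1y":      dict(hyd=0.18, mineral=0.40, yellow=0.05, lung_rho=0.38, med=1.00, med_y=0.60),
    "5y":      dict(hyd=0.11, mineral=0.58, yellow=0.30, lung_rho=0.33, med=0.85, med_y=0.75),
    "10y":     dict(hyd=0.06, mineral=0.75, yellow=0.60, lung_rho=0.30, med=0.60, med_y=0.85),
    "15y":     dict(hyd=0.025, mineral=0.90, yellow=0.85, lung_rho=0.28, med=0.50, med_y=0.95),
    "adult":   dict(hyd=0.0, mineral=1.00, yellow=1.00, lung_rho=0.26, med=0.25, med_y=1.00),
}

# skeletal sites 2-21: (name, adult cortical fraction, marrow fraction,
# cartilage fraction, adult yellow-marrow share of the marrow)
_SKELETAL_SITES = {
    2: ("Spongiosa, cranium", 0.55, 0.40, 0.05, 0.30),
    3: ("Spongiosa, mandible", 0.55, 0.40, 0.05, 0.30),
    4: ("Spongiosa, scapulae", 0.45, 0.50, 0.05, 0.50),
    5: ("Spongiosa, clavicles", 0.40, 0.55, 0.05, 0.50),
    6: ("Spongiosa, sternum", 0.25, 0.70, 0.05, 0.10),
    7: ("Spongiosa, ribs", 0.35, 0.60, 0.05, 0.15),
    8: ("Spongiosa, cervical vertebrae", 0.30, 0.63, 0.07, 0.10),
    9: ("Spongiosa, thoracic vertebrae", 0.28, 0.65, 0.07, 0.10),
    10: ("Spongiosa, lumbar vertebrae", 0.28, 0.65, 0.07, 0.10),
    11: ("Spongiosa, sacrum", 0.25, 0.68, 0.07, 0.10),
    12: ("Spongiosa, os coxae", 0.35, 0.60, 0.05, 0.20),
    13: ("Spongiosa, humeri proximal", 0.35, 0.60, 0.05, 0.60),
    14: ("Spongiosa, humeri distal", 0.40, 0.55, 0.05, 0.70),
    15: ("Spongiosa, ulnae and radii", 0.45, 0.48, 0.07, 0.80),
    16: ("Spongiosa, wrists and hands", 0.50, 0.42, 0.08, 0.85),
    17: ("Spongiosa, femora proximal", 0.35, 0.60, 0.05, 0.60),
    18: ("Spongiosa, femora distal", 0.40, 0.55, 0.05, 0.70),
    19: ("Spongiosa, tibiae and fibulae", 0.45, 0.48, 0.07, 0.80),
    20: ("Spongiosa, ankles and feet", 0.50, 0.42, 0.08, 0.85),
    21: ("Spongiosa, patellae", 0.40, 0.45, 0.15, 0.70),
}

# medullary-cavity sites 22-25: (name, mineral-admixture scale rel. humeri)
_MEDULLARY_SITES = {
    22: ("Medullary cavity, humeri", 1.00),
    23: ("Medullary cavity, femora", 1.00),
    24: ("Medullary cavity, tibiae and fibulae", 0.60),
    25: ("Medullary cavity, ulnae and radii", 0.80),
}

# soft organs 26-52: (name, adult70 source tissue id); sex-specific entries
# carry a (male_id, female_id) pair.
_SOFT_ORGANS = {
    26: ("Adipose, subcutaneous", 2),
    27: ("Adrenals", 4),
    28: ("Blood", 6),
    29: ("Brain", 9),
    30: ("Cartilage", 47),
    31: ("Eyes", 64),
    32: ("Gallbladder", 15),
    33: ("Stomach wall", 16),
    34: ("Small intestine wall", 17),
    35: ("Large intestine wall", 17),
    36: ("Heart", 21),
    37: ("Kidneys", 23),
    38: ("Liver", 26),
    39: ("Lungs", 29),
    40: ("Lymphatic tissue", 30),
    41: ("Muscle", 32),
    42: ("Gonads", (41, 34)),
    43: ("Oesophagus", 65),
    44: ("Pancreas", 35),
    45: ("Salivary glands", 35),
    46: ("Prostate/Uterus", (36, 43)),
    47: ("Skin", 38),
    48: ("Breast glandular tissue", (10, 11)),
    49: ("Spinal cord", 70),
    50: ("Spleen", 40),
    51: ("Thymus", 46),
    52: ("Thyroid", 42),
}

# fixed auxiliary components
_OSTEOID = ({"H": 0.070, "C": 0.250, "N": 0.070, "O": 0.591, "Na": 0.005,
             "P": 0.005, "S": 0.009}, 1.35)
_HYDROXYAPATITE = ({"H": 0.002, "O": 0.414, "P": 0.185, "Ca": 0.399}, 3.16)
_TEETH = ({"H": 0.022, "C": 0.095, "N": 0.029, "O": 0.421, "Mg": 0.007,
           "P": 0.137, "Ca": 0.289}, 2.20)
_AIR = ({"C": 0.013, "N": 0.755, "O": 0.232}, 0.0012)
_WATER = ({"H": 0.111894, "O": 0.888106}, 1.0)

#: Anchor for the medullary-cavity mineral admixture: the 1-year-old's
#: humeral medullary cavity has a theoretical CT number of 309 HU at 140 kVp.
MEDULLARY_ANCHOR_HU = 309.0
_ANCHOR_AGE = "1y"


def _mix(components: list[tuple[dict, float, float]]) -> tuple[dict, float]:
    """Mass-mix (fractions, density, mass share) components."""
    total = sum(share for _, _, share in components)
    fracs: dict[str, float] = {}
    inv_rho = 0.0
    for comp, rho, share in components:
        w = share / total
        inv_rho += w / rho
        for sym, f in comp.items():
            fracs[sym] = fracs.get(sym, 0.0) + w * f
    norm = sum(fracs.values())
    return {s: f / norm for s, f in fracs.items()}, 1.0 / inv_rho


def _hydrate(fracs: dict, rho: float, f: float) -> tuple[dict, float]:
    if f <= 0:
        return dict(fracs), rho
    return _mix([(fracs, rho, 1.0 - f), (_WATER[0], _WATER[1], f)])


def _adult_sources() -> dict[int, TissueComposition]:
    return {t.tissue_id: t for t in adult70()}


def _marrow(params: dict, yellow_share_adult: float, adult: dict[int, TissueComposition]) -> tuple[dict, float]:
    red = adult[50]
    yellow = adult[51]
    y = yellow_share_adult * params["yellow"]
    fracs, rho = _mix([
        (yellow.mass_fractions, yellow.density, y),
        (red.mass_fractions, red.density, 1.0 - y),
    ])
    return _hydrate(fracs, rho, params["hyd"])


def _spongiosa(site_id: int, params: dict, adult: dict[int, TissueComposition]) -> tuple[str, dict, float]:
    name, c0, m0, g0, y0 = _SKELETAL_SITES[site_id]
    cortical = adult[48]
    cartilage = adult[47]
    c = c0 * params["mineral"]
    osteoid_share = c0 - c
    marrow_fracs, marrow_rho = _marrow(params, y0, adult)
    fracs, rho = _mix([
        (cortical.mass_fractions, cortical.density, c),
        (_OSTEOID[0], _OSTEOID[1], osteoid_share),
        (cartilage.mass_fractions, cartilage.density, g0),
        (marrow_fracs, marrow_rho, m0),
    ])
    return name, fracs, rho


def _medullary(site_id: int, params: dict, q_anchor: float,
               adult: dict[int, TissueComposition]) -> tuple[str, dict, float]:
    name, scale = _MEDULLARY_SITES[site_id]
    red, yellow = adult[50], adult[51]
    y = params["med_y"]
    marrow_fracs, marrow_rho = _mix([
        (yellow.mass_fractions, yellow.density, y),
        (red.mass_fractions, red.density, 1.0 - y),
    ])
    q = q_anchor * scale * params["med"] / AGE_PARAMS[_ANCHOR_AGE]["med"]
    fracs, rho = _mix([
        (marrow_fracs, marrow_rho, 1.0 - q),
        (_HYDROXYAPATITE[0], _HYDROXYAPATITE[1], q),
    ])
    return name, fracs, rho


@lru_cache(maxsize=1)
def _anchor_q() -> float:
    """Mineral mass share of the 1y humeral medullary cavity hitting 309 HU."""
    xs = load_cross_sections()
    spectrum = builtin_spectrum("140kVp")
    adult = _adult_sources()
    params = AGE_PARAMS[_ANCHOR_AGE]

    def hu_of_q(q: float) -> float:
        red, yellow = adult[50], adult[51]
        marrow_fracs, marrow_rho = _mix([
            (yellow.mass_fractions, yellow.density, params["med_y"]),
            (red.mass_fractions, red.density, 1.0 - params["med_y"]),
        ])
        fracs, rho = _mix([
            (marrow_fracs, marrow_rho, 1.0 - q),
            (_HYDROXYAPATITE[0], _HYDROXYAPATITE[1], q),
        ])
        comp = TissueComposition(tissue_id=0, name="anchor", mass_fractions=fracs, density=rho)
        return theoretical_hu(comp, spectrum, xs)

    try:
        return brentq(lambda q: hu_of_q(q) - MEDULLARY_ANCHOR_HU, 0.01, 0.6, xtol=1e-8)
    except ValueError as exc:  # pragma: no cover - fixture breakage
        raise CalibrationError(f"cannot anchor medullary mineral share: {exc}") from exc


def build_pediatric_database(age_group: str, sex: str) -> TissueDatabase:
    """Build the synthetic 53-tissue database for one age group and sex."""
    if age_group not in AGE_PARAMS:
        raise ValueError(f"unknown age group {age_group!r}")
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    params = AGE_PARAMS[age_group]
    adult = _adult_sources()
    q_anchor = _anchor_q()
    tissues: list[TissueComposition] = []

    def add(tissue_id: int, name: str, fracs: dict, rho: float, group: str):
        tissues.append(TissueComposition(
            tissue_id=tissue_id, name=name, mass_fractions=fracs, density=rho,
            age_group=age_group, sex=sex, group=group, note="synthetic",
        ))

    add(1, "Teeth", *_TEETH, "excluded")
    for sid in _SKELETAL_SITES:
        name, fracs, rho = _spongiosa(sid, params, adult)
        add(sid, name, fracs, rho, "bone")
    for sid in _MEDULLARY_SITES:
        name, fracs, rho = _medullary(sid, params, q_anchor, adult)
        add(sid, name, fracs, rho, "soft")
    for sid, (name, source) in _SOFT_ORGANS.items():
        if isinstance(source, tuple):
            source = source[0] if sex == "male" else source[1]
            if sid == 42:
                name = "Testes" if sex == "male" else "Ovaries"
            elif sid == 46:
                name = "Prostate" if sex == "male" else "Uterus and cervix"
        base = adult[source]
        hyd = params["hyd"]
        if sid == 26:  # adipose loses lipid faster toward birth
            hyd = min(2.5 * params["hyd"], 0.55)
        fracs, rho = _hydrate(base.mass_fractions, base.density, hyd)
        if sid == 39:  # inflated lungs: age-dependent mean density
            rho = params["lung_rho"]
        add(sid, name, fracs, rho, "soft")
    add(53, "Air inside body", *_AIR, "excluded")

    db = TissueDatabase(source="pediatric53", tissues=tissues)
    db.validate()
    return db


def pediatric53(age_group: str, sex: str) -> TissueDatabase:
    """Alias for :func:`build_pediatric_database`."""
    return build_pediatric_database(age_group, sex)
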