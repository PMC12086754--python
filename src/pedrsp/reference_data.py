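"""Physical reference data: elements, photon cross sections, spectra, tissues.

This module owns all tabulated inputs of the analysis chain:

* the element table (atomic number, molar mass, mean excitation energy) for
  the 13 elements abundant in human tissue plus silicon (epoxy phantom
  inserts);
* elemental photon mass-attenuation coefficients on a 10-150 keV grid,
  interpolated log-log between nodes;
* discretized x-ray tube spectra (energy grid + relative fluence);
* tissue databases: the 70 standardized adult reference tissues, the Gammex
  RMI 467 electron-density phantom inserts, and a per-age/sex pediatric
  database (see :mod:`pedrsp.pediatric`).

Loaders validate every row and fail loudly with the offending tissue or line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EnergyRangeError, ParseError, ValidationError

__all__ = [
    "Element",
    "ElementTable",
    "PhotonCrossSectionTable",
    "Spectrum",
    "TissueComposition",
    "TissueDatabase",
    "load_elements",
    "load_cross_sections",
    "load_spectrum",
    "builtin_spectrum",
    "load_tissue_table",
    "adult70",
    "gammex",
    "BUILTIN_SPECTRUM_LABELS",
]

#: The 13 elements abundant in human tissue (spec order) plus Si.
TISSUE_ELEMENTS = ("H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca", "Fe", "I")
SUPPORTED_ELEMENTS = TISSUE_ELEMENTS + ("Si",)

AGE_GROUPS = ("newborn", "1y", "5y", "10y", "15y", "adult")
SEXES = ("male", "female")
TISSUE_GROUPS = ("soft", "bone", "lung", "excluded")

BUILTIN_SPECTRUM_LABELS = ("80kVp", "100kVp", "120kVp", "140kVp", "140kVp-Sn")

_FRACTION_TOL = 1e-3


def _data_path(*parts: str):
    return resources.files("pedrsp.data").joinpath("/".join(parts))


@dataclass(frozen=True)
class Element:
    """A chemical element with its stopping-power-relevant properties."""

    symbol: str
    Z: int  # atomic number
    A: float  # molar mass, g/mol
    I: float  # mean excitation energy, eV

    def __post_init__(self):
        if self.Z < 1:
            raise ValidationError(f"{self.symbol}: Z must be >= 1")
        if self.A <= 0 or self.I <= 0:
            raise ValidationError(f"{self.symbol}: A and I must be positive")


class ElementTable:
    """Lookup table of :class:`Element` objects keyed by symbol."""

    def __init__(self, elements: Iterable[Element]):
        self._by_symbol = {e.symbol: e for e in elements}
        missing = [s for s in TISSUE_ELEMENTS if s not in self._by_symbol]
        if missing:
            raise ValidationError(f"element table is missing tissue elements: {missing}")

    def __getitem__(self, symbol: str) -> Element:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise ValidationError(f"unknown element {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def symbols(self) -> tuple[str, ...]:
        return tuple(self._by_symbol)

    def with_i_values(self, i_values: Mapping[str, float]) -> "ElementTable":
        """Return a copy with some mean excitation energies replaced.

        Allows sensitivity checks with an alternative elemental I-value set.
        """
        out = []
        for sym, el in self._by_symbol.items():
            out.append(replace(el, I=float(i_values.get(sym, el.I))))
        return ElementTable(out)


class PhotonCrossSectionTable:
    """Elemental total mass attenuation coefficients (with coherent scatter).

    Values are interpolated log-log linearly between tabulated nodes, the
    standard choice for photon cross sections which are near power laws in
    energy away from absorption edges.  Queries outside the tabulated grid of
    an element raise :class:`EnergyRangeError`.
    """

    def __init__(self, table: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._table = {}
        for sym, (e, mu) in table.items():
            e = np.asarray(e, dtype=float)
            mu = np.asarray(mu, dtype=float)
            if e.ndim != 1 or e.shape != mu.shape:
                raise ValidationError(f"{sym}: energy and mu arrays must be 1-D and equal length")
            if not np.all(np.diff(e) > 0):
                raise ValidationError(f"{sym}: energy grid must be strictly increasing")
            if np.any(mu <= 0):
                raise ValidationError(f"{sym}: attenuation coefficients must be positive")
            self._table[sym] = (e, mu, np.log(e), np.log(mu))
        self.validate()

    def elements(self) -> tuple[str, ...]:
        return tuple(self._table)

    def energy_range(self, symbol: str) -> tuple[float, float]:
        e = self._table[symbol][0]
        return float(e[0]), float(e[-1])

    def validate(self) -> None:
        """Check grid coverage and monotone decrease above the last edge."""
        for sym, (e, mu, _, _) in self._table.items():
            if e[0] > 10.0 or e[-1] < 150.0:
                raise ValidationError(f"{sym}: grid must cover at least 10-150 keV")
            # locate the highest absorption edge (upward jump) in range
            jumps = np.where(np.diff(mu) > 0)[0]
            start = jumps[-1] + 1 if jumps.size else 0
            tail = mu[start:]
            if np.any(np.diff(tail) >= 0):
                raise ValidationError(f"{sym}: not monotone decreasing above highest edge")

    def mu_over_rho(self, symbol: str, energy_kev) -> np.ndarray | float:
        """Interpolated mass attenuation coefficient, cm^2/g."""
        if symbol not in self._table:
            raise ValidationError(f"no cross-section data for element {symbol!r}")
        e, _, log_e, log_mu = self._table[symbol]
        energy = np.asarray(energy_kev, dtype=float)
        if np.any(energy < e[0]) or np.any(energy > e[-1]):
            raise EnergyRangeError(
                f"{symbol}: energy outside tabulated range [{e[0]:g}, {e[-1]:g}] keV"
            )
        out = np.exp(np.interp(np.log(energy), log_e, log_mu))
        return float(out) if np.isscalar(energy_kev) else out


@dataclass(frozen=True)
class Spectrum:
    """A discretized x-ray tube spectrum (relative photon fluence per bin)."""

    label: str
    energies: np.ndarray  # keV
    fluence: np.ndarray  # dimensionless, normalized to sum 1

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if e.ndim != 1 or e.shape != f.shape or e.size == 0:
            raise ValidationError(f"{self.label}: energies/fluence must be equal-length 1-D")
        if not np.all(np.diff(e) > 0):
            raise ValidationError(f"{self.label}: energy grid must be strictly increasing")
        if np.any(f < 0):
            raise ValidationError(f"{self.label}: fluence must be non-negative")
        total = f.sum()
        if total <= 0:
            raise ValidationError(f"{self.label}: total fluence must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f / total)

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.fluence))

    @property
    def max_energy(self) -> float:
        return float(self.energies[self.fluence > 0].max())

    def validate_ct(self, kvp: float | None = None) -> None:
        """Invariants for a realistic CT tube spectrum."""
        if self.n_nonzero_bins < 20:
            raise ValidationError(f"{self.label}: CT spectrum needs >= 20 nonzero bins")
        if kvp is not None and self.max_energy > kvp + 1e-9:
            raise ValidationError(f"{self.label}: photons above the peak voltage {kvp} kVp")


@dataclass(frozen=True)
class TissueComposition:
    """A named material: elemental mass fractions, density and metadata."""

    tissue_id: int
    name: str
    mass_fractions: Mapping[str, float]
    density: float  # g/cm^3
    age_group: str = "adult"
    sex: str = "male"
    group: str = "soft"
    note: str = ""

    def __post_init__(self):
        if self.density <= 0:
            raise ValidationError(f"{self.name}: density must be positive")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"{self.name}: unknown age group {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"{self.name}: unknown sex {self.sex!r}")
        if self.group not in TISSUE_GROUPS:
            raise ValidationError(f"{self.name}: unknown tissue group {self.group!r}")
        fracs = {k: float(v) for k, v in self.mass_fractions.items() if float(v) != 0.0}
        unknown = [s for s in fracs if s not in SUPPORTED_ELEMENTS]
        if unknown:
            raise ValidationError(f"{self.name}: unsupported elements {unknown}")
        if any(v < 0 for v in fracs.values()):
            raise ValidationError(f"{self.name}: negative mass fraction")
        total = sum(fracs.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"{self.name}: mass fractions sum to {total:.4f}, expected 1 +/- {_FRACTION_TOL}"
            )
        object.__setattr__(self, "mass_fractions", fracs)

    def with_density(self, density: float) -> "TissueComposition":
        return replace(self, density=density)


_CSV_COLUMNS = [
    "tissue_id", "name", "age_group", "sex", "group", "density",
    "H", "C", "N", "O", "Na", "Mg", "Si", "P", "S", "Cl", "K", "Ca", "Fe", "I",
    "note",
]


@dataclass
class TissueDatabase:
    """An ordered collection of :class:`TissueComposition` with a source label."""

    source: str
    tissues: list[TissueComposition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tissues)

    def __iter__(self):
        return iter(self.tissues)

    def get(self, tissue_id: int) -> TissueComposition:
        for t in self.tissues:
            if t.tissue_id == tissue_id:
                return t
        raise KeyError(f"{self.source}: no tissue with id {tissue_id}")

    def by_group(self, group: str) -> list[TissueComposition]:
        return [t for t in self.tissues if t.group == group]

    def validate(self) -> None:
        if self.source == "adult70" and len(self) != 70:
            raise ValidationError(f"adult70 must have 70 entries, found {len(self)}")
        if self.source == "pediatric53":
            if len(self) != 53:
                raise ValidationError(f"pediatric53 must have 53 entries, found {len(self)}")
            for t in self.tissues:
                expected = pediatric_group_for_id(t.tissue_id)
                if t.group != expected:
                    raise ValidationError(
                        f"{t.name} (id {t.tissue_id}): group {t.group!r}, "
                        f"expected {expected!r} from its id"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tissues:
            row = {
                "tissue_id": t.tissue_id, "name": t.name, "age_group": t.age_group,
                "sex": t.sex, "group": t.group, "density": t.density, "note": t.note,
            }
            for sym in SUPPORTED_ELEMENTS:
                row[sym] = t.mass_fractions.get(sym, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)[_CSV_COLUMNS]

    def save(self, path: str | Path) -> None:
        # default float formatting is shortest-repr, which round-trips exactly
        self.to_frame().to_csv(path, index=False)


def pediatric_group_for_id(tissue_id: int) -> str:
    """Tissue-group rule of the pediatric numbering: bones 2-21, soft 22-52."""
    if 2 <= tissue_id <= 21:
        return "bone"
    if 22 <= tissue_id <= 52:
        return "soft"
    return "excluded"


# ---------------------------------------------------------------------------
# loaders


def load_elements(path: str | Path | None = None) -> ElementTable:
    """Load the element/I-value table (CSV: symbol,Z,A,I)."""
    src = Path(path) if path is not None else _data_path("elements.csv")
    df = pd.read_csv(io.StringIO(src.read_text()), comment="#")
    return ElementTable(
        Element(symbol=str(r.symbol), Z=int(r.Z), A=float(r.A), I=float(r.I))
        for r in df.itertuples()
    )


def load_cross_sections(path: str | Path | None = None) -> PhotonCrossSectionTable:
    """Load the elemental attenuation table (CSV: symbol,energy_keV,mu_rho)."""
    src = Path(path) if path is not None else _data_path("photon_mu_rho.csv")
    df = pd.read_csv(io.StringIO(src.read_text()), comment="#")
    table = {}
    for sym, sub in df.groupby("symbol", sort=False):
        table[sym] = (sub["energy_keV"].to_numpy(), sub["mu_rho"].to_numpy())
    return PhotonCrossSectionTable(table)


def load_spectrum(path: str | Path, label: str | None = None) -> Spectrum:
    """Load a spectrum from whitespace-delimited two-column text (keV, fluence)."""
    path = Path(path)
    energies, fluence = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path.name}:{lineno}: expected two columns, got {len(parts)}")
        try:
            e, f = float(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(f"{path.name}:{lineno}: non-numeric entry") from None
        energies.append(e)
        fluence.append(f)
    if not energies:
        raise ParseError(f"{path.name}: no data rows")
    return Spectrum(label or path.stem, np.asarray(energies), np.asarray(fluence))


def builtin_spectrum(label: str) -> Spectrum:
    """One of the shipped fixture spectra (see BUILTIN_SPECTRUM_LABELS)."""
    if label not in BUILTIN_SPECTRUM_LABELS:
        raise ValidationError(f"unknown spectrum label {label!r}; choose from {BUILTIN_SPECTRUM_LABELS}")
    with resources.as_file(_data_path("spectra", f"{label}.txt")) as p:
        return load_spectrum(p, label=label)


def _tissue_from_row(row: pd.Series, lineno: int, path_name: str) -> TissueComposition:
    try:
        fracs = {sym: float(row[sym]) for sym in SUPPORTED_ELEMENTS if sym in row and float(row[sym]) != 0.0}
        return TissueComposition(
            tissue_id=int(row["tissue_id"]),
            name=str(row["name"]),
            mass_fractions=fracs,
            density=float(row["density"]),
            age_group=str(row["age_group"]),
            sex=str(row["sex"]),
            group=str(row["group"]),
            note=str(row.get("note", "") or ""),
        )
    except ValidationError:
        raise
    except Exception as exc:  # malformed cell types etc.
        raise ParseError(f"{path_name}: malformed row {lineno}: {exc}") from exc


def load_tissue_table(path: str | Path, source: str | None = None) -> TissueDatabase:
    """Load and validate a tissue database from delimited text.

    The file must have a header naming the metadata columns, ``density`` and
    the elemental mass-fraction columns.  Every row is validated against the
    :class:`TissueComposition` invariants; failures name the tissue.
    """
    path = Path(path)
    try:
        df = pd.read_csv(io.StringIO(path.read_text()), comment="#",
                         float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path.name}: cannot parse: {exc}") from exc
    required = {"tissue_id", "name", "density"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path.name}: header must include {sorted(required)}")
    for col in ("age_group", "sex", "group", "note"):
        if col not in df.columns:
            df[col] = {"age_group": "adult", "sex": "male", "group": "soft", "note": ""}[col]
    db = TissueDatabase(
        source=source or path.stem,
        tissues=[_tissue_from_row(row, i + 2, path.name) for i, (_, row) in enumerate(df.iterrows())],
    )
    db.validate()
    return db


def adult70() -> TissueDatabase:
    """The 70 standardized adult reference tissues."""
    with resources.as_file(_data_path("tissues", "adult70.csv")) as p:
        return load_tissue_table(p, source="adult70")


def gammex() -> TissueDatabase:
    """The Gammex RMI 467 electron-density phantom inserts."""
    with resources.as_file(_data_path("tissues", "gammex.csv")) as p:
        return load_tissue_table(p, source="gammex")
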