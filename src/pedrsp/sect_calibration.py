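"""Single-energy CT stoichiometric calibration curves and RSP error statistics.

The calibration curve is a piece-wise linear HU -> RSP map.  Two kinds are
built here:

* ``conventional``: four segments (lung / adipose / soft / bone) fitted on
  the 70 standardized adult reference tissues, with the adipose-soft
  boundary depending on the tube voltage (-85/-75/-75/-95 HU at
  80/100/120/140 kVp);
* ``age-specific``: three segments (lung / soft / bone, boundaries
  -1000/-100/200/4100 HU) fitted per age group and sex on the pediatric
  tissue database, giving 12 curves in total.

Tissues are binned into segments by their *predicted* CT number from the
fitted stoichiometric parameterization (not their spectrum-exact theoretical
HU), matching how a clinical calibration is transferred from a phantom scan
to tabulated tissues.  Segment membership is half-open [lo, hi) with the top
segment closed; each segment is an unweighted ordinary least-squares line of
reference RSP against predicted HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ValidationError
from .photon_model import SchneiderFit, schneider_predict_hu
from .proton_model import ProtonBeamContext, tissue_rsp_ref
from .reference_data import ElementTable, TissueDatabase

__all__ = [
    "Segment",
    "CalibrationCurve",
    "ErrorStats",
    "ADIPOSE_SOFT_BOUNDARY",
    "build_conventional_curve",
    "build_age_specific_curve",
    "apply_curve",
    "rsp_error",
    "evaluate_database",
    "error_stats",
]

#: Adipose/soft segment boundary (HU) of the conventional curve per spectrum.
ADIPOSE_SOFT_BOUNDARY = {"80kVp": -85.0, "100kVp": -75.0, "120kVp": -75.0, "140kVp": -95.0}

HU_FLOOR = -1000.0


@dataclass(frozen=True)
class Segment:
    lo: float
    hi: float
    slope: float
    intercept: float
    name: str = ""

    def __call__(self, hu):
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


@dataclass
class CalibrationCurve:
    """Piece-wise linear HU -> RSP map with explicit segment boundaries."""

    kind: str  # "conventional" | "age-specific"
    spectrum_label: str
    segments: list[Segment]
    age_group: str | None = None
    sex: str | None = None
    discontinuities: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("conventional", "age-specific"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        expected = 4 if self.kind == "conventional" else 3
        if len(self.segments) != expected:
            raise ValidationError(
                f"{self.kind} curve must have {expected} segments, got {len(self.segments)}"
            )
        if self.segments[0].lo != HU_FLOOR:
            raise ValidationError("first segment must start at -1000 HU")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.hi != b.lo:
                raise ValidationError("segments must be contiguous and non-overlapping")

    @property
    def hi_max(self) -> float:
        return self.segments[-1].hi

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": self.kind,
            "spectrum": self.spectrum_label,
            "age_group": self.age_group,
            "sex": self.sex,
            "segments": [
                {"lo": s.lo, "hi": s.hi, "slope": s.slope, "intercept": s.intercept, "name": s.name}
                for s in self.segments
            ],
            "discontinuities": self.discontinuities,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CalibrationCurve":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        doc = json.loads(p.read_text() if p else str(text_or_path))
        return cls(
            kind=doc["kind"],
            spectrum_label=doc["spectrum"],
            segments=[Segment(**s) for s in doc["segments"]],
            age_group=doc.get("age_group"),
            sex=doc.get("sex"),
            discontinuities=doc.get("discontinuities", {}),
        )


def _fit_segments(
    hu: np.ndarray,
    rsp: np.ndarray,
    boundaries: Sequence[float],
    names: Sequence[str],
) -> list[Segment]:
    segments = []
    for i, name in enumerate(names):
        lo, hi = boundaries[i], boundaries[i + 1]
        last = i == len(names) - 1
        mask = (hu >= lo) & ((hu <= hi) if last else (hu < hi))
        seg_hu = hu[mask]
        seg_rsp = rsp[mask]
        if name == "lung":
            # the lung line is anchored at the air endpoint (-1000 HU, RSP 0),
            # as a clinical curve is; tissue tables contain few lung entries
            seg_hu = np.append(seg_hu, HU_FLOOR)
            seg_rsp = np.append(seg_rsp, 0.0)
        if seg_hu.size < 2 or np.ptp(seg_hu) == 0:
            raise CalibrationError(
                f"segment {name!r} [{lo:g}, {hi:g}) HU has {seg_hu.size} point(s); "
                "need >= 2 distinct CT numbers for a line"
            )
        slope, intercept = np.polyfit(seg_hu, seg_rsp, 1)
        segments.append(Segment(lo=lo, hi=hi, slope=float(slope), intercept=float(intercept), name=name))
    return segments


def _joint_gaps(segments: list[Segment]) -> dict:
    gaps = {}
    for a, b in zip(segments, segments[1:]):
        gaps[f"{a.name}/{b.name}@{a.hi:g}HU"] = float(b(a.hi) - a(a.hi))
    return gaps


def _predicted_table(
    db: TissueDatabase, fit: SchneiderFit, ctx: ProtonBeamContext, elements: ElementTable
) -> tuple[np.ndarray, np.ndarray]:
    hu = np.array([schneider_predict_hu(fit, t, elements) for t in db])
    rsp = np.array([tissue_rsp_ref(t, ctx) for t in db])
    return hu, rsp


def build_conventional_curve(
    fit: SchneiderFit,
    adult_db: TissueDatabase,
    ctx: ProtonBeamContext,
    elements: ElementTable,
) -> CalibrationCurve:
    """Four-segment stoichiometric calibration on the adult reference tissues."""
    if fit.spectrum_label not in ADIPOSE_SOFT_BOUNDARY:
        raise CalibrationError(
            f"no adipose/soft boundary defined for spectrum {fit.spectrum_label!r}"
        )
    b_adipose = ADIPOSE_SOFT_BOUNDARY[fit.spectrum_label]
    hu, rsp = _predicted_table(adult_db, fit, ctx, elements)
    segments = _fit_segments(
        hu, rsp,
        boundaries=(HU_FLOOR, -150.0, b_adipose, 200.0, 3100.0),
        names=("lung", "adipose", "soft", "bone"),
    )
    return CalibrationCurve(
        kind="conventional",
        spectrum_label=fit.spectrum_label,
        segments=segments,
        discontinuities=_joint_gaps(segments),
    )


def build_age_specific_curve(
    fit: SchneiderFit,
    pediatric_db: TissueDatabase,
    ctx: ProtonBeamContext,
    elements: ElementTable,
) -> CalibrationCurve:
    """Three-segment calibration on one age/sex pediatric tissue set.

    Excluded tissues (teeth, in-body air) do not participate in the fit.
    """
    fit_db = TissueDatabase(
        source=pediatric_db.source,
        tissues=[t for t in pediatric_db if t.group != "excluded"],
    )
    hu, rsp = _predicted_table(fit_db, fit, ctx, elements)
    segments = _fit_segments(
        hu, rsp,
        boundaries=(HU_FLOOR, -100.0, 200.0, 4100.0),
        names=("lung", "soft", "bone"),
    )
    ages = {t.age_group for t in fit_db}
    sexes = {t.sex for t in fit_db}
    return CalibrationCurve(
        kind="age-specific",
        spectrum_label=fit.spectrum_label,
        segments=segments,
        age_group=ages.pop() if len(ages) == 1 else None,
        sex=sexes.pop() if len(sexes) == 1 else None,
        discontinuities=_joint_gaps(segments),
    )


def apply_curve(curve: CalibrationCurve, hu) -> np.ndarray | float:
    """Evaluate the piece-wise linear curve at the given CT number(s).

    CT numbers below -1000 HU are clamped to -1000; above the last segment
    boundary the bone line extrapolates.  The result is floored at 0 (a
    treatment-planning curve never returns negative stopping power).
    """
    hu_arr = np.maximum(np.asarray(hu, dtype=float), HU_FLOOR)
    out = np.empty_like(hu_arr)
    for i, seg in enumerate(curve.segments):
        last = i == len(curve.segments) - 1
        mask = (hu_arr >= seg.lo) & (np.ones_like(hu_arr, bool) if last else (hu_arr < seg.hi))
        out[mask] = seg(hu_arr[mask])
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(hu) else out


def rsp_error(rsp_est, rsp_ref):
    """Relative RSP error (RSP_est - RSP_ref) / RSP_ref, as a fraction."""
    ref = np.asarray(rsp_ref, dtype=float)
    if np.any(ref <= 0):
        raise ValidationError("reference RSP must be positive")
    out = (np.asarray(rsp_est, dtype=float) - ref) / ref
    return float(out) if np.isscalar(rsp_ref) else out


def evaluate_database(
    db: TissueDatabase,
    curve: CalibrationCurve,
    fit: SchneiderFit,
    ctx: ProtonBeamContext,
    elements: ElementTable,
) -> pd.DataFrame:
    """Per-tissue table: predicted HU, reference and curve-estimated RSP, error."""
    rows = []
    for t in db:
        hu = schneider_predict_hu(fit, t, elements)
        ref = tissue_rsp_ref(t, ctx)
        est = apply_curve(curve, hu)
        rows.append(
            {
                "tissue_id": t.tissue_id, "name": t.name, "age_group": t.age_group,
                "sex": t.sex, "group": t.group, "hu": hu,
                "rsp_ref": ref, "rsp_est": est, "error": rsp_error(est, ref),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ErrorStats:
    """Per-group error statistics in percent, as reported per age and sex."""

    group: str
    mean: float
    sd: float
    min: float
    max: float
    n: int
    excluded_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("inconsistent error statistics (min <= mean <= max)")


def error_stats(
    table: pd.DataFrame,
    groups: Iterable[str] = ("soft", "bone"),
    exclude_ids: Iterable[int] = (),
) -> list[ErrorStats]:
    """Mean/sd/min/max of per-tissue RSP errors per tissue group, in percent.

    Tissues with group ``excluded`` (teeth, in-body air) never participate;
    ``exclude_ids`` removes additional tissues (e.g. the medullary-cavity
    tissues in a sensitivity variant).
    """
    exclude_ids = tuple(exclude_ids)
    out = []
    for group in groups:
        sub = table[(table["group"] == group) & ~table["tissue_id"].isin(exclude_ids)]
        if len(sub) < 2:
            raise ValidationError(f"group {group!r} has {len(sub)} tissues after exclusions")
        err = sub["error"].to_numpy() * 100.0
        out.append(
            ErrorStats(
                group=group,
                mean=float(err.mean()),
                sd=float(err.std(ddof=1)),
                min=float(err.min()),
                max=float(err.max()),
                n=int(err.size),
                excluded_ids=exclude_ids,
            )
        )
    return out
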