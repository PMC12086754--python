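"""High-level analysis pipeline: error-statistics tables and range demos.

Convenience layer tying the modules together the way the study is run:
fit the stoichiometric parameterization on the Gammex inserts, build the
conventional and age-specific SECT curves and the DECT model, evaluate RSP
errors over the pediatric databases per age group and sex, and run the
synthetic-phantom water-equivalent-range comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import pediatric
from .dect_calibration import DECTModel, calibrate_dect, estimate_rsp_dect
from .phantom_synth import (
    DECT_NOISE_HU,
    SECT_NOISE_HU,
    GeometryPrimitive,
    build_geometric_phantom,
    rsp_maps,
    sample_densities,
    simulate_ct,
    simulate_dect,
)
from .photon_model import SchneiderFit, schneider_fit, theoretical_hu
from .proton_model import ProtonBeamContext, tissue_rsp_ref
from .range_eval import Ray, wer_difference_report
from .reference_data import (
    AGE_GROUPS,
    SEXES,
    TissueDatabase,
    adult70,
    builtin_spectrum,
    gammex,
    load_cross_sections,
    load_elements,
)
from .sect_calibration import (
    CalibrationCurve,
    build_age_specific_curve,
    build_conventional_curve,
    error_stats,
    evaluate_database,
)

__all__ = ["Pipeline", "default_pipeline", "MEDULLARY_EXCLUSION"]

#: Medullary-cavity tissues excluded in the sensitivity variant.
MEDULLARY_EXCLUSION = (22, 23, 25)


@dataclass
class Pipeline:
    """Lazily-built analysis state for one SECT spectrum choice."""

    sect_spectrum: str = "140kVp"
    dect_low: str = "80kVp"
    dect_high: str = "140kVp-Sn"
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.xs = load_cross_sections()
        self.elements = load_elements()
        self.ctx = ProtonBeamContext(elements=self.elements)

    # -- building blocks ---------------------------------------------------

    def spectrum(self, label: str):
        key = ("spectrum", label)
        if key not in self._cache:
            self._cache[key] = builtin_spectrum(label)
        return self._cache[key]

    @property
    def schneider(self) -> SchneiderFit:
        if "fit" not in self._cache:
            sp = self.spectrum(self.sect_spectrum)
            inserts = [(t, theoretical_hu(t, sp, self.xs)) for t in gammex()]
            self._cache["fit"] = schneider_fit(inserts, self.sect_spectrum, self.elements)
        return self._cache["fit"]

    @property
    def conventional_curve(self) -> CalibrationCurve:
        if "curve" not in self._cache:
            self._cache["curve"] = build_conventional_curve(
                self.schneider, adult70(), self.ctx, self.elements
            )
        return self._cache["curve"]

    @property
    def dect_model(self) -> DECTModel:
        if "dect" not in self._cache:
            self._cache["dect"] = calibrate_dect(
                gammex(), self.spectrum(self.dect_low), self.spectrum(self.dect_high),
                adult70(), self.ctx, self.xs,
            )
        return self._cache["dect"]

    def pediatric_db(self, age_group: str, sex: str) -> TissueDatabase:
        key = ("db", age_group, sex)
        if key not in self._cache:
            self._cache[key] = pediatric.build_pediatric_database(age_group, sex)
        return self._cache[key]

    def age_specific_curve(self, age_group: str, sex: str) -> CalibrationCurve:
        key = ("age_curve", age_group, sex)
        if key not in self._cache:
            self._cache[key] = build_age_specific_curve(
                self.schneider, self.pediatric_db(age_group, sex), self.ctx, self.elements
            )
        return self._cache[key]

    # -- per-tissue evaluations --------------------------------------------

    def sect_evaluation(self, age_group: str, sex: str) -> pd.DataFrame:
        return evaluate_database(
            self.pediatric_db(age_group, sex), self.conventional_curve,
            self.schneider, self.ctx, self.elements,
        )

    def age_specific_evaluation(self, age_group: str, sex: str) -> pd.DataFrame:
        return evaluate_database(
            self.pediatric_db(age_group, sex), self.age_specific_curve(age_group, sex),
            self.schneider, self.ctx, self.elements,
        )

    def dect_evaluation(self, age_group: str, sex: str) -> pd.DataFrame:
        low = self.spectrum(self.dect_low)
        high = self.spectrum(self.dect_high)
        rows = []
        for t in self.pediatric_db(age_group, sex):
            ref = tissue_rsp_ref(t, self.ctx) if t.group != "excluded" else np.nan
            if t.group == "excluded":
                continue
            est = estimate_rsp_dect(
                self.dect_model,
                theoretical_hu(t, low, self.xs),
                theoretical_hu(t, high, self.xs),
                self.ctx,
            )
            rows.append({
                "tissue_id": t.tissue_id, "name": t.name, "age_group": age_group,
                "sex": sex, "group": t.group, "rsp_ref": ref, "rsp_est": est.rsp,
                "zeff": est.zeff, "rho_e": est.rho_e, "i_ev": est.i_ev,
                "error": (est.rsp - ref) / ref,
            })
        return pd.DataFrame(rows)

    # -- summary tables ----------------------------------------------------

    def _stats_table(self, evaluator, exclude_ids=()) -> pd.DataFrame:
        rows = []
        for age in AGE_GROUPS:
            for sex in SEXES:
                table = evaluator(age, sex)
                for st in error_stats(table, exclude_ids=exclude_ids):
                    rows.append({
                        "age_group": age, "sex": sex, "group": st.group,
                        "mean": st.mean, "sd": st.sd, "min": st.min, "max": st.max,
                        "n": st.n,
                    })
        return pd.DataFrame(rows)

    def sect_table(self, exclude_ids=()) -> pd.DataFrame:
        """Per-age/sex soft/bone error statistics, conventional SECT."""
        return self._stats_table(self.sect_evaluation, exclude_ids)

    def age_specific_table(self, exclude_ids=()) -> pd.DataFrame:
        return self._stats_table(self.age_specific_evaluation, exclude_ids)

    def dect_table(self, exclude_ids=()) -> pd.DataFrame:
        return self._stats_table(self.dect_evaluation, exclude_ids)

    def extreme_errors(self) -> dict:
        """Most extreme per-tissue SECT errors over all ages/sexes (percent)."""
        worst_min, worst_max = None, None
        for age in AGE_GROUPS:
            if age == "adult":
                continue
            for sex in SEXES:
                tab = self.sect_evaluation(age, sex)
                tab = tab[tab["group"] != "excluded"]
                lo = tab.loc[tab["error"].idxmin()]
                hi = tab.loc[tab["error"].idxmax()]
                if worst_min is None or lo["error"] < worst_min["error"]:
                    worst_min = lo
                if worst_max is None or hi["error"] > worst_max["error"]:
                    worst_max = hi
        return {
            "min_pct": float(worst_min["error"] * 100.0),
            "min_tissue": str(worst_min["name"]),
            "min_age": str(worst_min["age_group"]),
            "max_pct": float(worst_max["error"] * 100.0),
            "max_tissue": str(worst_max["name"]),
            "max_age": str(worst_max["age_group"]),
        }

    # -- synthetic phantom WER demo ----------------------------------------

    def slab_phantom_report(self, age_group: str = "10y", sex: str = "male",
                            seed: int = 0, shape=(24, 24, 60),
                            spacing=(2.0, 2.0, 2.0),
                            slab_tissue_ids: tuple[int, int] = (26, 38)) -> dict:
        """Range comparison on a layered soft-tissue slab phantom.

        Builds a muscle body with two slabs (by default adipose and liver)
        along z, simulates noisy SECT/DECT images, derives the three RSP
        maps, and traces axial rays through the slabs.  A bone slab can be
        substituted via ``slab_tissue_ids`` to study mixed-sign paths.
        """
        db = self.pediatric_db(age_group, sex)
        comps = {t.tissue_id: t for t in db}
        nx, ny, nz = shape
        ext = [s * n for s, n in zip(spacing, shape)]
        prims = [
            GeometryPrimitive("body", "box", (ext[0] / 2, ext[1] / 2, ext[2] / 2),
                              (ext[0] / 2, ext[1] / 2, ext[2] / 2), tissue_id=41, priority=0),
            GeometryPrimitive("slab_a", "box", (ext[0] / 2, ext[1] / 2, ext[2] * 0.25),
                              (ext[0] / 2, ext[1] / 2, ext[2] * 0.10),
                              tissue_id=slab_tissue_ids[0], priority=1),
            GeometryPrimitive("slab_b", "box", (ext[0] / 2, ext[1] / 2, ext[2] * 0.55),
                              (ext[0] / 2, ext[1] / 2, ext[2] * 0.10),
                              tissue_id=slab_tissue_ids[1], priority=2),
        ]
        phantom = build_geometric_phantom(prims, comps, shape, spacing, seed=seed)
        rng_seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
        phantom = phantom.with_density(sample_densities(phantom, seed=int(rng_seeds[0])))
        sect_img = simulate_ct(phantom, self.spectrum(self.sect_spectrum), self.xs,
                               SECT_NOISE_HU, seed=int(rng_seeds[1]))
        dect_img = simulate_dect(phantom, self.spectrum(self.dect_low),
                                 self.spectrum(self.dect_high), self.xs,
                                 DECT_NOISE_HU, seed=int(rng_seeds[2]))
        ref, sect, dect = rsp_maps(phantom, self.conventional_curve, self.dect_model,
                                   sect_img, dect_img, self.ctx)
        stop = ext[2] * 0.9
        rays = [
            Ray(origin=((i + 0.5) * spacing[0], (j + 0.5) * spacing[1], -1.0),
                direction=(0.0, 0.0, 1.0), stop_mm=stop)
            for i in range(4, nx - 4, 4) for j in range(4, ny - 4, 4)
        ]
        report = wer_difference_report(ref, sect, dect, rays, spacing)
        return {"report": report, "phantom": phantom, "maps": (ref, sect, dect)}


@lru_cache(maxsize=2)
def default_pipeline(sect_spectrum: str = "140kVp") -> Pipeline:
    return Pipeline(sect_spectrum=sect_spectrum)
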