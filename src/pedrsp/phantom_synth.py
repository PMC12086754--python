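"""Synthetic labeled voxel phantoms and simulated SECT/DECT images.

Stand-in for patient-derived virtual phantoms: a phantom is a labeled 3-D
grid built from geometric primitives (ellipsoids, boxes, cylinders), each
mapped to a tissue with known elemental composition.  The simulation chain
mirrors how the virtual-patient images are produced:

* per-voxel densities are drawn from a normal distribution centered on the
  tissue mean density with a 3-sigma relative variation of 1.7%
  (truncated at +/-3 sigma);
* theoretical CT numbers are computed voxelwise from composition and
  density, then i.i.d. Gaussian noise is added (7 HU for the SECT image;
  12 and 8 HU for the 80/140-kVp DECT pair, chosen dose-equivalent to the
  SECT noise);
* a 1-D k-means clustering on the CT numbers within a contour partitions
  its voxels among a pre-assigned candidate tissue list, clusters being
  matched to tissues by the rank order of their mean CT numbers;
* reference, SECT and DECT RSP maps are derived from the same phantom.

All stochastic operations are reproducible from (seed, configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm
from sklearn.cluster import KMeans

from .exceptions import ValidationError
from .photon_model import mean_mu_over_rho, water_composition
from .proton_model import ProtonBeamContext, tissue_rsp_ref
from .reference_data import (
    PhotonCrossSectionTable,
    Spectrum,
    TissueComposition,
)
from .sect_calibration import CalibrationCurve, apply_curve
from .dect_calibration import DECTModel, estimate_rsp_dect

__all__ = [
    "GeometryPrimitive",
    "VoxelPhantom",
    "SimulatedImage",
    "build_geometric_phantom",
    "sample_densities",
    "simulate_ct",
    "simulate_dect",
    "assign_tissues_kmeans",
    "rsp_maps",
    "DENSITY_REL_SD",
    "SECT_NOISE_HU",
    "DECT_NOISE_HU",
]

#: Per-voxel density variation: 3 sigma = 1.7% of the tissue mean density.
DENSITY_REL_SD = 0.017 / 3.0
#: Gaussian image noise defaults (HU).
SECT_NOISE_HU = 7.0
DECT_NOISE_HU = (12.0, 8.0)  # low (80 kVp), high (140 kVp Sn)


@dataclass(frozen=True)
class GeometryPrimitive:
    """A geometric primitive voxelized into the phantom grid.

    ``size_mm`` means semi-axes for an ellipsoid, half-sizes for a box, and
    (radius, radius, half-height along z) for a cylinder.  Higher priority
    wins where primitives overlap.
    """

    name: str
    shape: str  # "ellipsoid" | "box" | "cylinder"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    tissue_id: int
    priority: int = 0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        sx, sy, sz = self.size_mm
        dx, dy, dz = x - cx, y - cy, z - cz
        if self.shape == "ellipsoid":
            return (dx / sx) ** 2 + (dy / sy) ** 2 + (dz / sz) ** 2 <= 1.0
        if self.shape == "box":
            return (np.abs(dx) <= sx) & (np.abs(dy) <= sy) & (np.abs(dz) <= sz)
        if self.shape == "cylinder":
            return ((dx / sx) ** 2 + (dy / sy) ** 2 <= 1.0) & (np.abs(dz) <= sz)
        raise ValidationError(f"unknown primitive shape {self.shape!r}")


@dataclass
class VoxelPhantom:
    """Labeled 3-D grid with per-voxel density and per-label composition."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    labels: np.ndarray  # int16 tissue_id per voxel
    density: np.ndarray  # g/cm^3 per voxel
    compositions: Mapping[int, TissueComposition]
    contours: dict[str, np.ndarray] = field(default_factory=dict)  # boolean masks
    seed: int | None = None

    def __post_init__(self):
        if self.labels.shape != self.shape or self.density.shape != self.shape:
            raise ValidationError("label/density maps must match the grid shape")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.compositions)
        if missing:
            raise ValidationError(f"labels without composition: {sorted(missing)}")
        if np.any(self.density <= 0):
            raise ValidationError("densities must be positive")
        for name, mask in self.contours.items():
            if mask.shape != self.shape:
                raise ValidationError(f"contour {name!r} does not match the grid")

    def with_density(self, density: np.ndarray) -> "VoxelPhantom":
        return replace(self, density=density)

    def mean_density_map(self) -> np.ndarray:
        out = np.empty(self.shape, dtype=np.float32)
        for tid, comp in self.compositions.items():
            out[self.labels == tid] = comp.density
        return out


@dataclass(frozen=True)
class SimulatedImage:
    """One or two HU volumes with their spectrum labels and noise levels."""

    hu: tuple[np.ndarray, ...]
    spectrum_labels: tuple[str, ...]
    noise_sd_hu: tuple[float, ...]
    seed: int | None = None

    def __post_init__(self):
        if not (len(self.hu) == len(self.spectrum_labels) == len(self.noise_sd_hu)):
            raise ValidationError("channel counts disagree")


def build_geometric_phantom(
    primitives: Sequence[GeometryPrimitive],
    compositions: Mapping[int, TissueComposition],
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    background_tissue_id: int | None = None,
    seed: int | None = None,
) -> VoxelPhantom:
    """Voxelize primitives (by ascending priority) into a labeled phantom.

    Deterministic for a given geometry; the seed is recorded for downstream
    sampling.  Voxel centers are at (index + 0.5) * spacing in mm, 0-based.
    """
    if not primitives and background_tissue_id is None:
        raise ValidationError("need at least one primitive or a background tissue")
    for p in primitives:
        if p.tissue_id not in compositions:
            raise ValidationError(f"primitive {p.name!r}: unknown tissue id {p.tissue_id}")
    nx, ny, nz = shape
    sx, sy, sz = spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    xg, yg, zg = np.meshgrid(x, y, z, indexing="ij")

    if background_tissue_id is not None:
        if background_tissue_id not in compositions:
            raise ValidationError(f"unknown background tissue id {background_tissue_id}")
        labels = np.full(shape, background_tissue_id, dtype=np.int16)
    else:
        labels = np.full(shape, primitives[0].tissue_id, dtype=np.int16)

    contours: dict[str, np.ndarray] = {}
    for prim in sorted(primitives, key=lambda p: p.priority):
        mask = prim.contains(xg, yg, zg)
        labels[mask] = prim.tissue_id
        contours[prim.name] = mask

    density = np.empty(shape, dtype=np.float32)
    for tid in np.unique(labels):
        density[labels == tid] = compositions[int(tid)].density
    return VoxelPhantom(
        shape=shape, spacing_mm=spacing_mm, labels=labels, density=density,
        compositions=dict(compositions), contours=contours, seed=seed,
    )


def sample_densities(
    phantom: VoxelPhantom,
    rel_sd: float = DENSITY_REL_SD,
    seed: int | None = None,
) -> np.ndarray:
    """Per-voxel densities ~ Normal(rho_tissue, rel_sd * rho_tissue).

    The draw is truncated at +/-3 sigma so that all sampled densities stay
    within the stated 3-sigma band of 1.7% around the tissue mean.
    """
    mean = phantom.mean_density_map().astype(np.float64)
    if rel_sd == 0:
        return mean.astype(np.float32)
    rng = np.random.default_rng(seed)
    draws = truncnorm.rvs(-3.0, 3.0, size=phantom.shape, random_state=rng)
    return (mean * (1.0 + rel_sd * draws)).astype(np.float32)


def _hu_factors(
    phantom: VoxelPhantom,
    spectrum: Spectrum,
    xs: PhotonCrossSectionTable,
    weighting: str = "energy",
) -> dict[int, float]:
    """Per-label mass attenuation relative to water's linear attenuation."""
    mu_w = mean_mu_over_rho(water_composition(), spectrum, xs, weighting)
    return {
        int(tid): mean_mu_over_rho(comp, spectrum, xs, weighting) / mu_w
        for tid, comp in phantom.compositions.items()
    }


def simulate_ct(
    phantom: VoxelPhantom,
    spectrum: Spectrum,
    xs: PhotonCrossSectionTable,
    noise_sd_hu: float = SECT_NOISE_HU,
    seed: int | None = None,
    weighting: str = "energy",
) -> SimulatedImage:
    """Noisy theoretical CT image of the phantom for one spectrum."""
    factors = _hu_factors(phantom, spectrum, xs, weighting)
    factor_map = np.empty(phantom.shape, dtype=np.float64)
    for tid, fac in factors.items():
        factor_map[phantom.labels == tid] = fac
    hu = 1000.0 * (phantom.density * factor_map - 1.0)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=phantom.shape)
    return SimulatedImage(
        hu=(hu.astype(np.float32),),
        spectrum_labels=(spectrum.label,),
        noise_sd_hu=(noise_sd_hu,),
        seed=seed,
    )


def simulate_dect(
    phantom: VoxelPhantom,
    low: Spectrum,
    high: Spectrum,
    xs: PhotonCrossSectionTable,
    noise_sd_hu: tuple[float, float] = DECT_NOISE_HU,
    seed: int | None = None,
    weighting: str = "energy",
) -> SimulatedImage:
    """Noisy dual-energy image pair with independent channel noise."""
    seq = np.random.SeedSequence(seed).spawn(2)
    img_low = simulate_ct(phantom, low, xs, noise_sd_hu[0],
                          seed=int(seq[0].generate_state(1)[0]) % (2**31), weighting=weighting)
    img_high = simulate_ct(phantom, high, xs, noise_sd_hu[1],
                           seed=int(seq[1].generate_state(1)[0]) % (2**31), weighting=weighting)
    return SimulatedImage(
        hu=(img_low.hu[0], img_high.hu[0]),
        spectrum_labels=(low.label, high.label),
        noise_sd_hu=tuple(noise_sd_hu),
        seed=seed,
    )


def assign_tissues_kmeans(
    hu_map: np.ndarray,
    contour_mask: np.ndarray,
    candidates: Sequence[TissueComposition],
    spectrum: Spectrum,
    xs: PhotonCrossSectionTable,
    seed: int | None = None,
    weighting: str = "energy",
) -> np.ndarray:
    """Partition contour voxels among candidate tissues by 1-D k-means.

    Clusters of the contour's CT-number distribution are matched to the
    candidates by the rank order of cluster mean HU versus theoretical
    tissue HU.  Returns an int16 label map over the full grid (0 outside
    the contour).
    """
    if not len(candidates):
        raise ValidationError("need at least one candidate tissue")
    values = hu_map[contour_mask]
    if values.size == 0:
        raise ValidationError("empty contour")
    k = len(candidates)
    if k > np.unique(values).size:
        raise ValidationError(
            f"k={k} exceeds the number of distinct CT values in the contour"
        )
    labels_out = np.zeros(hu_map.shape, dtype=np.int16)
    if k == 1:
        labels_out[contour_mask] = candidates[0].tissue_id
        return labels_out

    from .photon_model import theoretical_hu  # local import to avoid cycle at module load

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(values.reshape(-1, 1))
    cluster_order = np.argsort(km.cluster_centers_.ravel())  # ascending mean HU
    tissue_order = np.argsort([theoretical_hu(c, spectrum, xs, weighting) for c in candidates])
    cluster_to_tissue = {
        int(cluster_order[i]): candidates[int(tissue_order[i])].tissue_id for i in range(k)
    }
    mapped = np.vectorize(cluster_to_tissue.get)(assignments)
    labels_out[contour_mask] = mapped.astype(np.int16)
    return labels_out


def rsp_maps(
    phantom: VoxelPhantom,
    curve: CalibrationCurve,
    dect_model: DECTModel,
    sect_image: SimulatedImage,
    dect_image: SimulatedImage,
    ctx: ProtonBeamContext,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three RSP volumes: reference, SECT-estimated, DECT-estimated.

    The reference map scales each tissue's theoretical RSP linearly with the
    voxel density (RSP is proportional to electron density at fixed
    composition); the SECT map applies the calibration curve to the noisy
    SECT image; the DECT map applies the DECT estimator to the noisy pair.
    """
    if sect_image.hu[0].shape != phantom.shape or dect_image.hu[0].shape != phantom.shape:
        raise ValidationError("image shapes do not match the phantom")
    rsp_per_rho = np.empty(phantom.shape, dtype=np.float64)
    for tid, comp in phantom.compositions.items():
        mask = phantom.labels == tid
        if mask.any():
            rsp_per_rho[mask] = tissue_rsp_ref(comp, ctx) / comp.density
    ref = (rsp_per_rho * phantom.density).astype(np.float32)
    sect = np.asarray(apply_curve(curve, sect_image.hu[0]), dtype=np.float32)
    dect = estimate_rsp_dect(dect_model, dect_image.hu[0], dect_image.hu[1], ctx).rsp
    return ref, sect, dect.astype(np.float32)
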