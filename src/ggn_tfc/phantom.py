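"""Voxel phantom: paired CT-attenuation and tracer-activity volumes.

The phantom realizes the generative model behind the tissue-fraction
correction: a spherical nodule of homogeneous tissue fraction ``k`` in a
lung background.  Inside the (unblurred, noise-free) nodule,

    hu       = k * hu_tissue + (1 - k) * hu_air
    activity = k * tissue_suv

so a VOI measurement followed by :func:`ggn_tfc.correction.correct_suv`
recovers ``tissue_suv`` exactly — the constructive demonstration that the
correction inverts the mixing model.  Optional Gaussian blur of the
activity volume emulates PET resolution (partial-volume loss); optional
additive noise stresses the pipeline stochastically.

Geometry: isotropic voxels, 0-based indices, membership by voxel-center
distance.  Blur applies to activity only (PET resolution; CT resolution is
out of scope here), noise is added after blur and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .correction import CorrectionParams

__all__ = ["PhantomSpec", "Phantom", "VoiMeasurement", "generate_phantom", "measure_voi"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic nodule-in-lung volume.

    All lengths in mm; HU in Hounsfield units; activity dimensionless
    (SUV scale).  ``psf_fwhm = 0`` disables blur, ``noise_sd = 0`` noise.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    nodule_center: Tuple[float, float, float] = (31.5, 31.5, 31.5)
    nodule_radius: float = 10.0
    nodule_tissue_fraction: float = 0.5
    tissue_suv: float = 4.0
    lung_background_hu: float = -850.0
    lung_background_suv: float = 0.4
    psf_fwhm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    params: CorrectionParams = field(default_factory=CorrectionParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.nodule_tissue_fraction <= 1.0:
            raise ValueError("nodule_tissue_fraction must lie in (0, 1]")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be non-negative")
        if self.tissue_suv < 0:
            raise ValueError("tissue_suv must be non-negative")
        r_vox = self.nodule_radius / self.voxel_size
        for c, n in zip(self.nodule_center, self.grid_shape):
            if c - r_vox < -0.5 or c + r_vox > n - 0.5:
                raise ValueError(
                    f"nodule (center {self.nodule_center}, radius {self.nodule_radius} mm) "
                    f"protrudes outside the {self.grid_shape} grid"
                )

    @property
    def nodule_hu(self) -> float:
        """Ground-truth nodule attenuation under the HU mixing model."""
        k = self.nodule_tissue_fraction
        return k * self.params.hu_tissue + (1.0 - k) * self.params.hu_air

    @property
    def nodule_activity(self) -> float:
        """Ground-truth nodule activity: tissue uptake scaled by tissue fraction."""
        return self.nodule_tissue_fraction * self.tissue_suv


@dataclass(frozen=True)
class Phantom:
    """Co-registered attenuation and activity volumes plus their generating spec."""

    hu_volume: np.ndarray
    activity_volume: np.ndarray
    truth: PhantomSpec


@dataclass(frozen=True)
class VoiMeasurement:
    """Statistics over a spherical volume of interest.

    ``suv_max`` is the voxel maximum of activity (PET convention);
    ``hu_mean`` is the voxel mean of attenuation — a mean, not a max,
    matching how a radiologist reports a single ROI HU value.
    """

    suv_max: float
    hu_mean: float
    voxel_count: int


def _sphere_mask(
    shape: Tuple[int, int, int],
    center: Tuple[float, float, float],
    radius_mm: float,
    voxel_size: float,
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 * voxel_size**2 <= radius_mm**2


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom volumes described by ``spec``.

    Deterministic given ``spec.seed``: identical specs produce
    bit-identical volumes.
    """
    mask = _sphere_mask(spec.grid_shape, spec.nodule_center, spec.nodule_radius, spec.voxel_size)
    hu = np.full(spec.grid_shape, spec.lung_background_hu, dtype=np.float64)
    act = np.full(spec.grid_shape, spec.lung_background_suv, dtype=np.float64)
    hu[mask] = spec.nodule_hu
    act[mask] = spec.nodule_activity
    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * _FWHM_TO_SIGMA / spec.voxel_size
        act = ndimage.gaussian_filter(act, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        act = np.clip(act + rng.normal(0.0, spec.noise_sd, size=act.shape), 0.0, None)
    return Phantom(hu_volume=hu, activity_volume=act, truth=spec)


def measure_voi(
    ph: Phantom, center: Tuple[float, float, float], radius: float
) -> VoiMeasurement:
    """Measure SUVmax and mean HU over a sphere of ``radius`` mm at ``center`` (voxel coords)."""
    mask = _sphere_mask(ph.hu_volume.shape, center, radius, ph.truth.voxel_size)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"VOI (center {center}, radius {radius} mm) contains no voxel centers"
        )
    return VoiMeasurement(
        suv_max=float(ph.activity_volume[mask].max()),
        hu_mean=float(ph.hu_volume[mask].mean()),
        voxel_count=n,
    )
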