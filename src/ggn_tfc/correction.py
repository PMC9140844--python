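"""Tissue-fraction correction of SUVmax for pure ground-glass nodules.

A pure ground-glass nodule (GGN) is modelled as a homogeneous mixture of
solid tissue and air.  Its CT attenuation is the linear mixture

    HU_ggn = k * HU_tissue + (1 - k) * HU_air,

where ``k`` is the tissue fraction.  Because FDG does not distribute into
the air compartment, the measured SUVmax underestimates the uptake of the
solid component by the factor ``k``; dividing it out yields the
tissue-fraction-corrected value

    SUVmaxTF = SUVmax / k,      k = (HU_ggn - HU_air) / (HU_tissue - HU_air).

Defaults follow radiology convention: air at -1000 HU, solid soft tissue
(liver-like) at +50 HU, and the conventional 2.5 positivity cutoff applied
inclusively to both the raw and the corrected value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "CorrectionParams",
    "SuvMeasurement",
    "CorrectedSuv",
    "compute_tissue_fraction",
    "correct_suv",
    "classify_positivity",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Constants of the HU mixing model and the positivity cutoff.

    Parameters
    ----------
    hu_tissue : float
        CT attenuation of pure solid tissue, Hounsfield units.
    hu_air : float
        CT attenuation of air, Hounsfield units.
    suv_cutoff : float
        Dimensionless positivity threshold applied inclusively.
    """

    hu_tissue: float = 50.0
    hu_air: float = -1000.0
    suv_cutoff: float = 2.5

    def __post_init__(self) -> None:
        if not self.hu_tissue > self.hu_air:
            raise ValueError(
                f"hu_tissue ({self.hu_tissue}) must exceed hu_air ({self.hu_air})"
            )
        if not self.suv_cutoff > 0:
            raise ValueError(f"suv_cutoff must be positive, got {self.suv_cutoff}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CorrectionParams":
        """Load parameters from a YAML mapping with keys hu_tissue, hu_air, suv_cutoff."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {"hu_tissue", "hu_air", "suv_cutoff"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class SuvMeasurement:
    """A single nodule's raw PET/CT reading: SUVmax plus nodule HU."""

    suv_max: float
    hu_ggn: float

    def __post_init__(self) -> None:
        if self.suv_max < 0:
            raise ValueError(f"suv_max must be non-negative, got {self.suv_max}")


@dataclass(frozen=True)
class CorrectedSuv:
    """Result of the correction: tissue fraction k and SUVmaxTF = SUVmax / k."""

    k: float
    suv_max_tf: float

    @property
    def k_display(self) -> float:
        """Tissue fraction rounded to 2 decimals (display convention)."""
        return round(self.k, 2)

    @property
    def suv_max_tf_display(self) -> float:
        """Corrected SUVmax rounded to 2 decimals (display convention)."""
        return round(self.suv_max_tf, 2)


def compute_tissue_fraction(hu_ggn: float, params: CorrectionParams = CorrectionParams()) -> float:
    """Tissue fraction k of a nodule from its CT attenuation.

    k = (hu_ggn - hu_air) / (hu_tissue - hu_air), clamped to 1 when the
    nodule is at least as dense as solid tissue (with a warning: a GGN
    denser than solid tissue violates the mixing model's premise).

    Raises
    ------
    ValueError
        If ``hu_ggn <= hu_air``: the implied tissue fraction would be
        non-positive and the correction is undefined.
    """
    if hu_ggn <= params.hu_air:
        raise ValueError(
            f"hu_ggn = {hu_ggn} HU is at or below hu_air = {params.hu_air} HU; "
            "tissue fraction would be <= 0 and the correction is undefined"
        )
    k = (hu_ggn - params.hu_air) / (params.hu_tissue - params.hu_air)
    if k > 1.0:
        warnings.warn(
            f"hu_ggn = {hu_ggn} HU exceeds hu_tissue = {params.hu_tissue} HU; "
            "clamping tissue fraction to 1 (no correction applied)",
            stacklevel=2,
        )
        k = 1.0
    return k


def correct_suv(
    m: SuvMeasurement, params: CorrectionParams = CorrectionParams()
) -> CorrectedSuv:
    """Apply the tissue-fraction correction to one measurement."""
    k = compute_tissue_fraction(m.hu_ggn, params)
    return CorrectedSuv(k=k, suv_max_tf=m.suv_max / k)


def classify_positivity(suv: float, params: CorrectionParams = CorrectionParams()) -> bool:
    """True iff ``suv`` meets the (inclusive) positivity cutoff."""
    if suv < 0:
        raise ValueError(f"SUV must be non-negative, got {suv}")
    return suv >= params.suv_cutoff
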