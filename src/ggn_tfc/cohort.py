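"""Synthetic nodule cohorts with the statistical structure of the study groups.

The study cohort is available only as per-group summaries: group sizes,
median (Q1-Q3) of SUVmax, nodule HU and size, and visual positivity rates
for three pathological groups (invasive adenocarcinoma, minimally invasive
adenocarcinoma, adenocarcinoma in situ).  This module turns those summaries
into a generative model:

* SUVmax     — log-normal, median pinned, log-scale set from the IQR
               (positive and right-skewed, the minimal family compatible
               with a median/IQR summary);
* HU, size   — normal matched to median/IQR, truncated to the physically
               admissible range ((-1000, 50) HU; size >= 10 mm, the study's
               inclusion criterion);
* visual read — Bernoulli at the group's positivity rate, drawn
               independently of SUVmax (no joint distribution is reported).

A master seed fans out to one independent stream per group, so appending a
group never perturbs the draws of existing groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "NoduleRecord",
    "GroupCalibration",
    "fit_lognormal_from_quartiles",
    "simulate_cohort",
    "default_calibrations",
    "load_calibrations",
    "records_to_frame",
    "frame_to_records",
    "read_cohort_csv",
    "write_cohort_csv",
    "PATHOLOGY_LABELS",
]

PATHOLOGY_LABELS = ("adenocarcinoma", "MIA", "AIS")

#: z-quantile at 0.75 of the standard normal; IQR = 2 * _Z75 * sigma.
_Z75 = float(sps.norm.ppf(0.75))


@dataclass
class NoduleRecord:
    """One nodule: measurements, labels, and pipeline-filled derived fields."""

    nodule_id: str
    pathology: str
    size_mm: float
    hu_ggn: float
    suv_max: float
    visual_positive: Optional[bool]
    suv_max_tf: Optional[float] = None
    semiquant_positive_before: Optional[bool] = None
    semiquant_positive_after: Optional[bool] = None

    def validate(self, hu_air: float = -1000.0, hu_tissue: float = 50.0) -> None:
        """Raise ValueError naming this nodule if any invariant fails."""
        problems = []
        if not self.size_mm >= 10.0:
            problems.append(f"size_mm = {self.size_mm} < 10 mm (inclusion criterion)")
        if not hu_air < self.hu_ggn < hu_tissue:
            problems.append(f"hu_ggn = {self.hu_ggn} outside ({hu_air}, {hu_tissue})")
        if not self.suv_max > 0:
            problems.append(f"suv_max = {self.suv_max} <= 0")
        if problems:
            raise ValueError(f"nodule {self.nodule_id!r}: " + "; ".join(problems))


@dataclass(frozen=True)
class GroupCalibration:
    """Summary statistics that define one pathological group's generator."""

    pathology: str
    n: int
    suv_median: float
    suv_q1: float
    suv_q3: float
    hu_median: float
    hu_q1: float
    hu_q3: float
    size_median: float
    size_q1: float
    size_q3: float
    visual_rate: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.pathology!r}: n must be >= 1")
        for name in ("suv", "hu", "size"):
            q1 = getattr(self, f"{name}_q1")
            med = getattr(self, f"{name}_median")
            q3 = getattr(self, f"{name}_q3")
            if not q1 <= med <= q3:
                raise ValueError(
                    f"group {self.pathology!r}: {name} quartiles violate q1 <= median <= q3"
                )
        if not 0.0 <= self.visual_rate <= 1.0:
            raise ValueError(f"group {self.pathology!r}: visual_rate outside [0, 1]")


def fit_lognormal_from_quartiles(
    median: float, q1: float, q3: float
) -> Tuple[float, float]:
    """Log-normal (location, scale) pinned at the median with IQR-matched spread.

    location = ln(median); scale = (ln q3 - ln q1) / (2 * z_0.75).  When the
    quartiles are symmetric in log space (q1 * q3 = median**2) the fitted
    law's quartiles equal the inputs exactly; asymmetric IQRs are reconciled
    by the symmetric-in-log fit with the median preserved.
    """
    if min(median, q1, q3) <= 0:
        raise ValueError("median and quartiles must be positive for a log-normal fit")
    if not q1 <= median <= q3:
        raise ValueError("quartiles must satisfy q1 <= median <= q3")
    return math.log(median), (math.log(q3) - math.log(q1)) / (2.0 * _Z75)


def _truncated_normal(
    median: float, q1: float, q3: float, lower: float, upper: float,
    size: int, rng: np.random.Generator,
) -> np.ndarray:
    """Draws from N(median, IQR / (2 z_0.75)) truncated to (lower, upper)."""
    scale = (q3 - q1) / (2.0 * _Z75)
    if scale == 0.0:
        return np.full(size, float(median))
    a, b = (lower - median) / scale, (upper - median) / scale
    return sps.truncnorm.rvs(a, b, loc=median, scale=scale, size=size, random_state=rng)


def simulate_cohort(
    calibrations: Sequence[GroupCalibration],
    seed: int,
    hu_bounds: Tuple[float, float] = (-1000.0, 50.0),
    size_min: float = 10.0,
) -> List[NoduleRecord]:
    """Draw one synthetic cohort; deterministic given ``seed``.

    Per group: ``n`` records with SUVmax from the fitted log-normal, HU and
    size from truncated normals, and the visual read from a Bernoulli at
    the group's rate.
    """
    if len(calibrations) == 0:
        raise ValueError("calibration list is empty")
    streams = np.random.SeedSequence(seed).spawn(len(calibrations))
    records: List[NoduleRecord] = []
    for cal, stream in zip(calibrations, streams):
        rng = np.random.default_rng(stream)
        loc, scale = fit_lognormal_from_quartiles(cal.suv_median, cal.suv_q1, cal.suv_q3)
        suv = np.exp(rng.normal(loc, scale, size=cal.n))
        hu = _truncated_normal(
            cal.hu_median, cal.hu_q1, cal.hu_q3, *hu_bounds, size=cal.n, rng=rng
        )
        size_mm = _truncated_normal(
            cal.size_median, cal.size_q1, cal.size_q3, size_min, np.inf,
            size=cal.n, rng=rng,
        )
        visual = rng.random(cal.n) < cal.visual_rate
        for i in range(cal.n):
            rec = NoduleRecord(
                nodule_id=f"{cal.pathology}-{i + 1:03d}",
                pathology=cal.pathology,
                size_mm=float(size_mm[i]),
                hu_ggn=float(hu[i]),
                suv_max=float(suv[i]),
                visual_positive=bool(visual[i]),
            )
            rec.validate(hu_air=hu_bounds[0], hu_tissue=hu_bounds[1])
            records.append(rec)
    return records


def load_calibrations(path: Union[str, Path]) -> List[GroupCalibration]:
    """Read group calibrations from a YAML file with a top-level ``groups`` list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'groups' list")
    return [GroupCalibration(**g) for g in raw["groups"]]


def default_calibrations() -> List[GroupCalibration]:
    """The packaged calibration mirroring the study's per-group summaries."""
    ref = resources.files("ggn_tfc.data").joinpath("table2_calibration.yaml")
    raw = yaml.safe_load(ref.read_text())
    return [GroupCalibration(**g) for g in raw["groups"]]


_COLUMNS = [f.name for f in fields(NoduleRecord)]


def records_to_frame(records: Sequence[NoduleRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame, one row per nodule."""
    return pd.DataFrame([vars(r) for r in records], columns=_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> List[NoduleRecord]:
    """Parse a cohort table back into records; optional columns may be absent."""
    required = {"nodule_id", "pathology", "size_mm", "hu_ggn", "suv_max", "visual_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        kwargs = {k: row[k] for k in _COLUMNS if k in row}
        for key in ("visual_positive", "semiquant_positive_before", "semiquant_positive_after"):
            if key in kwargs:
                kwargs[key] = _parse_bool(kwargs[key])
        if kwargs.get("suv_max_tf") is not None and pd.isna(kwargs["suv_max_tf"]):
            kwargs["suv_max_tf"] = None
        kwargs["nodule_id"] = str(kwargs["nodule_id"])
        records.append(NoduleRecord(**kwargs))
    return records


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    if text in {"", "nan", "na", "none"}:
        return None
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def write_cohort_csv(records: Sequence[NoduleRecord], path: Union[str, Path]) -> None:
    # %.17g guarantees bit-exact float round trips through the text table
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: Union[str, Path]) -> List[NoduleRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
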