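"""Lesion- and patient-level response logic.

RECIST categorisation from longest diameters, the two imaging
predictors of pathological response (``WI < 0 or size = 0`` and
``size = 0`` alone), the three-group survival stratification used for
distant disease-free survival, and the cohort-table schema that ties
imaging read-outs to pathology (residual cancer burden) and follow-up.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidBaselineError, NotEvaluableError, SchemaError
from .kinetics import CurveClass
from .lesion_image import LesionKinetics

logger = logging.getLogger(__name__)

#: Lesion-size stratification threshold in mm (strict "< 20" vs ">= 20").
SIZE_STRATUM_MM: float = 20.0

RECIST_PR_THRESHOLD: float = 0.30  # >= 30 % diameter decrease
RECIST_PD_THRESHOLD: float = 0.20  # >= 20 % diameter increase


class Timepoint(enum.Enum):
    PRE = "pre"
    MID = "mid"
    POST = "post"


class LesionType(enum.Enum):
    MASS = "mass"
    NME = "nme"  # non-mass enhancement
    MIXED = "mixed"


class RecistCategory(enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class SurvivalGroup(enum.Enum):
    CR_ON_MRI = "cr_on_mri"
    RD_FAST_WASHOUT = "rd_fast_washout"
    RD_OTHER = "rd_other"


class RcbClass(enum.Enum):
    RCB0 = 0
    RCB1 = 1
    RCB2 = 2
    RCB3 = 3


@dataclass(frozen=True)
class TimepointObservation:
    """One lesion at one timepoint.

    ``size_mm = 0`` encodes no enhancing lesion (radiological CR); in
    that case kinetics are absent and the curve class is ``None``.
    Kinetics may also be absent for a residual lesion that was excluded
    from the signal analysis (too small, protocol mismatch); such an
    observation is not evaluable by the kinetic predictors.
    """

    timepoint: Timepoint
    size_mm: float
    kinetics: Optional[LesionKinetics] = None
    wi: Optional[float] = None
    curve_class: Optional[CurveClass] = None

    def __post_init__(self) -> None:
        if self.size_mm < 0:
            raise ValueError(f"size_mm must be >= 0, got {self.size_mm}")
        if self.size_mm == 0 and (self.kinetics or self.curve_class or self.wi):
            raise ValueError("size 0 (no enhancing lesion) cannot carry kinetics")
        if self.kinetics is not None:
            if self.wi is None:
                object.__setattr__(self, "wi", self.kinetics.best_result.wi)
            if self.curve_class is None:
                object.__setattr__(
                    self, "curve_class", self.kinetics.best_result.curve_class
                )


@dataclass
class PatientRecord:
    """Pathology, per-timepoint imaging, and follow-up for one patient."""

    patient_id: str
    lesion_type: Optional[LesionType] = None
    rcb_index: Optional[float] = None
    rcb_class: Optional[RcbClass] = None
    pcr: Optional[bool] = None
    pt_size_mm: Optional[float] = None
    observations: dict[Timepoint, TimepointObservation] = field(default_factory=dict)
    ddfs_time_years: Optional[float] = None
    ddfs_event: Optional[bool] = None


def recist_category(baseline_size: float, followup_size: float) -> RecistCategory:
    """RECIST category from baseline and follow-up longest diameters (mm).

    CR when no enhancing lesion remains (follow-up size 0); PD on an
    increase of at least 20 %; PR on a decrease of at least 30 %; SD
    otherwise.  Both percentage thresholds are inclusive, and PD takes
    precedence over PR for determinism.
    """
    if baseline_size <= 0:
        raise InvalidBaselineError(
            f"baseline size must be > 0 mm, got {baseline_size}"
        )
    if followup_size == 0:
        return RecistCategory.CR
    change = (followup_size - baseline_size) / baseline_size
    if change >= RECIST_PD_THRESHOLD:
        return RecistCategory.PD
    if -change >= RECIST_PR_THRESHOLD:
        return RecistCategory.PR
    return RecistCategory.SD


def _wi_of(obs: TimepointObservation) -> float:
    if obs.wi is None:
        raise NotEvaluableError(
            "residual lesion without measured WI cannot be scored "
            "(excluded from the kinetic analysis)"
        )
    return obs.wi


def predict_pathresponse(obs: TimepointObservation) -> bool:
    """Kinetic predictor of pathological response: WI < 0 or size = 0.

    A negative washout index means the lesion shows no washout at all
    in the delayed phase; together with lesion disappearance it is the
    imaging criterion predicting pCR (and minimal residual disease).
    The WI comparison is strict: WI = 0 predicts residual disease.
    """
    if obs.size_mm == 0:
        return True
    return _wi_of(obs) < 0


def predict_by_size(obs: TimepointObservation) -> bool:
    """Size-only predictor: TRUE iff no enhancing lesion (size 0)."""
    return obs.size_mm == 0


def survival_group(obs: TimepointObservation) -> SurvivalGroup:
    """Three-group DDFS stratification at one timepoint.

    CR on MRI (no enhancing lesion), residual disease with a
    fast-washout curve, or residual disease with any other curve type.
    """
    if obs.size_mm == 0:
        return SurvivalGroup.CR_ON_MRI
    if obs.curve_class is None:
        raise NotEvaluableError(
            "residual lesion without curve class cannot be assigned a group"
        )
    if obs.curve_class is CurveClass.FAST_WASHOUT:
        return SurvivalGroup.RD_FAST_WASHOUT
    return SurvivalGroup.RD_OTHER


def size_stratum(size_mm: float, threshold: float = SIZE_STRATUM_MM) -> str:
    """Lesion-size stratum label: ``"<20"`` or ``">=20"`` (strict cut)."""
    return "<20" if size_mm < threshold else ">=20"


# ---------------------------------------------------------------------------
# Cohort tables

COHORT_COLUMNS = [
    "patient_id",
    "lesion_type",
    "rcb_index",
    "rcb_class",
    "pcr",
    "pt_mm",
    "size_pre",
    "size_mid",
    "size_post",
    "wi_pre",
    "wi_mid",
    "wi_post",
    "curve_pre",
    "curve_mid",
    "curve_post",
    "ddfs_years",
    "ddfs_event",
]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table (CSV, UTF-8, header row; empty field = missing).

    Raises :class:`SchemaError` listing any missing required columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def observation_from_row(row, timepoint: Timepoint) -> Optional[TimepointObservation]:
    """Build a TimepointObservation from one cohort-table row.

    Returns None when the size itself is missing (timepoint not
    imaged / excluded); missing WI with a residual lesion yields an
    observation that kinetic predictors will flag as not evaluable.
    """
    tp = timepoint.value
    size = row.get(f"size_{tp}")
    if size is None or (isinstance(size, float) and np.isnan(size)):
        return None
    size = float(size)
    if size == 0:
        return TimepointObservation(timepoint=timepoint, size_mm=0.0)
    wi = row.get(f"wi_{tp}")
    wi = None if wi is None or (isinstance(wi, float) and np.isnan(wi)) else float(wi)
    curve = row.get(f"curve_{tp}")
    if isinstance(curve, str) and curve:
        curve_class = CurveClass(curve)
    else:
        curve_class = None
    return TimepointObservation(
        timepoint=timepoint, size_mm=size, wi=wi, curve_class=curve_class
    )
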