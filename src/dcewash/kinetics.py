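"""Washout-index kinetics of a single ROI.

Three-phase dynamic contrast-enhanced MRI samples a lesion once before
contrast injection (``si_pre``), once in the early phase at 1-2 min
(``si_early``) and once in the delayed phase at 5-6 min (``si_delay``).
Two semi-quantitative descriptors summarise the time-signal-intensity
curve of an ROI:

* initial enhancement ratio  ``SI_early / SI_pre * 100``  (percent)
* washout index (WI)  ``(SI_early - SI_delay) / SI_pre * 100``  (percent)

A positive WI means the signal drops between the early and delayed
phases (washout); a negative WI means persistent enhancement.  An ROI
with enhancement ratio strictly above 200 % and WI of at least 10 % is
a *fast-washout* curve type, the kinetic pattern classically associated
with malignancy; every other combination is *other*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InvalidSampleError

#: Enhancement-ratio threshold (percent) of the fast-washout rule; the
#: rule requires the ratio to exceed this value strictly.
ENHANCEMENT_RATIO_THRESHOLD: float = 200.0

#: Washout-index threshold (percent) of the fast-washout rule; the rule
#: requires WI >= this value (inclusive).
WASHOUT_INDEX_THRESHOLD: float = 10.0


class CurveClass(enum.Enum):
    """Binary time-signal-intensity curve taxonomy."""

    FAST_WASHOUT = "fast_washout"
    OTHER = "other"


@dataclass(frozen=True)
class KineticSample:
    """Mean ROI signal intensity at the three DCE phases (arbitrary units)."""

    si_pre: float
    si_early: float
    si_delay: float

    def validate(self) -> None:
        if not self.si_pre > 0:
            raise InvalidSampleError(
                f"si_pre must be > 0 (got {self.si_pre}); the pre-contrast "
                "signal is the denominator of both kinetic indices"
            )
        if self.si_early < 0 or self.si_delay < 0:
            raise InvalidSampleError(
                "post-contrast signal intensities must be non-negative "
                f"(got si_early={self.si_early}, si_delay={self.si_delay})"
            )


@dataclass(frozen=True)
class KineticResult:
    """Kinetic descriptors of one ROI, all in percent."""

    wi: float
    enhancement_ratio: float
    curve_class: CurveClass


def washout_index(sample: KineticSample) -> float:
    """Washout index (SI_early - SI_delay) / SI_pre * 100, in percent.

    Negative values are legal and indicate persistent enhancement.

    Raises
    ------
    InvalidSampleError
        If ``si_pre <= 0`` (unusable pre-contrast signal).
    """
    sample.validate()
    return (sample.si_early - sample.si_delay) / sample.si_pre * 100.0


def enhancement_ratio(sample: KineticSample) -> float:
    """Initial enhancement ratio SI_early / SI_pre * 100, in percent."""
    sample.validate()
    return sample.si_early / sample.si_pre * 100.0


def classify_curve(
    sample: KineticSample,
    *,
    ratio_threshold: float = ENHANCEMENT_RATIO_THRESHOLD,
    wi_threshold: float = WASHOUT_INDEX_THRESHOLD,
) -> KineticResult:
    """Classify the ROI curve as fast-washout or other.

    Fast-washout requires the enhancement ratio to be strictly above
    ``ratio_threshold`` AND the washout index to be at least
    ``wi_threshold``; any other combination (including a ratio exactly
    at the threshold) is OTHER.  The thresholds default to the 200 % /
    10 % rule and are exposed for sensitivity analyses.
    """
    wi = washout_index(sample)
    ratio = enhancement_ratio(sample)
    fast = ratio > ratio_threshold and wi >= wi_threshold
    return KineticResult(
        wi=wi,
        enhancement_ratio=ratio,
        curve_class=CurveClass.FAST_WASHOUT if fast else CurveClass.OTHER,
    )
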