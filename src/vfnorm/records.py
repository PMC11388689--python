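"""Shared domain records: subjects and single-eye visual-field tests.

A :class:`VFTestRecord` holds one eye's thresholds for one administration of a
test pattern, in the pattern's point order (see :mod:`vfnorm.patterns`).
Thresholds are perimetric decibels of stimulus attenuation: higher = more
sensitive, clipped to the instrument range [0, 40] dB.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "PatternId",
    "Eye",
    "Sex",
    "Race",
    "Ethnicity",
    "ExclusionReason",
    "SubjectProfile",
    "VFTestRecord",
    "DB_FLOOR",
    "DB_CEIL",
]

DB_FLOOR = 0.0
DB_CEIL = 40.0


class PatternId(str, enum.Enum):
    """Supported static-perimetry test grids."""

    P24_2 = "24-2"
    P10_2 = "10-2"


class Eye(str, enum.Enum):
    OD = "OD"  # right
    OS = "OS"  # left


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    WHITE = "white"
    BLACK = "black"
    ASIAN = "asian"
    NATIVE_AMERICAN = "native_american"
    PACIFIC_ISLANDER = "pacific_islander"
    MULTIPLE = "multiple"
    OTHER = "other"


class Ethnicity(str, enum.Enum):
    HISPANIC = "hispanic"
    NOT_HISPANIC = "not_hispanic"


class ExclusionReason(str, enum.Enum):
    """Reasons a screened subject is dropped from the reference cohort."""

    OCULAR_CONDITION = "ocular_condition"
    RE_OUTSIDE_RANGE = "re_outside_range"
    EYE_NOT_ELIGIBLE_COMMITTEE = "eye_not_eligible_committee"
    INCOMPLETE = "incomplete"
    INTOLERANT_IMAGING = "intolerant_imaging"
    IOP_GE_22 = "iop_ge_22"
    UNRELIABLE = "unreliable"  # three failed reliability attempts
    NONE = "none"


@dataclass
class SubjectProfile:
    """Demographics plus the clinical fields eligibility screening reads.

    Per-eye fields are (OD, OS) pairs. ``exclusion_reason`` is
    :attr:`ExclusionReason.NONE` for subjects intended for inclusion.
    """

    subject_id: str
    age: int
    sex: Sex
    race: Race
    ethnicity: Ethnicity
    va_logmar: Optional[float] = None
    iop_mmhg: Optional[tuple[float, float]] = None
    se_diopters: Optional[tuple[float, float]] = None
    cyl_diopters: Optional[tuple[float, float]] = None
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    binocular_capable: bool = True


@dataclass
class VFTestRecord:
    """One eye's thresholds for one administration of a test pattern.

    ``values`` is in the pattern's point order *as enumerated in that eye's
    own field coordinates* (left-eye grids are the mirror image of the
    canonical right-eye grid); :func:`vfnorm.patterns.mirror_to_canonical`
    re-indexes a left-eye record onto the canonical frame.
    """

    subject_id: str
    eye: Eye
    pattern_id: PatternId
    values: list[float]
    foveal_db: float
    fl_rate: float  # fixation losses
    fp_rate: float  # false positives
    fn_rate: float  # false negatives
    duration_min: float
    attempt: int = 1
    is_practice: bool = False

    def copy_with(self, **kw) -> "VFTestRecord":
        return replace(self, **kw)
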