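"""Eligibility screening, reliability gating, study-eye selection, exclusions.

Boundary semantics follow the enrollment protocol with every printed bound
inclusive: age >= 22 passes at 22; acuity "20/40 or better" passes at
logMAR 0.3; pressure "<= 21 mmHg" passes at 21; refraction "exceeding
+/-6 D" (spherical equivalent) and "exceeding +/-2.5 D" (cylinder) fail only
strictly beyond the bound. The reliability gate is the strict ">25%" rule on
fixation losses, false positives and false negatives, so 0.25 passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import MissingDataError
from .records import ExclusionReason, Eye, SubjectProfile, VFTestRecord

__all__ = [
    "AGE_MIN",
    "VA_LOGMAR_MAX",
    "IOP_MAX",
    "SE_MAX_ABS",
    "CYL_MAX_ABS",
    "RELIABILITY_MAX_RATE",
    "ExclusionTally",
    "check_eligibility",
    "check_reliability",
    "retest_until_reliable",
    "select_study_eye",
    "apply_exclusions",
]

AGE_MIN = 22
VA_LOGMAR_MAX = 0.3  # 20/40
IOP_MAX = 21.0
SE_MAX_ABS = 6.0
CYL_MAX_ABS = 2.5
RELIABILITY_MAX_RATE = 0.25


@dataclass
class ExclusionTally:
    """Bookkeeping for the enrollment screen; counts are conserved."""

    n_enrolled: int = 0
    n_included: int = 0
    counts: dict = field(default_factory=dict)  # ExclusionReason -> int

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def check(self) -> None:
        assert self.n_enrolled == self.n_included + self.n_excluded


def _require(subject: SubjectProfile, name: str):
    value = getattr(subject, name)
    if value is None:
        raise MissingDataError(
            f"subject {subject.subject_id}: eligibility field {name!r} missing"
        )
    return value


def check_eligibility(subject: SubjectProfile) -> tuple[bool, list[str]]:
    """Apply the enrollment rules; returns (pass, violated-rule names).

    Raises :class:`MissingDataError` if any required field is absent —
    eligibility is never passed silently on missing data.
    """
    reasons: list[str] = []
    if _require(subject, "age") < AGE_MIN:
        reasons.append("age")
    if _require(subject, "va_logmar") > VA_LOGMAR_MAX:
        reasons.append("visual_acuity")
    if any(v > IOP_MAX for v in _require(subject, "iop_mmhg")):
        reasons.append("iop")
    if any(abs(v) > SE_MAX_ABS for v in _require(subject, "se_diopters")):
        reasons.append("refraction")
    if any(abs(v) > CYL_MAX_ABS for v in _require(subject, "cyl_diopters")):
        reasons.append("cylinder")
    return (not reasons, reasons)


def check_reliability(test: VFTestRecord) -> bool:
    """True unless any catch-trial rate strictly exceeds 25%."""
    return max(test.fl_rate, test.fp_rate, test.fn_rate) <= RELIABILITY_MAX_RATE


def retest_until_reliable(
    subject: SubjectProfile,
    truth,
    rng: np.random.Generator,
    max_attempts: int = 3,
    simulate_fn: Optional[Callable[..., VFTestRecord]] = None,
    config=None,
    g_std: Optional[float] = None,
) -> tuple[list[VFTestRecord], int, bool]:
    """Acquire a reliable binocular study test, re-running up to ``max_attempts``.

    Both eyes are re-acquired together when either fails (binocular
    acquisition). Returns ``(tests, attempts, reliable)`` where ``tests`` is
    the final [OD, OS] pair; ``reliable`` is False if every attempt failed,
    in which case the subject would be excluded from the reference database.

    ``simulate_fn(subject, truth, eye, rng, ...)`` defaults to
    :func:`vfnorm.cohort.simulate_test`; in live use it would request a new
    acquisition instead.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if simulate_fn is None:
        from .cohort import simulate_test as simulate_fn  # avoid import cycle
    if g_std is None:
        g_std = float(rng.standard_normal())
    attempt = 0
    while True:
        attempt += 1
        pair = [
            simulate_fn(subject, truth, eye, rng, config=config, g_std=g_std,
                        attempt=attempt)
            for eye in (Eye.OD, Eye.OS)
        ]
        if all(check_reliability(t) for t in pair):
            return pair, attempt, True
        if attempt >= max_attempts:
            return pair, attempt, False


def select_study_eye(subject: SubjectProfile, rng: np.random.Generator,
                     tested_eyes: tuple[Eye, ...] = (Eye.OD, Eye.OS)) -> Eye:
    """Randomly choose the single eye whose tests enter the reference database.

    A fair coin when both eyes were tested; deterministic when only one was.
    """
    if len(tested_eyes) == 1:
        return tested_eyes[0]
    return Eye.OD if rng.random() < 0.5 else Eye.OS


def apply_exclusions(subjects: list[SubjectProfile]) -> tuple[list[SubjectProfile], ExclusionTally]:
    """Drop flagged subjects and tally them per reason; counts conserved."""
    tally = ExclusionTally(n_enrolled=len(subjects))
    included = []
    for s in subjects:
        if s.exclusion_reason is ExclusionReason.NONE:
            included.append(s)
        else:
            tally.counts[s.exclusion_reason] = tally.counts.get(s.exclusion_reason, 0) + 1
    tally.n_included = len(included)
    tally.check()
    return included, tally
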