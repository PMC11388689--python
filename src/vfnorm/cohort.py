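"""Synthetic normative cohorts for the perimetric reference-database pipeline.

The generator emulates a healthy-eye reference cohort: an age-declining hill
of vision with eccentricity-dependent, left-skewed pointwise noise, a
subject-level "general height" offset shared across points and eyes, foveal
thresholds, reliability indices, and the enrollment/exclusion structure of a
multi-site screening study. Default parameters are calibrated once, in closed
form or by a single scalar root-find, so that the generated cohorts reproduce
the summary statistics the pipeline is meant to recover:

* 356 included subjects in 7 age bins (59/51/56/52/62/53/23), ages uniform
  within bins, cohort mean age ~52 years;
* mean sensitivity 29.1 (SD 1.3) dB on 24-2 and 32.4 (SD 1.0) dB on 10-2;
* foveal thresholds 34.1 (4.3) and 34.0 (4.7) dB;
* mean pointwise age decline 0.06 dB/yr (24-2) and 0.05 dB/yr (10-2), with
  across-point SD 0.01 dB/yr and a 24-2 maximum of 2.5 dB over 30 years;
* 376 enrolled, 20 excluded for six tabulated reasons, 15 included subjects
  capable only of monocular testing.

True thresholds are simulated directly; the generator does not model the
thresholding staircase, stimulus timing, or catch-trial mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError
from .patterns import TestPattern, build_pattern
from .records import (
    DB_CEIL,
    DB_FLOOR,
    Ethnicity,
    ExclusionReason,
    Eye,
    PatternId,
    Race,
    Sex,
    SubjectProfile,
    VFTestRecord,
)

__all__ = [
    "AGE_BINS",
    "DEFAULT_AGE_BIN_COUNTS",
    "NormTruth",
    "CohortConfig",
    "Cohort",
    "age_mixture_moments",
    "default_truth",
    "default_config",
    "sample_demographics",
    "true_threshold",
    "simulate_test",
    "simulate_cohort",
    "skew_noise",
]

# Age bins of the reference design: [lo, hi] inclusive, integer years.
AGE_BINS: tuple[tuple[int, int], ...] = (
    (22, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 89),
)
DEFAULT_AGE_BIN_COUNTS: tuple[int, ...] = (59, 51, 56, 52, 62, 53, 23)

DEFAULT_SEX_P = {Sex.MALE: 157 / 356, Sex.FEMALE: 199 / 356}
DEFAULT_RACE_P = {
    Race.WHITE: 240 / 356,
    Race.BLACK: 48 / 356,
    Race.ASIAN: 31 / 356,
    Race.NATIVE_AMERICAN: 1 / 356,
    Race.PACIFIC_ISLANDER: 3 / 356,
    Race.MULTIPLE: 17 / 356,
    Race.OTHER: 16 / 356,
}
DEFAULT_ETHNICITY_P = {Ethnicity.HISPANIC: 52 / 356, Ethnicity.NOT_HISPANIC: 304 / 356}

# Tabulated exclusion structure of the enrollment screen (counts sum to 20).
DEFAULT_EXCLUDED_BY_REASON = {
    ExclusionReason.OCULAR_CONDITION: 6,
    ExclusionReason.RE_OUTSIDE_RANGE: 3,
    ExclusionReason.EYE_NOT_ELIGIBLE_COMMITTEE: 4,
    ExclusionReason.INCOMPLETE: 5,
    ExclusionReason.INTOLERANT_IMAGING: 1,
    ExclusionReason.IOP_GE_22: 1,
}

REFERENCE_AGE = 52.3  # years; cohort mean, so base maps read as mean surfaces

# Per-pattern calibration targets (mean sensitivity dB, SD dB, foveal dB, etc.)
_TARGETS = {
    PatternId.P24_2: dict(
        ms_mean=29.1, ms_sd=1.3, slope_mean=0.06, slope_sd=0.01,
        slope_max=2.5 / 30.0, foveal_mean=34.1, foveal_sd_total=4.3,
        base_gradient=0.20, sigma_gradient=0.05, gh_sd=0.60, gamma=0.5,
        hemifield=+0.1, duration=(3.18, 0.38),
    ),
    PatternId.P10_2: dict(
        ms_mean=32.4, ms_sd=1.0, slope_mean=0.05, slope_sd=0.01,
        slope_max=None, foveal_mean=34.0, foveal_sd_total=4.7,
        base_gradient=0.15, sigma_gradient=0.03, gh_sd=0.33, gamma=0.3,
        hemifield=+0.1, duration=(3.58, 0.43),
    ),
}


@dataclass(frozen=True)
class NormTruth:
    """Ground-truth surfaces behind a simulated pattern.

    The noiseless threshold of a subject aged ``a`` at point ``p`` is
    ``base_map[p] - slope_map[p] * (a - reference_age)``; ``slope_map`` is the
    *decline*, positive. ``sigma_map`` is the pointwise noise SD,
    non-decreasing in eccentricity; ``skew_shape`` (gamma, in [0, 1)) blends a
    reflected-exponential component into the noise to give sensitivity losses
    a heavier tail than gains. ``gh_sd`` is the SD of the subject-level
    general-height offset shared across points and eyes.
    """

    pattern_id: PatternId
    base_map: tuple[float, ...]
    slope_map: tuple[float, ...]
    sigma_map: tuple[float, ...]
    skew_shape: float
    gh_sd: float
    reference_age: float
    foveal_base: float
    foveal_slope: float
    foveal_sd: float
    duration_mean: float
    duration_sd: float

    @property
    def n_points(self) -> int:
        return len(self.base_map)


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic study, reproducibly."""

    seed: int = 0
    age_bin_counts: tuple[int, ...] = DEFAULT_AGE_BIN_COUNTS
    sex_p: dict = field(default_factory=lambda: dict(DEFAULT_SEX_P))
    race_p: dict = field(default_factory=lambda: dict(DEFAULT_RACE_P))
    ethnicity_p: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_P))
    truths: dict = field(default_factory=dict)  # PatternId -> NormTruth
    n_excluded_by_reason: dict = field(
        default_factory=lambda: dict(DEFAULT_EXCLUDED_BY_REASON)
    )
    monocular_only_count: int = 15
    reliability_fail_prob: float = 0.0
    # mean catch-trial rates on the reliable side of the 25% gate
    fl_mean: float = 0.06
    fp_mean: float = 0.02
    fn_mean: float = 0.02

    def __post_init__(self):
        if len(self.age_bin_counts) != len(AGE_BINS):
            raise ConfigError("age_bin_counts must have 7 entries")
        if any(c < 0 for c in self.age_bin_counts):
            raise ConfigError("age bin counts must be non-negative")
        if any(c < 0 for c in self.n_excluded_by_reason.values()):
            raise ConfigError("exclusion counts must be non-negative")
        if not 0.0 <= self.reliability_fail_prob <= 1.0:
            raise ConfigError("reliability_fail_prob must be in [0, 1]")
        if not self.truths:
            self.truths = {pid: default_truth(pid) for pid in PatternId}

    @property
    def n_included(self) -> int:
        return int(sum(self.age_bin_counts))


@dataclass
class Cohort:
    """A generated study: subject profiles plus per-eye test records."""

    subjects: list[SubjectProfile]
    tests: list[VFTestRecord]
    config: CohortConfig

    def included_subjects(self) -> list[SubjectProfile]:
        return [s for s in self.subjects if s.exclusion_reason is ExclusionReason.NONE]

    def tests_for(
        self,
        pattern_id: PatternId,
        eye: Optional[Eye] = None,
        include_practice: bool = False,
    ) -> list[VFTestRecord]:
        return [
            t
            for t in self.tests
            if t.pattern_id is pattern_id
            and (include_practice or not t.is_practice)
            and (eye is None or t.eye is eye)
        ]


def age_mixture_moments(
    counts: Sequence[int] = DEFAULT_AGE_BIN_COUNTS,
) -> tuple[float, float]:
    """Exact mean and SD of age under the binned design: integer ages uniform
    within each bin, bin weights proportional to the fixed counts."""
    counts = np.asarray(counts, float)
    w = counts / counts.sum()
    m1 = m2 = 0.0
    for wi, (lo, hi) in zip(w, AGE_BINS):
        width = hi - lo + 1
        mean = (lo + hi) / 2.0
        var = (width * width - 1) / 12.0
        m1 += wi * mean
        m2 += wi * (var + mean * mean)
    return m1, math.sqrt(m2 - m1 * m1)


def _hemifield_sign(pattern: TestPattern) -> np.ndarray:
    return np.array([1.0 if p.y > 0 else 0.0 for p in pattern.points])


def _build_slope_map(pattern: TestPattern, tgt: dict) -> np.ndarray:
    """Decline map: smooth in eccentricity with a hemifield offset, rescaled
    exactly to the target across-point mean and SD over analyzed points, and
    (24-2 only) with its maximum pinned to the target maximum decline."""
    ecc = np.array(pattern.eccentricities())
    hemi = _hemifield_sign(pattern)
    an = np.array(pattern.analyzed_indices)
    h = tgt["hemifield"]

    def standardized(q: float) -> np.ndarray:
        r = (ecc / ecc.max()) ** q + h * hemi
        mu, sd = r[an].mean(), r[an].std(ddof=0)
        return (r - mu) / sd

    if tgt["slope_max"] is not None:
        want = (tgt["slope_max"] - tgt["slope_mean"]) / tgt["slope_sd"]
        q = brentq(
            lambda q: standardized(q)[an].max() - want, 0.8, 4.0, xtol=1e-14
        )
    else:
        q = 1.0
    z = standardized(q)
    return tgt["slope_mean"] + tgt["slope_sd"] * z


def _predicted_ms_sd(
    sigma0: float, tgt: dict, ecc_analyzed: np.ndarray, age_sd: float
) -> float:
    """Analytic between-subject SD of mean sensitivity: independent age,
    general-height, and averaged pointwise-noise contributions."""
    sigma = sigma0 + tgt["sigma_gradient"] * ecc_analyzed
    n = ecc_analyzed.size
    var = (
        (tgt["slope_mean"] * age_sd) ** 2
        + tgt["gh_sd"] ** 2
        + float(np.mean(sigma**2)) / n
    )
    return math.sqrt(var)


@lru_cache(maxsize=None)
def default_truth(pattern_id: PatternId) -> NormTruth:
    """Default calibrated ground truth for a pattern.

    The base map is affine in eccentricity with its analyzed-point mean pinned
    to the target mean sensitivity. The pointwise noise SD is affine in
    eccentricity; its intercept is solved (one scalar root-find) so the
    analytic between-subject SD of mean sensitivity matches the target given
    the configured general-height SD. The foveal noise SD is solved in closed
    form from the target total foveal SD.
    """
    pid = PatternId(pattern_id)
    tgt = _TARGETS[pid]
    pattern = build_pattern(pid)
    ecc = np.array(pattern.eccentricities())
    an = np.array(pattern.analyzed_indices)

    base = -tgt["base_gradient"] * ecc
    base = base + (tgt["ms_mean"] - base[an].mean())

    slope = _build_slope_map(pattern, tgt)

    _, age_sd = age_mixture_moments()
    sigma0 = brentq(
        lambda s0: _predicted_ms_sd(s0, tgt, ecc[an], age_sd) - tgt["ms_sd"],
        1e-3,
        10.0,
        xtol=1e-13,
    )
    sigma = sigma0 + tgt["sigma_gradient"] * ecc

    fov_var = (
        tgt["foveal_sd_total"] ** 2
        - (tgt["slope_mean"] * age_sd) ** 2
        - tgt["gh_sd"] ** 2
    )
    if fov_var <= 0:
        raise ConfigError("foveal SD target incompatible with cohort structure")

    return NormTruth(
        pattern_id=pid,
        base_map=tuple(base),
        slope_map=tuple(slope),
        sigma_map=tuple(sigma),
        skew_shape=tgt["gamma"],
        gh_sd=tgt["gh_sd"],
        reference_age=REFERENCE_AGE,
        foveal_base=tgt["foveal_mean"],
        foveal_slope=tgt["slope_mean"],
        foveal_sd=math.sqrt(fov_var),
        duration_mean=tgt["duration"][0],
        duration_sd=tgt["duration"][1],
    )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The shipped default study configuration (356 included, 376 enrolled)."""
    return CohortConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# sampling


def _draw_categorical(rng: np.random.Generator, probs: dict):
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _eligible_fields(rng: np.random.Generator) -> dict:
    """Clinical fields drawn inside the eligible ranges."""
    return dict(
        va_logmar=round(float(rng.uniform(-0.1, 0.3)), 3),
        iop_mmhg=(round(float(rng.uniform(10, 21)), 1), round(float(rng.uniform(10, 21)), 1)),
        se_diopters=(round(float(rng.uniform(-6, 6)), 2), round(float(rng.uniform(-6, 6)), 2)),
        cyl_diopters=(round(float(rng.uniform(-2.5, 2.5)), 2), round(float(rng.uniform(-2.5, 2.5)), 2)),
    )


def sample_demographics(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectProfile]:
    """Sample the included cohort's subject profiles.

    Ages are integer, uniform within each design bin; sex, race and ethnicity
    are drawn from the configured proportions; clinical fields are drawn
    inside the eligible ranges.
    """
    subjects: list[SubjectProfile] = []
    i = 0
    for count, (lo, hi) in zip(config.age_bin_counts, AGE_BINS):
        for _ in range(int(count)):
            i += 1
            subjects.append(
                SubjectProfile(
                    subject_id=f"S{i:04d}",
                    age=int(rng.integers(lo, hi + 1)),
                    sex=_draw_categorical(rng, config.sex_p),
                    race=_draw_categorical(rng, config.race_p),
                    ethnicity=_draw_categorical(rng, config.ethnicity_p),
                    **_eligible_fields(rng),
                )
            )
    return subjects


def true_threshold(truth: NormTruth, point_index: int, age: float) -> float:
    """Noiseless threshold at a point for a given age (dB)."""
    return truth.base_map[point_index] - truth.slope_map[point_index] * (
        age - truth.reference_age
    )


def skew_noise(rng: np.random.Generator, gamma: float, size=None) -> np.ndarray:
    """Unit-variance, zero-mean noise with a heavier lower tail for gamma > 0.

    ``(1 - gamma) * Z - gamma * (G - 1)`` with Z standard normal and G unit
    exponential, rescaled to unit variance. gamma = 0 is exactly Gaussian.
    """
    z = rng.standard_normal(size)
    g = rng.standard_gamma(1.0, size)
    raw = (1.0 - gamma) * z - gamma * (g - 1.0)
    return raw / math.sqrt((1.0 - gamma) ** 2 + gamma**2)


def _draw_rates(config: CohortConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    """Catch-trial failure rates. Reliable draws live strictly below the 25%
    gate (scaled Beta); with probability ``reliability_fail_prob`` one index
    is pushed above it."""
    out = []
    for mean in (config.fl_mean, config.fp_mean, config.fn_mean):
        frac = min(mean / 0.25, 0.95)
        a = 1.2
        b = a * (1.0 - frac) / frac
        out.append(0.25 * float(rng.beta(a, b)))
    if config.reliability_fail_prob > 0 and rng.random() < config.reliability_fail_prob:
        which = int(rng.integers(0, 3))
        out[which] = 0.25 + 0.75 * float(rng.beta(2, 8))
    return tuple(round(v, 4) for v in out)


def simulate_test(
    subject: SubjectProfile,
    truth: NormTruth,
    eye: Eye,
    rng: np.random.Generator,
    config: Optional[CohortConfig] = None,
    g_std: Optional[float] = None,
    is_practice: bool = False,
    attempt: int = 1,
) -> VFTestRecord:
    """Simulate one eye's test of one pattern.

    ``g_std`` is the subject's standard-normal general-height draw; pass the
    same value for every test of a subject so the offset ``g_std * gh_sd`` is
    shared across points, eyes and patterns. Values are listed in the eye's
    own enumeration order (left-eye grids mirrored), truth being left-right
    anatomically aligned, and clipped to the instrument range.
    """
    if config is None:
        config = default_config()
    pattern = build_pattern(truth.pattern_id)
    if g_std is None:
        g_std = float(rng.standard_normal())
    g = g_std * truth.gh_sd
    base = np.array(
        [true_threshold(truth, j, subject.age) for j in range(pattern.n_points)]
    )
    sigma = np.array(truth.sigma_map)
    if eye is Eye.OS:
        perm = np.array(pattern.mirror_permutation())
        base, sigma = base[perm], sigma[perm]
    eps = sigma * skew_noise(rng, truth.skew_shape, pattern.n_points)
    values = np.clip(base + g + eps, DB_FLOOR, DB_CEIL)
    foveal = float(
        np.clip(
            truth.foveal_base
            - truth.foveal_slope * (subject.age - truth.reference_age)
            + g
            + truth.foveal_sd * skew_noise(rng, truth.skew_shape),
            DB_FLOOR,
            DB_CEIL,
        )
    )
    fl, fp, fn = _draw_rates(config, rng)
    duration = max(
        0.5, float(rng.normal(truth.duration_mean, truth.duration_sd))
    )
    return VFTestRecord(
        subject_id=subject.subject_id,
        eye=eye,
        pattern_id=truth.pattern_id,
        values=[float(v) for v in values],
        foveal_db=foveal,
        fl_rate=fl,
        fp_rate=fp,
        fn_rate=fn,
        duration_min=round(duration, 2),
        attempt=attempt,
        is_practice=is_practice,
    )


def _excluded_profiles(
    config: CohortConfig, rng: np.random.Generator, start_index: int
) -> list[SubjectProfile]:
    """Enrolled-but-excluded subjects. Fields are made consistent with the
    reason where the reason is a measurable one (refraction, pressure)."""
    out = []
    i = start_index
    for reason, count in config.n_excluded_by_reason.items():
        for _ in range(int(count)):
            i += 1
            lo, hi = AGE_BINS[int(rng.integers(0, len(AGE_BINS)))]
            fields = _eligible_fields(rng)
            if reason is ExclusionReason.RE_OUTSIDE_RANGE:
                fields["se_diopters"] = (round(float(rng.uniform(6.25, 10)), 2),
                                         fields["se_diopters"][1])
            elif reason is ExclusionReason.IOP_GE_22:
                fields["iop_mmhg"] = (round(float(rng.uniform(22, 30)), 1),
                                      fields["iop_mmhg"][1])
            out.append(
                SubjectProfile(
                    subject_id=f"X{i:04d}",
                    age=int(rng.integers(lo, hi + 1)),
                    sex=_draw_categorical(rng, config.sex_p),
                    race=_draw_categorical(rng, config.race_p),
                    ethnicity=_draw_categorical(rng, config.ethnicity_p),
                    exclusion_reason=reason,
                    **fields,
                )
            )
    return out


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    patterns: Optional[Sequence[PatternId]] = None,
    include_practice: bool = True,
) -> Cohort:
    """Generate a full synthetic study, deterministically under the config seed.

    Each included subject receives, per pattern, a practice and a study test
    of both eyes (the per-phase pattern order is randomized per subject, as in
    binocular acquisition). Enrolled-but-excluded subjects carry their
    exclusion reason and no tests. ``monocular_only_count`` included subjects
    are flagged as unable to test binocularly; they are still tested one eye
    at a time and contribute identically to the statistics.

    Restricting ``patterns`` or disabling practice tests generates the
    corresponding subset only (used to keep simulations small); the subject
    stream is unaffected.
    """
    if config is None:
        config = default_config()
    if patterns is None:
        patterns = list(PatternId)
    rng = np.random.default_rng(config.seed)

    subjects = sample_demographics(config, rng)
    n_mono = min(config.monocular_only_count, len(subjects))
    if n_mono:
        mono_idx = rng.choice(len(subjects), size=n_mono, replace=False)
        for j in mono_idx:
            subjects[j].binocular_capable = False
    excluded = _excluded_profiles(config, rng, len(subjects))

    tests: list[VFTestRecord] = []
    phases = ([True, False] if include_practice else [False])
    for subj in subjects:
        g_std = float(rng.standard_normal())
        for is_practice in phases:
            order = list(patterns)
            rng.shuffle(order)
            for pid in order:
                truth = config.truths[PatternId(pid)]
                for eye in (Eye.OD, Eye.OS):
                    tests.append(
                        simulate_test(
                            subj, truth, eye, rng,
                            config=config, g_std=g_std,
                            is_practice=is_practice,
                        )
                    )
    return Cohort(subjects=subjects + excluded, tests=tests, config=config)
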