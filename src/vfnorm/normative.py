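"""Reference-database construction: pointwise age regression and limits.

Age correction is cross-sectional: at every analyzed grid point, threshold
sensitivity (dB) is regressed on age (years) by ordinary least squares, and
the fitted line ``alpha_p + b_p * age`` serves as the age-corrected
50th-percentile surface. Residuals are pooled across ages (spread is treated
as age-independent) and summarized nonparametrically: per-point quantile
tables at the 0.5/1/2/5 (and mirrored upper) percent levels give the total-
deviation significance limits, and the residual variance ``s2_p`` supplies
the weights for the mean-deviation and pattern-standard-deviation indices.
Global reference limits for MD (lower tail), PSD (upper tail) and the foveal
threshold (lower tail, from its own regression) are tabulated from the
cohort's own index distributions in a second pass.

Quantiles use the Hazen plotting position (i - 0.5)/n with linear
interpolation — a symmetric, standard choice for reference intervals; the
rule is a parameter so alternatives can be compared.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .errors import InsufficientDataError, ModelIntegrityError
from .patterns import TestPattern, build_pattern, mirror_to_canonical
from .records import Eye, ExclusionReason, PatternId, VFTestRecord
from . import qc

__all__ = [
    "STORED_LEVELS",
    "LIMIT_LEVELS",
    "PointwiseFit",
    "NormativeModel",
    "nonparametric_quantile",
    "select_study_eyes",
    "prepare_analysis_set",
    "fit_pointwise_regression",
    "predict_reference",
    "build_reference_database",
]

#: Residual quantile levels stored per point (%, lower-to-upper).
STORED_LEVELS = (0.5, 1.0, 2.0, 5.0, 50.0, 95.0, 98.0, 99.0, 99.5)
#: Reference-limit levels for every analysis parameter (%).
LIMIT_LEVELS = (5.0, 2.0, 1.0, 0.5)
#: Variance floor (dB^2) keeping index weights finite on degenerate input.
VARIANCE_FLOOR = 0.01
#: Age range outside which predictions warn about extrapolation.
AGE_GUARD = (22.0, 90.0)


@dataclass
class PointwiseFit:
    """OLS fit of threshold on age at one grid point."""

    point_index: int
    intercept: float  # dB at age 0
    slope: float  # dB per year, signed (expected negative)
    n: int
    residuals: np.ndarray

    def __post_init__(self):
        if self.n < 3:
            raise InsufficientDataError(
                f"point {self.point_index}: {self.n} subjects (< 3) for regression"
            )


@dataclass
class NormativeModel:
    """The product of reference-database construction for one pattern.

    Per-point arrays have the pattern's full length with NaN at blind-spot
    points. ``resid_quantiles[level]`` / ``pd_quantiles[level]`` map a stored
    percent level to a per-point array; ``md_limits`` / ``psd_limits`` /
    ``foveal_limits`` map a limit level (5/2/1/0.5) to a scalar limit, lower
    tail for MD and foveal deviation, upper tail for PSD.
    """

    pattern: TestPattern
    reference_age: float
    alpha: np.ndarray
    slope: np.ndarray
    s2: np.ndarray
    resid_quantiles: dict[float, np.ndarray]
    pd_quantiles: dict[float, np.ndarray]
    gh_k: int
    md_limits: dict[float, float]
    psd_limits: dict[float, float]
    foveal_alpha: float
    foveal_slope: float
    foveal_s2: float
    foveal_limits: dict[float, float]
    n_subjects: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def pattern_id(self) -> PatternId:
        return self.pattern.pattern_id

    def td_limits(self, level: float) -> np.ndarray:
        """Per-point lower-tail total-deviation limit at a percent level."""
        return self.resid_quantiles[float(level)]

    def validate(self) -> None:
        """Check internal invariants; raise :class:`ModelIntegrityError`."""
        an = np.array(self.pattern.analyzed_indices)
        levels = sorted(self.resid_quantiles)
        tab = np.array([self.resid_quantiles[l][an] for l in levels])
        if np.any(np.diff(tab, axis=0) < -1e-9):
            raise ModelIntegrityError("per-point quantile table not monotone in level")
        if np.any(~(self.s2[an] > 0)):
            raise ModelIntegrityError("residual variances must be positive")
        for name, limits, lower in (
            ("md", self.md_limits, True),
            ("foveal", self.foveal_limits, True),
            ("psd", self.psd_limits, False),
        ):
            ordered = [limits[l] for l in sorted(limits)]  # 0.5, 1, 2, 5
            diffs = np.diff(ordered)
            ok = np.all(diffs >= -1e-9) if lower else np.all(diffs <= 1e-9)
            if not ok:
                raise ModelIntegrityError(f"{name} limits not ordered across levels")


def nonparametric_quantile(
    values: Sequence[float], level: float, rule: str = "hazen"
) -> float:
    """Order-statistic quantile of ``values`` at ``level`` percent.

    The default Hazen rule places the i-th order statistic at probability
    (i - 0.5)/n and interpolates linearly, clamping beyond the extreme
    plotting positions. Other ``rule`` names are delegated to
    :func:`numpy.quantile`.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("quantile of empty data")
    if not 0.0 < level < 100.0:
        raise ValueError("level must be in (0, 100)")
    if rule != "hazen":
        return float(np.quantile(x, level / 100.0, method=rule))
    xs = np.sort(x)
    n = xs.size
    h = (level / 100.0) * n + 0.5  # 1-based fractional rank
    if h <= 1.0:
        return float(xs[0])
    if h >= n:
        return float(xs[-1])
    lo = int(math.floor(h))
    frac = h - lo
    return float(xs[lo - 1] + frac * (xs[lo] - xs[lo - 1]))


def select_study_eyes(
    cohort: Cohort, rng: Optional[np.random.Generator] = None
) -> dict[str, Eye]:
    """One randomly selected eye per included subject, shared by every
    pattern's analysis (a fair coin; deterministic for subjects with tests of
    only one eye)."""
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed)
    eyes_tested: dict[str, set] = {}
    for t in cohort.tests:
        if not t.is_practice:
            eyes_tested.setdefault(t.subject_id, set()).add(t.eye)
    out = {}
    for s in cohort.included_subjects():
        tested = tuple(sorted(eyes_tested.get(s.subject_id, {Eye.OD, Eye.OS}),
                              key=lambda e: e.value))
        out[s.subject_id] = qc.select_study_eye(s, rng, tested)
    return out


def prepare_analysis_set(
    cohort: Cohort,
    pattern_id: PatternId,
    eye_map: Optional[dict[str, Eye]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Assemble the regression inputs for one pattern.

    Takes each included subject's final reliable *study* test of the selected
    eye, mirrored onto the canonical right-eye frame. Returns
    ``(ages, values, foveal, subject_ids, eye_map)`` with ``values`` of shape
    (n_subjects, n_points).
    """
    if eye_map is None:
        eye_map = select_study_eyes(cohort, rng)
    pattern = build_pattern(pattern_id)
    by_subject: dict[str, VFTestRecord] = {}
    for t in cohort.tests:
        if t.is_practice or t.pattern_id is not pattern_id:
            continue
        if eye_map.get(t.subject_id) is not t.eye:
            continue
        if not qc.check_reliability(t):
            continue
        prev = by_subject.get(t.subject_id)
        if prev is None or t.attempt > prev.attempt:
            by_subject[t.subject_id] = t
    ages, rows, fov, ids = [], [], [], []
    for s in cohort.included_subjects():
        t = by_subject.get(s.subject_id)
        if t is None:
            continue  # no reliable study test: excluded from the RDB
        t = mirror_to_canonical(t, pattern)
        ages.append(float(s.age))
        rows.append(t.values)
        fov.append(t.foveal_db)
        ids.append(s.subject_id)
    return (
        np.array(ages),
        np.array(rows, dtype=float),
        np.array(fov, dtype=float),
        ids,
        eye_map,
    )


def _ols_by_column(ages: np.ndarray, values: np.ndarray):
    """Simultaneous single-predictor OLS of each column on age."""
    n = ages.size
    if n < 3:
        raise InsufficientDataError(f"{n} subjects (< 3) for regression")
    a_c = ages - ages.mean()
    denom = float(a_c @ a_c)
    slopes = (a_c @ (values - values.mean(axis=0))) / denom
    intercepts = values.mean(axis=0) - slopes * ages.mean()
    resid = values - (intercepts[None, :] + np.outer(ages, slopes))
    return intercepts, slopes, resid


def fit_pointwise_regression(
    cohort: Cohort,
    pattern_id: PatternId,
    eye_map: Optional[dict[str, Eye]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PointwiseFit]:
    """Cross-sectional pointwise linear age regression over a qc-passed cohort.

    Blind-spot points are skipped. Slopes are in dB/year, signed (a decline
    is negative).
    """
    ages, values, _, _, _ = prepare_analysis_set(cohort, pattern_id, eye_map, rng)
    pattern = build_pattern(pattern_id)
    an = list(pattern.analyzed_indices)
    intercepts, slopes, resid = _ols_by_column(ages, values[:, an])
    return [
        PointwiseFit(
            point_index=j,
            intercept=float(intercepts[k]),
            slope=float(slopes[k]),
            n=ages.size,
            residuals=resid[:, k],
        )
        for k, j in enumerate(an)
    ]


def predict_reference(model: NormativeModel, point_index: int, age: float) -> float:
    """Age-corrected 50th-percentile threshold at a point (dB).

    Warns (but still answers) outside the age guard range.
    """
    lo, hi = AGE_GUARD
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside the reference range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    return float(model.alpha[point_index] + model.slope[point_index] * age)


def build_reference_database(
    cohort: Cohort,
    pattern_id: PatternId,
    rng: Optional[np.random.Generator] = None,
    eye_map: Optional[dict[str, Eye]] = None,
    gh_fraction: float = 0.15,
    quantile_rule: str = "hazen",
) -> NormativeModel:
    """Build the full reference database for one pattern from a cohort.

    Two passes: first the pointwise (and foveal) age regressions with pooled
    residual quantile tables and variances; then every subject's deviation
    indices against those surfaces, from which the global MD / PSD / foveal
    limits and the per-point pattern-deviation limits are tabulated.
    Deterministic given the cohort and the eye selection.
    """
    from . import indices as _indices  # deferred: indices is also a consumer

    pattern = build_pattern(pattern_id)
    ages, values, foveal, ids, eye_map = prepare_analysis_set(
        cohort, pattern_id, eye_map, rng
    )
    an = np.array(pattern.analyzed_indices)
    intercepts, slopes, resid = _ols_by_column(ages, values[:, an])
    fov_a, fov_b, fov_resid = _ols_by_column(ages, foveal[:, None])

    n_pts = pattern.n_points
    alpha_full = np.full(n_pts, np.nan)
    slope_full = np.full(n_pts, np.nan)
    s2_full = np.full(n_pts, np.nan)
    alpha_full[an] = intercepts
    slope_full[an] = slopes
    s2_full[an] = np.maximum(resid.var(axis=0, ddof=1), VARIANCE_FLOOR)

    resid_quantiles = {}
    for level in STORED_LEVELS:
        arr = np.full(n_pts, np.nan)
        arr[an] = [
            nonparametric_quantile(resid[:, k], level, quantile_rule)
            for k in range(an.size)
        ]
        resid_quantiles[float(level)] = arr

    # pass 2: indices of every cohort subject against the fitted surfaces
    k_rank = math.ceil(gh_fraction * an.size)
    s2_an = s2_full[an]
    td = resid  # cohort members' total deviations are their residuals
    gh = np.array([_indices.general_height(row, k_rank) for row in td])
    pd_mat = np.array(
        [_indices.pattern_deviation(row, g) for row, g in zip(td, gh)]
    )
    md = np.array([_indices.mean_deviation(row, s2_an) for row in td])
    psd = np.array(
        [_indices.pattern_sd(row, m, s2_an) for row, m in zip(td, md)]
    )

    pd_quantiles = {}
    for level in LIMIT_LEVELS:
        arr = np.full(n_pts, np.nan)
        arr[an] = [
            nonparametric_quantile(pd_mat[:, k], level, quantile_rule)
            for k in range(an.size)
        ]
        pd_quantiles[float(level)] = arr

    md_limits = {
        float(l): nonparametric_quantile(md, l, quantile_rule) for l in LIMIT_LEVELS
    }
    psd_limits = {
        float(l): nonparametric_quantile(psd, 100.0 - l, quantile_rule)
        for l in LIMIT_LEVELS
    }
    foveal_limits = {
        float(l): nonparametric_quantile(fov_resid[:, 0], l, quantile_rule)
        for l in LIMIT_LEVELS
    }

    model = NormativeModel(
        pattern=pattern,
        reference_age=float(ages.mean()),
        alpha=alpha_full,
        slope=slope_full,
        s2=s2_full,
        resid_quantiles=resid_quantiles,
        pd_quantiles=pd_quantiles,
        gh_k=k_rank,
        md_limits=md_limits,
        psd_limits=psd_limits,
        foveal_alpha=float(fov_a[0]),
        foveal_slope=float(fov_b[0]),
        foveal_s2=float(max(fov_resid.var(ddof=1), VARIANCE_FLOOR)),
        foveal_limits=foveal_limits,
        n_subjects=int(ages.size),
        provenance={
            "n_subjects": int(ages.size),
            "pattern_id": pattern.pattern_id.value,
            "cohort_seed": cohort.config.seed,
            "quantile_rule": quantile_rule,
            "gh_fraction": gh_fraction,
            "build_date": _dt.date.today().isoformat(),
        },
    )
    model.validate()
    return model
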