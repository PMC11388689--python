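"""Deviation indices for one visual-field test against a normative model.

Conventions follow standard automated perimetry practice:

* total deviation ``TD_p = observed_p - (alpha_p + b_p * age)``;
* general height GH is the k-th highest TD, k = ceil(0.15 * N) (the 85th
  percentile rank) — a diffuse-offset estimate robust to focal loss;
* pattern deviation ``PD_p = TD_p - GH`` localizes focal loss;
* mean deviation is the variance-weighted TD average,
  ``MD = sum(TD_p / s2_p) / sum(1 / s2_p)``;
* pattern standard deviation,
  ``PSD^2 = mean(s2) * sum((TD_p - MD)^2 / s2_p) / (N - 1)``,
  is the weighted dispersion of TD about MD.

The GH rank rule and the MD/PSD weighting are conventions, not published
device equations; both are parameters of the build. Probability
classification flags the most extreme level whose limit a value crosses,
inclusively at the limit; TD/PD/MD/foveal use lower-tail limits (depressed
sensitivity), PSD the upper tail.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, MalformedRecordError, ModelIntegrityError
from .patterns import mirror_to_canonical
from .records import VFTestRecord

__all__ = [
    "ProbCategory",
    "DeviationResult",
    "total_deviation",
    "general_height",
    "pattern_deviation",
    "mean_deviation",
    "pattern_sd",
    "classify",
    "classify_map",
    "analyze",
    "format_report",
]


class ProbCategory(str, enum.Enum):
    """Significance category against the reference limits (P-levels, %)."""

    NS = "ns"
    P5 = "p5"
    P2 = "p2"
    P1 = "p1"
    P05 = "p05"


_LEVEL_TO_CATEGORY = {5.0: ProbCategory.P5, 2.0: ProbCategory.P2,
                      1.0: ProbCategory.P1, 0.5: ProbCategory.P05}


@dataclass
class DeviationResult:
    """All analysis parameters of one test against a normative model.

    Per-point arrays have the pattern's full length, NaN (or NS) at
    blind-spot points. ``pd = td - gh`` pointwise.
    """

    td: np.ndarray
    pd: np.ndarray
    gh: float
    md: float
    psd: float
    foveal_dev: float
    prob_td: list
    prob_pd: list
    prob_md: ProbCategory
    prob_psd: ProbCategory
    prob_foveal: ProbCategory


def total_deviation(test: VFTestRecord, model, age: float) -> np.ndarray:
    """Pointwise deviation of a canonical-frame test from the age-corrected
    reference surface; NaN at blind-spot points."""
    if test.pattern_id is not model.pattern_id:
        raise MalformedRecordError(
            f"test pattern {test.pattern_id.value} does not match model "
            f"pattern {model.pattern_id.value}"
        )
    if len(test.values) != model.pattern.n_points:
        raise MalformedRecordError("value list length does not match pattern")
    predicted = model.alpha + model.slope * age
    return np.asarray(test.values, dtype=float) - predicted


def general_height(td: np.ndarray, k: Optional[int] = None) -> float:
    """The k-th highest finite TD value; k defaults to ceil(0.15 * N)."""
    vals = np.asarray(td, dtype=float)
    vals = vals[np.isfinite(vals)]
    if k is None:
        k = math.ceil(0.15 * vals.size)
    if vals.size < k or k < 1:
        raise InsufficientDataError(
            f"need at least k={k} analyzed values, have {vals.size}"
        )
    return float(np.sort(vals)[-k])


def pattern_deviation(td: np.ndarray, gh: float) -> np.ndarray:
    """TD with the diffuse component removed: ``pd = td - gh``."""
    return np.asarray(td, dtype=float) - gh


def mean_deviation(td: np.ndarray, s2: np.ndarray) -> float:
    """Variance-weighted mean of TD over analyzed points."""
    td = np.asarray(td, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(td) & np.isfinite(s2)
    w = 1.0 / s2[ok]
    return float((td[ok] * w).sum() / w.sum())


def pattern_sd(td: np.ndarray, md: float, s2: np.ndarray) -> float:
    """Variance-weighted dispersion of TD about MD (dB, >= 0)."""
    td = np.asarray(td, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(td) & np.isfinite(s2)
    n = int(ok.sum())
    if n < 2:
        raise InsufficientDataError("PSD needs at least 2 analyzed points")
    psd2 = s2[ok].mean() * ((td[ok] - md) ** 2 / s2[ok]).sum() / (n - 1)
    return float(math.sqrt(max(psd2, 0.0)))


def classify(value: float, limits: dict, tail: str = "lower") -> ProbCategory:
    """Most extreme significance level whose limit ``value`` crosses.

    ``limits`` maps percent levels {5, 2, 1, 0.5} to limit values; a value
    exactly at a limit is flagged at that level (inclusive). ``tail`` is
    "lower" for TD/PD/MD/foveal deviation, "upper" for PSD.
    """
    levels = sorted(limits)  # 0.5, 1, 2, 5
    vals = [limits[l] for l in levels]
    diffs = np.diff(vals)
    ok = np.all(diffs >= -1e-12) if tail == "lower" else np.all(diffs <= 1e-12)
    if not ok:
        raise ModelIntegrityError("limits are not monotone across levels")
    for level in levels:  # most extreme first
        crossed = value <= limits[level] if tail == "lower" else value >= limits[level]
        if crossed:
            return _LEVEL_TO_CATEGORY[level]
    return ProbCategory.NS


def classify_map(values: np.ndarray, limits_by_level: dict, tail: str = "lower") -> list:
    """Per-point classification; NS wherever the value or limits are NaN."""
    n = len(values)
    out = []
    for i in range(n):
        lim = {l: limits_by_level[l][i] for l in limits_by_level}
        if not np.isfinite(values[i]) or any(not np.isfinite(v) for v in lim.values()):
            out.append(ProbCategory.NS)
        else:
            out.append(classify(float(values[i]), lim, tail))
    return out


def analyze(test: VFTestRecord, model, age: float) -> DeviationResult:
    """Full single-test analysis against a normative model.

    Left-eye records are mirrored onto the canonical frame first. The foveal
    threshold has its own regression and limits and never enters MD/PSD.
    """
    test = mirror_to_canonical(test, model.pattern)
    td = total_deviation(test, model, age)
    gh = general_height(td, model.gh_k)
    pd = pattern_deviation(td, gh)
    md = mean_deviation(td, model.s2)
    psd = pattern_sd(td, md, model.s2)
    foveal_dev = float(
        test.foveal_db - (model.foveal_alpha + model.foveal_slope * age)
    )
    td_lims = {l: model.resid_quantiles[l] for l in (5.0, 2.0, 1.0, 0.5)}
    return DeviationResult(
        td=td,
        pd=pd,
        gh=gh,
        md=md,
        psd=psd,
        foveal_dev=foveal_dev,
        prob_td=classify_map(td, td_lims),
        prob_pd=classify_map(pd, model.pd_quantiles),
        prob_md=classify(md, model.md_limits, "lower"),
        prob_psd=classify(psd, model.psd_limits, "upper"),
        prob_foveal=classify(foveal_dev, model.foveal_limits, "lower"),
    )


_GLYPH = {ProbCategory.NS: " .", ProbCategory.P5: " 5", ProbCategory.P2: " 2",
          ProbCategory.P1: " 1", ProbCategory.P05: " *"}


def format_report(result: DeviationResult, model) -> str:
    """Plain-text spatial layout of the TD and PD maps with category glyphs.

    Glyphs: '.' not significant, '5'/'2'/'1' the P-level (%), '*' P < 0.5%,
    'x' blind spot. Index conventions (GH rank, MD/PSD weighting) are noted
    in the footer because device-specific definitions are unpublished.
    """
    pattern = model.pattern
    xs = sorted({p.x for p in pattern.points})
    ys = sorted({p.y for p in pattern.points}, reverse=True)
    pos = {(p.x, p.y): i for i, p in enumerate(pattern.points)}

    def grid(values, probs=None) -> str:
        lines = []
        for y in ys:
            cells = []
            for x in xs:
                i = pos.get((x, y))
                if i is None:
                    cells.append("      ")
                elif pattern.points[i].is_blind_spot:
                    cells.append("   x  ")
                elif probs is not None:
                    cells.append(f"   {_GLYPH[probs[i]]} ")
                else:
                    cells.append(f"{values[i]:6.1f}")
            lines.append("".join(cells).rstrip())
        return "\n".join(lines)

    parts = [
        f"Pattern {pattern.pattern_id.value}  (n_ref = {model.n_subjects})",
        "", "Total deviation (dB):", grid(result.td),
        "", "TD probability:", grid(None, result.prob_td),
        "", "Pattern deviation (dB):", grid(result.pd),
        "", "PD probability:", grid(None, result.prob_pd),
        "",
        f"GH {result.gh:+.2f} dB   MD {result.md:+.2f} dB ({result.prob_md.value})"
        f"   PSD {result.psd:.2f} dB ({result.prob_psd.value})"
        f"   foveal dev {result.foveal_dev:+.2f} dB ({result.prob_foveal.value})",
        "",
        f"[GH = {model.gh_k}-th highest TD; MD/PSD variance-weighted; these "
        "rank and weighting conventions are configuration, not device "
        "specifications.]",
    ]
    return "\n".join(parts)
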