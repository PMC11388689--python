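"""File formats: cohort CSVs, model/pattern/result JSON, Snellen conversion.

Tabular data is CSV (UTF-8); models, patterns and analysis reports are
versioned JSON. Threshold columns may not be missing — untested points do
not occur at reference-database scale. Every file written here embeds the
tool version, the generating seed where applicable, and a configuration
hash, so outputs are self-describing. Documented schemas live in
``docs/schemas.md``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, NormTruth
from .errors import SchemaError, VfnormError
from .indices import DeviationResult
from .normative import NormativeModel
from .patterns import TestPattern, build_pattern, pattern_from_json, pattern_to_json
from .qc import ExclusionTally
from .records import (
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
    "snellen_to_logmar",
    "config_hash",
    "write_cohort",
    "read_cohort",
    "write_tests",
    "read_tests",
    "write_model",
    "read_model",
    "write_result",
    "tally_to_csv",
]

MODEL_FORMAT_VERSION = 1
_SNELLEN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")


def snellen_to_logmar(notation: str) -> float:
    """Convert a Snellen fraction string ("20/40") to logMAR (0.301)."""
    m = _SNELLEN_RE.match(notation)
    if not m:
        raise SchemaError(f"malformed Snellen notation: {notation!r}")
    num, den = float(m.group(1)), float(m.group(2))
    if num <= 0 or den <= 0:
        raise SchemaError(f"non-positive Snellen values: {notation!r}")
    return math.log10(den / num)


# ---------------------------------------------------------------------------
# config / truth serialization


def _truth_to_dict(t: NormTruth) -> dict:
    d = dataclasses.asdict(t)
    d["pattern_id"] = t.pattern_id.value
    return d


def _truth_from_dict(d: dict) -> NormTruth:
    d = dict(d)
    d["pattern_id"] = PatternId(d["pattern_id"])
    for key in ("base_map", "slope_map", "sigma_map"):
        d[key] = tuple(d[key])
    return NormTruth(**d)


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "seed": config.seed,
        "age_bin_counts": list(config.age_bin_counts),
        "sex_p": {k.value: v for k, v in config.sex_p.items()},
        "race_p": {k.value: v for k, v in config.race_p.items()},
        "ethnicity_p": {k.value: v for k, v in config.ethnicity_p.items()},
        "truths": {k.value: _truth_to_dict(v) for k, v in config.truths.items()},
        "n_excluded_by_reason": {
            k.value: v for k, v in config.n_excluded_by_reason.items()
        },
        "monocular_only_count": config.monocular_only_count,
        "reliability_fail_prob": config.reliability_fail_prob,
        "fl_mean": config.fl_mean,
        "fp_mean": config.fp_mean,
        "fn_mean": config.fn_mean,
    }


def config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(
        seed=int(d["seed"]),
        age_bin_counts=tuple(d["age_bin_counts"]),
        sex_p={Sex(k): v for k, v in d["sex_p"].items()},
        race_p={Race(k): v for k, v in d["race_p"].items()},
        ethnicity_p={Ethnicity(k): v for k, v in d["ethnicity_p"].items()},
        truths={PatternId(k): _truth_from_dict(v) for k, v in d["truths"].items()},
        n_excluded_by_reason={
            ExclusionReason(k): v for k, v in d["n_excluded_by_reason"].items()
        },
        monocular_only_count=int(d["monocular_only_count"]),
        reliability_fail_prob=float(d["reliability_fail_prob"]),
        fl_mean=float(d["fl_mean"]),
        fp_mean=float(d["fp_mean"]),
        fn_mean=float(d["fn_mean"]),
    )


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: Optional[CohortConfig] = None, seed: Optional[int] = None) -> dict:
    out = {"tool": "vfnorm", "version": __version__}
    if seed is not None:
        out["seed"] = seed
    if config is not None:
        out["config_hash"] = config_hash(config)
    return out


# ---------------------------------------------------------------------------
# cohort CSVs


def _subjects_frame(subjects: Iterable[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex.value,
                "race": s.race.value,
                "ethnicity": s.ethnicity.value,
                "va_logmar": s.va_logmar,
                "iop_od": None if s.iop_mmhg is None else s.iop_mmhg[0],
                "iop_os": None if s.iop_mmhg is None else s.iop_mmhg[1],
                "se_od": None if s.se_diopters is None else s.se_diopters[0],
                "se_os": None if s.se_diopters is None else s.se_diopters[1],
                "cyl_od": None if s.cyl_diopters is None else s.cyl_diopters[0],
                "cyl_os": None if s.cyl_diopters is None else s.cyl_diopters[1],
                "exclusion_reason": s.exclusion_reason.value,
                "binocular_capable": s.binocular_capable,
            }
        )
    return pd.DataFrame(rows)


def _subject_from_row(row: pd.Series) -> SubjectProfile:
    def pair(a, b):
        if pd.isna(row[a]) or pd.isna(row[b]):
            return None
        return (float(row[a]), float(row[b]))

    return SubjectProfile(
        subject_id=str(row["subject_id"]),
        age=int(row["age"]),
        sex=Sex(row["sex"]),
        race=Race(row["race"]),
        ethnicity=Ethnicity(row["ethnicity"]),
        va_logmar=None if pd.isna(row["va_logmar"]) else float(row["va_logmar"]),
        iop_mmhg=pair("iop_od", "iop_os"),
        se_diopters=pair("se_od", "se_os"),
        cyl_diopters=pair("cyl_od", "cyl_os"),
        exclusion_reason=ExclusionReason(row["exclusion_reason"]),
        binocular_capable=bool(row["binocular_capable"]),
    )


_TEST_META_COLS = [
    "subject_id", "eye", "pattern_id", "is_practice", "attempt",
    "foveal_db", "fl_rate", "fp_rate", "fn_rate", "duration_min",
]


def _tests_frame(
    tests: list[VFTestRecord],
    pattern: TestPattern,
    seqs: Optional[list[int]] = None,
) -> pd.DataFrame:
    rows = []
    for k, t in enumerate(tests):
        row = {
            **({"seq": seqs[k]} if seqs is not None else {}),
            "subject_id": t.subject_id,
            "eye": t.eye.value,
            "pattern_id": t.pattern_id.value,
            "is_practice": t.is_practice,
            "attempt": t.attempt,
            "foveal_db": t.foveal_db,
            "fl_rate": t.fl_rate,
            "fp_rate": t.fp_rate,
            "fn_rate": t.fn_rate,
            "duration_min": t.duration_min,
        }
        row.update({f"v{i:02d}": v for i, v in enumerate(t.values)})
        rows.append(row)
    cols = _TEST_META_COLS + [f"v{i:02d}" for i in range(pattern.n_points)]
    if seqs is not None:
        cols = ["seq"] + cols
    return pd.DataFrame(rows, columns=cols)


def write_tests(tests: list[VFTestRecord], path: str | Path) -> None:
    """Write test records of a single pattern to one CSV."""
    if not tests:
        raise VfnormError("no test records to write")
    pids = {t.pattern_id for t in tests}
    if len(pids) != 1:
        raise VfnormError("a tests CSV holds a single pattern; split by pattern")
    pattern = build_pattern(next(iter(pids)))
    _tests_frame(tests, pattern).to_csv(path, index=False)


def read_tests(path: str | Path) -> list[VFTestRecord]:
    """Read test records from CSV, validating the schema row by row."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TEST_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        return []
    pattern = build_pattern(PatternId(df["pattern_id"].iloc[0]))
    vcols = [f"v{i:02d}" for i in range(pattern.n_points)]
    missing_v = [c for c in vcols if c not in df.columns]
    if missing_v:
        raise SchemaError(f"{path}: missing threshold columns {missing_v}")
    out = []
    for i, row in df.iterrows():
        values = [row[c] for c in vcols]
        bad = [c for c, v in zip(vcols, values) if pd.isna(v)]
        if bad:
            raise SchemaError(f"{path}: row {i + 2}: missing thresholds in {bad}")
        out.append(
            VFTestRecord(
                subject_id=str(row["subject_id"]),
                eye=Eye(row["eye"]),
                pattern_id=PatternId(row["pattern_id"]),
                values=[float(v) for v in values],
                foveal_db=float(row["foveal_db"]),
                fl_rate=float(row["fl_rate"]),
                fp_rate=float(row["fp_rate"]),
                fn_rate=float(row["fn_rate"]),
                duration_min=float(row["duration_min"]),
                attempt=int(row["attempt"]),
                is_practice=bool(row["is_practice"]),
            )
        )
    return out


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Serialize a cohort: subjects.csv, per-pattern tests CSVs, meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _subjects_frame(cohort.subjects).to_csv(outdir / "subjects.csv", index=False)
    pattern_ids = sorted({t.pattern_id for t in cohort.tests}, key=lambda p: p.value)
    for pid in pattern_ids:
        indexed = [(i, t) for i, t in enumerate(cohort.tests) if t.pattern_id is pid]
        pattern = build_pattern(pid)
        # the seq column preserves the cohort's interleaved acquisition order
        _tests_frame(
            [t for _, t in indexed], pattern, seqs=[i for i, _ in indexed]
        ).to_csv(outdir / f"tests_{pid.value}.csv", index=False)
    meta = {
        **_stamp(cohort.config, cohort.config.seed),
        "config": config_to_dict(cohort.config),
        "patterns": {
            pid.value: json.loads(pattern_to_json(build_pattern(pid)))
            for pid in pattern_ids
        },
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_cohort(indir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort` (lossless)."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    config = config_from_dict(meta["config"])
    df = pd.read_csv(indir / "subjects.csv", float_precision="round_trip")
    subjects = [_subject_from_row(row) for _, row in df.iterrows()]
    indexed: list[tuple[int, VFTestRecord]] = []
    for pid_value in sorted(meta.get("patterns", {})):
        path = indir / f"tests_{pid_value}.csv"
        if path.exists():
            records = read_tests(path)
            seqs = pd.read_csv(path, usecols=["seq"])["seq"].tolist()
            indexed.extend(zip(seqs, records))
    indexed.sort(key=lambda pair: pair[0])
    return Cohort(
        subjects=subjects, tests=[t for _, t in indexed], config=config
    )


# ---------------------------------------------------------------------------
# model JSON


def write_model(model: NormativeModel, path: str | Path) -> None:
    """Serialize a normative model as versioned JSON (pattern embedded)."""

    def arr(a):
        return [None if not np.isfinite(v) else float(v) for v in np.asarray(a)]

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        **_stamp(),
        "pattern": json.loads(pattern_to_json(model.pattern)),
        "reference_age": model.reference_age,
        "alpha": arr(model.alpha),
        "slope": arr(model.slope),
        "s2": arr(model.s2),
        "resid_quantiles": {str(l): arr(v) for l, v in model.resid_quantiles.items()},
        "pd_quantiles": {str(l): arr(v) for l, v in model.pd_quantiles.items()},
        "gh_k": model.gh_k,
        "md_limits": {str(l): v for l, v in model.md_limits.items()},
        "psd_limits": {str(l): v for l, v in model.psd_limits.items()},
        "foveal_alpha": model.foveal_alpha,
        "foveal_slope": model.foveal_slope,
        "foveal_s2": model.foveal_s2,
        "foveal_limits": {str(l): v for l, v in model.foveal_limits.items()},
        "n_subjects": model.n_subjects,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: str | Path) -> NormativeModel:
    """Load a model JSON and re-validate its invariants."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: unsupported model format version "
            f"{payload.get('format_version')!r}"
        )

    def arr(a):
        return np.array([np.nan if v is None else float(v) for v in a])

    model = NormativeModel(
        pattern=pattern_from_json(json.dumps(payload["pattern"])),
        reference_age=float(payload["reference_age"]),
        alpha=arr(payload["alpha"]),
        slope=arr(payload["slope"]),
        s2=arr(payload["s2"]),
        resid_quantiles={
            float(l): arr(v) for l, v in payload["resid_quantiles"].items()
        },
        pd_quantiles={float(l): arr(v) for l, v in payload["pd_quantiles"].items()},
        gh_k=int(payload["gh_k"]),
        md_limits={float(l): float(v) for l, v in payload["md_limits"].items()},
        psd_limits={float(l): float(v) for l, v in payload["psd_limits"].items()},
        foveal_alpha=float(payload["foveal_alpha"]),
        foveal_slope=float(payload["foveal_slope"]),
        foveal_s2=float(payload["foveal_s2"]),
        foveal_limits={
            float(l): float(v) for l, v in payload["foveal_limits"].items()
        },
        n_subjects=int(payload["n_subjects"]),
        provenance=payload.get("provenance", {}),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# analysis results and tallies


def write_result(result: DeviationResult, model: NormativeModel, path: str | Path) -> None:
    """Single-test analysis report as JSON."""

    def arr(a):
        return [None if not np.isfinite(v) else float(v) for v in np.asarray(a)]

    payload = {
        **_stamp(),
        "pattern_id": model.pattern_id.value,
        "td": arr(result.td),
        "pd": arr(result.pd),
        "gh": result.gh,
        "md": result.md,
        "psd": result.psd,
        "foveal_dev": result.foveal_dev,
        "prob_td": [c.value for c in result.prob_td],
        "prob_pd": [c.value for c in result.prob_pd],
        "prob_md": result.prob_md.value,
        "prob_psd": result.prob_psd.value,
        "prob_foveal": result.prob_foveal.value,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def tally_to_csv(tally: ExclusionTally, path: str | Path) -> None:
    """Exclusion accounting as one CSV row per reason plus totals."""
    rows = [
        {"category": reason.value, "count": tally.counts.get(reason, 0)}
        for reason in ExclusionReason
        if reason is not ExclusionReason.NONE
    ]
    rows.append({"category": "excluded_total", "count": tally.n_excluded})
    rows.append({"category": "included", "count": tally.n_included})
    rows.append({"category": "enrolled", "count": tally.n_enrolled})
    pd.DataFrame(rows).to_csv(path, index=False)
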