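"""Test-point geometry for the 24-2 and 10-2 perimetric grids.

Coordinates are degrees of visual angle in a canonical *right-eye* frame:
``x > 0`` is nasal, ``y > 0`` is superior. The 24-2 grid is the standard
54-point chart (6-degree spacing, rows of 4/6/8/9/9/8/6/4) whose two extra
points sit at nasal 27 degrees; the two points straddling the physiologic
blind spot (temporal 15 degrees, y = +/-3) are flagged and excluded from all
statistics but never removed from the grid. The 10-2 grid is a 68-point,
2-degree-spacing lattice confined to within 10 degrees of fixation.

Point order is canonical and stable: rows superior to inferior, and within a
row temporal to nasal (x ascending). Left-eye (OS) grids are the mirror image
of the canonical grid, enumerated in the same spatial order in the left eye's
own field coordinates; :func:`mirror_to_canonical` maps an OS record onto the
canonical frame (an involution).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .errors import MalformedRecordError, UnsupportedPatternError
from .records import Eye, PatternId, VFTestRecord

__all__ = [
    "GridPoint",
    "TestPattern",
    "build_pattern",
    "eccentricity",
    "mirror_to_canonical",
    "pattern_to_json",
    "pattern_from_json",
]


@dataclass(frozen=True)
class GridPoint:
    """One stimulus location. ``is_blind_spot`` marks the two 24-2 points
    overlying the physiologic blind spot; they are tested but never analyzed."""

    x: int
    y: int
    is_blind_spot: bool = False


@dataclass(frozen=True)
class TestPattern:
    """An ordered grid of stimulus locations.

    ``spacing`` is the nearest-neighbor distance in degrees (6 for 24-2,
    2 for 10-2). ``analyzed_indices`` lists the positions that enter every
    statistic (non-blind-spot points).
    """

    pattern_id: PatternId
    points: tuple[GridPoint, ...]
    spacing: int

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def analyzed_indices(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.points) if not p.is_blind_spot)

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed_indices)

    def eccentricities(self) -> list[float]:
        return [eccentricity(p) for p in self.points]

    def index_of(self, x: int, y: int) -> int:
        return _coord_index(self)[(x, y)]

    def mirror_permutation(self) -> tuple[int, ...]:
        """``perm[i]`` = canonical index of the point homologous to the i-th
        point of the mirrored (left-eye) enumeration. Self-inverse."""
        return _mirror_permutation(self)


def _canonical_order(coords: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    # rows superior -> inferior, within row temporal (x<0) -> nasal (x>0)
    return sorted(coords, key=lambda c: (-c[1], c[0]))


@lru_cache(maxsize=None)
def _coord_index(pattern: TestPattern) -> dict[tuple[int, int], int]:
    return {(p.x, p.y): i for i, p in enumerate(pattern.points)}


@lru_cache(maxsize=None)
def _mirror_permutation(pattern: TestPattern) -> tuple[int, ...]:
    # The OS grid is {(-x, y)} enumerated in the same spatial order in OS field
    # coordinates; its i-th point maps to the canonical point at the negated x.
    os_coords = _canonical_order([(-p.x, p.y) for p in pattern.points])
    idx = _coord_index(pattern)
    return tuple(idx[(-x, y)] for (x, y) in os_coords)


def build_pattern(pattern_id: PatternId | str) -> TestPattern:
    """Construct a supported test pattern.

    Membership rules: 24-2 takes lattice points with both coordinates odd
    multiples of 3, ``|x| + |y| <= 30`` and ``|y| <= 21``, dropping the two
    temporal points at 27 degrees (the chart extends to 27 degrees only
    nasally, so rows run 4/6/8/9/9/8/6/4); 10-2 takes odd integer lattice
    points with ``x**2 + y**2 <= 89`` (17 per quadrant).

    Raises
    ------
    UnsupportedPatternError
        For any other identifier.
    """
    try:
        pid = PatternId(pattern_id)
    except ValueError:
        raise UnsupportedPatternError(f"unsupported test pattern: {pattern_id!r}")
    if pid is PatternId.P24_2:
        lattice = [o * 3 for o in (-9, -7, -5, -3, -1, 1, 3, 5, 7, 9)]
        coords = [
            (x, y)
            for x in lattice
            for y in lattice
            # chart extends to 27 deg only nasally: exclude temporal 27 and |y|>21
            if abs(x) + abs(y) <= 30 and abs(y) <= 21 and x != -27
        ]
        blind = {(-15, 3), (-15, -3)}
        spacing = 6
    else:
        odd = (-9, -7, -5, -3, -1, 1, 3, 5, 7, 9)
        coords = [(x, y) for x in odd for y in odd if x * x + y * y <= 89]
        blind = set()
        spacing = 2
    pts = tuple(
        GridPoint(x, y, (x, y) in blind) for x, y in _canonical_order(coords)
    )
    return TestPattern(pattern_id=pid, points=pts, spacing=spacing)


def eccentricity(point: GridPoint) -> float:
    """Euclidean distance of a point from fixation, in degrees."""
    return math.hypot(point.x, point.y)


def mirror_to_canonical(test: VFTestRecord, pattern: TestPattern | None = None) -> VFTestRecord:
    """Re-index a test record onto the canonical right-eye frame.

    Right-eye records are returned unchanged. For a left-eye record the value
    measured at field location ``(x, y)`` is moved to the canonical point
    ``(-x, y)``; applying the function twice returns the original record.

    Raises
    ------
    MalformedRecordError
        If the value list length does not match the pattern.
    """
    if pattern is None:
        pattern = build_pattern(test.pattern_id)
    if len(test.values) != pattern.n_points:
        raise MalformedRecordError(
            f"record has {len(test.values)} values, pattern "
            f"{pattern.pattern_id.value} has {pattern.n_points} points"
        )
    if test.eye is Eye.OD:
        return test
    perm = pattern.mirror_permutation()
    new_values = [0.0] * pattern.n_points
    for i, v in enumerate(test.values):
        new_values[perm[i]] = v
    return test.copy_with(values=new_values)


def pattern_to_json(pattern: TestPattern) -> str:
    """Serialize a pattern as self-describing JSON: the id, spacing, and the
    ordered ``[x, y, is_blind_spot]`` triples."""
    payload = {
        "pattern_id": pattern.pattern_id.value,
        "spacing": pattern.spacing,
        "points": [[p.x, p.y, bool(p.is_blind_spot)] for p in pattern.points],
    }
    return json.dumps(payload, indent=1)


def pattern_from_json(text: str) -> TestPattern:
    """Load a pattern from JSON, re-imposing canonical point order.

    This is the supported route for swapping in a vendor-exact 10-2 layout
    should one differ from the radial rule used here.
    """
    payload = json.loads(text)
    pid = PatternId(payload["pattern_id"])
    pts = tuple(
        GridPoint(int(x), int(y), bool(b))
        for x, y, b in sorted(payload["points"], key=lambda t: (-t[1], t[0]))
    )
    return TestPattern(pattern_id=pid, points=pts, spacing=int(payload["spacing"]))
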