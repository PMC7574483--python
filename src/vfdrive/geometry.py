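"""Perimetry test-pattern geometry: 24-2 / 30-2 grids, eccentricity rings,
blind-spot handling, and the eccentricity-weighted VFI weight matrix.

Coordinates are degrees of visual angle in visual-field space, the frame of a
Humphrey printout: +x is toward the subject's right, +y is superior.  Both
eyes share this frame, so a binocular overlay is coordinate-identical; only
the blind-spot column (temporal: x = +15 for OD, −15 for OS) and the nasal
extension of the 24-2 (x = −27 for OD, +27 for OS) differ between eyes.

The VFI weighting follows the five-concentric-ring convention in which the
four central points (|x| = |y| = 3) receive weight 3.29 and successive rings
receive 1.28, 0.79, 0.57 and 0.45, reflecting the cortical magnification of
central vision.  Ring boundaries are not standardized in print; the defaults
here place each 24-2 annulus in its own ring and are configurable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "Eye",
    "GridPoint",
    "TestPatternGrid",
    "WeightMatrix",
    "PatternError",
    "DEFAULT_RING_BOUNDARIES",
    "RING_WEIGHTS",
    "build_pattern",
    "assign_weights",
    "ring_of",
]


class PatternError(ValueError):
    """Raised for unknown patterns or geometry that violates the pattern rules."""


class Pattern(str, enum.Enum):
    """Supported Humphrey test patterns."""

    P24_2 = "24-2"
    P30_2 = "30-2"

    @classmethod
    def coerce(cls, value: "Pattern | str") -> "Pattern":
        if isinstance(value, cls):
            return value
        for member in cls:
            if value in (member.value, member.name):
                return member
        raise PatternError(f"unknown test pattern: {value!r} (expected 24-2 or 30-2)")


class Eye(str, enum.Enum):
    """Eye laterality: OD = right eye, OS = left eye."""

    OD = "OD"
    OS = "OS"

    @classmethod
    def coerce(cls, value: "Eye | str") -> "Eye":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise PatternError(f"unknown eye laterality: {value!r} (expected OD or OS)") from None

    @property
    def fellow(self) -> "Eye":
        return Eye.OS if self is Eye.OD else Eye.OD


#: Outer eccentricity (degrees) of rings 1–4; ring 5 is everything beyond.
DEFAULT_RING_BOUNDARIES: tuple[float, float, float, float] = (5.7, 12.8, 19.0, 25.5)

#: Per-ring VFI weights, central ring first.
RING_WEIGHTS: tuple[float, float, float, float, float] = (3.29, 1.28, 0.79, 0.57, 0.45)


def ring_of(eccentricity: float, boundaries: Sequence[float] = DEFAULT_RING_BOUNDARIES) -> int:
    """Map an eccentricity (degrees) to its concentric ring index (1-based).

    Boundaries are the outer edges of rings 1..len(boundaries); any location
    beyond the last boundary falls in the outermost ring.
    """
    bounds = list(boundaries)
    if len(bounds) != 4 or any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise PatternError(f"ring boundaries must be 4 strictly increasing values, got {boundaries!r}")
    if eccentricity < 0:
        raise PatternError("eccentricity must be non-negative")
    for idx, outer in enumerate(bounds, start=1):
        if eccentricity <= outer:
            return idx
    return len(bounds) + 1


@dataclass(frozen=True)
class GridPoint:
    """One tested location of a perimetry pattern."""

    x: float
    y: float
    eccentricity: float
    ring_index: int
    is_blind_spot: bool

    def __post_init__(self) -> None:
        if abs(self.eccentricity - math.hypot(self.x, self.y)) > 1e-9:
            raise PatternError(f"eccentricity of ({self.x},{self.y}) must equal sqrt(x²+y²)")


@dataclass(frozen=True)
class TestPatternGrid:
    """The tested locations of one eye's perimetry pattern.

    ``is_blind_spot`` marks the physiologic blind-spot column of ``eye``
    (temporal field, x = +15 for OD, −15 for OS, y = ±3).
    """

    pattern: Pattern
    eye: Eye
    points: tuple[GridPoint, ...]

    @property
    def n_locations(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    @property
    def eccentricity(self) -> np.ndarray:
        return np.array([p.eccentricity for p in self.points])

    @property
    def blind_spot_mask(self) -> np.ndarray:
        return np.array([p.is_blind_spot for p in self.points], dtype=bool)

    def mirror(self) -> "TestPatternGrid":
        """The fellow eye's grid: x → −x with blind-spot flags carried along."""
        pts = tuple(
            GridPoint(-p.x, p.y, p.eccentricity, p.ring_index, p.is_blind_spot)
            for p in self.points
        )
        return TestPatternGrid(self.pattern, self.eye.fellow, _sort_points(pts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_deg": [p.x for p in self.points],
                "y_deg": [p.y for p in self.points],
                "eccentricity_deg": [p.eccentricity for p in self.points],
                "ring": [p.ring_index for p in self.points],
                "blind_spot": [p.is_blind_spot for p in self.points],
            }
        )


@dataclass(frozen=True)
class WeightMatrix:
    """Per-location VFI weights for a grid (blind-spot locations carry 0)."""

    grid: TestPatternGrid
    weights: np.ndarray
    ring_weights: tuple[float, ...] = RING_WEIGHTS
    ring_boundaries: tuple[float, ...] = DEFAULT_RING_BOUNDARIES

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.n_locations,):
            raise PatternError("weights must align with grid locations")
        if np.any(w < 0):
            raise PatternError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def to_frame(self) -> pd.DataFrame:
        frame = self.grid.to_frame()[["x_deg", "y_deg", "ring"]].copy()
        frame["weight"] = self.weights
        return frame


def _sort_points(points: Sequence[GridPoint]) -> tuple[GridPoint, ...]:
    # superior-to-inferior rows, left-to-right within a row: printout order
    return tuple(sorted(points, key=lambda p: (-p.y, p.x)))


def _lattice(limit: int) -> list[tuple[int, int]]:
    coords = [c for c in range(-limit, limit + 1) if c % 6 == 3 or c % 6 == -3]
    return [(x, y) for y in coords for x in coords]


def build_pattern(
    pattern_id: Pattern | str,
    eye: Eye | str = Eye.OD,
    ring_boundaries: Sequence[float] = DEFAULT_RING_BOUNDARIES,
) -> TestPatternGrid:
    """Build the complete test grid of a pattern for one eye.

    The 24-2 covers the central 24° (30° nasally): 52 locations with
    |x|,|y| ≤ 21 and |x|+|y| ≤ 30 plus the two nasal points at 27° — 54 in
    total.  The 30-2 covers the central 30°: 76 locations with |x|,|y| ≤ 27
    and |x|+|y| ≤ 36.  Blind-spot flags are set for ``eye``.
    """
    pattern = Pattern.coerce(pattern_id)
    eye = Eye.coerce(eye)
    nasal_sign = -1 if eye is Eye.OD else +1
    if pattern is Pattern.P24_2:
        cells = [
            (x, y)
            for x, y in _lattice(21)
            if abs(x) + abs(y) <= 30
        ]
        cells += [(nasal_sign * 27, 3), (nasal_sign * 27, -3)]
    else:
        cells = [
            (x, y)
            for x, y in _lattice(27)
            if abs(x) + abs(y) <= 36
        ]
    blind_x = 15 if eye is Eye.OD else -15
    points = []
    for x, y in cells:
        ecc = math.hypot(x, y)
        points.append(
            GridPoint(
                x=float(x),
                y=float(y),
                eccentricity=ecc,
                ring_index=ring_of(ecc, ring_boundaries),
                is_blind_spot=(x == blind_x and abs(y) == 3),
            )
        )
    grid = TestPatternGrid(pattern, eye, _sort_points(points))
    if len({(p.x, p.y) for p in grid.points}) != grid.n_locations:
        raise PatternError("pattern grid contains duplicate coordinates")
    return grid


def assign_weights(
    grid: TestPatternGrid,
    ring_boundaries: Sequence[float] = DEFAULT_RING_BOUNDARIES,
    ring_weights: Sequence[float] = RING_WEIGHTS,
) -> WeightMatrix:
    """Assign the five-ring VFI weights to every location of ``grid``.

    Each non-blind-spot location receives its ring's weight; the blind-spot
    column receives 0 (a physiologic absolute scotoma carries no information
    about disease).  Every location must fall in exactly one ring, which the
    boundary convention guarantees because ring 5 is unbounded outward.
    """
    if len(ring_weights) != 5:
        raise PatternError("exactly five ring weights are required")
    weights = np.empty(grid.n_locations)
    for i, p in enumerate(grid.points):
        ring = ring_of(p.eccentricity, ring_boundaries)
        weights[i] = 0.0 if p.is_blind_spot else float(ring_weights[ring - 1])
    return WeightMatrix(
        grid=grid,
        weights=weights,
        ring_weights=tuple(float(w) for w in ring_weights),
        ring_boundaries=tuple(float(b) for b in ring_boundaries),
    )
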