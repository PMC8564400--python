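"""Honeycomb micropattern geometry.

The culture substrate is an array of cell-permissive hexagons (flat-top
orientation, edge length ``L``) separated by a uniform repulsive gap ``D``
measured perpendicular to facing flat edges.  Neighboring hexagon centers are
therefore ``sqrt(3)*L + D`` apart.  Patterns are addressed by axial
coordinates ``(q, r)`` on the hex lattice; positions falling in the gap map
to the :data:`OUTSIDE` sentinel.

Distances derived from the layout:

* ``apothem``  = (sqrt(3)/2) * L — center to flat edge of one hexagon
* ``spacing``  = sqrt(3)*L + D — center-to-center distance of edge neighbors
* ``l1``       = apothem + D — center to the *closest* edge of a nearest
  neighboring pattern
* ``l2``       = l1 + sqrt(3)*L — center to the *farthest* edge of that
  neighbor
* ``r1``, ``r2`` — radii of circles covering the first and second neighbor
  rings (``spacing + L`` and ``sqrt(3)*spacing + L``)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

SQRT3 = math.sqrt(3.0)


class InvalidSpecError(ValueError):
    """Raised for geometrically impossible lattice parameters."""


class _Outside:
    """Sentinel for positions not inside any pattern (the repulsive gap)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "OUTSIDE"

    def __bool__(self) -> bool:
        return False


OUTSIDE = _Outside()

#: pattern_id used for OUTSIDE in exported tables
OUTSIDE_ID = -1


class PatternIndex(NamedTuple):
    """Axial (q, r) address of one hexagonal pattern."""

    q: int
    r: int


# Axial step vectors to the six edge neighbors of a flat-top hexagon.
AXIAL_NEIGHBORS = (
    PatternIndex(1, 0),
    PatternIndex(1, -1),
    PatternIndex(0, -1),
    PatternIndex(-1, 0),
    PatternIndex(-1, 1),
    PatternIndex(0, 1),
)


def hex_distance(a: PatternIndex, b: PatternIndex) -> int:
    """Lattice (hop) distance between two axial indices."""
    dq, dr = a.q - b.q, a.r - b.r
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the hexagonal pattern array.

    Parameters
    ----------
    edge_length_L
        Hexagon edge length in μm (also the circumradius of a hexagon).
    gap_D
        Perpendicular gap between facing flat edges of adjacent hexagons, μm.
    origin
        Cartesian position (μm) of the center of pattern (0, 0).
    rotation
        Counter-clockwise rotation of the whole array, degrees.
    rows, cols
        Extent of the array in the offset (row, col) enumeration.
    """

    edge_length_L: float
    gap_D: float
    origin: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    rows: int = 10
    cols: int = 10

    def __post_init__(self) -> None:
        if self.edge_length_L <= 0:
            raise InvalidSpecError(f"edge_length_L must be > 0, got {self.edge_length_L}")
        if self.gap_D < 0:
            raise InvalidSpecError(f"gap_D must be >= 0, got {self.gap_D}")
        if self.rows < 1 or self.cols < 1:
            raise InvalidSpecError("rows and cols must be positive")

    # -- derived scalars ---------------------------------------------------
    @property
    def apothem(self) -> float:
        return SQRT3 / 2.0 * self.edge_length_L

    @property
    def spacing(self) -> float:
        """Center-to-center distance between edge-adjacent hexagons."""
        return SQRT3 * self.edge_length_L + self.gap_D

    @property
    def _cell_size(self) -> float:
        # circumradius of the *lattice* cell (hexagon + its share of gap)
        return self.spacing / SQRT3

    @property
    def n_patterns(self) -> int:
        return self.rows * self.cols

    # -- index bookkeeping -------------------------------------------------
    def offset_of(self, idx: PatternIndex) -> tuple[int, int]:
        """(row, col) of an axial index in the odd-q vertical layout."""
        col = idx.q
        row = idx.r + (idx.q - (idx.q & 1)) // 2
        return row, col

    def index_at(self, row: int, col: int) -> PatternIndex:
        q = col
        r = row - (col - (col & 1)) // 2
        return PatternIndex(q, r)

    def in_bounds(self, idx) -> bool:
        if idx is OUTSIDE:
            return False
        row, col = self.offset_of(idx)
        return 0 <= row < self.rows and 0 <= col < self.cols

    def serial_id(self, idx: PatternIndex) -> int:
        """1-based pattern id for exported tables (row-major over the array)."""
        row, col = self.offset_of(idx)
        return row * self.cols + col + 1

    def index_of_serial(self, pattern_id: int) -> PatternIndex:
        if not 1 <= pattern_id <= self.n_patterns:
            raise InvalidSpecError(f"pattern_id {pattern_id} out of range")
        row, col = divmod(pattern_id - 1, self.cols)
        return self.index_at(row, col)

    def all_indices(self) -> Iterator[PatternIndex]:
        for row in range(self.rows):
            for col in range(self.cols):
                yield self.index_at(row, col)


def derive_distances(spec: LatticeSpec) -> dict[str, float]:
    """Closed-form distances of the pattern layout (all μm).

    ``l1``/``l2`` are the distances from a pattern center to the closest and
    farthest edge of a nearest neighboring pattern; ``r1``/``r2`` are radii
    of circles covering the first and second rings of neighbors.
    """
    L, D = spec.edge_length_L, spec.gap_D
    apothem = SQRT3 / 2.0 * L
    spacing = SQRT3 * L + D
    return {
        "apothem": apothem,
        "spacing": spacing,
        "l1": apothem + D,
        "l2": 3.0 * SQRT3 / 2.0 * L + D,
        "r1": spacing + L,
        "r2": SQRT3 * spacing + L,
    }


def _rotate(x: np.ndarray, y: np.ndarray, degrees: float):
    if degrees == 0.0:
        return x, y
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    return c * x - s * y, c * y + s * x


def hex_center(spec: LatticeSpec, idx: PatternIndex) -> tuple[float, float]:
    """Cartesian center (μm) of an in-bounds pattern."""
    if idx is OUTSIDE:
        raise InvalidSpecError("OUTSIDE has no center")
    if not spec.in_bounds(idx):
        raise InvalidSpecError(f"index {idx} outside the {spec.rows}x{spec.cols} array")
    return _center_unchecked(spec, idx)


def _center_unchecked(spec: LatticeSpec, idx: PatternIndex) -> tuple[float, float]:
    size = spec._cell_size
    x = 1.5 * size * idx.q
    y = SQRT3 * size * (idx.r + idx.q / 2.0)
    x, y = _rotate(np.float64(x), np.float64(y), spec.rotation)
    return float(x + spec.origin[0]), float(y + spec.origin[1])


def hexagon_vertices(center: tuple[float, float], edge: float, rotation: float = 0.0) -> np.ndarray:
    """Vertices (6, 2) of a flat-top hexagon, counter-clockwise from angle 0."""
    ang = np.radians(np.arange(6) * 60.0 + rotation)
    return np.column_stack(
        [center[0] + edge * np.cos(ang), center[1] + edge * np.sin(ang)]
    )


def _in_hexagon(dx: float, dy: float, edge: float, tol: float = 1e-9) -> bool:
    # flat-top hexagon around the origin: three half-plane pairs
    a = SQRT3 / 2.0 * edge
    return (
        abs(dy) <= a + tol
        and abs(SQRT3 / 2.0 * dx + 0.5 * dy) <= a + tol
        and abs(SQRT3 / 2.0 * dx - 0.5 * dy) <= a + tol
    )


def _axial_round(qf: float, rf: float) -> PatternIndex:
    # cube-coordinate rounding
    sf = -qf - rf
    q, r, s = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(s - sf)
    if dq > dr and dq > ds:
        q = -r - s
    elif dr > ds:
        r = -q - s
    return PatternIndex(int(q), int(r))


def point_to_pattern(spec: LatticeSpec, point: tuple[float, float]):
    """Map a Cartesian point (μm) to the pattern containing it, else OUTSIDE.

    Hexagon interiors are boundary-inclusive; a point on a shared boundary
    (possible only when ``gap_D == 0``) is assigned to the hexagon with the
    lowest serial id.  Points in the gap or off the array map to OUTSIDE.
    """
    x = point[0] - spec.origin[0]
    y = point[1] - spec.origin[1]
    x, y = _rotate(np.float64(x), np.float64(y), -spec.rotation)
    size = spec._cell_size
    qf = (2.0 / 3.0) * x / size
    rf = (-x / 3.0 + SQRT3 / 3.0 * y) / size
    base = _axial_round(qf, rf)

    candidates = [base] + [PatternIndex(base.q + d.q, base.r + d.r) for d in AXIAL_NEIGHBORS]
    hits = []
    for idx in candidates:
        if not spec.in_bounds(idx):
            continue
        cx = 1.5 * size * idx.q
        cy = SQRT3 * size * (idx.r + idx.q / 2.0)
        if _in_hexagon(float(x) - cx, float(y) - cy, spec.edge_length_L):
            hits.append(idx)
    if not hits:
        return OUTSIDE
    return min(hits, key=spec.serial_id)


def neighbor_shell(spec: LatticeSpec, idx: PatternIndex, shell: int) -> set[PatternIndex]:
    """In-bounds patterns within ``shell`` lattice hops of ``idx`` (excluding it).

    Shell 1 is the ≤6 edge-adjacent hexagons (those covered by a circle of
    radius ``r1``); shell 2 adds the next ring of ≤12 (radius ``r2``).
    """
    if not spec.in_bounds(idx):
        raise InvalidSpecError(f"index {idx} outside the array")
    if shell not in (1, 2):
        raise InvalidSpecError("shell must be 1 or 2")
    out: set[PatternIndex] = set()
    for dq in range(-shell, shell + 1):
        for dr in range(max(-shell, -dq - shell), min(shell, -dq + shell) + 1):
            if dq == 0 and dr == 0:
                continue
            cand = PatternIndex(idx.q + dq, idx.r + dr)
            if spec.in_bounds(cand):
                out.add(cand)
    return out


def pattern_table(spec: LatticeSpec) -> pd.DataFrame:
    """Table of all patterns: pattern_id, q, r, center coordinates (μm)."""
    rows = []
    for idx in spec.all_indices():
        cx, cy = _center_unchecked(spec, idx)
        rows.append((spec.serial_id(idx), idx.q, idx.r, cx, cy))
    return pd.DataFrame(rows, columns=["pattern_id", "q", "r", "center_x_um", "center_y_um"])
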