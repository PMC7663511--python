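"""Ideal zigzag carbon-nanotube coordinate generation.

A zigzag (n, 0) tube is a graphene sheet wrapped so that the sheet
circumference n * sqrt(3) * a_cc is preserved as arc length, giving the
exact diameter

    d = sqrt(3) * a_cc * n / pi

(a_cc = 0.142 nm is the C-C bond length). Because arc length, not chord
length, is preserved, nearest-neighbour chords on the cylinder are slightly
shorter than a_cc (a curvature effect below 2% for n >= 40); the benefit is
that the realized diameter is exactly the nominal one.

Atoms are organised in zigzag rings of 2n atoms. Each ring occupies two
axial levels a_cc/2 apart; consecutive rings are 3*a_cc/2 apart
(centroid-to-centroid), so the axial atom rows repeat with the period
3*a_cc and alternating gaps a_cc/2, a_cc. The per-atom ring index is kept
on the generated wall so downstream ring-based interior counting never has
to re-derive it.

Multi-wall tubes are coaxial stacks of single walls; each requested wall
diameter is realized by the nearest integer chirality
n = round(pi * d / (sqrt(3) * a_cc)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CC_BOND_NM, DEFAULT_TUBE_LENGTH_NM

__all__ = ["NanotubeSpec", "Wall", "build_zigzag", "build_mwcnt",
           "zigzag_diameter", "chirality_for_diameter"]

_MIN_CHIRALITY = 8  # below this the wrapped sheet self-intersects


def zigzag_diameter(n: int, a_cc: float = CC_BOND_NM) -> float:
    """Diameter (nm) of a zigzag (n, 0) tube: sqrt(3) * a_cc * n / pi."""
    return math.sqrt(3.0) * a_cc * n / math.pi


def chirality_for_diameter(diameter: float, a_cc: float = CC_BOND_NM) -> int:
    """Nearest zigzag index n realizing the requested diameter (nm)."""
    return round(math.pi * diameter / (math.sqrt(3.0) * a_cc))


@dataclass(frozen=True)
class NanotubeSpec:
    """Geometric specification of one zigzag wall.

    ``origin`` is the axial midpoint of the tube; ``axis`` the unit tube
    direction (default y, matching a 20 x 80 x 20 nm box with the tube
    along the long side).
    """

    chirality_n: int
    length: float = DEFAULT_TUBE_LENGTH_NM      # nm
    bond_length: float = CC_BOND_NM             # nm
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.chirality_n < _MIN_CHIRALITY:
            raise ValueError(
                f"chirality_n must be >= {_MIN_CHIRALITY} (self-intersecting wrap below), "
                f"got {self.chirality_n}"
            )
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.bond_length <= 0:
            raise ValueError(f"bond_length must be > 0, got {self.bond_length}")
        norm = math.sqrt(sum(a * a for a in self.axis))
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            if norm == 0:
                raise ValueError("axis must be a nonzero vector")
            object.__setattr__(self, "axis", tuple(a / norm for a in self.axis))

    @property
    def diameter(self) -> float:
        return zigzag_diameter(self.chirality_n, self.bond_length)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class Wall:
    """One generated wall: atom coordinates plus the ring index per atom."""

    positions: np.ndarray          # (M, 3) nm
    ring_index: np.ndarray         # (M,) int, 0-based, ordered along the axis
    spec: NanotubeSpec

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_rings(self) -> int:
        return int(self.ring_index.max()) + 1 if self.n_atoms else 0

    @property
    def radius(self) -> float:
        return self.spec.radius


def _rotation_to(axis: tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix taking the local +z axis onto ``axis`` (unit)."""
    a = np.asarray(axis, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(np.dot(z, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def build_zigzag(spec: NanotubeSpec) -> Wall:
    """Generate the atoms of one zigzag wall.

    Whole rings only: the smallest ring count whose axial extent reaches
    ``spec.length`` is generated, so the realized tube is never shorter
    than requested and never contains a partial ring. Atom count is
    2 * chirality_n * n_rings.
    """
    n = spec.chirality_n
    a = spec.bond_length
    r = spec.radius
    period = 1.5 * a                      # centroid-to-centroid ring spacing
    # extent of k rings: (k - 1) * 1.5 a + a / 2
    n_rings = max(1, math.ceil((spec.length - 0.5 * a) / period) + 1)

    j = np.arange(n)
    base = 2.0 * math.pi * j / n
    half = math.pi / n
    pos = np.empty((2 * n * n_rings, 3), dtype=float)
    ring_index = np.repeat(np.arange(n_rings), 2 * n)
    for k in range(n_rings):
        off = half if k % 2 else 0.0
        phi_a = base + off
        phi_b = phi_a + half
        z_a = k * period
        z_b = z_a + 0.5 * a
        rows = np.concatenate([
            np.column_stack([r * np.cos(phi_a), r * np.sin(phi_a), np.full(n, z_a)]),
            np.column_stack([r * np.cos(phi_b), r * np.sin(phi_b), np.full(n, z_b)]),
        ])
        pos[2 * n * k: 2 * n * (k + 1)] = rows

    # centre axially, rotate local z onto the requested axis, translate
    extent = (n_rings - 1) * period + 0.5 * a
    pos[:, 2] -= extent / 2.0
    rot = _rotation_to(spec.axis)
    pos = pos @ rot.T + np.asarray(spec.origin, dtype=float)
    return Wall(positions=pos, ring_index=ring_index, spec=spec)


def build_mwcnt(
    diameters,
    length: float = DEFAULT_TUBE_LENGTH_NM,
    a_cc: float = CC_BOND_NM,
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[Wall]:
    """Coaxial multi-wall tube from a strictly increasing diameter list (nm).

    Each wall's chirality is the nearest integer matching its requested
    diameter; all walls share axis, origin and length. Walls are returned
    innermost first.
    """
    diameters = [float(d) for d in diameters]
    if not diameters:
        raise ValueError("need at least one wall diameter")
    for d1, d2 in zip(diameters, diameters[1:]):
        if d2 <= d1:
            raise ValueError(f"diameters must be strictly increasing, got {d1} -> {d2}")
    walls = []
    for d in diameters:
        n = chirality_for_diameter(d, a_cc)
        walls.append(build_zigzag(NanotubeSpec(
            chirality_n=n, length=length, bond_length=a_cc, axis=axis, origin=origin,
        )))
    return walls
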