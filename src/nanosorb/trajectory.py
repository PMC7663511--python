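"""Configuration analysis for drug/nanotube systems.

Operates on point-reduced molecular configurations: every drug molecule is
its centre of mass (COM), the nanotube is a set of carbon-atom coordinates
per wall. Four quantities are computed per frame:

* aggregate partition — single-linkage clustering of molecule COMs under a
  distance cutoff, with the whole nanotube acting as one super-node linked
  to any molecule within a contact cutoff of any wall atom (disjoint-set
  union-find);
* aggregate count and mean size (drug molecules per aggregate; the
  nanotube super-node is never counted as a member);
* fraction of molecules adsorbed onto the tube (members of the
  tube-containing aggregate, or a plain contact-distance count);
* interior occupancy — the tube's innermost wall is decomposed into its
  parallel carbon rings and a molecule counts as "inside" when its COM
  falls in the union of spheres centred on the ring centroids (each
  molecule counted once, however many spheres contain it).

All molecule-molecule and molecule-atom distances use the minimum-image
convention under the periodic box; the nanotube itself is never wrapped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnt import Wall

__all__ = [
    "MolecularConfiguration",
    "AggregateReport",
    "Partition",
    "Ring",
    "DisjointSet",
    "minimum_image",
    "cluster_molecules",
    "aggregate_stats",
    "fraction_on_cnt",
    "decompose_rings",
    "count_inside",
    "analyze_trajectory",
]

DEFAULT_CLUSTER_CUTOFF = 1.0   # nm, COM-COM single-linkage criterion
DEFAULT_CONTACT_CUTOFF = 0.5   # nm, COM-to-wall-atom adsorption criterion
DEFAULT_SPHERE_FACTOR = 0.9    # interior sphere radius as a fraction of the inner wall radius
AXIAL_TOLERANCE = 0.05         # nm, ring grouping tolerance along the axis


# ------------------------------------------------------------------ containers

@dataclass(frozen=True)
class MolecularConfiguration:
    """One frame: drug COMs, nanotube walls, periodic box, time stamp."""

    dox_positions: np.ndarray               # (N, 3) nm
    cnt_walls: tuple[Wall, ...] = ()        # innermost wall first
    box: tuple[float, float, float] = (20.0, 80.0, 20.0)  # nm
    time: float = 0.0                       # ns

    def __post_init__(self) -> None:
        pos = np.asarray(self.dox_positions, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "dox_positions", pos)
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite molecule coordinates")
        object.__setattr__(self, "cnt_walls", tuple(self.cnt_walls))
        for w in self.cnt_walls:
            if not np.all(np.isfinite(w.positions)):
                raise ValueError("non-finite wall coordinates")
        if any(b <= 0 for b in self.box):
            raise ValueError(f"box lengths must be > 0, got {self.box}")
        radii = [w.spec.radius for w in self.cnt_walls]
        if radii and radii != sorted(radii):
            raise ValueError("walls must be ordered innermost first")

    @property
    def n_molecules(self) -> int:
        return int(self.dox_positions.shape[0])


@dataclass(frozen=True)
class Partition:
    """Aggregate partition of one frame.

    ``labels[i]`` is the aggregate id of molecule i (ids are dense,
    0..n_aggregates-1); ``cnt_label`` is the id of the aggregate containing
    the nanotube super-node, or None when no molecule touches the tube (or
    there is no tube).
    """

    labels: np.ndarray
    cnt_label: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_molecules(self) -> int:
        return int(self.labels.size)

    @property
    def n_aggregates(self) -> int:
        return int(np.unique(self.labels).size) if self.labels.size else 0

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


@dataclass(frozen=True)
class Ring:
    """One carbon ring of a wall: member atom indices and their centroid."""

    members: np.ndarray   # atom indices into the wall
    centroid: np.ndarray  # (3,) nm


@dataclass(frozen=True)
class AggregateReport:
    """Per-frame aggregation metrics (fractions as percentages of all molecules)."""

    time: float
    n_aggregates: int
    mean_aggregate_size: float
    fraction_on_cnt: float
    fraction_inside_cnt: float
    aggregate_membership: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.aggregate_membership)
        if n > 0 and self.n_aggregates < 1:
            raise ValueError("n_aggregates must be >= 1 when any molecule exists")
        labels = set(self.aggregate_membership)
        if len(labels) != self.n_aggregates:
            raise ValueError(
                f"membership labels ({len(labels)}) inconsistent with "
                f"n_aggregates ({self.n_aggregates})"
            )
        if not (0.0 <= self.fraction_inside_cnt <= self.fraction_on_cnt <= 100.0 + 1e-9):
            raise ValueError(
                "fractions must satisfy 0 <= inside <= on <= 100, got "
                f"inside={self.fraction_inside_cnt}, on={self.fraction_on_cnt}"
            )
        if n > 0 and not math.isclose(self.mean_aggregate_size * self.n_aggregates, n,
                                      rel_tol=1e-9):
            raise ValueError("aggregate sizes must sum to the number of molecules")

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "n_aggregates": self.n_aggregates,
            "mean_aggregate_size": self.mean_aggregate_size,
            "fraction_on_cnt": self.fraction_on_cnt,
            "fraction_inside_cnt": self.fraction_inside_cnt,
            "aggregate_membership": list(self.aggregate_membership),
        }

    @classmethod
    def from_dict(cls, d) -> "AggregateReport":
        return cls(
            time=float(d["time"]),
            n_aggregates=int(d["n_aggregates"]),
            mean_aggregate_size=float(d["mean_aggregate_size"]),
            fraction_on_cnt=float(d["fraction_on_cnt"]),
            fraction_inside_cnt=float(d["fraction_inside_cnt"]),
            aggregate_membership=tuple(int(x) for x in d["aggregate_membership"]),
        )


# ------------------------------------------------------------------- distances

def minimum_image(delta: np.ndarray, box) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def _pairwise_mic_distances(pos: np.ndarray, box) -> np.ndarray:
    delta = pos[:, None, :] - pos[None, :, :]
    delta = minimum_image(delta, box)
    return np.sqrt((delta**2).sum(axis=-1))


def _min_dist_to_atoms(points: np.ndarray, atoms: np.ndarray, box) -> np.ndarray:
    """Per point, the minimum-image distance to the nearest atom."""
    out = np.empty(points.shape[0])
    for i, p in enumerate(points):
        d = minimum_image(atoms - p, box)
        out[i] = np.sqrt((d**2).sum(axis=1).min())
    return out


# ------------------------------------------------------------------ clustering

class DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


def cluster_molecules(
    config: MolecularConfiguration,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> Partition:
    """Single-linkage aggregate partition of the molecules in one frame.

    Two molecules belong to the same aggregate when a chain of COM-COM
    distances < ``cutoff`` links them (minimum image). When the frame has a
    nanotube, it participates as one super-node linked to every molecule
    within ``contact_cutoff`` of any wall atom.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    n = config.n_molecules
    if n == 0:
        return Partition(labels=np.empty(0, dtype=int), cnt_label=None)

    has_cnt = bool(config.cnt_walls)
    ds = DisjointSet(n + 1 if has_cnt else n)

    dist = _pairwise_mic_distances(config.dox_positions, config.box)
    ii, jj = np.nonzero(np.triu(dist < cutoff, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ds.union(i, j)

    if has_cnt:
        if contact_cutoff <= 0:
            raise ValueError(f"contact_cutoff must be > 0, got {contact_cutoff}")
        atoms = np.vstack([w.positions for w in config.cnt_walls])
        near = _min_dist_to_atoms(config.dox_positions, atoms, config.box) < contact_cutoff
        for i in np.nonzero(near)[0].tolist():
            ds.union(i, n)  # node n is the nanotube

    roots = [ds.find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = relabel.setdefault(r, len(relabel))
    cnt_label = None
    if has_cnt:
        cnt_root = ds.find(n)
        cnt_label = relabel.get(cnt_root)  # None when no molecule touches the tube
    return Partition(labels=labels, cnt_label=cnt_label)


def aggregate_stats(partition: Partition) -> tuple[int, float]:
    """(number of aggregates, mean molecules per aggregate).

    Counts only aggregates that contain molecules; the nanotube super-node
    is never a member, so a bare tube contributes no aggregate.
    """
    n = partition.n_molecules
    if n == 0:
        return 0, 0.0
    k = partition.n_aggregates
    return k, n / k


def fraction_on_cnt(
    config: MolecularConfiguration,
    partition: Partition | None = None,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: str = "cluster",
) -> float:
    """Percentage of molecules adsorbed onto the nanotube.

    mode "cluster": members of the tube-containing aggregate (requires
    ``partition``); mode "contact": molecules within ``contact_cutoff`` of
    any wall atom.
    """
    n = config.n_molecules
    if n == 0:
        return 0.0
    if mode == "cluster":
        if partition is None:
            partition = cluster_molecules(config, contact_cutoff=contact_cutoff)
        if partition.cnt_label is None:
            return 0.0
        return 100.0 * float((partition.labels == partition.cnt_label).sum()) / n
    if mode == "contact":
        if not config.cnt_walls:
            return 0.0
        atoms = np.vstack([w.positions for w in config.cnt_walls])
        near = _min_dist_to_atoms(config.dox_positions, atoms, config.box) < contact_cutoff
        return 100.0 * float(near.sum()) / n
    raise ValueError(f"mode must be 'cluster' or 'contact', got {mode!r}")


# ---------------------------------------------------------- interior occupancy

def decompose_rings(
    wall: Wall | np.ndarray,
    axis: Sequence[float] = (0.0, 1.0, 0.0),
    tol: float = AXIAL_TOLERANCE,
) -> list[Ring]:
    """Split a wall into its parallel carbon rings, ordered along the axis.

    A generated :class:`~nanosorb.cnt.Wall` carries its ring index and is
    grouped by it directly. A bare coordinate array is grouped by axial
    coordinate: atoms whose axial gaps are within ``tol`` share a ring; an
    atom isolated by a larger gap, or a group spreading beyond ``tol``,
    raises with the offending axial gap named.
    """
    if isinstance(wall, Wall):
        pos = wall.positions
        rings: list[Ring] = []
        for k in range(wall.n_rings):
            members = np.nonzero(wall.ring_index == k)[0]
            rings.append(Ring(members=members, centroid=pos[members].mean(axis=0)))
        a = np.asarray(wall.spec.axis, dtype=float)
        rings.sort(key=lambda r: float(r.centroid @ a))
        return rings

    pos = np.asarray(wall, dtype=float).reshape(-1, 3)
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = pos @ a
    order = np.argsort(z)
    groups: list[list[int]] = [[int(order[0])]]
    for idx in order[1:]:
        gap = z[idx] - z[groups[-1][-1]]
        if gap <= tol:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    rings = []
    for g in groups:
        zg = z[g]
        spread = float(zg.max() - zg.min())
        if len(g) < 2:
            prev_gap = min(
                (abs(float(z[i] - z[g[0]])) for i in order if i not in g),
                default=float("inf"),
            )
            raise ValueError(
                f"atom at axial coordinate {float(z[g[0]]):.4f} nm is isolated "
                f"(nearest axial gap {prev_gap:.4f} nm exceeds tolerance {tol} nm); "
                "wall is not partitionable into rings"
            )
        if spread > tol:
            raise ValueError(
                f"ring group with axial spread {spread:.4f} nm exceeds the "
                f"{tol} nm tolerance; wall is not partitionable into rings"
            )
        members = np.asarray(sorted(g), dtype=int)
        rings.append(Ring(members=members, centroid=pos[members].mean(axis=0)))
    rings.sort(key=lambda r: float(r.centroid @ a))
    return rings


def _innermost_radius(config: MolecularConfiguration) -> float:
    if not config.cnt_walls:
        raise ValueError("configuration has no nanotube walls")
    return config.cnt_walls[0].spec.radius


def count_inside(
    config: MolecularConfiguration,
    rings: Sequence[Ring],
    sphere_radius: float,
) -> tuple[int, np.ndarray]:
    """Molecules inside the tube channel, via the union-of-spheres criterion.

    One sphere of ``sphere_radius`` sits on each ring centroid; a molecule
    is inside when its COM falls in at least one sphere, and is counted
    once no matter how many spheres contain it. Returns (count, sorted
    member indices).
    """
    r_in = _innermost_radius(config)
    if not (0.0 < sphere_radius < r_in):
        raise ValueError(
            f"sphere_radius must lie in (0, inner wall radius {r_in:.4f}), "
            f"got {sphere_radius}"
        )
    if config.n_molecules == 0 or not rings:
        return 0, np.empty(0, dtype=int)
    centroids = np.vstack([r.centroid for r in rings])
    inside = np.zeros(config.n_molecules, dtype=bool)
    for i, p in enumerate(config.dox_positions):
        d = minimum_image(centroids - p, config.box)
        if float((d**2).sum(axis=1).min()) < sphere_radius**2:
            inside[i] = True
    members = np.nonzero(inside)[0]
    return int(members.size), members


# ------------------------------------------------------------------ trajectory

def _frame_report(
    config: MolecularConfiguration,
    cluster_cutoff: float,
    contact_cutoff: float,
    sphere_radius: float | None,
    mode: str,
) -> AggregateReport:
    n = config.n_molecules
    if n == 0:
        return AggregateReport(
            time=config.time, n_aggregates=0, mean_aggregate_size=0.0,
            fraction_on_cnt=0.0, fraction_inside_cnt=0.0, aggregate_membership=(),
        )
    part = cluster_molecules(config, cluster_cutoff, contact_cutoff)
    labels = part.labels.copy()
    cnt_label = part.cnt_label

    interior = np.empty(0, dtype=int)
    if config.cnt_walls:
        rings = decompose_rings(config.cnt_walls[0])
        sr = sphere_radius if sphere_radius is not None else DEFAULT_SPHERE_FACTOR * _innermost_radius(config)
        _, interior = count_inside(config, rings, sr)

    # Molecules inside the channel are adsorbed in the tube by definition:
    # merge their aggregates into the tube-containing one so that the
    # interior set is always a subset of the "on tube" set.
    if interior.size:
        if cnt_label is None:
            cnt_label = int(labels.max()) + 1
        for m in interior.tolist():
            old = labels[m]
            if old != cnt_label:
                labels[labels == old] = cnt_label
    # canonical dense labels: numbered by first occurrence in molecule order
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(int(x), len(remap)) for x in labels], dtype=int)
    cnt_dense = remap.get(int(cnt_label)) if cnt_label is not None else None

    k = len(remap)
    if mode == "cluster":
        on = 0 if cnt_dense is None else int((labels == cnt_dense).sum())
    elif mode == "contact":
        if config.cnt_walls:
            atoms = np.vstack([w.positions for w in config.cnt_walls])
            near = _min_dist_to_atoms(config.dox_positions, atoms, config.box) < contact_cutoff
        else:
            near = np.zeros(n, dtype=bool)
        near[interior] = True
        on = int(near.sum())
    else:
        raise ValueError(f"mode must be 'cluster' or 'contact', got {mode!r}")

    return AggregateReport(
        time=config.time,
        n_aggregates=k,
        mean_aggregate_size=n / k,
        fraction_on_cnt=100.0 * on / n,
        fraction_inside_cnt=100.0 * interior.size / n,
        aggregate_membership=tuple(labels.tolist()),
    )


def analyze_trajectory(
    frames: Sequence[MolecularConfiguration],
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    sphere_radius: float | None = None,
    mode: str = "cluster",
    csv_path=None,
) -> list[AggregateReport]:
    """Per-frame aggregation metrics for a whole trajectory, in time order.

    ``sphere_radius`` defaults to 0.9 x the innermost wall radius. When
    ``csv_path`` is given, a tidy per-frame CSV time series is written.
    """
    reports = [
        _frame_report(f, cluster_cutoff, contact_cutoff, sphere_radius, mode)
        for f in frames
    ]
    if csv_path is not None:
        df = pd.DataFrame([
            {k: v for k, v in r.to_dict().items() if k != "aggregate_membership"}
            for r in reports
        ])
        df.to_csv(csv_path, index=False)
    return reports
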