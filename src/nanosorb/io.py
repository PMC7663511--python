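"""Readers and writers: CSV measurement tables, multi-frame XYZ, JSON.

CSV tables are strict about column names: ``Ce,qe`` for isotherm data,
``t,qt`` (capacities) or ``t,Ct`` (raw concentrations, converted through
the batch mass balance) for kinetic data.

The XYZ dialect is the standard one (atom count line, comment line, then
``element x y z``), with the comment line carrying ``time=<ns>`` and
``box=<x>,<y>,<z>``; nanotube carbons are element ``C`` and point-reduced
drug molecules element ``X``. Wall boundaries and per-atom ring indices do
not fit in XYZ, so they travel in a sidecar JSON written next to the
trajectory; reading without the sidecar reconstructs a single wall with a
geometry estimated from the coordinates.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnt import NanotubeSpec, Wall, chirality_for_diameter
from .datatypes import BatchExperiment, IsothermDataset, KineticDataset
from .trajectory import MolecularConfiguration
from .uptake import capacity_at_time

__all__ = [
    "read_isotherm_csv", "write_isotherm_csv",
    "read_kinetic_csv", "write_kinetic_csv",
    "write_xyz", "read_xyz",
    "save_json", "load_json",
]


# ------------------------------------------------------------------------- CSV

def read_isotherm_csv(path, temperature: float = 298.15) -> IsothermDataset:
    """Read an equilibrium table with exactly the columns ``Ce,qe``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["Ce", "qe"]:
        raise ValueError(
            f"isotherm CSV must have exactly the columns ['Ce', 'qe'], got {list(df.columns)}"
        )
    return IsothermDataset(ce=tuple(df["Ce"]), qe=tuple(df["qe"]), temperature=temperature)


def write_isotherm_csv(data: IsothermDataset, path) -> None:
    pd.DataFrame({"Ce": data.ce, "qe": data.qe}).to_csv(path, index=False)


def read_kinetic_csv(
    path,
    qe_exp: float | None = None,
    volume: float | None = None,
    mass: float | None = None,
    c0: float | None = None,
) -> KineticDataset:
    """Read a kinetic table with columns ``t,qt`` or ``t,Ct``.

    A ``t,Ct`` table holds raw solution concentrations and requires the
    batch descriptors (``volume`` mL, ``mass`` g, ``c0`` mg mL^-1) to
    convert each row through qt = V (C0 - Ct) / m.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == ["t", "qt"]:
        return KineticDataset(t=tuple(df["t"]), qt=tuple(df["qt"]), qe_exp=qe_exp)
    if cols == ["t", "Ct"]:
        if volume is None or mass is None or c0 is None:
            raise ValueError("a (t, Ct) table needs volume, mass and c0 to convert to qt")
        qt = [
            capacity_at_time(BatchExperiment(
                total_volume=volume, adsorbent_mass=mass,
                initial_concentration=c0, measured_concentration=ct, time=t,
            ))
            for t, ct in zip(df["t"], df["Ct"])
        ]
        return KineticDataset(t=tuple(df["t"]), qt=tuple(qt), qe_exp=qe_exp)
    raise ValueError(
        f"kinetic CSV must have exactly the columns ['t', 'qt'] or ['t', 'Ct'], got {cols}"
    )


def write_kinetic_csv(data: KineticDataset, path) -> None:
    pd.DataFrame({"t": data.t, "qt": data.qt}).to_csv(path, index=False)


# ------------------------------------------------------------------------- XYZ

def write_xyz(frames: Sequence[MolecularConfiguration], path, sidecar_path=None) -> None:
    """Write a multi-frame XYZ trajectory (and optionally the wall sidecar)."""
    frames = list(frames)
    with open(path, "w") as fh:
        for frame in frames:
            n_wall = sum(w.n_atoms for w in frame.cnt_walls)
            n = n_wall + frame.n_molecules
            bx, by, bz = frame.box
            fh.write(f"{n}\n")
            fh.write(f"time={frame.time:.6f} box={bx:.6f},{by:.6f},{bz:.6f}\n")
            for w in frame.cnt_walls:
                for x, y, z in w.positions:
                    fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
            for x, y, z in frame.dox_positions:
                fh.write(f"X {x:.6f} {y:.6f} {z:.6f}\n")
    if sidecar_path is not None and frames:
        walls = frames[0].cnt_walls
        sidecar = {
            "walls": [
                {
                    "n_atoms": w.n_atoms,
                    "ring_index": w.ring_index.tolist(),
                    "spec": {
                        "chirality_n": w.spec.chirality_n,
                        "length": w.spec.length,
                        "bond_length": w.spec.bond_length,
                        "axis": list(w.spec.axis),
                        "origin": list(w.spec.origin),
                    },
                }
                for w in walls
            ]
        }
        Path(sidecar_path).write_text(json.dumps(sidecar))


def _parse_comment(line: str) -> tuple[float, tuple[float, float, float]]:
    time, box = 0.0, (20.0, 80.0, 20.0)
    for token in line.split():
        if token.startswith("time="):
            time = float(token[5:])
        elif token.startswith("box="):
            parts = token[4:].split(",")
            box = (float(parts[0]), float(parts[1]), float(parts[2]))
    return time, box


def _estimate_wall(positions: np.ndarray) -> Wall:
    """Single wall from bare carbon coordinates: tube along y assumed,
    chirality estimated from the mean radial distance, ring indices from
    axial grouping."""
    center = positions.mean(axis=0)
    radial = positions[:, [0, 2]] - center[[0, 2]]
    radius = float(np.sqrt((radial**2).sum(axis=1)).mean())
    spec = NanotubeSpec(
        chirality_n=max(8, chirality_for_diameter(2.0 * radius)),
        length=float(np.ptp(positions[:, 1])) or 1.0,
        axis=(0.0, 1.0, 0.0),
        origin=tuple(center),
    )
    z = positions[:, 1]
    order = np.argsort(z)
    ring_index = np.empty(len(z), dtype=int)
    ring, z_prev = 0, z[order[0]]
    for idx in order:
        if z[idx] - z_prev > 0.05:
            ring += 1
        ring_index[idx] = ring
        z_prev = z[idx]
    return Wall(positions=positions, ring_index=ring_index, spec=spec)


def read_xyz(path, sidecar_path=None) -> list[MolecularConfiguration]:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    sidecar = None
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
    frames: list[MolecularConfiguration] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            time, box = _parse_comment(fh.readline())
            elements, coords = [], []
            for _ in range(n):
                parts = fh.readline().split()
                elements.append(parts[0])
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            coords = np.asarray(coords, dtype=float).reshape(-1, 3)
            is_c = np.array([e == "C" for e in elements])
            wall_pos = coords[is_c]
            dox_pos = coords[~is_c]
            walls: tuple[Wall, ...] = ()
            if wall_pos.size:
                if sidecar is not None:
                    walls_list = []
                    offset = 0
                    for wd in sidecar["walls"]:
                        m = wd["n_atoms"]
                        walls_list.append(Wall(
                            positions=wall_pos[offset:offset + m],
                            ring_index=np.asarray(wd["ring_index"], dtype=int),
                            spec=NanotubeSpec(
                                chirality_n=wd["spec"]["chirality_n"],
                                length=wd["spec"]["length"],
                                bond_length=wd["spec"]["bond_length"],
                                axis=tuple(wd["spec"]["axis"]),
                                origin=tuple(wd["spec"]["origin"]),
                            ),
                        ))
                        offset += m
                    walls = tuple(walls_list)
                else:
                    walls = (_estimate_wall(wall_pos),)
            frames.append(MolecularConfiguration(
                dox_positions=dox_pos, cnt_walls=walls, box=box, time=time,
            ))
    return frames


# ------------------------------------------------------------------------ JSON

def save_json(obj, path) -> None:
    """Serialize a domain object (anything with ``to_dict``) or plain dict."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def load_json(path):
    return json.loads(Path(path).read_text())
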