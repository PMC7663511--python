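"""Synthetic inputs with known ground truth.

Every generator here emulates one class of input the analysis consumes:

* measurement series (isotherm / kinetic) drawn from the direct model
  forms with multiplicative lognormal noise — concentrations and
  capacities are positive, so noise enters as qt * exp(eps),
  eps ~ Normal(0, sd);
* planted molecular configurations — molecules placed inside the tube
  channel, adsorbed on the outer wall, and in free-standing clusters, with
  separations chosen so the planted partition is the unique answer under
  the analysis cutoffs; the returned ground truth is exact by construction;
* a toy sticky-aggregation dynamics: free clusters take Brownian steps in
  a periodic box and merge irreversibly on contact, qualitatively
  reproducing the fast decay of the aggregate count seen in
  diffusion-limited aggregation.

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .cnt import NanotubeSpec, Wall, build_zigzag
from .constants import (
    CARBON_MOLAR_MASS,
    DEFAULT_BOX_NM,
    DOX_CNT_MASS_RATIO,
    DOX_MOLAR_MASS_FREE_BASE,
    SAMPLING_TIMES_MIN,
)
from .datatypes import IsothermDataset, KineticDataset
from .isotherms import freundlich_qe, langmuir_qe, temkin_qe
from .kinetics import elovich_qt, fractional_power_qt, pseudo_first_qt, pseudo_second_qt
from .trajectory import (
    DEFAULT_CLUSTER_CUTOFF,
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_SPHERE_FACTOR,
    AggregateReport,
    MolecularConfiguration,
    minimum_image,
)

__all__ = [
    "gen_isotherm",
    "gen_kinetics",
    "plant_configuration",
    "toy_aggregation",
    "dox_count_for_mass_ratio",
    "intraparticle_qt",
]

_PLACEMENT_ATTEMPTS = 500


# ------------------------------------------------------------- measurement data

def gen_isotherm(
    model: str,
    params: Mapping[str, float],
    ce_grid: Sequence[float],
    noise_sd_relative: float = 0.01,
    seed: int | None = None,
    temperature: float = 298.15,
) -> tuple[IsothermDataset, dict]:
    """Equilibrium series from a named isotherm model plus lognormal noise.

    ``params``: freundlich {kF, 1/n}; langmuir {qmax, KL};
    temkin {b, kT}. Returns the dataset and a ground-truth record.
    """
    ce = np.asarray(ce_grid, dtype=float)
    if np.any(ce <= 0):
        raise ValueError("all Ce grid values must be > 0")
    if model == "freundlich":
        qe = freundlich_qe(ce, params["kF"], params["1/n"])
    elif model == "langmuir":
        qe = langmuir_qe(ce, params["qmax"], params["KL"])
    elif model == "temkin":
        qe = temkin_qe(ce, params["b"], params["kT"], temperature)
    else:
        raise ValueError(f"unknown isotherm model {model!r}")
    if np.any(qe <= 0):
        raise ValueError("model curve is non-positive on the requested grid")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd_relative, size=ce.size) if noise_sd_relative > 0 else np.zeros(ce.size)
    data = IsothermDataset(ce=tuple(ce), qe=tuple(qe * np.exp(eps)), temperature=temperature)
    truth = {"model": model, "params": dict(params),
             "noise_sd_relative": noise_sd_relative, "temperature": temperature,
             "seed": seed}
    return data, truth


def intraparticle_qt(t, k1: float, c1: float, k2: float, c2: float) -> np.ndarray:
    """Continuous two-stage diffusion curve in sqrt(t).

    The two lines ki * sqrt(t) + Ci meet at sqrt(t*) = (C2 - C1)/(k1 - k2);
    the first line applies up to t*, the second after, so the curve is
    continuous with a kink at t*.
    """
    if k1 == k2:
        raise ValueError("segment slopes must differ to induce a breakpoint")
    s_star = (c2 - c1) / (k1 - k2)
    if s_star < 0:
        raise ValueError("the two lines cross at negative sqrt(t); no admissible breakpoint")
    s = np.sqrt(np.asarray(t, dtype=float))
    return np.where(s <= s_star, k1 * s + c1, k2 * s + c2)


def gen_kinetics(
    model: str,
    params: Mapping[str, float],
    t_points: Sequence[float] = SAMPLING_TIMES_MIN,
    noise_sd_relative: float = 0.01,
    seed: int | None = None,
) -> tuple[KineticDataset, dict]:
    """Time course from a named kinetic model plus lognormal noise.

    ``params``: pseudo_first {qe, k1}; pseudo_second {qe, k2};
    elovich {alpha, beta} (full integrated form (1/beta) ln(1 + alpha beta t));
    elovich_simplified {alpha, beta} (the large-t linear-in-ln-t form the
    classical plot fits); fractional_power {KFP, v};
    intraparticle {k1, C1, k2, C2} (continuous two-stage sqrt(t) curve).
    The dataset's ``qe_exp`` is filled from ``params["qe"]`` when present.
    """
    t = np.asarray(t_points, dtype=float)
    if model == "pseudo_first":
        qt = pseudo_first_qt(t, params["qe"], params["k1"])
    elif model == "pseudo_second":
        qt = pseudo_second_qt(t, params["qe"], params["k2"])
    elif model == "elovich":
        qt = elovich_qt(t, params["alpha"], params["beta"])
    elif model == "elovich_simplified":
        if np.any(t <= 0):
            raise ValueError("the simplified Elovich form is undefined at t <= 0")
        a, b = params["alpha"], params["beta"]
        qt = np.log(a * b) / b + np.log(t) / b
    elif model == "fractional_power":
        qt = fractional_power_qt(t, params["KFP"], params["v"])
    elif model == "intraparticle":
        qt = intraparticle_qt(t, params["k1"], params["C1"], params["k2"], params["C2"])
    else:
        raise ValueError(f"unknown kinetic model {model!r}")
    if np.any(qt < 0):
        raise ValueError("model curve is negative on the requested time grid")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd_relative, size=t.size) if noise_sd_relative > 0 else np.zeros(t.size)
    qe_exp = params.get("qe")
    data = KineticDataset(t=tuple(t), qt=tuple(qt * np.exp(eps)),
                          qe_exp=None if qe_exp is None else float(qe_exp))
    truth = {"model": model, "params": dict(params),
             "noise_sd_relative": noise_sd_relative, "seed": seed}
    return data, truth


# --------------------------------------------------------------- configurations

def dox_count_for_mass_ratio(
    walls: Sequence[Wall],
    mass_ratio: float = DOX_CNT_MASS_RATIO,
    molar_mass: float = DOX_MOLAR_MASS_FREE_BASE,
) -> int:
    """Molecule count keeping drug:tube mass ratio fixed (free-base molar
    mass 543.52 g/mol by default)."""
    n_carbon = sum(w.n_atoms for w in walls)
    return round(mass_ratio * n_carbon * CARBON_MOLAR_MASS / molar_mass)


def _as_walls(tube, box) -> tuple[Wall, ...]:
    if tube is None:
        return ()
    center = tuple(b / 2.0 for b in box)
    if isinstance(tube, NanotubeSpec):
        spec = NanotubeSpec(
            chirality_n=tube.chirality_n, length=tube.length,
            bond_length=tube.bond_length, axis=tube.axis, origin=center,
        )
        return (build_zigzag(spec),)
    return tuple(tube)


def plant_configuration(
    tube,
    n_inside: int = 0,
    surface_clusters: Sequence[int] = (),
    free_clusters: Sequence[int] = (),
    min_separation: float | None = None,
    seed: int | None = None,
    box: Sequence[float] = DEFAULT_BOX_NM,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    sphere_radius: float | None = None,
    time: float = 0.0,
) -> tuple[MolecularConfiguration, AggregateReport]:
    """Plant molecules inside / on / away from a nanotube with exact truth.

    ``surface_clusters`` and ``free_clusters`` are per-cluster molecule
    counts. ``min_separation`` (default 2 x ``cluster_cutoff``) separates
    free clusters from everything else, guaranteeing that the analysis
    cutoffs recover exactly the planted partition. Molecule order in the
    configuration is inside, surface, free; ground-truth aggregate labels
    are numbered by first occurrence in that order (the tube aggregate,
    when populated, is label 0).

    Raises if a free cluster cannot be placed after bounded rejection
    sampling (box too crowded for the requested separations).
    """
    box = tuple(float(b) for b in box)
    if min_separation is None:
        min_separation = 2.0 * cluster_cutoff
    walls = _as_walls(tube, box)
    if (n_inside or surface_clusters) and not walls:
        raise ValueError("inside/surface placements need a nanotube")
    rng = np.random.default_rng(seed)
    center = np.array([b / 2.0 for b in box])

    positions: list[np.ndarray] = []
    labels: list[int] = []
    next_label = 0
    cnt_members = n_inside + int(sum(surface_clusters))
    cnt_label = 0 if cnt_members else None
    if cnt_members:
        next_label = 1

    if walls:
        inner = walls[0]
        outer = walls[-1]
        r_in = inner.spec.radius
        r_out = outer.spec.radius
        length = inner.spec.length
        axis = np.asarray(inner.spec.axis, dtype=float)
        sr = sphere_radius if sphere_radius is not None else DEFAULT_SPHERE_FACTOR * r_in
        # a radial frame perpendicular to the tube axis
        trial = np.array([1.0, 0.0, 0.0])
        if abs(float(trial @ axis)) > 0.9:
            trial = np.array([0.0, 0.0, 1.0])
        u = trial - (trial @ axis) * axis
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)

    # inside: well within the sphere-union region around the axis
    for _ in range(n_inside):
        rad = rng.uniform(0.0, 0.5 * sr)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        h = rng.uniform(-0.4 * length, 0.4 * length)
        positions.append(center + h * axis + rad * (math.cos(phi) * u + math.sin(phi) * v))
        labels.append(0)

    # surface: chains anchored within contact range of an outer-wall atom
    for size in surface_clusters:
        if size < 1:
            raise ValueError("surface cluster sizes must be >= 1")
        step = 0.45 * cluster_cutoff
        span = (size - 1) * step
        if span > 0.8 * length:
            raise ValueError(f"surface cluster of {size} molecules does not fit on the tube")
        anchor_idx = int(rng.integers(outer.n_atoms))
        atom = outer.positions[anchor_idx]
        radial = atom - center - ((atom - center) @ axis) * axis
        radial /= np.linalg.norm(radial)
        first = atom + 0.5 * contact_cutoff * radial
        # keep the chain on the tube
        h0 = float((first - center) @ axis)
        h0 = min(max(h0, -0.45 * length), 0.45 * length - span)
        first = center + h0 * axis + (r_out + 0.5 * contact_cutoff) * radial
        for i in range(size):
            positions.append(first + i * step * axis)
            labels.append(0)

    # free clusters: tight blobs far from everything
    placed = np.array(positions) if positions else np.empty((0, 3))
    for size in free_clusters:
        if size < 1:
            raise ValueError("free cluster sizes must be >= 1")
        blob_r = 0.3 * cluster_cutoff
        ok = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            c = rng.uniform(0.0, 1.0, 3) * np.asarray(box)
            if walls:
                rel = c - center
                ax_dist = float(np.linalg.norm(rel - (rel @ axis) * axis))
                along = abs(float(rel @ axis))
                near_tube = ax_dist < r_out + min_separation + blob_r and \
                    along < length / 2.0 + min_separation + blob_r
                if near_tube:
                    continue
            if placed.size:
                d = minimum_image(placed - c, box)
                if float(np.sqrt((d**2).sum(axis=1)).min()) < min_separation + 2.0 * blob_r:
                    continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place a free cluster of {size} molecules after "
                f"{_PLACEMENT_ATTEMPTS} attempts; box too crowded for "
                f"min_separation={min_separation}"
            )
        members = []
        for _ in range(size):
            d = rng.normal(0.0, 1.0, 3)
            d *= (rng.uniform(0.0, blob_r) / np.linalg.norm(d))
            members.append(c + d)
        positions.extend(members)
        labels.extend([next_label] * size)
        next_label += 1
        placed = np.array(positions)

    pos = np.array(positions).reshape(-1, 3) % np.asarray(box)
    config = MolecularConfiguration(dox_positions=pos, cnt_walls=walls, box=box, time=time)
    n = len(labels)
    k = len(set(labels))
    truth = AggregateReport(
        time=time,
        n_aggregates=k,
        mean_aggregate_size=(n / k) if k else 0.0,
        fraction_on_cnt=100.0 * cnt_members / n if n else 0.0,
        fraction_inside_cnt=100.0 * n_inside / n if n else 0.0,
        aggregate_membership=tuple(labels),
    )
    return config, truth


# ------------------------------------------------------------------ toy dynamics

def toy_aggregation(
    n_molecules: int,
    box: Sequence[float] = DEFAULT_BOX_NM,
    n_steps: int = 50,
    step_sd: float = 0.5,
    stick_cutoff: float = 1.0,
    seed: int | None = None,
) -> tuple[list[MolecularConfiguration], list[AggregateReport]]:
    """Brownian sticky-aggregation toy dynamics (no nanotube).

    Molecules start as singletons at uniform random positions; each step,
    every cluster takes one rigid Gaussian displacement (sd ``step_sd`` per
    coordinate), and any two clusters with a minimum-image inter-member
    distance below ``stick_cutoff`` merge irreversibly and move rigidly
    thereafter. Because merging is irreversible, the aggregate count is
    non-increasing and the molecule count is conserved. Returns one frame
    and one ground-truth report per step (frame times are step indices).
    """
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    box_arr = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, (n_molecules, 3)) * box_arr
    clusters: list[list[int]] = [[i] for i in range(n_molecules)]

    def merge_contacts() -> None:
        merged = True
        while merged:
            merged = False
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = minimum_image(pos[clusters[a]][:, None, :] - pos[clusters[b]][None, :, :],
                                      box_arr)
                    if float(np.sqrt((d**2).sum(axis=-1)).min()) < stick_cutoff:
                        clusters[a].extend(clusters[b])
                        del clusters[b]
                        merged = True
                        break
                if merged:
                    break

    frames: list[MolecularConfiguration] = []
    reports: list[AggregateReport] = []
    merge_contacts()
    for step in range(n_steps):
        if step > 0:
            for members in clusters:
                pos[members] += rng.normal(0.0, step_sd, 3)
            pos %= box_arr
            merge_contacts()
        labels = np.empty(n_molecules, dtype=int)
        for lab, members in enumerate(clusters):
            labels[members] = lab
        # canonical first-occurrence numbering, matching the analyzer
        remap: dict[int, int] = {}
        canon = tuple(remap.setdefault(int(x), len(remap)) for x in labels)
        k = len(clusters)
        frames.append(MolecularConfiguration(
            dox_positions=pos.copy(), cnt_walls=(), box=tuple(box_arr), time=float(step),
        ))
        reports.append(AggregateReport(
            time=float(step), n_aggregates=k, mean_aggregate_size=n_molecules / k,
            fraction_on_cnt=0.0, fraction_inside_cnt=0.0, aggregate_membership=canon,
        ))
    return frames, reports
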