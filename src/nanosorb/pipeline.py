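"""End-to-end workflow: generate or ingest data, fit, select, analyze, report.

The pipeline is configured by a single YAML document validated against a
strict pydantic schema (unknown keys are rejected with their field paths).
All randomness flows through the config seed; rerunning the same config
yields byte-identical numeric payloads.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cnt import build_mwcnt
from .constants import DEFAULT_TEMPERATURE_K, SAMPLING_TIMES_MIN
from .datatypes import ModelFit
from .io import read_isotherm_csv, read_kinetic_csv, read_xyz
from .isotherms import IsothermComparison, compare_isotherms, fit_isotherm
from .kinetics import KINETIC_MODEL_ORDER, SelectionEntry, fit_kinetic, select_kinetic_model
from .synthetic import gen_isotherm, gen_kinetics, plant_configuration
from .trajectory import AggregateReport, analyze_trajectory

__all__ = ["PipelineConfig", "PipelineBundle", "run_pipeline", "render_summary",
           "load_config"]


# ----------------------------------------------------------------------- schema

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticIsotherm(_Strict):
    model: Literal["freundlich", "langmuir", "temkin"] = "freundlich"
    params: dict[str, float] = Field(default_factory=lambda: {"kF": 64.99, "1/n": 0.1725})
    ce_start: float = 0.001
    ce_stop: float = 0.3
    n_points: int = 20
    log_spaced: bool = True
    noise_sd_relative: float = 0.01


class IsothermJob(_Strict):
    csv: Optional[str] = None
    synthetic: Optional[SyntheticIsotherm] = None
    models: list[Literal["freundlich", "langmuir", "temkin", "all"]] = Field(
        default_factory=lambda: ["all"])
    mode: Literal["linearized", "nonlinear"] = "linearized"
    temperature: float = DEFAULT_TEMPERATURE_K


class SyntheticKinetics(_Strict):
    model: Literal["pseudo_first", "pseudo_second", "elovich", "elovich_simplified",
                   "fractional_power", "intraparticle"] = "pseudo_second"
    params: dict[str, float] = Field(default_factory=lambda: {"qe": 4029.0, "k2": 6.92e-5})
    t_points: list[float] = Field(default_factory=lambda: list(SAMPLING_TIMES_MIN))
    noise_sd_relative: float = 0.01


class KineticsJob(_Strict):
    csv: Optional[str] = None
    synthetic: Optional[SyntheticKinetics] = None
    models: list[str] = Field(default_factory=lambda: ["all"])
    qe_exp: Optional[float] = None
    n_segments: int = 2
    selection_threshold: float = 0.20


class PlantedTrajectory(_Strict):
    diameters: list[float] = Field(default_factory=lambda: [6.42])
    length: float = 20.0
    n_inside: int = 5
    surface_clusters: list[int] = Field(default_factory=lambda: [10, 10])
    free_clusters: list[int] = Field(default_factory=lambda: [4, 4, 4])
    n_frames: int = 1


class TrajectoryJob(_Strict):
    xyz: Optional[str] = None
    sidecar: Optional[str] = None
    planted: Optional[PlantedTrajectory] = None
    cluster_cutoff: float = 1.0
    contact_cutoff: float = 0.5
    sphere_radius: Optional[float] = None
    mode: Literal["cluster", "contact"] = "cluster"


class PipelineConfig(_Strict):
    seed: int = 0
    isotherm: Optional[IsothermJob] = None
    kinetics: Optional[KineticsJob] = None
    trajectory: Optional[TrajectoryJob] = None


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; schema violations surface with
    their field paths, and a missing file is reported as such (distinct
    from a malformed one)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {p}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(raw or {})
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(x) for x in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ValueError(f"invalid config {p}: {paths}") from exc


# ----------------------------------------------------------------------- bundle

@dataclass
class PipelineBundle:
    outdir: Path
    isotherm: IsothermComparison | None = None
    kinetic_fits: list[ModelFit] = field(default_factory=list)
    selection: list[SelectionEntry] = field(default_factory=list)
    aggregate_reports: list[AggregateReport] = field(default_factory=list)


def _run_isotherm(job: IsothermJob, seed: int, outdir: Path) -> IsothermComparison:
    if job.csv:
        data = read_isotherm_csv(job.csv, temperature=job.temperature)
    elif job.synthetic:
        s = job.synthetic
        grid = (np.geomspace if s.log_spaced else np.linspace)(s.ce_start, s.ce_stop, s.n_points)
        data, _ = gen_isotherm(s.model, s.params, grid, s.noise_sd_relative,
                               seed=seed, temperature=job.temperature)
    else:
        raise ValueError("isotherm job needs either csv or synthetic input")
    if "all" in job.models:
        comparison = compare_isotherms(data, job.mode)
    else:
        fits = [fit_isotherm(data, m, job.mode) for m in job.models]
        comparison = IsothermComparison(fits=tuple(
            sorted(fits, key=lambda f: (not f.valid, -f.r_squared))))
    (outdir / "isotherm_fits.json").write_text(json.dumps(
        {"fits": [f.to_dict() for f in comparison.fits],
         "failures": list(comparison.failures),
         "ranking": list(comparison.ranking)}, indent=2))
    return comparison


def _run_kinetics(job: KineticsJob, seed: int, outdir: Path
                  ) -> tuple[list[ModelFit], list[SelectionEntry]]:
    if job.csv:
        data = read_kinetic_csv(job.csv, qe_exp=job.qe_exp)
    elif job.synthetic:
        s = job.synthetic
        data, _ = gen_kinetics(s.model, s.params, s.t_points, s.noise_sd_relative, seed=seed)
    else:
        raise ValueError("kinetics job needs either csv or synthetic input")
    qe_exp = job.qe_exp if job.qe_exp is not None else data.qe_exp
    models = list(KINETIC_MODEL_ORDER) if "all" in job.models else job.models
    fits: list[ModelFit] = []
    failures: list[tuple[str, str]] = []
    for m in models:
        try:
            fits.append(fit_kinetic(data, m, qe_exp=qe_exp, n_segments=job.n_segments))
        except Exception as exc:
            failures.append((m, str(exc)))
    selection = select_kinetic_model(fits, qe_exp, job.selection_threshold) if qe_exp else []
    (outdir / "kinetic_fits.json").write_text(json.dumps(
        {"fits": [f.to_dict() for f in fits], "failures": failures}, indent=2))
    (outdir / "kinetic_selection.json").write_text(json.dumps(
        {"qe_exp": qe_exp, "entries": [e.to_dict() for e in selection]}, indent=2))
    return fits, selection


def _run_trajectory(job: TrajectoryJob, seed: int, outdir: Path) -> list[AggregateReport]:
    if job.xyz:
        frames = read_xyz(job.xyz, job.sidecar)
    elif job.planted:
        p = job.planted
        walls = build_mwcnt(p.diameters, length=p.length,
                            origin=(10.0, 40.0, 10.0))
        frames = []
        for i in range(p.n_frames):
            cfg, _ = plant_configuration(
                walls, n_inside=p.n_inside, surface_clusters=p.surface_clusters,
                free_clusters=p.free_clusters, seed=seed + i,
                cluster_cutoff=job.cluster_cutoff, contact_cutoff=job.contact_cutoff,
                sphere_radius=job.sphere_radius, time=float(i),
            )
            frames.append(cfg)
    else:
        raise ValueError("trajectory job needs either xyz or planted input")
    return analyze_trajectory(
        frames, cluster_cutoff=job.cluster_cutoff, contact_cutoff=job.contact_cutoff,
        sphere_radius=job.sphere_radius, mode=job.mode,
        csv_path=outdir / "aggregates.csv",
    )


def run_pipeline(config: PipelineConfig, outdir) -> PipelineBundle:
    """Run every configured stage and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = PipelineBundle(outdir=outdir)
    if config.isotherm:
        bundle.isotherm = _run_isotherm(config.isotherm, config.seed, outdir)
    if config.kinetics:
        bundle.kinetic_fits, bundle.selection = _run_kinetics(
            config.kinetics, config.seed + 1, outdir)
    if config.trajectory:
        bundle.aggregate_reports = _run_trajectory(config.trajectory, config.seed + 2, outdir)
    run_log = {
        "nanosorb_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.model_dump(),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(run_log, sort_keys=True))
    (outdir / "summary.txt").write_text(render_summary(bundle))
    return bundle


# ---------------------------------------------------------------------- summary

def render_summary(bundle: PipelineBundle) -> str:
    """Human-readable table of every fit and trajectory metric in the bundle."""
    header = f"{'section':<12} {'model':<18} {'parameters':<48} {'R^2':>8}"
    lines = [header, "-" * len(header)]
    if bundle.isotherm:
        for fit in bundle.isotherm.fits:
            lines.append(_fit_row("isotherm", fit))
    for fit in bundle.kinetic_fits:
        lines.append(_fit_row("kinetics", fit))
    for entry in bundle.selection:
        flag = "REJECTED (qe mismatch)" if entry.rejected else "ok"
        lines.append(f"{'selection':<12} {entry.model_name:<18} "
                     f"{'qe_fit=' + (f'{entry.qe_fit:.4g}' if entry.qe_fit else 'n/a'):<48} "
                     f"{entry.r_squared:>8.4f}  {flag}")
    for rep in bundle.aggregate_reports:
        desc = (f"n_agg={rep.n_aggregates} mean_size={rep.mean_aggregate_size:.2f} "
                f"on={rep.fraction_on_cnt:.1f}% inside={rep.fraction_inside_cnt:.1f}%")
        lines.append(f"{'trajectory':<12} {'t=' + format(rep.time, '.2f'):<18} {desc:<48} {'':>8}")
    return "\n".join(lines) + "\n"


def _fit_row(section: str, fit: ModelFit) -> str:
    params = " ".join(f"{k}={v:.4g}" for k, v in fit.parameters.items())
    mark = "" if fit.valid else "  [invalid]"
    return f"{section:<12} {fit.model_name:<18} {params:<48} {fit.r_squared:>8.4f}{mark}"
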