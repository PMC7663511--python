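"""Domain types for batch adsorption experiments and their model fits.

Units are fixed package-wide: concentrations in mg mL^-1, adsorption
capacities in mg g^-1, time in minutes, temperature in K, lengths in nm.
Converters, where needed, live at the I/O boundary, never inside the types.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "BatchExperiment",
    "IsothermDataset",
    "KineticDataset",
    "ModelFit",
]

# model identifiers accepted by ModelFit
MODEL_NAMES = (
    "freundlich",
    "langmuir",
    "temkin",
    "pseudo_first",
    "pseudo_second",
    "intraparticle",
    "fractional_power",
    "elovich",
)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CalibrationCurve:
    """Spectrophotometric standard curve: absorbance = slope * C + intercept.

    Parameters
    ----------
    slope : float
        Absorbance per mg mL^-1; must be positive (absorbance grows with
        concentration at the analytical wavelength).
    intercept : float
        Absorbance at zero concentration (blank offset).
    wavelength : float
        Analytical wavelength in nm (484 nm for doxorubicin).
    r_squared : float
        Coefficient of determination of the standard-curve regression.
    """

    slope: float
    intercept: float
    wavelength: float = 484.0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        _require(self.slope > 0, f"calibration slope must be > 0, got {self.slope}")
        if not math.isnan(self.r_squared):
            _require(0.0 <= self.r_squared <= 1.0,
                     f"r_squared must lie in [0, 1], got {self.r_squared}")

    def to_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "wavelength": self.wavelength,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CalibrationCurve":
        return cls(**{k: float(d[k]) for k in ("slope", "intercept", "wavelength", "r_squared")})


@dataclass(frozen=True)
class BatchExperiment:
    """One batch adsorption mixture.

    ``measured_concentration`` is the solution concentration after contact:
    the equilibrium value Ce for isotherm points, or the time-point value Ct
    for kinetic points (``time`` set).
    """

    total_volume: float          # V, mL
    adsorbent_mass: float        # m, g
    initial_concentration: float  # C0, mg mL^-1
    measured_concentration: float  # Ce or Ct, mg mL^-1
    time: float | None = None    # min
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        _require(self.total_volume > 0, f"total_volume must be > 0, got {self.total_volume}")
        _require(self.adsorbent_mass > 0, f"adsorbent_mass must be > 0, got {self.adsorbent_mass}")
        _require(self.initial_concentration >= 0,
                 f"initial_concentration must be >= 0, got {self.initial_concentration}")
        _require(
            0 <= self.measured_concentration <= self.initial_concentration,
            "measured concentration must satisfy 0 <= C <= C0 "
            f"(got C={self.measured_concentration}, C0={self.initial_concentration}); "
            "a measured value above C0 is inconsistent with adsorption",
        )
        if self.time is not None:
            _require(self.time >= 0, f"time must be >= 0, got {self.time}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "total_volume": self.total_volume,
            "adsorbent_mass": self.adsorbent_mass,
            "initial_concentration": self.initial_concentration,
            "measured_concentration": self.measured_concentration,
            "time": self.time,
            "temperature": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "BatchExperiment":
        return cls(
            total_volume=float(d["total_volume"]),
            adsorbent_mass=float(d["adsorbent_mass"]),
            initial_concentration=float(d["initial_concentration"]),
            measured_concentration=float(d["measured_concentration"]),
            time=None if d.get("time") is None else float(d["time"]),
            temperature=float(d.get("temperature", 298.15)),
        )


@dataclass(frozen=True)
class IsothermDataset:
    """Equilibrium series (Ce, qe) at one temperature.

    Log-linearized isotherm fits require Ce > 0 and (for Freundlich)
    qe > 0; positivity of Ce is enforced here, model-specific positivity
    at fit time with the offending row named.
    """

    ce: tuple[float, ...]   # mg mL^-1
    qe: tuple[float, ...]   # mg g^-1
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        object.__setattr__(self, "ce", tuple(float(c) for c in self.ce))
        object.__setattr__(self, "qe", tuple(float(q) for q in self.qe))
        _require(len(self.ce) == len(self.qe),
                 f"Ce and qe lengths differ ({len(self.ce)} vs {len(self.qe)})")
        _require(self.temperature > 0, f"temperature must be > 0 K, got {self.temperature}")
        for i, (c, q) in enumerate(zip(self.ce, self.qe)):
            _require(math.isfinite(c) and math.isfinite(q), f"non-finite value in row {i}")
            _require(c > 0, f"Ce must be > 0 (row {i}: Ce={c})")
            _require(q >= 0, f"qe must be >= 0 (row {i}: qe={q})")

    def __len__(self) -> int:
        return len(self.ce)

    @property
    def ce_array(self) -> np.ndarray:
        return np.asarray(self.ce, dtype=float)

    @property
    def qe_array(self) -> np.ndarray:
        return np.asarray(self.qe, dtype=float)

    def to_dict(self) -> dict[str, Any]:
        return {"ce": list(self.ce), "qe": list(self.qe), "temperature": self.temperature}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "IsothermDataset":
        return cls(ce=tuple(d["ce"]), qe=tuple(d["qe"]),
                   temperature=float(d.get("temperature", 298.15)))


@dataclass(frozen=True)
class KineticDataset:
    """Time course (t, qt) of adsorption capacity, optionally with the
    experimentally observed equilibrium plateau ``qe_exp``."""

    t: tuple[float, ...]    # min, strictly increasing
    qt: tuple[float, ...]   # mg g^-1
    qe_exp: float | None = None  # mg g^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", tuple(float(x) for x in self.t))
        object.__setattr__(self, "qt", tuple(float(x) for x in self.qt))
        _require(len(self.t) == len(self.qt),
                 f"t and qt lengths differ ({len(self.t)} vs {len(self.qt)})")
        for i, (ti, qi) in enumerate(zip(self.t, self.qt)):
            _require(math.isfinite(ti) and math.isfinite(qi), f"non-finite value in row {i}")
            _require(ti >= 0, f"t must be >= 0 (row {i}: t={ti})")
            _require(qi >= 0, f"qt must be >= 0 (row {i}: qt={qi})")
        for i in range(1, len(self.t)):
            _require(self.t[i] > self.t[i - 1],
                     f"t must be strictly increasing (rows {i - 1}-{i}: "
                     f"{self.t[i - 1]} -> {self.t[i]})")
        if self.qe_exp is not None:
            _require(self.qe_exp > 0, f"qe_exp must be > 0, got {self.qe_exp}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def t_array(self) -> np.ndarray:
        return np.asarray(self.t, dtype=float)

    @property
    def qt_array(self) -> np.ndarray:
        return np.asarray(self.qt, dtype=float)

    def to_dict(self) -> dict[str, Any]:
        return {"t": list(self.t), "qt": list(self.qt), "qe_exp": self.qe_exp}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "KineticDataset":
        qe_exp = d.get("qe_exp")
        return cls(t=tuple(d["t"]), qt=tuple(d["qt"]),
                   qe_exp=None if qe_exp is None else float(qe_exp))


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one isotherm or kinetic model.

    ``parameters`` and ``parameter_sd`` share the same keys; SDs are
    first-order (delta-method) propagations of the OLS slope/intercept
    covariance for linearized fits, or curve_fit covariance diagonals for
    nonlinear fits. ``valid`` is False for non-physical fits (e.g. a
    negative Langmuir slope) so comparisons can still rank them.
    ``diagnostics`` holds model-specific extras (breakpoint time, per-segment
    statistics, excluded-point counts, raw slope/intercept).
    """

    model_name: str
    parameters: Mapping[str, float]
    parameter_sd: Mapping[str, float]
    r_squared: float
    fit_mode: str  # "linearized" | "nonlinear"
    valid: bool = True
    diagnostics: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.model_name in MODEL_NAMES,
                 f"unknown model_name {self.model_name!r}; expected one of {MODEL_NAMES}")
        _require(set(self.parameters) == set(self.parameter_sd),
                 "parameter_sd keys must equal parameters keys "
                 f"({sorted(self.parameters)} vs {sorted(self.parameter_sd)})")
        _require(self.fit_mode in ("linearized", "nonlinear"),
                 f"fit_mode must be 'linearized' or 'nonlinear', got {self.fit_mode!r}")
        if math.isfinite(self.r_squared):
            _require(self.r_squared <= 1.0 + 1e-12,
                     f"r_squared cannot exceed 1, got {self.r_squared}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "model_name": self.model_name,
            "parameters": dict(self.parameters),
            "parameter_sd": dict(self.parameter_sd),
            "r_squared": self.r_squared,
            "fit_mode": self.fit_mode,
            "valid": self.valid,
            "diagnostics": _jsonable(self.diagnostics),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelFit":
        return cls(
            model_name=str(d["model_name"]),
            parameters={k: float(v) for k, v in d["parameters"].items()},
            parameter_sd={k: float(v) for k, v in d["parameter_sd"].items()},
            r_squared=float(d["r_squared"]),
            fit_mode=str(d["fit_mode"]),
            valid=bool(d.get("valid", True)),
            diagnostics=dict(d.get("diagnostics", {})),
        )


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays into plain Python objects."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
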