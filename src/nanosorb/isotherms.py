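"""Equilibrium isotherm models and their fits.

Three models relate the equilibrium solution concentration Ce (mg mL^-1)
to the equilibrium capacity qe (mg g^-1):

* Freundlich (heterogeneous surface):  qe = kF * Ce**(1/n)
  linearized as  ln qe = ln kF + (1/n) ln Ce
* Langmuir (monolayer, identical sites):  qe = qmax * KL * Ce / (1 + KL * Ce)
  linearized as  Ce/qe = Ce/qmax + 1/(qmax * KL)
* Temkin (linearly falling heat of sorption):
  qe = (R T / b) ln kT + (R T / b) ln Ce
  with b in kJ mol^-1 (the heat of sorption is dH = -b) and kT in mL g^-1.

``fit_mode="linearized"`` reproduces the classical linear-plot estimates,
with R^2 computed in the transformed space where the regression was run —
this is the convention the linear plots use, and it is what makes the
reported R^2 comparable across the literature. ``fit_mode="nonlinear"``
refits the direct form by least squares, initialized from the linearized
estimates, with R^2 in the original (Ce, qe) space.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.optimize import curve_fit

from ._regression import LineFit, delta_sd, fit_line
from .constants import R_GAS_KJ
from .datatypes import IsothermDataset, ModelFit

__all__ = [
    "fit_freundlich",
    "fit_langmuir",
    "fit_temkin",
    "fit_isotherm",
    "compare_isotherms",
    "IsothermComparison",
    "freundlich_qe",
    "langmuir_qe",
    "temkin_qe",
    "ISOTHERM_MODEL_ORDER",
]

ISOTHERM_MODEL_ORDER = ("freundlich", "langmuir", "temkin")


# ---------------------------------------------------------------- direct forms

def freundlich_qe(ce, kf: float, one_over_n: float):
    """Freundlich direct form qe = kF * Ce**(1/n)."""
    return kf * np.asarray(ce, dtype=float) ** one_over_n


def langmuir_qe(ce, qmax: float, kl: float):
    """Langmuir direct form qe = qmax * KL * Ce / (1 + KL * Ce)."""
    ce = np.asarray(ce, dtype=float)
    return qmax * kl * ce / (1.0 + kl * ce)


def temkin_qe(ce, b: float, kt: float, temperature: float):
    """Temkin direct form qe = (R T / b) * ln(kT * Ce)."""
    ce = np.asarray(ce, dtype=float)
    return (R_GAS_KJ * temperature / b) * np.log(kt * ce)


# ------------------------------------------------------------------- utilities

def _check_positive_qe(data: IsothermDataset) -> None:
    for i, q in enumerate(data.qe):
        if q <= 0:
            raise ValueError(f"qe must be > 0 for log-linearization (row {i}: qe={q})")


def _nonlinear_r2(qe: np.ndarray, pred: np.ndarray) -> float:
    sse = float(np.sum((qe - pred) ** 2))
    sst = float(np.sum((qe - qe.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)


def _mode_check(mode: str) -> None:
    if mode not in ("linearized", "nonlinear"):
        raise ValueError(f"mode must be 'linearized' or 'nonlinear', got {mode!r}")


# ------------------------------------------------------------------------ fits

def fit_freundlich(data: IsothermDataset, mode: str = "linearized") -> ModelFit:
    """Fit the Freundlich isotherm; returns parameters ``kF`` and ``1/n``."""
    _mode_check(mode)
    _check_positive_qe(data)
    ce, qe = data.ce_array, data.qe_array
    line = fit_line(np.log(ce), np.log(qe))
    kf = float(np.exp(line.intercept))
    one_over_n = line.slope
    if mode == "linearized":
        return ModelFit(
            model_name="freundlich",
            parameters={"kF": kf, "1/n": one_over_n},
            parameter_sd={"kF": kf * line.intercept_sd, "1/n": line.slope_sd},
            r_squared=line.r_squared,
            fit_mode="linearized",
            diagnostics={"slope": line.slope, "intercept": line.intercept},
        )
    popt, pcov = curve_fit(freundlich_qe, ce, qe, p0=[kf, one_over_n],
                           bounds=([1e-12, -np.inf], np.inf), maxfev=10000)
    sd = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return ModelFit(
        model_name="freundlich",
        parameters={"kF": float(popt[0]), "1/n": float(popt[1])},
        parameter_sd={"kF": float(sd[0]), "1/n": float(sd[1])},
        r_squared=_nonlinear_r2(qe, freundlich_qe(ce, *popt)),
        fit_mode="nonlinear",
    )


def fit_langmuir(data: IsothermDataset, mode: str = "linearized") -> ModelFit:
    """Fit the Langmuir isotherm; returns ``qmax`` (mg g^-1) and ``KL`` (mL mg^-1).

    The linearization regresses Ce/qe on Ce (slope = 1/qmax,
    intercept = 1/(qmax KL)). A non-positive slope leaves qmax undefined;
    the fit is returned with ``valid=False`` instead of raising, so model
    comparison can still rank it.
    """
    _mode_check(mode)
    _check_positive_qe(data)
    ce, qe = data.ce_array, data.qe_array
    line = fit_line(ce, ce / qe)
    valid = line.slope > 0 and line.intercept >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        qmax = 1.0 / line.slope if line.slope != 0 else float("inf")
        kl = line.slope / line.intercept if line.intercept != 0 else float("inf")
    qmax_sd = delta_sd(line, -1.0 / line.slope**2 if line.slope != 0 else 0.0, 0.0)
    if line.intercept != 0:
        kl_sd = delta_sd(line, 1.0 / line.intercept, -line.slope / line.intercept**2)
    else:
        kl_sd = float("nan")
    if mode == "linearized":
        return ModelFit(
            model_name="langmuir",
            parameters={"qmax": float(qmax), "KL": float(kl)},
            parameter_sd={"qmax": qmax_sd, "KL": kl_sd},
            r_squared=line.r_squared,
            fit_mode="linearized",
            valid=valid,
            diagnostics={"slope": line.slope, "intercept": line.intercept},
        )
    # start from the linearized estimate; fall back to a heuristic start
    # when that estimate is unphysical (noisy low-coverage data)
    p0_qmax = qmax if np.isfinite(qmax) and qmax > 0 else 1.2 * float(qe.max())
    p0_kl = kl if np.isfinite(kl) and kl > 0 else 1.0 / float(np.median(ce))
    popt, pcov = curve_fit(langmuir_qe, ce, qe, p0=[p0_qmax, p0_kl],
                           bounds=(1e-12, np.inf), maxfev=10000)
    sd = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return ModelFit(
        model_name="langmuir",
        parameters={"qmax": float(popt[0]), "KL": float(popt[1])},
        parameter_sd={"qmax": float(sd[0]), "KL": float(sd[1])},
        r_squared=_nonlinear_r2(qe, langmuir_qe(ce, *popt)),
        fit_mode="nonlinear",
        valid=bool(popt[0] > 0 and popt[1] > 0),
    )


def fit_temkin(data: IsothermDataset, mode: str = "linearized") -> ModelFit:
    """Fit the Temkin isotherm; returns ``b`` (kJ mol^-1), ``kT`` (mL g^-1)
    and ``heat_of_sorption`` = -b (kJ mol^-1).

    Linearization: qe on ln Ce, slope = RT/b, intercept = (RT/b) ln kT.
    A non-positive slope (b < 0, unphysical) sets ``valid=False``.
    """
    _mode_check(mode)
    ce, qe = data.ce_array, data.qe_array
    rt = R_GAS_KJ * data.temperature
    line = fit_line(np.log(ce), qe)
    valid = line.slope > 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        b = rt / line.slope if line.slope != 0 else float("inf")
        kt = float(np.exp(line.intercept / line.slope)) if line.slope != 0 else float("nan")
    b_sd = delta_sd(line, -rt / line.slope**2 if line.slope != 0 else 0.0, 0.0)
    if line.slope != 0 and np.isfinite(kt):
        kt_sd = delta_sd(line, -kt * line.intercept / line.slope**2, kt / line.slope)
    else:
        kt_sd = float("nan")
    if mode == "linearized":
        return ModelFit(
            model_name="temkin",
            parameters={"b": float(b), "kT": kt, "heat_of_sorption": float(-b)},
            parameter_sd={"b": b_sd, "kT": kt_sd, "heat_of_sorption": b_sd},
            r_squared=line.r_squared,
            fit_mode="linearized",
            valid=valid,
            diagnostics={"slope": line.slope, "intercept": line.intercept,
                         "temperature": data.temperature},
        )
    if not valid:
        raise ValueError(f"nonlinear Temkin fit needs a positive linearized slope, got {line.slope:.3g}")
    popt, pcov = curve_fit(
        lambda c, b_, kt_: temkin_qe(c, b_, kt_, data.temperature),
        ce, qe, p0=[b, kt], bounds=(1e-12, np.inf), maxfev=10000,
    )
    sd = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return ModelFit(
        model_name="temkin",
        parameters={"b": float(popt[0]), "kT": float(popt[1]),
                    "heat_of_sorption": float(-popt[0])},
        parameter_sd={"b": float(sd[0]), "kT": float(sd[1]), "heat_of_sorption": float(sd[0])},
        r_squared=_nonlinear_r2(qe, temkin_qe(ce, *popt, data.temperature)),
        fit_mode="nonlinear",
        valid=bool(popt[0] > 0),
        diagnostics={"temperature": data.temperature},
    )


_FITTERS: dict[str, Callable[[IsothermDataset, str], ModelFit]] = {
    "freundlich": fit_freundlich,
    "langmuir": fit_langmuir,
    "temkin": fit_temkin,
}


def fit_isotherm(data: IsothermDataset, model: str, mode: str = "linearized") -> ModelFit:
    """Dispatch to one of the isotherm fitters by model name."""
    try:
        fitter = _FITTERS[model]
    except KeyError:
        raise ValueError(f"unknown isotherm model {model!r}; expected one of {ISOTHERM_MODEL_ORDER}")
    return fitter(data, mode)


# ------------------------------------------------------------------ comparison

@dataclass(frozen=True)
class IsothermComparison:
    """All isotherm fits on one dataset, ranked best-first by R^2.

    Invalid (non-physical) fits rank after valid ones regardless of R^2;
    remaining ties break by fewer non-finite parameters, then by the fixed
    model order (freundlich, langmuir, temkin). Per-model failures are kept
    as (model, message) records and never abort the comparison.
    """

    fits: tuple[ModelFit, ...]
    failures: tuple[tuple[str, str], ...] = field(default=())

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(f.model_name for f in self.fits)

    @property
    def best(self) -> ModelFit:
        if not self.fits:
            raise ValueError("no successful isotherm fits to rank")
        return self.fits[0]


def compare_isotherms(data: IsothermDataset, mode: str = "linearized") -> IsothermComparison:
    """Fit all three isotherm models and rank them."""
    fits: list[ModelFit] = []
    failures: list[tuple[str, str]] = []
    for name in ISOTHERM_MODEL_ORDER:
        try:
            fits.append(_FITTERS[name](data, mode))
        except Exception as exc:  # per-model failure record, never aborts
            failures.append((name, str(exc)))

    def n_bad(fit: ModelFit) -> int:
        return sum(0 if np.isfinite(v) else 1 for v in fit.parameters.values())

    fits.sort(key=lambda f: (
        not f.valid,
        -f.r_squared if np.isfinite(f.r_squared) else np.inf,
        n_bad(f),
        ISOTHERM_MODEL_ORDER.index(f.model_name),
    ))
    return IsothermComparison(fits=tuple(fits), failures=tuple(failures))
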