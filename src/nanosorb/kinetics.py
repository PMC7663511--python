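"""Sorption kinetic models and the two-stage diffusion regression.

Five classical models describe the capacity time course qt (mg g^-1):

* pseudo-first order (Lagergren):
  log10(qe - qt) = log10(qe) - (k1 / 2.303) t        [k1 in min^-1]
* pseudo-second order (Ho-McKay):
  t/qt = 1/(k2 qe^2) + t/qe                          [k2 in g mg^-1 min^-1]
  with integrated form qt = qe^2 k2 t / (1 + qe k2 t)
* intra-particle diffusion (Weber-Morris), piecewise:
  qt = ki sqrt(t) + Ci  per diffusion stage i
* fractional power:  ln qt = ln KFP + v ln t
* Elovich (large-t simplified form):
  qt = (1/beta) ln(alpha beta) + (1/beta) ln t

All fits are the classical linearizations: base-10 logs for the
pseudo-first-order plot (the 2.303 factor), natural logs elsewhere.
t = 0 is excluded wherever the transform is undefined (t/qt, ln t).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._regression import LineFit, delta_sd, fit_line
from .datatypes import KineticDataset, ModelFit

__all__ = [
    "fit_pseudo_first",
    "fit_pseudo_second",
    "fit_intraparticle",
    "fit_fractional_power",
    "fit_elovich",
    "fit_kinetic",
    "select_kinetic_model",
    "SelectionEntry",
    "pseudo_first_qt",
    "pseudo_second_qt",
    "elovich_qt",
    "fractional_power_qt",
    "KINETIC_MODEL_ORDER",
]

log = logging.getLogger(__name__)

KINETIC_MODEL_ORDER = (
    "pseudo_first", "pseudo_second", "intraparticle", "fractional_power", "elovich",
)

LOG10_FACTOR = float(np.log(10.0))  # the "2.303" of the classical Lagergren plot, exact


# ----------------------------------------------------------- integrated forms

def pseudo_first_qt(t, qe: float, k1: float):
    """Integrated pseudo-first-order curve qt = qe (1 - exp(-k1 t))."""
    return qe * (1.0 - np.exp(-k1 * np.asarray(t, dtype=float)))


def pseudo_second_qt(t, qe: float, k2: float):
    """Integrated pseudo-second-order curve qt = qe^2 k2 t / (1 + qe k2 t)."""
    t = np.asarray(t, dtype=float)
    return qe**2 * k2 * t / (1.0 + qe * k2 * t)


def elovich_qt(t, alpha: float, beta: float):
    """Full Elovich curve qt = (1/beta) ln(1 + alpha beta t)."""
    return np.log(1.0 + alpha * beta * np.asarray(t, dtype=float)) / beta


def fractional_power_qt(t, kfp: float, v: float):
    """Fractional-power curve qt = KFP t**v."""
    return kfp * np.asarray(t, dtype=float) ** v


# ------------------------------------------------------------------------ fits

def fit_pseudo_first(data: KineticDataset, qe_exp: float | None = None) -> ModelFit:
    """Pseudo-first-order fit; needs the experimental plateau ``qe_exp``
    because the linearization transforms qe_exp - qt before any qe is fitted.

    Points with qt >= qe_exp (log undefined) are excluded with a logged count.
    Returns parameters ``qe`` (the fitted intercept capacity) and ``k1``.
    """
    if qe_exp is None:
        qe_exp = data.qe_exp
    if qe_exp is None:
        raise ValueError("pseudo-first-order fit requires qe_exp (experimental plateau)")
    if qe_exp <= 0:
        raise ValueError(f"qe_exp must be > 0, got {qe_exp}")
    t, qt = data.t_array, data.qt_array
    usable = qt < qe_exp
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("pseudo-first-order fit: excluded %d point(s) with qt >= qe_exp", n_excluded)
    if usable.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable points after excluding qt >= qe_exp ({int(usable.sum())} left)"
        )
    line = fit_line(t[usable], np.log10(qe_exp - qt[usable]))
    k1 = -LOG10_FACTOR * line.slope
    qe_fit = float(10.0 ** line.intercept)
    return ModelFit(
        model_name="pseudo_first",
        parameters={"qe": qe_fit, "k1": float(k1)},
        parameter_sd={
            "qe": float(np.log(10.0) * qe_fit * line.intercept_sd),
            "k1": float(LOG10_FACTOR * line.slope_sd),
        },
        r_squared=line.r_squared,
        fit_mode="linearized",
        diagnostics={"qe_exp": float(qe_exp), "n_excluded": n_excluded,
                     "slope": line.slope, "intercept": line.intercept},
    )


def fit_pseudo_second(data: KineticDataset) -> ModelFit:
    """Pseudo-second-order fit of t/qt on t (slope = 1/qe,
    intercept = 1/(k2 qe^2)); t = 0 is excluded. Returns ``qe`` and ``k2``."""
    t, qt = data.t_array, data.qt_array
    keep = t > 0
    t, qt = t[keep], qt[keep]
    for i, q in enumerate(qt):
        if q <= 0:
            raise ValueError(f"qt must be > 0 for the t/qt transform (row {i}: qt={q})")
    line = fit_line(t, t / qt)
    if line.slope == 0 or line.intercept == 0:
        raise ValueError(
            f"degenerate pseudo-second-order regression (slope={line.slope}, "
            f"intercept={line.intercept})"
        )
    qe = 1.0 / line.slope
    k2 = line.slope**2 / line.intercept
    return ModelFit(
        model_name="pseudo_second",
        parameters={"qe": float(qe), "k2": float(k2)},
        parameter_sd={
            "qe": delta_sd(line, -1.0 / line.slope**2, 0.0),
            "k2": delta_sd(line, 2.0 * line.slope / line.intercept,
                           -(line.slope**2) / line.intercept**2),
        },
        r_squared=line.r_squared,
        fit_mode="linearized",
        valid=bool(line.slope > 0 and line.intercept > 0),
        diagnostics={"slope": line.slope, "intercept": line.intercept},
    )


@dataclass(frozen=True)
class _Segment:
    start: int          # first point index (into the fitted arrays)
    stop: int           # one past the last point index
    line: LineFit


def fit_intraparticle(data: KineticDataset, n_segments: int = 2) -> ModelFit:
    """Piecewise Weber-Morris fit of qt on sqrt(t).

    The breakpoints are found by exhaustive search over every admissible
    split (each segment keeps >= 3 points), minimizing the total SSE; SSE
    ties break toward the earlier breakpoint. Parameters are ``k<i>`` and
    ``C<i>`` per segment; diagnostics carry per-segment R^2 and the
    breakpoint times (the time of the last point in each earlier segment).
    """
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")
    t, qt = data.t_array, data.qt_array
    n = t.size
    if n < 3 * n_segments:
        raise ValueError(
            f"{n} points cannot support {n_segments} segment(s) of >= 3 points each"
        )
    s = np.sqrt(t)

    def segmentation_sse(bounds: tuple[int, ...]) -> tuple[float, list[_Segment]]:
        segs: list[_Segment] = []
        total = 0.0
        edges = (0, *bounds, n)
        for a, b in zip(edges[:-1], edges[1:]):
            line = fit_line(s[a:b], qt[a:b])
            segs.append(_Segment(a, b, line))
            total += line.sse
        return total, segs

    # admissible interior boundaries: each segment takes >= 3 points
    best_sse = np.inf
    best: list[_Segment] | None = None
    candidates = combinations(range(3, n - 2), n_segments - 1)
    for bounds in candidates:
        if any(b2 - b1 < 3 for b1, b2 in zip((0, *bounds), (*bounds, n))):
            continue
        sse, segs = segmentation_sse(bounds)
        if sse < best_sse:  # strict '<' keeps the earlier breakpoint on ties
            best_sse, best = sse, segs
    assert best is not None

    params: dict[str, float] = {}
    sds: dict[str, float] = {}
    seg_diag = []
    for i, seg in enumerate(best, start=1):
        params[f"k{i}"] = seg.line.slope
        params[f"C{i}"] = seg.line.intercept
        sds[f"k{i}"] = seg.line.slope_sd
        sds[f"C{i}"] = seg.line.intercept_sd
        seg_diag.append({
            "start": seg.start, "stop": seg.stop,
            "r_squared": seg.line.r_squared, "sse": seg.line.sse,
        })
    breakpoints = [float(t[seg.stop - 1]) for seg in best[:-1]]
    sst = float(np.sum((qt - qt.mean()) ** 2))
    r2_total = 1.0 - best_sse / sst if sst > 0 else 1.0
    return ModelFit(
        model_name="intraparticle",
        parameters=params,
        parameter_sd=sds,
        r_squared=float(min(r2_total, 1.0)),
        fit_mode="linearized",
        diagnostics={"segments": seg_diag, "breakpoint_times": breakpoints,
                     "total_sse": float(best_sse)},
    )


def fit_fractional_power(data: KineticDataset) -> ModelFit:
    """Fractional-power fit of ln qt on ln t (slope = v, intercept = ln KFP);
    t = 0 is excluded. Diagnostics flag v < 1 (the model's usual validity note)."""
    t, qt = data.t_array, data.qt_array
    keep = t > 0
    t, qt = t[keep], qt[keep]
    for i, q in enumerate(qt):
        if q <= 0:
            raise ValueError(f"qt must be > 0 for the ln transform (row {i}: qt={q})")
    line = fit_line(np.log(t), np.log(qt))
    kfp = float(np.exp(line.intercept))
    return ModelFit(
        model_name="fractional_power",
        parameters={"KFP": kfp, "v": line.slope},
        parameter_sd={"KFP": kfp * line.intercept_sd, "v": line.slope_sd},
        r_squared=line.r_squared,
        fit_mode="linearized",
        diagnostics={"v_below_unity": bool(line.slope < 1.0),
                     "slope": line.slope, "intercept": line.intercept},
    )


def fit_elovich(data: KineticDataset) -> ModelFit:
    """Elovich fit of qt on ln t (slope = 1/beta,
    intercept = (1/beta) ln(alpha beta)); t = 0 is excluded.
    Returns ``alpha`` (mg g^-1 min^-1) and ``beta`` (g mg^-1); a
    non-positive slope (qt not increasing with ln t) sets ``valid=False``."""
    t, qt = data.t_array, data.qt_array
    keep = t > 0
    t, qt = t[keep], qt[keep]
    line = fit_line(np.log(t), qt)
    valid = line.slope > 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        beta = 1.0 / line.slope if line.slope != 0 else float("inf")
        # alpha = slope * exp(intercept / slope)
        alpha = (
            float(line.slope * np.exp(line.intercept / line.slope))
            if line.slope != 0 else float("nan")
        )
    if line.slope != 0 and np.isfinite(alpha):
        ratio = line.intercept / line.slope
        alpha_sd = delta_sd(
            line,
            float(np.exp(ratio) * (1.0 - ratio)),
            float(np.exp(ratio)),
        )
        beta_sd = delta_sd(line, -1.0 / line.slope**2, 0.0)
    else:
        alpha_sd = float("nan")
        beta_sd = float("nan")
    return ModelFit(
        model_name="elovich",
        parameters={"alpha": alpha, "beta": float(beta)},
        parameter_sd={"alpha": alpha_sd, "beta": beta_sd},
        r_squared=line.r_squared,
        fit_mode="linearized",
        valid=valid,
        diagnostics={"slope": line.slope, "intercept": line.intercept},
    )


def fit_kinetic(
    data: KineticDataset,
    model: str,
    qe_exp: float | None = None,
    n_segments: int = 2,
) -> ModelFit:
    """Dispatch to one of the kinetic fitters by model name."""
    if model == "pseudo_first":
        return fit_pseudo_first(data, qe_exp)
    if model == "pseudo_second":
        return fit_pseudo_second(data)
    if model == "intraparticle":
        return fit_intraparticle(data, n_segments)
    if model == "fractional_power":
        return fit_fractional_power(data)
    if model == "elovich":
        return fit_elovich(data)
    raise ValueError(f"unknown kinetic model {model!r}; expected one of {KINETIC_MODEL_ORDER}")


# ------------------------------------------------------------- model selection

@dataclass(frozen=True)
class SelectionEntry:
    """One row of the kinetic model-selection report."""

    model_name: str
    r_squared: float
    qe_fit: float | None          # None for models without a fitted capacity
    qe_relative_deviation: float | None
    rejected: bool                # True: good R^2 but capacity inconsistent

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "r_squared": self.r_squared,
            "qe_fit": self.qe_fit,
            "qe_relative_deviation": self.qe_relative_deviation,
            "rejected": self.rejected,
        }


def select_kinetic_model(
    fits: list[ModelFit] | tuple[ModelFit, ...],
    qe_exp: float,
    rel_threshold: float = 0.20,
) -> list[SelectionEntry]:
    """Rank kinetic fits by R^2 and reject capacity-inconsistent models.

    A model reporting a fitted equilibrium capacity ``qe`` that deviates from
    the experimental plateau ``qe_exp`` by more than ``rel_threshold``
    (relative) is flagged ``rejected`` regardless of its R^2 — a good
    straight-line fit with the wrong plateau does not describe the process.
    An empty fit list yields an empty report.
    """
    if qe_exp <= 0:
        raise ValueError(f"qe_exp must be > 0, got {qe_exp}")
    entries: list[SelectionEntry] = []
    for fit in fits:
        qe_fit = fit.parameters.get("qe")
        if qe_fit is not None and np.isfinite(qe_fit):
            dev = abs(qe_fit - qe_exp) / qe_exp
            rejected = dev > rel_threshold
        else:
            qe_fit, dev, rejected = None, None, False
        entries.append(SelectionEntry(
            model_name=fit.model_name,
            r_squared=fit.r_squared,
            qe_fit=qe_fit,
            qe_relative_deviation=dev,
            rejected=rejected,
        ))
    entries.sort(key=lambda e: (-e.r_squared if np.isfinite(e.r_squared) else np.inf,
                                KINETIC_MODEL_ORDER.index(e.model_name)
                                if e.model_name in KINETIC_MODEL_ORDER else 99))
    return entries
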