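"""Batch mass-balance computations and spectrophotometric calibration.

The adsorbed amount per unit mass of adsorbent follows from the depletion
of the solution:

    q = V * (C0 - C) / m

with V the total mixture volume (mL), m the adsorbent mass (g), C0 the
initial and C the measured (equilibrium Ce or time-point Ct) solution
concentration (mg mL^-1), giving q in mg g^-1. Measured concentrations come
from absorbance readings through a linear standard curve.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from ._regression import fit_line
from .datatypes import BatchExperiment, CalibrationCurve

__all__ = [
    "capacity_at_equilibrium",
    "capacity_at_time",
    "fit_calibration",
    "concentration_from_absorbance",
    "absorbance_from_concentration",
]

log = logging.getLogger(__name__)


def _capacity(exp: BatchExperiment) -> float:
    # BatchExperiment guarantees 0 <= C <= C0, V > 0, m > 0, so q >= 0.
    return exp.total_volume * (exp.initial_concentration - exp.measured_concentration) / exp.adsorbent_mass


def capacity_at_equilibrium(exp: BatchExperiment) -> float:
    """Equilibrium adsorption capacity qe = V (C0 - Ce) / m, mg g^-1."""
    return _capacity(exp)


def capacity_at_time(exp: BatchExperiment) -> float:
    """Time-point adsorption capacity qt = V (C0 - Ct) / m, mg g^-1."""
    return _capacity(exp)


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    wavelength: float = 484.0,
) -> CalibrationCurve:
    """Fit the standard curve absorbance = slope * concentration + intercept.

    Parameters
    ----------
    standards : sequence of (concentration mg mL^-1, absorbance) pairs
        At least 3 standards with distinct concentrations.
    wavelength : float
        Analytical wavelength (nm) recorded on the curve.
    """
    if len(standards) < 3:
        raise ValueError(f"need at least 3 calibration standards, got {len(standards)}")
    conc = np.array([s[0] for s in standards], dtype=float)
    absb = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("calibration standards have zero concentration variance")
    line = fit_line(conc, absb)
    return CalibrationCurve(
        slope=line.slope,
        intercept=line.intercept,
        wavelength=wavelength,
        r_squared=max(line.r_squared, 0.0),
    )


def concentration_from_absorbance(curve: CalibrationCurve, absorbance: float) -> float:
    """Invert the standard curve: C = (A - intercept) / slope, mg mL^-1.

    A negative back-calculated concentration (absorbance below the blank,
    i.e. measurement noise) is clipped to 0 with a logged warning rather
    than raised.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; curve is not invertible")
    conc = (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        log.warning(
            "absorbance %.6g below calibration intercept %.6g; "
            "clipping concentration %.6g to 0",
            absorbance, curve.intercept, conc,
        )
        return 0.0
    return conc


def absorbance_from_concentration(curve: CalibrationCurve, concentration: float) -> float:
    """Forward standard curve: A = slope * C + intercept."""
    return curve.slope * concentration + curve.intercept
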