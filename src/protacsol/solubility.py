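"""Shake-flask solubility quantification and GSK classification.

The experimental chain: an HPLC-UV calibration line (AUC versus known
concentration) is inverted to quantify saturated samples after dilution
correction; concentrations convert to molar log S via the molecular
weight; the GSK three-class scheme (low < 30 uM, intermediate 30-200 uM,
high > 200 uM) labels each compound. Measurements below the quantification
limit are censored ("ND"): they keep the low class label but carry no
numeric value and are excluded from every regression.

Experimental conditions of the reference protocol (pH 7 phosphate buffer,
25 degC, 1 h shake, 0.45 um filtration) are carried as metadata only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .datatypes import Dataset, GskClass, SolubilityMeasurement
from .errors import DegenerateDesignError, DomainError, UnusableCurveError

GSK_LOW_UM = 30.0
GSK_HIGH_UM = 200.0

#: protocol metadata attached to outputs; gates nothing
SHAKE_FLASK_CONDITIONS = {
    "buffer": "10 mM PBS (0.15 M KCl), pH 7",
    "temperature_c": "25",
    "incubation_h": "1",
    "filter_um": "0.45",
}


@dataclass
class CalibrationCurve:
    """OLS line AUC = slope*conc + intercept over >=5 points (fewer points
    fit with an under-powered warning)."""

    concentrations: tuple[float, ...]
    aucs: tuple[float, ...]
    slope: float
    intercept: float
    r2: float


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Fit a calibration line from (concentration mg/mL, AUC) pairs."""
    conc = np.array([p[0] for p in points], dtype=float)
    auc = np.array([p[1] for p in points], dtype=float)
    if len(set(conc.tolist())) < 2:
        raise DegenerateDesignError("calibration needs >=2 distinct concentrations")
    if len(points) < 5:
        warnings.warn(f"calibration curve with only {len(points)} points (5-10 recommended)")
    slope, intercept = np.polyfit(conc, auc, 1)
    fitted = slope * conc + intercept
    ss_tot = float(np.sum((auc - auc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((auc - fitted) ** 2)) / ss_tot
    return CalibrationCurve(tuple(conc), tuple(auc), float(slope), float(intercept), float(r2))


def quantify(
    auc: float,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
    compound_id: str = "?",
) -> SolubilityMeasurement:
    """Interpolate a sample AUC into the calibration line.

    conc = dilution_factor * (auc - intercept) / slope, in mg/mL. A
    non-positive interpolation censors the measurement (below LOQ) rather
    than reporting a negative concentration.
    """
    if curve.slope == 0:
        raise UnusableCurveError("calibration slope is zero; curve cannot be inverted")
    if dilution_factor < 1:
        raise DomainError(f"dilution factor must be >=1, got {dilution_factor}")
    conc = dilution_factor * (auc - curve.intercept) / curve.slope
    if conc <= 0:
        return SolubilityMeasurement(compound_id=compound_id, censored=True,
                                     gsk_class=GskClass.LOW)
    return SolubilityMeasurement(compound_id=compound_id, conc_mg_ml=float(conc))


def to_log_s(conc_mg_ml: float, mw: float) -> float:
    """log10 molar solubility from mg/mL (numerically g/L) and MW g/mol."""
    if conc_mg_ml <= 0 or mw <= 0:
        raise DomainError(f"need positive concentration and MW, got ({conc_mg_ml}, {mw})")
    return math.log10(conc_mg_ml / mw)


def micromolar_from_log_s(log_s: float) -> float:
    """uM saturation concentration from log S (mol/L)."""
    return 10.0 ** log_s * 1e6


def gsk_class(s_micromolar: Optional[float] = None, *, censored: bool = False) -> GskClass:
    """GSK class: <30 uM low, [30, 200] uM intermediate, >200 uM high.

    The boundaries fall in the closed middle interval. Censored (ND)
    measurements are assigned to the low class.
    """
    if censored:
        return GskClass.LOW
    if s_micromolar is None or s_micromolar < 0:
        raise DomainError(f"concentration must be >=0 uM, got {s_micromolar}")
    if s_micromolar < GSK_LOW_UM:
        return GskClass.LOW
    if s_micromolar <= GSK_HIGH_UM:
        return GskClass.INTERMEDIATE
    return GskClass.HIGH


def finalize_measurement(meas: SolubilityMeasurement, mw: float) -> SolubilityMeasurement:
    """Fill the derived fields (molar scale, log S, uM, class) in place."""
    if meas.censored:
        meas.gsk_class = GskClass.LOW
        return meas
    if meas.conc_mg_ml is None:
        raise DomainError(f"{meas.compound_id}: no concentration to convert")
    meas.log_s = to_log_s(meas.conc_mg_ml, mw)
    meas.s_molar = 10.0 ** meas.log_s
    meas.s_micromolar = meas.s_molar * 1e6
    meas.gsk_class = gsk_class(meas.s_micromolar)
    return meas


def summarize_replicates(values: Sequence[float]) -> tuple[float, Optional[float], Optional[float]]:
    """Mean, sample SD (n-1) and RSD% of replicate measurements.

    A single value yields (mean, None, None) with a warning; RSD is None
    when the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("no replicate values")
    mean = float(arr.mean())
    if arr.size < 2:
        warnings.warn("single replicate: standard deviation undefined")
        return mean, None, None
    sd = float(arr.std(ddof=1))
    rsd = None if mean == 0 else 100.0 * sd / mean
    return mean, sd, rsd


def filter_quantitative(
    measurements: Union[Dataset, Iterable[SolubilityMeasurement]],
) -> list[SolubilityMeasurement]:
    """All and only the non-censored measurements, order preserved.

    Censored (ND) entries stay in the low class for classification but
    never enter quantitative analyses; idempotent by construction.
    """
    if isinstance(measurements, Dataset):
        items: Iterable[SolubilityMeasurement] = measurements.solubility.values()
    else:
        items = measurements
    return [m for m in items if m.is_quantitative()]
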