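"""Chromatographic descriptor transforms.

Raw retention times become three experimental descriptors:

* **BRlogD** — lipophilicity of bRo5 molecules from RP18 retention at
  60% acetonitrile: BRlogD = 3.31*log k'60 + 2.79.
* **log kw_IAM** — lipophilicity against immobilised-artificial-membrane
  phospholipids: log k' measured at several acetonitrile fractions and
  extrapolated linearly to 0% organic (100% aqueous).
* **Delta log kw_IAM** — polarity: the excess of log kw_IAM over the value
  expected for a PSA-zero neutral analyte, clog kw_IAM = 0.92*BRlogD - 1.03.

EPSA (supercritical-fluid-chromatography polarity) is ingested, never
recomputed; an optional user-supplied calibration line maps raw SFC
retention to the EPSA scale.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np

from .datatypes import (
    ChromatographicDescriptors,
    ColumnSystem,
    RetentionPoint,
    RetentionSeries,
)
from .errors import (
    DeadTimeError,
    InsufficientDataError,
    NegativeRetentionError,
    UndefinedLogError,
)

# printed coefficients of the two published transfer equations
BRLOGD_SLOPE = 3.31
BRLOGD_INTERCEPT = 2.79
CLOGKW_SLOPE = 0.92
CLOGKW_INTERCEPT = -1.03


def capacity_factor(t_r: float, t0: float) -> float:
    """k' = (t_R - t0) / t0 for one injection (times in minutes)."""
    if t0 <= 0:
        raise DeadTimeError(f"dead time must be positive, got t0={t0}")
    if t_r < t0:
        raise NegativeRetentionError(f"t_R={t_r} earlier than dead time t0={t0}")
    return (t_r - t0) / t0


def log_capacity_factor(t_r: float, t0: float) -> float:
    k = capacity_factor(t_r, t0)
    if k <= 0:
        raise UndefinedLogError(f"unretained analyte (k'=0 at t_R={t_r}, t0={t0}); log k' undefined")
    return math.log10(k)


def brlogd_from_logk60(log_k60: float) -> float:
    """BRlogD from the RP18 60% ACN capacity factor: 3.31*x + 2.79."""
    if not math.isfinite(log_k60):
        raise UndefinedLogError(f"log k'60 must be finite, got {log_k60}")
    return BRLOGD_SLOPE * log_k60 + BRLOGD_INTERCEPT


def brlogd_from_series(series: RetentionSeries) -> float:
    """BRlogD from an RP18 isocratic series; replicate log k' averaged."""
    logs = [log_capacity_factor(p.t_r, p.t0) for p in series.points]
    if not logs:
        raise InsufficientDataError(f"{series.compound_id}: no RP18 retention points")
    return brlogd_from_logk60(float(np.mean(logs)))


def clog_kw_iam(brlogd: float) -> float:
    """Expected log kw_IAM of a PSA-zero neutral analyte: 0.92*BRlogD - 1.03."""
    return CLOGKW_SLOPE * brlogd + CLOGKW_INTERCEPT


def delta_log_kw_iam(log_kw_iam: float, brlogd: float) -> float:
    """Polarity descriptor: log kw_IAM - clog kw_IAM."""
    if not (math.isfinite(log_kw_iam) and math.isfinite(brlogd)):
        raise UndefinedLogError("delta log kw_IAM needs finite inputs")
    return log_kw_iam - clog_kw_iam(brlogd)


def extrapolate_log_kw_iam(series: RetentionSeries) -> tuple[float, float]:
    """Extrapolate IAM log k' to 0% acetonitrile.

    Replicates at the same organic fraction are averaged on the log k'
    scale first, then an ordinary least-squares line of mean log k' versus
    %ACN is fitted. Returns ``(intercept_at_0pct, r_squared)``. Requires at
    least three distinct organic levels.
    """
    by_level: dict[float, list[float]] = defaultdict(list)
    for p in series.points:
        k = capacity_factor(p.t_r, p.t0)
        if k <= 0:
            raise UndefinedLogError(
                f"{series.compound_id}: k'<=0 at {p.percent_organic}% (t_R={p.t_r}, t0={p.t0})")
        by_level[p.percent_organic].append(math.log10(k))
    if len(by_level) < 3:
        raise InsufficientDataError(
            f"{series.compound_id}: IAM extrapolation needs >=3 distinct organic "
            f"levels, got {len(by_level)}")
    levels = sorted(by_level)
    x = np.array(levels, dtype=float)
    y = np.array([np.mean(by_level[lv]) for lv in levels])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(intercept), float(r2)


def apply_epsa_calibration(retention: float, slope: float, intercept: float) -> float:
    """Map a raw SFC retention value onto the EPSA scale with a user line."""
    return slope * retention + intercept


def descriptors_from_series(
    series_list: Iterable[RetentionSeries],
    *,
    epsa: Optional[dict[str, float]] = None,
) -> dict[str, ChromatographicDescriptors]:
    """Assemble chromatographic descriptors per compound from raw series.

    The clog/delta identities hold exactly on every returned profile:
    ``clog_kw_iam == 0.92*brlogd - 1.03`` and
    ``delta_log_kw_iam == log_kw_iam - clog_kw_iam``.
    """
    out: dict[str, ChromatographicDescriptors] = {}
    for series in series_list:
        desc = out.setdefault(series.compound_id, ChromatographicDescriptors())
        if series.system == ColumnSystem.RP18_ISOCRATIC_60ACN:
            desc.brlogd = brlogd_from_series(series)
        elif series.system == ColumnSystem.IAM_GRADIENT_POINTS:
            desc.log_kw_iam, desc.extrapolation_r2 = extrapolate_log_kw_iam(series)
    for cid, desc in out.items():
        if desc.brlogd is not None:
            desc.clog_kw_iam = clog_kw_iam(desc.brlogd)
            if desc.log_kw_iam is not None:
                desc.delta_log_kw_iam = desc.log_kw_iam - desc.clog_kw_iam
        if epsa and cid in epsa:
            desc.epsa = epsa[cid]
    return out
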