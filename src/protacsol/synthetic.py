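"""Synthetic datasets with the statistical structure of the measured study.

The generator emulates a bRo5 degrader panel: 2D descriptors sampled
uniformly over the observed chemical-space ranges (TPSA 166-335 Å², nC
34-58, PHI 9-27), chromatographic lipophilicity BRlogD uniform over
0.5-5.5, IAM retention tied to BRlogD through the PSA-zero baseline plus a
polarity excess, and thermodynamic solubility generated from the linear
model log S = -0.75*BRlogD - 3.29 with Gaussian noise calibrated to a
target R². Measurements below a quantification limit are censored and
assigned to the low GSK class. Retention tables can be produced by
inverting the chromatographic transforms so the whole pipeline
round-trips.

Synthetic compounds carry no structures: structure-dependent descriptors
(nC, TPSA, PHI) are drawn, not computed, and molecular weight is sampled
from 700-1100 g/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chromatography import BRLOGD_INTERCEPT, BRLOGD_SLOPE, clog_kw_iam
from .datatypes import (
    ColumnSystem,
    CompoundRecord,
    Dataset,
    DescriptorProfile,
    GskClass,
    RetentionPoint,
    RetentionSeries,
    SolubilityMeasurement,
)
from .errors import DomainError
from .psa3d import Conformer, ConformerEnsemble
from .solubility import gsk_class

DEFAULT_SLOPE = -0.75
DEFAULT_INTERCEPT = -3.29
DEFAULT_TARGET_R2 = 0.67


def calibrated_noise_sd(
    slope: float = DEFAULT_SLOPE,
    brlogd_range: tuple[float, float] = (0.5, 5.5),
    target_r2: float = DEFAULT_TARGET_R2,
) -> float:
    """Noise SD giving an asymptotic R² of ``target_r2``.

    For x ~ Uniform(a, b), var(slope*x) = slope²(b-a)²/12 and
    sigma² = var(slope*x) * (1 - R²) / R².
    """
    if not 0 < target_r2 < 1:
        raise DomainError(f"target R² must be in (0,1), got {target_r2}")
    a, b = brlogd_range
    signal_var = slope ** 2 * (b - a) ** 2 / 12.0
    return math.sqrt(signal_var * (1.0 - target_r2) / target_r2)


@dataclass
class GeneratorConfig:
    n_compounds: int = 21
    seed: int = 0
    brlogd_range: tuple[float, float] = (0.5, 5.5)
    tpsa_range: tuple[float, float] = (166.0, 335.0)
    nc_range: tuple[int, int] = (34, 58)
    phi_range: tuple[float, float] = (9.0, 27.0)
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: Optional[float] = None       # None -> calibrated for target_r2
    target_r2: float = DEFAULT_TARGET_R2
    iam_delta_sd: float = 0.4              # SD of the polarity excess Delta log kw_IAM
    loq_log_s: float = -6.5                # censoring threshold (log mol/L)
    mw_range: tuple[float, float] = (700.0, 1100.0)

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            if self.noise_sd < 0:
                raise DomainError("noise_sd must be >= 0")
            return self.noise_sd
        return calibrated_noise_sd(self.slope, self.brlogd_range, self.target_r2)

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise DomainError("n_compounds must be >= 1")
        for name in ("brlogd_range", "tpsa_range", "nc_range", "phi_range", "mw_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise DomainError(f"{name} is empty: ({lo}, {hi})")


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """One reproducible synthetic dataset per (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    sd = config.resolved_noise_sd()

    brlogd = rng.uniform(*config.brlogd_range, size=n)
    tpsa = rng.uniform(*config.tpsa_range, size=n)
    nc = rng.integers(config.nc_range[0], config.nc_range[1] + 1, size=n)
    phi = rng.uniform(*config.phi_range, size=n)
    delta_iam = rng.normal(0.0, config.iam_delta_sd, size=n)
    log_s = config.slope * brlogd + config.intercept + rng.normal(0.0, sd, size=n)
    mw = rng.uniform(*config.mw_range, size=n)

    ds = Dataset(metadata={"generator_seed": str(config.seed)})
    for i in range(n):
        cid = f"SYN-{i + 1:03d}"
        ds.compounds.append(CompoundRecord(id=cid, name=f"synthetic degrader {i + 1}",
                                           mw=float(mw[i])))
        clog = clog_kw_iam(float(brlogd[i]))
        ds.descriptors[cid] = DescriptorProfile(
            compound_id=cid,
            nc=int(nc[i]), tpsa=float(tpsa[i]), phi=float(phi[i]),
            brlogd=float(brlogd[i]),
            log_kw_iam=clog + float(delta_iam[i]),
            clog_kw_iam=clog,
            delta_log_kw_iam=float(delta_iam[i]),
        )
        censored = bool(log_s[i] < config.loq_log_s)
        if censored:
            ds.solubility[cid] = SolubilityMeasurement(
                compound_id=cid, censored=True, gsk_class=GskClass.LOW)
        else:
            s_molar = 10.0 ** float(log_s[i])
            ds.solubility[cid] = SolubilityMeasurement(
                compound_id=cid,
                conc_mg_ml=s_molar * float(mw[i]),
                s_molar=s_molar,
                log_s=float(log_s[i]),
                s_micromolar=s_molar * 1e6,
                gsk_class=gsk_class(s_molar * 1e6),
            )
    return ds


def generate_retention_tables(
    dataset: Dataset,
    *,
    t0_rp18: float = 1.0,
    t0_iam: float = 2.0,
    iam_slope: float = -0.04,   # d(log k')/d(%ACN), typical IAM gradient
    jitter_tau: float = 0.0,    # replicate SD on the log k' scale
    replicates: int = 2,
    seed: int = 0,
) -> list[RetentionSeries]:
    """Retention tables whose descriptor transforms invert to the dataset.

    RP18: t_R = t0*(1 + 10^((BRlogD - 2.79)/3.31)). IAM: log k' linear in
    %ACN over 10-50% with intercept log kw_IAM. At ``jitter_tau`` 0 the
    chromatography module recovers BRlogD and log kw_IAM exactly.
    """
    rng = np.random.default_rng(seed)
    series: list[RetentionSeries] = []
    for cid, prof in dataset.descriptors.items():
        if prof.brlogd is not None:
            s = RetentionSeries(compound_id=cid, system=ColumnSystem.RP18_ISOCRATIC_60ACN)
            log_k60 = (prof.brlogd - BRLOGD_INTERCEPT) / BRLOGD_SLOPE
            for rep in range(1, replicates + 1):
                lk = log_k60 + (rng.normal(0.0, jitter_tau) if jitter_tau > 0 else 0.0)
                s.points.append(RetentionPoint(
                    percent_organic=60.0, t_r=t0_rp18 * (1.0 + 10.0 ** lk),
                    t0=t0_rp18, replicate=rep))
            series.append(s)
        if prof.log_kw_iam is not None:
            s = RetentionSeries(compound_id=cid, system=ColumnSystem.IAM_GRADIENT_POINTS)
            for pct in (10.0, 20.0, 30.0, 40.0, 50.0):
                log_k = prof.log_kw_iam + iam_slope * pct
                for rep in range(1, replicates + 1):
                    lk = log_k + (rng.normal(0.0, jitter_tau) if jitter_tau > 0 else 0.0)
                    s.points.append(RetentionPoint(
                        percent_organic=pct, t_r=t0_iam * (1.0 + 10.0 ** lk),
                        t0=t0_iam, replicate=rep))
            series.append(s)
    return series


# base geometry of the toy polar fragment: an O-C-N triangle (Å)
_TOY_ELEMENTS = ("O", "C", "N")
_TOY_COORDS = np.array([
    [1.23, 0.00, 0.00],
    [0.00, 0.00, 0.00],
    [-0.67, 1.18, 0.00],
])


def generate_toy_ensemble(
    n_conformers: int,
    seed: int = 0,
    jitter: float = 0.3,
    compound_id: str = "TOY",
) -> ConformerEnsemble:
    """A rigid O-C-N fragment with seeded per-conformer coordinate jitter.

    Per-conformer 3D-PSA is analytically bounded: at least the largest
    single polar-atom sphere, at most the sum of the O and N sphere areas.
    """
    if n_conformers < 1:
        raise DomainError("n_conformers must be >= 1")
    rng = np.random.default_rng(seed)
    ens = ConformerEnsemble(compound_id=compound_id, source="other")
    for _ in range(n_conformers):
        coords = _TOY_COORDS + (rng.normal(0.0, jitter, size=_TOY_COORDS.shape)
                                if jitter > 0 else 0.0)
        ens.conformers.append(Conformer(elements=_TOY_ELEMENTS, coords=coords))
    return ens
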