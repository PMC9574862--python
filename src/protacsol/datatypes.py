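"""Core domain types.

The pipeline moves PROTACs and their building blocks through four layers of
data: structures (:class:`CompoundRecord`), raw chromatographic retention
(:class:`RetentionSeries`), derived descriptors (:class:`DescriptorProfile`)
and quantified thermodynamic solubility (:class:`SolubilityMeasurement`).
A :class:`Dataset` bundles them and enforces referential integrity through
:func:`protacsol.io.validate_dataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Role(str, Enum):
    PROTAC = "protac"
    BUILDING_BLOCK = "building_block"


class GskClass(str, Enum):
    """GSK thermodynamic-solubility classes (low < 30 uM, intermediate
    30-200 uM, high > 200 uM)."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return {"low": 0, "intermediate": 1, "high": 2}[self.value]

    def __lt__(self, other: "GskClass") -> bool:  # type: ignore[override]
        return self.rank < other.rank

    def __le__(self, other: "GskClass") -> bool:  # type: ignore[override]
        return self.rank <= other.rank


class ColumnSystem(str, Enum):
    """Chromatographic systems feeding the descriptor layer."""

    RP18_ISOCRATIC_60ACN = "RP18_isocratic_60ACN"
    IAM_GRADIENT_POINTS = "IAM_gradient_points"
    SFC_EPSA = "SFC_EPSA"


class Moiety(str, Enum):
    """The three building blocks of a heterobifunctional degrader."""

    WARHEAD = "warhead"
    LINKER = "linker"
    E3_LIGAND = "e3_ligand"


@dataclass
class CompoundRecord:
    """One chemical entity - a PROTAC or one of its building blocks."""

    id: str
    smiles: Optional[str] = None
    name: str = ""
    mw: Optional[float] = None
    role: Role = Role.PROTAC
    charge_note: str = ""
    pair_tags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RetentionPoint:
    percent_organic: float  # % v/v organic modifier
    t_r: float              # retention time, minutes
    t0: float               # dead time, minutes
    replicate: int = 1


@dataclass
class RetentionSeries:
    """Replicate retention measurements for one compound on one system."""

    compound_id: str
    system: ColumnSystem
    points: list[RetentionPoint] = field(default_factory=list)


@dataclass
class ChromatographicDescriptors:
    """Derived chromatographic descriptors for one compound.

    ``clog_kw_iam`` is the IAM retention expected for a neutral analyte of
    zero polar surface area at the same lipophilicity
    (clog kw_IAM = 0.92*BRlogD - 1.03); ``delta_log_kw_iam`` is the excess
    over that baseline and acts as an experimental polarity descriptor.
    """

    brlogd: Optional[float] = None
    log_kw_iam: Optional[float] = None
    clog_kw_iam: Optional[float] = None
    delta_log_kw_iam: Optional[float] = None
    epsa: Optional[float] = None
    extrapolation_r2: Optional[float] = None


@dataclass
class DescriptorProfile:
    """Per-compound descriptor vector (2D, chromatographic and external)."""

    compound_id: str
    nc: Optional[int] = None
    tpsa: Optional[float] = None
    phi: Optional[float] = None
    brlogd: Optional[float] = None
    log_kw_iam: Optional[float] = None
    clog_kw_iam: Optional[float] = None
    delta_log_kw_iam: Optional[float] = None
    epsa: Optional[float] = None
    extrapolation_r2: Optional[float] = None
    external: dict[str, float] = field(default_factory=dict)


@dataclass
class SolubilityMeasurement:
    """Quantified thermodynamic solubility for one compound.

    A censored measurement (below the quantification limit, "ND") carries no
    numeric concentration; it is assigned to the low class and excluded from
    every regression.
    """

    compound_id: str
    conc_mg_ml: Optional[float] = None
    s_molar: Optional[float] = None
    log_s: Optional[float] = None
    s_micromolar: Optional[float] = None
    sd: Optional[float] = None
    rsd: Optional[float] = None
    censored: bool = False
    gsk_class: Optional[GskClass] = None

    def is_quantitative(self) -> bool:
        return not self.censored


@dataclass
class Dataset:
    """A full study dataset with referential integrity across layers."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    retention: list[RetentionSeries] = field(default_factory=list)
    solubility: dict[str, SolubilityMeasurement] = field(default_factory=dict)
    descriptors: dict[str, DescriptorProfile] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def get_compound(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        from .errors import ReferenceError_

        raise ReferenceError_(f"unknown compound id: {compound_id!r}")


def _is_finite(x: Optional[float]) -> bool:
    return x is not None and math.isfinite(x)
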